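"""Construct design: stitching, cassette assembly, restriction-site work,
repertoire loss, and blocking oligos."""

import itertools
import random

import pytest

from tcrscreen.design import (
    ENZYMES,
    RestrictionEnzyme,
    assemble_cassette,
    default_elements,
    design_blocking_oligos,
    design_silent_site,
    estimate_repertoire_loss,
    scan_restriction_sites,
    stitch_full_length,
)
from tcrscreen.errors import DesignError
from tcrscreen.germline import translate
from tcrscreen.sim import SimParams, simulate_repertoire
from tcrscreen.util import kmers, revcomp


class TestStitch:
    def test_roundtrip_matches_simulator(self, db):
        clones = simulate_repertoire(db, SimParams(n_clones=20, seed=41))
        for c in clones:
            assert stitch_full_length(c.beta.v_gene, c.beta.j_gene,
                                      c.beta.junction_nt, "beta", db) == c.beta.full_nt
            assert stitch_full_length(c.alpha.v_gene, c.alpha.j_gene,
                                      c.alpha.junction_nt, "alpha", db) == c.alpha.full_nt

    def test_translation_contains_junction_aa(self, db):
        clones = simulate_repertoire(db, SimParams(n_clones=10, seed=43))
        for c in clones:
            full = stitch_full_length(c.beta.v_gene, c.beta.j_gene,
                                      c.beta.junction_nt, "beta", db)
            assert translate(full).count(c.beta.junction_aa) == 1

    def test_unknown_gene_is_named_in_error(self, db):
        with pytest.raises(Exception, match="TRBV99"):
            stitch_full_length("TRBV99", "TRBJ1-1", "TGTTTT", "beta", db)


class TestScan:
    def test_single_agei_site(self):
        assert scan_restriction_sites("AAACCGGTAA", [ENZYMES["AgeI"]]) == [("AgeI", 2)]

    def test_no_sites(self):
        assert scan_restriction_sites("AAAAAA") == []

    def test_palindrome_reported_once(self):
        hits = scan_restriction_sites("TTACGCGTTT", [ENZYMES["MluI"]])
        assert hits == [("MluI", 2)]

    def test_nonpalindromic_enzyme_found_on_either_strand(self):
        bsai = RestrictionEnzyme("BsaI", "GGTCTC")
        seq = "AA" + revcomp("GGTCTC") + "AA"  # site only on the minus strand
        assert scan_restriction_sites(seq, [bsai]) == [("BsaI", 2)]

    def test_multiple_sites_sorted(self):
        seq = "ACCGGT" + "AAA" + "TTCGAA" + "ACGCGT"
        names = [n for n, _ in scan_restriction_sites(seq)]
        assert names == ["AgeI", "BstBI", "MluI"]


class TestSilentSite:
    def test_single_edit_silent_mlui(self):
        designs = design_silent_site("ACCCGT", 0, ENZYMES["MluI"])
        assert designs and designs[0].mutated_nt == "ACGCGT"
        assert designs[0].n_edits == 1 and designs[0].silent

    def test_met_codons_admit_no_silent_edit(self):
        # both ATG codons would need changing; Met has no synonym
        assert design_silent_site("ATGATG", 0, ENZYMES["MluI"]) == []

    def test_nonsilent_mode_reports_everything(self):
        designs = design_silent_site("ATGATG", 0, ENZYMES["MluI"], "allow_nonsilent")
        assert len(designs) == 1 and not designs[0].silent

    def test_brute_force_oracle(self):
        """Exhaustive enumeration over synonymous codon substitutions agrees
        with the direct per-placement design on random regions <= 30 nt."""
        from Bio.Data.CodonTable import standard_dna_table

        by_aa: dict[str, list[str]] = {}
        for codon, aa in standard_dna_table.forward_table.items():
            if "U" not in codon:
                by_aa.setdefault(aa, []).append(codon)

        rng = random.Random(53)
        for enz in (ENZYMES["MluI"], ENZYMES["SpeI"]):
            for _ in range(25):
                n_codons = rng.randint(2, 10)
                codons = []
                while len(codons) < n_codons:
                    c = "".join(rng.choice("ACGT") for _ in range(3))
                    if translate(c) != "*":
                        codons.append(c)
                region = "".join(codons)
                # oracle: all synonymous codon replacements, site presence per offset
                silent_offsets = set()
                options = [sorted(by_aa[translate(c)]) for c in codons]
                for combo in itertools.product(*options):
                    mutated = "".join(combo)
                    for off in range(len(region) - 5):
                        if mutated[off : off + 6] == enz.recognition:
                            # minimal design only rewrites bases under the site
                            hybrid = region[:off] + enz.recognition + region[off + 6 :]
                            if all(translate(hybrid[i:i+3]) == translate(region[i:i+3])
                                   for i in range(0, len(region), 3)):
                                silent_offsets.add(off)
                designs = design_silent_site(region, 0, enz)
                assert {d.placement_offset for d in designs} == silent_offsets
                for d in designs:
                    assert translate(d.mutated_nt) == translate(d.original_nt)
                    assert d.mutated_nt[d.placement_offset : d.placement_offset + 6] == enz.recognition


class TestCassette:
    def test_fixture_clone_cassette_satisfies_invariants(self, db):
        clones = simulate_repertoire(db, SimParams(n_clones=5, seed=47))
        c = clones[0]
        cass = assemble_cassette(c.beta.full_nt, c.alpha.full_nt)
        for enz in ENZYMES.values():
            assert cass.full_nt.count(enz.recognition) == 1
        aa = cass.orf_aa
        assert aa.startswith("M") and aa.endswith("*") and "*" not in aa[:-1]
        assert translate(default_elements().p2a) in aa
        assert c.beta.junction_aa in aa and c.alpha.junction_aa in aa

    def test_internal_agei_site_rejected(self, db):
        clones = simulate_repertoire(db, SimParams(n_clones=1, seed=47))
        c = clones[0]
        beta = c.beta.full_nt[:100] + "ACCGGT" + c.beta.full_nt[106:]
        with pytest.raises(DesignError, match="AgeI"):
            assemble_cassette(beta, c.alpha.full_nt)

    def test_empty_alpha_chain_rejected(self, db):
        clones = simulate_repertoire(db, SimParams(n_clones=1, seed=47))
        with pytest.raises(DesignError):
            assemble_cassette(clones[0].beta.full_nt, "")

    def test_invariants_on_100_random_clones(self, db):
        """Every simulated clone passing the duplicate-site screen assembles
        into a cassette with unique sites and a clean ORF."""
        clones = simulate_repertoire(db, SimParams(n_clones=100, seed=59))
        n_ok = 0
        for c in clones:
            try:
                cass = assemble_cassette(c.beta.full_nt, c.alpha.full_nt)
            except DesignError:
                continue  # natural site in a junction: correctly screened out
            n_ok += 1
            assert all(cass.full_nt.count(e.recognition) == 1 for e in ENZYMES.values())
            assert "*" not in cass.orf_aa[:-1]
        assert n_ok >= 80


class TestRepertoireLoss:
    def test_counting(self):
        clean = [("AAAAAA",), ("CCCCCC",)]
        assert estimate_repertoire_loss(clean) == 0.0
        with_site = clean + [("AAACCGGTAA",)]
        assert estimate_repertoire_loss(with_site) == pytest.approx(1 / 3)

    def test_deterministic(self, db):
        clones = simulate_repertoire(db, SimParams(n_clones=50, seed=61))
        seqs = [(c.beta.full_nt, c.alpha.full_nt) for c in clones]
        assert estimate_repertoire_loss(seqs) == estimate_repertoire_loss(seqs)


class TestBlockingOligos:
    ALPHA_T = "ACGGATCCTGAGGATTCAAGGCATCATCG"
    BETA_T = "TTGACCAGGAGCATCCGGATTACAGGACT"

    def test_tails_plus_revcomp_structure(self):
        oa, ob = design_blocking_oligos(self.ALPHA_T, self.BETA_T, seed=3)
        assert oa.endswith(revcomp(self.ALPHA_T))
        assert ob.endswith(revcomp(self.BETA_T))
        assert len(oa) == 20 + len(self.ALPHA_T)

    def test_tails_share_no_8mer_with_context(self):
        linker = "ACTAGTCCCAGAGTTTTCCTCGGCACGCGT"
        oa, ob = design_blocking_oligos(self.ALPHA_T, self.BETA_T,
                                        linker_nt=linker, seed=3)
        tail_a, tail_b = oa[:20], ob[:20]
        context = set()
        for s in (self.ALPHA_T, self.BETA_T, linker):
            context |= kmers(s, 8) | kmers(revcomp(s), 8)
        for tail, other in ((tail_a, tail_b), (tail_b, tail_a)):
            assert not (kmers(tail, 8) | kmers(revcomp(tail), 8)) & context
        assert not kmers(tail_a, 8) & (kmers(tail_b, 8) | kmers(revcomp(tail_b), 8))

    def test_deterministic_per_seed(self):
        a1 = design_blocking_oligos(self.ALPHA_T, self.BETA_T, seed=5)
        a2 = design_blocking_oligos(self.ALPHA_T, self.BETA_T, seed=5)
        a3 = design_blocking_oligos(self.ALPHA_T, self.BETA_T, seed=6)
        assert a1 == a2 and a1 != a3

    def test_impossible_constraints_error(self):
        with pytest.raises(DesignError):
            # k=2: every dinucleotide is forbidden somewhere in the context
            design_blocking_oligos(self.ALPHA_T, self.BETA_T,
                                   forbidden_kmers_k=2, seed=1, max_tries=50)

    def test_short_inputs_rejected(self):
        with pytest.raises(DesignError):
            design_blocking_oligos("ACGTACGT", self.BETA_T)
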