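"""Expression-construct design: full-length stitching, bicistronic cassette
assembly, restriction-site scanning and silent-site design, repertoire-loss
estimation, and suppression-PCR blocking-oligo design.

The expression cassette follows the cloning scheme used for library
construction: the linked TCRα:β amplicon enters the lentiviral backbone via
AgeI/BstBI, after which the linker is swapped via SpeI/MluI for an insert
carrying the remainder of the TCRβ constant region, a P2A ribosomal-skip
element, and a modified TCRα leader bearing an MluI site — yielding a single
β→P2A→α open reading frame.  Each of the four cloning sites must occur
exactly once in the final cassette; chains that naturally contain one of the
recognition sequences are rejected (and counted by the repertoire-loss
estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import DesignError
from .germline import GermlineDB, translate
from .util import kmers, revcomp, validate_dna


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "recognition", validate_dna(self.recognition, what=self.name)
        )
        if len(self.recognition) < 4:
            raise DesignError(f"{self.name}: recognition sequence too short")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition


#: The four cloning enzymes (recognition sequences per the standard REBASE
#: entries; all four happen to be palindromic 6-cutters).
ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in (
        RestrictionEnzyme("AgeI", "ACCGGT"),
        RestrictionEnzyme("BstBI", "TTCGAA"),
        RestrictionEnzyme("MluI", "ACGCGT"),
        RestrictionEnzyme("SpeI", "ACTAGT"),
    )
}


def scan_restriction_sites(
    seq: str, enzymes: Iterable[RestrictionEnzyme] | None = None
) -> list[tuple[str, int]]:
    """All exact recognition-site occurrences, 0-based, sorted by offset.

    Both strands are scanned; for palindromic sites the two strands coincide
    and each physical occurrence is reported once.
    """
    seq = validate_dna(seq, what="scan target")
    enzymes = list(enzymes) if enzymes is not None else list(ENZYMES.values())
    hits: set[tuple[int, str]] = set()
    for enz in enzymes:
        patterns = {enz.recognition}
        if not enz.is_palindromic:
            patterns.add(revcomp(enz.recognition))
        for pat in patterns:
            start = seq.find(pat)
            while start != -1:
                hits.add((start, enz.name))
                start = seq.find(pat, start + 1)
    return [(name, off) for off, name in sorted(hits)]


def stitch_full_length(
    v_call: str,
    j_call: str,
    junction_nt: str,
    chain: str,
    db: GermlineDB,
    include_c: bool = True,
) -> str:
    """Recreate a full-length chain from a clonotype's V/J calls and junction.

    The junction owns both anchor codons: the germline V contributes up to
    (excluding) its anchor, the germline J from just after its anchor, then
    the constant region.
    """
    v = db.get(chain, "V", v_call)
    j = db.get(chain, "J", j_call)
    junction_nt = validate_dna(junction_nt, what="junction")
    assert v.anchor_offset is not None and j.anchor_offset is not None
    seq = v.nt_sequence[: v.anchor_offset] + junction_nt + j.nt_sequence[j.anchor_offset + 3 :]
    if include_c:
        c_segs = db.of_type(chain, "C")
        if not c_segs:
            raise DesignError(f"no constant region for chain {chain}")
        seq += c_segs[0].nt_sequence
    return seq


@dataclass
class CassetteElements:
    """Sequences of the fixed cassette parts (leaders, Cβ remainder, P2A)."""

    leader_length: int
    beta_leader_mod: str
    alpha_leader_mod: str
    cbeta_rest: str
    p2a: str
    default_linker: str

    def __post_init__(self) -> None:
        for name in ("beta_leader_mod", "alpha_leader_mod", "cbeta_rest", "p2a"):
            seq = validate_dna(getattr(self, name), what=name)
            object.__setattr__(self, name, seq)
            if len(seq) % 3:
                raise DesignError(f"{name} length must be a multiple of 3")
            if "*" in translate(seq):
                raise DesignError(f"{name} contains an in-frame stop codon")
        if "ACGCGT" not in self.alpha_leader_mod:
            raise DesignError("alpha_leader_mod must carry the MluI site")


def default_elements() -> CassetteElements:
    """Bundled synthetic cassette elements (see data/cassette_elements_synthetic.yaml)."""
    path = resources.files("tcrscreen") / "data" / "cassette_elements_synthetic.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return CassetteElements(**raw)


@dataclass
class CassetteDesign:
    """An assembled β→P2A→α expression cassette."""

    elements: list[tuple[str, str]]
    full_nt: str
    orf_interval: tuple[int, int]

    @property
    def orf_nt(self) -> str:
        return self.full_nt[self.orf_interval[0] : self.orf_interval[1]]

    @property
    def orf_aa(self) -> str:
        return translate(self.orf_nt)


def assemble_cassette(
    beta_nt: str, alpha_nt: str, elements: CassetteElements | None = None
) -> CassetteDesign:
    """Assemble the bicistronic cassette and enforce its invariants.

    ``beta_nt``/``alpha_nt`` are full-length stitched chains (germline
    leader + V + junction + J + constant part).  The germline leaders are
    replaced by the modified leaders carrying the cloning sites.  Raises
    :class:`DesignError` naming the offending element/site when any
    invariant fails (duplicate recognition site, broken ORF).
    """
    elements = elements or default_elements()
    L = elements.leader_length
    for name, seq in (("beta chain", beta_nt), ("alpha chain", alpha_nt)):
        if len(seq) <= L:
            raise DesignError(f"{name} shorter than the leader ({len(seq)} nt)")
    parts = [
        ("AgeI", ENZYMES["AgeI"].recognition),
        ("beta_leader_mod", elements.beta_leader_mod),
        ("beta_vdj_c5p", validate_dna(beta_nt, what="beta chain")[L:]),
        ("SpeI", ENZYMES["SpeI"].recognition),
        ("cbeta_rest", elements.cbeta_rest),
        ("P2A", elements.p2a),
        ("alpha_leader_mod", elements.alpha_leader_mod),
        ("alpha_vj_c", validate_dna(alpha_nt, what="alpha chain")[L:]),
        ("stop", "TAA"),
        ("BstBI", ENZYMES["BstBI"].recognition),
    ]
    full = "".join(seq for _, seq in parts)
    hits = scan_restriction_sites(full)
    by_enzyme: dict[str, list[int]] = {}
    for name, off in hits:
        by_enzyme.setdefault(name, []).append(off)
    for enz in ENZYMES:
        offs = by_enzyme.get(enz, [])
        if len(offs) != 1:
            raise DesignError(
                f"{enz} site must occur exactly once in the cassette; "
                f"found at offsets {offs}"
            )
    orf = (len(ENZYMES["AgeI"].recognition), len(full) - len(ENZYMES["BstBI"].recognition))
    if (orf[1] - orf[0]) % 3:
        raise DesignError("cassette ORF length is not a multiple of 3")
    aa = translate(full[orf[0] : orf[1]])
    if not aa.startswith("M"):
        raise DesignError("cassette ORF does not start with Met")
    if "*" in aa[:-1] or not aa.endswith("*"):
        raise DesignError("cassette ORF is not stop-free up to the terminal stop")
    if translate(elements.p2a) not in aa:
        raise DesignError("P2A is not encoded in frame")
    return CassetteDesign(elements=parts, full_nt=full, orf_interval=orf)


@dataclass(frozen=True)
class SilentSiteDesign:
    original_nt: str
    mutated_nt: str
    site: RestrictionEnzyme
    n_edits: int
    silent: bool
    placement_offset: int


def design_silent_site(
    region_nt: str,
    frame: int,
    enzyme: RestrictionEnzyme,
    mode: str = "silent_only",
) -> list[SilentSiteDesign]:
    """Enumerate placements of a recognition site within a coding region.

    For every placement offset, the bases under the site are overwritten
    with the recognition sequence; the design is *silent* when every altered
    codon remains synonymous (codons are read at phase ``frame``; an edit
    falling in a codon that is incomplete within the region can never be
    verified synonymous and disqualifies the placement).  ``silent_only``
    returns silent designs; ``allow_nonsilent`` returns all.  Results are
    ranked by (number of edits, offset).  An empty list is a valid outcome.
    """
    region = validate_dna(region_nt, what="region")
    site = enzyme.recognition
    if len(region) < len(site):
        raise DesignError("region shorter than the recognition sequence")
    if mode not in ("silent_only", "allow_nonsilent"):
        raise DesignError(f"unknown mode {mode!r}")
    designs = []
    for off in range(len(region) - len(site) + 1):
        mutated = region[:off] + site + region[off + len(site) :]
        edited = [i for i in range(off, off + len(site)) if region[i] != mutated[i]]
        silent = True
        for ci in sorted({(i - frame) // 3 for i in edited if i >= frame} |
                         {-1 for i in edited if i < frame}):
            if ci < 0:
                silent = False
                break
            start = frame + 3 * ci
            if start + 3 > len(region):
                silent = False
                break
            if translate(region[start : start + 3]) != translate(mutated[start : start + 3]):
                silent = False
                break
        if mode == "silent_only" and not silent:
            continue
        designs.append(
            SilentSiteDesign(
                original_nt=region,
                mutated_nt=mutated,
                site=enzyme,
                n_edits=len(edited),
                silent=silent,
                placement_offset=off,
            )
        )
    designs.sort(key=lambda d: (d.n_edits, d.placement_offset))
    return designs


def estimate_repertoire_loss(
    clone_seqs: Sequence[Sequence[str]],
    enzymes: Iterable[RestrictionEnzyme] | None = None,
) -> float:
    """Fraction of clones destroyed by naturally occurring cloning sites.

    ``clone_seqs`` gives, per clone, the insert-region sequences that end up
    inside the cassette (i.e. the stitched chains *without* the designed
    boundary sites).  A clone is lost if any of its sequences contains at
    least one recognition site of any cloning enzyme.
    """
    if not clone_seqs:
        return 0.0
    enzymes = list(enzymes) if enzymes is not None else list(ENZYMES.values())
    lost = sum(
        1
        for seqs in clone_seqs
        if any(scan_restriction_sites(s, enzymes) for s in seqs)
    )
    return lost / len(clone_seqs)


def design_blocking_oligos(
    alpha_3prime_nt: str,
    beta_3prime_nt: str,
    tail_length: int = 20,
    forbidden_kmers_k: int = 8,
    *,
    linker_nt: str = "",
    seed: int = 0,
    max_tries: int = 5000,
) -> tuple[str, str]:
    """Design the two suppression-PCR blocking oligonucleotides.

    Each oligo is a nonsense 5' tail joined to the reverse complement of the
    corresponding chain's 3' terminal region; the tails share no k-mer
    (default k=8) with either terminal region, the linker, or each other, so
    that unlinked single-chain amplicons cannot re-associate by overlap
    extension while natively linked amplicons are unaffected.  Deterministic
    for a fixed seed.
    """
    alpha_t = validate_dna(alpha_3prime_nt, what="alpha terminal region")
    beta_t = validate_dna(beta_3prime_nt, what="beta terminal region")
    if min(len(alpha_t), len(beta_t)) < 15:
        raise DesignError("terminal regions must be >= 15 nt")
    if tail_length < 10:
        raise DesignError("tail_length must be >= 10")
    k = forbidden_kmers_k
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE5]))
    context = [alpha_t, beta_t, linker_nt] if linker_nt else [alpha_t, beta_t]
    forbidden: set[str] = set()
    for s in context:
        forbidden |= kmers(s, k) | kmers(revcomp(s), k)

    def make_tail() -> str:
        for _ in range(max_tries):
            tail = "".join("ACGT"[i] for i in rng.integers(4, size=tail_length))
            if not (kmers(tail, k) | kmers(revcomp(tail), k)) & forbidden:
                return tail
        raise DesignError("no valid blocking-oligo tail found within retry budget")

    tail_a = make_tail()
    forbidden |= kmers(tail_a, k) | kmers(revcomp(tail_a), k)
    tail_b = make_tail()
    return tail_a + revcomp(alpha_t), tail_b + revcomp(beta_t)
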