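"""One-off generator for the synthetic IMGT-like germline fixture and the
synthetic cassette element sequences. Run from the repo root:

    python scripts/make_germline_fixture.py

Writes src/tcrscreen/data/germline_synthetic.fasta, *_anchors.tsv and
cassette_elements_synthetic.yaml. Deterministic (fixed seed); the shipped
data files were produced by this script and are not expected to change.
"""

import random
from pathlib import Path

SITES = ["ACCGGT", "TTCGAA", "ACGCGT", "ACTAGT"]  # AgeI BstBI MluI SpeI
STOPS = {"TAA", "TAG", "TGA"}
CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in STOPS]

rng = random.Random(20230517)


def clean(seq):
    """True if seq contains no restriction site on either strand."""
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return not any(s in seq or s in rc for s in SITES)


def random_orf(n_codons, prefix="", suffix=""):
    """Random stop-free codon string, site-free including junctions with prefix/suffix."""
    for _ in range(10000):
        body = "".join(rng.choice(CODONS) for _ in range(n_codons))
        full = prefix + body + suffix
        if clean(full):
            return body
    raise RuntimeError("could not generate clean ORF")


V_LEN, LEADER_LEN, V_ANCHOR = 228, 48, 210
J_LEN, J_ANCHOR = 48, 21
C_LEN = 120

# post-anchor V tails (anchor codon + 15 nt germline remainder, CASS / CAV style)
BETA_V_TAIL = {"anchor": "TGT", "tail": "GCCAGCAGCCTGGGG"}   # C A S S L G
ALPHA_V_TAIL = {"anchor": "TGT", "tail": "GCTGTGAGTGACACC"}  # C A V S D T

# J: 21 nt trimmable head + anchor codon + 24 nt F/W-G-X-G region
BETA_J_POST = "GGGCCAGGGACCCGGCTGACCGTC"   # G P G T R L T V
ALPHA_J_POST = "GGAGGAAGCCAAGGAAATCTCATC"  # G G S Q G N L I


def make_v(name, chain):
    tail = BETA_V_TAIL if chain == "beta" else ALPHA_V_TAIL
    post = tail["anchor"] + tail["tail"]
    # leader starts ATG; body random; total V_LEN with anchor at V_ANCHOR
    n_body = (V_ANCHOR - LEADER_LEN) // 3
    for _ in range(1000):
        leader = "ATG" + "".join(rng.choice(CODONS) for _ in range((LEADER_LEN - 3) // 3))
        body = "".join(rng.choice(CODONS) for _ in range(n_body))
        seq = leader + body + post
        assert len(seq) == V_LEN, len(seq)
        if clean(seq):
            return seq
    raise RuntimeError("V generation failed")


def make_j(chain, anchor_codon):
    post = BETA_J_POST if chain == "beta" else ALPHA_J_POST
    for _ in range(1000):
        head = "".join(rng.choice(CODONS) for _ in range(J_ANCHOR // 3))
        seq = head + anchor_codon + post
        assert len(seq) == J_LEN
        if clean(seq):
            return seq
    raise RuntimeError("J generation failed")


def make_c():
    return random_orf(C_LEN // 3)


segments = []  # (name, chain, type, seq, anchor, frame)
for name in ["TRBV15-1", "TRBV19", "TRBV28", "TRBV6-5"]:
    segments.append((name, "beta", "V", make_v(name, "beta"), V_ANCHOR, 0))
for name in ["TRAV12-1", "TRAV19", "TRAV29", "TRAV8-2"]:
    segments.append((name, "alpha", "V", make_v(name, "alpha"), V_ANCHOR, 0))
segments.append(("TRBJ1-1", "beta", "J", make_j("beta", "TTC"), J_ANCHOR, 0))
segments.append(("TRBJ2-3", "beta", "J", make_j("beta", "TTT"), J_ANCHOR, 0))
segments.append(("TRBJ2-7", "beta", "J", make_j("beta", "TTC"), J_ANCHOR, 0))
segments.append(("TRAJ33", "alpha", "J", make_j("alpha", "TGG"), J_ANCHOR, 0))
segments.append(("TRAJ42", "alpha", "J", make_j("alpha", "TTC"), J_ANCHOR, 0))
segments.append(("TRAJ49", "alpha", "J", make_j("alpha", "TTT"), J_ANCHOR, 0))
segments.append(("TRBD1", "beta", "D", "GGGACAGGGGGC", None, 0))
segments.append(("TRBC1", "beta", "C", make_c(), None, 0))
segments.append(("TRAC", "alpha", "C", make_c(), None, 0))

assert len(segments) == 17

outdir = Path("src/tcrscreen/data")
outdir.mkdir(parents=True, exist_ok=True)
with open(outdir / "germline_synthetic.fasta", "w") as fh:
    for name, chain, st, seq, anchor, frame in segments:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
with open(outdir / "germline_synthetic_anchors.tsv", "w") as fh:
    fh.write("gene_name\tchain\tsegment_type\tanchor_offset\tframe_offset\n")
    for name, chain, st, seq, anchor, frame in segments:
        fh.write(f"{name}\t{chain}\t{st}\t{'' if anchor is None else anchor}\t{frame}\n")

# ---- cassette elements (synthetic leaders / Cb remainder; canonical P2A) ----
P2A = "GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT"
assert len(P2A) % 3 == 0 and clean(P2A)

beta_leader_mod = "ATG" + random_orf((LEADER_LEN - 3) // 3, prefix="ATG")
# modified TRAV8-2-style leader with an MluI site (ACG CGT = Thr Arg) at codons 11-12
def count_sites(seq):
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return {s: seq.count(s) + (0 if s == rc_site(s) else rc.count(s)) for s in SITES}

def rc_site(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

for _ in range(10000):
    alpha_left = "".join(rng.choice(CODONS) for _ in range(10))
    alpha_right = "".join(rng.choice(CODONS) for _ in range((LEADER_LEN - 3) // 3 - 12))
    alpha_leader_mod = "ATG" + alpha_left + "ACGCGT" + alpha_right
    counts = {s: alpha_leader_mod.count(s) for s in SITES}
    if counts == {"ACCGGT": 0, "TTCGAA": 0, "ACGCGT": 1, "ACTAGT": 0}:
        break
else:
    raise RuntimeError("alpha leader generation failed")
assert len(alpha_leader_mod) == LEADER_LEN

cbeta_rest = random_orf(30)
for _ in range(10000):
    linker = "ACTAGT" + "".join(rng.choice("ACGT") for _ in range(18)) + "ACGCGT"
    if {s: linker.count(s) for s in SITES} == {
        "ACCGGT": 0, "TTCGAA": 0, "ACGCGT": 1, "ACTAGT": 1,
    }:
        break
else:
    raise RuntimeError("linker generation failed")
assert len(linker) == 30

with open(outdir / "cassette_elements_synthetic.yaml", "w") as fh:
    fh.write("# Synthetic stand-ins for the expression-cassette elements\n")
    fh.write("# (leaders, constant-region remainder); P2A is the canonical\n")
    fh.write("# teschovirus-derived ribosomal-skip sequence.\n")
    fh.write(f"leader_length: {LEADER_LEN}\n")
    fh.write(f"beta_leader_mod: {beta_leader_mod}\n")
    fh.write(f"alpha_leader_mod: {alpha_leader_mod}\n")
    fh.write(f"cbeta_rest: {cbeta_rest}\n")
    fh.write(f"p2a: {P2A}\n")
    fh.write(f"default_linker: {linker}\n")

print("wrote fixture:", len(segments), "segments")
print("alpha_leader_mod:", alpha_leader_mod)
print("linker:", linker)
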