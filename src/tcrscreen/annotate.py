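"""V/J gene assignment, CDR3 junction extraction, and productivity calls.

Segment assignment uses semi-global alignment (end gaps free on both
sequences, affine penalties) of the read against every candidate germline
segment; the best score wins, with ties broken by lexicographically smallest
gene name.  The junction is then read off the alignment: it spans from the
read position mapped to the first base of the V-gene cysteine anchor codon
through the read position mapped to the last base of the J-gene Phe/Trp
anchor codon, inclusive of both anchor codons (the IMGT junction
convention).  A read whose alignment does not cover an anchor codon is
excluded with a machine-readable reason.

Reads are tried in the given orientation and as reverse complements; the
orientation with the better combined V+J score wins.  D segments are not
called — downstream clonotype keys use CDR3 plus V/J identity only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .errors import AnnotationError
from .germline import GermlineDB, GermlineSegment, translate
from .util import revcomp, validate_dna


@dataclass
class AlignParams:
    """Alignment scoring and acceptance thresholds."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1
    min_v_score: float = 50.0
    min_j_score: float = 15.0
    seed_kmer: int = 12

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise AnnotationError("need match > 0 > mismatch")
        if self.min_v_score < 0 or self.min_j_score < 0:
            raise AnnotationError("score thresholds must be >= 0")


def make_aligner(params: AlignParams | None = None) -> Align.PairwiseAligner:
    """Semi-global aligner: global mode with free end gaps on both sequences."""
    params = params or AlignParams()
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    a.open_end_gap_score = 0
    a.extend_end_gap_score = 0
    return a


@dataclass(frozen=True)
class SegmentHit:
    gene_name: str
    score: float
    read_interval: tuple[int, int]
    germline_interval: tuple[int, int]
    #: aligned blocks as ((read_start, read_end), (germ_start, germ_end)) pairs
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def map_to_read(self, germ_start: int, germ_end: int) -> tuple[int, int] | None:
        """Map a germline interval to read coordinates.

        Returns None unless the interval lies gap-free inside one aligned
        block (an anchor codon interrupted by an indel is unusable).
        """
        for (rs, re_), (gs, ge) in self.blocks:
            if gs <= germ_start and germ_end <= ge:
                off = germ_start - gs
                return (rs + off, rs + off + (germ_end - germ_start))
        return None


@dataclass
class AnnotatedRead:
    """AIRR-style annotation of one read."""

    read_id: str
    chain: str
    v_call: str
    j_call: str
    v_score: float
    j_score: float
    junction_nt: str
    in_frame: bool
    productive: bool
    rev_comp: bool = False

    @property
    def junction_aa(self) -> str:
        return translate(self.junction_nt) if self.in_frame else ""


@dataclass(frozen=True)
class Exclusion:
    read_id: str
    reason: str


def assign_segment(
    read_seq: str,
    candidates: Sequence[GermlineSegment],
    params: AlignParams | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> SegmentHit:
    """Best semi-global hit of the read against candidate germline segments.

    Ties are broken by lexicographically smallest gene name.  Thresholding
    is the caller's concern (see :func:`annotate_read`).
    """
    if not candidates:
        raise AnnotationError("no candidate segments")
    aligner = aligner or make_aligner(params)
    best_seg: GermlineSegment | None = None
    best_score = float("-inf")
    for seg in sorted(candidates, key=lambda s: s.gene_name):
        score = aligner.score(read_seq, seg.nt_sequence)
        if score > best_score:
            best_seg, best_score = seg, score
    assert best_seg is not None
    aln = aligner.align(read_seq, best_seg.nt_sequence)[0]
    tb, qb = aln.aligned  # target = read, query = germline
    blocks = tuple(
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(tb, qb)
    )
    if not blocks:
        raise AnnotationError("empty alignment")
    return SegmentHit(
        gene_name=best_seg.gene_name,
        score=float(best_score),
        read_interval=(blocks[0][0][0], blocks[-1][0][1]),
        germline_interval=(blocks[0][1][0], blocks[-1][1][1]),
        blocks=blocks,
    )


def extract_junction(
    read_seq: str, v_hit: SegmentHit, j_hit: SegmentHit, db: GermlineDB, chain: str
) -> str | None:
    """CDR3 junction: V anchor codon start through J anchor codon end.

    Returns None when either anchor codon is not covered gap-free by its
    alignment, or the mapped coordinates are inconsistent.
    """
    v_seg = db.get(chain, "V", v_hit.gene_name)
    j_seg = db.get(chain, "J", j_hit.gene_name)
    assert v_seg.anchor_offset is not None and j_seg.anchor_offset is not None
    v_pos = v_hit.map_to_read(v_seg.anchor_offset, v_seg.anchor_offset + 3)
    j_pos = j_hit.map_to_read(j_seg.anchor_offset, j_seg.anchor_offset + 3)
    if v_pos is None or j_pos is None:
        return None
    start, end = v_pos[0], j_pos[1]
    if start >= end:
        return None
    return read_seq[start:end]


def classify_productivity(junction_nt: str) -> tuple[bool, bool]:
    """(in_frame, productive): in frame iff length % 3 == 0; productive iff
    additionally stop-free."""
    in_frame = len(junction_nt) % 3 == 0 and len(junction_nt) > 0
    productive = in_frame and "*" not in translate(junction_nt)
    return in_frame, productive


def annotate_read(
    read_id: str,
    seq: str,
    chain: str,
    db: GermlineDB,
    params: AlignParams | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> AnnotatedRead | Exclusion:
    """Annotate one read; returns an :class:`Exclusion` on any failure."""
    params = params or AlignParams()
    aligner = aligner or make_aligner(params)
    if not seq:
        return Exclusion(read_id, "empty_read")
    seq = validate_dna(seq, allow_n=True, what=f"read {read_id}").replace("N", "A")
    v_cands = db.of_type(chain, "V")
    j_cands = db.of_type(chain, "J")

    def orient_score(s: str) -> float:
        best_v = max(aligner.score(s, v.nt_sequence) for v in v_cands)
        best_j = max(aligner.score(s, j.nt_sequence) for j in j_cands)
        return best_v + best_j

    fwd = orient_score(seq)
    rc_seq = revcomp(seq)
    rev = orient_score(rc_seq)
    use_rc = rev > fwd
    oriented = rc_seq if use_rc else seq

    v_hit = assign_segment(oriented, v_cands, params, aligner)
    if v_hit.score < params.min_v_score:
        return Exclusion(read_id, "low_v_score")
    j_hit = assign_segment(oriented, j_cands, params, aligner)
    if j_hit.score < params.min_j_score:
        return Exclusion(read_id, "low_j_score")
    junction = extract_junction(oriented, v_hit, j_hit, db, chain)
    if junction is None:
        return Exclusion(read_id, "anchor_lost")
    in_frame, productive = classify_productivity(junction)
    return AnnotatedRead(
        read_id=read_id,
        chain=chain,
        v_call=v_hit.gene_name,
        j_call=j_hit.gene_name,
        v_score=v_hit.score,
        j_score=j_hit.score,
        junction_nt=junction,
        in_frame=in_frame,
        productive=productive,
        rev_comp=use_rc,
    )


def annotate_reads(
    reads: Iterable[tuple[str, str]],
    chain: str,
    db: GermlineDB,
    params: AlignParams | None = None,
) -> tuple[list[AnnotatedRead], list[Exclusion]]:
    """Annotate (read_id, seq) pairs, memoizing on the read sequence.

    Amplicon libraries are highly redundant (a few hundred clones at depth
    10^4–10^5), so identical sequences are annotated once.
    """
    params = params or AlignParams()
    aligner = make_aligner(params)
    cache: dict[str, AnnotatedRead | Exclusion] = {}
    annotated: list[AnnotatedRead] = []
    excluded: list[Exclusion] = []
    for read_id, seq in reads:
        hit = cache.get(seq)
        if hit is None:
            hit = annotate_read(read_id, seq, chain, db, params, aligner)
            cache[seq] = hit
        if isinstance(hit, Exclusion):
            excluded.append(Exclusion(read_id, hit.reason))
        else:
            annotated.append(
                AnnotatedRead(
                    read_id=read_id,
                    chain=hit.chain,
                    v_call=hit.v_call,
                    j_call=hit.j_call,
                    v_score=hit.v_score,
                    j_score=hit.j_score,
                    junction_nt=hit.junction_nt,
                    in_frame=hit.in_frame,
                    productive=hit.productive,
                    rev_comp=hit.rev_comp,
                )
            )
    return annotated, excluded


def to_airr_table(annotations: Sequence[AnnotatedRead]) -> pd.DataFrame:
    """AIRR-Rearrangement-style table of annotations."""
    locus = {"alpha": "TRA", "beta": "TRB"}
    return pd.DataFrame(
        {
            "sequence_id": [a.read_id for a in annotations],
            "locus": [locus[a.chain] for a in annotations],
            "v_call": [a.v_call for a in annotations],
            "j_call": [a.j_call for a in annotations],
            "junction": [a.junction_nt for a in annotations],
            "junction_aa": [a.junction_aa for a in annotations],
            "productive": [a.productive for a in annotations],
            "v_score": [a.v_score for a in annotations],
            "j_score": [a.j_score for a in annotations],
            "rev_comp": [a.rev_comp for a in annotations],
        }
    )


def write_exclusion_log(exclusions: Sequence[Exclusion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for e in exclusions:
            fh.write(f"{e.read_id}\t{e.reason}\n")
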