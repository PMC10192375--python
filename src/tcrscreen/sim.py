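"""Simulation of natively paired TCRα:β repertoires and amplicon sequencing.

The generator emulates the experimental system end to end:

* **V(D)J recombination** — each chain is built as a trimmed germline V, a
  random N-nucleotide insert (two inserts flanking a trimmed D for β), and a
  trimmed germline J; junctions are resampled until in frame and stop-free
  (for the configured productive fraction), mirroring thymic selection of
  productive rearrangements.
* **Clone abundance skew** — relative clone frequencies follow a Zipf power
  law; exponent 0 is the uniform control.
* **α:β chimera formation** — linked amplicons are normally built from the α
  and β of one clone.  Without suppression PCR, a fraction ``chimera_rate``
  of amplicons instead draws α and β independently from the abundance
  distribution (overlap-extension mispairing); with suppression (blocking
  oligos) the residual rate applies.
* **Activation sorting** — presort and sorted samples are multinomial draws,
  with designated antigen-specific clones up-weighted by an activation
  factor in the sorted sample.
* **Sequencing** — 2×300 paired reads over the linked amplicon (R1 = β side,
  R2 = reverse-complemented α side) or a single merged read over the β-chain
  recovery amplicon, with per-base substitution errors at the Phred-implied
  rate and Phred+33 qualities.

All randomness derives from ``SimParams.seed``; identical parameters give
byte-identical FASTQ output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import SimulationError, TcrScreenError
from .germline import GermlineDB, GermlineSegment, translate
from .util import revcomp, validate_dna

logger = logging.getLogger(__name__)

#: Default 30-nt linker joining β and α in the linked amplicon.  Carries the
#: SpeI and MluI sites used to swap in the full expression cassette.
DEFAULT_LINKER = "ACTAGTCCCAGAGTTTTCCTCGGCACGCGT"

_MAX_CLONE_RETRIES = 500


@dataclass
class SimParams:
    """Free parameters of the repertoire/read simulator.

    ``error_profile`` is either a single Phred score applied to every base or
    a per-position template (cycled/truncated to the read length).
    """

    n_clones: int = 300
    abundance_exponent: float = 1.0
    trim_mean: float = 2.5
    n_insert_mean: float = 5.0
    chimera_rate: float = 0.9
    suppression_on: bool = True
    residual_chimera_rate: float = 0.02
    read_length: int = 300
    depth: int = 30_000
    error_profile: int | Sequence[int] = 30
    productive_frac: float = 1.0
    linker: str = DEFAULT_LINKER
    orientation: str = "beta_first"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise SimulationError("n_clones must be >= 1")
        if not 0 <= self.residual_chimera_rate <= self.chimera_rate <= 1:
            raise SimulationError(
                "need 0 <= residual_chimera_rate <= chimera_rate <= 1"
            )
        if self.depth < 0:
            raise SimulationError("depth must be >= 0")
        if self.read_length < 50:
            raise SimulationError("read_length must be >= 50")
        if self.abundance_exponent < 0:
            raise SimulationError("abundance_exponent must be >= 0")
        if not 0 <= self.productive_frac <= 1:
            raise SimulationError("productive_frac must be in [0, 1]")
        if self.orientation not in ("beta_first", "alpha_first"):
            raise SimulationError(f"unknown orientation {self.orientation!r}")

    def qual_template(self, length: int) -> np.ndarray:
        prof = np.atleast_1d(np.asarray(self.error_profile, dtype=int))
        if (prof < 0).any():
            raise SimulationError("Phred scores must be >= 0")
        reps = int(np.ceil(length / prof.size))
        return np.tile(prof, reps)[:length]


@dataclass(frozen=True)
class ChainRecord:
    """One rearranged chain of a simulated clone."""

    v_gene: str
    j_gene: str
    junction_nt: str
    full_nt: str
    d_gene: str | None = None

    @property
    def junction_aa(self) -> str:
        return translate(self.junction_nt)


@dataclass(frozen=True)
class PairedClone:
    """Ground-truth simulated clone with natively paired chains."""

    clone_id: int
    alpha: ChainRecord
    beta: ChainRecord
    abundance: float
    is_specific: bool = False


@dataclass(frozen=True)
class SortSpec:
    """Activation-sort model: specific clones gain ``activation_factor``
    weight in the sorted sample, everything else keeps ``background_rate``."""

    specific_clone_ids: frozenset[int]
    activation_factor: float = 25.0
    background_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.activation_factor <= 1:
            raise SimulationError("activation_factor must be > 1")
        if self.background_rate > 1:
            raise SimulationError("background_rate must be <= 1")


@dataclass(frozen=True)
class PoolRecord:
    """One sampled amplicon with its ground truth."""

    read_id: str
    amplicon: str
    alpha_clone: int
    beta_clone: int
    mispaired: bool


def _abundances(n: int, exponent: float) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    return w / w.sum()


def _geometric0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0,1,2,...} with the given mean (0 if mean == 0)."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


def _sample_chain(
    rng: np.random.Generator,
    v: GermlineSegment,
    j: GermlineSegment,
    d: GermlineSegment | None,
    c: GermlineSegment,
    params: SimParams,
    want_productive: bool,
) -> ChainRecord:
    """Draw trims/inserts until the junction satisfies the frame constraint."""
    assert v.anchor_offset is not None and j.anchor_offset is not None
    bases = "ACGT"
    max_v_trim = len(v.nt_sequence) - (v.anchor_offset + 3)
    max_j_trim = j.anchor_offset
    for _ in range(_MAX_CLONE_RETRIES):
        v_trim = min(_geometric0(rng, params.trim_mean), max_v_trim)
        j_trim = min(_geometric0(rng, params.trim_mean), max_j_trim)
        n1 = "".join(rng.choice(list(bases), size=rng.poisson(params.n_insert_mean)))
        v_part = v.nt_sequence[v.anchor_offset : len(v.nt_sequence) - v_trim]
        j_part = j.nt_sequence[j_trim : j.anchor_offset + 3]
        if d is not None:
            d5 = min(_geometric0(rng, params.trim_mean), len(d.nt_sequence))
            d3 = min(_geometric0(rng, params.trim_mean), len(d.nt_sequence) - d5)
            d_part = d.nt_sequence[d5 : len(d.nt_sequence) - d3]
            n2 = "".join(rng.choice(list(bases), size=rng.poisson(params.n_insert_mean)))
            junction = v_part + n1 + d_part + n2 + j_part
        else:
            junction = v_part + n1 + j_part
        in_frame = len(junction) % 3 == 0
        productive = in_frame and "*" not in translate(junction) if in_frame else False
        if want_productive and not productive:
            continue
        if not want_productive and productive:
            continue
        full = (
            v.nt_sequence[: v.anchor_offset]
            + junction
            + j.nt_sequence[j.anchor_offset + 3 :]
            + c.nt_sequence
        )
        return ChainRecord(
            v_gene=v.gene_name,
            j_gene=j.gene_name,
            d_gene=d.gene_name if d is not None else None,
            junction_nt=junction,
            full_nt=full,
        )
    raise SimulationError(
        f"could not sample a {'productive' if want_productive else 'non-productive'} "
        f"junction for {v.gene_name}/{j.gene_name} within {_MAX_CLONE_RETRIES} tries"
    )


def simulate_repertoire(
    db: GermlineDB,
    params: SimParams,
    specific_clone_ids: Iterable[int] = (),
) -> list[PairedClone]:
    """Generate ``n_clones`` distinct paired clones with Zipf abundances.

    Clone ids run 0..n_clones-1 in decreasing abundance order.  Distinctness
    is enforced on the CDR3β junction at both nucleotide and amino-acid level
    so that amino-acid clone tracking is unambiguous.
    """
    db.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA1]))
    specific = frozenset(specific_clone_ids)
    if specific and not specific <= set(range(params.n_clones)):
        raise SimulationError("specific_clone_ids outside the clone id range")

    alpha_v = db.of_type("alpha", "V")
    alpha_j = db.of_type("alpha", "J")
    beta_v = db.of_type("beta", "V")
    beta_j = db.of_type("beta", "J")
    beta_d = db.of_type("beta", "D") or [None]
    alpha_c = db.of_type("alpha", "C")
    beta_c = db.of_type("beta", "C")
    if not alpha_c or not beta_c:
        raise SimulationError("germline database lacks constant regions")

    abund = _abundances(params.n_clones, params.abundance_exponent)
    clones: list[PairedClone] = []
    seen_nt: set[str] = set()
    seen_aa: set[str] = set()
    for cid in range(params.n_clones):
        want_productive = bool(rng.random() < params.productive_frac)
        for _ in range(_MAX_CLONE_RETRIES):
            beta = _sample_chain(
                rng,
                beta_v[rng.integers(len(beta_v))],
                beta_j[rng.integers(len(beta_j))],
                beta_d[rng.integers(len(beta_d))],
                beta_c[0],
                params,
                want_productive,
            )
            if beta.junction_nt in seen_nt:
                continue
            if want_productive and beta.junction_aa in seen_aa:
                continue
            break
        else:
            raise SimulationError("could not generate a distinct CDR3β")
        alpha = _sample_chain(
            rng,
            alpha_v[rng.integers(len(alpha_v))],
            alpha_j[rng.integers(len(alpha_j))],
            None,
            alpha_c[0],
            params,
            want_productive,
        )
        seen_nt.add(beta.junction_nt)
        if want_productive:
            seen_aa.add(beta.junction_aa)
        clones.append(
            PairedClone(
                clone_id=cid,
                alpha=alpha,
                beta=beta,
                abundance=float(abund[cid]),
                is_specific=cid in specific,
            )
        )
    return clones


def build_linked_amplicon(
    alpha_nt: str,
    beta_nt: str,
    linker_nt: str,
    orientation: str = "beta_first",
) -> str:
    """Concatenate the two chains through the linker (β-linker-α by default)."""
    alpha_nt = validate_dna(alpha_nt, what="alpha chain")
    beta_nt = validate_dna(beta_nt, what="beta chain")
    if not linker_nt:
        raise SimulationError("linker must be non-empty (it carries MluI/SpeI)")
    linker_nt = validate_dna(linker_nt, what="linker")
    if "ACGCGT" not in linker_nt and "ACTAGT" not in linker_nt:
        logger.warning("linker contains neither an MluI nor a SpeI site")
    if orientation == "beta_first":
        return beta_nt + linker_nt + alpha_nt
    if orientation == "alpha_first":
        return alpha_nt + linker_nt + beta_nt
    raise SimulationError(f"unknown orientation {orientation!r}")


def sample_amplicon_pool(
    clones: Sequence[PairedClone], params: SimParams
) -> list[PoolRecord]:
    """Draw ``depth`` linked amplicons with the chimera (mispairing) model.

    With probability ``chimera_rate`` (suppression off) or
    ``residual_chimera_rate`` (on), the α and β chains are drawn
    independently from the abundance distribution — the overlap-extension
    artifact that suppression PCR blocks.  A chimeric draw that happens to
    pick the same clone twice is, by definition, correctly paired.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xB2]))
    abund = np.array([c.abundance for c in clones])
    if abs(abund.sum() - 1.0) > 1e-9:
        raise SimulationError("clone abundances must be normalized")
    p_chim = params.residual_chimera_rate if params.suppression_on else params.chimera_rate
    n = params.depth
    is_chim = rng.random(n) < p_chim
    primary = rng.choice(len(clones), size=n, p=abund)
    alt = rng.choice(len(clones), size=n, p=abund)
    pool = []
    for i in range(n):
        b = int(primary[i])
        a = int(alt[i]) if is_chim[i] else b
        amp = build_linked_amplicon(
            clones[a].alpha.full_nt,
            clones[b].beta.full_nt,
            params.linker,
            params.orientation,
        )
        pool.append(
            PoolRecord(
                read_id=f"amp{i:06d}",
                amplicon=amp,
                alpha_clone=clones[a].clone_id,
                beta_clone=clones[b].clone_id,
                mispaired=a != b,
            )
        )
    return pool


def simulate_sort(
    clones: Sequence[PairedClone],
    spec: SortSpec,
    depth: int,
    seed: int,
) -> tuple[dict[int, int], dict[int, int]]:
    """Multinomial presort and sorted read-count tables (clone_id -> count).

    Sorted-sample probabilities re-normalize abundance × activation_factor
    for specific clones and abundance × background_rate otherwise.
    """
    if not spec.specific_clone_ids <= {c.clone_id for c in clones}:
        raise SimulationError("specific_clone_ids not a subset of the repertoire")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC3]))
    abund = np.array([c.abundance for c in clones])
    weights = np.array(
        [
            c.abundance
            * (spec.activation_factor if c.clone_id in spec.specific_clone_ids
               else spec.background_rate)
            for c in clones
        ]
    )
    ids = [c.clone_id for c in clones]
    if depth == 0:
        return {}, {}
    presort = rng.multinomial(depth, abund / abund.sum())
    sorted_counts = rng.multinomial(depth, weights / weights.sum())
    return (
        {i: int(k) for i, k in zip(ids, presort) if k > 0},
        {i: int(k) for i, k in zip(ids, sorted_counts) if k > 0},
    )


def expected_sorted_freq(clones: Sequence[PairedClone], spec: SortSpec) -> dict[int, float]:
    """Closed-form expected sorted-sample frequency per clone."""
    weights = {
        c.clone_id: c.abundance
        * (spec.activation_factor if c.clone_id in spec.specific_clone_ids
           else spec.background_rate)
        for c in clones
    }
    total = sum(weights.values())
    return {cid: w / total for cid, w in weights.items()}


def counts_to_beta_pool(
    clones: Sequence[PairedClone], counts: dict[int, int], sample: str
) -> list[PoolRecord]:
    """Expand a clone count table into β-chain recovery amplicons."""
    by_id = {c.clone_id: c for c in clones}
    pool = []
    i = 0
    for cid in sorted(counts):
        for _ in range(counts[cid]):
            pool.append(
                PoolRecord(
                    read_id=f"{sample}_read{i:06d}",
                    amplicon=by_id[cid].beta.full_nt,
                    alpha_clone=cid,
                    beta_clone=cid,
                    mispaired=False,
                )
            )
            i += 1
    return pool


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_OTHER = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


def _inject_errors(
    seq: str, quals: np.ndarray, rng: np.random.Generator
) -> tuple[str, int]:
    p = 10.0 ** (-quals / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if hits.size == 0:
        return seq, 0
    chars = list(seq)
    for i in hits:
        chars[i] = _OTHER[chars[i]][rng.integers(3)]
    return "".join(chars), int(hits.size)


def _qual_string(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def write_fastq(
    pool: Sequence[PoolRecord],
    params: SimParams,
    mode: str,
    out_prefix: str | Path,
    *,
    sample_barcode: str | None = None,
    truth_path: str | Path | None = None,
) -> list[Path]:
    """Emit FASTQ (Phred+33) for a pool of amplicons.

    ``paired_linked`` mode writes R1 (first ``read_length`` nt, β side) and
    R2 (reverse complement of the last ``read_length`` nt, α side) sharing a
    read identifier; ``beta_only`` writes one merged read spanning the whole
    β amplicon.  Substitution errors are injected per base with probability
    10^(−Q/10).  When ``truth_path`` is given, a per-read ground-truth TSV
    (clone ids, mispaired flag, error counts, truncation flag) is written.
    """
    if not pool:
        raise SimulationError("empty amplicon pool")
    if mode not in ("paired_linked", "beta_only"):
        raise SimulationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xD4]))
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    bc = sample_barcode or ""
    if bc:
        bc = validate_dna(bc, what="sample barcode")
    paths: list[Path]
    truth_rows = []

    def finalize(seq: str, rng: np.random.Generator) -> tuple[str, str, int]:
        quals = params.qual_template(len(seq))
        errseq, nerr = _inject_errors(seq, quals, rng)
        if bc:
            errseq = bc + errseq
            quals = np.concatenate([np.full(len(bc), 40), quals])
        return errseq, _qual_string(quals), nerr

    if mode == "paired_linked":
        p1 = out_prefix.with_name(out_prefix.name + "_R1.fastq")
        p2 = out_prefix.with_name(out_prefix.name + "_R2.fastq")
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for rec in pool:
                L = params.read_length
                truncated = len(rec.amplicon) < L
                r1 = rec.amplicon[:L]
                r2 = revcomp(rec.amplicon[-L:] if not truncated else rec.amplicon)
                s1, q1, e1 = finalize(r1, rng)
                s2, q2, e2 = finalize(r2, rng)
                f1.write(f"@{rec.read_id}\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rec.read_id}\n{s2}\n+\n{q2}\n")
                truth_rows.append((rec, e1, e2, truncated))
        paths = [p1, p2]
    else:
        p = out_prefix.with_name(out_prefix.name + "_merged.fastq")
        with open(p, "w") as fh:
            for rec in pool:
                s, q, e = finalize(rec.amplicon, rng)
                fh.write(f"@{rec.read_id}\n{s}\n+\n{q}\n")
                truth_rows.append((rec, e, 0, False))
        paths = [p]

    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write(
                "read_id\talpha_clone\tbeta_clone\tmispaired\tn_err_r1\tn_err_r2\ttruncated\n"
            )
            for rec, e1, e2, trunc in truth_rows:
                fh.write(
                    f"{rec.read_id}\t{rec.alpha_clone}\t{rec.beta_clone}\t"
                    f"{int(rec.mispaired)}\t{e1}\t{e2}\t{int(trunc)}\n"
                )
    return paths


def write_truth_table(clones: Sequence[PairedClone], path: str | Path) -> None:
    """Ground-truth clone table as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "clone_id\tabundance\tis_specific\tbeta_v\tbeta_d\tbeta_j\t"
            "beta_junction_nt\tbeta_junction_aa\talpha_v\talpha_j\talpha_junction_nt\n"
        )
        for c in clones:
            fh.write(
                f"{c.clone_id}\t{c.abundance:.8g}\t{int(c.is_specific)}\t"
                f"{c.beta.v_gene}\t{c.beta.d_gene or ''}\t{c.beta.j_gene}\t"
                f"{c.beta.junction_nt}\t{translate(c.beta.junction_nt) if len(c.beta.junction_nt) % 3 == 0 else ''}\t"
                f"{c.alpha.v_gene}\t{c.alpha.j_gene}\t{c.alpha.junction_nt}\n"
            )
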