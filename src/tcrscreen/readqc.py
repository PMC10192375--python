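"""FASTQ parsing, Phred quality filtering, and sample demultiplexing.

The quality rule retains a read only if a Phred score of at least
``q_threshold`` (default 20, i.e. 99% base-call accuracy) is reached in at
least ``min_fraction`` (default 50%) of its bases.  Boundaries are inclusive.
``N`` bases count as failing the threshold regardless of their stated quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import ConfigError, TcrScreenError
from .util import hamming

logger = logging.getLogger(__name__)


@dataclass
class SequencingRead:
    """A single read with per-base Phred qualities."""

    read_id: str
    mate: str  # "1" | "2" | "merged"
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise TcrScreenError("read_id must be non-empty")
        if len(self.seq) != len(self.quals):
            raise TcrScreenError(
                f"{self.read_id}: sequence and quality lengths differ"
            )


@dataclass
class QCParams:
    q_threshold: int = 20
    min_fraction: float = 0.5
    pair_policy: str = "both_mates"  # or "per_read"

    def __post_init__(self) -> None:
        if self.q_threshold < 0:
            raise ConfigError("q_threshold must be >= 0")
        if not 0 < self.min_fraction <= 1:
            raise ConfigError("min_fraction must be in (0, 1]")
        if self.pair_policy not in ("both_mates", "per_read"):
            raise ConfigError(f"unknown pair_policy {self.pair_policy!r}")


def phred_to_accuracy(q: int | float) -> float:
    """Base-call accuracy implied by a Phred score: 1 − 10^(−q/10).

    Q20 → 0.99, Q30 → 0.999.
    """
    if q < 0:
        raise TcrScreenError("Phred score must be >= 0")
    return 1.0 - 10.0 ** (-q / 10.0)


def read_fastq(path: str | Path, mate: str = "merged") -> Iterator[SequencingRead]:
    """Stream a Phred+33 FASTQ file as :class:`SequencingRead` objects."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield SequencingRead(
            read_id=rec.id,
            mate=mate,
            seq=str(rec.seq).upper(),
            quals=list(rec.letter_annotations["phred_quality"]),
        )


def quality_filter(read: SequencingRead, params: QCParams) -> bool:
    """Keep iff the fraction of bases at/above the threshold is >= min_fraction.

    Zero-length reads are discarded.  N bases never count as passing.
    """
    n = len(read.seq)
    if n == 0:
        logger.info("discarding zero-length read %s", read.read_id)
        return False
    good = sum(
        1
        for base, q in zip(read.seq, read.quals)
        if base != "N" and q >= params.q_threshold
    )
    return good / n >= params.min_fraction


def filter_pairs(
    pairs: Iterable[tuple[SequencingRead, SequencingRead]], params: QCParams
) -> tuple[list[tuple[SequencingRead, SequencingRead]], dict[str, int]]:
    """Apply the quality rule to read pairs.

    Under the default ``both_mates`` policy a pair survives only if both
    mates pass individually.  Returns the kept pairs and a counter dict.
    """
    kept = []
    stats = {"pairs_in": 0, "pairs_kept": 0}
    for r1, r2 in pairs:
        stats["pairs_in"] += 1
        ok1, ok2 = quality_filter(r1, params), quality_filter(r2, params)
        keep = (ok1 and ok2) if params.pair_policy == "both_mates" else (ok1 or ok2)
        if keep:
            kept.append((r1, r2))
            stats["pairs_kept"] += 1
    return kept, stats


def filter_reads(
    reads: Iterable[SequencingRead], params: QCParams
) -> tuple[list[SequencingRead], dict[str, int]]:
    kept = []
    stats = {"reads_in": 0, "reads_kept": 0}
    for r in reads:
        stats["reads_in"] += 1
        if quality_filter(r, params):
            kept.append(r)
            stats["reads_kept"] += 1
    return kept, stats


def validate_barcodes(barcode_table: dict[str, str], max_mismatches: int = 0) -> None:
    """Barcodes must be equal length and pairwise farther apart than
    ``max_mismatches`` (otherwise assignment would be ambiguous)."""
    barcodes = list(barcode_table)
    if not barcodes:
        raise ConfigError("barcode table is empty")
    length = len(barcodes[0])
    if any(len(b) != length for b in barcodes):
        raise ConfigError("barcodes must all have the same length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if hamming(a, b) <= max_mismatches:
                raise ConfigError(
                    f"barcodes {a!r} and {b!r} are within {max_mismatches} "
                    "mismatches of each other"
                )


def demultiplex(
    reads: Iterable[SequencingRead],
    barcode_table: dict[str, str],
    max_mismatches: int = 0,
) -> dict[str, list[SequencingRead]]:
    """Assign reads to samples by prefix barcode; trim the barcode off.

    Reads matching no barcode within ``max_mismatches`` (or matching two
    equally well) land in the ``"undetermined"`` bin untrimmed.
    """
    validate_barcodes(barcode_table, max_mismatches)
    length = len(next(iter(barcode_table)))
    out: dict[str, list[SequencingRead]] = {s: [] for s in barcode_table.values()}
    out["undetermined"] = []
    for read in reads:
        prefix = read.seq[:length]
        best: str | None = None
        best_d = max_mismatches + 1
        tie = False
        for bc, sample in barcode_table.items():
            if len(prefix) < length:
                break
            d = hamming(prefix, bc)
            if d < best_d:
                best, best_d, tie = sample, d, False
            elif d == best_d and best is not None:
                tie = True
        if best is None or tie:
            out["undetermined"].append(read)
        else:
            out[best].append(
                SequencingRead(
                    read_id=read.read_id,
                    mate=read.mate,
                    seq=read.seq[length:],
                    quals=read.quals[length:],
                )
            )
    return out


def write_qc_report(stats_by_sample: dict[str, dict[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\treads_in\treads_kept\tfraction_kept\n")
        for sample, st in sorted(stats_by_sample.items()):
            n_in = st.get("reads_in", st.get("pairs_in", 0))
            n_kept = st.get("reads_kept", st.get("pairs_kept", 0))
            frac = n_kept / n_in if n_in else 0.0
            fh.write(f"{sample}\t{n_in}\t{n_kept}\t{frac:.4f}\n")
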