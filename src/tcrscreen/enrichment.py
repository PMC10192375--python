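"""Per-sample clone frequencies, sorted-vs-presort enrichment, hit calling.

A clone's frequency is its read count divided by the sample's filtered-read
total.  The enrichment ratio is the sorted-sample frequency over the presort
frequency; a clone absent from the presort gets a pseudo-frequency of
0.5/presort_total (flagged ``presort_absent``) instead of an infinite ratio.
A hit is a clone enriched strictly more than ``fold_threshold`` (default 10)
with at least ``min_sorted_reads`` sorted reads (default 2, consistent with
the pipeline's aversion to singleton evidence).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .clonotype import PipelineConfig
from .errors import TcrScreenError


@dataclass
class EnrichmentRecord:
    track_key: str
    reads_presort: int
    reads_sorted: int
    freq_presort: float
    freq_sorted: float
    ratio: float
    presort_absent: bool
    hit: bool


def compute_frequencies(counts: Mapping[str, int]) -> dict[str, float]:
    """counts -> frequencies; errors on a zero read total."""
    total = sum(counts.values())
    if total <= 0:
        raise TcrScreenError("cannot compute frequencies with zero total reads")
    return {k: v / total for k, v in counts.items()}


def enrichment_ratio(
    reads_presort: int,
    reads_sorted: int,
    presort_total: int,
    sorted_total: int,
    pseudo_policy: str = "half_read",
) -> tuple[float, bool]:
    """(ratio, presort_absent flag) for one clone.

    ``half_read`` replaces a zero presort frequency with 0.5/presort_total.
    """
    if presort_total <= 0 or sorted_total <= 0:
        raise TcrScreenError("sample totals must be > 0")
    freq_sorted = reads_sorted / sorted_total
    if reads_presort > 0:
        return freq_sorted / (reads_presort / presort_total), False
    if pseudo_policy != "half_read":
        raise TcrScreenError(f"unknown pseudo_policy {pseudo_policy!r}")
    return freq_sorted / (0.5 / presort_total), True


def build_enrichment_records(
    clone_table: pd.DataFrame,
    presort_sample: str,
    sorted_sample: str,
    config: PipelineConfig | None = None,
) -> list[EnrichmentRecord]:
    """Enrichment records for every tracked clone in a clone table.

    ``clone_table`` is the output of :func:`tcrscreen.clonotype.track_clones`
    (or any frame with a ``track_key`` column plus per-sample count columns).
    """
    config = config or PipelineConfig()
    for col in (presort_sample, sorted_sample):
        if col not in clone_table.columns:
            raise TcrScreenError(f"clone table lacks sample column {col!r}")
    presort_total = int(clone_table[presort_sample].sum())
    sorted_total = int(clone_table[sorted_sample].sum())
    records = []
    for _, row in clone_table.iterrows():
        rp, rs = int(row[presort_sample]), int(row[sorted_sample])
        ratio, absent = enrichment_ratio(rp, rs, presort_total, sorted_total)
        records.append(
            EnrichmentRecord(
                track_key=row["track_key"],
                reads_presort=rp,
                reads_sorted=rs,
                freq_presort=rp / presort_total,
                freq_sorted=rs / sorted_total,
                ratio=ratio,
                presort_absent=absent,
                hit=False,
            )
        )
    return call_hits(records, config)


def call_hits(
    records: Sequence[EnrichmentRecord],
    config: PipelineConfig | None = None,
    min_sorted_reads: int | None = None,
) -> list[EnrichmentRecord]:
    """Flag hits: ratio strictly above the fold threshold with enough sorted
    reads.  Returns the same records with ``hit`` set."""
    config = config or PipelineConfig()
    if min_sorted_reads is None:
        min_sorted_reads = config.min_sorted_reads
    for rec in records:
        rec.hit = rec.ratio > config.fold_threshold and rec.reads_sorted >= min_sorted_reads
    return records


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    if not df.empty:
        df = df.sort_values("ratio", ascending=False).reset_index(drop=True)
    return df


def write_enrichment_report(
    records: Sequence[EnrichmentRecord],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> None:
    config = config or PipelineConfig()
    df = enrichment_table(records)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = {
            "n_clones": len(records),
            "n_hits": int(sum(r.hit for r in records)),
            "fold_threshold": config.fold_threshold,
            "min_sorted_reads": config.min_sorted_reads,
            "reads_presort_total": int(sum(r.reads_presort for r in records)),
            "reads_sorted_total": int(sum(r.reads_sorted for r in records)),
            "hits": [r.track_key for r in records if r.hit],
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))
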