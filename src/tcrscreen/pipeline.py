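"""End-to-end pipeline: simulate → qc → annotate → clonotype → enrich → design.

A single YAML configuration drives all stages; every stage writes its
artifacts under the output directory and contributes record counts to a run
manifest (JSON) that is emitted even on partial failure.  All randomness
derives from the top-level seed.

Two modes mirror the two sequencing strategies:

* ``paired_linked`` — linked α:β amplicons from one library, 2×300 paired
  reads, α/β pairing by read id (library construction / chimera QC).
* ``beta_only`` — β-chain recovery amplicons from a presort and a sorted
  sample (barcoded, multiplexed), merged reads, enrichment calling
  (activation-screening readout).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .annotate import AlignParams, annotate_reads, to_airr_table, write_exclusion_log
from .clonotype import (
    PipelineConfig,
    cluster_cdr3,
    compile_clonotypes,
    filter_singletons,
    pair_by_read_id,
    track_clones,
    write_cluster_members,
)
from .design import (
    assemble_cassette,
    default_elements,
    design_blocking_oligos,
    estimate_repertoire_loss,
    stitch_full_length,
)
from .enrichment import build_enrichment_records, write_enrichment_report
from .errors import ConfigError, DesignError, TcrScreenError
from .germline import bundled_germline, load_germline
from .readqc import QCParams, demultiplex, filter_pairs, filter_reads, read_fastq, write_qc_report
from .sim import (
    SimParams,
    SortSpec,
    counts_to_beta_pool,
    sample_amplicon_pool,
    simulate_repertoire,
    simulate_sort,
    write_fastq,
    write_truth_table,
)

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "outdir", "mode", "germline", "sim", "sort", "samples", "qc",
         "annotate", "clonotype", "enrichment", "design"},
    "germline": {"fasta", "anchors", "collapse_alleles"},
    "sim": {"n_clones", "abundance_exponent", "trim_mean", "n_insert_mean",
            "chimera_rate", "suppression_on", "residual_chimera_rate",
            "read_length", "depth", "error_profile", "productive_frac"},
    "sort": {"specific_clone_ids", "activation_factor", "background_rate", "depth"},
    "qc": {"q_threshold", "min_fraction", "max_mismatches", "pair_policy"},
    "annotate": {"min_v_score", "min_j_score"},
    "clonotype": {"cluster_identity", "min_cluster_reads", "singleton_scope"},
    "enrichment": {"fold_threshold", "min_sorted_reads"},
    "design": {"enabled", "tail_length", "forbidden_kmers_k", "max_cassettes"},
}


def validate_config(cfg: dict[str, Any]) -> None:
    """Strict schema check: any unknown key aborts before any compute."""
    unknown = set(cfg) - _SCHEMA[""]
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SCHEMA.items():
        if not section or section not in cfg:
            continue
        sub = cfg[section]
        if section == "samples":
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown keys in section {section!r}: {sorted(bad)}")
    mode = cfg.get("mode", "paired_linked")
    if mode not in ("paired_linked", "beta_only"):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode == "beta_only" and "sort" in cfg and "samples" not in cfg:
        raise ConfigError("beta_only sort runs need a 'samples' barcode table")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping")
    validate_config(cfg)
    return cfg


def demo_config_path() -> Path:
    """Bundled demo configuration (β-only activation screen, desk scale)."""
    return Path(str(resources.files("tcrscreen") / "data" / "demo_config.yaml"))


@dataclass
class RunManifest:
    """Per-run record counts, thresholds, digests, and hit list."""

    tool_version: str = __version__
    seed: int = 0
    mode: str = ""
    config: dict = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, Any] = field(default_factory=dict)
    hits: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    status: str = "incomplete"
    error: str | None = None

    def digest(self, label: str, path: Path) -> None:
        h = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        self.outputs[label] = f"{path.name}:{h}"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _sim_params(cfg: dict, seed: int) -> SimParams:
    return SimParams(seed=seed, **cfg.get("sim", {}))


def run_pipeline(
    config: str | Path | dict[str, Any],
    *,
    seed: int | None = None,
    outdir: str | Path | None = None,
    mode: str | None = None,
) -> RunManifest:
    """Execute all enabled stages; returns (and writes) the run manifest.

    The manifest is written to ``<outdir>/manifest.json`` even when a stage
    fails; in that case the exception is re-raised after writing.
    """
    cfg = load_config(config) if not isinstance(config, dict) else copy.deepcopy(config)
    validate_config(cfg)
    if seed is not None:
        cfg["seed"] = seed
    if mode is not None:
        cfg["mode"] = mode
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    run_seed = int(cfg.get("seed", 0))
    run_mode = cfg.get("mode", "paired_linked")
    out = Path(cfg.get("outdir", "tcrscreen_out"))
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(seed=run_seed, mode=run_mode, config=copy.deepcopy(cfg))
    try:
        _run_stages(cfg, run_seed, run_mode, out, manifest)
        manifest.status = "ok"
    except Exception as exc:
        manifest.status = "failed"
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _run_stages(
    cfg: dict, run_seed: int, run_mode: str, out: Path, manifest: RunManifest
) -> None:
    gl_cfg = cfg.get("germline", {})
    if gl_cfg.get("fasta"):
        db = load_germline(
            gl_cfg["fasta"], gl_cfg["anchors"],
            collapse_alleles=bool(gl_cfg.get("collapse_alleles", False)),
        )
    else:
        db = bundled_germline()

    params = _sim_params(cfg, run_seed)
    qc_params = QCParams(**{k: v for k, v in cfg.get("qc", {}).items()
                            if k in ("q_threshold", "min_fraction", "pair_policy")})
    align_params = AlignParams(**cfg.get("annotate", {}))
    pipe_cfg = PipelineConfig(
        mode=run_mode,
        q_threshold=qc_params.q_threshold,
        min_fraction=qc_params.min_fraction,
        **cfg.get("clonotype", {}),
        **cfg.get("enrichment", {}),
    )
    manifest.thresholds = {
        "q_threshold": pipe_cfg.q_threshold,
        "min_fraction": pipe_cfg.min_fraction,
        "cluster_identity": pipe_cfg.cluster_identity,
        "min_cluster_reads": pipe_cfg.min_cluster_reads,
        "fold_threshold": pipe_cfg.fold_threshold,
        "min_sorted_reads": pipe_cfg.min_sorted_reads,
    }

    # --- simulate -----------------------------------------------------------
    sort_cfg = cfg.get("sort")
    specific = sort_cfg.get("specific_clone_ids", []) if sort_cfg else []
    clones = simulate_repertoire(db, params, specific_clone_ids=specific)
    write_truth_table(clones, out / "truth_clones.tsv")
    manifest.counts["clones_simulated"] = len(clones)
    logger.info("simulated %d clones", len(clones))

    if run_mode == "beta_only":
        _run_beta_only(cfg, clones, params, qc_params, align_params, pipe_cfg,
                       db, out, manifest, run_seed)
    else:
        _run_paired(cfg, clones, params, qc_params, align_params, pipe_cfg,
                    db, out, manifest)

    # --- design -------------------------------------------------------------
    d_cfg = cfg.get("design", {})
    if d_cfg.get("enabled", True):
        chain_seqs = [
            (
                stitch_full_length(c.beta.v_gene, c.beta.j_gene, c.beta.junction_nt,
                                   "beta", db),
                stitch_full_length(c.alpha.v_gene, c.alpha.j_gene, c.alpha.junction_nt,
                                   "alpha", db),
            )
            for c in clones
        ]
        loss = estimate_repertoire_loss(chain_seqs)
        n_cassettes = 0
        max_cassettes = int(d_cfg.get("max_cassettes", 10))
        with open(out / "cassettes.fasta", "w") as fh:
            for c, (b_nt, a_nt) in zip(clones, chain_seqs):
                if n_cassettes >= max_cassettes:
                    break
                try:
                    cass = assemble_cassette(b_nt, a_nt)
                except DesignError:
                    continue
                fh.write(f">cassette_clone{c.clone_id}\n{cass.full_nt}\n")
                n_cassettes += 1
        elements = default_elements()
        oligo_a, oligo_b = design_blocking_oligos(
            clones[0].alpha.full_nt[-30:],
            clones[0].beta.full_nt[-30:],
            tail_length=int(d_cfg.get("tail_length", 20)),
            forbidden_kmers_k=int(d_cfg.get("forbidden_kmers_k", 8)),
            linker_nt=elements.default_linker,
            seed=run_seed,
        )
        (out / "blocking_oligos.fasta").write_text(
            f">blocking_alpha\n{oligo_a}\n>blocking_beta\n{oligo_b}\n"
        )
        manifest.counts["cassettes_written"] = n_cassettes
        manifest.thresholds["repertoire_loss_fraction"] = loss
        manifest.digest("cassettes", out / "cassettes.fasta")


def _finish_clonotyping(
    records_by_sample, pipe_cfg, out, manifest
):
    clonotypes = compile_clonotypes(records_by_sample, mode=pipe_cfg.mode)
    manifest.counts["exact_clonotypes"] = len(clonotypes)
    clusters = cluster_cdr3(clonotypes, pipe_cfg)
    manifest.counts["clusters_prefilter"] = len(clusters)
    kept, removed = filter_singletons(clusters, pipe_cfg)
    manifest.counts["clusters_postfilter"] = len(kept)
    write_cluster_members(kept, out / "clusters.tsv")
    clone_table = track_clones(kept)
    manifest.counts["tracked_clones"] = len(clone_table)
    clone_table.to_csv(out / "clone_table.tsv", sep="\t", index=False)
    manifest.digest("clone_table", out / "clone_table.tsv")
    # read conservation: cluster totals (pre-filter) match clonotype totals
    total_ct = sum(c.total_reads for c in clonotypes)
    total_cl = sum(c.total_reads for c in clusters)
    if total_ct != total_cl:
        raise TcrScreenError("read-count conservation violated in clustering")
    return clone_table


def _run_beta_only(cfg, clones, params, qc_params, align_params, pipe_cfg,
                   db, out, manifest, run_seed):
    sort_cfg = cfg.get("sort")
    if not sort_cfg:
        raise ConfigError("beta_only mode requires a 'sort' section")
    samples: dict[str, str] = cfg["samples"]  # sample -> barcode
    spec = SortSpec(
        specific_clone_ids=frozenset(sort_cfg.get("specific_clone_ids", [])),
        activation_factor=float(sort_cfg.get("activation_factor", 25.0)),
        background_rate=float(sort_cfg.get("background_rate", 1.0)),
    )
    depth = int(sort_cfg.get("depth", params.depth))
    presort, sorted_counts = simulate_sort(clones, spec, depth, run_seed)
    count_tables = {"presort": presort, "sorted": sorted_counts}

    # one multiplexed FASTQ with per-sample barcodes
    combined = out / "multiplexed_merged.fastq"
    with open(combined, "w") as fh:
        pass
    for i, (sample, counts) in enumerate(count_tables.items()):
        pool = counts_to_beta_pool(clones, counts, sample)
        if not pool:
            continue
        sub_params = SimParams(**{**_plain_sim_kwargs(params), "seed": run_seed + i + 1})
        paths = write_fastq(pool, sub_params, "beta_only", out / f"tmp_{sample}",
                            sample_barcode=samples[sample])
        with open(combined, "a") as fh, open(paths[0]) as src:
            fh.write(src.read())
        paths[0].unlink()
    manifest.digest("fastq", combined)

    reads = list(read_fastq(combined, mate="merged"))
    manifest.counts["reads_in"] = len(reads)
    barcode_to_sample = {bc: s for s, bc in samples.items()}
    binned = demultiplex(reads, barcode_to_sample,
                         int(cfg.get("qc", {}).get("max_mismatches", 0)))
    manifest.counts["reads_undetermined"] = len(binned.get("undetermined", []))
    if manifest.counts["reads_in"] != sum(len(v) for v in binned.values()):
        raise TcrScreenError("demultiplexing lost reads")

    records_by_sample = {}
    qc_stats = {}
    n_kept = n_annotated = n_excluded = 0
    for sample in samples:
        kept, stats = filter_reads(binned.get(sample, []), qc_params)
        qc_stats[sample] = stats
        n_kept += len(kept)
        anns, excl = annotate_reads(
            ((r.read_id, r.seq) for r in kept), "beta", db, align_params
        )
        n_annotated += len(anns)
        n_excluded += len(excl)
        to_airr_table(anns).to_csv(out / f"annotations_{sample}.tsv", sep="\t", index=False)
        write_exclusion_log(excl, out / f"excluded_{sample}.tsv")
        records_by_sample[sample] = [a for a in anns if a.productive]
    write_qc_report(qc_stats, out / "qc_report.tsv")
    manifest.counts["reads_kept"] = n_kept
    manifest.counts["reads_annotated"] = n_annotated
    manifest.counts["reads_excluded"] = n_excluded
    if n_annotated + n_excluded != n_kept:
        raise TcrScreenError("annotation count reconciliation failed")

    clone_table = _finish_clonotyping(records_by_sample, pipe_cfg, out, manifest)
    if not clone_table.empty:
        for s in samples:
            if s not in clone_table.columns:
                clone_table[s] = 0
        records = build_enrichment_records(clone_table, "presort", "sorted", pipe_cfg)
        write_enrichment_report(records, out / "enrichment.tsv",
                                out / "enrichment_summary.json", pipe_cfg)
        manifest.hits = [r.track_key for r in records if r.hit]
        manifest.counts["hits"] = len(manifest.hits)
        manifest.digest("enrichment", out / "enrichment.tsv")


def _run_paired(cfg, clones, params, qc_params, align_params, pipe_cfg,
                db, out, manifest):
    pool = sample_amplicon_pool(clones, params)
    manifest.counts["amplicons"] = len(pool)
    paths = write_fastq(pool, params, "paired_linked", out / "library",
                        truth_path=out / "truth_reads.tsv")
    manifest.digest("fastq_r1", paths[0])
    manifest.digest("fastq_r2", paths[1])

    r1 = list(read_fastq(paths[0], mate="1"))
    r2 = list(read_fastq(paths[1], mate="2"))
    manifest.counts["reads_in"] = len(r1) + len(r2)
    pairs, stats = filter_pairs(zip(r1, r2), qc_params)
    write_qc_report({"library": stats}, out / "qc_report.tsv")
    manifest.counts["pairs_kept"] = len(pairs)

    beta_reads = [(p[0].read_id, p[0].seq) for p in pairs]
    alpha_reads = [(p[1].read_id, p[1].seq) for p in pairs]
    beta_anns, beta_excl = annotate_reads(beta_reads, "beta", db, align_params)
    alpha_anns, alpha_excl = annotate_reads(alpha_reads, "alpha", db, align_params)
    manifest.counts["reads_annotated"] = len(beta_anns) + len(alpha_anns)
    manifest.counts["reads_excluded"] = len(beta_excl) + len(alpha_excl)
    if manifest.counts["reads_annotated"] + manifest.counts["reads_excluded"] != 2 * len(pairs):
        raise TcrScreenError("annotation count reconciliation failed")
    to_airr_table(beta_anns).to_csv(out / "annotations_beta.tsv", sep="\t", index=False)
    to_airr_table(alpha_anns).to_csv(out / "annotations_alpha.tsv", sep="\t", index=False)
    write_exclusion_log(beta_excl + alpha_excl, out / "excluded.tsv")

    paired, drops = pair_by_read_id(alpha_anns, beta_anns)
    manifest.counts["pairs_productive"] = len(paired)
    manifest.counts["pairs_dropped"] = len(drops)
    _finish_clonotyping({"library": paired}, pipe_cfg, out, manifest)


def _plain_sim_kwargs(params: SimParams) -> dict:
    d = asdict(params)
    return d
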