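"""Repertoire simulation: junction construction, abundances, chimera model,
sort counts, and FASTQ emission."""

import logging
import math

import numpy as np
import pytest

from tcrscreen.errors import SimulationError
from tcrscreen.germline import translate
from tcrscreen.readqc import read_fastq
from tcrscreen.sim import (
    SimParams,
    SortSpec,
    build_linked_amplicon,
    expected_sorted_freq,
    sample_amplicon_pool,
    simulate_repertoire,
    simulate_sort,
    write_fastq,
)
from tcrscreen.util import revcomp


def test_zero_noise_junction_is_germline_concatenation(db):
    params = SimParams(n_clones=1, trim_mean=0.0, n_insert_mean=0.0, seed=11)
    (clone,) = simulate_repertoire(db, params)
    v = db.get("beta", "V", clone.beta.v_gene)
    j = db.get("beta", "J", clone.beta.j_gene)
    d = db.get("beta", "D", clone.beta.d_gene)
    expected = (
        v.nt_sequence[v.anchor_offset :] + d.nt_sequence
        + j.nt_sequence[: j.anchor_offset + 3]
    )
    assert clone.beta.junction_nt == expected
    va = db.get("alpha", "V", clone.alpha.v_gene)
    ja = db.get("alpha", "J", clone.alpha.j_gene)
    assert clone.alpha.junction_nt == (
        va.nt_sequence[va.anchor_offset :] + ja.nt_sequence[: ja.anchor_offset + 3]
    )


def test_junction_anchors_and_productivity(db):
    clones = simulate_repertoire(db, SimParams(n_clones=100, seed=5))
    aas = set()
    for c in clones:
        for chain in (c.alpha, c.beta):
            aa = translate(chain.junction_nt)
            assert len(chain.junction_nt) % 3 == 0
            assert aa.startswith("C")
            assert aa[-1] in "FW"
            assert "*" not in aa
        aas.add(c.beta.junction_aa)
    assert len(aas) == 100  # CDR3β distinct at the aa level
    assert math.isclose(sum(c.abundance for c in clones), 1.0, abs_tol=1e-9)


def test_repertoire_deterministic_for_fixed_seed(db):
    p = SimParams(n_clones=50, seed=7)
    a = simulate_repertoire(db, p)
    b = simulate_repertoire(db, p)
    assert a == b


def test_uniform_abundance_limit(db):
    clones = simulate_repertoire(db, SimParams(n_clones=4, abundance_exponent=0.0, seed=1))
    assert [c.abundance for c in clones] == [0.25] * 4


def test_linked_amplicon_is_concatenation():
    assert build_linked_amplicon("AAA", "CCC", "GGG") == "CCCGGGAAA"
    assert build_linked_amplicon("AAA", "CCC", "GGG", "alpha_first") == "AAAGGGCCC"


def test_linked_amplicon_requires_linker():
    with pytest.raises(SimulationError):
        build_linked_amplicon("AAA", "CCC", "")


def test_linker_without_swap_sites_warns(caplog):
    with caplog.at_level(logging.WARNING, logger="tcrscreen.sim"):
        build_linked_amplicon("AAA", "CCC", "GGGGGG")
    assert any("MluI" in r.message for r in caplog.records)


def test_amplicon_length_adds_up(db):
    (clone,) = simulate_repertoire(db, SimParams(n_clones=1, seed=3))
    linker = "ACTAGTACGCGT"
    amp = build_linked_amplicon(clone.alpha.full_nt, clone.beta.full_nt, linker)
    assert len(amp) == len(clone.alpha.full_nt) + len(clone.beta.full_nt) + len(linker)


@pytest.mark.parametrize("rate", [1.0, 0.5])
def test_chimera_fraction_matches_closed_form(db, rate):
    """Observed mispair fraction ≈ rate · (1 − Σ abundance²) within 3 SDs."""
    params = SimParams(
        n_clones=30, depth=10_000, seed=13,
        chimera_rate=rate, suppression_on=False,
    )
    clones = simulate_repertoire(db, params)
    pool = sample_amplicon_pool(clones, params)
    p_exp = rate * (1.0 - sum(c.abundance**2 for c in clones))
    observed = sum(r.mispaired for r in pool) / len(pool)
    sd = math.sqrt(p_exp * (1 - p_exp) / len(pool))
    assert abs(observed - p_exp) <= 3 * sd


def test_suppression_with_zero_residual_eliminates_mispairing(db):
    params = SimParams(
        n_clones=20, depth=2000, seed=2,
        chimera_rate=0.9, suppression_on=True, residual_chimera_rate=0.0,
    )
    clones = simulate_repertoire(db, params)
    pool = sample_amplicon_pool(clones, params)
    assert sum(r.mispaired for r in pool) == 0


def test_sort_counts_conserve_depth(db):
    clones = simulate_repertoire(db, SimParams(n_clones=40, seed=9))
    spec = SortSpec(specific_clone_ids=frozenset({5, 10}))
    presort, sorted_counts = simulate_sort(clones, spec, depth=5000, seed=9)
    assert sum(presort.values()) == 5000
    assert sum(sorted_counts.values()) == 5000


def test_sort_zero_depth_gives_empty_tables(db):
    clones = simulate_repertoire(db, SimParams(n_clones=5, seed=9))
    presort, sorted_counts = simulate_sort(
        clones, SortSpec(specific_clone_ids=frozenset({0})), depth=0, seed=1
    )
    assert presort == {} and sorted_counts == {}


def test_sorted_frequency_matches_renormalization(db):
    """One specific clone at known abundance: empirical sorted frequency falls
    within 3 binomial SDs of a·F / (a·F + (1−a)·B)."""
    clones = simulate_repertoire(
        db, SimParams(n_clones=60, abundance_exponent=1.0, seed=21)
    )
    target = clones[10]
    spec = SortSpec(specific_clone_ids=frozenset({target.clone_id}),
                    activation_factor=25.0, background_rate=1.0)
    depth = 50_000
    _, sorted_counts = simulate_sort(clones, spec, depth, seed=21)
    p_exp = expected_sorted_freq(clones, spec)[target.clone_id]
    observed = sorted_counts.get(target.clone_id, 0) / depth
    sd = math.sqrt(p_exp * (1 - p_exp) / depth)
    assert abs(observed - p_exp) <= 3 * sd


def test_fastq_deterministic_and_well_formed(db, tmp_path):
    params = SimParams(n_clones=10, depth=100, seed=17)
    clones = simulate_repertoire(db, params)
    pool = sample_amplicon_pool(clones, params)
    paths1 = write_fastq(pool, params, "paired_linked", tmp_path / "a")
    paths2 = write_fastq(pool, params, "paired_linked", tmp_path / "b")
    assert paths1[0].read_bytes() == paths2[0].read_bytes()
    assert paths1[1].read_bytes() == paths2[1].read_bytes()
    r1 = list(read_fastq(paths1[0], "1"))
    r2 = list(read_fastq(paths1[1], "2"))
    assert len(r1) == len(r2) == 100
    assert all(len(r.seq) == params.read_length for r in r1)


def test_r2_is_revcomp_of_amplicon_tail(db, tmp_path):
    params = SimParams(n_clones=3, depth=10, seed=4, error_profile=90)
    clones = simulate_repertoire(db, params)
    pool = sample_amplicon_pool(clones, params)
    paths = write_fastq(pool, params, "paired_linked", tmp_path / "x")
    by_id = {r.read_id: r for r in read_fastq(paths[1], "2")}
    for rec in pool:
        assert by_id[rec.read_id].seq == revcomp(rec.amplicon[-params.read_length :])


def test_error_rate_tracks_phred(db, tmp_path):
    """At Q40 (p = 1e-4) > 99.99% of emitted bases match the truth over ~1e5."""
    params = SimParams(n_clones=20, depth=250, seed=6, error_profile=40)
    clones = simulate_repertoire(db, params)
    pool = sample_amplicon_pool(clones, params)
    paths = write_fastq(pool, params, "paired_linked", tmp_path / "q")
    truth = {r.read_id: r.amplicon for r in pool}
    n_bases = n_errors = 0
    for read in read_fastq(paths[0], "1"):
        t = truth[read.read_id][: params.read_length]
        n_bases += len(t)
        n_errors += sum(a != b for a, b in zip(read.seq, t))
    assert n_bases >= 7.0e4
    # mean 1e-4·n ≈ 7.5; 3 binomial SDs above the mean
    lam = 1e-4 * n_bases
    assert n_errors <= lam + 3 * math.sqrt(lam)


def test_q0_profile_writes_bang_qualities(db, tmp_path):
    params = SimParams(n_clones=2, depth=5, seed=8, error_profile=0)
    clones = simulate_repertoire(db, params)
    pool = sample_amplicon_pool(clones, params)
    paths = write_fastq(pool, params, "beta_only", tmp_path / "z")
    with open(paths[0]) as fh:
        lines = fh.read().splitlines()
    quals = lines[3::4]
    assert all(set(q) == {"!"} for q in quals)


def test_mispair_reduction_under_suppression(db):
    """Suppression reduces the non-native pair fraction >= 10-fold."""
    base = dict(n_clones=30, depth=10_000, seed=15, chimera_rate=0.9,
                residual_chimera_rate=0.02)
    clones = simulate_repertoire(db, SimParams(suppression_on=False, **base))
    off = sample_amplicon_pool(clones, SimParams(suppression_on=False, **base))
    on = sample_amplicon_pool(clones, SimParams(suppression_on=True, **base))
    f_off = sum(r.mispaired for r in off) / len(off)
    f_on = sum(r.mispaired for r in on) / len(on)
    assert f_off >= 10 * f_on
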