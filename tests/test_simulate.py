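"""Generative model of the engineered-depletion screen and the detection
evaluator, checked against closed-form expectations and brute-force sweeps."""

import numpy as np
import pandas as pd
import pytest

from shscreen import (
    SimConfig,
    SimTruth,
    align_reads,
    emit_fastq,
    evaluate_detection,
    make_depletion_design,
    random_library,
    read_fastq,
    simulate_screen,
    subsample_counts,
)


def test_same_seed_reproduces_everything():
    design = make_depletion_design(500, [(50, 0.5)], seed=9)
    cfg = SimConfig(n_hairpins=500, depletion_design=design,
                    reads_per_sample=100_000, n_replicates=2, seed=9)
    t1, c1, s1 = simulate_screen(cfg)
    t2, c2, s2 = simulate_screen(cfg)
    assert t1.table.equals(t2.table)
    assert c1.equals(c2)
    assert s1.equals(s2)


def test_adding_replicates_preserves_earlier_samples():
    design = make_depletion_design(300, [(30, 0.5)], seed=2)
    base = dict(n_hairpins=300, depletion_design=design, reads_per_sample=60_000, seed=2)
    _, c1, _ = simulate_screen(SimConfig(n_replicates=1, **base))
    _, c3, _ = simulate_screen(SimConfig(n_replicates=3, **base))
    assert c3[c1.columns].equals(c1)


def test_null_and_depleted_count_ratios_match_expectation():
    # null: test/ref -> 1; d=0.5 group mean ratio -> 0.5, noise-free
    design = make_depletion_design(2000, [(200, 0.5)], seed=3)
    cfg = SimConfig(n_hairpins=2000, depletion_design=design, noise_sigma=0.0,
                    reads_per_sample=20_000_000, seed=3)
    truth, counts, _ = simulate_screen(cfg)
    ratio = counts["test_1"] / counts["ref_1"]
    d = truth.table["d"]
    renorm = 1 / (truth.table["p"] @ d)  # test arm renormalization
    null_mean = ratio[d == 1].mean()
    assert null_mean == pytest.approx(renorm, rel=0.01)
    grp = ratio[d == 0.5] / renorm
    assert grp.mean() == pytest.approx(0.5, abs=3 * grp.std() / np.sqrt(len(grp)))


def test_design_validation():
    with pytest.raises(ValueError, match="unknown hairpins"):
        simulate_screen(SimConfig(n_hairpins=100, reads_per_sample=1000,
                                  depletion_design={"nope": 0.5}))
    with pytest.raises(ValueError, match="retention"):
        SimConfig(n_hairpins=100, reads_per_sample=1000,
                  depletion_design={"h001": 0.0})
    with pytest.raises(ValueError, match="more hairpins"):
        make_depletion_design(10, [(20, 0.5)])


def test_subsample_identity_and_thinning_moments():
    rng = np.random.default_rng(4)
    lam = 400.0
    counts = pd.DataFrame({"s": rng.poisson(lam, 20000)})
    assert subsample_counts(counts, 1.0, seed=1).equals(counts)
    half = subsample_counts(counts, 0.5, seed=1)["s"]
    # thinned Poisson(400) at 0.5 is Poisson(200): mean ~ var ~ 200
    se = np.sqrt(lam / 2 / len(half))
    assert half.mean() == pytest.approx(lam / 2, abs=3 * se)
    assert half.var() == pytest.approx(lam / 2, rel=0.05)
    quarter = subsample_counts(counts, 0.25, seed=2)["s"]
    tot_se = np.sqrt((counts["s"] * 0.25 * 0.75).sum())
    assert quarter.sum() == pytest.approx(0.25 * counts["s"].sum(), abs=3 * tot_se)


def test_thinning_composition_matches_single_step():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame({"s": rng.poisson(1000, 20000)})
    two_step = subsample_counts(subsample_counts(counts, 0.8, seed=1), 0.5, seed=2)["s"]
    one_step = subsample_counts(counts, 0.4, seed=3)["s"]
    for a, b in ((two_step, one_step),):
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert a.mean() - b.mean() == pytest.approx(0, abs=3 * se)
        assert a.var() == pytest.approx(b.var(), rel=0.06)


def test_fastq_round_trip_error_free():
    lib = random_library(60, seed=6)
    cfg = SimConfig(n_hairpins=60, reads_per_sample=6000, read_error_rate=0.0,
                    n_rate=0.0, noise_sigma=0.0, seed=6)
    truth, _, _ = simulate_screen(SimConfig(n_hairpins=60, reads_per_sample=6000, seed=6))
    import tempfile, os
    with tempfile.TemporaryDirectory() as td:
        path = os.path.join(td, "s.fq")
        n_emitted = emit_fastq(truth, lib, cfg, "ref_1", path)
        tally = align_reads(read_fastq(path), lib)
    assert tally.total_reads == n_emitted.sum()
    assert tally.unique_reads == tally.total_reads  # every read at distance 0
    assert tally.unique_by_distance() == {0: tally.total_reads, 1: 0, 2: 0}
    recovered = tally.total_counts(lib)
    assert (recovered.to_numpy() == n_emitted).all()


def test_fastq_counts_track_truth_fractions():
    lib = random_library(100, seed=7)
    cfg = SimConfig(n_hairpins=100, reads_per_sample=100_000, noise_sigma=0.0,
                    read_error_rate=0.005, n_rate=0.001, seed=7)
    truth, _, _ = simulate_screen(SimConfig(n_hairpins=100, reads_per_sample=100_000, seed=7))
    import tempfile, os
    with tempfile.TemporaryDirectory() as td:
        path = os.path.join(td, "s.fq")
        emit_fastq(truth, lib, cfg, "ref_1", path)
        tally = align_reads(read_fastq(path), lib)
    frac = tally.total_counts(lib) / tally.unique_reads
    p = truth.table["p"]
    se = np.sqrt(p * (1 - p) / tally.unique_reads)
    assert (np.abs(frac - p) <= 4 * se + 1e-4).all()


# ---------------------------------------------------------------------------
# evaluator
# ---------------------------------------------------------------------------

def _truth_from(ids, d):
    n = len(ids)
    return SimTruth(pd.DataFrame({"p": np.full(n, 1 / n), "d": d},
                                 index=pd.Index(ids, name="construct_id")))


def test_evaluator_separable_and_degenerate_cases():
    ids = [f"h{i}" for i in range(100)]
    d = np.where(np.arange(100) < 20, 0.5, 1.0)
    truth = _truth_from(ids, d)
    sep = pd.Series(np.where(d < 1, -10.0, 0.0) + np.arange(100) * 1e-4, index=ids)
    res = evaluate_detection(sep, truth)
    assert res.fnr_at_zero_fpr[0.5] == 0.0
    assert res.fpr_at_fnr5[0.5] == 0.0
    # depleted scores identical to nulls: nothing separable
    res2 = evaluate_detection(pd.Series(np.zeros(100), index=ids), truth)
    assert res2.fnr_at_zero_fpr[0.5] == 1.0


def test_evaluator_matches_bruteforce_threshold_sweep():
    ids = [f"h{i}" for i in range(10)]
    d = np.array([0.5] * 4 + [1.0] * 6)
    scores = pd.Series([-5.0, -3.0, -1.5, -0.5, -2.0, -1.0, 0.0, 0.5, 1.0, 2.0],
                       index=ids)
    truth = _truth_from(ids, d)
    res = evaluate_detection(scores, truth)

    grp = scores[:4].to_numpy()
    null = scores[4:].to_numpy()
    # brute force: enumerate every candidate threshold (call = score < t)
    best_fnr = 1.0
    for t in np.concatenate([scores.to_numpy(), [-np.inf, np.inf]]):
        fpr = (null < t).mean()
        fnr = (grp >= t).mean()
        if fpr == 0:
            best_fnr = min(best_fnr, fnr)
    assert res.fnr_at_zero_fpr[0.5] == best_fnr == 0.5
    best_fpr = 1.0
    for t in np.concatenate([scores.to_numpy(), [np.inf]]):
        if (grp > t).mean() <= 0.05:
            best_fpr = min(best_fpr, (null <= t).mean())
    assert res.fpr_at_fnr5[0.5] == best_fpr == pytest.approx(1 / 3)


def test_roc_is_monotone():
    rng = np.random.default_rng(8)
    ids = [f"h{i}" for i in range(500)]
    d = np.where(np.arange(500) < 100, 0.5, 1.0)
    scores = pd.Series(np.where(d < 1, rng.normal(-2, 1, 500), rng.normal(0, 1, 500)),
                       index=ids)
    res = evaluate_detection(scores, _truth_from(ids, d))
    assert (np.diff(res.roc["fpr"]) >= 0).all()
    assert (np.diff(res.roc["fnr"]) <= 0).all()


def test_evaluator_mean_ratio_and_r2_plumbing():
    design = make_depletion_design(1000, [(100, 0.25)], seed=10)
    cfg = SimConfig(n_hairpins=1000, depletion_design=design,
                    reads_per_sample=1_000_000, n_replicates=2, seed=10)
    truth, counts, sheet = simulate_screen(cfg)
    l2 = np.log2(counts + 0.5)
    m1 = l2["test_1"] - l2["ref_1"]
    m2 = l2["test_2"] - l2["ref_2"]
    res = evaluate_detection(m1, truth, counts=counts, sheet=sheet,
                             replicate_scores=pd.DataFrame({"1": m1, "2": m2}))
    assert res.mean_ratio[0.25] == pytest.approx(0.25 / (truth.table["p"] @ truth.table["d"]),
                                                 rel=0.1)
    assert 0 < res.replicate_r2 <= 1
    with pytest.raises(ValueError, match="no depleted"):
        evaluate_detection(m1, _truth_from(list(counts.index), np.ones(1000)))
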