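"""Moderated differential accessibility: consolidation, normalization,
empirical-Bayes limits, BH, set calling, nested contrasts, directionality."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from epicontext import diffacc
from epicontext.genomic_core import RegionSet
from epicontext.synthetic_data import SimConfig, simulate_accessibility
from oracles import bh_textbook, bitmap


# ---------------------------------------------------------------------------
# consolidate_peaks
# ---------------------------------------------------------------------------


def _rs(*ivs):
    return RegionSet.from_intervals(list(ivs))


def test_consolidate_min_support_one_is_merged_union():
    peaks = {("t1", "adult"): [_rs(("c1", 0, 10)), _rs(("c1", 5, 20))]}
    out = diffacc.consolidate_peaks(peaks, min_support=1)
    assert out.df[["chrom", "start", "end"]].values.tolist() == [["c1", 0, 20]]


def test_consolidate_drops_unsupported_peak():
    peaks = {
        ("t1", "adult"): [
            _rs(("c1", 0, 10), ("c1", 100, 120)),
            _rs(("c1", 0, 10)),
            _rs(("c1", 0, 10)),
        ]
    }
    out = diffacc.consolidate_peaks(peaks, min_support=2)
    assert out.df[["chrom", "start", "end"]].values.tolist() == [["c1", 0, 10]]


def test_consolidate_unions_across_groups():
    peaks = {
        ("t1", "adult"): [_rs(("c1", 0, 10)), _rs(("c1", 0, 10))],
        ("t1", "fetal"): [_rs(("c1", 8, 30)), _rs(("c1", 8, 30))],
    }
    out = diffacc.consolidate_peaks(peaks, min_support=2)
    assert out.df[["chrom", "start", "end"]].values.tolist() == [["c1", 0, 30]]


def test_consolidate_matches_per_bp_support_oracle(rng):
    genome = {"c1": 5000}
    groups = {}
    for g in range(3):
        reps = []
        for _ in range(4):
            rows = []
            for _ in range(10):
                s = int(rng.integers(0, 4900))
                rows.append(("c1", s, s + int(rng.integers(10, 100))))
            reps.append(RegionSet.from_intervals(rows))
        groups[(f"t{g}", "adult")] = reps
    min_support = 2
    out = diffacc.consolidate_peaks(groups, min_support=min_support)
    # oracle: per-bp replicate support within each group, then union
    keep = np.zeros(5000, dtype=bool)
    for reps in groups.values():
        depth = np.zeros(5000, dtype=int)
        for rep in reps:
            depth += bitmap(
                rep.df[["chrom", "start", "end"]].values.tolist(), genome
            )["c1"].astype(int)
        keep |= depth >= min_support
    got = bitmap(out.df[["chrom", "start", "end"]].values.tolist(), genome)["c1"]
    assert (got == keep).all()


def test_consolidate_empty_input_raises():
    with pytest.raises(ValueError):
        diffacc.consolidate_peaks({})


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_constant_counts_equal_libraries():
    counts = pd.DataFrame(np.full((10, 4), 50))
    logmat, w = diffacc.normalize_counts(counts)
    assert w is None
    assert np.allclose(logmat.to_numpy(), logmat.iloc[0, 0])


def test_normalize_library_scaling_law():
    """Doubling one sample's library halves its cpm (one log2 unit),
    up to the pseudocount."""
    counts = pd.DataFrame({"a": [100, 900], "b": [200, 1800]})
    logmat, _ = diffacc.normalize_counts(counts, pseudocount=0)
    assert np.allclose(logmat["a"], logmat["b"])
    counts2 = pd.DataFrame({"a": [100, 900], "b": [100, 1900]})
    logmat2, _ = diffacc.normalize_counts(counts2, pseudocount=0)
    assert logmat2.loc[0, "b"] < logmat2.loc[0, "a"]


def test_normalize_rejects_zero_library():
    counts = pd.DataFrame({"a": [0, 0], "b": [1, 2]})
    with pytest.raises(ValueError):
        diffacc.normalize_counts(counts)


def test_precision_weights_follow_refit_trend(rng):
    """Weights equal the lowess trend evaluated at each row mean, to the -4
    power (refit oracle)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.05, size=(200, 6)), columns=list("abcdef")
    )
    logmat, w = diffacc.normalize_counts(counts, weights=True)
    mean = logmat.mean(axis=1).to_numpy()
    sd = logmat.std(axis=1, ddof=1).to_numpy()
    trend = lowess(np.sqrt(np.clip(sd, 1e-8, None)), mean, frac=0.5,
                   return_sorted=False)
    expected = np.clip(trend, 1e-4, None) ** -4
    assert np.allclose(w.iloc[:, 0].to_numpy(), expected)
    assert (w.nunique(axis=1) == 1).all()  # one weight per region


# ---------------------------------------------------------------------------
# moderated fit
# ---------------------------------------------------------------------------


def _toy_fit_inputs(rng, n_regions=120, n=8):
    Y = pd.DataFrame(
        rng.normal(0, 1, size=(n_regions, n)) * rng.gamma(3, 0.4, (n_regions, 1)),
        index=[f"r{i}" for i in range(n_regions)],
    )
    X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
    return Y, X


def test_moderated_t_no_shrinkage_limit_equals_ordinary_t(rng):
    """d0 = 0 reduces exactly to the per-region ordinary t-test."""
    from scipy import stats

    Y, X = _toy_fit_inputs(rng)
    res = diffacc.moderated_fit(Y, X, d0_override=0.0)
    n = X.shape[0]
    g1 = Y.iloc[:, : n // 2].to_numpy()
    g2 = Y.iloc[:, n // 2:].to_numpy()
    t_ref, p_ref = stats.ttest_ind(g2, g1, axis=1)
    assert np.allclose(res["t"], t_ref, rtol=1e-8)
    assert np.allclose(res["p"], p_ref, rtol=1e-8)


def test_moderated_t_infinite_prior_limit_is_pooled_variance_t(rng):
    """d0 -> inf with fixed s0^2 replaces every residual variance by s0^2."""
    Y, X = _toy_fit_inputs(rng)
    s0 = 0.7
    res = diffacc.moderated_fit(Y, X, d0_override=np.inf, s0_sq_override=s0)
    xtx_inv = np.linalg.inv(X.T @ X)
    su = np.sqrt(xtx_inv[1, 1])
    expected_t = res["log2fc"] / (su * np.sqrt(s0))
    assert np.allclose(res["t"], expected_t, rtol=1e-8)


def test_moderated_fit_matches_reference_implementation(tmp_path, rng):
    """Dual-route check against the Bioconductor empirical-Bayes fit."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable: reference cross-check cannot run")
    Y, X = _toy_fit_inputs(rng, n_regions=150, n=10)
    Y.to_csv(tmp_path / "y.tsv", sep="\t")
    pd.DataFrame(X).to_csv(tmp_path / "x.tsv", sep="\t", index=False)
    script = f"""
    suppressMessages(library(limma))
    y <- as.matrix(read.delim("{tmp_path}/y.tsv", row.names=1))
    x <- as.matrix(read.delim("{tmp_path}/x.tsv"))
    fit <- eBayes(lmFit(y, x))
    out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
    write.table(out, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE)
    cat(fit$df.prior, fit$s2.prior)
    """
    r = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert r.returncode == 0, r.stderr
    d0_ref, s0_ref = map(float, r.stdout.split())
    ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
    res = diffacc.moderated_fit(Y, X)
    assert res.attrs["d0"] == pytest.approx(d0_ref, rel=1e-6)
    assert res.attrs["s0_sq"] == pytest.approx(s0_ref, rel=1e-6)
    assert np.allclose(res["t"], ref["t"], rtol=1e-8, atol=1e-10)
    assert np.allclose(res["p"], ref["p"], rtol=1e-8, atol=1e-12)


def test_moderated_fit_rejects_bad_designs(rng):
    Y, X = _toy_fit_inputs(rng)
    with pytest.raises(ValueError):
        diffacc.moderated_fit(Y, np.column_stack([X, X[:, 1]]))
    Yc = Y.copy()
    Yc.iloc[0] = 3.0
    with pytest.raises(ValueError):
        diffacc.moderated_fit(Yc, X)


def test_null_simulation_p_uniform_and_unbiased(rng):
    """Global-null fit: p-values uniform (KS), log2fc unbiased."""
    from scipy import stats

    Y, X = _toy_fit_inputs(rng, n_regions=500)
    res = diffacc.moderated_fit(Y, X)
    assert stats.kstest(res["p"], "uniform").pvalue > 1e-3
    se = res["log2fc"].std() / np.sqrt(len(res))
    assert abs(res["log2fc"].mean()) < 4 * se


def test_calls_invariant_to_row_and_column_order(rng):
    cfg = SimConfig(seed=21, n_regions=80, n_variants=100, n_genes=20)
    counts, meta, regions, truth = simulate_accessibility(cfg)
    res1 = diffacc.differential_accessibility(counts, meta)
    perm_rows = rng.permutation(counts.index)
    perm_cols = rng.permutation(counts.columns)
    res2 = diffacc.differential_accessibility(
        counts.loc[perm_rows, perm_cols], meta
    )
    pd.testing.assert_frame_equal(res1, res2.loc[res1.index], check_like=True)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------


def test_bh_matches_textbook_definition_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(5):
        p = rng.uniform(size=40)
        got = diffacc.bh_adjust(p)
        assert np.allclose(got, bh_textbook(p))
        assert np.allclose(got, multipletests(p, method="fdr_bh")[1])
    # monotone in p
    p = np.sort(rng.uniform(size=30))
    assert (np.diff(diffacc.bh_adjust(p)) >= -1e-12).all()


# ---------------------------------------------------------------------------
# set calling / nested / directionality
# ---------------------------------------------------------------------------


def test_call_stage_sets_rules(sim):
    res = diffacc.differential_accessibility(sim.counts, sim.meta)
    empty_a, empty_f = diffacc.call_stage_sets(res, sim.regions, fdr_cut=0.0)
    assert len(empty_a) == 0 and len(empty_f) == 0
    fake = pd.DataFrame(
        {"fdr": [0.04, 0.04, 0.2], "log2fc": [1.0, -1.0, 5.0]},
        index=sim.regions.df["name"][:3],
    )
    a, f = diffacc.call_stage_sets(fake, sim.regions, fdr_cut=0.05)
    assert list(a.df["name"]) == [fake.index[0]]
    assert list(f.df["name"]) == [fake.index[1]]


def test_planted_regions_recovered(sim):
    res = diffacc.differential_accessibility(sim.counts, sim.meta)
    a, f = diffacc.call_stage_sets(res, sim.regions)
    called = set(a.df["name"]) | set(f.df["name"])
    truth = set(sim.truth.region_ids("adult")) | set(sim.truth.region_ids("fetal"))
    m = diffacc.recovery_metrics(called, truth, res.index)
    assert m["sensitivity"] >= 0.8
    assert m["empirical_fdr"] <= 0.15
    # directions match the planted classes
    assert set(a.df["name"]) <= set(res.index)
    adult_called_true = set(a.df["name"]) & set(sim.truth.region_ids("adult"))
    assert len(adult_called_true) / len(sim.truth.region_ids("adult")) >= 0.8


def test_age_split_boundary():
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "tissue": ["t"] * 3,
            "stage": ["adult"] * 3,
            "age": [49.0, 51.0, 50.0],
            "replicate": [1, 2, 3],
        }
    )
    out = diffacc.split_age_groups(meta, age_split=50)
    assert out["age_group"].tolist() == ["young", "old", "old"]


def test_nested_contrast_recovers_planted_age_shifts(sim):
    res = diffacc.differential_accessibility(sim.counts, sim.meta)
    a, f = diffacc.call_stage_sets(res, sim.regions)
    dev = list(a.df["name"]) + list(f.df["name"])
    age_res = diffacc.nested_age_contrast(sim.counts, sim.meta, dev)
    truth_age = set(sim.truth.nested_ids("old")) | set(sim.truth.nested_ids("young"))
    called = set(age_res.index[age_res["fdr"] < 0.05])
    overlap = called & truth_age
    assert len(overlap) / max(1, len(truth_age & set(dev))) >= 0.7
    with pytest.raises(ValueError):
        diffacc.nested_age_contrast(sim.counts, sim.meta, [])


def test_nested_contrast_requires_both_age_groups(sim):
    meta = sim.meta.copy()
    meta.loc[meta["stage"] == "adult", "age"] = 30.0
    with pytest.raises(ValueError):
        diffacc.nested_age_contrast(sim.counts, meta, list(sim.counts.index[:10]))


def test_directionality_hand_computed_values():
    """[[50,0],[0,50]] gives chi-square 100 plain, 96.04 with Yates."""
    dev = pd.Series([1] * 50 + [-1] * 50)
    age = pd.Series([1] * 50 + [-1] * 50)
    plain = diffacc.directionality_test(dev, age, yates=False)
    assert plain["statistic"] == pytest.approx(100.0)
    corrected = diffacc.directionality_test(dev, age, yates=True)
    assert corrected["statistic"] == pytest.approx(96.04)


def test_directionality_independent_table_near_zero():
    dev = pd.Series([1, 1, -1, -1] * 25)
    age = pd.Series([1, -1, 1, -1] * 25)
    out = diffacc.directionality_test(dev, age)
    assert out["statistic"] == pytest.approx(0.0, abs=1e-9)


def test_directionality_zero_margin_flagged():
    dev = pd.Series([1, 1, 1])
    age = pd.Series([1, -1, 1])
    out = diffacc.directionality_test(dev, age)
    assert out["statistic"] is None and out["reason"]


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def test_promoter_window_coordinates():
    genes = pd.DataFrame({"gene": ["g"], "chrom": ["c1"], "tss": [5000]})
    rs = diffacc.promoter_windows(genes, pad=1000)
    assert rs.df[["start", "end"]].values.tolist() == [[4000, 6000]]
    near_edge = pd.DataFrame({"gene": ["g"], "chrom": ["c1"], "tss": [300]})
    rs2 = diffacc.promoter_windows(near_edge, pad=1000, genome={"c1": 1000})
    assert rs2.df[["start", "end"]].values.tolist() == [[0, 1000]]
    with pytest.raises(ValueError):
        diffacc.promoter_windows(
            pd.DataFrame({"gene": ["g"], "chrom": ["c1"], "tss": [np.nan]})
        )
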