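"""Conservation averaging, rank tests, permutation enrichment, variant
density and distribution-shift tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicontext import evo
from epicontext.genomic_core import RegionSet, ScoreTrack
from oracles import mann_whitney_exact_p, mann_whitney_u_bruteforce

GENOME = {"c1": 10_000}


def make_track(rows):
    return ScoreTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))


# ---------------------------------------------------------------------------
# region_conservation
# ---------------------------------------------------------------------------


def test_constant_track_gives_constant_means():
    track = make_track([("c1", 0, 10_000, 2.5)])
    regions = RegionSet.from_intervals([("c1", 0, 100, "a"), ("c1", 500, 900, "b")])
    out = evo.region_conservation(regions, track, GENOME)
    assert np.allclose(out["mean_score"], 2.5)
    assert np.allclose(out["coverage"], 1.0)


def test_half_and_half_region_averages():
    track = make_track([("c1", 0, 50, 0.0), ("c1", 50, 100, 1.0)])
    regions = RegionSet.from_intervals([("c1", 0, 100, "r")])
    out = evo.region_conservation(regions, track, GENOME)
    assert out.loc["r", "mean_score"] == pytest.approx(0.5)


def test_uncovered_region_reported_missing():
    track = make_track([("c1", 0, 50, 1.0)])
    regions = RegionSet.from_intervals([("c1", 0, 40, "a"), ("c1", 60, 80, "b"),
                                        ("c1", 40, 70, "c")])
    out = evo.region_conservation(regions, track, GENOME)
    assert np.isnan(out.loc["b", "mean_score"]) and out.loc["b", "coverage"] == 0
    assert out.loc["c", "coverage"] == pytest.approx(10 / 30)


def test_region_conservation_matches_per_bp_loop(rng):
    rows = []
    for s in range(0, 2000, 10):
        if rng.random() < 0.7:
            rows.append(("c1", s, s + 10, float(rng.normal())))
    track = make_track(rows)
    regions = RegionSet.from_intervals(
        [("c1", int(s), int(s) + 150, f"r{s}") for s in rng.integers(0, 1800, 20)]
    )
    out = evo.region_conservation(regions, track, GENOME)
    for row in regions.df.itertuples(index=False):
        vals = [track.value_at("c1", p) for p in range(row.start, row.end)]
        vals = [v for v in vals if not np.isnan(v)]
        expect = np.mean(vals) if vals else np.nan
        got = out.loc[row.name, "mean_score"]
        assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(expect)


# ---------------------------------------------------------------------------
# compare_sets
# ---------------------------------------------------------------------------


def test_compare_sets_matches_bruteforce_pair_counting(rng):
    a = rng.normal(size=20).round(1)  # rounding forces ties
    b = rng.normal(size=15).round(1)
    res = evo.compare_sets(a, b)
    assert res["U"] == pytest.approx(mann_whitney_u_bruteforce(a, b))
    assert res["effect_size"] == pytest.approx(res["U"] / (20 * 15))


def test_compare_sets_matches_exact_enumeration(rng):
    a = rng.normal(size=5)
    b = rng.normal(size=4)
    res = evo.compare_sets(a, b)
    assert res["p"] == pytest.approx(mann_whitney_exact_p(a, b), abs=1e-9)


def test_compare_sets_detects_shift(rng):
    base = rng.normal(size=200)
    res = evo.compare_sets(base + 1.0, base)
    assert res["p"] < 1e-6
    assert res["effect_size"] > 0.5
    with pytest.raises(ValueError):
        evo.compare_sets([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# feature_enrichment
# ---------------------------------------------------------------------------


def test_enrichment_fold_is_one_when_feature_is_genome(rng):
    target = RegionSet.from_intervals(
        [("c1", int(s), int(s) + 50) for s in rng.integers(0, 9000, 10)],
        label="adult_biased",
    )
    genome_feature = RegionSet.from_intervals([("c1", 0, 10_000)])
    res = evo.feature_enrichment(target, genome_feature, GENOME, n_perm=20, seed=1)
    assert res.fold == 1.0
    assert res.observed_per_bp == 1.0


def test_enrichment_empirical_p_lower_bound():
    target = RegionSet.from_intervals([("c1", 0, 100)])
    feature = RegionSet.from_intervals([("c1", 0, 100)])
    res = evo.feature_enrichment(target, feature, GENOME, n_perm=99, seed=2)
    assert res.empirical_p >= 1 / 100
    with pytest.raises(ValueError):
        evo.feature_enrichment(target, feature, GENOME, n_perm=0)


def test_enrichment_fold_matches_analytic_expectation(rng):
    """Target inside a feature covering 10% of the genome: fold ~= 10."""
    genome = {"c1": 100_000}
    feature = RegionSet.from_intervals([("c1", 0, 10_000)])
    target = RegionSet.from_intervals(
        [("c1", int(s), int(s) + 100) for s in rng.integers(0, 9_900, 20)]
    )
    res = evo.feature_enrichment(target, feature, genome, n_perm=300, seed=3)
    assert res.observed_per_bp == 1.0
    assert res.fold == pytest.approx(10.0, rel=0.15)
    assert res.empirical_p <= 2 / 301 * 2


# ---------------------------------------------------------------------------
# variant_density
# ---------------------------------------------------------------------------


def variant_frame(rng, n, genome=GENOME):
    chroms = list(genome)
    return pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(n)],
            "chrom": rng.choice(chroms, size=n),
            "pos": rng.integers(0, min(genome.values()), size=n),
            "maf": rng.uniform(0, 0.5, size=n),
        }
    )


def test_variant_density_maf_threshold(rng):
    target = RegionSet.from_intervals([("c1", 0, 1000)])
    variants = pd.DataFrame(
        {
            "id": ["a", "b"],
            "chrom": ["c1", "c1"],
            "pos": [10, 20],
            "maf": [0.049, 0.05],
        }
    )
    res = evo.variant_density(target, variants, GENOME, maf_cut=0.05, n_perm=5, seed=1)
    assert res["n_common"] == 1  # 0.049 excluded at the >= 0.05 rule
    assert res["density_per_bp"] == pytest.approx(1 / 1000)


def test_variant_density_no_variants(rng):
    target = RegionSet.from_intervals([("c1", 0, 1000)])
    empty = variant_frame(rng, 0)
    res = evo.variant_density(target, empty, GENOME, n_perm=5, seed=1)
    assert res["density_per_bp"] == 0.0


def test_uniform_variants_density_covered_by_null(rng):
    variants = variant_frame(rng, 2000)
    target = RegionSet.from_intervals(
        [("c1", int(s), int(s) + 200) for s in rng.integers(0, 9000, 8)]
    )
    res = evo.variant_density(target, variants, GENOME, maf_cut=0.0, n_perm=200, seed=4)
    lam = 2000 / 10_000
    assert res["density_per_bp"] == pytest.approx(lam, rel=0.35)
    assert res["null_ci"][0] <= res["density_per_bp"] <= res["null_ci"][1]


# ---------------------------------------------------------------------------
# variant profiles
# ---------------------------------------------------------------------------


def test_profile_annotation_and_planted_contrast(sim):
    tsets = sim.truth_region_sets()
    prof = evo.annotate_variant_profiles(
        sim.variants, sim.conserved_elements, tsets, window=sim.cfg.proximity_window
    )
    out = evo.variant_profile_contrast(prof, metrics=("allele_age", "functional_score"))
    means = out["functional_score"]["group_means"]
    assert means["fetal_biased"] > means["adult_biased"]
    # conserved variants are younger by construction
    strat = evo.conserved_stratification(
        prof.rename(columns={"allele_age": "z_cross"}), metric="z_cross"
    )
    assert strat["mean_inside"] < strat["mean_outside"]
    assert strat["p"] < 1e-3


def test_profile_membership_matches_bruteforce(sim):
    prof = evo.annotate_variant_profiles(
        sim.variants.head(200), sim.conserved_elements, {}, window=0
    )
    elements = sim.conserved_elements.df[["chrom", "start", "end"]].values.tolist()
    from oracles import brute_force_near

    pts = list(zip(prof["chrom"], prof["pos"]))
    assert (
        prof["in_conserved_element"].to_numpy()
        == brute_force_near(pts, elements, 0)
    ).all()


def test_identical_groups_no_excess_significance(rng):
    prof = pd.DataFrame(
        {
            "nearest_set": rng.choice(["a", "b", "c"], size=600),
            "allele_age": rng.normal(size=600),
            "in_conserved_element": rng.random(600) < 0.2,
        }
    )
    out = evo.variant_profile_contrast(prof, metrics=("allele_age",))
    assert all(t["fdr"] > 0.05 for t in out["allele_age"]["pairwise"])


# ---------------------------------------------------------------------------
# cdf_shift_test
# ---------------------------------------------------------------------------


def test_cdf_shift_null_p_uniform(rng):
    base = rng.normal(size=5000)
    ps = [
        evo.cdf_shift_test(rng.normal(size=80), base)["p"] for _ in range(100)
    ]
    assert stats.kstest(ps, "uniform").pvalue > 1e-3


def test_cdf_shift_detects_one_sd_shift(rng):
    base = rng.normal(size=5000)
    res = evo.cdf_shift_test(rng.normal(1.0, 1.0, size=100), base)
    assert res["p"] < 1e-3
    assert not res["low_power"]


def test_cdf_shift_self_fold_change_is_one(rng):
    base = rng.normal(size=1000)
    res = evo.cdf_shift_test(base, base)
    assert res["fold_change"] == pytest.approx(1.0)
    small = evo.cdf_shift_test(base[:3], base)
    assert small["low_power"]
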