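"""Evolutionary characterization of region sets.

Per-region conservation averaging, per-bp overlap enrichment against
length/chromosome-matched randomized backgrounds, common-variant density,
and per-variant conservation / allele-age / functional-score contrasts
between region classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import (
    RegionSet,
    ScoreTrack,
    merge,
    nearest_assignment,
    overlap_bp,
    shuffle_regions,
)

DEFAULT_MAF_CUT = 0.05
DEFAULT_N_PERM = 200


@dataclass
class EnrichmentResult:
    """Per-bp overlap of a target set with a feature, against shuffled nulls."""

    target_label: str
    feature_label: str
    observed_per_bp: float
    null_mean_per_bp: float
    fold: float
    empirical_p: float
    n_perm: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


def region_conservation(
    regions: RegionSet, track: ScoreTrack, genome: Mapping[str, int]
) -> pd.DataFrame:
    """Arithmetic mean conservation score of covered bases, per region.

    Track gaps are skipped (not zero-filled); ``coverage`` reports the
    fraction of region bases with a score, and a region with no covered
    bases gets a missing mean.
    """
    arrays = track.per_base_arrays(genome)
    rows = []
    for i, row in enumerate(regions.df.itertuples(index=False)):
        arr = arrays.get(row.chrom)
        name = getattr(row, "name", None) or f"region_{i}"
        if arr is None:
            rows.append((name, np.nan, 0.0, 0))
            continue
        vals = arr[int(row.start): int(row.end)]
        covered = ~np.isnan(vals)
        n_cov = int(covered.sum())
        mean = float(np.nanmean(vals)) if n_cov else np.nan
        rows.append((name, mean, n_cov / len(vals), n_cov))
    return pd.DataFrame(
        rows, columns=["region", "mean_score", "coverage", "n_covered"]
    ).set_index("region")


def compare_sets(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U between two per-region metric vectors.

    Also reports the common-language effect size P(a > b) + 0.5 P(a = b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per set")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    cles = res.statistic / (len(a) * len(b))
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "effect_size": float(cles),
        "n_a": len(a),
        "n_b": len(b),
    }


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------


def _two_sided_empirical_p(null: np.ndarray, observed: float) -> float:
    """Double the smaller add-one tail, capped at 1 (never exactly zero)."""
    n = len(null)
    ge = (1 + int((null >= observed).sum())) / (n + 1)
    le = (1 + int((null <= observed).sum())) / (n + 1)
    return min(1.0, 2.0 * min(ge, le))


def feature_enrichment(
    target: RegionSet,
    feature: RegionSet,
    genome: Mapping[str, int],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    exclude: RegionSet | None = None,
) -> EnrichmentResult:
    """Per-bp overlap of target with feature vs shuffled backgrounds.

    observed = overlap_bp / target.total_bp; the null re-places each target
    interval uniformly on its own chromosome (length-preserving). The
    empirical p doubles the smaller add-one tail, so enrichment and
    depletion are both detectable and p >= 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    tbp = target.total_bp
    if tbp == 0:
        raise ValueError("empty target set")
    observed = overlap_bp(target, feature) / tbp
    null = np.empty(n_perm)
    for k, draw in enumerate(
        shuffle_regions(target, genome, n_perm, seed=seed, exclude=exclude)
    ):
        null[k] = overlap_bp(draw, feature) / draw.total_bp
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else np.inf
    return EnrichmentResult(
        target_label=target.label,
        feature_label=feature.label,
        observed_per_bp=float(observed),
        null_mean_per_bp=null_mean,
        fold=float(fold),
        empirical_p=_two_sided_empirical_p(null, observed),
        n_perm=n_perm,
    )


def variant_density(
    target: RegionSet,
    variants: pd.DataFrame,
    genome: Mapping[str, int],
    maf_cut: float = DEFAULT_MAF_CUT,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    feature_sets: Mapping[str, RegionSet] | None = None,
) -> dict:
    """Common-variant density (per bp) inside a region set.

    Variants with MAF >= ``maf_cut`` count; density is compared against
    shuffled placements of the target and, optionally, against the same
    density computed inside named feature sets (introns, promoters, repeats).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    common = variants[variants["maf"] >= maf_cut]
    pts = list(zip(common["chrom"], common["pos"]))

    def density(rs: RegionSet) -> float:
        bp = rs.total_bp
        if bp == 0:
            return np.nan
        inside = nearest_assignment(pts, rs, window=0)
        return float(inside.sum()) / bp

    obs = density(target)
    null = np.array(
        [density(d) for d in shuffle_regions(target, genome, n_perm, seed=rng)]
    )
    out = {
        "density_per_bp": obs,
        "n_common": len(common),
        "null_mean": float(null.mean()),
        "null_ci": (float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975))),
        "fold": obs / null.mean() if null.mean() > 0 else np.inf,
        "empirical_p": _two_sided_empirical_p(null, obs),
    }
    if feature_sets:
        out["feature_densities"] = {
            name: density(rs) for name, rs in feature_sets.items()
        }
    return out


# ---------------------------------------------------------------------------
# per-variant profiles
# ---------------------------------------------------------------------------


def annotate_variant_profiles(
    variants: pd.DataFrame,
    conserved_elements: RegionSet,
    labelled_sets: Mapping[str, RegionSet],
    window: int,
) -> pd.DataFrame:
    """Attach conserved-element membership and nearest region-set label.

    Expects columns ``id, chrom, pos`` plus any metric columns
    (``allele_age``, ``functional_score``, ``z_cross`` ...).
    """
    from .genomic_core import assign_nearest_label

    out = variants.copy()
    pts = list(zip(out["chrom"], out["pos"]))
    out["in_conserved_element"] = nearest_assignment(pts, conserved_elements, window=0)
    out["nearest_set"] = assign_nearest_label(out, labelled_sets, window=window).to_numpy()
    return out


def variant_profile_contrast(
    profiles: pd.DataFrame,
    metrics: Sequence[str] = ("allele_age", "functional_score"),
    group_col: str = "nearest_set",
) -> dict:
    """Group summaries and pairwise rank tests of per-variant metrics.

    For every metric: per-group means; Mann-Whitney between each pair of
    groups (BH-adjusted within metric). Conserved-element membership rate
    is always summarised per group. Groups with < 2 members are dropped
    with a note.
    """
    from .diffacc import bh_adjust

    groups = {g: sub for g, sub in profiles.groupby(group_col) if len(sub) >= 2}
    dropped = sorted(set(profiles[group_col]) - set(groups))
    out: dict = {"dropped_groups": dropped, "group_sizes": {g: len(s) for g, s in groups.items()}}
    if "in_conserved_element" in profiles.columns:
        out["conserved_rate"] = {
            g: float(sub["in_conserved_element"].mean()) for g, sub in groups.items()
        }
    labels = sorted(groups)
    for metric in metrics:
        if metric not in profiles.columns:
            continue
        summary = {g: float(groups[g][metric].mean()) for g in labels}
        tests = []
        for i, ga in enumerate(labels):
            for gb in labels[i + 1:]:
                r = compare_sets(groups[ga][metric], groups[gb][metric])
                tests.append({"group_a": ga, "group_b": gb, **r})
        if tests:
            adj = bh_adjust([t["p"] for t in tests])
            for t, q in zip(tests, adj):
                t["fdr"] = float(q)
        out[metric] = {"group_means": summary, "pairwise": tests}
    return out


def conserved_stratification(
    profiles: pd.DataFrame, metric: str = "z_cross"
) -> dict:
    """Compare a metric between variants inside vs outside conserved elements."""
    inside = profiles.loc[profiles["in_conserved_element"], metric]
    outside = profiles.loc[~profiles["in_conserved_element"], metric]
    res = compare_sets(inside, outside)
    res.update(
        mean_inside=float(inside.mean()), mean_outside=float(outside.mean())
    )
    return res


def cdf_shift_test(
    target_scores: Sequence[float],
    baseline_scores: Sequence[float],
    min_target: int = 5,
) -> dict:
    """Distribution-shift test of target scores against a baseline-fitted normal.

    A normal is fit (location/scale) to the baseline population and the
    target vector is tested against it with a one-sample KS test. The
    ``fold_change`` field is -log10 p of the target test divided by -log10 p
    of the same test run on the full baseline, so the all-variants test
    against itself is exactly 1.
    """
    base = np.asarray(baseline_scores, dtype=float)
    tgt = np.asarray(target_scores, dtype=float)
    base, tgt = base[~np.isnan(base)], tgt[~np.isnan(tgt)]
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate baseline (zero spread)")
    p_target = float(stats.kstest(tgt, "norm", args=(mu, sd)).pvalue)
    p_all = float(stats.kstest(base, "norm", args=(mu, sd)).pvalue)
    neglog = lambda p: -np.log10(max(p, np.finfo(float).tiny))
    fold = neglog(p_target) / neglog(p_all) if neglog(p_all) > 0 else np.inf
    return {
        "p": p_target,
        "p_all_variants": p_all,
        "fold_change": float(fold),
        "n_target": len(tgt),
        "low_power": len(tgt) < min_target,
        "baseline_mu": mu,
        "baseline_sd": sd,
    }
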