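"""Cross-disease per-SNP aggregation and per-disease regional enrichment.

The cross-set score combines unsigned association evidence across many
disease GWAS panels. For each disease the two-sided p becomes
``z_i = Phi^-1(1 - p_i / 2)`` (the magnitude of the corresponding
standard-normal deviate); the per-variant score is the standardized sum

    z_cross = (sum_i z_i - n * E0) / (sqrt(n) * SD0)

with ``E0 = sqrt(2/pi)`` and ``SD0 = sqrt(1 - 2/pi)`` the mean and sd of
|N(0,1)|, so a variant with no association anywhere has mean 0 and unit
variance under the global null. Signs are not combined because effect
directions are incommensurable across traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffacc import bh_adjust
from .evo import compare_sets
from .genomic_core import RegionSet, nearest_assignment

E0_HALF_NORMAL = float(np.sqrt(2.0 / np.pi))
SD_HALF_NORMAL = float(np.sqrt(1.0 - 2.0 / np.pi))

DEFAULT_P_STRONG = 1e-5
DEFAULT_WINDOW = 10_000


@dataclass
class GwasPanel:
    """Per-disease summary statistics over a shared variant universe.

    ``pvalues`` is a variants x diseases frame (NaN = variant untested in
    that disease); ``betas`` is optional with the same shape.
    """

    pvalues: pd.DataFrame
    betas: pd.DataFrame | None = None
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.pvalues.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmax(p, initial=0.0) > 1.0 or np.nanmin(p, initial=1.0) < 0.0:
                raise ValueError("p-values must lie in [0, 1]")

    @property
    def diseases(self) -> list[str]:
        return list(self.pvalues.columns)

    @property
    def variant_universe(self) -> pd.Index:
        return self.pvalues.index

    @classmethod
    def from_tables(cls, tables: Mapping[str, pd.DataFrame]) -> "GwasPanel":
        """Build from one (id, p[, beta]) table per disease."""
        pv = {d: t.set_index("id")["p"] for d, t in tables.items()}
        pvalues = pd.DataFrame(pv)
        betas = None
        if all("beta" in t.columns for t in tables.values()):
            betas = pd.DataFrame({d: t.set_index("id")["beta"] for d, t in tables.items()})
        return cls(pvalues=pvalues, betas=betas)


def cross_set_metric(
    panel: GwasPanel, min_diseases: int | None = None, method: str = "abs_z"
) -> pd.DataFrame:
    """Aggregate per-variant association evidence across diseases.

    Default ``abs_z`` is the standardized unsigned-Z sum described in the
    module docstring; ``mean_neglogp`` (mean -log10 p) is the exposed
    alternative. Variants observed in fewer than ``min_diseases`` panels
    (default: all diseases present) get NaN. Zero p-values are clamped to
    the smallest positive float with a warning.
    """
    if panel.pvalues.empty:
        raise ValueError("empty panel")
    P = panel.pvalues.to_numpy(dtype=float).copy()
    n_dis = P.shape[1]
    if min_diseases is None:
        min_diseases = n_dis
    if (P == 0).any():
        warnings.warn("p=0 clamped to smallest positive float", RuntimeWarning)
        P[P == 0] = np.finfo(float).tiny
    observed = ~np.isnan(P)
    n_obs = observed.sum(axis=1)
    if method == "abs_z":
        Z = stats.norm.isf(P / 2.0)  # |z| for a two-sided p
        zsum = np.nansum(np.where(observed, Z, 0.0), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = (zsum - n_obs * E0_HALF_NORMAL) / (
                np.sqrt(n_obs) * SD_HALF_NORMAL
            )
    elif method == "mean_neglogp":
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.nansum(np.where(observed, -np.log10(P), 0.0), axis=1) / n_obs
    else:
        raise ValueError(f"unknown method {method!r}")
    score = np.where(n_obs >= min_diseases, score, np.nan)
    return pd.DataFrame(
        {"z_cross": score, "n_diseases_observed": n_obs},
        index=panel.variant_universe,
    )


def per_disease_enrichment(
    panel: GwasPanel,
    target: RegionSet,
    variants: pd.DataFrame,
    p_strong: float = DEFAULT_P_STRONG,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Signed hypergeometric enrichment of strong variants near a region set.

    For each disease the 2x2 is (strong vs not) x (near target vs not) over
    the tested universe; the smaller of the upper/lower hypergeometric tail
    is reported as signed -log10 adjusted p (positive = enrichment of
    strong variants near the target). BH across diseases.
    """
    if len(target) == 0:
        raise ValueError("empty target set")
    variants = variants.set_index("id").loc[panel.variant_universe]
    near = nearest_assignment(
        list(zip(variants["chrom"], variants["pos"])), target, window=window
    )
    N = len(variants)
    K = int(near.sum())  # variants near target
    rows = []
    for disease in panel.diseases:
        p = panel.pvalues[disease]
        tested = ~p.isna()
        n_tested = int(tested.sum())
        strong = (p < p_strong) & tested
        n_strong = int(strong.sum())
        k = int((strong.to_numpy() & near).sum())
        K_d = int(near[tested.to_numpy()].sum())
        if K_d in (0, n_tested) or n_strong == 0:
            rows.append((disease, n_strong, k, np.nan, np.nan, 0, True))
            continue
        hg = stats.hypergeom(n_tested, K_d, n_strong)
        p_up = float(hg.sf(k - 1))  # P(X >= k): enrichment
        p_lo = float(hg.cdf(k))  # P(X <= k): depletion
        sign = 1 if p_up <= p_lo else -1
        rows.append((disease, n_strong, k, min(p_up, p_lo), None, sign, False))
    out = pd.DataFrame(
        rows,
        columns=["disease", "n_strong", "k_near", "p", "fdr", "sign", "degenerate"],
    ).set_index("disease")
    ok = ~out["p"].isna()
    out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["signed_neglog_fdr"] = np.where(
        ok, out["sign"] * -np.log10(out["fdr"].astype(float).clip(lower=np.finfo(float).tiny)), np.nan
    )
    out.attrs["n_universe"] = N
    out.attrs["n_near_target"] = K
    return out


def group_contrast(
    scores: pd.DataFrame,
    groups: pd.Series,
    score_col: str = "z_cross",
    control_order: tuple[str, str] = ("unaltered", "non_accessible"),
) -> dict:
    """Per-group cross-set score distributions and pairwise rank tests.

    ``groups`` maps variant id -> region-class label (the partition by
    nearest region set). Pairwise Mann-Whitney tests are BH-adjusted; the
    control ordering check compares the unaltered-accessible group to the
    non-accessible group (one-sided direction reported via group means).
    """
    joined = scores.join(groups.rename("group"), how="inner").dropna(
        subset=[score_col, "group"]
    )
    by_group = {g: sub[score_col] for g, sub in joined.groupby("group") if len(sub) >= 2}
    if not by_group:
        raise ValueError("no group with >= 2 scored variants")
    labels = sorted(by_group)
    means = {g: float(v.mean()) for g, v in by_group.items()}
    medians = {g: float(v.median()) for g, v in by_group.items()}
    tests = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1:]:
            r = compare_sets(by_group[ga], by_group[gb])
            tests.append({"group_a": ga, "group_b": gb, **r})
    if tests:
        for t, q in zip(tests, bh_adjust([t["p"] for t in tests])):
            t["fdr"] = float(q)
    out = {
        "group_means": means,
        "group_medians": medians,
        "group_sizes": {g: int(len(v)) for g, v in by_group.items()},
        "pairwise": tests,
    }
    a, b = control_order
    if a in by_group and b in by_group:
        r = compare_sets(by_group[a], by_group[b])
        r["ordering_holds"] = means[a] > means[b]
        out["control_check"] = r
    return out
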