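"""Peak consolidation and moderated differential accessibility.

The statistical core is an empirical-Bayes moderated t-test over a shared
linear design: each region is fit by least squares, per-region residual
variances ``s_i^2`` (on ``d_i`` df) are shrunk toward a prior ``s_0^2``
estimated across regions,

    s_tilde_i^2 = (d0 * s0^2 + d_i * s_i^2) / (d0 + d_i),

and the contrast coefficient is tested with a t-statistic on ``d0 + d_i``
degrees of freedom. The prior ``(d0, s0^2)`` is obtained by moment-matching
the scaled-F distribution of the sample variances on the log scale
(Smyth-style), so the procedure reduces to the ordinary per-region t-test
when ``d0 = 0`` and to a pooled-prior-variance t-test as ``d0 -> inf``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .genomic_core import RegionSet, merge, overlap_bp

DEFAULT_FDR = 0.05
DEFAULT_AGE_SPLIT = 50.0  # years: adults strictly younger are "young"
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_SUPPORT = 2


@dataclass
class SampleMeta:
    """Per-sample metadata for the accessibility design."""

    sample_id: str
    tissue: str
    stage: str  # "fetal" | "adult"
    age: float | None = None  # years, adults only
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.stage not in ("fetal", "adult"):
            raise ValueError(f"stage must be fetal/adult, got {self.stage!r}")


def align_meta(meta: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Reorder sample metadata rows to match a count-matrix column order."""
    out = meta.set_index("sample_id").loc[list(columns)]
    out.index.name = "sample_id"
    return out.reset_index()


def meta_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.tissue, s.stage, s.age, s.replicate) for s in samples],
        columns=["sample_id", "tissue", "stage", "age", "replicate"],
    )


# ---------------------------------------------------------------------------
# peak consolidation
# ---------------------------------------------------------------------------


def consolidate_peaks(
    per_replicate_peaks: Mapping[tuple[str, str], Sequence[RegionSet]],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> RegionSet:
    """Keep bases supported by >= ``min_support`` replicates within any
    tissue/stage group, then union across groups and merge.

    ``per_replicate_peaks`` maps ``(tissue, stage)`` to one peak set per
    biological replicate. Support is counted per base so that partially
    overlapping replicate peaks contribute exactly where they agree.
    """
    if not per_replicate_peaks:
        raise ValueError("no peak sets supplied")
    kept_frames = []
    for (tissue, stage), replicates in per_replicate_peaks.items():
        if len(replicates) == 0:
            raise ValueError(f"group ({tissue},{stage}) has no replicates")
        support = min(min_support, len(replicates))
        # sweep over per-replicate merged boundaries counting coverage depth
        events: dict[str, list[tuple[int, int]]] = {}
        for rep in replicates:
            for row in merge(rep).df.itertuples(index=False):
                events.setdefault(row.chrom, []).append((int(row.start), +1))
                events[row.chrom].append((int(row.end), -1))
        rows = []
        for chrom, evs in events.items():
            evs.sort()
            depth = 0
            open_start = None
            for pos, delta in evs:
                new_depth = depth + delta
                if depth < support <= new_depth:
                    open_start = pos
                elif new_depth < support <= depth and open_start is not None:
                    if pos > open_start:
                        rows.append((chrom, open_start, pos))
                    open_start = None
                depth = new_depth
        if rows:
            kept_frames.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    if not kept_frames:
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]), label="custom")
    return merge(RegionSet(pd.concat(kept_frames, ignore_index=True)), label="custom")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_counts(
    counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    weights: bool = False,
    lowess_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Library-size scaling to log2 counts-per-million.

    ``logcpm = log2((count + pseudocount) / (libsize + 2*pseudocount) * 1e6)``.
    With ``weights=True`` a lowess trend of sqrt residual standard deviation
    against mean log-cpm provides inverse-variance precision weights
    (voom-style, computed without a design: residuals about the row mean).
    """
    libsizes = counts.sum(axis=0).astype(float)
    if (libsizes <= 0).any():
        bad = list(libsizes.index[libsizes <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    logcpm = np.log2(
        (counts + pseudocount).div(libsizes + 2 * pseudocount, axis=1) * 1e6
    )
    w = None
    if weights:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        row_mean = logcpm.mean(axis=1).to_numpy()
        row_sd = logcpm.std(axis=1, ddof=1).to_numpy()
        sqrt_sd = np.sqrt(np.clip(row_sd, 1e-8, None))
        fitted = lowess(sqrt_sd, row_mean, frac=lowess_frac, return_sorted=False)
        fitted = np.clip(fitted, 1e-4, None)
        w_row = fitted ** -4
        w = pd.DataFrame(
            np.tile(w_row[:, None], (1, logcpm.shape[1])),
            index=logcpm.index,
            columns=logcpm.columns,
        )
    return logcpm, w


# ---------------------------------------------------------------------------
# empirical-Bayes machinery
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float]:
    """Moment-match ``s2 ~ s0^2 * F(df, d0)`` on the log scale.

    Returns ``(d0, s0^2)``; ``d0`` is ``inf`` when the spread of the sample
    variances is no larger than expected from their own chi-square noise.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need >= 2 positive variances to fit prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def squeeze_variances(
    s2: np.ndarray, df: np.ndarray | float, d0: float, s0_sq: float
) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    dfb = np.broadcast_to(np.asarray(df, dtype=float), np.shape(s2))
    return (d0 * s0_sq + dfb * s2) / (d0 + dfb)


def bh_adjust(pvals: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# moderated fit
# ---------------------------------------------------------------------------


def build_design(
    meta: pd.DataFrame, contrast: str = "stage", adult_level: str = "adult"
) -> tuple[np.ndarray, int]:
    """Design matrix: intercept + contrast indicator + tissue dummies.

    ``contrast='stage'`` codes adult = 1, fetal = 0; ``contrast='age'``
    codes old (age >= split, stored in column 'age_group') = 1. Tissue
    enters additively so the tested coefficient is the pan-tissue shift.
    Returns (X, index of the contrast column).
    """
    n = len(meta)
    cols = [np.ones(n)]
    if contrast == "stage":
        cols.append((meta["stage"] == adult_level).to_numpy(float))
    elif contrast == "age":
        cols.append((meta["age_group"] == "old").to_numpy(float))
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    contrast_idx = 1
    tissues = sorted(meta["tissue"].unique())
    for t in tissues[1:]:
        cols.append((meta["tissue"] == t).to_numpy(float))
    return np.column_stack(cols), contrast_idx


def moderated_fit(
    logmat: pd.DataFrame,
    design: np.ndarray,
    contrast_idx: int = 1,
    weights: pd.DataFrame | None = None,
    d0_override: float | None = None,
    s0_sq_override: float | None = None,
) -> pd.DataFrame:
    """Per-region least squares + empirical-Bayes moderated t on one contrast.

    Returns a frame indexed like ``logmat`` with columns
    ``log2fc, t, p, fdr, direction, s2, df_residual, df_total`` plus the
    fitted prior in ``.attrs['d0'] / .attrs['s0_sq']``. ``d0_override``
    pins the prior df (0 disables shrinkage; ``inf`` uses the prior
    variance alone, taking ``s0_sq_override`` when given).
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    d_resid = n - p
    if d_resid < 1:
        raise ValueError("no residual degrees of freedom")
    Y = logmat.to_numpy(dtype=float)
    if weights is None:
        pinv = np.linalg.pinv(X)
        beta = Y @ pinv.T  # regions x p
        fitted = beta @ X.T
        resid = Y - fitted
        s2 = (resid ** 2).sum(axis=1) / d_resid
        xtx_inv = np.linalg.inv(X.T @ X)
        su = np.sqrt(xtx_inv[contrast_idx, contrast_idx])
        su = np.full(len(Y), su)
    else:
        W = weights.to_numpy(dtype=float)
        # batched weighted normal equations
        xtwx = np.einsum("np,rn,nq->rpq", X, W, X)
        xtwy = np.einsum("np,rn,rn->rp", X, W, Y)
        beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
        resid = Y - beta @ X.T
        s2 = np.einsum("rn,rn->r", W, resid ** 2) / d_resid
        cov = np.linalg.inv(xtwx)
        su = np.sqrt(cov[:, contrast_idx, contrast_idx])
    if np.any(s2 <= 1e-12):  # numerically zero residual variance
        const = logmat.index[np.where(s2 <= 1e-12)[0]].tolist()[:5]
        raise ValueError(f"all-constant regions (zero residual variance): {const}")
    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0):
            s0_sq = s0_sq_override if s0_sq_override is not None else float(
                np.exp(np.mean(np.log(s2)))
            )
        elif d0 == 0.0:
            s0_sq = float(np.mean(s2))  # irrelevant at zero weight
        else:
            _, s0_sq = fit_f_dist(s2, d_resid)
    else:
        d0, s0_sq = fit_f_dist(s2, d_resid)
    s2_post = squeeze_variances(s2, d_resid, d0, s0_sq)
    coef = beta[:, contrast_idx]
    t = coef / (su * np.sqrt(s2_post))
    df_total = d_resid + d0
    # cap at the pooled residual df: the data cannot support more
    df_total = min(df_total, d_resid * len(Y))
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "log2fc": coef,
            "t": t,
            "p": pvals,
            "fdr": bh_adjust(pvals),
            "direction": np.sign(coef).astype(int),
            "s2": s2,
            "df_residual": float(d_resid),
            "df_total": float(df_total),
        },
        index=logmat.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def differential_accessibility(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: str = "stage",
    use_weights: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Normalize + design + moderated fit in one call.

    ``meta`` rows must align with ``counts`` columns by ``sample_id``.
    """
    meta = align_meta(meta, counts.columns)
    logmat, w = normalize_counts(counts, pseudocount=pseudocount, weights=use_weights)
    X, idx = build_design(meta, contrast=contrast)
    return moderated_fit(logmat, X, contrast_idx=idx, weights=w)


# ---------------------------------------------------------------------------
# set calling and nested contrasts
# ---------------------------------------------------------------------------


def call_stage_sets(
    results: pd.DataFrame,
    regions: RegionSet,
    fdr_cut: float = DEFAULT_FDR,
    pos_label: str = "adult_biased",
    neg_label: str = "fetal_biased",
) -> tuple[RegionSet, RegionSet]:
    """Partition significant regions by direction of the stage coefficient."""
    sig = results["fdr"] < fdr_cut
    rdf = regions.df.set_index("name") if "name" in regions.df.columns else regions.df
    pos_ids = results.index[sig & (results["log2fc"] > 0)]
    neg_ids = results.index[sig & (results["log2fc"] < 0)]

    def subset(ids, label):
        sub = rdf.loc[rdf.index.intersection(ids)]
        sub.index.name = "name"
        sub = sub.reset_index()
        cols = [c for c in ["chrom", "start", "end", "name"] if c in sub.columns]
        return RegionSet(sub.loc[:, cols], label=label)

    return subset(pos_ids, pos_label), subset(neg_ids, neg_label)


def split_age_groups(meta: pd.DataFrame, age_split: float = DEFAULT_AGE_SPLIT) -> pd.DataFrame:
    """Label adult samples young (< split) / old (>= split)."""
    meta = meta.copy()
    adults = meta["stage"] == "adult"
    if meta.loc[adults, "age"].isna().any():
        raise ValueError("age-stratified contrast requires ages for all adults")
    meta.loc[adults, "age_group"] = np.where(
        meta.loc[adults, "age"] < age_split, "young", "old"
    )
    return meta


def nested_age_contrast(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    dev_region_ids: Sequence[str],
    age_split: float = DEFAULT_AGE_SPLIT,
    fdr_cut: float = DEFAULT_FDR,
    use_weights: bool = False,
) -> pd.DataFrame:
    """Young/old moderated contrast restricted to developmentally-altered regions.

    Only adult samples enter; BH correction is applied within the restricted
    family. Positive log2fc means more accessible in old samples.
    """
    if len(dev_region_ids) == 0:
        raise ValueError("no developmentally-altered regions supplied")
    meta = align_meta(meta, counts.columns)
    meta = split_age_groups(meta, age_split)
    adult_ids = meta.loc[meta["stage"] == "adult", "sample_id"]
    sub_meta = meta[meta["sample_id"].isin(adult_ids)].reset_index(drop=True)
    for grp in ("young", "old"):
        if (sub_meta["age_group"] == grp).sum() == 0:
            raise ValueError(f"age group {grp!r} is empty")
    sub_counts = counts.loc[list(dev_region_ids), adult_ids]
    logmat, w = normalize_counts(sub_counts, weights=use_weights)
    X, idx = build_design(sub_meta, contrast="age")
    res = moderated_fit(logmat, X, contrast_idx=idx, weights=w)
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res


def directionality_test(
    dev_direction: pd.Series, age_direction: pd.Series, yates: bool = False
) -> dict:
    """Chi-square test for shared direction of development and ageing shifts.

    Builds the 2x2 table of (dev gain/loss) x (age gain/loss) over regions
    significant in both contrasts and applies Pearson's chi-square with 1 df.
    Returns the table, statistic and p; a zero margin yields
    ``statistic=None`` with a reason.
    """
    joined = pd.concat(
        {"dev": dev_direction, "age": age_direction}, axis=1
    ).dropna()
    table = np.zeros((2, 2), dtype=int)
    for d in (-1, 1):
        for a in (-1, 1):
            table[(d + 1) // 2, (a + 1) // 2] = int(
                ((joined["dev"] == d) & (joined["age"] == a)).sum()
            )
    out = {"table": table, "n": int(table.sum())}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        out.update(statistic=None, p=None, reason="zero margin in contingency table")
        return out
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    out.update(statistic=float(stat), p=float(p), reason=None)
    return out


def promoter_windows(
    genes: pd.DataFrame, pad: int = 1000, genome: Mapping[str, int] | None = None
) -> RegionSet:
    """Promoter regions: TSS padded ``pad`` bp up- and downstream.

    ``genes`` needs columns ``gene, chrom, tss``; windows are clipped to
    chromosome bounds when ``genome`` is given.
    """
    if genes["tss"].isna().any():
        raise ValueError("missing TSS for some genes")
    df = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": (genes["tss"] - pad).clip(lower=0).astype(int),
            "end": (genes["tss"] + pad).astype(int),
            "name": genes["gene"],
        }
    )
    if genome is not None:
        sizes = df["chrom"].map(genome)
        df["end"] = np.minimum(df["end"], sizes.astype(int))
    return RegionSet(df, label="custom")


def promoter_accessibility(
    promoter_counts: pd.DataFrame,
    meta: pd.DataFrame,
    use_weights: bool = False,
) -> pd.DataFrame:
    """Stage contrast on promoter-window counts via the same moderated engine."""
    return differential_accessibility(
        promoter_counts, meta, contrast="stage", use_weights=use_weights
    )


def recovery_metrics(
    called_ids: set, truth_positive: set, universe: Sequence
) -> dict:
    """Sensitivity and empirical FDR of a called set against planted truth."""
    called = set(called_ids)
    pos = set(truth_positive)
    tp = len(called & pos)
    fp = len(called - pos)
    sens = tp / len(pos) if pos else float("nan")
    fdr = fp / len(called) if called else 0.0
    return {"n_called": len(called), "sensitivity": sens, "empirical_fdr": fdr}
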