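"""Cross-tissue gene-expression shift calling.

Fetal/adult calls use a deliberately lenient sign-consistency rule rather
than a formal differential test, because few tissues have enough adult
replicates for a powered per-tissue fit: a gene is called adult-up when its
adult-vs-fetal log2 fold-change clears a magnitude threshold in enough
tissues and never clears it in the opposite direction (a veto), and
symmetrically for fetal-up. Young/old calls within adults reuse the
moderated engine from :mod:`epicontext.diffacc` with precision weights.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .diffacc import (
    DEFAULT_AGE_SPLIT,
    align_meta,
    bh_adjust,
    build_design,
    moderated_fit,
    normalize_counts,
    split_age_groups,
)

DEFAULT_MIN_LOGFC = 1.0


def filter_expressed(
    expr: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> tuple[pd.DataFrame, int]:
    """Drop lowly-expressed genes: keep genes with cpm >= ``min_cpm`` in at
    least ``min_fraction`` of samples. Returns (filtered, n_dropped)."""
    lib = expr.sum(axis=0).astype(float)
    cpm = expr.div(lib, axis=1) * 1e6
    keep = (cpm >= min_cpm).mean(axis=1) >= min_fraction
    return expr.loc[keep], int((~keep).sum())


def per_tissue_logfc(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Adult-minus-fetal mean log2-cpm per tissue (genes x tissues)."""
    meta = align_meta(meta, expr.columns)
    logcpm, _ = normalize_counts(expr)
    out = {}
    for tissue, sub in meta.groupby("tissue"):
        adult = sub.loc[sub["stage"] == "adult", "sample_id"]
        fetal = sub.loc[sub["stage"] == "fetal", "sample_id"]
        if len(adult) == 0 or len(fetal) == 0:
            continue
        out[tissue] = logcpm[adult].mean(axis=1) - logcpm[fetal].mean(axis=1)
    if not out:
        raise ValueError("no tissue has both stages")
    return pd.DataFrame(out)


def consistency_shift(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    min_tissues: int | None = None,
    min_logfc: float = DEFAULT_MIN_LOGFC,
    min_cpm: float = 1.0,
) -> dict:
    """Call stage-biased genes by cross-tissue sign consistency.

    adult-up: log2fc >= min_logfc in >= min_tissues tissues and
    <= -min_logfc in none; fetal-up symmetric. ``min_tissues`` defaults to
    ceil(T/2) over the T tissues with both stages.
    """
    filtered, n_dropped = filter_expressed(expr, min_cpm=min_cpm)
    if filtered.empty:
        raise ValueError("no gene passes the expression filter")
    lfc = per_tissue_logfc(filtered, meta)
    T = lfc.shape[1]
    if T < 2:
        raise ValueError("need >= 2 tissues with both stages")
    if min_tissues is None:
        min_tissues = math.ceil(T / 2)
    up = (lfc >= min_logfc).sum(axis=1)
    down = (lfc <= -min_logfc).sum(axis=1)
    adult_up = set(lfc.index[(up >= min_tissues) & (down == 0)])
    fetal_up = set(lfc.index[(down >= min_tissues) & (up == 0)])
    return {
        "adult_up": adult_up,
        "fetal_up": fetal_up,
        "n_dropped_low_expression": n_dropped,
        "n_tested": len(lfc),
        "min_tissues": min_tissues,
        "min_logfc": min_logfc,
        "logfc": lfc,
    }


def age_expression_contrast(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    age_split: float = DEFAULT_AGE_SPLIT,
    use_weights: bool = True,
    min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Young/old moderated contrast on adult expression counts.

    Same engine as the accessibility fits; positive log2fc = higher in old.
    """
    filtered, _ = filter_expressed(expr, min_cpm=min_cpm)
    meta = align_meta(meta, filtered.columns)
    meta = split_age_groups(meta, age_split)
    adults = meta.loc[meta["stage"] == "adult", "sample_id"]
    sub_meta = meta[meta["sample_id"].isin(adults)].reset_index(drop=True)
    for grp in ("young", "old"):
        if (sub_meta["age_group"] == grp).sum() == 0:
            raise ValueError(f"age group {grp!r} is empty")
    sub = filtered[adults]
    logmat, w = normalize_counts(sub, weights=use_weights)
    X, idx = build_design(sub_meta, contrast="age")
    res = moderated_fit(logmat, X, contrast_idx=idx, weights=w)
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res
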