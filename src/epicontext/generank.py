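"""Gene-locus cross-disease prioritization.

Each gene receives, per disease, the most significant p-value among SNPs
within its locus (TSS ± window, optionally extended by capture-linked
regions). Per-disease ascending ranks (1 = strongest) are aggregated by
geometric mean, and candidate gene sets are scored against same-size
random draws from the universe.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import RegionSet, nearest_assignment
from .gwas import GwasPanel

DEFAULT_LOCUS_WINDOW = 100_000


def build_loci(
    genes: pd.DataFrame,
    window: int = DEFAULT_LOCUS_WINDOW,
    linked_regions: Mapping[str, RegionSet] | None = None,
) -> pd.DataFrame:
    """Locus definitions: symmetric window around each TSS plus optional
    capture-linked regions per gene (kept as an auxiliary mapping in attrs).
    """
    loci = genes.loc[:, ["gene", "chrom", "tss"]].copy()
    loci["start"] = (loci["tss"] - window).clip(lower=0).astype(int)
    loci["end"] = (loci["tss"] + window).astype(int)
    loci.attrs["linked_regions"] = dict(linked_regions or {})
    return loci


def gene_scores(
    panel: GwasPanel,
    loci: pd.DataFrame,
    variants: pd.DataFrame,
    variant_filter: RegionSet | None = None,
    filter_window: int = 0,
) -> pd.DataFrame:
    """Per-disease per-gene best (minimum) p over candidate SNPs.

    Candidates are SNPs inside the gene's locus window or inside any
    capture-linked region for the gene (union). An optional
    ``variant_filter`` restricts candidates to SNPs within
    ``filter_window`` bp of the filter set. Genes with no candidate SNP in
    a disease get NaN (flagged no-data; ranked last downstream).
    """
    if panel.pvalues.empty:
        raise ValueError("empty panel")
    v = variants.set_index("id").loc[panel.variant_universe]
    keep = np.ones(len(v), dtype=bool)
    if variant_filter is not None:
        keep = nearest_assignment(
            list(zip(v["chrom"], v["pos"])), variant_filter, window=filter_window
        )
    linked: Mapping[str, RegionSet] = loci.attrs.get("linked_regions", {})
    pos = v["pos"].to_numpy()
    chrom = v["chrom"].to_numpy()
    scores = {}
    for row in loci.itertuples(index=False):
        in_window = (chrom == row.chrom) & (pos >= row.start) & (pos < row.end)
        cand = in_window & keep
        extra = linked.get(row.gene)
        if extra is not None and len(extra):
            in_linked = nearest_assignment(list(zip(chrom, pos)), extra, window=0)
            cand = cand | (in_linked & keep)
        ids = v.index[cand]
        if len(ids) == 0:
            scores[row.gene] = pd.Series(np.nan, index=panel.diseases)
        else:
            scores[row.gene] = panel.pvalues.loc[ids].min(axis=0)
    out = pd.DataFrame(scores).T  # genes x diseases
    out.index.name = "gene"
    return out


def aggregate_ranks(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank genes per disease (ascending p, rank 1 strongest; ties averaged)
    and aggregate across diseases by geometric mean.

    No-data genes in a disease are placed after all ranked genes at
    ``n_ranked + (n_nodata + 1)/2`` (the average of the tied trailing
    positions), which keeps ranks monotone-transform invariant.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 diseases to aggregate")
    if scores.isna().all(axis=1).all():
        raise ValueError("all genes have no data")
    ranks = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for d in scores.columns:
        col = scores[d]
        r = col.rank(method="average", na_option="keep")
        n_ranked = int(col.notna().sum())
        n_nodata = int(col.isna().sum())
        r = r.fillna(n_ranked + (n_nodata + 1) / 2.0)
        ranks[d] = r
    agg = np.exp(np.log(ranks).mean(axis=1))
    out = ranks.copy()
    out["aggregate"] = agg
    out["n_nodata"] = scores.isna().sum(axis=1)
    return out.sort_values("aggregate")


def gene_set_test(
    table: pd.DataFrame,
    gene_set: Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation test: is the set's mean aggregate rank better (smaller)
    than same-size uniform draws from the universe?

    empirical p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = table.index
    genes = [g for g in gene_set if g in universe]
    if len(genes) == 0:
        raise ValueError("gene set disjoint from universe")
    if len(genes) > len(universe):
        raise ValueError("gene set larger than universe")
    agg = table["aggregate"]
    observed = float(agg.loc[genes].mean())
    values = agg.to_numpy()
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = values[rng.choice(len(values), size=len(genes), replace=False)].mean()
    p = (1 + int((null <= observed).sum())) / (n_perm + 1)
    return {
        "observed_mean_aggregate": observed,
        "null_mean": float(null.mean()),
        "empirical_p": float(p),
        "n_set": len(genes),
        "n_perm": n_perm,
    }
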