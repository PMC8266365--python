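"""Region-to-gene linking via promoter-capture pairs, promoter windows
and optional regulatory-domain annotations."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import RegionSet, overlap_bp

CAPTURE_COLUMNS = ["chrom", "start", "end", "gene", "tissue"]
DEFAULT_MIN_TISSUES = 2


def filter_capture(pairs: pd.DataFrame, min_tissues: int = DEFAULT_MIN_TISSUES) -> pd.DataFrame:
    """Keep (region, gene) interactions seen in >= ``min_tissues`` distinct
    tissues/cell-types; duplicate records within a tissue count once.

    The default of 2 drops contacts exclusive to a single dataset.
    """
    missing = [c for c in CAPTURE_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"capture table missing columns {missing}")
    dedup = pairs.drop_duplicates(CAPTURE_COLUMNS)
    counts = dedup.groupby(["chrom", "start", "end", "gene"])["tissue"].nunique()
    keep = counts[counts >= min_tissues].reset_index()
    keep = keep.rename(columns={"tissue": "n_tissues"})
    return keep.sort_values(["chrom", "start", "end", "gene"]).reset_index(drop=True)


def regions_to_genes(
    region_set: RegionSet,
    capture: pd.DataFrame | None = None,
    promoters: RegionSet | None = None,
    domains: pd.DataFrame | None = None,
    rules: Sequence[str] = ("capture", "promoter", "domain"),
) -> set[str]:
    """Genes linked to a region set by the union of three rules.

    capture: a filtered capture pair's region overlaps the set;
    promoter: the set overlaps the gene's promoter window (``name`` = gene);
    domain: the set overlaps an interval of the gene's regulatory domain
    (frame with chrom/start/end/gene). ``rules`` restricts which apply.
    """
    genes: set[str] = set()

    def overlapping_genes(frame: pd.DataFrame) -> set[str]:
        found = set()
        rdf = region_set.df
        for chrom, sub in frame.groupby("chrom"):
            regions = rdf[rdf["chrom"] == chrom]
            if regions.empty:
                continue
            rs = regions["start"].to_numpy()
            re_ = regions["end"].to_numpy()
            for row in sub.itertuples(index=False):
                if np.any((rs < row.end) & (re_ > row.start)):
                    found.add(row.gene)
        return found

    if "capture" in rules and capture is not None and len(capture):
        genes |= overlapping_genes(capture)
    if "promoter" in rules and promoters is not None and len(promoters):
        pf = promoters.df.rename(columns={"name": "gene"})
        genes |= overlapping_genes(pf)
    if "domain" in rules and domains is not None and len(domains):
        genes |= overlapping_genes(domains)
    return genes


def set_overlap_test(
    gene_set_a: set[str], gene_set_b: set[str], universe: set[str]
) -> dict:
    """One-sided hypergeometric enrichment of the overlap of two gene sets."""
    if not universe:
        raise ValueError("empty universe")
    a = set(gene_set_a) & set(universe)
    b = set(gene_set_b) & set(universe)
    k = len(a & b)
    hg = stats.hypergeom(len(universe), len(a), len(b))
    return {
        "overlap": k,
        "n_a": len(a),
        "n_b": len(b),
        "n_universe": len(universe),
        "p": float(hg.sf(k - 1)),
        "expected": len(a) * len(b) / len(universe),
    }
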