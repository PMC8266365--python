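"""Interval arithmetic, randomized backgrounds and plain-text genomic I/O.

All coordinates are 0-based half-open (BED convention). Region sets are
thin wrappers around a sorted :class:`pandas.DataFrame` with columns
``chrom, start, end`` plus optional ``name`` and ``score``; every
operation in the package goes through this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGION_COLUMNS = ["chrom", "start", "end"]

#: Region-set class labels used throughout the pipeline.
REGION_LABELS = (
    "fetal_biased",
    "adult_biased",
    "young_biased",
    "old_biased",
    "unaltered",
    "background",
    "custom",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """An ordered set of intervals with a class label.

    The backing frame is always sorted by ``(chrom, start, end)``.
    """

    df: pd.DataFrame
    label: str = "custom"

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REGION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region frame missing columns {missing}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("malformed coordinates: require start < end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval | tuple], label: str = "custom"
    ) -> "RegionSet":
        rows = []
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                rows.append((iv.chrom, iv.start, iv.end, iv.name, iv.score))
            else:
                chrom, start, end, *rest = iv
                name = rest[0] if rest else None
                score = rest[1] if len(rest) > 1 else None
                rows.append((chrom, int(start), int(end), name, score))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
        return cls(df, label=label)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom,
                int(row.start),
                int(row.end),
                getattr(row, "name", None),
                getattr(row, "score", None),
            )

    @property
    def total_bp(self) -> int:
        """Total covered base pairs after merging internal overlaps."""
        merged = merge(self)
        return int((merged.df["end"] - merged.df["start"]).sum())

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def merge(regions: RegionSet | Iterable, label: str | None = None) -> RegionSet:
    """Union overlapping or adjacent intervals into a minimal sorted set."""
    if not isinstance(regions, RegionSet):
        regions = RegionSet.from_intervals(regions)
    out_label = label if label is not None else regions.label
    if len(regions) == 0:
        return RegionSet(regions.df.loc[:, REGION_COLUMNS].copy(), label=out_label)
    rows = []
    for chrom, sub in regions.df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlapping or book-ended intervals fuse
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return RegionSet(pd.DataFrame(rows, columns=REGION_COLUMNS), label=out_label)


def overlap_bp(a: RegionSet, b: RegionSet) -> int:
    """Shared base pairs between two region sets (symmetric)."""
    ma, mb = merge(a).df, merge(b).df
    total = 0
    for chrom, sa in ma.groupby("chrom"):
        sb = mb[mb["chrom"] == chrom]
        if sb.empty:
            continue
        astarts, aends = sa["start"].to_numpy(), sa["end"].to_numpy()
        bstarts, bends = sb["start"].to_numpy(), sb["end"].to_numpy()
        i = j = 0
        while i < len(astarts) and j < len(bstarts):
            lo = max(astarts[i], bstarts[j])
            hi = min(aends[i], bends[j])
            if hi > lo:
                total += int(hi - lo)
            if aends[i] < bends[j]:
                i += 1
            else:
                j += 1
    return total


def shuffle_regions(
    regions: RegionSet,
    genome: Mapping[str, int],
    n: int,
    seed: int | np.random.Generator = 0,
    exclude: RegionSet | None = None,
    max_tries: int = 1000,
) -> list[RegionSet]:
    """Draw ``n`` length- and chromosome-preserving randomizations.

    Each interval is re-placed uniformly over all start positions that keep
    it on its own chromosome; when ``exclude`` is given, placements that
    touch the mask are rejection-sampled away.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = regions.df
    for row in df.itertuples(index=False):
        size = genome.get(row.chrom)
        if size is None:
            raise ValueError(f"chromosome {row.chrom} missing from genome")
        if row.end - row.start > size:
            raise ValueError(
                f"interval of {row.end - row.start} bp exceeds {row.chrom} ({size} bp)"
            )
    excl_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if exclude is not None:
        for chrom, sub in merge(exclude).df.groupby("chrom"):
            excl_by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())

    def hits_mask(chrom: str, start: int, end: int) -> bool:
        if chrom not in excl_by_chrom:
            return False
        s, e = excl_by_chrom[chrom]
        i = np.searchsorted(e, start, side="right")
        return i < len(s) and s[i] < end

    draws = []
    chroms = df["chrom"].to_numpy()
    lens = (df["end"] - df["start"]).to_numpy()
    for _ in range(n):
        rows = []
        for chrom, length in zip(chroms, lens):
            hi = genome[chrom] - int(length)
            for _try in range(max_tries):
                start = int(rng.integers(0, hi + 1))
                if not hits_mask(chrom, start, start + int(length)):
                    break
            else:
                raise RuntimeError(
                    f"could not place {length} bp interval on {chrom} outside mask"
                )
            rows.append((chrom, start, start + int(length)))
        draws.append(
            RegionSet(pd.DataFrame(rows, columns=REGION_COLUMNS), label="background")
        )
    return draws


def nearest_assignment(
    points: Sequence[tuple[str, int]] | pd.DataFrame,
    regions: RegionSet,
    window: int = 0,
) -> np.ndarray:
    """Flag each point that lies within ``window`` bp of some region.

    A point ``(chrom, pos)`` is near interval ``[s, e)`` iff
    ``s - window <= pos < e + window``.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    if isinstance(points, pd.DataFrame):
        pts = list(zip(points["chrom"], points["pos"]))
    else:
        pts = list(points)
    merged = merge(regions).df
    by_chrom = {
        chrom: (sub["start"].to_numpy() - window, sub["end"].to_numpy() + window)
        for chrom, sub in merged.groupby("chrom")
    }
    flags = np.zeros(len(pts), dtype=bool)
    for i, (chrom, pos) in enumerate(pts):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        j = np.searchsorted(ends, pos, side="right")
        flags[i] = j < len(starts) and starts[j] <= pos
    return flags


def distance_to_set(
    points: Sequence[tuple[str, int]] | pd.DataFrame, regions: RegionSet
) -> np.ndarray:
    """Distance in bp from each point to the nearest interval (0 if inside)."""
    if isinstance(points, pd.DataFrame):
        pts = list(zip(points["chrom"], points["pos"]))
    else:
        pts = list(points)
    merged = merge(regions).df
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in merged.groupby("chrom")
    }
    out = np.full(len(pts), np.inf)
    for i, (chrom, pos) in enumerate(pts):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        j = np.searchsorted(starts, pos, side="right")
        d = np.inf
        if j > 0:
            d = min(d, max(0, pos - (ends[j - 1] - 1)))
        if j < len(starts):
            d = min(d, max(0, starts[j] - pos))
        out[i] = d
    return out


def assign_nearest_label(
    points: pd.DataFrame,
    labelled_sets: Mapping[str, RegionSet],
    window: int,
    fallback: str = "non_accessible",
) -> pd.Series:
    """Assign each point the label of the closest region set within ``window``.

    Ties are broken by the iteration order of ``labelled_sets``; points
    further than ``window`` from every set get ``fallback``.
    """
    n = len(points)
    best = np.full(n, np.inf)
    labels = pd.Series([fallback] * n, index=points.index, dtype=object)
    for label, regions in labelled_sets.items():
        if len(regions) == 0:
            continue
        d = distance_to_set(points, regions)
        take = (d <= window) & (d < best)
        best = np.where(take, d, best)
        labels[take] = label
    return labels


# ---------------------------------------------------------------------------
# file I/O — BED / chrom.sizes / bedGraph-style score tracks
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, label: str = "custom") -> RegionSet:
    """Read BED3/BED6 (tab-separated, no header, '#' comments allowed)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(df.shape[1], 6)]
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols
    return RegionSet(df, label=label)


def write_bed(regions: RegionSet, path: str | Path, header: str | None = None) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score"] if c in regions.df.columns]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        regions.df.loc[:, cols].to_csv(fh, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.items():
            fh.write(f"{chrom}\t{size}\n")


@dataclass
class ScoreTrack:
    """bedGraph-style per-bp score track: constant score over each interval.

    Bases not covered by any interval have no score (gaps are skipped, not
    zero-filled, by consumers).
    """

    df: pd.DataFrame  # columns chrom, start, end, score

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "score"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"score track needs columns {sorted(need)}")
        self.df = self.df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def read(cls, path: str | Path) -> "ScoreTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "score"],
        )
        return cls(df)

    def write(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.df.to_csv(fh, sep="\t", header=False, index=False)

    def per_base_arrays(self, genome: Mapping[str, int]) -> dict[str, np.ndarray]:
        """Expand to one float array per chromosome with NaN at uncovered bases."""
        arrays = {c: np.full(int(s), np.nan) for c, s in genome.items()}
        for row in self.df.itertuples(index=False):
            if row.chrom in arrays:
                arrays[row.chrom][int(row.start): int(row.end)] = row.score
        return arrays

    def value_at(self, chrom: str, pos: int) -> float:
        """Score at one base, NaN if uncovered."""
        sub = self.df[self.df["chrom"] == chrom]
        if sub.empty:
            return float("nan")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        scores = sub["score"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        if j >= 0 and pos < ends[j]:
            return float(scores[j])
        return float("nan")
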