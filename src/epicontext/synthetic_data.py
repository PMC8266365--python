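"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a multi-tissue
fetal/adult chromatin-accessibility study: negative-binomial read-count
matrices over called regions with planted stage-biased accessibility
shifts (and nested young/old shifts inside them), per-replicate peak
calls, per-bp conservation tracks that differ between region classes,
variant tables with a realistic MAF spectrum and planted pleiotropic GWAS
signal near a chosen region class, gene annotations, promoter-capture
pairs and expression matrices. Planted labels are returned as a
:class:`GroundTruth` so every downstream stage has a recoverable oracle.

Counts are overdispersed (gamma-Poisson) so the moderated variance model
downstream has real work to do; all coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .diffacc import SampleMeta, meta_frame
from .genomic_core import (
    RegionSet,
    ScoreTrack,
    merge,
    write_bed,
    write_chrom_sizes,
)


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults describe a desk-scale genome (two 500 kb chromosomes) with
    three tissues sampled at fetal and adult stages, four replicates per
    tissue/stage, moderate planted accessibility shifts (|log2 FC| = 2)
    and mildly overdispersed counts.
    """

    n_chrom: int = 2
    chrom_len: int = 500_000
    n_regions: int = 300
    region_len: int = 400
    n_tissues: int = 3
    replicates_per_group: int = 4
    frac_adult_biased: float = 0.15
    frac_fetal_biased: float = 0.15
    effect_logfc: float = 2.0
    dispersion: float = 0.1
    # nested young/old structure inside developmentally-altered regions
    frac_age_nested: float = 0.4
    age_share_direction: float = 0.8
    age_effect_logfc: float = 1.5
    # variants / GWAS
    n_variants: int = 4000
    n_diseases: int = 50
    frac_pleiotropic: float = 0.02
    pleiotropy_strength: float = 3.0
    pleiotropy_disease_frac: float = 0.7
    pleiotropy_target: str = "adult_biased"
    n_pleiotropy_hubs: int = 6
    frac_clinical: float = 0.01
    proximity_window: int = 10_000
    # conservation / allele age / functional scores
    cons_shift: float = 0.5
    cons_noise_sd: float = 1.0
    conserved_quantile: float = 0.9
    age_mixing_weight: float = 0.7
    allele_age_mean: float = 1.0
    allele_age_mean_conserved: float = 0.3
    # genes / expression
    n_genes: int = 200
    locus_window: int = 10_000
    frac_expr_shift: float = 0.1
    frac_expr_antagonistic: float = 0.05
    frac_expr_age: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chrom", "chrom_len", "n_regions", "region_len", "n_tissues",
            "replicates_per_group", "n_variants", "n_diseases", "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.frac_adult_biased + self.frac_fetal_biased > 1:
            raise ValueError("biased fractions must sum to <= 1")
        if self.chrom_len <= self.region_len:
            raise ValueError("chrom_len must exceed region length")

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len for i in range(self.n_chrom)}

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic independent stream keyed on (seed, stream)."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted labels recoverable by the pipeline."""

    region_labels: dict[str, str] = field(default_factory=dict)  # adult/fetal/null
    nested_age_labels: dict[str, str] = field(default_factory=dict)  # young/old/null
    pleiotropic_variants: set[str] = field(default_factory=set)
    clinical_variants: set[str] = field(default_factory=set)
    core_genes: set[str] = field(default_factory=set)
    expr_adult_up: set[str] = field(default_factory=set)
    expr_fetal_up: set[str] = field(default_factory=set)
    expr_age_genes: set[str] = field(default_factory=set)

    def region_ids(self, label: str) -> list[str]:
        return [r for r, l in self.region_labels.items() if l == label]

    def nested_ids(self, label: str) -> list[str]:
        return [r for r, l in self.nested_age_labels.items() if l == label]


# ---------------------------------------------------------------------------
# regions + accessibility counts
# ---------------------------------------------------------------------------


def simulate_regions(cfg: SimConfig) -> tuple[RegionSet, GroundTruth]:
    """Place non-overlapping equal-length regions on a grid with jitter and
    assign planted class labels."""
    rng = cfg.rng(1)
    per_chrom = int(np.ceil(cfg.n_regions / cfg.n_chrom))
    rows = []
    idx = 0
    for c in range(cfg.n_chrom):
        spacing = cfg.chrom_len // (per_chrom + 1)
        if spacing <= cfg.region_len:
            raise ValueError("too many regions for the genome size")
        jitter_span = max(1, (spacing - cfg.region_len) // 2)
        for k in range(per_chrom):
            if idx >= cfg.n_regions:
                break
            anchor = (k + 1) * spacing
            start = int(anchor + rng.integers(-jitter_span, jitter_span))
            start = max(0, min(start, cfg.chrom_len - cfg.region_len))
            rows.append((f"chr{c + 1}", start, start + cfg.region_len, f"r{idx:05d}"))
            idx += 1
    regions = RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]), label="custom"
    )
    ids = regions.df["name"].tolist()
    n_adult = int(round(cfg.frac_adult_biased * cfg.n_regions))
    n_fetal = int(round(cfg.frac_fetal_biased * cfg.n_regions))
    perm = rng.permutation(len(ids))
    truth = GroundTruth()
    for j, i in enumerate(perm):
        if j < n_adult:
            truth.region_labels[ids[i]] = "adult"
        elif j < n_adult + n_fetal:
            truth.region_labels[ids[i]] = "fetal"
        else:
            truth.region_labels[ids[i]] = "null"
    # nested young/old shifts inside dev-altered regions; direction shared
    # with the developmental bias a stated fraction of the time
    dev = [r for r in ids if truth.region_labels[r] != "null"]
    n_nested = int(round(cfg.frac_age_nested * len(dev)))
    nested = list(rng.permutation(dev)[:n_nested])
    for r in ids:
        truth.nested_age_labels[r] = "null"
    for r in nested:
        share = rng.random() < cfg.age_share_direction
        dev_gain = truth.region_labels[r] == "adult"  # gains accessibility over dev
        age_gain = dev_gain if share else not dev_gain
        truth.nested_age_labels[r] = "old" if age_gain else "young"
    return regions, truth


def simulate_samples(cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet: tissues x {fetal, adult} x replicates; adult replicates
    alternate young/old ages so the 50-year split is balanced."""
    ages = [30.0, 40.0, 60.0, 70.0]
    samples = []
    for t in range(cfg.n_tissues):
        tissue = f"tissue{t + 1}"
        for stage in ("fetal", "adult"):
            for rep in range(cfg.replicates_per_group):
                age = ages[rep % len(ages)] if stage == "adult" else None
                samples.append(
                    SampleMeta(
                        sample_id=f"{tissue}_{stage}_rep{rep + 1}",
                        tissue=tissue,
                        stage=stage,
                        age=age,
                        replicate=rep + 1,
                    )
                )
    return meta_frame(samples)


def simulate_accessibility(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, RegionSet, GroundTruth]:
    """Negative-binomial count matrix with planted stage and age shifts.

    Returns ``(counts, meta, regions, truth)``. Adult-biased regions carry
    a +effect_logfc adult/fetal log2 fold-change in every tissue,
    fetal-biased -effect_logfc, null regions none; nested age shifts add
    ±age_effect_logfc between old and young adults.
    """
    regions, truth = simulate_regions(cfg)
    meta = simulate_samples(cfg)
    rng = cfg.rng(2)
    ids = regions.df["name"].tolist()
    n_r, n_s = len(ids), len(meta)
    base = rng.lognormal(mean=np.log(100.0), sigma=0.7, size=n_r)
    beta = np.array(
        [
            {"adult": cfg.effect_logfc, "fetal": -cfg.effect_logfc, "null": 0.0}[
                truth.region_labels[r]
            ]
            for r in ids
        ]
    )
    gamma = np.array(
        [
            {"old": cfg.age_effect_logfc, "young": -cfg.age_effect_logfc, "null": 0.0}[
                truth.nested_age_labels[r]
            ]
            for r in ids
        ]
    )
    x = np.where(meta["stage"] == "adult", 0.5, -0.5)  # stage half-coding
    is_adult = (meta["stage"] == "adult").to_numpy()
    old = np.zeros(n_s)
    old[is_adult] = np.where(meta.loc[is_adult, "age"] >= 50, 0.5, -0.5)
    mu = base[:, None] * 2.0 ** (beta[:, None] * x[None, :] + gamma[:, None] * old[None, :])
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=ids, columns=meta["sample_id"])
    return counts_df, meta, regions, truth


def simulate_replicate_peaks(
    cfg: SimConfig, regions: RegionSet
) -> dict[tuple[str, str], list[RegionSet]]:
    """Per-replicate peak calls: each true region appears in most replicates
    with jittered boundaries, plus singleton noise peaks that reproducible-
    region consolidation should drop."""
    rng = cfg.rng(3)
    out: dict[tuple[str, str], list[RegionSet]] = {}
    df = regions.df
    for t in range(cfg.n_tissues):
        tissue = f"tissue{t + 1}"
        for stage in ("fetal", "adult"):
            reps = []
            for _rep in range(cfg.replicates_per_group):
                present = rng.random(len(df)) < 0.9
                sub = df.loc[present, ["chrom", "start", "end"]].copy()
                jit = rng.integers(-20, 21, size=(len(sub), 2))
                sub["start"] = np.maximum(0, sub["start"] + jit[:, 0])
                sub["end"] = np.minimum(cfg.chrom_len, sub["end"] + jit[:, 1])
                sub = sub[sub["start"] < sub["end"]]
                # singleton noise peaks, unique to this replicate
                n_noise = max(1, len(df) // 20)
                starts = rng.integers(0, cfg.chrom_len - cfg.region_len, size=n_noise)
                chroms = [f"chr{int(c) + 1}" for c in rng.integers(0, cfg.n_chrom, n_noise)]
                noise = pd.DataFrame(
                    {"chrom": chroms, "start": starts, "end": starts + cfg.region_len}
                )
                reps.append(RegionSet(pd.concat([sub, noise], ignore_index=True)))
            out[(tissue, stage)] = reps
    return out


# ---------------------------------------------------------------------------
# conservation tracks / conserved elements
# ---------------------------------------------------------------------------


def simulate_tracks(
    cfg: SimConfig, regions: RegionSet, truth: GroundTruth
) -> tuple[ScoreTrack, RegionSet]:
    """Per-bp conservation over the region space and conserved elements.

    Fetal-biased regions get a mean shifted up by ``cons_shift``
    (phyloP-like units) relative to adult-biased and null regions;
    conserved elements are the merged runs of bases whose score exceeds
    the ``conserved_quantile`` of all emitted scores.
    """
    rng = cfg.rng(4)
    rows = []
    all_scores = []
    for row in regions.df.itertuples(index=False):
        label = truth.region_labels.get(row.name, "null")
        mu = cfg.cons_shift if label == "fetal" else 0.0
        scores = rng.normal(mu, cfg.cons_noise_sd, size=int(row.end - row.start))
        all_scores.append(scores)
        pos = np.arange(int(row.start), int(row.end))
        rows.append(
            pd.DataFrame(
                {"chrom": row.chrom, "start": pos, "end": pos + 1, "score": scores}
            )
        )
    track = ScoreTrack(pd.concat(rows, ignore_index=True))
    threshold = float(np.quantile(np.concatenate(all_scores), cfg.conserved_quantile))
    above = track.df[track.df["score"] > threshold]
    if above.empty:
        elements = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    else:
        elements = merge(
            RegionSet(above.loc[:, ["chrom", "start", "end"]].copy()), label="custom"
        )
    track.df.attrs["conserved_threshold"] = threshold
    return track, elements


# ---------------------------------------------------------------------------
# variants + GWAS panel
# ---------------------------------------------------------------------------


def simulate_gwas_panel(
    cfg: SimConfig,
    regions: RegionSet,
    truth: GroundTruth,
    conserved_elements: RegionSet | None = None,
    track: ScoreTrack | None = None,
) -> tuple[pd.DataFrame, "GwasPanel"]:
    """Variant table and per-disease summary statistics with planted signal.

    Non-pleiotropic variants draw per-disease Z ~ N(0,1); pleiotropic
    variants sit within ``proximity_window`` of the designated region class
    and draw |mean| = pleiotropy_strength Z (random sign per disease) in a
    majority of diseases. MAF follows a Beta(0.6, 2.2)/2 spectrum, giving
    appreciable mass on both sides of the 0.05 common-variant threshold.
    A small clinical set mirrors annotated risk variants with the same
    boost. Allele age is anti-correlated with conserved-element membership
    through ``age_mixing_weight``; the functional score reads the
    conservation track at the variant base (unit-normal noise off-track).
    """
    from .gwas import GwasPanel
    from .genomic_core import nearest_assignment

    if len(regions) == 0:
        raise ValueError("regions must be simulated first")
    rng = cfg.rng(5)
    n = cfg.n_variants
    genome = cfg.genome
    chrom_names = list(genome)
    chroms = [chrom_names[int(c)] for c in rng.integers(0, len(chrom_names), n)]
    pos = rng.integers(0, cfg.chrom_len, size=n)

    # re-place planted pleiotropic variants near the target region class
    target_label = {"adult_biased": "adult", "fetal_biased": "fetal"}.get(
        cfg.pleiotropy_target, cfg.pleiotropy_target
    )
    target_ids = truth.region_ids(target_label)
    # concentrate the planted signal on a handful of target regions so the
    # implied core-gene set stays small relative to the gene universe
    if target_ids:
        k = min(cfg.n_pleiotropy_hubs, len(target_ids))
        target_ids = list(np.array(target_ids)[rng.permutation(len(target_ids))[:k]])
    n_pleio = int(round(cfg.frac_pleiotropic * n))
    pleio_idx = rng.permutation(n)[:n_pleio] if target_ids else np.array([], dtype=int)
    tdf = regions.df.set_index("name")
    for i in pleio_idx:
        r = target_ids[int(rng.integers(0, len(target_ids)))]
        row = tdf.loc[r]
        lo = max(0, int(row["start"]) - cfg.proximity_window // 2)
        hi = min(cfg.chrom_len, int(row["end"]) + cfg.proximity_window // 2)
        chroms[i] = row["chrom"]
        pos[i] = int(rng.integers(lo, hi))

    ids = [f"v{i:06d}" for i in range(n)]
    maf = rng.beta(0.6, 2.2, size=n) * 0.5
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": pos, "maf": maf}
    )

    pleio = np.zeros(n, dtype=bool)
    pleio[pleio_idx] = True
    n_clin = int(round(cfg.frac_clinical * n))
    clin_pool = np.where(~pleio)[0]
    clin_idx = rng.permutation(clin_pool)[:n_clin]
    clinical = np.zeros(n, dtype=bool)
    clinical[clin_idx] = True

    Z = rng.normal(0.0, 1.0, size=(n, cfg.n_diseases))
    for idx_set, strength in ((pleio_idx, cfg.pleiotropy_strength),
                              (clin_idx, cfg.pleiotropy_strength)):
        for i in idx_set:
            hit = rng.random(cfg.n_diseases) < cfg.pleiotropy_disease_frac
            signs = rng.choice([-1.0, 1.0], size=cfg.n_diseases)
            Z[i, hit] = rng.normal(strength * signs[hit], 1.0)
    from scipy import stats as _stats

    P = 2.0 * _stats.norm.sf(np.abs(Z))
    P = np.clip(P, np.finfo(float).tiny, 1.0)
    diseases = [f"disease{d + 1:03d}" for d in range(cfg.n_diseases)]
    pvalues = pd.DataFrame(P, index=ids, columns=diseases)
    betas = pd.DataFrame(Z * 0.05, index=ids, columns=diseases)
    panel = GwasPanel(pvalues=pvalues, betas=betas)

    truth.pleiotropic_variants = set(np.array(ids)[pleio])
    truth.clinical_variants = set(np.array(ids)[clinical])
    variants["pleiotropic"] = pleio
    variants["clinical"] = clinical

    # evolutionary annotations
    if conserved_elements is not None:
        in_cons = nearest_assignment(
            list(zip(variants["chrom"], variants["pos"])), conserved_elements, window=0
        )
    else:
        in_cons = np.zeros(n, dtype=bool)
    age = rng.gamma(2.0, cfg.allele_age_mean / 2.0, size=n)
    young = rng.gamma(2.0, cfg.allele_age_mean_conserved / 2.0, size=n)
    use_young = in_cons & (rng.random(n) < cfg.age_mixing_weight)
    variants["allele_age"] = np.where(use_young, young, age)
    if track is not None:
        arrays = track.per_base_arrays(genome)
        fs = np.array(
            [arrays[c][p] for c, p in zip(variants["chrom"], variants["pos"])]
        )
        noise = rng.normal(0.0, cfg.cons_noise_sd, size=n)
        variants["functional_score"] = np.where(np.isnan(fs), noise, fs)
    else:
        variants["functional_score"] = rng.normal(0.0, cfg.cons_noise_sd, size=n)
    variants["in_conserved_element"] = in_cons
    return variants, panel


# ---------------------------------------------------------------------------
# genes, capture pairs, expression
# ---------------------------------------------------------------------------


def simulate_genes(cfg: SimConfig) -> pd.DataFrame:
    rng = cfg.rng(6)
    chrom_names = list(cfg.genome)
    chroms = [chrom_names[int(c)] for c in rng.integers(0, len(chrom_names), cfg.n_genes)]
    tss = rng.integers(cfg.locus_window, cfg.chrom_len - cfg.locus_window, cfg.n_genes)
    strand = rng.choice(["+", "-"], size=cfg.n_genes)
    return pd.DataFrame(
        {
            "gene": [f"g{i:04d}" for i in range(cfg.n_genes)],
            "chrom": chroms,
            "tss": tss,
            "strand": strand,
        }
    )


def derive_core_genes(
    cfg: SimConfig, genes: pd.DataFrame, variants: pd.DataFrame, truth: GroundTruth
) -> set[str]:
    """Core genes = genes whose locus window contains a planted pleiotropic
    variant (computed from placement, not from simulated statistics)."""
    pleio = variants[variants["pleiotropic"]]
    core = set()
    for row in genes.itertuples(index=False):
        hit = (
            (pleio["chrom"] == row.chrom)
            & (pleio["pos"] >= row.tss - cfg.locus_window)
            & (pleio["pos"] < row.tss + cfg.locus_window)
        )
        if hit.any():
            core.add(row.gene)
    truth.core_genes = core
    return core


def simulate_capture_pairs(
    cfg: SimConfig, regions: RegionSet, genes: pd.DataFrame
) -> pd.DataFrame:
    """Promoter-capture pairs: each region contacts its nearest gene in 2-3
    tissues (reproducible) and a random gene in exactly 1 tissue (noise)."""
    rng = cfg.rng(7)
    tissues = [f"tissue{t + 1}" for t in range(max(3, cfg.n_tissues))]
    rows = []
    gsub = {c: sub for c, sub in genes.groupby("chrom")}
    for row in regions.df.itertuples(index=False):
        sub = gsub.get(row.chrom)
        if sub is None or sub.empty:
            continue
        mid = (row.start + row.end) // 2
        nearest = sub.iloc[(sub["tss"] - mid).abs().argmin()]
        n_t = int(rng.integers(2, 4))
        for t in rng.permutation(tissues)[:n_t]:
            rows.append((row.chrom, row.start, row.end, nearest["gene"], t))
        noise_gene = genes["gene"].iloc[int(rng.integers(0, len(genes)))]
        rows.append((row.chrom, row.start, row.end, noise_gene,
                     tissues[int(rng.integers(0, len(tissues)))]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "tissue"])
    return df.drop_duplicates().reset_index(drop=True)


def simulate_expression(
    cfg: SimConfig, genes: pd.DataFrame, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-expression counts with planted cross-tissue consistent shifts,
    antagonistic (mixed-sign) genes that the consistency rule must not
    call, and young/old shifted genes for the adult age contrast."""
    rng = cfg.rng(8)
    meta = simulate_samples(cfg)
    gids = genes["gene"].tolist()
    n_g, n_s = len(gids), len(meta)
    n_shift = int(round(cfg.frac_expr_shift * n_g))
    n_ant = int(round(cfg.frac_expr_antagonistic * n_g))
    n_age = int(round(cfg.frac_expr_age * n_g))
    perm = rng.permutation(n_g)
    adult_up = perm[:n_shift]
    fetal_up = perm[n_shift: 2 * n_shift]
    antagonistic = perm[2 * n_shift: 2 * n_shift + n_ant]
    age_genes = perm[2 * n_shift + n_ant: 2 * n_shift + n_ant + n_age]
    truth.expr_adult_up = {gids[i] for i in adult_up}
    truth.expr_fetal_up = {gids[i] for i in fetal_up}
    truth.expr_age_genes = {gids[i] for i in age_genes}

    base = rng.lognormal(np.log(200.0), 0.8, size=n_g)
    x = np.where(meta["stage"] == "adult", 0.5, -0.5)
    is_adult = (meta["stage"] == "adult").to_numpy()
    old = np.zeros(n_s)
    old[is_adult] = np.where(meta.loc[is_adult, "age"] >= 50, 0.5, -0.5)
    tissue_idx = meta["tissue"].str.extract(r"(\d+)$")[0].astype(int).to_numpy() - 1

    beta = np.zeros((n_g, cfg.n_tissues))
    beta[adult_up, :] = cfg.effect_logfc
    beta[fetal_up, :] = -cfg.effect_logfc
    # antagonistic: strong shift whose sign flips between tissues
    for i in antagonistic:
        signs = rng.choice([-1.0, 1.0], size=cfg.n_tissues)
        if np.all(signs == signs[0]):
            signs[0] = -signs[0]
        beta[i, :] = signs * cfg.effect_logfc
    gamma = np.zeros(n_g)
    gamma[age_genes] = np.where(rng.random(n_age) < 0.5, 1.0, -1.0) * cfg.age_effect_logfc

    logmu = (
        np.log2(base)[:, None]
        + beta[:, tissue_idx] * x[None, :]
        + gamma[:, None] * old[None, :]
    )
    mu = 2.0 ** logmu
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam)
    expr = pd.DataFrame(counts, index=gids, columns=meta["sample_id"])
    return expr, meta


# ---------------------------------------------------------------------------
# orchestration + disk round-trip
# ---------------------------------------------------------------------------


@dataclass
class SimData:
    """Everything one simulated study produces, in memory."""

    cfg: SimConfig
    regions: RegionSet
    truth: GroundTruth
    counts: pd.DataFrame
    meta: pd.DataFrame
    replicate_peaks: dict
    track: ScoreTrack
    conserved_elements: RegionSet
    variants: pd.DataFrame
    panel: object
    genes: pd.DataFrame
    capture_pairs: pd.DataFrame
    expression: pd.DataFrame
    expr_meta: pd.DataFrame

    def truth_region_sets(self) -> dict[str, RegionSet]:
        """Region sets keyed by planted class label (truth, not calls)."""
        rdf = self.regions.df.set_index("name")
        out = {}
        for label, key in (
            ("adult_biased", "adult"),
            ("fetal_biased", "fetal"),
            ("unaltered", "null"),
        ):
            ids = self.truth.region_ids(key)
            sub = rdf.loc[ids].reset_index()
            out[label] = RegionSet(
                sub.loc[:, ["chrom", "start", "end", "name"]], label=label
            )
        for label, key in (("young_biased", "young"), ("old_biased", "old")):
            ids = self.truth.nested_ids(key)
            sub = rdf.loc[ids].reset_index()
            out[label] = RegionSet(
                sub.loc[:, ["chrom", "start", "end", "name"]], label=label
            )
        return out


def simulate_all(cfg: SimConfig) -> SimData:
    """Run every generator stage in dependency order under one seed."""
    counts, meta, regions, truth = simulate_accessibility(cfg)
    peaks = simulate_replicate_peaks(cfg, regions)
    track, elements = simulate_tracks(cfg, regions, truth)
    variants, panel = simulate_gwas_panel(
        cfg, regions, truth, conserved_elements=elements, track=track
    )
    genes = simulate_genes(cfg)
    derive_core_genes(cfg, genes, variants, truth)
    capture = simulate_capture_pairs(cfg, regions, genes)
    expr, expr_meta = simulate_expression(cfg, genes, truth)
    return SimData(
        cfg=cfg,
        regions=regions,
        truth=truth,
        counts=counts,
        meta=meta,
        replicate_peaks=peaks,
        track=track,
        conserved_elements=elements,
        variants=variants,
        panel=panel,
        genes=genes,
        capture_pairs=capture,
        expression=expr,
        expr_meta=expr_meta,
    )


def write_simulation(sim: SimData, outdir: str | Path, header: str = "") -> None:
    """Write the study to plain-text files (BED/TSV/YAML)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(sim.cfg.genome, out / "genome.chrom.sizes")
    write_bed(sim.regions, out / "regions.bed", header=header)
    write_bed(sim.conserved_elements, out / "conserved_elements.bed", header=header)
    sim.track.write(out / "conservation.bedgraph", header=header)

    def tsv(df: pd.DataFrame, path: Path, index: bool) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            df.to_csv(fh, sep="\t", index=index)

    tsv(sim.counts, out / "counts.tsv", True)
    tsv(sim.meta, out / "samples.tsv", False)
    tsv(sim.variants, out / "variants.tsv", False)
    tsv(sim.genes, out / "genes.tsv", False)
    tsv(sim.capture_pairs, out / "capture_pairs.tsv", False)
    tsv(sim.expression, out / "expression.tsv", True)
    tsv(sim.expr_meta, out / "expression_samples.tsv", False)
    gdir = out / "gwas"
    gdir.mkdir(exist_ok=True)
    manifest = []
    vmap = sim.variants.set_index("id")
    for disease in sim.panel.diseases:
        t = pd.DataFrame(
            {
                "id": sim.panel.variant_universe,
                "chrom": vmap["chrom"].to_numpy(),
                "pos": vmap["pos"].to_numpy(),
                "beta": (
                    sim.panel.betas[disease].to_numpy()
                    if sim.panel.betas is not None
                    else np.nan
                ),
                "p": sim.panel.pvalues[disease].to_numpy(),
            }
        )
        fn = f"{disease}.tsv"
        tsv(t, gdir / fn, False)
        manifest.append((disease, f"gwas/{fn}", "aging"))
    tsv(
        pd.DataFrame(manifest, columns=["disease", "path", "category"]),
        out / "gwas_manifest.tsv",
        False,
    )
    peaks_rows = []
    for (tissue, stage), reps in sim.replicate_peaks.items():
        for k, rep in enumerate(reps):
            d = rep.df.copy()
            d["tissue"], d["stage"], d["replicate"] = tissue, stage, k + 1
            peaks_rows.append(d)
    tsv(pd.concat(peaks_rows, ignore_index=True), out / "replicate_peaks.tsv", False)
    def plain(names):  # numpy str scalars are not YAML-representable
        return [str(x) for x in sorted(names)]

    truth_doc = {
        "region_labels": {str(k): str(v) for k, v in sim.truth.region_labels.items()},
        "nested_age_labels": {
            str(k): str(v) for k, v in sim.truth.nested_age_labels.items()
        },
        "pleiotropic_variants": plain(sim.truth.pleiotropic_variants),
        "clinical_variants": plain(sim.truth.clinical_variants),
        "core_genes": plain(sim.truth.core_genes),
        "expr_adult_up": plain(sim.truth.expr_adult_up),
        "expr_fetal_up": plain(sim.truth.expr_fetal_up),
        "expr_age_genes": plain(sim.truth.expr_age_genes),
        "config": asdict(sim.cfg),
    }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)
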