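"""Stage orchestration behind the command-line interface.

A single YAML config drives every stage; outputs are TSV/BED files whose
first line records the config hash and seed so any results directory can
be traced back to the exact run that produced it. Stage toggles let the
pipeline degrade gracefully when an analysis is switched off.

Key thresholds (named here once, used everywhere): differential calls at
Benjamini-Hochberg FDR < 0.05; common variants at MAF >= 0.05; adult age
split at 50 years; promoter windows TSS +/- 1 kb; promoter-capture pairs
reproducible in >= 2 tissues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffacc, evo, expression, gene_links, generank, gwas
from .genomic_core import RegionSet, read_bed, write_bed
from .synthetic_data import SimConfig, SimData, simulate_all, write_simulation

log = logging.getLogger("epicontext")

DEFAULT_STAGES = ("consolidate", "diffacc", "evo", "gwas", "generank", "expression")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "epicontext_results",
    "stages": list(DEFAULT_STAGES),
    "simulate": {},  # SimConfig overrides
    "fdr_cut": 0.05,
    "maf_cut": 0.05,
    "age_split": 50,
    "promoter_pad": 1000,
    "capture_min_tissues": 2,
    "proximity_window": 10000,
    "locus_window": 20000,
    "min_support": 2,
    "p_strong": 1e-5,
    "n_perm_enrichment": 100,
    "n_perm_generank": 999,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a YAML mapping")
    cfg = {**DEFAULT_CONFIG, **user}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    bad_stages = set(cfg["stages"]) - set(DEFAULT_STAGES)
    if bad_stages:
        raise ConfigError(f"unknown stages: {sorted(bad_stages)}")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    bad_sim = set(cfg["simulate"]) - sim_fields
    if bad_sim:
        raise ConfigError(f"unknown simulate keys: {sorted(bad_sim)}")
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def sim_config(cfg: Mapping) -> SimConfig:
    params = dict(cfg.get("simulate", {}))
    params.setdefault("seed", cfg["seed"])
    params.setdefault("proximity_window", cfg["proximity_window"])
    params.setdefault("locus_window", cfg["locus_window"])
    return SimConfig(**params)


def _header(cfg: Mapping) -> str:
    return f"epicontext config_hash={config_hash(cfg)} seed={cfg['seed']}"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: Mapping, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg)}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_simulate(cfg: Mapping) -> SimData:
    sim = simulate_all(sim_config(cfg))
    outdir = Path(cfg["outdir"])
    write_simulation(sim, outdir / "inputs", header=_header(cfg))
    log.info(
        "simulated %d regions, %d samples, %d variants, %d diseases, %d genes",
        len(sim.regions), len(sim.meta), len(sim.variants),
        len(sim.panel.diseases), len(sim.genes),
    )
    return sim


def run_pipeline(cfg: Mapping, sim: SimData | None = None) -> dict:
    """Execute the enabled stages in dependency order; returns a summary
    dict (also written to ``<outdir>/report.yaml``)."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    if sim is None:
        sim = run_simulate(cfg)
    stages = list(cfg["stages"])
    report: dict[str, Any] = {"config_hash": config_hash(cfg), "seed": cfg["seed"]}
    state: dict[str, Any] = {}

    if "consolidate" in stages:
        consolidated = diffacc.consolidate_peaks(
            sim.replicate_peaks, min_support=cfg["min_support"]
        )
        write_bed(consolidated, outdir / "consolidated_peaks.bed", header=_header(cfg))
        report["consolidate"] = {
            "n_peaks": len(consolidated),
            "total_bp": consolidated.total_bp,
        }
        log.info("consolidated %d reproducible peaks", len(consolidated))

    called_sets: dict[str, RegionSet] = {}
    if "diffacc" in stages:
        res = diffacc.differential_accessibility(sim.counts, sim.meta)
        adult_set, fetal_set = diffacc.call_stage_sets(
            res, sim.regions, fdr_cut=cfg["fdr_cut"]
        )
        _write_tsv(res, outdir / "diffacc_results.tsv", cfg)
        write_bed(adult_set, outdir / "adult_biased.bed", header=_header(cfg))
        write_bed(fetal_set, outdir / "fetal_biased.bed", header=_header(cfg))
        called_sets["adult_biased"] = adult_set
        called_sets["fetal_biased"] = fetal_set
        dev_ids = list(adult_set.df["name"]) + list(fetal_set.df["name"])
        report["diffacc"] = {
            "n_adult_biased": len(adult_set),
            "n_fetal_biased": len(fetal_set),
        }
        truth_dev = set(sim.truth.region_ids("adult")) | set(sim.truth.region_ids("fetal"))
        report["diffacc"]["recovery"] = diffacc.recovery_metrics(
            set(dev_ids), truth_dev, sim.counts.index
        )
        log.info(
            "diffacc: %d adult-biased, %d fetal-biased regions",
            len(adult_set), len(fetal_set),
        )
        if dev_ids and sim.cfg.replicates_per_group >= 2:
            age_res = diffacc.nested_age_contrast(
                sim.counts, sim.meta, dev_ids, age_split=cfg["age_split"],
                fdr_cut=cfg["fdr_cut"],
            )
            old_set, young_set = diffacc.call_stage_sets(
                age_res, sim.regions, fdr_cut=cfg["fdr_cut"],
                pos_label="old_biased", neg_label="young_biased",
            )
            _write_tsv(age_res, outdir / "nested_age_results.tsv", cfg)
            write_bed(old_set, outdir / "old_biased.bed", header=_header(cfg))
            write_bed(young_set, outdir / "young_biased.bed", header=_header(cfg))
            called_sets["old_biased"] = old_set
            called_sets["young_biased"] = young_set
            both = res.loc[
                res.index.intersection(age_res.index[age_res["fdr"] < cfg["fdr_cut"]])
            ]
            both = both[both["fdr"] < cfg["fdr_cut"]]
            dir_test = diffacc.directionality_test(
                both["direction"], age_res.loc[both.index, "direction"]
            )
            report["diffacc"]["nested"] = {
                "n_old_biased": len(old_set),
                "n_young_biased": len(young_set),
                "directionality_chi2": dir_test["statistic"],
                "directionality_p": dir_test["p"],
            }
        # promoter accessibility via the same engine
        prom = diffacc.promoter_windows(
            sim.genes, pad=cfg["promoter_pad"], genome=sim.cfg.genome
        )
        report["diffacc"]["n_promoters"] = len(prom)
        state["promoters"] = prom
    else:
        # fall back to planted truth sets so downstream stages can run
        called_sets = sim.truth_region_sets()
        state["promoters"] = diffacc.promoter_windows(
            sim.genes, pad=cfg["promoter_pad"], genome=sim.cfg.genome
        )

    if "diffacc" in stages and "adult_biased" in called_sets:
        dev_called = set(called_sets["adult_biased"].df.get("name", [])) | set(
            called_sets["fetal_biased"].df.get("name", [])
        )
        rest = sim.regions.df[~sim.regions.df["name"].isin(dev_called)]
        called_sets["unaltered"] = RegionSet(
            rest.loc[:, ["chrom", "start", "end", "name"]], label="unaltered"
        )
    # nested (age) classes first so they take precedence over the broader
    # developmental classes when a variant sits inside both
    order = ["young_biased", "old_biased", "adult_biased", "fetal_biased", "unaltered"]
    labelled = {
        k: called_sets[k] for k in order if k in called_sets and len(called_sets[k])
    }

    if "evo" in stages and labelled:
        rng = np.random.default_rng([int(cfg["seed"]), 99])
        evo_report = {}
        cons = {
            label: evo.region_conservation(rs, sim.track, sim.cfg.genome)
            for label, rs in labelled.items()
        }
        if "fetal_biased" in cons and "adult_biased" in cons:
            cmp_res = evo.compare_sets(
                cons["fetal_biased"]["mean_score"], cons["adult_biased"]["mean_score"]
            )
            evo_report["conservation_fetal_vs_adult"] = cmp_res
        enr = {}
        for label, rs in labelled.items():
            r = evo.feature_enrichment(
                rs, sim.conserved_elements, sim.cfg.genome,
                n_perm=cfg["n_perm_enrichment"], seed=rng,
            )
            enr[label] = r.as_dict()
        evo_report["conserved_element_enrichment"] = enr
        dens = {
            label: evo.variant_density(
                rs, sim.variants, sim.cfg.genome, maf_cut=cfg["maf_cut"],
                n_perm=cfg["n_perm_enrichment"], seed=rng,
            )
            for label, rs in labelled.items()
        }
        evo_report["common_variant_density"] = {
            k: {kk: vv for kk, vv in v.items() if kk != "feature_densities"}
            for k, v in dens.items()
        }
        report["evo"] = evo_report
        state["conservation"] = cons
        log.info("evo: %d region classes characterized", len(labelled))

    scores = None
    if "gwas" in stages:
        scores = gwas.cross_set_metric(sim.panel)
        _write_tsv(scores, outdir / "cross_set_scores.tsv", cfg)
        groups = evo.annotate_variant_profiles(
            sim.variants, sim.conserved_elements, labelled,
            window=cfg["proximity_window"],
        )
        state["profiles"] = groups.join(scores["z_cross"], on="id")
        contrast = gwas.group_contrast(
            scores, groups.set_index("id")["nearest_set"]
        )
        report["gwas"] = {
            "n_scored": int(scores["z_cross"].notna().sum()),
            "group_means": contrast["group_means"],
            "group_sizes": contrast["group_sizes"],
        }
        if labelled:
            first = next(iter(labelled.values()))
            per_dis = gwas.per_disease_enrichment(
                sim.panel, first, sim.variants,
                p_strong=cfg["p_strong"], window=cfg["proximity_window"],
            )
            _write_tsv(per_dis, outdir / "per_disease_enrichment.tsv", cfg)
            report["gwas"]["n_enriched_diseases"] = int(
                (per_dis["signed_neglog_fdr"] > -np.log10(cfg["fdr_cut"])).sum()
            )
        log.info("gwas: scored %d variants", report["gwas"]["n_scored"])

    if "generank" in stages:
        loci = generank.build_loci(sim.genes, window=cfg["locus_window"])
        gscores = generank.gene_scores(sim.panel, loci, sim.variants)
        table = generank.aggregate_ranks(gscores)
        _write_tsv(table, outdir / "gene_ranks.tsv", cfg)
        report["generank"] = {"n_genes_ranked": len(table)}
        if sim.truth.core_genes:
            gst = generank.gene_set_test(
                table, sorted(sim.truth.core_genes),
                n_perm=cfg["n_perm_generank"],
                seed=np.random.default_rng([int(cfg["seed"]), 98]),
            )
            report["generank"]["core_gene_set"] = gst
        log.info("generank: ranked %d genes", len(table))

    if "expression" in stages:
        calls = expression.consistency_shift(sim.expression, sim.expr_meta)
        filt = gene_links.filter_capture(
            sim.capture_pairs, min_tissues=cfg["capture_min_tissues"]
        )
        report["expression"] = {
            "n_adult_up": len(calls["adult_up"]),
            "n_fetal_up": len(calls["fetal_up"]),
            "n_capture_pairs_reproducible": len(filt),
        }
        if "adult_biased" in labelled:
            linked = gene_links.regions_to_genes(
                labelled["adult_biased"], capture=filt, promoters=state.get("promoters")
            )
            universe = set(sim.genes["gene"])
            if linked and calls["adult_up"]:
                ov = gene_links.set_overlap_test(linked, calls["adult_up"], universe)
                report["expression"]["adult_overlap"] = ov
        log.info(
            "expression: %d adult-up, %d fetal-up genes",
            report["expression"]["n_adult_up"], report["expression"]["n_fetal_up"],
        )

    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=False)
    return report


def _plain(obj):
    """Coerce numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
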