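"""End-to-end orchestration of the germplasm characterization workflow.

Stage order mirrors the study design: pool calling and profile discovery
→ validation of pool predictions against the genotyped panel → marker QC
→ shared-allele tree → admixture sweep with Evanno ΔK → consensus
core-set selection → supervised classification against the cores → PCA
projection and kinship graph.  Every stage's output is persisted so any
number in the final JSON report is recomputable from the intermediates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import germpool
from germpool import io as gio
from germpool.admixture import McmcConfig, admixture_sweep, supervised_assignment
from germpool.classify import classify_accessions, compute_fst, select_core_sets
from germpool.discovery import (
    PoolCallConfig,
    call_pool_table,
    classify_profiles,
    profile_chi_square,
    validate_against_genotypes,
)
from germpool.kinship import king_kinship, pca_fit, pca_project, relatedness_graph
from germpool.qc import filter_markers
from germpool.simulate import SimulationConfig, sample_panel, simulate_collection
from germpool.tree import bootstrap_support, cut_k_clusters, psa_distance, ward_tree


@dataclass
class PipelineConfig:
    """All thresholds, paths and the seed for a full run."""

    out_dir: str = "germpool_out"
    seed: int = 0
    # synthetic-input settings (used when no real tables are supplied)
    simulation: SimulationConfig | None = None
    pool_table: str | None = None
    genotypes: str | None = None
    metadata: str | None = None
    # stage settings
    pool_call: PoolCallConfig = field(default_factory=PoolCallConfig)
    locus_na_max: float = 0.10
    sample_na_max: float = 0.30
    pic_min: float = 0.1
    ld_r2_max: float = 0.7
    n_boot: int = 200
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    q_threshold: float = 0.85
    minor_component_min: float = 0.15
    kinship_threshold: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        mcmc = raw.pop("mcmc", None)
        pool_call = raw.pop("pool_call", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if mcmc is not None:
            cfg.mcmc = McmcConfig(**mcmc)
        if pool_call is not None:
            cfg.pool_call = PoolCallConfig(**pool_call)
        return cfg

    def validate_paths(self) -> None:
        for p in (self.pool_table, self.genotypes, self.metadata):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    blob = json.dumps(asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the consolidated report."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "version": germpool.__version__,
        }
    }

    stage = "inputs"
    try:
        if cfg.pool_table and cfg.genotypes and cfg.metadata:
            pools = gio.read_pool_count_table(cfg.pool_table)
            genos = gio.read_genotype_matrix(cfg.genotypes)
            meta = gio.read_metadata(cfg.metadata)
            truth = None
        else:
            sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
            pools, genos, meta, truth = simulate_collection(sim)
            gio.write_pool_count_table(pools, out / "pool_counts.tsv")
            gio.write_genotype_matrix(genos, out / "genotypes.csv")
            gio.write_metadata(meta, out / "metadata.csv")

        stage = "discover"
        calls = call_pool_table(pools, cfg.pool_call)
        calls.calls_as_text().to_csv(out / "pool_calls.csv")
        profiles = classify_profiles(calls)
        report["profiles"] = profiles.to_dict()
        cats = [profiles.category_counts[k] for k in (3, 2, 1)]
        if min(cats) > 0:
            stat, df, p = profile_chi_square(cats)
            report["profiles"]["category_chi2"] = {"statistic": stat, "df": df, "p": p}

        stage = "panel"
        if truth is not None:
            # mimic assay design: sample the validation panel from loci
            # discovered as polymorphic in at least one pool
            discovered = np.flatnonzero((calls.call == 1).any(axis=1))
            size = min(cfg.simulation.panel_size if cfg.simulation else 192, discovered.size)
            panel = sample_panel(genos, size, seed=cfg.seed + 101, candidate_idx=discovered)
        else:
            panel = genos
        gio.write_genotype_matrix(panel, out / "panel_genotypes.csv")

        stage = "validate"
        validation = validate_against_genotypes(calls, pools, panel, meta)
        report["validation"] = validation.to_dict()

        stage = "filter"
        filtered, filter_report = filter_markers(
            panel,
            locus_na_max=cfg.locus_na_max,
            sample_na_max=cfg.sample_na_max,
            pic_min=cfg.pic_min,
            ld_r2_max=cfg.ld_r2_max,
        )
        gio.write_genotype_matrix(filtered, out / "filtered_genotypes.csv")
        report["filter"] = filter_report.to_dict()

        stage = "tree"
        dist = psa_distance(filtered)
        tree = ward_tree(dist)
        tree = bootstrap_support(filtered, n_boot=cfg.n_boot, seed=cfg.seed + 202, tree=tree)
        gio.write_newick(tree, out / "tree.nwk")
        clusters = cut_k_clusters(tree, k=3)
        report["tree"] = {
            "n_boot": cfg.n_boot,
            "presented_supports": tree.presented_supports(),
            "clusters_k3": clusters,
        }

        stage = "admixture"
        mcmc = McmcConfig(**{**vars(cfg.mcmc), "seed": cfg.seed + 303})
        runs_by_k, averaged, evanno = admixture_sweep(filtered, mcmc, list(cfg.k_values))
        for k, qm in averaged.items():
            qm.q.to_csv(out / f"q_K{k}.csv")
        report["evanno"] = evanno.to_dict() if evanno else None
        k_for_cores = 3 if 3 in averaged else max(averaged)
        q_unsup = averaged[k_for_cores]

        stage = "core_sets"
        core_assign = select_core_sets(
            meta, clusters, q_unsup, genos=filtered, q_threshold=cfg.q_threshold
        )
        core_assign.table.to_csv(out / "core_assignments.csv")
        report["core_sets"] = {
            "method_counts": core_assign.method_counts.replace({np.nan: None}).to_dict(orient="index"),
            "core_members": core_assign.core_members(),
        }

        stage = "supervised"
        core_labels = {
            a: race for race, members in core_assign.core_members().items() for a in members
        }
        if len(set(core_labels.values())) >= 2:
            sup_cfg = McmcConfig(**{**vars(cfg.mcmc), "seed": cfg.seed + 404})
            q_sup = supervised_assignment(filtered, core_labels, sup_cfg)
            q_sup.q.to_csv(out / "q_supervised.csv")
            assignment = classify_accessions(q_sup, cfg.minor_component_min)
            assignment.table.to_csv(out / "race_assignments.csv")
            report["assignments"] = {
                "categories": assignment.table["category"].value_counts().to_dict()
            }
        else:
            report["assignments"] = None

        stage = "kinship_pca"
        core_names = [a for a in core_labels]
        if len(core_names) >= 3:
            core_idx = [filtered.accessions.index(a) for a in core_names]
            model = pca_fit(filtered.subset_accessions(core_idx))
            coords = pca_project(model, filtered)
            coords.to_csv(out / "pca_coordinates.csv")
            report["pca"] = {
                "explained_variance_ratio": model.explained_variance_ratio[:5].tolist()
            }
        kin = king_kinship(filtered)
        kin.as_frame().to_csv(out / "kinship.csv")
        graph = relatedness_graph(kin, threshold=cfg.kinship_threshold)
        report["kinship"] = graph.to_dict()
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    gio.write_json_report(report, out / "report.json")
    return report
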