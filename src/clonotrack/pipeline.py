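"""End-to-end pipeline: simulate -> filter -> clonality -> track -> signatures -> report.

Each stage persists its outputs as TSV/JSON/MTX so it can be re-run and
inspected independently; the final RunReport JSON aggregates every stage's
key numbers.  Under a fixed seed the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clonality, signatures, simulate, tracking
from .errors import ConfigurationError
from .repertoire import collapse_to_clones, filter_repertoire
from .signatures import QCThresholds
from .simulate import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; serialised alongside the outputs.

    Defaults are the canonical analysis settings: top_k=100 tracked clones,
    clonal expansion at >= 2 cells, bulk read filter at >= 2 reads,
    50-gene modules, marker alpha 0.01.
    """

    outdir: str = "clonotrack_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    top_k: int = 100
    min_cells: int = 2
    min_count: int = 2
    productive_only: bool = True
    top_n_genes: int = 50
    alpha: float = 0.01
    min_pct: float = 0.25
    min_log2fc: float = 0.25
    n_bins: int = 25
    n_ctrl: int = 100
    top_pct: float = 5.0
    qc: QCThresholds = field(default_factory=QCThresholds)

    def __post_init__(self) -> None:
        # keep the simulator on the pipeline's seed unless set explicitly
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.qc, dict):
            self.qc = QCThresholds(**self.qc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        # json round-trip turns tuples into plain lists for safe_dump
        data = json.loads(json.dumps(dataclasses.asdict(self)))
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full simulated-study analysis; returns the RunReport dict.

    Stages: simulate the paired study, apply the bulk repertoire filters,
    collapse to clones, compute expansion/dominance/overlap statistics,
    track the top tissue clones into the single-cell data, derive reactivity
    modules from labelled cells and score them per cluster, and write
    everything under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    cfg.sim.validate()
    cfg.to_yaml(outdir / "run_config.yaml")
    report: dict = {"seed": cfg.seed}

    # -- stage: simulate ----------------------------------------------------
    study = simulate.simulate_study(cfg.sim)
    simulate.write_study(study, outdir / "simulated")

    # -- stage: filter + collapse -------------------------------------------
    clone_sets = {}
    filter_counts = {}
    for rep in (study.tissue, study.blood_pd1pos, study.blood_pd1neg):
        filt = filter_repertoire(rep, min_count=cfg.min_count, productive_only=cfg.productive_only)
        filter_counts[rep.compartment] = filt.filter_report
        clone_sets[rep.compartment] = collapse_to_clones(filt)
    report["filter"] = filter_counts

    # -- stage: clonality ----------------------------------------------------
    liver = clone_sets["liver"]
    sc_cts = clonality.clonotypes_from_table(study.sc_clonotypes, key="paired")
    expansion = clonality.classify_expansion(sc_cts, min_cells=cfg.min_cells)
    report["expansion"] = dataclasses.asdict(expansion)
    report["dominance"] = {
        "top_n": cfg.top_k,
        "liver_top_share": clonality.top_n_cumulative_share(liver, cfg.top_k),
    }
    overlaps = {}
    for comp in ("blood_pd1pos", "blood_pd1neg"):
        ov = clonality.repertoire_overlap(liver, clone_sets[comp])
        overlaps[comp] = {
            "n_shared": ov.n_shared,
            "frac_of_liver": ov.frac_of_a,
            "frac_of_subset": ov.frac_of_b,
            "mass_in_liver": ov.mass_in_a,
            "mass_in_subset": ov.mass_in_b,
            "subset_share_of_top_clones": clonality.subset_share_of_top_clones(
                liver, clone_sets[comp], k=cfg.top_k
            ),
        }
    report["overlap"] = overlaps

    # -- stage: tracking ------------------------------------------------------
    beta_cts = clonality.clonotypes_from_table(study.sc_clonotypes, key="beta")
    cluster_of_cell = study.adata.obs["cluster"].to_dict()
    tr = tracking.track(liver, beta_cts, cluster_of_cell, k=cfg.top_k)
    tr.rows.assign(cluster_votes=tr.rows["cluster_votes"].map(json.dumps)).to_csv(
        outdir / "tracking.tsv", sep="\t", index=False
    )
    report["tracking"] = {
        "top_k": cfg.top_k,
        "n_tracked_found": tr.n_tracked_found,
        "aggregate": tr.aggregate,
    }

    # -- stage: signatures -----------------------------------------------------
    adata = signatures.qc_filter_cells(study.adata, cfg.qc)
    report["qc"] = signatures.qc_report(adata)
    adata = signatures.normalize_log(adata)
    labelled = adata[adata.obs["reactivity"] != "unlabeled"].copy()
    markers = signatures.find_markers(
        labelled, "reactivity",
        min_pct=cfg.min_pct, min_log2fc=cfg.min_log2fc, alpha=cfg.alpha,
    )
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    module_report = {}
    for group in study.config.reactivity_groups:
        module = signatures.build_reactivity_module(markers, group, top_n=cfg.top_n_genes)
        scores = signatures.module_score(
            adata, module, n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=cfg.seed
        )
        comparison = signatures.compare_cluster_scores(scores, adata.obs["cluster"])
        top_cells = signatures.top_percent_cells(scores, pct=cfg.top_pct)
        planted = set(study.truth.planted_modules.get(group, []))
        module_report[group] = {
            "module_size": len(module),
            "planted_recovery": (
                len(planted & set(module.genes)) / len(planted) if planted else None
            ),
            "kruskal_p": comparison.kruskal_p,
            "per_cluster_mean": dict(
                zip(comparison.per_cluster["cluster"], comparison.per_cluster["mean"])
            ),
            "top_cluster": comparison.per_cluster.loc[
                comparison.per_cluster["mean"].idxmax(), "cluster"
            ],
            "n_top_pct_cells": len(top_cells),
        }
    report["signatures"] = module_report
    report["truth"] = {
        "autoreactive_cluster_id": study.truth.autoreactive_cluster_id,
        "n_shared_clones_pd1pos": sum(
            "blood_pd1pos" in c for c in study.truth.clone_compartments.values()
        ),
    }

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    logger.info("pipeline complete; report at %s", outdir / "run_report.json")
    return report
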