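"""Synthetic paired bulk-TCRbeta / single-cell datasets with known ground truth.

The generator emulates the statistical structure the tracking and signature
analyses assume, at desk scale:

* a heavy-tailed (truncated Zipf over ranks) intrahepatic clone-size law,
  sequenced by multinomial read sampling at a fixed depth, so that the top
  clones dominate the repertoire;
* two circulating memory CD4 subsets (PD-1+CXCR5- and PD-1-) that share top
  tissue clones at different, configurable rates — the PD-1+ subset being
  the one enriched for dominant intrahepatic clonotypes;
* a single-cell dataset of the PD-1+ compartment with negative-binomial UMI
  counts, planted cluster-marker and reactivity-signature genes, and cells
  of shared clones preferentially placed in a designated autoreactive
  cluster;
* complete ground truth (clone compartment membership, cell-to-clone map,
  planted gene modules, cluster labels) for validation.

Every sub-generator draws from its own RNG stream spawned from the master
seed, so adding a generator does not perturb the others and every output is
reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .errors import ConfigurationError
from .repertoire import Repertoire

# 61 sense codons (stop codons excluded) for in-frame CDR3 interiors
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
# conserved junction flanks: Cys-Ala-Ser at the V end, Phe-Gly at the J end
_PREFIX = "TGTGCCAGC"
_SUFFIX = "TTTGGA"

_V_GENES = [f"TRBV{i}-1*01" for i in (2, 4, 5, 6, 7, 9, 11, 12, 19, 20, 28, 30)]
_J_GENES = [f"TRBJ{i}-{j}*01" for i in (1, 2) for j in (1, 2, 3, 5)]


@dataclass
class SimConfig:
    """Parameters of the paired-compartment study generator.

    Defaults are the study conditions the analyses are validated under:
    a 5000-clone liver repertoire at depth 1e6 with Zipf exponent 1.2
    (heavy-tailed enough that the top 100 clones carry a majority of reads),
    top-100 clone sharing fractions of 0.10 (PD-1+) and 0.02 (PD-1-), and a
    2000-cell, 2000-gene, 6-cluster single-cell dataset with 50 planted
    signature genes per reactivity group shifted by one log2 unit.
    """

    seed: int = 0
    # tissue (liver) repertoire
    n_tissue_clones: int = 5000
    zipf_exponent: float = 1.2
    tissue_depth: int = 1_000_000
    clone_size_law: str = "zipf"  # "zipf" | "lognormal"
    lognormal_sigma: float = 2.0
    # blood subsets
    n_blood_clones_per_subset: int = 1000
    blood_depth: int = 100_000
    top_k_shared: int = 100
    sharing_fraction_pd1pos: float = 0.10
    sharing_fraction_pd1neg: float = 0.02
    # single-cell dataset
    n_cells_sc: int = 2000
    n_genes: int = 2000
    n_clusters: int = 6
    n_cluster_marker_genes: int = 20
    n_signature_genes_per_group: int = 50
    signature_log2fc: float = 1.0
    nb_dispersion: float = 2.0
    mean_library_size: int = 5000
    tcr_cell_fraction: float = 0.9
    autoreactive_enrichment: float = 0.8
    reactivity_groups: tuple[str, ...] = ("auto-reactivity", "H1N1")
    autoreactive_cluster_id: str = "c2"
    donor_id: str = "sim_donor"

    def validate(self) -> None:
        if self.clone_size_law not in ("zipf", "lognormal"):
            raise ConfigurationError(f"unknown clone_size_law {self.clone_size_law!r}")
        if self.clone_size_law == "zipf" and self.zipf_exponent <= 1:
            raise ConfigurationError(
                "zipf_exponent must be > 1 for a normalizable clone-size law"
            )
        for name in (
            "sharing_fraction_pd1pos", "sharing_fraction_pd1neg",
            "tcr_cell_fraction", "autoreactive_enrichment",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_tissue_clones", "tissue_depth", "n_blood_clones_per_subset",
            "blood_depth", "n_cells_sc", "n_genes", "n_clusters",
            "mean_library_size",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if len(self.reactivity_groups) > self.n_clusters:
            raise ConfigurationError("more reactivity groups than clusters")
        needed = (
            len(self.reactivity_groups) * self.n_signature_genes_per_group
            + self.n_clusters * self.n_cluster_marker_genes
        )
        if needed > self.n_genes - 50:  # leave headroom for mito/ribo/background
            raise ConfigurationError(
                f"planted gene sets ({needed}) exceed the gene budget ({self.n_genes})"
            )

    def clusters(self) -> list[str]:
        return [f"c{i}" for i in range(self.n_clusters)]

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """One independent RNG stream per sub-generator, all from the master seed."""
        names = ("cdr3", "tissue", "blood", "sc_structure", "sc_expression")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SimGroundTruth:
    """Generator-side truth used to validate the analysis end to end."""

    clone_compartments: dict[str, list[str]]  # cdr3_nt -> compartments it occurs in
    cell_to_clone: dict[str, str]  # cell id -> cdr3b_nt of its clone
    planted_modules: dict[str, list[str]]  # reactivity label -> signature genes
    cluster_markers: dict[str, list[str]]  # cluster -> planted marker genes
    cluster_of_cell: dict[str, str]
    reactivity_of_cluster: dict[str, str]  # anchor mapping group -> cluster
    autoreactive_cluster_id: str


@dataclass
class SimStudy:
    """All outputs of one simulated study."""

    config: SimConfig
    tissue: Repertoire
    blood_pd1pos: Repertoire
    blood_pd1neg: Repertoire
    adata: AnnData
    sc_clonotypes: pd.DataFrame
    truth: SimGroundTruth


# ---------------------------------------------------------------------------
# CDR3 sequence generation
# ---------------------------------------------------------------------------

def _random_cdr3_nt(rng: np.random.Generator, existing: set[str]) -> str:
    """A random productive in-frame CDR3 (27-54 nt) with conserved flanks.

    Uniqueness is enforced by rejection against ``existing``.
    """
    while True:
        n_mid = int(rng.integers(4, 14))  # 12..39 interior nt -> total 27..54
        mid = "".join(rng.choice(_CODONS, size=n_mid))
        seq = _PREFIX + mid + _SUFFIX
        if seq not in existing:
            existing.add(seq)
            return seq


def _make_clone_table(
    n: int, rng: np.random.Generator, existing: set[str]
) -> pd.DataFrame:
    seqs = [_random_cdr3_nt(rng, existing) for _ in range(n)]
    return pd.DataFrame(
        {
            "junction": seqs,
            "v_call": rng.choice(_V_GENES, size=n),
            "j_call": rng.choice(_J_GENES, size=n),
        }
    )


# ---------------------------------------------------------------------------
# Clone-size laws
# ---------------------------------------------------------------------------

def zipf_weights(exponent: float, n: int) -> np.ndarray:
    """Normalised truncated-Zipf weights over ranks 1..n."""
    if exponent <= 1:
        raise ConfigurationError("zipf exponent must be > 1")
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def zipf_top_share(exponent: float, n: int, k: int) -> float:
    """Analytic cumulative share of the top-k ranks under truncated Zipf."""
    w = zipf_weights(exponent, n)
    return float(w[: min(k, n)].sum())


def _clone_weights(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.clone_size_law == "zipf":
        return zipf_weights(cfg.zipf_exponent, n)
    w = np.sort(rng.lognormal(0.0, cfg.lognormal_sigma, size=n))[::-1]
    return w / w.sum()


# ---------------------------------------------------------------------------
# Bulk repertoires
# ---------------------------------------------------------------------------

def simulate_tissue_repertoire(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    cdr3_rng: np.random.Generator | None = None,
    existing: set[str] | None = None,
) -> Repertoire:
    """Liver repertoire: Zipf clone-size law, multinomial reads at fixed depth.

    Clones with zero sampled reads are unobserved and omitted; total reads
    always equal ``tissue_depth`` exactly.  Rows are ordered by true rank.
    """
    cfg.validate()
    if rng is None or cdr3_rng is None:
        streams = cfg.rng_streams()
        rng = rng or streams["tissue"]
        cdr3_rng = cdr3_rng or streams["cdr3"]
    table = _make_clone_table(cfg.n_tissue_clones, cdr3_rng, existing if existing is not None else set())
    weights = _clone_weights(cfg, cfg.n_tissue_clones, rng)
    counts = rng.multinomial(cfg.tissue_depth, weights)
    table = table.assign(duplicate_count=counts, productive=True)
    table = table[table["duplicate_count"] > 0].reset_index(drop=True)
    return Repertoire(cfg.donor_id, "liver", table)


def simulate_blood_subsets(
    cfg: SimConfig,
    tissue: Repertoire,
    rng: np.random.Generator | None = None,
    cdr3_rng: np.random.Generator | None = None,
    existing: set[str] | None = None,
) -> tuple[Repertoire, Repertoire, dict[str, list[str]]]:
    """PD-1+ and PD-1- blood subsets sharing top tissue clones at set rates.

    Each of the top-K tissue clones is independently included in the PD-1+
    subset with probability ``sharing_fraction_pd1pos`` and in the PD-1-
    subset with ``sharing_fraction_pd1neg``; the remaining clones of each
    subset are novel.  Every emitted clone is guaranteed >= 2 reads (so the
    standard min-count filter cannot delete a planted shared clone) and the
    subset depth is conserved exactly.  Returns both subsets and the map
    cdr3_nt -> list of blood compartments it was planted in.
    """
    cfg.validate()
    if len(tissue) == 0:
        raise ConfigurationError("tissue repertoire is empty")
    if rng is None or cdr3_rng is None:
        streams = cfg.rng_streams()
        rng = rng or streams["blood"]
        cdr3_rng = cdr3_rng or streams["cdr3"]
    if existing is None:
        existing = set(tissue.rearrangements["junction"])
    top = (
        tissue.rearrangements.sort_values(
            ["duplicate_count", "junction"], ascending=[False, True], kind="mergesort"
        )
        .head(cfg.top_k_shared)
        .reset_index(drop=True)
    )
    shared_in: dict[str, list[str]] = {}

    def build(compartment: str, fraction: float) -> Repertoire:
        include = rng.random(len(top)) < fraction
        shared = top.loc[include, ["junction", "v_call", "j_call"]].reset_index(drop=True)
        for j in shared["junction"]:
            shared_in.setdefault(j, []).append(compartment)
        novel = _make_clone_table(cfg.n_blood_clones_per_subset, cdr3_rng, existing)
        clones = pd.concat([shared, novel], ignore_index=True)
        n = len(clones)
        order = rng.permutation(n)  # shared clones land at random abundance ranks
        weights = _clone_weights(cfg, n, rng)[np.argsort(order)]
        base = 2 * n
        if cfg.blood_depth <= base:
            raise ConfigurationError("blood_depth too small for the clone count")
        counts = 2 + rng.multinomial(cfg.blood_depth - base, weights / weights.sum())
        clones = clones.assign(duplicate_count=counts, productive=True)
        return Repertoire(cfg.donor_id, compartment, clones)

    pd1pos = build("blood_pd1pos", cfg.sharing_fraction_pd1pos)
    pd1neg = build("blood_pd1neg", cfg.sharing_fraction_pd1neg)
    return pd1pos, pd1neg, shared_in


# ---------------------------------------------------------------------------
# Single-cell dataset
# ---------------------------------------------------------------------------

def _gene_names(cfg: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Gene name vector with small mito and ribo families for QC realism."""
    n_mito, n_ribo = 5, 12
    n_generic = cfg.n_genes - n_mito - n_ribo
    names = (
        [f"MT-G{i}" for i in range(1, n_mito + 1)]
        + [f"RPS{i}" for i in range(1, n_ribo // 2 + 1)]
        + [f"RPL{i}" for i in range(1, n_ribo - n_ribo // 2 + 1)]
        + [f"GENE{i:04d}" for i in range(1, n_generic + 1)]
    )
    is_mito = np.array([n.startswith("MT-") for n in names])
    is_ribo = np.array([n.startswith(("RPS", "RPL")) for n in names])
    return names, is_mito, is_ribo


def simulate_sc_dataset(
    cfg: SimConfig,
    shared_clones: pd.DataFrame,
    rng_structure: np.random.Generator | None = None,
    rng_expression: np.random.Generator | None = None,
    cdr3_rng: np.random.Generator | None = None,
    existing: set[str] | None = None,
) -> tuple[AnnData, pd.DataFrame, SimGroundTruth]:
    """Single-cell dataset of the circulating PD-1+ compartment.

    ``shared_clones`` (columns junction, v_call, j_call) are the tissue
    clones present in this compartment; their cells are placed in the
    autoreactive cluster with probability ``autoreactive_enrichment``.  UMI
    counts are negative binomial around per-cluster mean profiles in which
    cluster-marker genes and reactivity-signature genes are shifted by
    ``signature_log2fc``.  Each reactivity group is anchored to one cluster
    (the auto-reactivity group to ``autoreactive_cluster_id``) and its
    cells carry the group label in ``obs["reactivity"]``; other cells are
    "unlabeled".

    Returns (AnnData of raw counts, cell-clonotype table, ground truth).
    """
    cfg.validate()
    streams = cfg.rng_streams() if (
        rng_structure is None or rng_expression is None or cdr3_rng is None
    ) else {}
    rng_structure = rng_structure or streams["sc_structure"]
    rng_expression = rng_expression or streams["sc_expression"]
    cdr3_rng = cdr3_rng or streams["cdr3"]
    if existing is None:
        existing = set(shared_clones["junction"])

    clusters = cfg.clusters()
    # anchor each reactivity group to a cluster; auto-reactivity gets the
    # configured autoreactive cluster, remaining groups fill other clusters
    if cfg.autoreactive_cluster_id not in clusters:
        raise ConfigurationError(
            f"autoreactive_cluster_id {cfg.autoreactive_cluster_id!r} not in clusters"
        )
    anchors: dict[str, str] = {}
    free = [c for c in clusters if c != cfg.autoreactive_cluster_id]
    for g in cfg.reactivity_groups:
        if g == "auto-reactivity":
            anchors[g] = cfg.autoreactive_cluster_id
        else:
            anchors[g] = free.pop(0)
    if "auto-reactivity" not in anchors:  # custom group names: first is autoreactive
        anchors[cfg.reactivity_groups[0]] = cfg.autoreactive_cluster_id

    # --- cells, clusters, clonotypes -------------------------------------
    cell_ids = [f"cell{i:05d}" for i in range(cfg.n_cells_sc)]
    cluster_of_cell = dict(
        zip(cell_ids, rng_structure.choice(clusters, size=cfg.n_cells_sc))
    )

    n_tcr = int(round(cfg.tcr_cell_fraction * cfg.n_cells_sc))
    tcr_cells = list(rng_structure.choice(cell_ids, size=n_tcr, replace=False))
    cell_to_clone: dict[str, str] = {}
    clonotype_rows = []

    # cells of shared (tissue) clones, preferentially in the autoreactive cluster
    pool = list(tcr_cells)
    for row in shared_clones.itertuples(index=False):
        n_cells_clone = 1 + int(rng_structure.poisson(1.5))
        n_cells_clone = min(n_cells_clone, len(pool))
        if n_cells_clone == 0:
            break
        chosen = [pool.pop() for _ in range(n_cells_clone)]
        cdr3a = _random_cdr3_nt(cdr3_rng, existing)
        for cell in chosen:
            if rng_structure.random() < cfg.autoreactive_enrichment:
                cluster_of_cell[cell] = cfg.autoreactive_cluster_id
            cell_to_clone[cell] = row.junction
            clonotype_rows.append(
                {
                    "cell_id": cell,
                    "cdr3b_nt": row.junction,
                    "cdr3a_nt": cdr3a,
                    "v_call_b": row.v_call,
                    "j_call_b": row.j_call,
                }
            )
    # remaining TCR+ cells: novel clonotypes, mostly singletons, some expanded
    while pool:
        size = 1 if rng_structure.random() < 0.7 else 2 + int(rng_structure.poisson(1.0))
        size = min(size, len(pool))
        beta = _random_cdr3_nt(cdr3_rng, existing)
        alpha = _random_cdr3_nt(cdr3_rng, existing)
        v_call = str(rng_structure.choice(_V_GENES))
        j_call = str(rng_structure.choice(_J_GENES))
        for _ in range(size):
            cell = pool.pop()
            cell_to_clone[cell] = beta
            clonotype_rows.append(
                {
                    "cell_id": cell,
                    "cdr3b_nt": beta,
                    "cdr3a_nt": alpha,
                    "v_call_b": v_call,
                    "j_call_b": j_call,
                }
            )
    sc_clonotypes = pd.DataFrame(clonotype_rows).sort_values("cell_id").reset_index(drop=True)

    # --- reactivity labels -----------------------------------------------
    reactivity_of_cluster = {c: "unlabeled" for c in clusters}
    for g, c in anchors.items():
        reactivity_of_cluster[c] = g
    reactivity = {cell: reactivity_of_cluster[cluster_of_cell[cell]] for cell in cell_ids}

    # --- planted gene programs -------------------------------------------
    gene_names, is_mito, is_ribo = _gene_names(cfg)
    generic = [g for g in gene_names if g.startswith("GENE")]
    cursor = 0
    planted_modules: dict[str, list[str]] = {}
    for g in cfg.reactivity_groups:
        planted_modules[g] = generic[cursor: cursor + cfg.n_signature_genes_per_group]
        cursor += cfg.n_signature_genes_per_group
    seen: set[str] = set()
    for genes in planted_modules.values():
        if seen & set(genes):
            raise ConfigurationError("planted module genes overlap across groups")
        seen |= set(genes)
    # a cluster anchored to a reactivity group has that group's signature as
    # its identity program; separate markers are planted only for the rest
    cluster_markers: dict[str, list[str]] = {}
    for c in clusters:
        label = reactivity_of_cluster[c]
        if label != "unlabeled":
            cluster_markers[c] = list(planted_modules[label])
        else:
            cluster_markers[c] = generic[cursor: cursor + cfg.n_cluster_marker_genes]
            cursor += cfg.n_cluster_marker_genes

    # --- expression model -------------------------------------------------
    n_genes = cfg.n_genes
    base = rng_expression.lognormal(0.0, 1.5, size=n_genes)
    # steer housekeeping families so default cells pass the QC rules
    base[is_mito] = base.sum() * 0.03 / max(is_mito.sum(), 1)
    base[is_ribo] = base.sum() * 0.12 / max(is_ribo.sum(), 1)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    fc = np.zeros((cfg.n_clusters, n_genes))
    for ci, c in enumerate(clusters):
        for g in cluster_markers[c]:
            fc[ci, gene_index[g]] += cfg.signature_log2fc
    cluster_profiles = base[None, :] * 2.0 ** fc
    cluster_profiles /= cluster_profiles.sum(axis=1, keepdims=True)

    cluster_idx = np.array([clusters.index(cluster_of_cell[c]) for c in cell_ids])
    libs = cfg.mean_library_size * rng_expression.lognormal(0.0, 0.2, size=cfg.n_cells_sc)
    mu = cluster_profiles[cluster_idx] * libs[:, None]
    theta = cfg.nb_dispersion
    p = theta / (theta + mu)
    counts = rng_expression.negative_binomial(theta, p)

    adata = AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame(
            {
                "donor": cfg.donor_id,
                "cluster": [cluster_of_cell[c] for c in cell_ids],
                "reactivity": [reactivity[c] for c in cell_ids],
            },
            index=pd.Index(cell_ids, name="cell_id"),
        ),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )

    truth = SimGroundTruth(
        clone_compartments={},  # filled by simulate_study
        cell_to_clone=cell_to_clone,
        planted_modules=planted_modules,
        cluster_markers=cluster_markers,
        cluster_of_cell=cluster_of_cell,
        reactivity_of_cluster={g: c for g, c in anchors.items()},
        autoreactive_cluster_id=cfg.autoreactive_cluster_id,
    )
    return adata, sc_clonotypes, truth


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate the full paired study: liver + two blood subsets + single cells.

    The single-cell dataset models the sorted PD-1+CXCR5- compartment, so
    the clones passed to it are the top tissue clones planted in the PD-1+
    subset.
    """
    cfg.validate()
    streams = cfg.rng_streams()
    existing: set[str] = set()
    tissue = simulate_tissue_repertoire(
        cfg, rng=streams["tissue"], cdr3_rng=streams["cdr3"], existing=existing
    )
    pd1pos, pd1neg, shared_in = simulate_blood_subsets(
        cfg, tissue, rng=streams["blood"], cdr3_rng=streams["cdr3"], existing=existing
    )
    shared_pd1pos = pd1pos.rearrangements[
        pd1pos.rearrangements["junction"].isin(
            [j for j, comps in shared_in.items() if "blood_pd1pos" in comps]
        )
    ][["junction", "v_call", "j_call"]].reset_index(drop=True)
    adata, sc_clonotypes, truth = simulate_sc_dataset(
        cfg,
        shared_pd1pos,
        rng_structure=streams["sc_structure"],
        rng_expression=streams["sc_expression"],
        cdr3_rng=streams["cdr3"],
        existing=existing,
    )
    compartments: dict[str, list[str]] = {}
    for j in tissue.rearrangements["junction"]:
        compartments.setdefault(j, []).append("liver")
    for rep in (pd1pos, pd1neg):
        for j in rep.rearrangements["junction"]:
            compartments.setdefault(j, []).append(rep.compartment)
    for j in set(sc_clonotypes["cdr3b_nt"]):
        compartments.setdefault(j, []).append("sc_pd1pos")
    truth.clone_compartments = {
        j: comps for j, comps in compartments.items() if len(comps) > 1
    }
    return SimStudy(
        config=cfg,
        tissue=tissue,
        blood_pd1pos=pd1pos,
        blood_pd1neg=pd1neg,
        adata=adata,
        sc_clonotypes=sc_clonotypes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_study(study: SimStudy, outdir: str | Path) -> dict[str, str]:
    """Persist a simulated study as plain-text files; returns path map.

    AIRR Rearrangement TSV per compartment, MTX + row/column TSVs for the
    count matrix, TSVs for cell metadata and clonotypes, JSON for the
    ground truth and config.
    """
    from .repertoire import write_airr_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for rep in (study.tissue, study.blood_pd1pos, study.blood_pd1neg):
        p = outdir / f"{rep.compartment}.airr.tsv"
        write_airr_tsv(rep, p)
        paths[rep.compartment] = str(p)
    mtx = outdir / "counts.mtx"
    scipy.io.mmwrite(str(mtx), sp.csr_matrix(study.adata.X))
    paths["counts"] = str(mtx)
    pd.Series(study.adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(study.adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    study.adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t")
    paths["cell_metadata"] = str(outdir / "cell_metadata.tsv")
    study.sc_clonotypes.to_csv(outdir / "sc_clonotypes.tsv", sep="\t", index=False)
    paths["sc_clonotypes"] = str(outdir / "sc_clonotypes.tsv")
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(dataclasses.asdict(study.truth), indent=1))
    paths["ground_truth"] = str(truth_path)
    cfg_path = outdir / "sim_config.json"
    cfg_path.write_text(json.dumps(dataclasses.asdict(study.config), indent=1))
    paths["config"] = str(cfg_path)
    return paths
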