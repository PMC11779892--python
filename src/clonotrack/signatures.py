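"""Reactivity gene modules: derivation from labelled cells and transfer as scores.

The workflow mirrors the standard single-cell signature analysis for
antigen-reactivity studies:

1. QC-filter cells on mitochondrial / ribosomal / spike-in content and gene
   detection.
2. Depth-normalise to a fixed target sum and log1p ("standard log
   normalization").
3. Derive per-group marker genes with a one-vs-rest two-sided Wilcoxon
   rank-sum test, prefiltered on detection fraction (min_pct) and log2
   fold change, Benjamini-Hochberg adjusted within group, kept at
   adjusted p < alpha.
4. Build a reactivity module as the top-n genes by avg_log2FC.
5. Transfer the module to any dataset as a per-cell module score: mean
   normalised expression of module genes minus the mean of control genes
   drawn from expression-matched bins.
6. Compare scores across clusters (Kruskal-Wallis + pairwise rank-sum) or
   between two groups (Mann-Whitney), and highlight top-percentile cells.

avg_log2FC is computed as log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))
on the log-normalised matrix; the formula is stated here because published
analyses rarely print theirs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataIntegrityError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Cell-level QC rules; comparisons are strict, matching the stated rules.

    A cell is removed if: pct_mito > max_pct_mito; n_genes < min_n_genes;
    pct_ercc > max_pct_ercc; ercc_accuracy < min_ercc_accuracy;
    pct_ribo < min_pct_ribo.  Boundary cells (exactly at a threshold) are
    kept.  Fractions are in [0, 1].
    """

    max_pct_mito: float = 0.10
    min_n_genes: int = 400
    max_pct_ercc: float = 0.25
    min_ercc_accuracy: float = 0.70
    min_pct_ribo: float = 0.05


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def compute_qc_metrics(adata: AnnData) -> None:
    """Fill missing per-cell QC metrics in ``adata.obs`` from raw counts.

    Gene classes are recognised by name prefix: ``MT-`` mitochondrial,
    ``RPS``/``RPL`` ribosomal protein, ``ERCC-`` spike-in.  ERCC
    quantification accuracy (Pearson r between log1p observed spike-in
    counts and log1p input molarities) can only be computed when
    ``adata.uns["ercc_molarity"]`` supplies the input amounts; otherwise the
    metric is left absent and its rule is skipped.
    """
    X = _dense(adata.X)
    totals = X.sum(axis=1)
    names = adata.var_names.str.upper()
    is_mito = names.str.startswith("MT-")
    is_ribo = names.str.startswith(("RPS", "RPL"))
    is_ercc = names.str.startswith("ERCC-")
    with np.errstate(invalid="ignore", divide="ignore"):
        if "pct_mito" not in adata.obs:
            adata.obs["pct_mito"] = np.where(totals > 0, X[:, is_mito].sum(1) / totals, 0.0)
        if "pct_ribo" not in adata.obs:
            adata.obs["pct_ribo"] = np.where(totals > 0, X[:, is_ribo].sum(1) / totals, 0.0)
        if "pct_ercc" not in adata.obs:
            adata.obs["pct_ercc"] = np.where(totals > 0, X[:, is_ercc].sum(1) / totals, 0.0)
    if "n_genes" not in adata.obs:
        adata.obs["n_genes"] = (X[:, ~is_ercc] > 0).sum(axis=1)
    if "ercc_accuracy" not in adata.obs and "ercc_molarity" in adata.uns and is_ercc.any():
        mol = np.log1p(np.asarray(adata.uns["ercc_molarity"], dtype=float))
        obs = np.log1p(X[:, is_ercc])
        acc = np.full(adata.n_obs, np.nan)
        for i in range(adata.n_obs):
            if obs[i].std() > 0 and mol.std() > 0:
                acc[i] = np.corrcoef(obs[i], mol)[0, 1]
        adata.obs["ercc_accuracy"] = acc


def qc_filter_cells(adata: AnnData, thresholds: QCThresholds | None = None) -> AnnData:
    """Remove cells violating any QC rule; per-rule removal counts are logged.

    Metrics absent from ``adata.obs`` are computed from raw counts where
    possible (:func:`compute_qc_metrics`); a rule whose metric cannot be
    obtained is skipped with a warning rather than silently passing cells.
    """
    thr = thresholds or QCThresholds()
    adata = adata.copy()
    compute_qc_metrics(adata)
    keep = np.ones(adata.n_obs, dtype=bool)
    report: dict[str, int] = {"n_before": adata.n_obs}
    rules = [
        ("pct_mito", lambda m: m <= thr.max_pct_mito),
        ("n_genes", lambda m: m >= thr.min_n_genes),
        ("pct_ercc", lambda m: m <= thr.max_pct_ercc),
        ("ercc_accuracy", lambda m: m >= thr.min_ercc_accuracy),
        ("pct_ribo", lambda m: m >= thr.min_pct_ribo),
    ]
    for metric, rule in rules:
        if metric not in adata.obs:
            warnings.warn(f"QC metric '{metric}' unavailable; rule skipped")
            report[f"removed_{metric}"] = 0
            continue
        vals = adata.obs[metric].to_numpy(dtype=float)
        ok = rule(vals) | np.isnan(vals)  # cells with unknown metric are not removed
        report[f"removed_{metric}"] = int((keep & ~ok).sum())
        keep &= ok
    report["n_after"] = int(keep.sum())
    logger.info("qc_filter_cells: %s", report)
    out = adata[keep].copy()
    out.uns["qc_filter_report"] = report
    return out


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_log(adata: AnnData, target_sum: float = 10_000.0) -> AnnData:
    """Depth-normalise each cell to ``target_sum`` total counts, then log1p.

    Raw counts are preserved in ``layers["counts"]``.  Zero-depth cells are
    removed with a warning (they carry no information and would divide by
    zero).
    """
    X = _dense(adata.X).astype(float)
    depth = X.sum(axis=1)
    if (depth == 0).any():
        n0 = int((depth == 0).sum())
        warnings.warn(f"removing {n0} zero-depth cell(s) before normalization")
        adata = adata[depth > 0].copy()
        X = X[depth > 0]
        depth = depth[depth > 0]
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(X / depth[:, None] * target_sum)
    out.uns["normalization"] = {"target_sum": target_sum, "log_base": "e", "pseudocount": 1}
    return out


# ---------------------------------------------------------------------------
# Marker derivation
# ---------------------------------------------------------------------------

def _rank_sum_pvalues(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p-values per gene (columns), tie-corrected
    normal approximation, vectorised across genes."""
    res = stats.mannwhitneyu(x_in, x_out, axis=0, method="asymptotic", alternative="two-sided")
    return np.atleast_1d(res.pvalue)


def find_markers(
    adata: AnnData,
    groupby: str,
    groups: Sequence[str] | None = None,
    min_pct: float = 0.25,
    min_log2fc: float = 0.25,
    alpha: float = 0.01,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker genes per group on the normalised matrix.

    For each group, genes detected in at least ``min_pct`` of cells (in
    either the group or the rest) and with |avg_log2FC| >= ``min_log2fc``
    are tested with a two-sided Wilcoxon rank-sum test; p-values are BH
    adjusted within the group and rows with adjusted p >= ``alpha`` are
    dropped.  Groups below ``min_group_size`` cells are skipped with a
    warning.  Returns a MarkerTable with columns group, gene, avg_log2fc,
    p_value, adjusted_p, pct_in, pct_out.
    """
    if groupby not in adata.obs:
        raise DataIntegrityError(f"obs column '{groupby}' not found")
    labels = adata.obs[groupby].astype(str).to_numpy()
    X = _dense(adata.X)
    detected = X > 0
    all_groups = sorted(set(labels)) if groups is None else list(groups)
    usable = [g for g in all_groups if (labels == g).sum() >= min_group_size]
    if len(usable) < 2 and groups is None:
        raise DataIntegrityError("need >= 2 groups with enough cells for marker derivation")
    frames = []
    for g in all_groups:
        mask = labels == g
        if (n_in := int(mask.sum())) < min_group_size:
            warnings.warn(f"group '{g}' has {n_in} < {min_group_size} cells; skipped")
            continue
        x_in, x_out = X[mask], X[~mask]
        pct_in = detected[mask].mean(axis=0)
        pct_out = detected[~mask].mean(axis=0)
        lfc = np.log2(
            (np.expm1(x_in).mean(axis=0) + 1) / (np.expm1(x_out).mean(axis=0) + 1)
        )
        test = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= min_log2fc)
        if not test.any():
            continue
        pvals = _rank_sum_pvalues(x_in[:, test], x_out[:, test])
        adj = multipletests(pvals, method="fdr_bh")[1]
        tbl = pd.DataFrame(
            {
                "group": g,
                "gene": adata.var_names[test],
                "avg_log2fc": lfc[test],
                "p_value": pvals,
                "adjusted_p": adj,
                "pct_in": pct_in[test],
                "pct_out": pct_out[test],
            }
        )
        frames.append(tbl[tbl["adjusted_p"] < alpha])
    if not frames:
        return pd.DataFrame(
            columns=["group", "gene", "avg_log2fc", "p_value", "adjusted_p", "pct_in", "pct_out"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class GeneModule:
    """An ordered reactivity gene list with derivation provenance."""

    label: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def build_reactivity_module(
    markers: pd.DataFrame, group: str, top_n: int = 50
) -> GeneModule:
    """Top-``top_n`` genes of ``group`` ordered by avg_log2FC descending.

    Only up-regulated markers (avg_log2FC > 0) are eligible: a reactivity
    signature is the program the group expresses, not what it lacks.  Ties
    in fold change are broken lexicographically by gene name.  Fewer than
    ``top_n`` eligible genes yields a shorter module with a warning.
    """
    sub = markers[(markers["group"] == group) & (markers["avg_log2fc"] > 0)]
    ordered = sub.sort_values(
        ["avg_log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    genes = ordered["gene"].head(top_n).tolist()
    if len(genes) < top_n:
        warnings.warn(
            f"group '{group}': only {len(genes)} significant genes (< top_n={top_n})"
        )
    return GeneModule(
        label=group,
        genes=genes,
        provenance={"top_n": top_n, "n_significant": len(sub)},
    )


# ---------------------------------------------------------------------------
# Module scoring
# ---------------------------------------------------------------------------

def module_score(
    adata: AnnData,
    module: GeneModule,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score with expression-matched control genes.

    Genes are binned into ``n_bins`` equal-size bins by mean normalised
    expression; for each module gene, up to ``n_ctrl`` control genes are
    drawn (seeded, without replacement) from its bin.  The score is the mean
    expression of module genes minus the mean expression of the pooled
    control-gene set.  Module genes absent from the matrix are dropped with
    a warning; an empty intersection is an error.
    """
    present = [g for g in module.genes if g in adata.var_names]
    missing = set(module.genes) - set(present)
    if missing:
        warnings.warn(f"module '{module.label}': {len(missing)} gene(s) absent, dropped")
    if not present:
        raise DataIntegrityError(f"module '{module.label}' has no genes in the matrix")
    X = _dense(adata.X)
    avg = pd.Series(X.mean(axis=0), index=adata.var_names)
    # equal-occupancy bins on the rank of average expression
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    rng = np.random.default_rng(seed)
    ctrl: set[str] = set()
    for gene in present:
        pool = bins.index[bins == bins[gene]]
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False))
    var_index = pd.Index(adata.var_names)
    mod_idx = var_index.get_indexer(present)
    ctrl_idx = var_index.get_indexer(sorted(ctrl))
    score = X[:, mod_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name=f"score_{module.label}")


# ---------------------------------------------------------------------------
# Score comparisons
# ---------------------------------------------------------------------------

@dataclass
class ClusterScoreReport:
    """Kruskal-Wallis across clusters plus BH-adjusted pairwise rank-sum tests."""

    kruskal_stat: float
    kruskal_p: float
    pairwise: pd.DataFrame  # cluster_a, cluster_b, p_value, adjusted_p
    per_cluster: pd.DataFrame  # cluster, n, mean, median


def compare_cluster_scores(
    scores: pd.Series, cluster_labels: pd.Series | Mapping[str, str]
) -> ClusterScoreReport:
    """Compare a per-cell score across clusters.

    Global Kruskal-Wallis test, then all pairwise two-sided rank-sum tests
    with BH adjustment, plus per-cluster mean/median.  Clusters with < 2
    cells are excluded with a warning.
    """
    labels = pd.Series(cluster_labels).reindex(scores.index)
    groups = {}
    for name, idx in scores.groupby(labels.to_numpy()).groups.items():
        vals = scores.loc[idx].to_numpy()
        if len(vals) < 2:
            warnings.warn(f"cluster '{name}' has < 2 cells; excluded from comparison")
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise DataIntegrityError("need >= 2 clusters with >= 2 cells each")
    names = sorted(groups)
    stat, p = stats.kruskal(*[groups[n] for n in names])
    pairs, pvals = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pv = stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided"
            ).pvalue
            pairs.append((a, b))
            pvals.append(pv)
    adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    pairwise = pd.DataFrame(
        {
            "cluster_a": [a for a, _ in pairs],
            "cluster_b": [b for _, b in pairs],
            "p_value": pvals,
            "adjusted_p": adj,
        }
    )
    per_cluster = pd.DataFrame(
        {
            "cluster": names,
            "n": [len(groups[n]) for n in names],
            "mean": [float(np.mean(groups[n])) for n in names],
            "median": [float(np.median(groups[n])) for n in names],
        }
    )
    return ClusterScoreReport(float(stat), float(p), pairwise, per_cluster)


def top_percent_cells(scores: pd.Series, pct: float = 5.0) -> set[str]:
    """Cells at or above the (100 - pct) percentile of the score.

    Ties at the cut are included, so the returned set can exceed pct% of
    cells (all cells, in the degenerate all-equal case).
    """
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    thr = np.percentile(scores.to_numpy(), 100 - pct)
    return set(scores.index[scores >= thr])


@dataclass
class GroupContrast:
    """Two-group score comparison (e.g. tetramer-positive vs -negative cells)."""

    n_a: int
    n_b: int
    statistic: float
    p_value: float
    median_difference: float  # median(a) - median(b)


def score_group_contrast(
    scores: pd.Series, binary_labels: pd.Series | np.ndarray
) -> GroupContrast:
    """Two-sided Mann-Whitney test between the two label groups.

    ``binary_labels`` is boolean (True = group of interest) or two-level;
    the comparison is group-of-interest vs the rest.  scipy's exact method
    is used automatically at small sample sizes.
    """
    lab = np.asarray(pd.Series(binary_labels).reindex(scores.index) if isinstance(
        binary_labels, pd.Series) else binary_labels)
    if lab.dtype != bool:
        levels = sorted(pd.unique(lab))
        if len(levels) != 2:
            raise ValueError(f"expected 2 label levels, got {levels}")
        lab = lab == levels[1]
    a = scores.to_numpy()[lab]
    b = scores.to_numpy()[~lab]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupContrast(
        n_a=len(a),
        n_b=len(b),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_difference=float(np.median(a) - np.median(b)),
    )


def qc_report(adata: AnnData) -> dict:
    """The QC filter report stored by :func:`qc_filter_cells`, if any."""
    return dict(adata.uns.get("qc_filter_report", {}))
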