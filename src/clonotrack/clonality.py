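"""Clonal expansion, dominance, and cross-repertoire overlap statistics.

Clonal expansion in single-cell data follows the standard convention: a
clonotype observed in >= 2 cells is "expanded".  Dominance is summarised by
the cumulative frequency share of the top-n clones (e.g. the share of all
intrahepatic reads held by the 100 most abundant liver clones).  Overlap
between two collapsed clone sets is reported both as clone counts and as
frequency mass, since the two answer different questions (how many clones
recirculate vs how much of the repertoire they occupy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .repertoire import CloneSet

OverlapKey = Literal["cdr3_nt", "cdr3_nt+v"]


@dataclass
class SCClonotype:
    """A single-cell clonotype: the cells sharing one (paired) CDR3 identity."""

    clonotype_id: str
    cdr3b_nt: str
    cdr3a_nt: str | None
    v_call_b: str
    j_call_b: str
    cell_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.cell_ids)


@dataclass
class ExpansionSummary:
    """Expansion of a set of single-cell clonotypes (pie-chart semantics).

    ``proportion_clonotypes`` and ``proportion_cells`` each map
    {"expanded", "unique"} to proportions summing to 1 (both zero on empty
    input).
    """

    n_cells_with_tcr: int
    n_clonotypes: int
    n_expanded_clonotypes: int
    proportion_cells_in_expanded: float
    proportion_clonotypes: dict = field(default_factory=dict)
    proportion_cells: dict = field(default_factory=dict)


@dataclass
class OverlapReport:
    """Overlap between two collapsed clone sets under a matching key."""

    key: OverlapKey
    shared: pd.DataFrame  # columns: cdr3_nt (+ v_gene), count_a, count_b, frequency_a, frequency_b
    n_shared: int
    n_a: int
    n_b: int
    frac_of_a: float  # |shared| / |a|
    frac_of_b: float
    mass_in_a: float  # frequency mass of shared clones within a
    mass_in_b: float


def clonotypes_from_table(
    cells: pd.DataFrame, key: Literal["paired", "beta"] = "paired"
) -> list[SCClonotype]:
    """Group a cell-level clonotype table into :class:`SCClonotype` objects.

    ``cells`` needs columns cell_id, cdr3b_nt and optionally cdr3a_nt,
    v_call_b, j_call_b.  ``key`` selects the clonal-identity definition:
    paired (cdr3a_nt, cdr3b_nt) where the alpha chain is available, or
    beta-only (the definition that bridges to bulk TCRbeta data).
    """
    df = cells.copy()
    if "cdr3a_nt" not in df.columns:
        df["cdr3a_nt"] = ""
    df["cdr3a_nt"] = df["cdr3a_nt"].fillna("")
    for col in ("v_call_b", "j_call_b"):
        if col not in df.columns:
            df[col] = ""
    if key == "paired":
        group_cols = ["cdr3b_nt", "cdr3a_nt"]
    else:
        group_cols = ["cdr3b_nt"]
    out: list[SCClonotype] = []
    for i, (gkey, sub) in enumerate(df.groupby(group_cols, sort=True)):
        cdr3b = gkey[0]
        cdr3a = gkey[1] if key == "paired" else None
        out.append(
            SCClonotype(
                clonotype_id=f"ct{i:05d}",
                cdr3b_nt=cdr3b,
                cdr3a_nt=cdr3a or None,
                v_call_b=sub["v_call_b"].iloc[0],
                j_call_b=sub["j_call_b"].iloc[0],
                cell_ids=sorted(sub["cell_id"].tolist()),
            )
        )
    return out


def classify_expansion(
    clonotypes: Sequence[SCClonotype], min_cells: int = 2
) -> ExpansionSummary:
    """Label clonotypes as expanded (size >= ``min_cells``) and summarise.

    Returns proportions over clonotypes and over cells; both views are
    reported because a few large clones can dominate cells while being a
    minority of clonotypes.
    """
    if min_cells < 2:
        raise ValueError("min_cells must be >= 2")
    if len(clonotypes) == 0:
        return ExpansionSummary(0, 0, 0, 0.0, {}, {})
    sizes = [c.size for c in clonotypes]
    n_cells = sum(sizes)
    n_expanded = sum(1 for s in sizes if s >= min_cells)
    cells_expanded = sum(s for s in sizes if s >= min_cells)
    return ExpansionSummary(
        n_cells_with_tcr=n_cells,
        n_clonotypes=len(sizes),
        n_expanded_clonotypes=n_expanded,
        proportion_cells_in_expanded=cells_expanded / n_cells,
        proportion_clonotypes={
            "expanded": n_expanded / len(sizes),
            "unique": 1 - n_expanded / len(sizes),
        },
        proportion_cells={
            "expanded": cells_expanded / n_cells,
            "unique": 1 - cells_expanded / n_cells,
        },
    )


def top_n_cumulative_share(clones: CloneSet, n: int) -> float:
    """Frequency share of the ``n`` most abundant clones (dominance measure).

    Uses the deterministic rank order (count desc, cdr3_nt asc).  ``n``
    beyond the clone count returns 1.0; n = 0 returns 0.0.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if len(clones) == 0 or n == 0:
        return 0.0
    ranked = clones.ranked()
    return float(ranked["frequency"].head(n).sum())


def _collapse_allele(v_call: str) -> str:
    """TRBV12-3*01 -> TRBV12-3 (allele-collapsed gene-level comparison)."""
    return v_call.split("*", 1)[0]


def _overlap_keys(cs: CloneSet, key: OverlapKey) -> pd.DataFrame:
    df = cs.clones[["cdr3_nt", "v_call", "count", "frequency"]].copy()
    if key == "cdr3_nt+v":
        df["v_gene"] = df["v_call"].map(_collapse_allele)
        df["_key"] = df["cdr3_nt"] + "|" + df["v_gene"]
    else:
        df["_key"] = df["cdr3_nt"]
    return df


def repertoire_overlap(
    a: CloneSet, b: CloneSet, key: OverlapKey = "cdr3_nt"
) -> OverlapReport:
    """Shared clones between two collapsed repertoires.

    The shared-clone *set* is symmetric; the normalised fractions and
    frequency masses are per-repertoire.  Matching is exact on the CDR3
    nucleotide string, optionally also requiring V-gene agreement at the
    allele-collapsed level.
    """
    da, db = _overlap_keys(a, key), _overlap_keys(b, key)
    merged = da.merge(db, on="_key", suffixes=("_a", "_b"))
    cols = {
        "cdr3_nt": merged["cdr3_nt_a"],
        "count_a": merged["count_a"],
        "count_b": merged["count_b"],
        "frequency_a": merged["frequency_a"],
        "frequency_b": merged["frequency_b"],
    }
    if key == "cdr3_nt+v":
        cols["v_gene"] = merged["v_gene_a"]
    shared = pd.DataFrame(cols).sort_values("cdr3_nt", kind="mergesort").reset_index(drop=True)
    n_shared = len(shared)
    return OverlapReport(
        key=key,
        shared=shared,
        n_shared=n_shared,
        n_a=len(a),
        n_b=len(b),
        frac_of_a=n_shared / len(a) if len(a) else 0.0,
        frac_of_b=n_shared / len(b) if len(b) else 0.0,
        mass_in_a=float(shared["frequency_a"].sum()),
        mass_in_b=float(shared["frequency_b"].sum()),
    )


def subset_share_of_top_clones(
    tissue: CloneSet, subset: CloneSet, k: int = 100
) -> float:
    """Frequency mass, within ``subset``, of the top-``k`` tissue clones.

    This is the "proportion of cells within the top-k tissue sequences"
    statistic used to compare circulating PD-1+ vs PD-1- memory CD4
    populations: a blood subset enriched for dominant intrahepatic clones
    carries more of its reads in top-k tissue sequences.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(tissue) == 0 or len(subset) == 0:
        return 0.0
    top = set(tissue.ranked()["cdr3_nt"].head(k))
    in_top = subset.clones["cdr3_nt"].isin(top)
    return float(subset.clones.loc[in_top, "frequency"].sum())
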