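"""Bulk TCRbeta repertoire I/O, filtering, and clone collapsing.

A repertoire is a table of rearrangements in the AIRR Rearrangement TSV
dialect (``junction``, ``v_call``, ``j_call``, ``duplicate_count``,
``productive``).  Bulk genomic-DNA TCRbeta-seq output is processed with the
standard repertoire cleaning rules for this assay: non-productive
rearrangements and sequences with fewer than two reads are discarded, and
every unique CDR3 nucleotide sequence is treated as one clone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio.Seq import Seq

from .errors import AirrFormatError

logger = logging.getLogger(__name__)

Compartment = Literal["liver", "blood_pd1pos", "blood_pd1neg", "other"]

#: AIRR columns required to interpret a rearrangement row.  ``junction`` may
#: appear under the older ``cdr3`` header and ``duplicate_count`` may fall back
#: to ``consensus_count``; both dialects occur in tool outputs.
MANDATORY_COLUMNS = ("junction", "v_call", "j_call", "duplicate_count", "productive")

_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n", ""}


@dataclass
class Rearrangement:
    """One unique rearrangement (a row of an AIRR Rearrangement TSV)."""

    cdr3_nt: str
    v_call: str
    j_call: str
    count: int
    productive: bool

    @property
    def cdr3_aa(self) -> str:
        return translate_junction(self.cdr3_nt)


@dataclass
class Repertoire:
    """A bulk repertoire: one donor, one compartment, a rearrangement table.

    ``rearrangements`` columns: junction, v_call, j_call, duplicate_count,
    productive (+ any extra columns preserved verbatim from the input file).
    """

    donor_id: str
    compartment: Compartment
    rearrangements: pd.DataFrame
    filter_report: dict = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        if len(self.rearrangements) == 0:
            return 0
        return int(self.rearrangements["duplicate_count"].sum())

    def __len__(self) -> int:
        return len(self.rearrangements)

    def iter_rearrangements(self) -> Iterable[Rearrangement]:
        for row in self.rearrangements.itertuples(index=False):
            yield Rearrangement(
                cdr3_nt=row.junction,
                v_call=row.v_call,
                j_call=row.j_call,
                count=int(row.duplicate_count),
                productive=bool(row.productive),
            )


@dataclass
class CloneSet:
    """Clones of one repertoire after collapsing by CDR3 nucleotide sequence.

    ``clones`` columns: cdr3_nt, cdr3_aa, v_call, j_call, count, frequency.
    Frequencies are computed over the post-filter read total and sum to 1.
    """

    donor_id: str
    compartment: Compartment
    clones: pd.DataFrame
    total_reads: int

    def __len__(self) -> int:
        return len(self.clones)

    def ranked(self) -> pd.DataFrame:
        """Clones in the deterministic dominance order.

        Count descending, ties broken by cdr3_nt ascending so that top-k
        selection is reproducible across runs and row orders.
        """
        return self.clones.sort_values(
            ["count", "cdr3_nt"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def translate_junction(cdr3_nt: str) -> str:
    """Translate a junction with the standard genetic code, frame anchored at 0.

    Trailing bases that do not fill a codon are ignored (non-productive
    junctions need not be a multiple of three).
    """
    usable = len(cdr3_nt) - len(cdr3_nt) % 3
    if usable == 0:
        return ""
    try:
        return str(Seq(cdr3_nt[:usable]).translate())
    except Exception:
        # junctions with ambiguity codes or non-nucleotide characters have no
        # defined translation; the nucleotide key is still usable downstream
        return ""


def _parse_productive(values: pd.Series) -> pd.Series:
    def one(v) -> bool:
        if isinstance(v, bool):
            return v
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise AirrFormatError(f"unparseable value in 'productive' column: {v!r}")

    return values.map(one)


def read_airr_tsv(
    path: str | Path,
    donor_id: str = "",
    compartment: Compartment = "other",
) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Accepts ``cdr3`` as a synonym for ``junction`` and falls back from
    ``duplicate_count`` to ``consensus_count``.  Unknown columns are preserved
    as opaque annotations.  A file with a header but no rows yields an empty
    repertoire with a warning; a missing mandatory column raises
    :class:`AirrFormatError` naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "junction" not in df.columns and "cdr3" in df.columns:
        df = df.rename(columns={"cdr3": "junction"})
    if "duplicate_count" not in df.columns and "consensus_count" in df.columns:
        df = df.rename(columns={"consensus_count": "duplicate_count"})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise AirrFormatError(f"{path}: mandatory AIRR column '{col}' is missing")
    if len(df) == 0:
        warnings.warn(f"{path}: no rearrangement rows; returning empty repertoire")
        df = df.astype({"duplicate_count": int, "productive": bool}, errors="ignore")
        return Repertoire(donor_id=donor_id, compartment=compartment, rearrangements=df)
    df = df.copy()
    df["junction"] = df["junction"].str.upper()
    df["duplicate_count"] = df["duplicate_count"].astype(int)
    df["productive"] = _parse_productive(df["productive"])
    return Repertoire(donor_id=donor_id, compartment=compartment, rearrangements=df)


def write_airr_tsv(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire back to AIRR Rearrangement TSV."""
    df = rep.rearrangements.copy()
    if len(df):
        df["productive"] = df["productive"].map({True: "T", False: "F"})
    df.to_csv(path, sep="\t", index=False)


def filter_repertoire(
    rep: Repertoire, min_count: int = 2, productive_only: bool = True
) -> Repertoire:
    """Apply the bulk TCRbeta cleaning rules.

    Rearrangements with fewer than ``min_count`` reads are discarded, as are
    non-productive rearrangements when ``productive_only``.  The defaults are
    the assay's standard thresholds (count >= 2, productive only).  A report
    of before/after counts is attached to the returned repertoire and logged.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    df = rep.rearrangements
    n_before = len(df)
    keep = df["duplicate_count"] >= min_count
    n_low_count = int((~keep).sum())
    n_nonproductive = 0
    if productive_only and n_before:
        prod = df["productive"].astype(bool)
        n_nonproductive = int((keep & ~prod).sum())
        keep = keep & prod
    out = df.loc[keep].reset_index(drop=True)
    report = {
        "n_before": n_before,
        "n_after": len(out),
        "n_removed_low_count": n_low_count,
        "n_removed_nonproductive": n_nonproductive,
        "min_count": min_count,
        "productive_only": productive_only,
    }
    logger.info(
        "filter_repertoire[%s/%s]: %d -> %d rearrangements "
        "(%d below min_count=%d, %d non-productive)",
        rep.donor_id, rep.compartment, n_before, len(out),
        n_low_count, min_count, n_nonproductive,
    )
    return Repertoire(
        donor_id=rep.donor_id,
        compartment=rep.compartment,
        rearrangements=out,
        filter_report=report,
    )


def collapse_to_clones(rep: Repertoire) -> CloneSet:
    """Collapse rearrangements to clones: one clone per unique CDR3 nucleotide sequence.

    Counts of rows sharing a junction are summed; the V/J calls of the
    highest-count constituent are retained.  Frequencies are computed over
    the post-filter read total.
    """
    df = rep.rearrangements
    if len(df) == 0:
        empty = pd.DataFrame(
            columns=["cdr3_nt", "cdr3_aa", "v_call", "j_call", "count", "frequency"]
        )
        return CloneSet(rep.donor_id, rep.compartment, empty, total_reads=0)
    # stable sort so the max-count representative is deterministic under ties
    ordered = df.sort_values(
        ["junction", "duplicate_count"], ascending=[True, False], kind="mergesort"
    )
    rep_rows = ordered.drop_duplicates("junction", keep="first")
    counts = df.groupby("junction", sort=True)["duplicate_count"].sum()
    clones = pd.DataFrame(
        {
            "cdr3_nt": counts.index.to_numpy(),
            "cdr3_aa": [translate_junction(j) for j in counts.index],
            "v_call": rep_rows.set_index("junction").loc[counts.index, "v_call"].to_numpy(),
            "j_call": rep_rows.set_index("junction").loc[counts.index, "j_call"].to_numpy(),
            "count": counts.to_numpy(),
        }
    )
    total = int(clones["count"].sum())
    clones["frequency"] = clones["count"] / total
    return CloneSet(rep.donor_id, rep.compartment, clones.reset_index(drop=True), total)
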