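"""Track dominant tissue clones into circulating single-cell data.

The procedure: take the top-K clones of a (filtered, collapsed) tissue
repertoire, find every circulating cell whose CDR3beta nucleotide sequence
matches one of them exactly, and assign each tracked clone a transcriptional
cluster by majority vote over its matched cells.  Clones with no matched
cell are listed but excluded from the per-cluster aggregate (the aggregate
covers clones actually found in circulation).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .clonality import SCClonotype, _collapse_allele
from .errors import ConfigurationError, DataIntegrityError
from .repertoire import CloneSet

logger = logging.getLogger(__name__)


@dataclass
class TrackingResult:
    """Per-donor tracking table plus the per-cluster aggregate.

    ``rows`` columns: rank, cdr3_nt, tissue_count, tissue_frequency,
    n_matched_cells, cluster_votes (dict), assigned_cluster, ambiguous.
    ``aggregate`` maps cluster -> number of tracked clones assigned to it,
    counting only clones with >= 1 matched cell.
    """

    donor_id: str
    rows: pd.DataFrame
    aggregate: dict

    @property
    def n_tracked_found(self) -> int:
        return int((self.rows["n_matched_cells"] > 0).sum())


def select_top_clones(tissue: CloneSet, k: int = 100) -> CloneSet:
    """First ``k`` clones under the deterministic rank order.

    Ties at the boundary are resolved by the lexicographic cdr3_nt rule so
    the selection is stable across runs and input row orders.
    """
    if k <= 0:
        raise ConfigurationError(f"top-k must be positive, got {k}")
    ranked = tissue.ranked()
    if k > len(ranked):
        warnings.warn(
            f"requested top {k} clones but repertoire has only {len(ranked)}; using all"
        )
    return CloneSet(tissue.donor_id, tissue.compartment, ranked.head(k), tissue.total_reads)


def match_clones_to_cells(
    top: CloneSet,
    sc_clonotypes: list[SCClonotype],
    require_v: bool = False,
    match_on: str = "nt",
) -> dict[str, list[str]]:
    """Map each top clone to the circulating cells carrying its CDR3beta.

    Matching is an exact string comparison on the CDR3beta nucleotide
    sequence (``match_on="aa"`` switches to amino acid for cross-platform
    inputs); ``require_v`` additionally demands V-gene agreement at the
    allele-collapsed level.  A matched clone maps to the union of member
    cells of every matching single-cell clonotype.  Clones with no match are
    absent from the returned dict.
    """
    if match_on not in ("nt", "aa"):
        raise ConfigurationError(f"match_on must be 'nt' or 'aa', got {match_on!r}")
    # index single-cell clonotypes by their matching key
    index: dict[tuple, list[str]] = {}
    for ct in sc_clonotypes:
        seq = ct.cdr3b_nt
        if match_on == "aa":
            from .repertoire import translate_junction

            seq = translate_junction(seq)
        key = (seq, _collapse_allele(ct.v_call_b)) if require_v else (seq,)
        index.setdefault(key, []).extend(ct.cell_ids)
    matches: dict[str, list[str]] = {}
    for row in top.clones.itertuples(index=False):
        seq = row.cdr3_nt if match_on == "nt" else row.cdr3_aa
        key = (seq, _collapse_allele(row.v_call)) if require_v else (seq,)
        cells = index.get(key)
        if cells:
            matches[row.cdr3_nt] = sorted(set(cells))
    return matches


def assign_cluster_affiliation(
    top: CloneSet,
    matches: Mapping[str, list[str]],
    cluster_of_cell: Mapping[str, str],
    donor_id: str | None = None,
) -> TrackingResult:
    """Assign each tracked clone a cluster by majority vote over matched cells.

    A vote tie flags the clone ``ambiguous`` and is resolved in favour of
    the cluster with more cells overall, then the smaller cluster label.
    A matched cell without a cluster label is a data-integrity error.
    """
    cluster_sizes = Counter(cluster_of_cell.values())
    ranked = top.ranked()
    rows = []
    aggregate: Counter = Counter()
    for rank, row in enumerate(ranked.itertuples(index=False), start=1):
        cells = matches.get(row.cdr3_nt, [])
        votes: Counter = Counter()
        for cell in cells:
            if cell not in cluster_of_cell:
                raise DataIntegrityError(
                    f"matched cell '{cell}' has no cluster label"
                )
            votes[cluster_of_cell[cell]] += 1
        assigned = None
        ambiguous = False
        if votes:
            best = max(votes.values())
            tied = sorted(c for c, v in votes.items() if v == best)
            ambiguous = len(tied) > 1
            # tie-break: larger cluster overall, then smaller label
            assigned = min(tied, key=lambda c: (-cluster_sizes.get(c, 0), c))
            aggregate[assigned] += 1
        rows.append(
            {
                "rank": rank,
                "cdr3_nt": row.cdr3_nt,
                "tissue_count": row.count,
                "tissue_frequency": row.frequency,
                "n_matched_cells": len(cells),
                "cluster_votes": dict(sorted(votes.items())),
                "assigned_cluster": assigned,
                "ambiguous": ambiguous,
            }
        )
    result = TrackingResult(
        donor_id=donor_id if donor_id is not None else top.donor_id,
        rows=pd.DataFrame(rows),
        aggregate=dict(sorted(aggregate.items())),
    )
    logger.info(
        "tracking[%s]: %d/%d top clones found in circulation; aggregate=%s",
        result.donor_id, result.n_tracked_found, len(ranked), result.aggregate,
    )
    return result


def track(
    tissue: CloneSet,
    sc_clonotypes: list[SCClonotype],
    cluster_of_cell: Mapping[str, str],
    k: int = 100,
    require_v: bool = False,
) -> TrackingResult:
    """Convenience wrapper: select top-k, match, and assign clusters."""
    top = select_top_clones(tissue, k)
    matches = match_clones_to_cells(top, sc_clonotypes, require_v=require_v)
    return assign_cluster_affiliation(top, matches, cluster_of_cell)
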