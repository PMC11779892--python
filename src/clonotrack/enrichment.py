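"""Antigen-specific CD4 T-cell frequency from magnetic enrichment assays.

In the CD154 enrichment assay, antigen-specific cells are magnetically
enriched after brief peptide stimulation while a small non-enriched aliquot
(by default 1/10) is saved to count the total CD4 pool.  The frequency is
F = n / N, where n is the number of positive cells in the bound fraction and
N is the total CD4 count estimated from the saved aliquot (count / saved
fraction).  Frequencies are conventionally reported per million CD4 T cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError


@dataclass
class EnrichmentAssay:
    """Counts from one enrichment experiment."""

    n_positive_bound: int
    n_reference_in_saved_fraction: int
    saved_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_positive_bound < 0 or self.n_reference_in_saved_fraction < 0:
            raise ConfigurationError("counts must be non-negative")
        if not (0 < self.saved_fraction <= 1):
            raise ConfigurationError("saved_fraction must be in (0, 1]")

    @property
    def n_total_reference(self) -> float:
        """Estimated total reference-cell count N (saved count / saved fraction)."""
        return self.n_reference_in_saved_fraction / self.saved_fraction


def estimate_frequency(assay: EnrichmentAssay, per: int = 1_000_000) -> float:
    """F = n / N, scaled to events per ``per`` reference cells.

    Scale-invariant: multiplying both counts by a constant leaves F
    unchanged.  A zero reference count makes the frequency undefined.
    """
    if assay.n_reference_in_saved_fraction <= 0:
        raise ZeroDivisionError(
            "frequency undefined: no reference cells counted in the saved fraction"
        )
    return assay.n_positive_bound / assay.n_total_reference * per


def frequency_ci(
    assay: EnrichmentAssay, per: int = 1_000_000, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval on n out of N, scaled.

    ``level=0`` degenerates to the point estimate.  With n = 0 the lower
    bound is exactly 0.
    """
    if not (0 <= level < 1):
        raise ConfigurationError("level must be in [0, 1)")
    point = estimate_frequency(assay, per=per)
    if level == 0:
        return (point, point)
    n_total = int(round(assay.n_total_reference))
    lo, hi = proportion_confint(
        assay.n_positive_bound, n_total, alpha=1 - level, method="beta"
    )
    return (float(lo) * per, float(hi) * per)


def simulate_enrichment_assay(
    true_frequency: float,
    n_total_cells: int,
    saved_fraction: float = 0.1,
    capture_efficiency: float = 1.0,
    rng: np.random.Generator | None = None,
) -> EnrichmentAssay:
    """Simulate the split-and-enrich counting process.

    A pool of ``n_total_cells`` reference cells contains antigen-specific
    cells at ``true_frequency`` (binomially sampled).  The saved aliquot is
    a binomial subsample at ``saved_fraction`` used only for counting the
    denominator; the enrichment step captures each specific cell with
    ``capture_efficiency`` (the idealised assay captures all of them).  The
    randomness of the saved-fraction count is what the estimator must be
    robust to; at default settings F = n/N is unbiased up to the negligible
    Jensen term of the 1/N estimate.
    """
    rng = rng or np.random.default_rng()
    n_specific = rng.binomial(n_total_cells, true_frequency)
    n_bound = rng.binomial(n_specific, capture_efficiency)
    n_saved = rng.binomial(n_total_cells, saved_fraction)
    return EnrichmentAssay(
        n_positive_bound=int(n_bound),
        n_reference_in_saved_fraction=int(n_saved),
        saved_fraction=saved_fraction,
    )
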