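"""Dual-allele decomposition of transcription-onset variability.

Two identical reporter alleles in the same nucleus see the same upstream
signalling, so variability shared between them is extrinsic (cell-to-cell)
while the residual allele-to-allele scatter is intrinsic to each
transcription event.  For onset (or end) times scored per allele:

    total      = variance of all 2n values, both alleles pooled
    extrinsic  = sample covariance between allele 1 and allele 2 across cells
    intrinsic  = total - extrinsic

Allele labels carry no meaning (they are randomly assigned), so the
decomposition is invariant to swapping labels within any subset of cells;
the covariance is symmetrized accordingly.  Sample (n-1) normalization is
used throughout.

Cells where only one allele ever activates are excluded from the variance
decomposition but still counted in the ever-both-active denominator of the
synchrony metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .traces import TraceAnnotation

__all__ = [
    "VariabilityDecomposition",
    "InsufficientPairsError",
    "pairs_from_annotations",
    "decompose_variability",
    "synchrony_metrics",
]

MIN_COMPLETE_PAIRS = 3


class InsufficientPairsError(ValueError):
    """Fewer than 3 cells with both alleles scored."""


@dataclass(frozen=True)
class VariabilityDecomposition:
    """Intrinsic/extrinsic split of onset (or end) time variance, in s^2."""

    total_variance: float
    extrinsic_variance: float
    intrinsic_variance: float
    intrinsic_fraction: float
    n_pairs: int
    which: str = "onset"


def pairs_from_annotations(
    annotations: Sequence[TraceAnnotation],
) -> pd.DataFrame:
    """Paired-onset table (cell_id, allele, onset, end) from burst calls.

    Onset and end are the first burst's start and last burst's end; alleles
    that never burst get NaN.  Complements the import path for externally
    (manually) scored onset tables, which use the same long format.
    """
    rows = []
    for ann in annotations:
        rows.append(
            {
                "cell_id": ann.cell_id,
                "allele": ann.allele_id,
                "onset": np.nan if ann.onset_time is None else ann.onset_time,
                "end": np.nan if ann.end_time is None else ann.end_time,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "allele", "onset", "end"])


def _complete_pairs(
    pairs: pd.DataFrame, which: Literal["onset", "end"]
) -> tuple[np.ndarray, np.ndarray]:
    """(allele-1 values, allele-2 values) for cells where both are scored."""
    if which not in ("onset", "end"):
        raise ValueError("which must be 'onset' or 'end'")
    a, b = [], []
    for _, group in pairs.groupby("cell_id", sort=True):
        values = group[which].to_numpy(dtype=float)
        if len(values) >= 2 and np.isfinite(values[:2]).all():
            a.append(values[0])
            b.append(values[1])
    return np.asarray(a), np.asarray(b)


def decompose_variability(
    pairs: pd.DataFrame,
    which: Literal["onset", "end"] = "onset",
) -> VariabilityDecomposition:
    """Intrinsic/extrinsic decomposition of onset or end times.

    ``pairs`` is a long table with columns cell_id, allele, onset, end
    (two rows per cell).  Total variance pools the 2n values of the complete
    pairs; extrinsic is the (label-symmetrized) inter-allele covariance;
    intrinsic is their difference, with the reported fraction clamped to
    [0, 1].
    """
    a, b = _complete_pairs(pairs, which)
    n = len(a)
    if n < MIN_COMPLETE_PAIRS:
        raise InsufficientPairsError(
            f"{n} complete pairs < required {MIN_COMPLETE_PAIRS}"
        )
    # Pooled moments about the common mean with a consistent (n-1)
    # normalization for variance and covariance.  This makes the identity
    # intrinsic = total - extrinsic = <(a-b)^2>/2 exact: intrinsic is the
    # half mean squared allele difference, non-negative by construction,
    # and every component is invariant to swapping the (arbitrary) allele
    # labels within any subset of cells.
    mu = np.concatenate([a, b]).mean()
    total = float(np.sum((a - mu) ** 2 + (b - mu) ** 2) / (2 * (n - 1)))
    extrinsic = float(np.sum((a - mu) * (b - mu)) / (n - 1))
    intrinsic = total - extrinsic
    fraction = float(np.clip(intrinsic / total, 0.0, 1.0)) if total > 0 else 0.0
    return VariabilityDecomposition(
        total_variance=total,
        extrinsic_variance=extrinsic,
        intrinsic_variance=intrinsic,
        intrinsic_fraction=fraction,
        n_pairs=n,
        which=which,
    )


def synchrony_metrics(
    pairs: pd.DataFrame,
    window: float = 300.0,
) -> dict[str, float]:
    """Allele-synchrony summary of a paired-onset table.

    Returns

    * ``fraction_onset_within_window`` — among cells where both alleles
      activate, the fraction whose onsets differ by at most ``window``
      seconds (default 5 min);
    * ``fraction_both_ever_active`` — fraction of *all* cells in the table
      whose two alleles are both scored;
    * ``fraction_simultaneous`` — fraction of all cells whose alleles'
      [onset, end] intervals overlap, i.e. the two loci were ever
      transcribing at the same time;
    * ``n_cells`` and ``n_both_active``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_cells = pairs["cell_id"].nunique()
    on1, on2 = _complete_pairs(pairs, "onset")
    n_both = len(on1)
    within = float(np.mean(np.abs(on1 - on2) <= window)) if n_both else np.nan

    e1, e2 = _complete_pairs(pairs, "end")
    if len(e1) == n_both and n_both:
        simultaneous = np.maximum(on1, on2) < np.minimum(e1, e2)
        frac_simultaneous = float(simultaneous.sum()) / n_cells
    else:
        frac_simultaneous = np.nan
    return {
        "fraction_onset_within_window": within,
        "fraction_both_ever_active": n_both / n_cells if n_cells else np.nan,
        "fraction_simultaneous": frac_simultaneous,
        "n_cells": float(n_cells),
        "n_both_active": float(n_both),
    }
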