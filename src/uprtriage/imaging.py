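"""Nuclear-translocation quantification from per-cell intensity tables.

Works downstream of image segmentation: the input is one row per cell with
nuclear and ER reporter intensities.  The activation threshold is adaptive,
chosen per plate from the stressed-vs-vehicle ratio histograms: the lowest
histogram bin whose left edge lies strictly above 1 and in which the
stressed-cell count strictly exceeds the vehicle count.  Bins are aligned
to integer multiples of the bin width (left-edge convention); binning is
not part of the published procedure and is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NoSeparationError",
    "ActivationThreshold",
    "cell_ratio",
    "add_ratios",
    "activation_threshold",
    "percent_activated",
    "percent_activated_by_well",
    "imaging_hit_call",
]


class NoSeparationError(ValueError):
    """Raised when stressed cells never outnumber vehicle cells above ratio 1."""


@dataclass
class ActivationThreshold:
    """Adaptive per-plate activation threshold with its binning provenance."""

    threshold: float
    bin_width: float
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.threshold <= 1.0:
            raise ValueError("activation threshold must exceed 1")


def cell_ratio(nuc_intensity, er_intensity):
    """Per-cell nuclear:ER intensity ratio."""
    nuc = np.asarray(nuc_intensity, dtype=float)
    er = np.asarray(er_intensity, dtype=float)
    if np.any(er <= 0):
        raise ValueError("ER intensity must be positive")
    if np.any(nuc < 0):
        raise ValueError("nuclear intensity must be non-negative")
    out = nuc / er
    return out if out.ndim else float(out)


def add_ratios(cells: pd.DataFrame) -> pd.DataFrame:
    """Return the per-cell table with a derived ``ratio`` column."""
    out = cells.copy()
    out["ratio"] = cell_ratio(
        out["nuc_intensity"].to_numpy(float), out["er_intensity"].to_numpy(float)
    )
    return out


def activation_threshold(
    stressed_ratios, vehicle_ratios, bin_width: float = 0.05
) -> ActivationThreshold:
    """Adaptive threshold from stressed and vehicle ratio histograms.

    Both samples are histogrammed on identical bins (width ``bin_width``,
    edges at integer multiples of it, spanning the union of both samples).
    The threshold is the left edge of the lowest bin with left edge > 1
    where the stressed count strictly exceeds the vehicle count.

    Raises :class:`NoSeparationError` if no such bin exists — the assay
    shows no stress-dependent shift.
    """
    stressed = np.asarray(stressed_ratios, dtype=float)
    vehicle = np.asarray(vehicle_ratios, dtype=float)
    if stressed.size == 0 or vehicle.size == 0:
        raise ValueError("both samples must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    # bin by integer multiples of bin_width so a value lying exactly on an
    # edge lands in the bin whose left edge it is (nudge absorbs float error)
    def bin_index(x: np.ndarray) -> np.ndarray:
        return np.floor(x / bin_width + 1e-9).astype(int)

    ks, kv = bin_index(stressed), bin_index(vehicle)
    k_lo = int(min(ks.min(), kv.min()))
    k_hi = int(max(ks.max(), kv.max()))
    n_bins = k_hi - k_lo + 1
    counts_s = np.bincount(ks - k_lo, minlength=n_bins)
    counts_v = np.bincount(kv - k_lo, minlength=n_bins)
    edges = np.arange(k_lo, k_hi + 2) * bin_width

    left = edges[:-1]
    # strict "> 1": an edge at exactly 1.0 is excluded despite float rounding
    candidates = np.flatnonzero((left > 1.0 + 1e-9 * bin_width) & (counts_s > counts_v))
    if candidates.size == 0:
        raise NoSeparationError(
            "stressed cells never outnumber vehicle cells above ratio 1"
        )
    return ActivationThreshold(float(left[candidates[0]]), bin_width, edges)


def percent_activated(well_ratios, threshold: float) -> float:
    """Percent of cells with ratio strictly above the threshold."""
    ratios = np.asarray(well_ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("well has no cells")
    return 100.0 * float(np.count_nonzero(ratios > threshold)) / ratios.size


def percent_activated_by_well(cells: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Per-well percent activation for a per-cell table (with ratio column)."""
    if "ratio" not in cells.columns:
        cells = add_ratios(cells)
    rows = [
        dict(
            well_id=well_id,
            treatment=group["treatment"].iloc[0] if "treatment" in group else "",
            n_cells=len(group),
            pct_activated=percent_activated(group["ratio"].to_numpy(float), threshold),
        )
        for well_id, group in cells.groupby("well_id", sort=True)
    ]
    return pd.DataFrame(rows)


def imaging_hit_call(
    well_table: pd.DataFrame,
    *,
    vehicle_label: str = "vehicle",
    sd_mult: float = 3.0,
    min_wells: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Call imaging hits against a vehicle-derived cutoff.

    ``cutoff = mean(vehicle well percents) + sd_mult * sample SD``; a
    treatment is a hit when its mean percent activation over its wells
    strictly exceeds the cutoff.  One-sided above, since translocation is
    the direction of interest.  Treatments with fewer than ``min_wells``
    wells are reported but flagged.

    Returns (per-treatment table, cutoff).
    """
    vehicle = well_table.loc[
        well_table["treatment"] == vehicle_label, "pct_activated"
    ].to_numpy(float)
    if vehicle.size < 2:
        raise ValueError("need >= 2 vehicle wells to derive a cutoff")
    cutoff = float(vehicle.mean() + sd_mult * vehicle.std(ddof=1))

    rows = []
    for treatment, group in well_table.groupby("treatment", sort=True):
        if treatment == vehicle_label:
            continue
        mean_pct = float(group["pct_activated"].mean())
        rows.append(
            dict(
                treatment=treatment,
                n_wells=len(group),
                mean_pct_activated=mean_pct,
                hit=mean_pct > cutoff,
                enough_wells=len(group) >= min_wells,
            )
        )
    return pd.DataFrame(rows), cutoff
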