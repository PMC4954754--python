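"""Plate normalization and quality control.

Raw per-well luminescence is normalized to percent activation against the
in-plate control medians; plate quality is summarized by the
Zhang-Chung-Oldenburg screening-window coefficient (Z') and the
signal/background ratio.  Normalization uses control *medians* (that is the
published percent-of-control formula); Z' uses control means and sample
standard deviations, standard screening practice.  Percent activation is
deliberately not clamped: negative values (inhibitors, toxic wells) carry
information and are preserved.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DegeneratePlateError",
    "MissingControlsError",
    "PlateQCReport",
    "percent_activation",
    "z_prime",
    "signal_background",
    "normalize_plate_set",
]


class DegeneratePlateError(ValueError):
    """Raised when a plate's control statistics are unusable."""


class MissingControlsError(ValueError):
    """Raised when a plate lacks one of the two control classes."""


@dataclass
class PlateQCReport:
    """Per-plate control summary and quality statistics."""

    plate_id: str
    z_prime: float
    signal_background: float
    high_median: float
    low_median: float
    high_mean: float
    low_mean: float
    high_sd: float
    low_sd: float
    n_high: int
    n_low: int
    passed: bool

    def to_dict(self) -> dict:
        return asdict(self)


def percent_activation(test_signal, low_median: float, high_median: float):
    """Percent-of-control activation.

    ``100 * (test - median(low)) / (median(high) - median(low))``; the value
    may fall below 0 or above 100 and is returned unclamped.
    """
    if high_median == low_median:
        raise DegeneratePlateError("high and low control medians coincide")
    test_signal = np.asarray(test_signal, dtype=float)
    out = 100.0 * (test_signal - low_median) / (high_median - low_median)
    return out if out.ndim else float(out)


def z_prime(pos_mean: float, pos_sd: float, neg_mean: float, neg_sd: float) -> float:
    """Screening-window coefficient Z' = 1 - 3(sd+ + sd-)/|mean+ - mean-|."""
    if pos_mean == neg_mean:
        raise DegeneratePlateError("control means coincide; Z' undefined")
    if pos_sd < 0 or neg_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    return 1.0 - 3.0 * (pos_sd + neg_sd) / abs(pos_mean - neg_mean)


def signal_background(pos_mean: float, neg_mean: float) -> float:
    """Signal/background ratio of control means."""
    if neg_mean <= 0:
        raise DegeneratePlateError("background mean must be positive")
    return pos_mean / neg_mean


def _plate_qc(plate_id: str, group: pd.DataFrame, zprime_floor: float) -> PlateQCReport:
    high = group.loc[group["role"] == "high_control", "raw_signal"].to_numpy(float)
    low = group.loc[group["role"] == "low_control", "raw_signal"].to_numpy(float)
    if len(high) < 2 or len(low) < 2:
        raise MissingControlsError(
            f"plate {plate_id}: need >= 2 wells of each control class "
            f"(got {len(high)} high, {len(low)} low)"
        )
    report = PlateQCReport(
        plate_id=plate_id,
        z_prime=z_prime(high.mean(), high.std(ddof=1), low.mean(), low.std(ddof=1)),
        signal_background=signal_background(high.mean(), low.mean()),
        high_median=float(np.median(high)),
        low_median=float(np.median(low)),
        high_mean=float(high.mean()),
        low_mean=float(low.mean()),
        high_sd=float(high.std(ddof=1)),
        low_sd=float(low.std(ddof=1)),
        n_high=len(high),
        n_low=len(low),
        passed=False,
    )
    report.passed = report.z_prime >= zprime_floor
    return report


def normalize_plate_set(
    plates: pd.DataFrame, *, zprime_floor: float = 0.4
) -> tuple[pd.DataFrame, list[PlateQCReport], dict[str, str]]:
    """Normalize every well of every plate against its own plate's controls.

    Parameters
    ----------
    plates
        Long table with at least columns plate_id, well_id, role,
        compound_id, raw_signal (the synthetic-data dialect).
    zprime_floor
        Plates with Z' below this are flagged (``plate_pass = False``) but
        their compounds are kept — flag-and-keep policy.

    Returns
    -------
    activations, reports, failures
        ``activations``: the input rows plus pct_activation and plate_pass
        columns (controls included; filter ``role == 'compound'`` for the
        compound table).  ``reports``: one :class:`PlateQCReport` per
        successfully processed plate.  ``failures``: plate_id -> error
        message for plates that could not be processed; their wells are
        excluded from ``activations``.
    """
    required = {"plate_id", "role", "raw_signal"}
    if not required <= set(plates.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    if (plates["raw_signal"] < 0).any():
        raise ValueError("raw_signal must be non-negative")

    chunks: list[pd.DataFrame] = []
    reports: list[PlateQCReport] = []
    failures: dict[str, str] = {}
    for plate_id, group in plates.groupby("plate_id", sort=True):
        try:
            report = _plate_qc(str(plate_id), group, zprime_floor)
        except (MissingControlsError, DegeneratePlateError) as exc:
            failures[str(plate_id)] = str(exc)
            continue
        reports.append(report)
        out = group.copy()
        out["pct_activation"] = percent_activation(
            group["raw_signal"].to_numpy(float), report.low_median, report.high_median
        )
        out["plate_pass"] = report.passed
        chunks.append(out)

    activations = (
        pd.concat(chunks, ignore_index=True) if chunks else plates.iloc[0:0].copy()
    )
    return activations, reports, failures
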