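"""Secretion kinetics: pulse-chase fractions, CHX-chase fractions, 4PL fits,
and kinetic-rate recovery.

Fractions follow the printed densitometry/ELISA conventions and are never
clamped — a fraction above 1 reflects measurement error and is flagged, not
silenced.  The dose-response model is the four-parameter logistic

    R(d) = bottom + (top - bottom) / (1 + (d / ec50)^slope)

fitted by least squares with EC50 parameterized on the log10 scale.  Rate
recovery inverts the irreversible two-compartment first-order chase model
(secretion rate ``ks``, intracellular degradation rate ``kd``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from uprtriage.synthetic import chase_closed_form

__all__ = [
    "DoseResponseFit",
    "RateEstimate",
    "FitError",
    "fraction_secreted",
    "fraction_remaining",
    "normalize_to_vehicle",
    "chx_fractions",
    "fit_4pl",
    "logistic_4pl",
    "invert_4pl",
    "estimate_rates",
    "chase_fraction_table",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


def fraction_secreted(e_t, e_0, i_0):
    """Fraction secreted at time t: E(t) / (E(0) + I(0)).  Unclamped."""
    e_t = np.asarray(e_t, dtype=float)
    denom = np.asarray(e_0, dtype=float) + np.asarray(i_0, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("E(0) + I(0) must be positive")
    out = e_t / denom
    return out if out.ndim else float(out)


def fraction_remaining(e_t, i_t, e_0, i_0):
    """Fraction remaining at time t: (E(t) + I(t)) / (E(0) + I(0))."""
    num = np.asarray(e_t, dtype=float) + np.asarray(i_t, dtype=float)
    denom = np.asarray(e_0, dtype=float) + np.asarray(i_0, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("E(0) + I(0) must be positive")
    out = num / denom
    return out if out.ndim else float(out)


def normalize_to_vehicle(metric_treated, metric_vehicle):
    """Treated / vehicle ratio of any secretion metric; 1 means no effect."""
    vehicle = np.asarray(metric_vehicle, dtype=float)
    if np.any(vehicle <= 0):
        raise ValueError("vehicle metric must be positive")
    out = np.asarray(metric_treated, dtype=float) / vehicle
    return out if out.ndim else float(out)


def chx_fractions(lysate_t, media_t, lysate_0, media_0):
    """CHX-chase fractions: (secreted, intracellular, remaining).

    All three share the t=0 total as denominator, so
    remaining = secreted + intracellular holds identically.
    """
    denom = np.asarray(media_0, dtype=float) + np.asarray(lysate_0, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("t=0 total must be positive")
    secreted = np.asarray(media_t, dtype=float) / denom
    intracellular = np.asarray(lysate_t, dtype=float) / denom
    remaining = secreted + intracellular
    if secreted.ndim:
        return secreted, intracellular, remaining
    return float(secreted), float(intracellular), float(remaining)


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

def logistic_4pl(dose, bottom: float, top: float, ec50: float, slope: float):
    """Four-parameter logistic response."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** slope)


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    slope: float
    sse: float
    extrapolated: bool  # EC50 outside the fitted dose range
    degenerate: bool = False  # flat response; EC50 unidentifiable
    dose_range: tuple[float, float] = (float("nan"), float("nan"))

    def predict(self, dose):
        return logistic_4pl(dose, self.bottom, self.top, self.ec50, self.slope)


def _4pl_model(log10_dose, bottom, top, log10_ec50, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (log10_dose - log10_ec50)))


def fit_4pl(
    doses,
    responses,
    *,
    min_doses: int = 5,
    constrain: dict[str, float] | None = None,
    flat_rtol: float = 1e-3,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 dose.

    Parameters
    ----------
    doses, responses
        Paired observations; doses must be positive.  Replicates are passed
        as repeated dose values.
    min_doses
        Minimum number of *distinct* doses required.
    constrain
        Optional fixed values for 'bottom' and/or 'top' (constrained fit).
    flat_rtol
        Response range below ``flat_rtol`` times the mean absolute response
        marks the curve degenerate (EC50 unidentifiable) without fitting.

    Initialization comes from data quantiles: bottom/top from the response
    extremes and EC50 from the dose whose response is nearest mid-range.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape:
        raise ValueError("doses and responses must align")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    distinct = np.unique(d)
    if distinct.size < min_doses:
        raise ValueError(f"need >= {min_doses} distinct doses, got {distinct.size}")

    span = float(r.max() - r.min())
    scale = max(float(np.mean(np.abs(r))), 1e-12)
    d_range = (float(distinct.min()), float(distinct.max()))
    if span <= flat_rtol * scale:
        return DoseResponseFit(
            bottom=float(r.mean()), top=float(r.mean()), ec50=float("nan"),
            slope=float("nan"), sse=float(((r - r.mean()) ** 2).sum()),
            extrapolated=False, degenerate=True, dose_range=d_range,
        )

    logd = np.log10(d)
    constrain = constrain or {}
    # responses may rise or fall with dose; initialize accordingly
    rising = np.corrcoef(logd, r)[0, 1] >= 0
    r_lo, r_hi = float(r.min()), float(r.max())
    bottom0 = constrain.get("bottom", r_lo if rising else r_hi)
    top0 = constrain.get("top", r_hi if rising else r_lo)
    mid = (r_lo + r_hi) / 2.0
    ec50_0 = float(d[np.argmin(np.abs(r - mid))])
    slope0 = -1.0 if rising else 1.0  # sign convention of (d/ec50)^slope

    free = [k for k in ("bottom", "top") if k not in constrain]

    def unpack(theta):
        params = dict(constrain)
        i = 0
        for k in free:
            params[k] = theta[i]
            i += 1
        log10_ec50, slope = theta[i], theta[i + 1]
        return params["bottom"], params["top"], log10_ec50, slope

    def residuals(theta):
        b, t, le, s = unpack(theta)
        return _4pl_model(logd, b, t, le, s) - r

    theta0 = [
        *[{"bottom": bottom0, "top": top0}[k] for k in free],
        np.log10(ec50_0),
        slope0,
    ]
    result = optimize.least_squares(residuals, theta0, method="lm", max_nfev=10000)
    if not result.success:
        raise FitError(f"4PL fit did not converge: {result.message}")
    b, t, log10_ec50, slope = unpack(result.x)
    ec50 = float(10.0 ** log10_ec50)
    sse = float((result.fun**2).sum())
    return DoseResponseFit(
        bottom=float(b), top=float(t), ec50=ec50, slope=float(slope), sse=sse,
        extrapolated=not (d_range[0] <= ec50 <= d_range[1]), dose_range=d_range,
    )


def invert_4pl(
    fit: DoseResponseFit, response, *, standards_range: tuple[float, float] | None = None
):
    """Concentration from response via the fitted standard curve.

    Values mapping outside ``standards_range`` (or the fitted dose range by
    default) come back as NaN — flagged for re-dilution, never extrapolated.
    """
    if fit.degenerate:
        raise FitError("cannot invert a degenerate (flat) standard curve")
    lo, hi = standards_range if standards_range is not None else fit.dose_range
    r = np.asarray(response, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (fit.top - fit.bottom) / (r - fit.bottom) - 1.0
        dose = fit.ec50 * frac ** (1.0 / fit.slope)
    dose = np.where((dose >= lo) & (dose <= hi), dose, np.nan)
    return dose if dose.ndim else float(dose)


# ---------------------------------------------------------------------------
# rate recovery
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    ks: float
    kd: float
    label0: float
    sse: float
    ks_ci: tuple[float, float] = (float("nan"), float("nan"))
    kd_ci: tuple[float, float] = (float("nan"), float("nan"))
    n_bootstrap: int = 0
    _: dict = field(default_factory=dict, repr=False)


def _fit_rates(t, intra, extra) -> tuple[float, float, float, float]:
    total0 = float(intra[t == 0].mean() + extra[t == 0].mean())

    def residuals(theta):
        ks, kd, label0 = np.exp(theta[0]), np.exp(theta[1]), theta[2]
        model_i, model_e = chase_closed_form(ks, kd, t, label0)
        return np.concatenate([model_i - intra, model_e - extra])

    # crude initialization: total decay rate from the last remaining fraction
    t_max = float(t.max()) if t.max() > 0 else 1.0
    remaining = float(
        (intra[t == t.max()].mean() + extra[t == t.max()].mean()) / max(total0, 1e-12)
    )
    k0 = max(-np.log(np.clip(remaining, 1e-6, 1.0)) / t_max, 1e-3)
    secreted_frac = float(np.clip(extra[t == t.max()].mean() / max(total0, 1e-12), 1e-4, 1 - 1e-4))
    theta0 = [np.log(max(k0 * secreted_frac, 1e-6)),
              np.log(max(k0 * (1 - secreted_frac), 1e-6)),
              total0]
    result = optimize.least_squares(residuals, theta0, method="lm", max_nfev=20000)
    if not result.success:
        raise FitError(f"rate fit did not converge: {result.message}")
    ks, kd = float(np.exp(result.x[0])), float(np.exp(result.x[1]))
    return ks, kd, float(result.x[2]), float((result.fun**2).sum())


def estimate_rates(
    chase: pd.DataFrame,
    *,
    n_bootstrap: int = 0,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RateEstimate:
    """Recover (ks, kd) from a long-format chase table.

    Expects columns replicate, t_hours, compartment ('lysate'|'media'),
    signal, with t=0 present and >= 3 time points.  When ``n_bootstrap`` > 0
    and the series has >= 2 replicates, percentile confidence intervals are
    computed by resampling replicates.
    """
    wide = chase.pivot_table(
        index=["replicate", "t_hours"], columns="compartment", values="signal"
    ).reset_index()
    if {"lysate", "media"} - set(wide.columns):
        raise ValueError("chase table needs lysate and media compartments")
    t_all = np.sort(wide["t_hours"].unique())
    if t_all.size < 3 or 0.0 not in t_all:
        raise ValueError("need >= 3 time points including 0")

    t = wide["t_hours"].to_numpy(float)
    intra = wide["lysate"].to_numpy(float)
    extra = wide["media"].to_numpy(float)
    ks, kd, label0, sse = _fit_rates(t, intra, extra)
    est = RateEstimate(ks=ks, kd=kd, label0=label0, sse=sse)

    replicates = wide["replicate"].unique()
    if n_bootstrap > 0 and replicates.size >= 2:
        rng = np.random.default_rng(seed)
        ks_bs, kd_bs = [], []
        for _ in range(n_bootstrap):
            chosen = rng.choice(replicates, size=replicates.size, replace=True)
            sub = pd.concat([wide[wide["replicate"] == r] for r in chosen])
            try:
                b_ks, b_kd, _, _ = _fit_rates(
                    sub["t_hours"].to_numpy(float),
                    sub["lysate"].to_numpy(float),
                    sub["media"].to_numpy(float),
                )
            except FitError:
                continue
            ks_bs.append(b_ks)
            kd_bs.append(b_kd)
        if ks_bs:
            q = [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100]
            est.ks_ci = tuple(np.percentile(ks_bs, q))
            est.kd_ci = tuple(np.percentile(kd_bs, q))
            est.n_bootstrap = len(ks_bs)
    return est


def chase_fraction_table(
    chase: pd.DataFrame, *, vehicle_series: str | None = None
) -> pd.DataFrame:
    """Per-series, per-time fraction secreted / remaining from a chase table.

    Signals are averaged over replicates per (series, time, compartment)
    first.  When ``vehicle_series`` names a series, fractions are also
    normalized to it (matching time points).  Fractions above 1 are flagged
    in the ``qc_exceeds_one`` column, not clamped.
    """
    mean = (
        chase.groupby(["series_id", "t_hours", "compartment"])["signal"]
        .mean()
        .unstack("compartment")
        .reset_index()
    )
    rows = []
    for series_id, g in mean.groupby("series_id"):
        g = g.sort_values("t_hours")
        at0 = g[g["t_hours"] == 0]
        if at0.empty:
            raise ValueError(f"series {series_id!r} lacks a t=0 point")
        i0, e0 = float(at0["lysate"].iloc[0]), float(at0["media"].iloc[0])
        for _, row in g.iterrows():
            fs = fraction_secreted(row["media"], e0, i0)
            fr = fraction_remaining(row["media"], row["lysate"], e0, i0)
            rows.append(
                dict(series_id=series_id, t_hours=row["t_hours"],
                     fraction_secreted=fs, fraction_remaining=fr,
                     qc_exceeds_one=bool(fs > 1 or fr > 1))
            )
    out = pd.DataFrame(rows)
    if vehicle_series is not None:
        veh = out[out["series_id"] == vehicle_series].set_index("t_hours")
        if veh.empty:
            raise ValueError(f"vehicle series {vehicle_series!r} not found")
        out["fraction_secreted_vs_vehicle"] = [
            normalize_to_vehicle(fs, veh.loc[t, "fraction_secreted"])
            if t in veh.index and veh.loc[t, "fraction_secreted"] > 0
            else float("nan")
            for fs, t in zip(out["fraction_secreted"], out["t_hours"])
        ]
    return out
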