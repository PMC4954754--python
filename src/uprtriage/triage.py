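"""Staged hit calling for the three-tier screening funnel.

Stages, in order: primary percent-activation cutoff (strict >), blacklist
removal, confirmation against a DMSO-derived 3-SD cutoff, re-application of
the primary-screen stringency, and dual-reporter selectivity.  All
inequalities are strict; boundary values fail.  Flags are monotone along
the funnel: a compound can only be confirmed if it was a primary hit and
not blacklisted, only stringent if confirmed, and selectivity is evaluated
for stringent compounds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TriageConfig",
    "call_primary_hits",
    "apply_blacklist",
    "confirmation_cutoff",
    "call_confirmed",
    "apply_stringency",
    "selectivity_call",
    "confirmation_rate",
    "run_funnel",
]

STAGES = ("screened", "primary", "post_blacklist", "confirmed", "stringent", "selective")


@dataclass
class TriageConfig:
    """Thresholds for the staged funnel.

    Defaults follow the published campaign: 25.1% primary cutoff, 3-SD
    confirmation rule, 2-fold reporter selectivity.
    """

    primary_cutoff: float = 25.1
    confirmation_sd_mult: float = 3.0
    selectivity_fold: float = 2.0
    blacklist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.primary_cutoff <= 0 or self.selectivity_fold <= 0:
            raise ValueError("cutoffs must be positive")
        if self.confirmation_sd_mult < 0:
            raise ValueError("confirmation_sd_mult must be non-negative")
        self.blacklist = frozenset(self.blacklist)


def call_primary_hits(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Flag primary hits: ``primary_hit`` iff ``primary_pct > cutoff`` (strict)."""
    out = records.copy()
    out["primary_hit"] = out["primary_pct"].to_numpy(float) > cutoff
    return out


def apply_blacklist(records: pd.DataFrame, blacklist: set[str]) -> pd.DataFrame:
    """Flag blacklisted compounds; they are excluded from downstream stages.

    Blacklist ids absent from the records are ignored with a warning.
    """
    out = records.copy()
    blacklist = set(blacklist)
    out["blacklisted"] = out["compound_id"].isin(blacklist)
    missing = blacklist - set(out["compound_id"])
    if missing:
        logger.warning("blacklist ids not present in records: %s", sorted(missing))
    return out


def confirmation_cutoff(dmso_pcts, sd_mult: float = 3.0) -> float:
    """Confirmation cutoff: DMSO mean + ``sd_mult`` sample SDs (ddof=1)."""
    dmso = np.asarray(dmso_pcts, dtype=float)
    if dmso.size < 2:
        raise ValueError("need >= 2 DMSO values to estimate a cutoff")
    return float(dmso.mean() + sd_mult * dmso.std(ddof=1))


def _confirm_mean(records: pd.DataFrame) -> np.ndarray:
    if "confirm_mean" in records.columns:
        return records["confirm_mean"].to_numpy(float)
    raise ValueError("records lack a confirm_mean column (run summarize first)")


def call_confirmed(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Confirmed iff eligible (primary hit, not blacklisted) and mean
    confirmation activation strictly exceeds ``cutoff``."""
    out = records.copy()
    eligible = out["primary_hit"].to_numpy(bool) & ~out["blacklisted"].to_numpy(bool)
    out["confirmed"] = eligible & (_confirm_mean(out) > cutoff)
    return out


def apply_stringency(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Stringent iff confirmed and mean confirmation activation > ``cutoff``."""
    out = records.copy()
    out["stringent"] = out["confirmed"].to_numpy(bool) & (_confirm_mean(out) > cutoff)
    return out


def selectivity_call(erse_pct, xbp1_pct, fold: float = 2.0):
    """Dual-reporter selectivity: ERSE activation > ``fold`` x XBP1 activation.

    Negative XBP1 percents are floored at 0 before the comparison, so a
    compound with positive ERSE activation and a negative counterscreen
    reads as selective (the fold ratio is otherwise sign-flipped).  Strict
    inequality; works elementwise on arrays.
    """
    erse = np.asarray(erse_pct, dtype=float)
    xbp1 = np.maximum(np.asarray(xbp1_pct, dtype=float), 0.0)
    out = erse > fold * xbp1
    return out if out.ndim else bool(out)


def confirmation_rate(n_confirmed: int, n_rescreened: int) -> float:
    """Confirmation rate of the secondary screen, as a percentage."""
    if n_rescreened <= 0:
        raise ValueError("n_rescreened must be positive")
    if n_confirmed < 0 or n_confirmed > n_rescreened:
        raise ValueError("n_confirmed must be in [0, n_rescreened]")
    return 100.0 * n_confirmed / n_rescreened


def summarize_replicates(
    pcts: pd.DataFrame, *, value_col: str = "pct_activation", prefix: str = "confirm"
) -> pd.DataFrame:
    """Collapse a long replicate table (compound_id, ``value_col``) to
    per-compound mean / sd / n columns named ``{prefix}_mean`` etc."""
    g = pcts.groupby("compound_id")[value_col]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out.columns = ["compound_id", f"{prefix}_mean", f"{prefix}_sd", f"{prefix}_n"]
    return out


def run_funnel(
    records: pd.DataFrame,
    config: TriageConfig,
    *,
    dmso_pcts=None,
    confirmation_cutoff_value: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full staged funnel over a per-compound record table.

    Parameters
    ----------
    records
        One row per compound with columns compound_id, primary_pct,
        confirm_mean (mean of confirmation replicates), counter_mean (mean
        of counterscreen replicates).  confirm_sd / confirm_n are carried
        through when present.
    config
        Stage thresholds and blacklist.
    dmso_pcts, confirmation_cutoff_value
        Either the DMSO percent activations from which the confirmation
        cutoff is derived (mean + sd_mult * SD), or an explicit cutoff.

    Returns
    -------
    flagged, report
        ``flagged``: records with the five stage flags.  ``report``: stage
        counts (non-increasing along the funnel), cutoffs used, and the
        confirmation rate in percent.
    """
    if confirmation_cutoff_value is None:
        if dmso_pcts is None:
            raise ValueError("provide dmso_pcts or an explicit confirmation cutoff")
        confirmation_cutoff_value = confirmation_cutoff(
            dmso_pcts, config.confirmation_sd_mult
        )

    out = call_primary_hits(records, config.primary_cutoff)
    out = apply_blacklist(out, config.blacklist)
    out = call_confirmed(out, confirmation_cutoff_value)
    out = apply_stringency(out, config.primary_cutoff)

    stringent = out["stringent"].to_numpy(bool)
    selective = np.zeros(len(out), dtype=bool)
    selective[stringent] = selectivity_call(
        out.loc[stringent, "confirm_mean"],
        out.loc[stringent, "counter_mean"],
        config.selectivity_fold,
    )
    out["selective"] = selective

    n_primary = int(out["primary_hit"].sum())
    n_post_blacklist = int((out["primary_hit"] & ~out["blacklisted"]).sum())
    counts = {
        "screened": int(len(out)),
        "primary": n_primary,
        "post_blacklist": n_post_blacklist,
        "confirmed": int(out["confirmed"].sum()),
        "stringent": int(out["stringent"].sum()),
        "selective": int(out["selective"].sum()),
    }
    report = {
        "counts": counts,
        "n_blacklisted_hits": n_primary - n_post_blacklist,
        "primary_cutoff": config.primary_cutoff,
        "confirmation_cutoff": confirmation_cutoff_value,
        "selectivity_fold": config.selectivity_fold,
        "confirmation_rate_pct": (
            confirmation_rate(counts["confirmed"], counts["post_blacklist"])
            if counts["post_blacklist"]
            else float("nan")
        ),
    }
    return out, report
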