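"""Seeded synthetic-data generators with planted ground truth.

Every generator in this module is a stand-in: the screening campaign this
package models published summary statistics, not raw measurement
distributions, so all distributional shapes here (log-normal luminescence
noise, two-component log-normal nuclear:ER ratio mixture, first-order
two-compartment chase kinetics) are explicit modelling choices, chosen so
that downstream statistics stay analytically checkable.

All randomness flows from a single integer seed through named streams
(:func:`uprtriage._rng.named_rng`), so each table type is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from uprtriage._rng import named_rng

__all__ = [
    "ScreenSimConfig",
    "ConfigError",
    "CatalogError",
    "generate_plate_set",
    "generate_screen",
    "generate_expression_profiles",
    "generate_cell_ratios",
    "generate_chase_data",
    "chase_closed_form",
    "default_geneset_catalog",
    "DEFAULT_CLASS_EFFECTS",
    "DEFAULT_EXPRESSION_EFFECTS",
]

UPR_GENESETS = ("ATF6", "XBP1s", "PERK")
OFF_PATHWAY_GENESETS = ("HSR", "Nrf2", "NFkB")

#: class -> (ERSE reporter % activation, XBP1 reporter % activation)
DEFAULT_CLASS_EFFECTS: dict[str, tuple[float, float]] = {
    "global": (80.0, 70.0),
    "atf6_preferential": (60.0, 10.0),
    "inactive": (2.0, 1.0),
}

#: class -> geneset -> induction as a fraction of the reference stressor's
#: log fold change (so 0.5 scores ~50% of reference downstream).
DEFAULT_EXPRESSION_EFFECTS: dict[str, dict[str, float]] = {
    "global": {"ATF6": 0.8, "XBP1s": 0.8, "PERK": 0.8},
    "atf6_preferential": {"ATF6": 0.5, "XBP1s": 0.05, "PERK": 0.05},
    "inactive": {"ATF6": 0.0, "XBP1s": 0.0, "PERK": 0.0},
}


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


class CatalogError(ValueError):
    """Raised for invalid geneset catalogs (e.g. a gene in two sets)."""


@dataclass
class ScreenSimConfig:
    """Configuration for the simulated reporter screen.

    Raw luminescence for a well with true fractional activation ``a`` is
    log-normal with mean ``low_mean + a * (high_mean - low_mean)`` and
    coefficient of variation ``cv``; ``cv = 0`` gives the mean exactly.
    """

    n_plates: int = 2
    wells_per_plate: int = 1536
    n_high_controls: int = 32
    n_low_controls: int = 32
    high_mean: float = 620.0
    low_mean: float = 100.0
    cv: float = 0.05
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"global": 0.02, "atf6_preferential": 0.05, "inactive": 0.93}
    )
    class_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("class_fractions must sum to 1 within 1e-9")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigError("class_fractions must be non-negative")
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")
        if self.low_mean <= 0 or self.high_mean <= 0:
            raise ConfigError("control means must be positive")
        if self.high_mean <= self.low_mean:
            raise ConfigError("high_mean must exceed low_mean")
        n_controls = self.n_high_controls + self.n_low_controls
        if self.n_high_controls < 2 or self.n_low_controls < 2:
            raise ConfigError("need >= 2 wells per control class")
        if self.wells_per_plate <= n_controls:
            raise ConfigError("wells_per_plate must exceed the number of control wells")
        unknown = set(self.class_fractions) - set(self.class_effects)
        if unknown:
            raise ConfigError(f"no class_effects entry for classes: {sorted(unknown)}")


def _lognormal_signals(rng: np.random.Generator, means: np.ndarray, cv: float) -> np.ndarray:
    """Draw log-normal values with the given means and coefficient of variation."""
    means = np.asarray(means, dtype=float)
    if cv == 0.0:
        return means.copy()
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    mu = np.log(means) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=sigma)


def _well_label(index: int, n_cols: int) -> tuple[int, int, str]:
    row, col = divmod(index, n_cols)
    return row + 1, col + 1, f"R{row + 1:02d}C{col + 1:02d}"


def _assign_classes(rng: np.random.Generator, n: int, fractions: dict[str, float]) -> np.ndarray:
    labels = sorted(fractions)
    probs = np.array([fractions[c] for c in labels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def generate_plate_set(
    config: ScreenSimConfig,
    *,
    reporter: str = "ERSE",
    stage: str = "primary",
    replicate: int = 1,
    compound_classes: pd.Series | None = None,
    stream: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one set of screening plates.

    Parameters
    ----------
    config
        Simulation parameters; see :class:`ScreenSimConfig`.
    reporter
        Which reporter channel ('ERSE' or 'XBP1') drives the planted effect.
    stage, replicate
        Labels carried into the output table (primary / confirmation /
        counterscreen funnel stages).
    compound_classes
        Optional pre-assigned ``compound_id -> class`` mapping, used to keep
        class identity consistent across funnel stages.  When omitted,
        classes are drawn from ``config.class_fractions``.
    stream
        Override for the named RNG stream (defaults to a stage/replicate
        derived name).

    Returns
    -------
    plates, truth
        ``plates`` has one row per well with columns plate_id, well_id, row,
        col, role, compound_id, raw_signal, stage, replicate, reporter.
        ``truth`` maps compound_id to its planted class and reporter effects.
    """
    channel = {"ERSE": 0, "XBP1": 1}
    if reporter not in channel:
        raise ConfigError(f"unknown reporter {reporter!r}")
    rng = named_rng(config.seed, stream or f"plates/{stage}/{reporter}/{replicate}")

    n_compound = config.wells_per_plate - config.n_high_controls - config.n_low_controls
    n_total = n_compound * config.n_plates
    compound_ids = np.array([f"CPD{i:06d}" for i in range(n_total)])

    if compound_classes is None:
        classes = _assign_classes(rng, n_total, config.class_fractions)
    else:
        classes = compound_classes.reindex(compound_ids).to_numpy()
        if pd.isna(classes).any():
            raise ConfigError("compound_classes missing entries for generated compounds")

    effects = np.array(
        [config.class_effects[c][channel[reporter]] for c in classes], dtype=float
    )
    span = config.high_mean - config.low_mean
    compound_means = config.low_mean + (effects / 100.0) * span

    n_cols = 48 if config.wells_per_plate % 48 == 0 else math.ceil(math.sqrt(config.wells_per_plate))
    rows: list[dict] = []
    for p in range(config.n_plates):
        plate_id = f"P{p + 1:03d}"
        # controls occupy the leading wells; compounds fill the rest
        idx = 0
        for _ in range(config.n_high_controls):
            r, c, well = _well_label(idx, n_cols)
            rows.append(
                dict(plate_id=plate_id, well_id=well, row=r, col=c, role="high_control",
                     compound_id="", true_mean=config.high_mean)
            )
            idx += 1
        for _ in range(config.n_low_controls):
            r, c, well = _well_label(idx, n_cols)
            rows.append(
                dict(plate_id=plate_id, well_id=well, row=r, col=c, role="low_control",
                     compound_id="", true_mean=config.low_mean)
            )
            idx += 1
        for j in range(n_compound):
            k = p * n_compound + j
            r, c, well = _well_label(idx, n_cols)
            rows.append(
                dict(plate_id=plate_id, well_id=well, row=r, col=c, role="compound",
                     compound_id=compound_ids[k], true_mean=compound_means[k])
            )
            idx += 1

    plates = pd.DataFrame(rows)
    plates["raw_signal"] = _lognormal_signals(rng, plates["true_mean"].to_numpy(), config.cv)
    plates = plates.drop(columns="true_mean")
    plates["stage"] = stage
    plates["replicate"] = replicate
    plates["reporter"] = reporter

    truth = pd.DataFrame(
        {
            "compound_id": compound_ids,
            "true_class": classes,
            "erse_pct": [config.class_effects[c][0] for c in classes],
            "xbp1_pct": [config.class_effects[c][1] for c in classes],
        }
    )
    return plates, truth


def generate_screen(
    config: ScreenSimConfig, *, n_confirmation_reps: int = 3, n_counter_reps: int = 3
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate all three funnel stages with consistent compound identities.

    Returns a dict of raw plate tables keyed by stage ('primary',
    'confirmation', 'counterscreen' — replicate plate sets concatenated) and
    the planted-truth table.
    """
    primary, truth = generate_plate_set(config, reporter="ERSE", stage="primary")
    class_map = truth.set_index("compound_id")["true_class"]

    confirm = pd.concat(
        [
            generate_plate_set(
                config, reporter="ERSE", stage="confirmation", replicate=r,
                compound_classes=class_map,
            )[0]
            for r in range(1, n_confirmation_reps + 1)
        ],
        ignore_index=True,
    )
    counter = pd.concat(
        [
            generate_plate_set(
                config, reporter="XBP1", stage="counterscreen", replicate=r,
                compound_classes=class_map,
            )[0]
            for r in range(1, n_counter_reps + 1)
        ],
        ignore_index=True,
    )
    return {"primary": primary, "confirmation": confirm, "counterscreen": counter}, truth


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------

def default_geneset_catalog(genes_per_set: int = 6) -> pd.DataFrame:
    """Synthetic geneset catalog: three UPR arms plus off-pathway controls.

    Two-column frame (gene_id, geneset); no gene belongs to two sets.
    """
    rows = []
    for name in UPR_GENESETS + OFF_PATHWAY_GENESETS:
        for i in range(genes_per_set):
            rows.append({"gene_id": f"{name}_g{i + 1}", "geneset": name})
    return pd.DataFrame(rows)


def _validate_catalog(genesets: pd.DataFrame) -> None:
    if not {"gene_id", "geneset"} <= set(genesets.columns):
        raise CatalogError("geneset catalog needs columns gene_id, geneset")
    dup = genesets["gene_id"].duplicated()
    if dup.any():
        bad = sorted(genesets.loc[dup, "gene_id"].unique())
        raise CatalogError(f"genes assigned to more than one geneset: {bad}")


def generate_expression_profiles(
    classes: pd.Series | dict[str, str],
    genesets: pd.DataFrame | None = None,
    effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    *,
    noise_sigma: float = 0.05,
    reference_name: str = "Tg",
    reference_fold_range: tuple[float, float] = (2.0, 6.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x conditions linear fold-change matrix.

    A reference condition (global stressor analogue, default 'Tg') induces
    every UPR geneset gene by a fold drawn from ``reference_fold_range``;
    off-pathway genesets stay at baseline.  A class-``c`` compound induces
    gene ``g`` of geneset ``s`` with log fold change ``effects[c][s]`` times
    the reference's log fold change, times log-normal noise of log-scale sd
    ``noise_sigma``.  ``noise_sigma = 0`` is exact.

    Returns (table, truth): ``table`` indexed by gene_id with one column per
    condition (reference first), ``truth`` mapping condition -> class.
    """
    if genesets is None:
        genesets = default_geneset_catalog()
    _validate_catalog(genesets)
    if effects is None:
        effects = DEFAULT_EXPRESSION_EFFECTS
    classes = pd.Series(dict(classes)) if not isinstance(classes, pd.Series) else classes
    rng = named_rng(seed, "expression")

    gene_ids = genesets["gene_id"].to_numpy()
    set_of = genesets.set_index("gene_id")["geneset"]
    is_upr = set_of.isin(UPR_GENESETS).to_numpy()

    lo, hi = reference_fold_range
    ref_fold = np.where(is_upr, rng.uniform(lo, hi, size=len(gene_ids)), 1.0)
    log_ref = np.log(ref_fold)

    data = {reference_name: ref_fold}
    for cond, cls in classes.items():
        if cls not in effects:
            raise ConfigError(f"no expression effects for class {cls!r}")
        eff = np.array([effects[cls].get(set_of[g], 0.0) for g in gene_ids])
        log_fc = eff * log_ref
        if noise_sigma > 0:
            log_fc = log_fc + rng.normal(0.0, noise_sigma, size=len(gene_ids))
        data[cond] = np.exp(log_fc)

    table = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {"condition": list(classes.index), "true_class": list(classes.to_numpy())}
    )
    return table, truth


# ---------------------------------------------------------------------------
# per-cell nuclear:ER ratios
# ---------------------------------------------------------------------------

@dataclass
class RatioMixtureParams:
    """Two-component log-normal mixture for per-cell nuclear:ER ratios.

    Components are parameterized by their medians; the resting mode sits
    below 1 and the activated mode above it.
    """

    resting_median: float = 0.7
    activated_median: float = 1.6
    sigma: float = 0.18

    def __post_init__(self) -> None:
        if not (0 < self.resting_median < 1 < self.activated_median):
            raise ConfigError("need resting_median < 1 < activated_median")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")


def generate_cell_ratios(
    n_wells: int,
    cells_per_well: int,
    activated_fraction: float,
    ratio_params: RatioMixtureParams | None = None,
    seed: int = 0,
    *,
    treatment: str = "compound",
    contamination: float = 0.0,
    er_mean: float = 100.0,
    well_prefix: str = "W",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell intensity rows for ``n_wells`` wells of one treatment.

    Each cell is activated with probability ``activated_fraction`` (plus
    ``contamination`` for nominally quiescent populations); its nuclear:ER
    ratio is drawn from the matching mixture component.  ER intensity is
    fixed at ``er_mean`` and the nuclear intensity set to ratio * ER, so the
    per-cell ratio is exactly the planted draw.

    Returns (cells, truth): cells has columns cell_id, well_id, treatment,
    nuc_intensity, er_intensity; truth records each well's planted fraction.
    """
    if not 0.0 <= activated_fraction <= 1.0:
        raise ConfigError("activated_fraction must be in [0, 1]")
    if not 0.0 <= contamination <= 1.0:
        raise ConfigError("contamination must be in [0, 1]")
    params = ratio_params or RatioMixtureParams()
    rng = named_rng(seed, f"cells/{treatment}")

    p_active = min(1.0, activated_fraction + contamination)
    rows = []
    truth_rows = []
    for w in range(n_wells):
        well_id = f"{well_prefix}{w + 1:03d}"
        active = rng.random(cells_per_well) < p_active
        medians = np.where(active, params.activated_median, params.resting_median)
        ratios = np.exp(rng.normal(np.log(medians), params.sigma))
        for i in range(cells_per_well):
            rows.append(
                dict(
                    cell_id=f"{well_id}_c{i + 1:04d}",
                    well_id=well_id,
                    treatment=treatment,
                    nuc_intensity=ratios[i] * er_mean,
                    er_intensity=er_mean,
                )
            )
        truth_rows.append(
            dict(well_id=well_id, treatment=treatment,
                 planted_fraction=activated_fraction, n_activated=int(active.sum()))
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# pulse-chase kinetics
# ---------------------------------------------------------------------------

def chase_closed_form(
    ks: float, kd: float, t: np.ndarray | float, label0: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form two-compartment chase model.

    Intracellular pool decays by secretion (rate ``ks``) and degradation
    (rate ``kd``), both first order; only secretion feeds the extracellular
    pool, which is stable once secreted::

        I(t) = label0 * exp(-(ks + kd) t)
        E(t) = label0 * ks/(ks+kd) * (1 - exp(-(ks + kd) t))

    with ``E(t) = 0`` when ``ks + kd = 0``.
    """
    if ks < 0 or kd < 0:
        raise ConfigError("rates must be non-negative")
    t = np.asarray(t, dtype=float)
    k = ks + kd
    intracellular = label0 * np.exp(-k * t)
    if k == 0.0:
        extracellular = np.zeros_like(t)
    else:
        extracellular = label0 * (ks / k) * (1.0 - np.exp(-k * t))
    return intracellular, extracellular


def generate_chase_data(
    ks: float,
    kd: float,
    t_points: np.ndarray | list[float],
    label0: float = 100.0,
    seed: int = 0,
    *,
    n_replicates: int = 1,
    noise_cv: float = 0.0,
    series_id: str = "series",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a pulse-chase series in long format.

    Returns (chase, truth).  ``chase`` has columns series_id, replicate,
    t_hours, compartment ('lysate'|'media'), signal; ``truth`` records the
    planted rates.  Multiplicative log-normal noise with coefficient of
    variation ``noise_cv`` is applied per measurement when non-zero.
    """
    t_points = np.asarray(t_points, dtype=float)
    if 0.0 not in t_points:
        raise ConfigError("t_points must include 0")
    rng = named_rng(seed, f"chase/{series_id}")
    intra, extra = chase_closed_form(ks, kd, t_points, label0)

    rows = []
    for rep in range(1, n_replicates + 1):
        for compartment, values in (("lysate", intra), ("media", extra)):
            noisy = _lognormal_signals(rng, np.maximum(values, 1e-300), noise_cv)
            noisy = np.where(values == 0.0, 0.0, noisy)
            for t, v in zip(t_points, noisy):
                rows.append(
                    dict(series_id=series_id, replicate=rep, t_hours=t,
                         compartment=compartment, signal=v)
                )
    truth = {"ks": ks, "kd": kd, "label0": label0}
    return pd.DataFrame(rows), truth
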