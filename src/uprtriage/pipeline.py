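"""End-to-end orchestration of the synthetic screen.

One master seed and one config drive simulate -> qc -> triage ->
expression scoring -> imaging -> kinetics; each stage draws from its own
named random stream, so identical config + seed gives a byte-identical
report and any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from uprtriage import expression, imaging, kinetics, plate_qc, synthetic, triage

__all__ = ["RunConfig", "run_pipeline", "crosswalk", "build_records"]

DEFAULT_STAGES = ("screen", "expression", "imaging", "kinetics")


@dataclass
class RunConfig:
    """Master configuration for a full synthetic run."""

    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    screen: synthetic.ScreenSimConfig | None = None
    triage: triage.TriageConfig | None = None
    classifier: expression.ClassifierConfig | None = None
    zprime_floor: float = 0.4
    expression_noise_sigma: float = 0.05
    imaging: dict[str, Any] = field(default_factory=dict)
    kinetics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        stages = tuple(raw.pop("stages", DEFAULT_STAGES))
        screen_cfg = raw.pop("screen", None)
        cfg = cls(
            seed=seed,
            stages=stages,
            screen=synthetic.ScreenSimConfig(seed=seed, **screen_cfg)
            if screen_cfg is not None
            else None,
            triage=triage.TriageConfig(**raw.pop("triage", {})),
            classifier=expression.ClassifierConfig(**raw.pop("classifier", {})),
            zprime_floor=float(raw.pop("zprime_floor", 0.4)),
            expression_noise_sigma=float(raw.pop("expression_noise_sigma", 0.05)),
            imaging=raw.pop("imaging", {}),
            kinetics=raw.pop("kinetics", {}),
        )
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cfg

    def hash(self) -> str:
        """Stable content hash of the configuration (stamped on outputs)."""
        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items() if not k.startswith("_")}
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        blob = json.dumps(vars(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_records(
    stage_activations: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble per-compound funnel records from normalized stage tables.

    ``stage_activations`` maps stage name ('primary', 'confirmation',
    'counterscreen') to a normalized well table (plate_qc output).  Returns
    (records, dmso_pcts): one row per compound with primary_pct,
    confirm_mean/sd/n and counter_mean, plus the confirmation-stage
    low-control (DMSO) percent activations for cutoff derivation.
    """
    def compounds(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["role"] == "compound"]

    primary = (
        compounds(stage_activations["primary"])
        .groupby("compound_id")["pct_activation"]
        .mean()
        .rename("primary_pct")
        .reset_index()
    )
    confirm = triage.summarize_replicates(
        compounds(stage_activations["confirmation"]), prefix="confirm"
    )
    counter = triage.summarize_replicates(
        compounds(stage_activations["counterscreen"]), prefix="counter"
    )
    records = primary.merge(confirm, on="compound_id", how="left").merge(
        counter, on="compound_id", how="left"
    )
    dmso = stage_activations["confirmation"]
    dmso_pcts = dmso.loc[dmso["role"] == "low_control", "pct_activation"].to_numpy(float)
    return records, dmso_pcts


def crosswalk(flags: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Join funnel survival with expression classification and rank.

    Rank order: compounds that are both reporter-selective and classified
    preferential_ATF6 first, then descending ATF6 geneset score, ties broken
    by compound id.  An empty key intersection yields an empty table.
    """
    calls = calls.rename(columns={"condition": "compound_id"})
    merged = flags.merge(calls, on="compound_id", how="inner")
    if merged.empty:
        return merged.assign(priority=pd.Series(dtype=bool), rank=pd.Series(dtype=int))
    merged["priority"] = merged["selective"] & (merged["call"] == "preferential_ATF6")
    merged = merged.sort_values(
        by=["priority", "atf6_score", "compound_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    merged["rank"] = np.arange(1, len(merged) + 1)
    return merged


def _screen_stage(cfg: RunConfig) -> dict[str, Any]:
    screen_cfg = cfg.screen or synthetic.ScreenSimConfig(seed=cfg.seed)
    plates, truth = synthetic.generate_screen(screen_cfg)
    activations, qc_failures = {}, {}
    qc_reports = []
    for stage, table in plates.items():
        act, reports, failures = plate_qc.normalize_plate_set(
            table, zprime_floor=cfg.zprime_floor
        )
        activations[stage] = act
        qc_reports.extend({"stage": stage, **r.to_dict()} for r in reports)
        if failures:
            qc_failures[stage] = failures
    records, dmso_pcts = build_records(activations)
    flagged, funnel_report = triage.run_funnel(
        records, cfg.triage or triage.TriageConfig(), dmso_pcts=dmso_pcts
    )
    return {
        "truth": truth,
        "flagged": flagged,
        "funnel": funnel_report,
        "qc_reports": qc_reports,
        "qc_failures": qc_failures,
        "screen_config": screen_cfg,
    }


def _expression_stage(cfg: RunConfig, screen_out: dict[str, Any]) -> dict[str, Any]:
    flagged = screen_out["flagged"]
    truth = screen_out["truth"].set_index("compound_id")["true_class"]
    stringent_ids = flagged.loc[flagged["stringent"], "compound_id"].tolist()
    if not stringent_ids:
        return {"scores": pd.DataFrame(), "calls": pd.DataFrame(),
                "note": "no stringent compounds to profile"}
    classes = truth.loc[stringent_ids]
    table, _ = synthetic.generate_expression_profiles(
        classes, seed=cfg.seed, noise_sigma=cfg.expression_noise_sigma
    )
    catalog = synthetic.default_geneset_catalog()
    scores, calls = expression.score_conditions(
        table, catalog, reference="Tg", classifier=cfg.classifier
    )
    return {"scores": scores, "calls": calls}


def _imaging_stage(cfg: RunConfig) -> dict[str, Any]:
    opts = dict(
        n_wells=3, cells_per_well=1000, stressor_fraction=0.5,
        compound_fractions={"cmpA": 0.4, "cmpB": 0.0}, contamination=0.01,
        bin_width=0.05,
    )
    opts.update(cfg.imaging)
    params = synthetic.RatioMixtureParams()
    frames, truths = [], []
    specs = [("vehicle", 0.0), ("Tg", opts["stressor_fraction"])]
    specs += [(name, f) for name, f in opts["compound_fractions"].items()]
    for idx, (label, fraction) in enumerate(specs):
        cells, truth = synthetic.generate_cell_ratios(
            opts["n_wells"], opts["cells_per_well"], fraction, params,
            seed=cfg.seed, treatment=label,
            contamination=opts["contamination"] if fraction == 0.0 else 0.0,
            well_prefix=f"W{idx}",
        )
        frames.append(cells)
        truths.append(truth)
    cells = imaging.add_ratios(pd.concat(frames, ignore_index=True))
    thr = imaging.activation_threshold(
        cells.loc[cells["treatment"] == "Tg", "ratio"],
        cells.loc[cells["treatment"] == "vehicle", "ratio"],
        bin_width=opts["bin_width"],
    )
    wells = imaging.percent_activated_by_well(cells, thr.threshold)
    hits, cutoff = imaging.imaging_hit_call(wells, vehicle_label="vehicle")
    return {
        "threshold": thr.threshold,
        "hit_cutoff": cutoff,
        "wells": wells,
        "hits": hits,
        "truth": pd.concat(truths, ignore_index=True),
    }


def _kinetics_stage(cfg: RunConfig) -> dict[str, Any]:
    opts = dict(
        series={"vehicle": (0.30, 0.05), "treated": (0.15, 0.12)},
        t_points=[0.0, 1.0, 2.0, 4.0], label0=100.0, noise_cv=0.02,
        n_replicates=3,
        dose_response=dict(bottom=20.0, top=100.0, ec50=1.0e-6, slope=1.0,
                           doses=np.geomspace(1e-8, 1e-4, 8).tolist(), noise_cv=0.02),
    )
    opts.update(cfg.kinetics)
    chase_frames, rate_rows = [], []
    for name, (ks, kd) in opts["series"].items():
        chase, truth = synthetic.generate_chase_data(
            ks, kd, opts["t_points"], opts["label0"], seed=cfg.seed,
            n_replicates=opts["n_replicates"], noise_cv=opts["noise_cv"],
            series_id=name,
        )
        chase_frames.append(chase)
        est = kinetics.estimate_rates(chase)
        rate_rows.append(
            dict(series_id=name, ks_true=truth["ks"], kd_true=truth["kd"],
                 ks_est=est.ks, kd_est=est.kd)
        )
    chase = pd.concat(chase_frames, ignore_index=True)
    fractions = kinetics.chase_fraction_table(chase, vehicle_series="vehicle")

    dr = opts["dose_response"]
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(99,)))
    doses = np.asarray(dr["doses"], dtype=float)
    clean = kinetics.logistic_4pl(doses, dr["bottom"], dr["top"], dr["ec50"], dr["slope"])
    responses = clean * np.exp(rng.normal(0.0, dr["noise_cv"], size=doses.size))
    fit = kinetics.fit_4pl(doses, responses)
    return {
        "fractions": fractions,
        "rates": pd.DataFrame(rate_rows),
        "dose_response": dict(
            ec50=fit.ec50, ec50_true=dr["ec50"], bottom=fit.bottom, top=fit.top,
            slope=fit.slope, extrapolated=fit.extrapolated,
        ),
    }


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the enabled stages in dependency order and build a report.

    A stage failure is recorded in the report and halts its dependents only;
    independent stages still run.  When ``out_dir`` is given, the report is
    written as JSON plus a Markdown summary, both stamped with the config
    hash and master seed.
    """
    report: dict[str, Any] = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages_enabled": list(config.stages),
        "failures": {},
    }
    screen_out = None
    if "screen" in config.stages:
        try:
            screen_out = _screen_stage(config)
            report["plate_qc"] = screen_out["qc_reports"]
            report["qc_failures"] = screen_out["qc_failures"]
            report["funnel"] = screen_out["funnel"]
        except Exception as exc:  # pragma: no cover - defensive
            report["failures"]["screen"] = str(exc)

    if "expression" in config.stages:
        if screen_out is None:
            report["failures"]["expression"] = "screen stage unavailable"
        else:
            try:
                expr_out = _expression_stage(config, screen_out)
                report["upr_calls"] = expr_out["calls"]
                xwalk = crosswalk(screen_out["flagged"], expr_out["calls"])
                report["crosswalk"] = xwalk
            except Exception as exc:  # pragma: no cover - defensive
                report["failures"]["expression"] = str(exc)

    if "imaging" in config.stages:
        try:
            img_out = _imaging_stage(config)
            report["imaging"] = {
                "threshold": img_out["threshold"],
                "hit_cutoff": img_out["hit_cutoff"],
                "hits": img_out["hits"],
            }
        except Exception as exc:  # pragma: no cover - defensive
            report["failures"]["imaging"] = str(exc)

    if "kinetics" in config.stages:
        try:
            kin_out = _kinetics_stage(config)
            report["kinetics"] = {
                "rates": kin_out["rates"],
                "dose_response": kin_out["dose_response"],
            }
        except Exception as exc:  # pragma: no cover - defensive
            report["failures"]["kinetics"] = str(exc)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True)
        )
        (out / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: dict[str, Any]) -> str:
    lines = [
        "# Screening run report",
        f"- config hash: `{report['config_hash']}`",
        f"- seed: {report['seed']}",
        f"- stages: {', '.join(report['stages_enabled'])}",
        "",
    ]
    if "funnel" in report:
        lines.append("## Funnel")
        for stage, n in report["funnel"]["counts"].items():
            lines.append(f"- {stage}: {n}")
        rate = report["funnel"].get("confirmation_rate_pct")
        if rate == rate:  # not NaN
            lines.append(f"- confirmation rate: {rate:.1f}%")
        lines.append("")
    if "imaging" in report:
        lines.append("## Imaging")
        lines.append(f"- activation threshold: {report['imaging']['threshold']:.3f}")
        lines.append(f"- hit cutoff: {report['imaging']['hit_cutoff']:.2f}%")
        lines.append("")
    if "kinetics" in report:
        dr = report["kinetics"]["dose_response"]
        lines.append("## Kinetics")
        lines.append(f"- fitted EC50: {dr['ec50']:.3e} (true {dr['ec50_true']:.3e})")
        lines.append("")
    if report["failures"]:
        lines.append("## Failures")
        for stage, msg in report["failures"].items():
            lines.append(f"- {stage}: {msg}")
    return "\n".join(lines) + "\n"
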