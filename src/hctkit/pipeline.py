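"""Scenario runner: seeded, re-runnable end-to-end analyses.

Each scenario reproduces one study design on synthetic blood panels:

``standard_curve``
    Duplicate RLU readings at 8 HCT levels (25–60%), OLS calibration, fit
    quality.
``interference``
    Four endogenous interferents (albumin 500, triglycerides 1000, bilirubin
    50, cholesterol 2000 mg/dL) in 11-step volumetric mixing series, judged
    against the 10% deviation rule.
``hct_effect``
    45-sample panel (9 HCT levels x 5 cTnI spikes 0.1–50 ng/mL), residual
    deviation vs HCT, 4PL fit, and recovery under no / volume-only / full
    correction.
``repeatability``
    Three cTnI levels aspirated repeatedly under sedimentation heterogeneity;
    CV with and without per-draw HCT correction.
``accuracy``
    Paired whole-blood/plasma cohort; correlation, Passing–Bablok and
    relative Bland–Altman before and after correction, using the *estimated*
    HCT from a simulated RLU reading so the full measurement chain is
    exercised.

All randomness flows from the single config seed; rerunning an identical
config reproduces identical tables and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assay import HctStandardCurve, evaluate_interference
from .correction import (
    REFERENCE_CTNI_BIAS,
    FourPLBiasModel,
    FourPLParams,
    HctCorrector,
    correct_two_stage,
    recovery,
)
from .errors import ConfigError, StageFailure
from .simulate import (
    DEFAULT_RLU_INTERCEPT,
    DEFAULT_RLU_SLOPE,
    BloodSample,
    NoiseSpec,
    PanelSpec,
    make_hct_panel,
    make_interference_series,
    make_paired_cohort,
    simulate_repeatability_draws,
    simulate_rlu,
    simulate_wb_measurement,
)
from .stats import bland_altman, correlation, passing_bablok, repeatability_cv

__all__ = ["ScenarioConfig", "ScenarioReport", "run_scenario", "write_report", "SCENARIOS"]

logger = logging.getLogger(__name__)

SCENARIOS = (
    "standard_curve",
    "interference",
    "hct_effect",
    "repeatability",
    "accuracy",
)

# Study conditions shared by scenarios.
_CAL_HCT_LEVELS = [25, 30, 35, 40, 45, 50, 55, 60]
_EFFECT_HCT_LEVELS = [0, 25, 30, 35, 40, 45, 50, 55, 60]
_CTNI_SPIKES = list(np.geomspace(0.1, 50.0, 5))
_REPEAT_LEVELS = [0.114, 0.522, 5.471]  # ng/mL cTnI tube levels
_INTERFERENT_STOCKS = {
    "human_serum_albumin": 500.0,
    "triglycerides": 1000.0,
    "bilirubin": 50.0,
    "total_cholesterol": 2000.0,
}
_MIX_RATIOS = [(10 - k, k) for k in range(11)]


@dataclass(frozen=True)
class ScenarioConfig:
    """One runnable scenario: design, noise, bias model, seed, output path."""

    scenario: str
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    panel: PanelSpec | None = None
    model: FourPLParams | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        try:
            noise = d.get("noise", {})
            panel = d.get("panel")
            model = d.get("model")
            return cls(
                scenario=d["scenario"],
                seed=int(d.get("seed", 0)),
                noise=NoiseSpec(**noise) if isinstance(noise, dict) else noise,
                panel=PanelSpec(**panel) if isinstance(panel, dict) else panel,
                model=(
                    FourPLParams.from_dict(model) if isinstance(model, dict) else model
                ),
                output_dir=d.get("output_dir"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad scenario config: {exc}") from exc

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "noise": dataclasses.asdict(self.noise),
            "panel": (
                {
                    "hct_levels": list(self.panel.hct_levels),
                    "analyte_levels": {
                        k: list(v) for k, v in self.panel.analyte_levels.items()
                    },
                    "replicates": self.panel.replicates,
                }
                if self.panel
                else None
            ),
            "model": self.model.to_dict() if self.model else None,
            "output_dir": self.output_dir,
        }


@dataclass
class ScenarioReport:
    """Tables + statistics produced by one scenario run."""

    scenario: str
    tables: dict
    stats: dict
    config: dict
    inputs_digest: str
    runtime_s: float


def _digest(tables: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(tables):
        h.update(name.encode())
        h.update(tables[name].to_csv(index=False).encode())
    return h.hexdigest()


def _rng(config: ScenarioConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


# ---------------------------------------------------------------------------
# scenario bodies


def _run_standard_curve(config: ScenarioConfig):
    noise = config.noise.with_seed(config.seed)
    rng = _rng(config, 11)
    levels = list(config.panel.hct_levels) if config.panel else _CAL_HCT_LEVELS
    reps = config.panel.replicates if config.panel else 2
    rows = []
    for hct in levels:
        sample = BloodSample(f"CAL{hct:02.0f}", float(hct), {})
        for rep in range(1, reps + 1):
            rlu = simulate_rlu(
                sample, DEFAULT_RLU_SLOPE, DEFAULT_RLU_INTERCEPT, noise, rng=rng
            )
            rows.append({"true_hct": float(hct), "replicate": rep, "rlu": rlu})
    table = pd.DataFrame(rows)
    curve = HctStandardCurve().fit(table["true_hct"], table["rlu"])
    return {"calibration": table}, {"standard_curve": curve.to_dict()}


def _run_interference(config: ScenarioConfig):
    noise = config.noise.with_seed(config.seed)
    rng = _rng(config, 12)
    base = BloodSample("IFBASE", 40.0, {})
    tables, reports = [], {}
    for name, stock in _INTERFERENT_STOCKS.items():
        series = make_interference_series(base, name, stock, _MIX_RATIOS)
        rows, mean_rlus = [], []
        for (ps, pk), sample in zip(_MIX_RATIOS, series):
            # background-free signal so the volumetric expectation applies
            reps = [
                simulate_rlu(sample, DEFAULT_RLU_SLOPE, 0.0, noise, rng=rng)
                for _ in range(2)
            ]
            mean_rlus.append(((ps, pk), float(np.mean(reps))))
            for rep, rlu in enumerate(reps, start=1):
                rows.append(
                    {
                        "interferent": name,
                        "parts_sample": ps,
                        "parts_stock": pk,
                        "interferent_conc": sample.interferents[name],
                        "replicate": rep,
                        "rlu": rlu,
                    }
                )
        reference = mean_rlus[0][1]  # the 10/0 unspiked mix
        report = evaluate_interference(
            mean_rlus[1:], reference, threshold=10.0, interferent=name
        )
        reports[name] = dataclasses.asdict(report)
        tables.append(pd.DataFrame(rows))
    return {"interference": pd.concat(tables, ignore_index=True)}, {
        "interference": reports
    }


def _run_hct_effect(config: ScenarioConfig):
    noise = config.noise.with_seed(config.seed)
    rng = _rng(config, 13)
    if config.panel is not None:
        panel_spec = config.panel
    else:
        panel_spec = PanelSpec(
            hct_levels=_EFFECT_HCT_LEVELS,
            analyte_levels={"cTnI": _CTNI_SPIKES},
        )
    gen_model = config.model or REFERENCE_CTNI_BIAS
    samples = make_hct_panel(panel_spec)
    rows = []
    for s in samples:
        for analyte, true_conc in sorted(s.analytes.items()):
            measured = simulate_wb_measurement(s, analyte, gen_model, noise, rng=rng)
            vol = measured / (1.0 - s.true_hct / 100.0)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "true_hct": s.true_hct,
                    "analyte": analyte,
                    "true_conc": true_conc,
                    "measured_conc": measured,
                    "volume_corrected": vol,
                    "residual_deviation": 100.0 * (1.0 - vol / true_conc),
                }
            )
    table = pd.DataFrame(rows)

    fitter = FourPLBiasModel().fit(
        table["true_hct"].to_numpy(), table["residual_deviation"].to_numpy()
    )
    model_used = config.model or fitter.params_

    nonzero = table[table["true_hct"] > 0]
    truth = nonzero["true_conc"].to_numpy()
    raw = nonzero["measured_conc"].to_numpy()
    pairs = nonzero[["measured_conc", "true_hct"]].to_numpy()
    vol_only = HctCorrector(mode="volume_only").fit().transform(pairs)
    full = HctCorrector(params=model_used, mode="two_stage").fit().transform(pairs)
    stats = {
        "fitted_model": fitter.params_.to_dict(),
        "fit_pearson_r": fitter.pearson_r_,
        "recovery_uncorrected": dataclasses.asdict(recovery(raw, truth)),
        "recovery_volume_only": dataclasses.asdict(recovery(vol_only, truth)),
        "recovery_full": dataclasses.asdict(recovery(full, truth)),
    }
    return {"panel": table}, stats


def _run_repeatability(config: ScenarioConfig):
    noise = config.noise.with_seed(config.seed)
    rng = _rng(config, 14)
    model = config.model or REFERENCE_CTNI_BIAS
    n_draws = config.panel.replicates if config.panel else 10
    levels = (
        list(config.panel.analyte_levels["cTnI"])
        if config.panel and "cTnI" in config.panel.analyte_levels
        else _REPEAT_LEVELS
    )
    rows, precision = [], {}
    for li, level in enumerate(levels, start=1):
        sample = BloodSample(f"REP{li}", 45.0, {"cTnI": level})
        draws = simulate_repeatability_draws(
            sample, "cTnI", n_draws, model, noise, rng=rng
        )
        uncorrected = [m for _, m in draws]
        corrected = [
            correct_two_stage(m, h, model).final_value for h, m in draws
        ]
        for d, ((h, m), c) in enumerate(zip(draws, corrected), start=1):
            rows.append(
                {
                    "level": li,
                    "true_conc": level,
                    "draw": d,
                    "apparent_hct": h,
                    "measured_conc": m,
                    "corrected_conc": c,
                }
            )
        precision[f"level_{li}"] = {
            "true_conc": level,
            "uncorrected": dataclasses.asdict(repeatability_cv(uncorrected)),
            "corrected": dataclasses.asdict(repeatability_cv(corrected)),
        }
    return {"draws": pd.DataFrame(rows)}, {"repeatability": precision}


def _run_accuracy(config: ScenarioConfig):
    noise = config.noise.with_seed(config.seed)
    rng = _rng(config, 15)
    model = config.model or REFERENCE_CTNI_BIAS

    # calibrate the HCT channel inside the scenario
    cal_h, cal_rlu = [], []
    for hct in _CAL_HCT_LEVELS:
        s = BloodSample(f"CAL{hct:02.0f}", float(hct), {})
        for _ in range(2):
            cal_h.append(float(hct))
            cal_rlu.append(
                simulate_rlu(s, DEFAULT_RLU_SLOPE, DEFAULT_RLU_INTERCEPT, noise, rng=rng)
            )
    curve = HctStandardCurve().fit(cal_h, cal_rlu)

    pairs = make_paired_cohort(
        n=86,
        conc_range=(0.1, 50.0),
        hct_range=(25.0, 55.0),
        noise=noise,
        bias_model=model,
        rng=rng,
    )
    rows = []
    for i, (plasma, wb, hct) in enumerate(pairs, start=1):
        s = BloodSample(f"ACC{i:03d}", hct, {})
        rlu = simulate_rlu(s, DEFAULT_RLU_SLOPE, DEFAULT_RLU_INTERCEPT, noise, rng=rng)
        est = curve.estimate_hct(rlu)
        corr = correct_two_stage(wb, est.value, model)
        rows.append(
            {
                "pair": i,
                "plasma": plasma,
                "whole_blood": wb,
                "true_hct": hct,
                "estimated_hct": est.value,
                "corrected": corr.final_value,
            }
        )
    table = pd.DataFrame(rows)
    plasma = table["plasma"].to_numpy()
    stats = {}
    for label, col in (("uncorrected", "whole_blood"), ("corrected", "corrected")):
        vals = table[col].to_numpy()
        r, r2 = correlation(plasma, vals)
        stats[label] = {
            "pearson_r": r,
            "r_squared": r2,
            "bland_altman_relative": dataclasses.asdict(
                bland_altman(plasma, vals, mode="relative")
            ),
            "passing_bablok": dataclasses.asdict(passing_bablok(plasma, vals)),
        }
    return {"paired": table}, stats


_BODIES = {
    "standard_curve": _run_standard_curve,
    "interference": _run_interference,
    "hct_effect": _run_hct_effect,
    "repeatability": _run_repeatability,
    "accuracy": _run_accuracy,
}


def run_scenario(config: ScenarioConfig) -> ScenarioReport:
    """Execute one scenario; deterministic under a fixed config + seed."""
    t0 = time.perf_counter()
    logger.info("scenario %s: starting (seed %d)", config.scenario, config.seed)
    try:
        tables, stats = _BODIES[config.scenario](config)
    except Exception as exc:
        raise StageFailure(config.scenario, str(exc)) from exc
    report = ScenarioReport(
        scenario=config.scenario,
        tables=tables,
        stats=stats,
        config=config.to_dict(),
        inputs_digest=_digest(tables),
        runtime_s=time.perf_counter() - t0,
    )
    logger.info(
        "scenario %s: done in %.2fs (digest %s)",
        config.scenario,
        report.runtime_s,
        report.inputs_digest[:12],
    )
    return report


def write_report(report: ScenarioReport, out_dir) -> dict:
    """Write a report's tables (CSV) and stats (JSON) plus a manifest.

    The manifest lists every emitted file with its sha256 checksum and echoes
    the config and seed, so a rerun can be verified byte for byte.
    """
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    files = []

    def _register(path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files.append({"name": str(path.relative_to(out)), "sha256": digest})

    for name, table in sorted(report.tables.items()):
        path = out / "tables" / f"{name}.csv"
        table.to_csv(path, index=False)
        _register(path)
    stats_path = out / "stats.json"
    stats_path.write_text(
        json.dumps(report.stats, indent=2, sort_keys=True), encoding="utf-8"
    )
    _register(stats_path)
    manifest = {
        "scenario": report.scenario,
        "seed": report.config.get("seed"),
        "config": report.config,
        "inputs_digest": report.inputs_digest,
        "files": files,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
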