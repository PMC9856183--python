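"""Synthetic whole-blood panel generator.

Emulates the statistical structure of reconstituted-blood experiments on a
chemiluminescence analyzer so every downstream stage (calibration, correction,
method-comparison statistics) is testable without patient data:

- panels reconstituted to fixed HCT levels and spiked analyte gradients;
- an RLU signal linear in HCT with multiplicative log-normal noise;
- whole-blood concentrations suppressed by the plasma-volume factor
  ``1 - h/100`` times the residual-bias factor ``1 - y(h)/100`` of the 4PL
  model in :mod:`hctkit.correction`;
- per-aspiration HCT jitter emulating erythrocyte sedimentation heterogeneity;
- volumetric interferent mixing series; and paired whole-blood/plasma cohorts.

All randomness flows from ``NoiseSpec.seed``; each operation draws from an
independent substream derived from that master seed, so a fixed spec + seed
reproduces byte-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .correction import FourPLParams, fourpl_eval
from .errors import DomainError, InvalidSpecificationError, ModelDomainError

__all__ = [
    "BloodSample",
    "NoiseSpec",
    "PanelSpec",
    "PairedMeasurement",
    "make_hct_panel",
    "simulate_rlu",
    "simulate_wb_measurement",
    "simulate_repeatability_draws",
    "make_interference_series",
    "make_paired_cohort",
    "panel_frame",
    "write_panel_csv",
    "DEFAULT_RLU_SLOPE",
    "DEFAULT_RLU_INTERCEPT",
]

logger = logging.getLogger(__name__)

#: Default RLU-per-HCT% sensitivity and blank signal of the simulated reader.
DEFAULT_RLU_SLOPE = 1000.0
DEFAULT_RLU_INTERCEPT = 500.0

# Substream tags: fixed per operation so substreams never collide.
_TAG_RLU = 1
_TAG_WB = 2
_TAG_REPEAT = 3
_TAG_COHORT = 4


@dataclass(frozen=True)
class BloodSample:
    """Ground truth of one specimen: HCT, plasma analyte levels, interferents."""

    sample_id: str
    true_hct: float
    analytes: Mapping[str, float]
    interferents: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.true_hct <= 100:
            raise InvalidSpecificationError(
                f"true_hct must be in [0, 100], got {self.true_hct}"
            )
        for name, conc in {**self.analytes, **self.interferents}.items():
            if conc < 0:
                raise InvalidSpecificationError(
                    f"concentration of {name!r} must be >= 0, got {conc}"
                )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes (as CVs / SDs) and the master RNG seed.

    rlu_cv and conc_cv parameterise multiplicative log-normal noise with unit
    mean; sedimentation_sd is the per-aspiration Gaussian jitter on effective
    HCT, in HCT percentage points.
    """

    rlu_cv: float = 0.02
    conc_cv: float = 0.03
    sedimentation_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rlu_cv", "conc_cv", "sedimentation_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecificationError(f"{name} must be >= 0")

    def with_seed(self, seed: int) -> "NoiseSpec":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class PanelSpec:
    """Factorial layout of a reconstituted panel: HCT levels x spike levels."""

    hct_levels: Sequence[float]
    analyte_levels: Mapping[str, Sequence[float]]
    replicates: int = 1

    def __post_init__(self) -> None:
        if not self.hct_levels:
            raise InvalidSpecificationError("hct_levels must be nonempty")
        if not self.analyte_levels or any(
            len(v) == 0 for v in self.analyte_levels.values()
        ):
            raise InvalidSpecificationError("analyte_levels must be nonempty")
        if self.replicates < 1:
            raise InvalidSpecificationError("replicates must be >= 1")


def _substream(noise: NoiseSpec, tag: int) -> np.random.Generator:
    """Independent RNG substream for one operation, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(noise.seed), tag]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def make_hct_panel(spec: PanelSpec) -> list[BloodSample]:
    """Full-factorial panel over HCT levels and analyte spike levels.

    Samples are ordered by HCT then by spike-level combination, with unique
    sequential ids. The number of samples is ``|hct_levels| * prod(|levels|)``.
    """
    names = sorted(spec.analyte_levels)
    combos = list(product(*(sorted(spec.analyte_levels[n]) for n in names)))
    samples: list[BloodSample] = []
    k = 0
    for hct in sorted(spec.hct_levels):
        for combo in combos:
            k += 1
            samples.append(
                BloodSample(
                    sample_id=f"S{k:04d}",
                    true_hct=float(hct),
                    analytes={n: float(c) for n, c in zip(names, combo)},
                )
            )
    return samples


def simulate_rlu(
    sample: BloodSample,
    slope: float,
    intercept: float,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulated integrated chemiluminescence reading for one aspiration.

    The noiseless signal is ``slope * true_hct + intercept`` (photon yield
    linear in red-cell content); multiplicative noise with CV ``rlu_cv`` is
    applied. A negative result is clamped to 0 with a logged warning.
    """
    if slope <= 0:
        raise InvalidSpecificationError("slope must be > 0")
    if rng is None:
        rng = _substream(noise, _TAG_RLU)
    value = (slope * sample.true_hct + intercept) * _lognormal_factor(
        rng, noise.rlu_cv
    )
    if value < 0:
        logger.warning(
            "negative RLU %.3f for sample %s clamped to 0", value, sample.sample_id
        )
        value = 0.0
    return float(value)


def simulate_wb_measurement(
    sample: BloodSample,
    analyte: str,
    bias_model: FourPLParams,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
    hct: float | None = None,
) -> float:
    """Measured whole-blood concentration under the HCT suppression model.

    Returns ``C_true * (1 - h/100) * (1 - y(h)/100) * eps`` where ``h`` is the
    effective HCT (``sample.true_hct`` unless overridden), ``y`` the 4PL
    residual bias, and ``eps`` unit-mean log-normal noise with CV ``conc_cv``.
    """
    if analyte not in sample.analytes:
        raise InvalidSpecificationError(
            f"analyte {analyte!r} not present in sample {sample.sample_id}"
        )
    h = sample.true_hct if hct is None else float(hct)
    if h >= 100:
        raise DomainError(f"HCT must be < 100, got {h}")
    y = fourpl_eval(bias_model, h)
    if y >= 100:
        raise ModelDomainError(f"bias model gives {y:.2f}% >= 100% at HCT {h}")
    if rng is None:
        rng = _substream(noise, _TAG_WB)
    c_true = sample.analytes[analyte]
    eps = _lognormal_factor(rng, noise.conc_cv)
    return float(c_true * (1.0 - h / 100.0) * (1.0 - y / 100.0) * eps)


def simulate_repeatability_draws(
    sample: BloodSample,
    analyte: str,
    n: int,
    bias_model: FourPLParams,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Repeated aspirations of one tube under sedimentation heterogeneity.

    Each draw perturbs the effective HCT as ``h_i = true_hct + delta_i`` with
    ``delta_i ~ N(0, sedimentation_sd)`` truncated to [0, 99], then measures
    the concentration at ``h_i``. Returns ``[(h_i, measured_i), ...]``; the
    reported ``h_i`` is what the analyzer's HCT channel would see, before any
    estimation noise.
    """
    if n < 2:
        raise InvalidSpecificationError("need n >= 2 repeatability draws")
    if rng is None:
        rng = _substream(noise, _TAG_REPEAT)
    if noise.sedimentation_sd > 0:
        h = sample.true_hct + rng.normal(0.0, noise.sedimentation_sd, size=n)
    else:
        h = np.full(n, sample.true_hct)
    h = np.clip(h, 0.0, 99.0)
    draws = [
        (
            float(hi),
            simulate_wb_measurement(
                sample, analyte, bias_model, noise, rng=rng, hct=float(hi)
            ),
        )
        for hi in h
    ]
    return draws


def make_interference_series(
    base: BloodSample,
    interferent: str,
    stock_conc: float,
    ratios: Sequence[tuple[float, float]],
) -> list[BloodSample]:
    """Volumetric mixing series of a blood sample with an interferent stock.

    Mix ``k`` combines ``parts_sample`` volumes of ``base`` with
    ``parts_stock`` volumes of interferent stock: HCT and all analyte (and
    pre-existing interferent) concentrations scale by ``parts_sample/total``
    and the spiked interferent is ``stock_conc * parts_stock/total``. The
    10/0 mix reproduces ``base`` exactly; 0/10 is pure stock (HCT 0).
    """
    if stock_conc < 0:
        raise InvalidSpecificationError("stock_conc must be >= 0")
    out: list[BloodSample] = []
    for k, (ps, pk) in enumerate(ratios):
        if ps < 0 or pk < 0:
            raise InvalidSpecificationError("ratio parts must be >= 0")
        total = ps + pk
        if total <= 0:
            raise InvalidSpecificationError("ratio parts must sum to > 0")
        f = ps / total
        interferents = {n: c * f for n, c in base.interferents.items()}
        spike = stock_conc * pk / total
        interferents[interferent] = interferents.get(interferent, 0.0) + spike
        out.append(
            BloodSample(
                sample_id=f"{base.sample_id}_mix{k:02d}",
                true_hct=base.true_hct * f,
                analytes={n: c * f for n, c in base.analytes.items()},
                interferents=interferents,
            )
        )
    return out


class PairedMeasurement(NamedTuple):
    """One patient pair: plasma reading, whole-blood reading, true HCT (%)."""

    plasma: float
    whole_blood: float
    true_hct: float


def make_paired_cohort(
    n: int,
    conc_range: tuple[float, float],
    hct_range: tuple[float, float],
    noise: NoiseSpec,
    bias_model: FourPLParams,
    analyte: str = "cTnI",
    rng: np.random.Generator | None = None,
) -> list[PairedMeasurement]:
    """Paired plasma/whole-blood cohort with known suppression.

    True concentrations are log-uniform over ``conc_range`` (clinical analyte
    levels span decades), HCT uniform over ``hct_range``. The plasma reading
    is ``C_true * eps``; the whole-blood reading goes through the full
    suppression model at the sample's HCT.
    """
    if n < 2:
        raise InvalidSpecificationError("need n >= 2 pairs")
    for lo, hi, what in (*conc_range, "conc_range"), (*hct_range, "hct_range"):
        if not lo < hi:
            raise InvalidSpecificationError(f"{what}: low must be < high")
    if conc_range[0] <= 0:
        raise InvalidSpecificationError("conc_range must be positive")
    if rng is None:
        rng = _substream(noise, _TAG_COHORT)
    conc = np.exp(
        rng.uniform(math.log(conc_range[0]), math.log(conc_range[1]), size=n)
    )
    hct = rng.uniform(hct_range[0], hct_range[1], size=n)
    pairs = []
    for i in range(n):
        sample = BloodSample(
            sample_id=f"P{i + 1:04d}",
            true_hct=float(hct[i]),
            analytes={analyte: float(conc[i])},
        )
        plasma = float(conc[i] * _lognormal_factor(rng, noise.conc_cv))
        wb = simulate_wb_measurement(sample, analyte, bias_model, noise, rng=rng)
        pairs.append(PairedMeasurement(plasma, wb, float(hct[i])))
    return pairs


# ---------------------------------------------------------------------------
# CSV layout

_PANEL_COLUMNS = [
    "sample_id",
    "true_hct",
    "analyte",
    "true_conc",
    "measured_conc",
    "rlu",
    "replicate",
    "interferent",
    "interferent_conc",
]


def panel_frame(samples: Sequence[BloodSample]) -> pd.DataFrame:
    """Long-format table of a panel: one row per sample x analyte.

    Measurement columns (measured_conc, rlu, replicate) are left NaN; callers
    append them as readings are simulated.
    """
    rows = []
    for s in samples:
        interferent = next(iter(s.interferents), "")
        for name, conc in sorted(s.analytes.items()):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "true_hct": s.true_hct,
                    "analyte": name,
                    "true_conc": conc,
                    "measured_conc": np.nan,
                    "rlu": np.nan,
                    "replicate": 1,
                    "interferent": interferent,
                    "interferent_conc": s.interferents.get(interferent, np.nan),
                }
            )
        if not s.analytes:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "true_hct": s.true_hct,
                    "analyte": "",
                    "true_conc": np.nan,
                    "measured_conc": np.nan,
                    "rlu": np.nan,
                    "replicate": 1,
                    "interferent": interferent,
                    "interferent_conc": s.interferents.get(interferent, np.nan),
                }
            )
    return pd.DataFrame(rows, columns=_PANEL_COLUMNS)


def write_panel_csv(samples: Sequence[BloodSample], path) -> None:
    """Write a panel as headered UTF-8 CSV (comma separator, '.' decimal)."""
    panel_frame(samples).to_csv(path, index=False)
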