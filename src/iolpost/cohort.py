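"""Seeded synthetic post-myopic-LASIK cohorts.

The generator emulates the biometry of eyes presenting for cataract surgery
years after myopic LASIK/PRK: long axial lengths, flat corneas, and a
measured Scheimpflug K that systematically over- or under-states the
corneal power the IOL formula actually needed.  Each synthetic eye carries:

* biometry drawn from truncated normals (truncated, not clipped, inside the
  published group ranges, so there are no boundary atoms),
* a hidden "true" effective corneal power linked to the measured K through
  a straight line plus Gaussian residual — the same regression structure a
  Group-I calibration recovers,
* an implanted power chosen by the Haigis formula from the *measured* K for
  a -0.5 D target, rounded to clinical 0.5 D labelling steps,
* a postoperative SE computed by forward vergence optics from the *true* K
  (plus optional measurement noise, off by default).

Because the postoperative refraction is produced by the same physics the
back-calculation inverts, a noise-free cohort recovers its hidden truth
exactly — the end-to-end consistency the test suite asserts.

Residual-SD defaults are derived (not hard-coded) from the published
calibration correlations: for a straight line with slope b fitted to x with
SD s_x, the population correlation satisfies r^2 = b^2 s_x^2 / (b^2 s_x^2 +
sigma^2), so sigma = |b| * s_x * sqrt(1/r^2 - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .biometry import EyeBiometry, IOLConstants, Refraction, SurgeryOutcome
from .calibration import PAPER_TCRP4, PAPER_TRP4
from .errors import InvalidGeometryError
from .haigis import (
    back_calculate_k_values,
    elp_mm,
    iol_power_for_target,
    predicted_refraction,
    round_iol_power,
)

# Example community-optimized (ULIB-style) Haigis triple for the one-piece
# acrylic monofocal implanted throughout the source cohorts.  Example
# configuration for simulation and demos — real analyses supply their own
# constants file (see biometry.load_constants).
EXAMPLE_CONSTANTS = IOLConstants(
    a0=-1.302, a1=0.210, a2=0.251, label="one-piece acrylic monofocal (ULIB-style)"
)


def residual_sd_from_correlation(slope: float, sd_x: float, r: float) -> float:
    """Gaussian residual SD consistent with a target Pearson correlation.

    Solves r^2 = slope^2 sd_x^2 / (slope^2 sd_x^2 + sigma^2) for sigma.
    """
    if not 0 < abs(r) <= 1:
        raise ValueError(f"correlation must be in (0, 1], got {r}")
    return abs(slope) * sd_x * math.sqrt(1.0 / r**2 - 1.0)


# Derived Group-I residual SDs (D): published r of 0.873 (TCRP) and 0.898
# (TRP) with the published slopes and K SDs.
RESIDUAL_SD_TCRP = residual_sd_from_correlation(PAPER_TCRP4.slope, 2.38, 0.873)
RESIDUAL_SD_TRP = residual_sd_from_correlation(PAPER_TRP4.slope, 2.49, 0.898)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults reproduce the Group-I (calibration, n=50) demographics: AL
    28.08 +/- 2.50 mm on (22.55, 31.62), ACD 3.63 +/- 0.34 mm on (2.83,
    4.3), TCRP-4mm K 39.24 +/- 2.38 D and TRP-4mm K 39.13 +/- 2.49 D on the
    published K range (34.45, 45.96).  ``k_source`` selects which map
    drives the cohort (its marginal and its true regression); the other map
    is left unmeasured, since no joint TCRP/TRP structure is published.
    """

    n: int = 50
    seed: int = 0
    k_source: str = "tcrp4"
    al_mean: float = 28.08
    al_sd: float = 2.50
    al_range: tuple[float, float] = (22.55, 31.62)
    acd_mean: float = 3.63
    acd_sd: float = 0.34
    acd_range: tuple[float, float] = (2.83, 4.3)
    k_tcrp_mean: float = 39.24
    k_tcrp_sd: float = 2.38
    k_trp_mean: float = 39.13
    k_trp_sd: float = 2.49
    k_range: tuple[float, float] = (34.45, 45.96)
    true_regression_tcrp: tuple[float, float] = (PAPER_TCRP4.slope, PAPER_TCRP4.intercept)
    true_regression_trp: tuple[float, float] = (PAPER_TRP4.slope, PAPER_TRP4.intercept)
    residual_sd_tcrp: float = RESIDUAL_SD_TCRP
    residual_sd_trp: float = RESIDUAL_SD_TRP
    measurement_noise_sd: float = 0.0   # D, added to the postop SE
    target_refraction: float = -0.5     # D
    iol_step: float = 0.5               # D labelling step; 0 disables rounding

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("al_sd", "acd_sd", "k_tcrp_sd", "k_trp_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_source not in ("tcrp4", "trp4"):
            raise ValueError("k_source must be 'tcrp4' or 'trp4'")

    @property
    def k_mean(self) -> float:
        return self.k_tcrp_mean if self.k_source == "tcrp4" else self.k_trp_mean

    @property
    def k_sd(self) -> float:
        return self.k_tcrp_sd if self.k_source == "tcrp4" else self.k_trp_sd

    @property
    def true_regression(self) -> tuple[float, float]:
        return (
            self.true_regression_tcrp
            if self.k_source == "tcrp4"
            else self.true_regression_trp
        )

    @property
    def residual_sd(self) -> float:
        return self.residual_sd_tcrp if self.k_source == "tcrp4" else self.residual_sd_trp


def group1_spec(k_source: str = "tcrp4", n: int = 50, seed: int = 0, **overrides) -> CohortSpec:
    """Calibration-group preset (defaults of :class:`CohortSpec`)."""
    return CohortSpec(n=n, seed=seed, k_source=k_source, **overrides)


def group2_spec(k_source: str = "tcrp4", n: int = 30, seed: int = 0, **overrides) -> CohortSpec:
    """Validation-group preset: AL 28.21 +/- 2.24 mm (24.03-31.25), ACD
    3.61 +/- 0.32 mm (3.17-4.49), mean K 38.83 +/- 2.94 D."""
    defaults = dict(
        al_mean=28.21,
        al_sd=2.24,
        al_range=(24.03, 31.25),
        acd_mean=3.61,
        acd_sd=0.32,
        acd_range=(3.17, 4.49),
        k_tcrp_mean=38.83,
        k_tcrp_sd=2.94,
        k_trp_mean=38.83,
        k_trp_sd=2.94,
        k_range=(34.45, 45.96),
    )
    defaults.update(overrides)
    return CohortSpec(n=n, seed=seed, k_source=k_source, **defaults)

PRESET_SPECS = {"group1": group1_spec, "group2": group2_spec}

_MAX_REDRAWS = 100


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_moments(mean, sd, lo, hi) -> tuple[float, float]:
    """Exact mean and SD of the truncated normal actually sampled."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    m, v = truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(m), float(np.sqrt(v))


def generate(
    spec: CohortSpec, constants: IOLConstants = EXAMPLE_CONSTANTS
) -> tuple[list[tuple[EyeBiometry, SurgeryOutcome]], pd.DataFrame]:
    """Generate a cohort and its hidden-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per eye with
    the measured K, the hidden true corneal power ``k_true_d``, the exact
    (unrounded) formula power and the noise-free postoperative SE.
    Deterministic for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    slope, intercept = spec.true_regression

    al = _truncated_normal(rng, spec.al_mean, spec.al_sd, *spec.al_range, spec.n)
    acd = _truncated_normal(rng, spec.acd_mean, spec.acd_sd, *spec.acd_range, spec.n)
    k_meas = _truncated_normal(rng, spec.k_mean, spec.k_sd, *spec.k_range, spec.n)
    k_true = slope * k_meas + intercept + rng.normal(0.0, spec.residual_sd, spec.n) \
        if spec.residual_sd > 0 else slope * k_meas + intercept
    noise = (
        rng.normal(0.0, spec.measurement_noise_sd, spec.n)
        if spec.measurement_noise_sd > 0
        else np.zeros(spec.n)
    )

    records: list[tuple[EyeBiometry, SurgeryOutcome]] = []
    truth_rows = []
    for i in range(spec.n):
        for attempt in range(_MAX_REDRAWS + 1):
            d = float(elp_mm(acd[i], al[i], constants))
            ok = 0.0 < d < al[i] and 25.0 <= k_true[i] <= 60.0
            if ok:
                break
            if attempt == _MAX_REDRAWS:
                raise InvalidGeometryError(
                    f"could not draw a valid eye after {_MAX_REDRAWS} retries "
                    f"(last ELP {d:.2f} mm for AL {al[i]:.2f} mm)"
                )
            al[i] = _truncated_normal(rng, spec.al_mean, spec.al_sd, *spec.al_range, 1)[0]
            acd[i] = _truncated_normal(rng, spec.acd_mean, spec.acd_sd, *spec.acd_range, 1)[0]
            k_meas[i] = _truncated_normal(rng, spec.k_mean, spec.k_sd, *spec.k_range, 1)[0]
            k_true[i] = slope * k_meas[i] + intercept + (
                rng.normal(0.0, spec.residual_sd) if spec.residual_sd > 0 else 0.0
            )

        p_exact = iol_power_for_target(
            k_meas[i], spec.target_refraction, al[i], d, constants
        )
        p_implanted = (
            round_iol_power(p_exact, spec.iol_step) if spec.iol_step > 0 else p_exact
        )
        se_clean = predicted_refraction(k_true[i], p_implanted, al[i], d, constants)
        se_postop = se_clean + noise[i]

        eye_id = f"syn{i:05d}"
        bio_kwargs = {"tcrp4": "k_tcrp_4mm", "trp4": "k_trp_4mm"}[spec.k_source]
        bio = EyeBiometry(
            axial_length=float(al[i]),
            acd=float(acd[i]),
            eye_id=eye_id,
            **{bio_kwargs: float(k_meas[i])},
        )
        outcome = SurgeryOutcome(
            implanted_power=float(p_implanted),
            target_refraction=spec.target_refraction,
            postop_refraction=Refraction(sphere=float(se_postop), cylinder=0.0),
        )
        records.append((bio, outcome))
        truth_rows.append(
            {
                "eye_id": eye_id,
                "k_measured_d": float(k_meas[i]),
                "k_true_d": float(k_true[i]),
                "elp_mm": d,
                "iol_power_exact_d": float(p_exact),
                "iol_power_implanted_d": float(p_implanted),
                "postop_se_clean_d": float(se_clean),
                "postop_se_d": float(se_postop),
            }
        )

    return records, pd.DataFrame(truth_rows)


def back_calculate_cohort(
    records: list[tuple[EyeBiometry, SurgeryOutcome]],
    constants: IOLConstants,
    k_source: str = "tcrp4",
) -> pd.DataFrame:
    """Vectorized per-eye Krd for a whole cohort (eye_id, measured K, Krd)."""
    al = np.array([b.axial_length for b, _ in records])
    acd = np.array([b.acd for b, _ in records])
    p = np.array([o.implanted_power for _, o in records])
    se = np.array([o.postop_refraction.spherical_equivalent for _, o in records])
    d = elp_mm(acd, al, constants)
    if np.any(d <= 0) or np.any(d >= al):
        raise InvalidGeometryError("ELP outside (0, AL) for at least one eye")
    krd = back_calculate_k_values(p, se, al, d, constants)
    return pd.DataFrame(
        {
            "eye_id": [b.eye_id for b, _ in records],
            "k_measured_d": [b.k_value(k_source) for b, _ in records],
            "krd_d": krd,
        }
    )
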