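"""Krd regression calibration: apply fixed corrections, or refit from a cohort.

The correction is a simple straight line mapping a measured Scheimpflug K
onto the refraction-derived K (Krd) that the Haigis formula would have
needed to reproduce the achieved refraction::

    Krd = slope * K_measured + intercept

Two published calibrations for post-myopic-LASIK eyes are shipped as frozen
presets (``PAPER_TCRP4``, ``PAPER_TRP4``); :func:`calibrate_from_cohort`
re-derives such a line from any cohort by ordinary least squares on
(measured K, back-calculated Krd) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .biometry import EyeBiometry, IOLConstants, SurgeryOutcome
from .errors import DegenerateFitError
from .haigis import back_calculate_k


@dataclass(frozen=True)
class KrdRegression:
    """A slope/intercept correction with its fit diagnostics.

    ``slope_se``/``intercept_se`` are the OLS standard errors (None for
    fixed presets, whose uncertainty was not published at full precision).
    """

    slope: float
    intercept: float           # D
    pearson_r: float
    n: int
    k_source: str              # 'tcrp4' or 'trp4'
    slope_se: float | None = None
    intercept_se: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError(f"pearson_r={self.pearson_r} outside [-1, 1]")

    def predict(self, k_measured):
        return self.slope * np.asarray(k_measured) + self.intercept

    def to_dict(self) -> dict:
        return asdict(self)


# Fixed published calibrations (Group-I regression of Krd on measured K,
# n=50 post-myopic-LASIK eyes), kept frozen: cohort calibration never
# silently overwrites these.
PAPER_TCRP4 = KrdRegression(
    slope=0.989,
    intercept=0.179,
    pearson_r=0.873,
    n=50,
    k_source="tcrp4",
    provenance="published Group-I calibration, Scheimpflug TCRP 4.0 mm zone",
)
PAPER_TRP4 = KrdRegression(
    slope=0.974,
    intercept=0.882,
    pearson_r=0.898,
    n=50,
    k_source="trp4",
    provenance="published Group-I calibration, Scheimpflug TRP 4.0 mm zone",
)

PRESETS = {"tcrp4": PAPER_TCRP4, "trp4": PAPER_TRP4}


def apply_krd(k_measured, regression: KrdRegression):
    """Corrected corneal power: slope * k + intercept (elementwise)."""
    out = regression.predict(k_measured)
    return out.item() if np.ndim(out) == 0 else out


def fit_krd_regression(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    k_source: str = "tcrp4",
    weights: Sequence[float] | None = None,
) -> KrdRegression:
    """OLS of Krd on measured K with Pearson product-moment r attached.

    ``pairs`` is a sequence of (k_measured, k_rd).  Per-point ``weights``
    give a weighted least-squares fit (unweighted by default; no outlier
    rejection).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (k_measured, k_rd)")
    x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise DegenerateFitError(f"need at least 3 points, got {len(x)}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in measured K; cannot fit a slope")

    if weights is None:
        res = stats.linregress(x, y)
        # constant y: correlation undefined, reported as 0 (no association)
        rvalue = res.rvalue if np.isfinite(res.rvalue) else 0.0
        return KrdRegression(
            slope=float(res.slope),
            intercept=float(res.intercept),
            pearson_r=float(np.clip(rvalue, -1.0, 1.0)),
            n=len(x),
            k_source=k_source,
            slope_se=float(res.stderr),
            intercept_se=float(res.intercept_stderr),
            provenance="fitted",
        )

    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative, same length as pairs")
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    # weighted Pearson r
    mx, my = np.average(x, weights=w), np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    denom = np.sqrt(
        np.average((x - mx) ** 2, weights=w) * np.average((y - my) ** 2, weights=w)
    )
    r = cov / denom if denom > 0 else 0.0
    return KrdRegression(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=float(np.clip(r, -1.0, 1.0)),
        n=len(x),
        k_source=k_source,
        provenance="fitted (weighted)",
    )


def calibrate_from_cohort(
    records: Sequence[tuple[EyeBiometry, SurgeryOutcome]],
    constants: IOLConstants,
    k_source: str = "tcrp4",
) -> KrdRegression:
    """Back-calculate Krd for every eye and regress it on the measured K.

    Equivalent to composing :func:`iolpost.haigis.back_calculate_k` per eye
    with :func:`fit_krd_regression`; order of records does not matter.
    """
    pairs = []
    for bio, outcome in records:
        k_measured = bio.k_value(k_source)
        krd = back_calculate_k(outcome, bio, constants)
        pairs.append((k_measured, krd))
    if len(pairs) < 3:
        raise DegenerateFitError(f"need at least 3 usable eyes, got {len(pairs)}")
    return fit_krd_regression(pairs, k_source=k_source)
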