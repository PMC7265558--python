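"""Haigis thin-lens vergence optics.

The Haigis model predicts the effective lens position (ELP) from anterior
chamber depth and axial length only::

    d = a0 + a1 * ACD + a2 * AL        (all in mm)

and treats the pseudophakic eye as two thin refracting elements (cornea of
power D_c at the corneal vertex, IOL of power P at distance d) in a medium
of index n, with retina at axial length L.  All vergence arithmetic is done
in metres and diopters; millimetres are converted at the boundary.

Three closed forms are exposed:

* ``predicted_refraction`` — spectacle-plane spherical equivalent produced
  by a given (D_c, P, L, d),
* ``iol_power_for_target`` — the exact algebraic inverse in P,
* ``back_calculate_k`` — the exact algebraic inverse in D_c, i.e. the
  refraction-derived corneal power (Krd): the K that, entered into the
  formula with the implanted lens, reproduces the achieved postoperative
  refraction.

The corneal-plane <-> spectacle-plane conversion convention is pinned down
by the round-trip identities (predicted_refraction o iol_power_for_target
is the identity on the target; back-calculation recovers a simulating K
exactly), which the test suite asserts to 1e-9 D.

All functions accept scalars or numpy arrays elementwise.
"""

from __future__ import annotations

import warnings

import numpy as np

from .biometry import EyeBiometry, IOLConstants, SurgeryOutcome
from .errors import InvalidGeometryError, OpticalSingularityError

MM_PER_M = 1000.0

# keratometric index used by topographers (simulated K) vs the index the
# classical Haigis formula assumes when converting radius to corneal power
N_KERATOMETRIC = 1.3375
N_HAIGIS_CORNEA = 1.3315


def elp(biometry: EyeBiometry, constants: IOLConstants) -> float:
    """Predicted effective lens position in mm: a0 + a1*ACD + a2*AL.

    Raises
    ------
    InvalidGeometryError
        If the prediction is non-positive or not strictly inside the eye.
    """
    d = elp_mm(biometry.acd, biometry.axial_length, constants)
    _check_elp(d, biometry.axial_length, constants)
    return float(d)


def elp_mm(acd_mm, axial_length_mm, constants: IOLConstants):
    """Array-friendly ELP in mm (no geometry check)."""
    return constants.a0 + constants.a1 * np.asarray(acd_mm) + constants.a2 * np.asarray(
        axial_length_mm
    )


def _check_elp(d_mm, axial_length_mm, constants: IOLConstants) -> None:
    d_mm = np.asarray(d_mm, dtype=float)
    al = np.asarray(axial_length_mm, dtype=float)
    if np.any(d_mm <= 0) or np.any(d_mm >= al):
        raise InvalidGeometryError(
            f"ELP must satisfy 0 < d < AL; got d={d_mm} mm for AL={al} mm with "
            f"constants (a0={constants.a0}, a1={constants.a1}, a2={constants.a2})"
        )


def corneal_power(k_entered: float, mode: str = "direct") -> float:
    """Corneal power to feed into the vergence formula.

    ``direct`` enters the measured K unchanged (total-power Scheimpflug maps
    are already true corneal powers).  ``reindex`` reinterprets a K quoted
    with the keratometric index 1.3375 under the 1.3315 index the classical
    Haigis formula assumes: r_mm = 337.5 / K, then D_c = 331.5 / r_mm.
    """
    k = np.asarray(k_entered, dtype=float)
    if np.any(k <= 0):
        raise ValueError(f"corneal power must be positive, got {k_entered}")
    if mode == "direct":
        out = k
    elif mode == "reindex":
        out = k * (N_HAIGIS_CORNEA - 1.0) / (N_KERATOMETRIC - 1.0)
    else:
        raise ValueError(f"unknown keratometric mode {mode!r}")
    return out.item() if np.isscalar(k_entered) else out


def _guard(denom, step: str):
    denom = np.asarray(denom, dtype=float)
    if np.any(np.abs(denom) < 1e-12) or not np.all(np.isfinite(denom)):
        raise OpticalSingularityError(f"vergence denominator vanished at step: {step}")
    return denom


def _aqueous_vergence(iol_power, axial_length_mm, elp_mm_, n: float):
    """Vergence z (D) required at the corneal plane, given IOL power and
    geometry: z = n / (d + n / (n/(L-d) - P))."""
    L = np.asarray(axial_length_mm, dtype=float) / MM_PER_M
    d = np.asarray(elp_mm_, dtype=float) / MM_PER_M
    P = np.asarray(iol_power, dtype=float)
    v1 = _guard(n / _guard(L - d, "retinal distance L-d") - P, "post-IOL vergence")
    return n / _guard(d + n / v1, "corneal-plane distance")


def predicted_refraction(
    corneal_power_d,
    iol_power,
    axial_length_mm,
    elp_mm_,
    constants: IOLConstants,
):
    """Spectacle-plane SE (D) predicted for an eye with corneal power D_c,
    IOL power P, axial length L and lens position d.  Pure closed form.
    """
    n = constants.n_aqueous
    dx = constants.vertex_distance / MM_PER_M
    z = _aqueous_vergence(iol_power, axial_length_mm, elp_mm_, n)
    r_c = z - np.asarray(corneal_power_d, dtype=float)
    r_x = r_c / _guard(1.0 + r_c * dx, "vertex conversion")
    return r_x.item() if np.ndim(r_x) == 0 else r_x


def iol_power_for_target(
    corneal_power_d,
    target_rx,
    axial_length_mm,
    elp_mm_,
    constants: IOLConstants,
):
    """IOL power (D) that yields the target spectacle refraction.

    Exact algebraic inverse of :func:`predicted_refraction` in P:
    z = D_c + Rx/(1 - Rx*dx); P = n/(L-d) - n/(n/z - d).
    """
    n = constants.n_aqueous
    dx = constants.vertex_distance / MM_PER_M
    L = np.asarray(axial_length_mm, dtype=float) / MM_PER_M
    d = np.asarray(elp_mm_, dtype=float) / MM_PER_M
    rx = np.asarray(target_rx, dtype=float)
    r_c = rx / _guard(1.0 - rx * dx, "vertex conversion")
    z = _guard(np.asarray(corneal_power_d, dtype=float) + r_c, "corneal vergence")
    p = n / _guard(L - d, "retinal distance L-d") - n / _guard(
        n / z - d, "post-corneal distance"
    )
    return p.item() if np.ndim(p) == 0 else p


def back_calculate_k_values(
    iol_power,
    postop_se,
    axial_length_mm,
    elp_mm_,
    constants: IOLConstants,
):
    """Refraction-derived corneal power (Krd, D), array form.

    Solves the vergence formula for the corneal power that makes the
    predicted refraction equal the achieved postoperative SE:
    Krd = z - Rx/(1 - Rx*dx) with z the corneal-plane vergence implied by
    the implanted power and geometry.  Exact inverse of
    :func:`predicted_refraction` in D_c.
    """
    n = constants.n_aqueous
    dx = constants.vertex_distance / MM_PER_M
    z = _aqueous_vergence(iol_power, axial_length_mm, elp_mm_, n)
    rx = np.asarray(postop_se, dtype=float)
    r_c = rx / _guard(1.0 - rx * dx, "vertex conversion")
    k = z - r_c
    return k.item() if np.ndim(k) == 0 else k


SUSPICIOUS_KRD_DELTA = 5.0  # D; |Krd - measured K| beyond this flags the record


def back_calculate_k(
    outcome: SurgeryOutcome,
    biometry: EyeBiometry,
    constants: IOLConstants,
) -> float:
    """Refraction-derived K for one eye.

    Uses the Haigis ELP (which depends on ACD and AL only, so the inversion
    is closed-form) and the achieved postoperative spherical equivalent.
    Emits a warning if Krd departs from every measured K by more than
    5 D — a plausible sign of a data-entry problem.
    """
    d = elp(biometry, constants)
    krd = back_calculate_k_values(
        outcome.implanted_power,
        outcome.postop_refraction.spherical_equivalent,
        biometry.axial_length,
        d,
        constants,
    )
    measured = [k for k in (biometry.k_tcrp_4mm, biometry.k_trp_4mm) if k is not None]
    if measured and all(abs(krd - k) > SUSPICIOUS_KRD_DELTA for k in measured):
        warnings.warn(
            f"eye {biometry.eye_id!r}: back-calculated K {krd:.2f} D differs from "
            f"every measured K by more than {SUSPICIOUS_KRD_DELTA} D — check the record",
            stacklevel=2,
        )
    return float(krd)


def round_iol_power(power, step: float = 0.5):
    """Round an exact IOL power to the labelled step (default 0.5 D).

    Ties round toward higher power (the more myopic postoperative result),
    the conservative clinical choice after myopic laser correction.
    Evaluation uses unrounded predictions unless asked otherwise.
    """
    p = np.asarray(power, dtype=float)
    out = np.floor(p / step + 0.5) * step
    return out.item() if np.ndim(out) == 0 else out


def predict_for_eye(
    biometry: EyeBiometry,
    constants: IOLConstants,
    iol_power: float,
    k_source: str = "tcrp4",
    k_mode: str = "direct",
    krd_regression=None,
) -> float:
    """Predicted spectacle SE for one eye and a given implanted power.

    ``krd_regression`` (a :class:`iolpost.calibration.KrdRegression`), if
    given, corrects the measured K before it enters the formula.
    """
    k = corneal_power(biometry.k_value(k_source), k_mode)
    if krd_regression is not None:
        k = krd_regression.slope * k + krd_regression.intercept
    d = elp(biometry, constants)
    return predicted_refraction(k, iol_power, biometry.axial_length, d, constants)
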