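"""Vergence-optics unit and property tests.

Independent oracles used here:

* a stepwise forward vergence trace (spectacle lens -> cornea -> IOL ->
  retina) root-solved for the spectacle refraction,
* a brute-force grid search over IOL power at 1e-4 D resolution,
* a bisection search over corneal power for the back-calculation.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from iolpost import (
    EyeBiometry,
    IOLConstants,
    Refraction,
    SurgeryOutcome,
    back_calculate_k,
    corneal_power,
    elp,
    iol_power_for_target,
    predicted_refraction,
    round_iol_power,
)
from iolpost.errors import InvalidGeometryError, OpticalSingularityError
from iolpost.haigis import back_calculate_k_values, elp_mm

from conftest import sample_valid_states


# ---------------------------------------------------------------- oracles
def trace_refraction(dc, p, al_mm, d_mm, constants):
    """Forward vergence propagation solved for the spectacle refraction.

    Propagates vergence step by step (thin spectacle lens at the vertex
    distance, cornea, aqueous gap to the IOL, IOL) and finds the spectacle
    power for which the image lands on the retina.
    """
    n = constants.n_aqueous
    L, d, dx = al_mm / 1000.0, d_mm / 1000.0, constants.vertex_distance / 1000.0

    def retinal_miss(rx):
        v = rx                      # vergence leaving the spectacle plane
        v = v / (1.0 - dx * v)      # translate dx of air to the cornea
        v = v + dc                  # refraction at the cornea
        v = n / (n / v - d)         # translate d inside the eye (index n)
        v = v + p                   # refraction at the IOL
        return n / v - (L - d)      # image distance vs distance to retina

    # coarse scan for a finite sign-change bracket (the trace has poles),
    # then root-polish inside it
    grid = np.arange(-80.0, 40.0, 0.125)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.array([retinal_miss(g) for g in grid])
    ok = np.isfinite(vals[:-1]) & np.isfinite(vals[1:])
    sign_change = ok & (np.sign(vals[:-1]) != np.sign(vals[1:]))
    # discard brackets straddling a pole (huge jump) — keep smooth crossings
    smooth = np.abs(vals[1:] - vals[:-1]) < 1.0
    idx = np.flatnonzero(sign_change & smooth)
    assert idx.size >= 1, "no smooth bracket found for the vergence trace"
    i = idx[0]
    return brentq(retinal_miss, grid[i], grid[i + 1], xtol=1e-12)


def grid_search_power(dc, target, al_mm, d_mm, constants, step=1e-4):
    """IOL power minimizing |predicted - target| on a 1e-4 D grid."""
    grid = np.arange(-10.0, 40.0, step)
    pred = predicted_refraction(dc, grid, al_mm, d_mm, constants)
    return grid[np.argmin(np.abs(pred - target))]


def bisect_k(observed_se, p, al_mm, d_mm, constants, lo=25.0, hi=60.0):
    """Bisection over corneal power: predicted SE is decreasing in K."""
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if predicted_refraction(mid, p, al_mm, d_mm, constants) > observed_se:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -------------------------------------------------------------------- ELP
class TestElp:
    def test_direct_arithmetic(self):
        c = IOLConstants(a0=1.0, a1=0.4, a2=0.1)
        eye = EyeBiometry(28.08, 3.63, k_tcrp_4mm=39.24)
        assert elp(eye, c) == pytest.approx(1.0 + 0.4 * 3.63 + 0.1 * 28.08, abs=1e-12)
        assert elp(eye, c) == pytest.approx(5.260, abs=1e-3)

    def test_degenerate_constants_rejected(self, mean_eye):
        with pytest.raises(InvalidGeometryError):
            elp(mean_eye, IOLConstants(a0=0.0, a1=0.0, a2=0.0))

    def test_published_triple_gives_plausible_position(self, mean_eye, constants):
        d = elp(mean_eye, constants)
        assert mean_eye.acd < d < 8.0


# --------------------------------------------------------- corneal power
class TestCornealPower:
    def test_direct_is_identity(self):
        assert corneal_power(40.0, "direct") == 40.0

    def test_reindex_rescales_by_index_ratio(self):
        assert corneal_power(40.0, "reindex") == pytest.approx(
            40.0 * 331.5 / 337.5, abs=1e-12
        )

    def test_reindex_ten_mm_radius(self):
        # K = 33.75 D corresponds to r = 10 mm exactly; 331.5/10 mm = 33.15 D
        assert corneal_power(33.75, "reindex") == pytest.approx(33.15, abs=1e-12)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            corneal_power(0.0, "direct")


# ---------------------------------------------------------- closed forms
class TestClosedForms:
    def test_emmetropic_aphakia_limit(self):
        # P = 0, vertex 0, corneal power exactly n/L: retina conjugate to
        # infinity, refraction 0.
        c = IOLConstants(a0=0.1, a1=0.5, a2=0.1, vertex_distance=0.0)
        al, d = 24.0, 4.0
        dc = c.n_aqueous / (al / 1000.0)
        assert predicted_refraction(dc, 0.0, al, d, c) == pytest.approx(0.0, abs=1e-9)

    def test_longer_eye_needs_lower_power(self, constants):
        d = 5.2
        p_short = iol_power_for_target(40.0, -0.5, 26.0, d, constants)
        p_long = iol_power_for_target(40.0, -0.5, 29.0, d, constants)
        assert p_long < p_short

    def test_power_decreases_with_more_myopic_target(self, constants):
        # asking for more myopia means a stronger IOL: dP/dtarget < 0
        targets = np.linspace(-3.0, 0.5, 50)
        powers = iol_power_for_target(40.0, targets, 27.0, 5.2, constants)
        assert np.all(np.diff(powers) < 0)

    def test_singularity_reported(self, constants):
        # IOL power equal to the vergence n/(L-d) makes the post-IOL step blow up
        al, d = 27.0, 5.2
        p_bad = constants.n_aqueous / ((al - d) / 1000.0)
        with pytest.raises(OpticalSingularityError):
            predicted_refraction(40.0, p_bad, al, d, constants)

    @given(
        dc=st.floats(33.0, 48.0),
        target=st.floats(-3.0, 1.0),
        al=st.floats(22.5, 31.5),
        acd=st.floats(2.9, 4.3),
    )
    def test_power_refraction_round_trip(self, dc, target, al, acd):
        constants = IOLConstants(a0=-1.302, a1=0.210, a2=0.251)
        d = float(elp_mm(acd, al, constants))
        p = iol_power_for_target(dc, target, al, d, constants)
        assert predicted_refraction(dc, p, al, d, constants) == pytest.approx(
            target, abs=1e-9
        )

    @given(
        dc=st.floats(33.0, 48.0),
        p=st.floats(5.0, 28.0),
        al=st.floats(22.5, 31.5),
        acd=st.floats(2.9, 4.3),
    )
    def test_back_calculation_round_trip(self, dc, p, al, acd):
        constants = IOLConstants(a0=-1.302, a1=0.210, a2=0.251)
        d = float(elp_mm(acd, al, constants))
        se = predicted_refraction(dc, p, al, d, constants)
        assert back_calculate_k_values(p, se, al, d, constants) == pytest.approx(
            dc, abs=1e-9
        )

    def test_zero_surprise_back_calculation(self, mean_eye, constants):
        # postop SE exactly as predicted with the measured K -> Krd = measured K
        d = elp(mean_eye, constants)
        p = iol_power_for_target(mean_eye.k_tcrp_4mm, -0.5, mean_eye.axial_length, d, constants)
        outcome = SurgeryOutcome(p, -0.5, Refraction(-0.5, 0.0))
        assert back_calculate_k(outcome, mean_eye, constants) == pytest.approx(
            mean_eye.k_tcrp_4mm, abs=1e-9
        )

    def test_suspicious_krd_warns(self, mean_eye, constants):
        d = elp(mean_eye, constants)
        # power for a much steeper cornea -> Krd far from the measured K
        p = iol_power_for_target(50.0, -0.5, mean_eye.axial_length, d, constants)
        outcome = SurgeryOutcome(p, -0.5, Refraction(-0.5, 0.0))
        with pytest.warns(UserWarning, match="check the record"):
            back_calculate_k(outcome, mean_eye, constants)


# --------------------------------------------------------------- oracles
class TestOracleAgreement:
    def test_predicted_refraction_matches_vergence_trace(self, constants):
        rx = predicted_refraction(38.99, 16.0, 28.08, 5.0, constants)
        assert rx == pytest.approx(
            trace_refraction(38.99, 16.0, 28.08, 5.0, constants), abs=1e-6
        )

    def test_predicted_refraction_matches_trace_randomly(self, rng, constants):
        dc, p, al, d, _ = sample_valid_states(rng, 25, constants)
        for i in range(25):
            assert predicted_refraction(dc[i], p[i], al[i], d[i], constants) == (
                pytest.approx(trace_refraction(dc[i], p[i], al[i], d[i], constants),
                              abs=1e-6)
            )

    def test_power_for_target_matches_grid_search(self, mean_eye, constants):
        d = elp(mean_eye, constants)
        p = iol_power_for_target(39.24, -0.5, mean_eye.axial_length, d, constants)
        p_grid = grid_search_power(39.24, -0.5, mean_eye.axial_length, d, constants)
        assert p == pytest.approx(p_grid, abs=1e-4)

    def test_back_calculation_matches_bisection(self, rng, constants):
        dc, p, al, d, _ = sample_valid_states(rng, 25, constants)
        se = predicted_refraction(dc, p, al, d, constants)
        for i in range(25):
            k_bisect = bisect_k(se[i], p[i], al[i], d[i], constants)
            assert back_calculate_k_values(
                p[i], se[i], al[i], d[i], constants
            ) == pytest.approx(k_bisect, abs=1e-6)


# --------------------------------------------------------------- rounding
@pytest.mark.parametrize(
    "exact, expected",
    [
        (16.20, 16.0),
        (16.30, 16.5),
        (16.25, 16.5),    # tie rounds to the higher power (more myopic result)
        (-0.25, 0.0),
        (18.75, 19.0),
    ],
)
def test_iol_power_rounding(exact, expected):
    assert round_iol_power(exact) == pytest.approx(expected)
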