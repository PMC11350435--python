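import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepdsim import (
    CouplingParams,
    KNDyParams,
    MePDParams,
    coupled_rhs,
    kndy_rhs,
    mepd_inputs,
    mepd_jacobian,
    mepd_rhs,
    phi,
    update,
)
from mepdsim.models import mepd_rates, phi_prime


# --- phi ------------------------------------------------------------------

@given(
    a=st.floats(0.1, 10.0),
    theta=st.floats(0.1, 10.0),
)
def test_phi_zero_input_is_exactly_zero(a, theta):
    assert phi(a, 0.0, theta) == 0.0


@given(
    a=st.floats(0.1, 2.0),
    theta=st.floats(0.1, 4.0),
    f1=st.floats(-8.0, 8.0),
    df=st.floats(1e-2, 4.0),
)
def test_phi_strictly_increasing(a, theta, f1, df):
    # domain kept clear of deep float saturation, where increments underflow
    assert phi(a, f1 + df, theta) > phi(a, f1, theta)


@given(a=st.floats(0.1, 5.0), theta=st.floats(0.1, 8.0), f=st.floats(-50.0, 50.0))
def test_phi_upper_bound(a, theta, f):
    # supremum 1 - 1/(1+exp(a*theta)); attained only in the F -> inf limit,
    # but float rounding can reach it at deep saturation
    assert phi(a, f, theta) <= 1.0 - 1.0 / (1.0 + math.exp(a * theta))


def test_phi_at_threshold():
    # F = theta forces the first term to 1/2
    assert phi(2.0, 3.7, 3.7) == pytest.approx(0.5 - 1.0 / (1.0 + math.exp(7.4)), abs=1e-15)


def test_phi_saturation_limit():
    assert phi(1.3, 1e6, 4.0) == pytest.approx(1.0 - 1.0 / (1.0 + math.exp(5.2)), abs=1e-12)


def test_phi_rejects_non_finite():
    with pytest.raises(ValueError):
        phi(1.0, float("nan"), 1.0)
    with pytest.raises(ValueError):
        phi(1.0, float("inf"), 1.0)


def test_phi_vectorised():
    out = phi(2.0, np.array([0.0, 3.7]), 3.7)
    assert out.shape == (2,)
    assert out[0] == 0.0


# --- mepd inputs / rhs ----------------------------------------------------

def test_inputs_zero_state_reduce_to_split_drive():
    p = update(MePDParams(), Kp=2.3)
    Fl, Fi, Fe = mepd_inputs((0.0, 0.0, 0.0), p)
    assert Fl == pytest.approx(0.9 * 2.3)
    assert Fi == pytest.approx(0.1 * 2.3)
    assert Fe == 0.0


def test_inputs_full_suppression_removes_interactions():
    p = update(MePDParams(), Kp=5.0, beta1=1.0, beta2=1.0)
    Fl, Fi, Fe = mepd_inputs((0.7, 0.4, 0.9), p)
    assert Fl == pytest.approx(0.9 * 5.0)
    assert Fi == pytest.approx(0.1 * 5.0)
    assert Fe == 0.0


def test_inputs_hand_evaluated_regression():
    # direct substitution at state (0.5, 0.2, 0.1), defaults, Kp = 2.3
    p = update(MePDParams(), Kp=2.3)
    Fl, Fi, Fe = mepd_inputs((0.5, 0.2, 0.1), p)
    assert Fl == pytest.approx(18 * 0.5 - 35 * 0.2 + 0.9 * 2.3, abs=1e-14)   # 4.07
    assert Fi == pytest.approx(16 * 0.5 + 0.1 * 2.3, abs=1e-14)              # 8.23
    assert Fe == pytest.approx(40 * 0.5 - 25 * 0.2, abs=1e-14)               # 15.0


def test_origin_is_equilibrium_without_drive():
    p = MePDParams()  # Kp = 0
    np.testing.assert_allclose(mepd_rhs(0.0, (0.0, 0.0, 0.0), p), 0.0, atol=1e-15)


def test_refractory_ceiling():
    # at Gl = 1 the first component is exactly -delta * Gl
    p = update(MePDParams(), Kp=3.0)
    d = mepd_rhs(0.0, (1.0, 0.3, 0.2), p)
    assert d[0] == pytest.approx(-p.delta, abs=1e-14)


def test_rhs_matches_independent_scalar_formula():
    """Duplicate-implementation oracle written with plain math only."""
    p = update(MePDParams(), Kp=2.3)
    Gl, Gi, Ge = 0.3, 0.3, 0.3

    def sig(a, F, th):
        return 1.0 / (1.0 + math.exp(-a * (F - th))) - 1.0 / (1.0 + math.exp(a * th))

    Fl = 18.0 * Gl - 35.0 * Gi + 0.9 * 2.3
    Fi = 16.0 * Gl + 0.1 * 2.3
    Fe = 40.0 * Gl - 25.0 * Gi
    expected = [
        3.0 * (-Gl + (1 - Gl) * sig(1.3, Fl, 4.0)),
        3.0 * (-Gi + (1 - Gi) * sig(2.0, Fi, 3.7)),
        3.0 * (-Ge + (1 - Ge) * sig(2.0, Fe, 3.7)),
    ]
    np.testing.assert_allclose(mepd_rhs(0.0, (Gl, Gi, Ge), p), expected, rtol=1e-14)


def test_dimensionless_form_is_rhs_without_delta():
    p = update(MePDParams(), Kp=1.7)
    s = (0.2, 0.4, 0.1)
    np.testing.assert_allclose(mepd_rhs(0.0, s, p), p.delta * mepd_rates(s, p), rtol=1e-15)


def test_rhs_autonomous():
    p = update(MePDParams(), Kp=2.0)
    s = (0.1, 0.2, 0.3)
    np.testing.assert_array_equal(mepd_rhs(0.0, s, p), mepd_rhs(123.4, s, p))


# --- Jacobian -------------------------------------------------------------

def _fd_jacobian(state, p, h=1e-6):
    J = np.zeros((3, 3))
    state = np.asarray(state, float)
    for j in range(3):
        sp, sm = state.copy(), state.copy()
        sp[j] += h
        sm[j] -= h
        J[:, j] = (mepd_rhs(0.0, sp, p) - mepd_rhs(0.0, sm, p)) / (2 * h)
    return J


def test_jacobian_matches_finite_differences_randomised(rng):
    for _ in range(100):
        state = rng.uniform(0.0, 1.0, size=3)
        p = update(
            MePDParams(),
            Kp=rng.uniform(0, 10),
            alpha=rng.uniform(0, 1),
            beta1=rng.uniform(0, 1),
            beta2=rng.uniform(0, 1),
        )
        J = mepd_jacobian(state, p)
        Jfd = _fd_jacobian(state, p)
        np.testing.assert_allclose(J, Jfd, rtol=1e-6, atol=1e-8)


def test_jacobian_structure_at_origin():
    # J = delta * (-(1 + phi) I + diag(phi') C) with phi(0) = 0 at Kp = 0
    p = MePDParams()
    J = mepd_jacobian((0.0, 0.0, 0.0), p)
    C = np.array([[18.0, -35.0, 0.0], [16.0, 0.0, 0.0], [40.0, -25.0, 0.0]])
    slopes = np.array(
        [phi_prime(1.3, 0.0, 4.0), phi_prime(2.0, 0.0, 3.7), phi_prime(2.0, 0.0, 3.7)]
    )
    expected = 3.0 * (-np.eye(3) + slopes[:, None] * C)
    np.testing.assert_allclose(J, expected, rtol=1e-12)


def test_jacobian_full_suppression_decouples():
    p = update(MePDParams(), beta1=1.0, beta2=1.0, Kp=4.0)
    J = mepd_jacobian((0.3, 0.5, 0.2), p)
    off = J - np.diag(np.diag(J))
    np.testing.assert_allclose(off, 0.0, atol=1e-14)


def test_origin_stable_without_drive():
    ev = np.linalg.eigvals(mepd_jacobian((0.0, 0.0, 0.0), MePDParams()))
    assert np.all(ev.real < 0)


# --- KNDy -----------------------------------------------------------------

def test_dyn_production_half_saturation():
    p = KNDyParams()
    d = kndy_rhs(0.0, (0.0, 0.0, p.K_v1), p)
    # dD/dT = k_D/2 - d_D*D with D = 0
    assert d[0] == pytest.approx(p.k_D / 2, rel=1e-12)
    assert d[0] == pytest.approx(2.0)


def test_nkb_production_quarter_point():
    p = KNDyParams()
    d = kndy_rhs(0.0, (p.K_D, 0.0, p.K_v2), p)
    # both Hill factors are 1/2: k_N/4 minus zero decay (N = 0)
    assert d[1] == pytest.approx(p.k_N / 4, rel=1e-12)
    assert d[1] == pytest.approx(10.0)


def test_basal_input_at_rest():
    p = KNDyParams()
    d = kndy_rhs(0.0, (0.0, 0.0, 0.0), p, ext=(0.0, 0.0))
    expected_fv = p.v0 / (1.0 + math.exp(p.k * (-p.I0 + p.m)))
    assert d[2] == pytest.approx(expected_fv, rel=1e-12)


def test_kndy_rejects_non_finite_ext():
    with pytest.raises(ValueError):
        kndy_rhs(0.0, (0.0, 0.0, 0.0), KNDyParams(), ext=(float("nan"), 0.0))


# --- coupled --------------------------------------------------------------

def test_coupled_zero_weights_match_uncoupled():
    mp = update(MePDParams(), Kp=2.3)
    kp = KNDyParams()
    cp = CouplingParams(0.0, 0.0)
    s = np.array([0.3, 0.2, 0.1, 0.5, 1.0, 300.0])
    full = coupled_rhs(0.0, s, mp, kp, cp)
    np.testing.assert_allclose(full[3:], kndy_rhs(0.0, s[3:], kp, ext=(0.0, 0.0)), rtol=1e-14)


def test_coupled_mepd_block_independent_of_kndy_state():
    mp = update(MePDParams(), Kp=2.3)
    kp = KNDyParams()
    cp = CouplingParams(1.0, 1.0)
    s1 = np.array([0.3, 0.2, 0.1, 0.5, 1.0, 300.0])
    s2 = np.array([0.3, 0.2, 0.1, 9.9, 7.7, 55.0])
    np.testing.assert_array_equal(
        coupled_rhs(0.0, s1, mp, kp, cp)[:3], coupled_rhs(0.0, s2, mp, kp, cp)[:3]
    )
    np.testing.assert_allclose(
        coupled_rhs(0.0, s1, mp, kp, cp)[:3], mepd_rhs(0.0, s1[:3], mp), rtol=1e-14
    )


def test_coupled_at_mepd_equilibrium_equals_shifted_basal_input():
    """With the MePD frozen at an equilibrium, coupling == an I0 shift."""
    from scipy.integrate import solve_ivp

    from mepdsim.continuation import find_equilibrium

    mp = update(MePDParams(), Kp=1.0)  # below the Hopf point: stable equilibrium
    kp = KNDyParams()
    cp = CouplingParams(1.0, 1.0)
    eq = find_equilibrium(mp, (0.1, 0.1, 0.1))
    shift = cp.j_l * eq[0] - cp.j_e * eq[2]
    kp_shifted = update(kp, I0=kp.I0 + shift)

    y0 = [0.2, 0.2, 5.0]
    t_eval = np.linspace(0.0, 120.0, 400)
    a = solve_ivp(
        lambda t, y: kndy_rhs(t, y, kp, ext=(eq[0], eq[2]), cp=cp),
        (0, 120), y0, rtol=1e-10, atol=1e-12, t_eval=t_eval, method="LSODA",
    )
    b = solve_ivp(
        lambda t, y: kndy_rhs(t, y, kp_shifted, ext=(0.0, 0.0)),
        (0, 120), y0, rtol=1e-10, atol=1e-12, t_eval=t_eval, method="LSODA",
    )
    np.testing.assert_allclose(a.y, b.y, rtol=1e-6, atol=1e-6)
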