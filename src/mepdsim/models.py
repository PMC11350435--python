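"""Right-hand sides and Jacobians of the MePD, KNDy and coupled ODE systems.

State layouts
-------------
MePD     : ``(Gl, Gi, Ge)`` — mean activities of the glutamatergic,
           GABA-interneuron and GABA-efferent populations (dimensionless,
           bounded above by 1 along trajectories).
KNDy     : ``(D, N, v)`` — dynorphin (nM), neurokinin B (nM) and mean
           firing rate (spikes/min); non-negative along trajectories.
Coupled  : ``(Gl, Gi, Ge, D, N, v)`` with strictly one-way MePD -> KNDy
           coupling through the synaptic input ``I``.

All systems are autonomous; the leading time argument exists only for
ODE-solver compatibility.  Time is measured in minutes (the MePD block
carries the ``delta`` scaling factor); the dimensionless-time form of the
MePD equations is available as :func:`mepd_rates`.
"""

from __future__ import annotations

import numpy as np

from .params import CouplingParams, KNDyParams, MePDParams

__all__ = [
    "phi",
    "phi_prime",
    "mepd_inputs",
    "mepd_rates",
    "mepd_rhs",
    "mepd_jacobian",
    "kndy_rhs",
    "coupled_rhs",
    "make_mepd_rhs",
    "make_kndy_rhs",
    "make_coupled_rhs",
]

#: Sigmoid arguments are clipped here before exponentiation; exp(500) already
#: overflows float64, and in the operating range |arg| stays below ~100.
_EXP_CLIP = 500.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(np.clip(-x, -_EXP_CLIP, _EXP_CLIP)))


def phi(a, F, theta):
    """Stimulus-response sigmoid, shifted so that ``phi(a, 0, theta) == 0``.

    ``phi = 1/(1+exp(-a(F-theta))) - 1/(1+exp(a*theta))``.  Strictly
    increasing in ``F`` and bounded above by ``1 - 1/(1+exp(a*theta))``.
    Accepts scalars or arrays (broadcast).
    """
    a = np.asarray(a, dtype=float)
    F = np.asarray(F, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(F)) and np.all(np.isfinite(theta))):
        raise ValueError("phi: non-finite input")
    out = _sigmoid(a * (F - theta)) - _sigmoid(-a * theta)
    return out if out.ndim else float(out)


def phi_prime(a, F, theta):
    """Derivative of :func:`phi` with respect to ``F``: ``a * s * (1 - s)``."""
    s = _sigmoid(np.asarray(a, float) * (np.asarray(F, float) - np.asarray(theta, float)))
    out = a * s * (1.0 - s)
    return out if np.ndim(out) else float(out)


def mepd_inputs(state, p: MePDParams):
    """Synaptic inputs ``(Fl, Fi, Fe)`` to the three MePD populations.

    Linear sums of the population activities weighted by the interaction
    strengths, with the antagonism factors ``(1 - beta1)`` on GABAergic and
    ``(1 - beta2)`` on glutamatergic terms, plus the split kisspeptin drive.
    """
    Gl, Gi, _Ge = state
    g2 = 1.0 - p.beta2
    g1 = 1.0 - p.beta1
    Fl = g2 * p.c_ll * Gl - g1 * p.c_il * Gi + p.alpha * p.Kp
    Fi = g2 * p.c_li * Gl + (1.0 - p.alpha) * p.Kp
    Fe = g2 * p.c_le * Gl - g1 * p.c_ie * Gi
    return Fl, Fi, Fe


def mepd_rates(state, p: MePDParams) -> np.ndarray:
    """Dimensionless-time MePD rates ``(fl, fi, fe)`` (without ``delta``).

    Each component is ``-G + (1 - G) * phi(a, F, theta)``; the ``(1 - G)``
    factor models refractoriness and keeps activities below 1.
    """
    Gl, Gi, Ge = state
    Fl, Fi, Fe = mepd_inputs(state, p)
    return np.array(
        [
            -Gl + (1.0 - Gl) * phi(p.a_l, Fl, p.theta_l),
            -Gi + (1.0 - Gi) * phi(p.a_i, Fi, p.theta_i),
            -Ge + (1.0 - Ge) * phi(p.a_e, Fe, p.theta_e),
        ]
    )


def mepd_rhs(_T: float, state, p: MePDParams) -> np.ndarray:
    """MePD right-hand side on the minutes time scale: ``delta * rates``."""
    return p.delta * mepd_rates(state, p)


def mepd_jacobian(state, p: MePDParams) -> np.ndarray:
    """Analytic Jacobian of :func:`mepd_rhs` with respect to ``(Gl, Gi, Ge)``."""
    Gl, Gi, Ge = state
    Fl, Fi, Fe = mepd_inputs(state, p)
    g2 = 1.0 - p.beta2
    g1 = 1.0 - p.beta1
    # dF_k/dG_j
    dF = np.array(
        [
            [g2 * p.c_ll, -g1 * p.c_il, 0.0],
            [g2 * p.c_li, 0.0, 0.0],
            [g2 * p.c_le, -g1 * p.c_ie, 0.0],
        ]
    )
    ph = np.array(
        [phi(p.a_l, Fl, p.theta_l), phi(p.a_i, Fi, p.theta_i), phi(p.a_e, Fe, p.theta_e)]
    )
    dph = np.array(
        [
            phi_prime(p.a_l, Fl, p.theta_l),
            phi_prime(p.a_i, Fi, p.theta_i),
            phi_prime(p.a_e, Fe, p.theta_e),
        ]
    )
    G = np.asarray(state, dtype=float)
    J = ((1.0 - G) * dph)[:, None] * dF
    J[np.diag_indices(3)] += -1.0 - ph
    return p.delta * J


def kndy_rhs(
    _T: float,
    state,
    p: KNDyParams,
    ext=(0.0, 0.0),
    cp: CouplingParams | None = None,
) -> np.ndarray:
    """KNDy right-hand side with optional external MePD drive.

    ``ext = (Gl, Ge)`` are the instantaneous MePD activities; with
    ``cp=None`` or ``ext=(0, 0)`` the system is the free-running pulse
    generator.  The synaptic input is
    ``I = I0 + p_v * N^2/(N^2 + K_N^2) * v + j_l*Gl - j_e*Ge``.
    """
    D, N, v = state
    Gl, Ge = ext
    if not (np.isfinite(Gl) and np.isfinite(Ge)):
        raise ValueError("kndy_rhs: non-finite external input")
    j_l, j_e = (cp.j_l, cp.j_e) if cp is not None else (1.0, 1.0)
    v2 = v * v
    I = p.I0 + p.p_v * N * N / (N * N + p.K_N**2) * v + j_l * Gl - j_e * Ge
    f_D = p.k_D * v2 / (v2 + p.K_v1**2)
    f_N = p.k_N * v2 / (v2 + p.K_v2**2) * p.K_D**2 / (p.K_D**2 + D * D)
    f_v = p.v0 * _sigmoid(-p.k * (-I + p.m))
    return np.array([f_D - p.d_D * D, f_N - p.d_N * N, f_v - p.d_v * v])


def coupled_rhs(
    T: float,
    state,
    mp: MePDParams,
    kp: KNDyParams,
    cp: CouplingParams,
) -> np.ndarray:
    """Six-dimensional coupled system; the MePD block drives the KNDy block.

    The KNDy state never feeds back into the MePD equations.
    """
    mepd = mepd_rhs(T, state[:3], mp)
    kndy = kndy_rhs(T, state[3:], kp, ext=(state[0], state[2]), cp=cp)
    return np.concatenate([mepd, kndy])


# --- fast scalar closures -------------------------------------------------
#
# solve_ivp spends most of its time in right-hand-side callbacks; for long
# sweeps the array-based functions above are dominated by numpy overhead on
# 3-element states.  These factories bake the parameters into plain-float
# closures (identical mathematics, same exp clipping) and are what the
# simulation layer integrates.  The array versions remain the reference
# implementation; equivalence is covered by tests.

import math as _math


def _scalar_sigmoid(x: float) -> float:
    if x > _EXP_CLIP:
        x = _EXP_CLIP
    elif x < -_EXP_CLIP:
        x = -_EXP_CLIP
    return 1.0 / (1.0 + _math.exp(-x))


def make_mepd_rhs(p: MePDParams):
    """Parameter-baked scalar MePD right-hand side ``f(t, y) -> list``."""
    d = p.delta
    g2, g1 = 1.0 - p.beta2, 1.0 - p.beta1
    cll, cil, cli, cle, cie = g2 * p.c_ll, g1 * p.c_il, g2 * p.c_li, g2 * p.c_le, g1 * p.c_ie
    akp, ikp = p.alpha * p.Kp, (1.0 - p.alpha) * p.Kp
    al, ai, ae = p.a_l, p.a_i, p.a_e
    tl, ti, te = p.theta_l, p.theta_i, p.theta_e
    ol = 1.0 / (1.0 + _math.exp(al * tl))
    oi = 1.0 / (1.0 + _math.exp(ai * ti))
    oe = 1.0 / (1.0 + _math.exp(ae * te))
    sig = _scalar_sigmoid

    def rhs(_t, y):
        Gl, Gi, Ge = y[0], y[1], y[2]
        pl = sig(al * (cll * Gl - cil * Gi + akp - tl)) - ol
        pi = sig(ai * (cli * Gl + ikp - ti)) - oi
        pe = sig(ae * (cle * Gl - cie * Gi - te)) - oe
        return (
            d * (-Gl + (1.0 - Gl) * pl),
            d * (-Gi + (1.0 - Gi) * pi),
            d * (-Ge + (1.0 - Ge) * pe),
        )

    return rhs


def make_kndy_rhs(p: KNDyParams):
    """Parameter-baked scalar free-running KNDy right-hand side."""
    kD, kN, pv, v0 = p.k_D, p.k_N, p.p_v, p.v0
    dD, dN, dv = p.d_D, p.d_N, p.d_v
    KD2, KN2 = p.K_D**2, p.K_N**2
    Kv1s, Kv2s = p.K_v1**2, p.K_v2**2
    kk, m, I0 = p.k, p.m, p.I0
    sig = _scalar_sigmoid

    def rhs(_t, y):
        D, N, v = y[0], y[1], y[2]
        v2 = v * v
        I = I0 + pv * N * N / (N * N + KN2) * v
        return (
            kD * v2 / (v2 + Kv1s) - dD * D,
            kN * v2 / (v2 + Kv2s) * KD2 / (KD2 + D * D) - dN * N,
            v0 * sig(kk * (I - m)) - dv * v,
        )

    return rhs


def make_coupled_rhs(mp: MePDParams, kp: KNDyParams, cp: CouplingParams):
    """Parameter-baked scalar coupled right-hand side (one-way MePD->KNDy)."""
    mepd = make_mepd_rhs(mp)
    kD, kN, pv, v0 = kp.k_D, kp.k_N, kp.p_v, kp.v0
    dD, dN, dv = kp.d_D, kp.d_N, kp.d_v
    KD2, KN2 = kp.K_D**2, kp.K_N**2
    Kv1s, Kv2s = kp.K_v1**2, kp.K_v2**2
    kk, m, I0 = kp.k, kp.m, kp.I0
    jl, je = cp.j_l, cp.j_e
    sig = _scalar_sigmoid

    def rhs(t, y):
        dGl, dGi, dGe = mepd(t, y)
        D, N, v = y[3], y[4], y[5]
        v2 = v * v
        I = I0 + pv * N * N / (N * N + KN2) * v + jl * y[0] - je * y[2]
        return (
            dGl,
            dGi,
            dGe,
            kD * v2 / (v2 + Kv1s) - dD * D,
            kN * v2 / (v2 + Kv2s) * KD2 / (KD2 + D * D) - dN * N,
            v0 * sig(kk * (I - m)) - dv * v,
        )

    return rhs
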