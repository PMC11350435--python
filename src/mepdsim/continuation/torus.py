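"""Torus-bifurcation location for the coupled MePD-KNDy system.

Below the MePD Hopf point the MePD block settles to an equilibrium, so the
coupled attractor is the KNDy limit cycle under constant drive; above it
the periodic MePD forcing (period ~ minutes) combines with the KNDy cycle
(period ~ tens of minutes) into a quasi-periodic orbit on a torus.  The
transition therefore coincides with the MePD subsystem Hopf bifurcation,
which is how the primary locator works; Poincare-section and spectral
diagnostics verify the limit-cycle / torus character on either side.
"""

from __future__ import annotations

import numpy as np

from ..params import CouplingParams, KNDyParams, MePDParams
from ..simulate import integrate
from .equilibria import BifurcationPoint, continue_equilibria, detect_codim1

__all__ = [
    "locate_torus_bifurcation",
    "poincare_returns",
    "return_diameter",
    "spectral_peaks",
]


def locate_torus_bifurcation(
    mepd: MePDParams,
    kndy: KNDyParams,
    coupling: CouplingParams,
    free_param: str = "Kp",
    prange: tuple[float, float] = (0.0, 14.0),
) -> BifurcationPoint | None:
    """Locate the limit-cycle -> torus transition of the coupled system.

    Returns the MePD-subsystem Hopf point relabelled ``TR`` (the coupled
    transition aligns with it), or ``None`` when no Hopf point exists in
    range or the coupling is absent (``j_l = j_e = 0``, no forcing reaches
    the KNDy block).
    """
    if coupling.j_l == 0.0 and coupling.j_e == 0.0:
        return None
    branch = continue_equilibria(mepd, free_param, prange)
    hbs = [b for b in detect_codim1(branch) if b.kind == "HB"]
    if not hbs:
        return None
    hb = hbs[0]
    return BifurcationPoint(
        kind="TR",
        params=dict(hb.params),
        state=hb.state,
        eigenvalues=hb.eigenvalues,
        info={**hb.info, "method": "MePD subsystem HB alignment"},
    )


def poincare_returns(
    mepd: MePDParams,
    kndy: KNDyParams,
    coupling: CouplingParams,
    window: float = 600.0,
    section_component: str = "v",
    init=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Post-transient Poincare return points of the coupled system.

    The section is the upward crossing of the chosen component through the
    midpoint of its post-transient range; returns the full state at each
    crossing (linearly interpolated), one row per return.
    """
    traj = integrate(
        "coupled", mepd=mepd, kndy=kndy, coupling=coupling,
        t_span=(0.0, window), rtol=rtol, atol=atol,
    )
    t = traj.post_times
    Y = traj.post_states
    x = traj.post_component(section_component)
    level = 0.5 * (x.max() + x.min())
    idx = np.flatnonzero((x[:-1] < level) & (x[1:] >= level))
    if idx.size == 0:
        return np.empty((0, Y.shape[1]))
    frac = (level - x[idx]) / (x[idx + 1] - x[idx])
    return Y[idx] + frac[:, None] * (Y[idx + 1] - Y[idx])


def return_diameter(returns: np.ndarray, skip: int = 3) -> float:
    """Normalised diameter of the Poincare return-point cloud.

    Coordinates are scaled by their trace ranges (falling back to 1 for
    frozen components) so the diameter is comparable across state scales.
    A periodic orbit gives a diameter near 0; a torus gives order 1.
    """
    pts = returns[skip:]
    if len(pts) < 2:
        return 0.0
    scale = pts.max(axis=0) - pts.min(axis=0)
    ref = np.maximum(np.abs(pts).max(axis=0), 1.0)
    # normalise by typical magnitude, not spread, so tight clusters stay tight
    z = pts / ref
    d = z[:, None, :] - z[None, :, :]
    return float(np.sqrt((d * d).sum(axis=2)).max())


def spectral_peaks(
    times: np.ndarray,
    values: np.ndarray,
    n_peaks: int = 4,
    min_rel_power: float = 1e-4,
) -> np.ndarray:
    """Dominant frequencies (cycles/min) of a uniformly sampled trace.

    Returns up to ``n_peaks`` local maxima of the periodogram above
    ``min_rel_power`` times the largest peak, sorted by power (descending).
    """
    v = np.asarray(values, float)
    t = np.asarray(times, float)
    dt = float(np.median(np.diff(t)))
    v = v - v.mean()
    spec = np.abs(np.fft.rfft(v * np.hanning(v.size))) ** 2
    freqs = np.fft.rfftfreq(v.size, d=dt)
    mask = (spec[1:-1] > spec[:-2]) & (spec[1:-1] > spec[2:])
    cand = np.flatnonzero(mask) + 1
    if cand.size == 0:
        return np.array([])
    cand = cand[spec[cand] >= min_rel_power * spec[cand].max()]
    order = cand[np.argsort(spec[cand])[::-1]]
    return freqs[order[:n_peaks]]
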