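"""Limit-cycle continuation by single shooting on a Poincare section.

A cycle at one parameter value is represented by a point on the section
(Gl fixed at a reference level, crossing with dGl/dT > 0) plus the period.
The shooting residual is the return-map mismatch; its Jacobian is formed
by finite differences of the flow map.  Stability comes from the Floquet
multipliers of the finite-difference monodromy matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ..models import make_mepd_rhs
from ..params import MePDParams, unchecked_replace
from .equilibria import BifurcationPoint, ContinuationError

__all__ = ["LimitCycleBranch", "continue_limit_cycle", "shoot_cycle"]

_RTOL = 1e-10
_ATOL = 1e-12


def _flow(x0: np.ndarray, T: float, p: MePDParams, dense: bool = False):
    sol = solve_ivp(
        make_mepd_rhs(p),
        (0.0, T),
        np.asarray(x0, float),
        method="DOP853",
        rtol=_RTOL,
        atol=_ATOL,
        dense_output=dense,
    )
    if not sol.success:
        raise ContinuationError(f"flow integration failed: {sol.message}")
    return sol if dense else sol.y[:, -1]


def shoot_cycle(
    p: MePDParams,
    section_level: float,
    y_guess: np.ndarray,
    T_guess: float,
    tol: float = 1e-10,
    max_iter: int = 25,
) -> tuple[np.ndarray, float]:
    """Newton solve for a periodic orbit through the section ``Gl = level``.

    Unknowns are ``(Gi0, Ge0, T)`` with ``Gl0`` pinned to the section
    level (phase condition).  Returns the section state and the period.
    """
    z = np.array([y_guess[1], y_guess[2], T_guess], dtype=float)

    def resid(z: np.ndarray) -> np.ndarray:
        x0 = np.array([section_level, z[0], z[1]])
        xT = _flow(x0, z[2], p)
        return xT - x0

    r = resid(z)
    for _ in range(max_iter):
        if np.linalg.norm(r) < tol:
            break
        Jm = np.empty((3, 3))
        h = 1e-7
        for j in range(3):
            zp = z.copy()
            zp[j] += h * max(1.0, abs(z[j]))
            Jm[:, j] = (resid(zp) - r) / (zp[j] - z[j])
        try:
            dz = np.linalg.solve(Jm, -r)
        except np.linalg.LinAlgError as exc:
            raise ContinuationError(f"singular shooting Jacobian: {exc}") from exc
        lam = 1.0
        nr = np.linalg.norm(r)
        for _ls in range(20):
            zn = z + lam * dz
            if zn[2] <= 0:
                lam *= 0.5
                continue
            rn = resid(zn)
            if np.linalg.norm(rn) < nr or np.linalg.norm(rn) < tol:
                break
            lam *= 0.5
        else:
            raise ContinuationError("shooting line search stalled")
        z, r = zn, rn
    if np.linalg.norm(r) >= tol:
        raise ContinuationError(
            f"shooting Newton did not converge (residual {np.linalg.norm(r):.2e})"
        )
    return np.array([section_level, z[0], z[1]]), float(z[2])


def _march_cycle_arclength(
    p: MePDParams,
    free_param: str,
    level: float,
    x0: np.ndarray,
    T: float,
    lam: float,
    T_stop: float,
    lam_bounds: tuple[float, float],
    ds0: float = 0.02,
    ds_min: float = 1e-6,
    ds_max: float = 0.15,
    tol: float = 1e-9,
    max_steps: int = 400,
):
    """Pseudo-arclength continuation of the shooting system in
    ``u = (Gi0, Ge0, T, lam)`` with the section level pinned.

    Traverses folds of cycles, which natural parameter stepping cannot —
    in particular the fold-and-snake structure on the approach to a
    homoclinic connection, where the period climbs while the parameter
    oscillates towards its critical value.  Yields ``(lam, x0, T)``
    tuples for each accepted point; stops at ``T >= T_stop`` (period
    blow-up), at the parameter bounds, or on step underflow.
    """

    def resid(u: np.ndarray) -> np.ndarray:
        pe = unchecked_replace(p, **{free_param: u[3]})
        xs = np.array([level, u[0], u[1]])
        return _flow(xs, u[2], pe) - xs

    def jac(u: np.ndarray, r: np.ndarray) -> np.ndarray:
        Jm = np.empty((3, 4))
        for j in range(4):
            h = 1e-7 * max(1.0, abs(u[j]))
            up = u.copy()
            up[j] += h
            Jm[:, j] = (resid(up) - r) / h
        return Jm

    u = np.array([x0[1], x0[2], T, lam], dtype=float)
    tangent = None
    ds = ds0
    out = []
    for _ in range(max_steps):
        r = resid(u)
        A = jac(u, r)
        _, _, vt = np.linalg.svd(A)
        t_new = vt[-1]
        if tangent is None:
            if t_new[2] < 0:
                t_new = -t_new  # start towards growing period
        elif np.dot(t_new, tangent) < 0:
            t_new = -t_new
        tangent = t_new

        converged = False
        while ds >= ds_min:
            u_pred = u + ds * tangent
            un = u_pred.copy()
            ok = False
            for _n in range(12):
                rn = resid(un)
                res = np.concatenate([rn, [np.dot(tangent, un - u_pred)]])
                if np.linalg.norm(res) < tol:
                    ok = True
                    break
                Aug = np.vstack([jac(un, rn), tangent])
                try:
                    dun = np.linalg.solve(Aug, -res)
                except np.linalg.LinAlgError:
                    break
                un = un + dun
                if not np.all(np.isfinite(un)) or un[2] <= 0:
                    break
            if ok:
                converged = True
                break
            ds *= 0.5
        if not converged:
            return out, "newton_failure"
        if np.linalg.norm(un - u) < 1e-9:
            # predictor/corrector cycling on the spot (sharp cycle fold):
            # no further progress is possible at this step scale
            return out, "newton_failure"
        u = un
        out.append((float(u[3]), np.array([level, u[0], u[1]]), float(u[2])))
        ds = min(ds * 1.3, ds_max)
        if u[2] >= T_stop:
            return out, "period_blowup"
        if not (lam_bounds[0] <= u[3] <= lam_bounds[1]):
            return out, "range_end"
    return out, "max_steps"


def _monodromy(x0: np.ndarray, T: float, p: MePDParams, h: float = 1e-7) -> np.ndarray:
    base = _flow(x0, T, p)
    M = np.empty((3, 3))
    for j in range(3):
        xp = x0.copy()
        xp[j] += h
        M[:, j] = (_flow(xp, T, p) - base) / h
    return M


def _cycle_extrema(x0: np.ndarray, T: float, p: MePDParams, n: int = 600):
    sol = _flow(x0, T, p, dense=True)
    ts = np.linspace(0.0, T, n)
    Y = sol.sol(ts)
    return Y.max(axis=1), Y.min(axis=1), Y.mean(axis=1)


def _seed_from_hb(
    p: MePDParams, free_param: str, hb: BifurcationPoint, dp: float, direction: float
) -> tuple[MePDParams, np.ndarray, float, float]:
    """Simulate just past the Hopf point to land on the emerging cycle."""
    lam = hb.params[free_param] + direction * dp
    pe = unchecked_replace(p, **{free_param: lam})
    T_hopf = hb.info.get("period", 2.0)
    x = np.asarray(hb.state, float) + 1e-3
    sol = solve_ivp(
        make_mepd_rhs(pe),
        (0.0, 120.0 * T_hopf),
        x,
        method="RK45",
        rtol=1e-9,
        atol=1e-11,
        dense_output=True,
    )
    ts = np.linspace(100.0 * T_hopf, 120.0 * T_hopf, 4000)
    Y = sol.sol(ts)
    gl = Y[0]
    level = 0.5 * (gl.max() + gl.min())
    if gl.max() - gl.min() < 1e-7:
        raise ContinuationError(
            f"no oscillation found at {free_param}={lam:.5g} (amplitude "
            f"{gl.max() - gl.min():.2e}); wrong HB or subcritical case"
        )
    # first upward crossing of the level in the settled window
    idx = np.flatnonzero((gl[:-1] < level) & (gl[1:] >= level))
    if idx.size < 2:
        raise ContinuationError("could not find section crossings while seeding")
    i = idx[0]
    frac = (level - gl[i]) / (gl[i + 1] - gl[i])
    t_cross = ts[i] + frac * (ts[i + 1] - ts[i])
    y_cross = sol.sol(t_cross)
    T_guess = float(np.mean(np.diff(ts[idx]))) if idx.size > 2 else T_hopf
    return pe, y_cross, T_guess, level


@dataclass
class LimitCycleBranch:
    """Periodic-orbit family tracked in one free parameter."""

    free_param: str
    params: np.ndarray        # (n,)
    periods: np.ndarray       # (n,)
    maxima: np.ndarray        # (n, 3) per-variable cycle maxima
    minima: np.ndarray        # (n, 3)
    section_states: np.ndarray  # (n, 3) point on the section
    floquet: np.ndarray       # (n, 3) complex multipliers
    base: MePDParams = field(default_factory=MePDParams)
    status: str = "ok"        # 'ok' | 'period_blowup' | 'newton_failure' | 'range_end'

    def __len__(self) -> int:
        return len(self.params)

    @property
    def stable(self) -> np.ndarray:
        # one multiplier is ~1 (phase direction); stability from the rest
        mods = np.sort(np.abs(self.floquet), axis=1)[:, :2]
        return (mods < 1.0 + 1e-6).all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.free_param: self.params, "period": self.periods})
        for k, name in enumerate(("Gl", "Gi", "Ge")):
            df[f"{name}_max"] = self.maxima[:, k]
            df[f"{name}_min"] = self.minima[:, k]
        df["stable"] = self.stable
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def continue_limit_cycle(
    hb: BifurcationPoint,
    p: MePDParams,
    free_param: str,
    prange: tuple[float, float],
    dp0: float = 0.02,
    dp_min: float = 1e-6,
    dp_max: float = 0.1,
    period_blowup_ratio: float = 50.0,
    max_steps: int = 2000,
    seed: tuple[float, np.ndarray, float] | None = None,
    T_onset: float | None = None,
    compute_floquet: bool = True,
) -> LimitCycleBranch:
    """Track the limit-cycle family emerging from a Hopf point.

    Continuation proceeds from just past the Hopf point towards the far
    end of ``prange`` with natural-parameter stepping (warm-started
    shooting, halving on failure); when parameter stepping stalls on the
    homoclinic period asymptote it switches to stepping the period with
    the parameter free.  Terminates when the period exceeds
    ``period_blowup_ratio`` times the onset period (homoclinic proxy), on
    persistent Newton failure, or at the range end.

    ``seed=(param_value, section_state, period)`` bypasses the
    simulate-past-the-Hopf seeding (e.g. to resume a branch mid-way);
    ``T_onset`` then sets the blow-up reference period (defaults to the
    Hopf period if available, else the seed period).
    """
    if hb.kind != "HB":
        raise ValueError("continue_limit_cycle requires a Hopf point")
    lo, hi = prange
    lam_hb = hb.params[free_param]
    direction = 1.0 if (hi - lam_hb) >= (lam_hb - lo) else -1.0
    target = hi if direction > 0 else lo

    if seed is None:
        pe, y_seed, T_seed, level = _seed_from_hb(p, free_param, hb, dp0, direction)
        x0, T = shoot_cycle(pe, level, y_seed, T_seed)
    else:
        lam_seed, y_seed, T_seed = seed
        pe = unchecked_replace(p, **{free_param: float(lam_seed)})
        x0, T = shoot_cycle(pe, float(y_seed[0]), np.asarray(y_seed, float), float(T_seed))
    if T_onset is None:
        T_onset = hb.info.get("period", T) if seed is not None else T

    lams, periods, maxs, mins, secs, flqs = [], [], [], [], [], []

    def record(lam: float, x0: np.ndarray, T: float, pe: MePDParams):
        mx, mn, _ = _cycle_extrema(x0, T, pe)
        lams.append(lam)
        periods.append(T)
        maxs.append(mx)
        mins.append(mn)
        secs.append(x0.copy())
        if compute_floquet:
            flqs.append(np.linalg.eigvals(_monodromy(x0, T, pe)))
        else:
            flqs.append(np.full(3, np.nan, dtype=complex))
        return mx, mn

    def recenter_section(x0: np.ndarray, T: float, pe: MePDParams,
                         mx: np.ndarray, mn: np.ndarray):
        """Move the section to mid-range in Gl if it has drifted off-centre.

        The section level is pinned per shooting solve; as the cycle
        deforms along the branch the old level can approach a fold of the
        orbit in Gl, where the crossing turns tangential and the shooting
        Jacobian degenerates.
        """
        rng = mx[0] - mn[0]
        if rng <= 0:
            return x0, T
        rel = (x0[0] - mn[0]) / rng
        if 0.3 <= rel <= 0.7:
            return x0, T
        level = mn[0] + 0.5 * rng
        sol = _flow(x0, T, pe, dense=True)
        ts = np.linspace(0.0, T, 800)
        gl = sol.sol(ts)[0]
        idx = np.flatnonzero((gl[:-1] < level) & (gl[1:] >= level))
        if idx.size == 0:
            return x0, T
        i = idx[0]
        frac = (level - gl[i]) / (gl[i + 1] - gl[i])
        y_new = sol.sol(ts[i] + frac * (ts[i + 1] - ts[i]))
        try:
            return shoot_cycle(pe, level, y_new, T)
        except ContinuationError:
            return x0, T

    lam = getattr(pe, free_param)
    mx, mn = record(lam, x0, T, pe)
    x0, T = recenter_section(x0, T, pe, mx, mn)
    dp = dp0
    status = "range_end"
    for _ in range(max_steps):
        if (direction > 0 and lam >= target) or (direction < 0 and lam <= target):
            break
        stepped = False
        while dp >= dp_min:
            lam_try = lam + direction * dp
            if direction > 0:
                lam_try = min(lam_try, target)
            else:
                lam_try = max(lam_try, target)
            pe_try = unchecked_replace(p, **{free_param: lam_try})
            level = x0[0]
            try:
                x_new, T_new = shoot_cycle(pe_try, level, x0, T)
            except ContinuationError:
                dp *= 0.5
                continue
            # reject spurious convergence onto the equilibrium
            if T_new < 1e-3 or np.linalg.norm(_cycle_amp(x_new, T_new, pe_try)) < 1e-9:
                dp *= 0.5
                continue
            stepped = True
            break
        if not stepped:
            # Parameter stepping stalls on the near-vertical period asymptote
            # approaching a homoclinic: switch to stepping the period itself
            # with the parameter free.
            pts, arc_status = _march_cycle_arclength(
                p, free_param, x0[0], x0, T, lam,
                T_stop=period_blowup_ratio * T_onset,
                lam_bounds=(min(lo, hi) - 1.0, max(lo, hi) + 1.0),
            )
            for lam_a, x_a, T_a in pts:
                pe_a = unchecked_replace(p, **{free_param: lam_a})
                record(lam_a, x_a, T_a, pe_a)
            status = arc_status if pts else "newton_failure"
            break
        lam, x0, T, pe = lam_try, x_new, T_new, pe_try
        mx, mn = record(lam, x0, T, pe)
        x0, T = recenter_section(x0, T, pe, mx, mn)
        dp = min(dp * 1.2, dp_max)
        # blow-up only counts once the period has risen off its branch
        # minimum (the period first *dips* after onset in this system)
        if T > period_blowup_ratio * T_onset and T > 1.5 * min(periods):
            status = "period_blowup"
            break
    return LimitCycleBranch(
        free_param=free_param,
        params=np.array(lams),
        periods=np.array(periods),
        maxima=np.array(maxs),
        minima=np.array(mins),
        section_states=np.array(secs),
        floquet=np.array(flqs),
        base=p,
        status=status,
    )


def _cycle_amp(x0: np.ndarray, T: float, p: MePDParams) -> np.ndarray:
    mx, mn, _ = _cycle_extrema(x0, T, p, n=120)
    return mx - mn
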