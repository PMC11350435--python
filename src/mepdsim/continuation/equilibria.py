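"""Equilibrium location, pseudo-arclength branch continuation and
codim-1 bifurcation detection for the MePD system."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from ..models import mepd_jacobian, mepd_rhs
from ..params import MePDParams, unchecked_replace

__all__ = [
    "ContinuationError",
    "BifurcationPoint",
    "EquilibriumBranch",
    "find_equilibrium",
    "continue_equilibria",
    "detect_codim1",
    "char_coeffs",
    "hopf_test",
    "sn_test",
]


class ContinuationError(RuntimeError):
    pass


def _rhs(x: np.ndarray, p: MePDParams) -> np.ndarray:
    return mepd_rhs(0.0, x, p)


def _set(p: MePDParams, name: str, value: float) -> MePDParams:
    return unchecked_replace(p, **{name: float(value)})


def _dF_dparam(x: np.ndarray, p: MePDParams, name: str, h: float = 1e-7) -> np.ndarray:
    """Central finite difference of the rhs with respect to one parameter."""
    v = getattr(p, name)
    hh = h * max(1.0, abs(v))
    lo = max(0.0, v - hh) if name in ("Kp", "beta1", "beta2", "alpha") else v - hh
    hi = v + hh
    if name in ("beta1", "beta2", "alpha"):
        hi = min(1.0, hi)
    return (_rhs(x, _set(p, name, hi)) - _rhs(x, _set(p, name, lo))) / (hi - lo)


def char_coeffs(J: np.ndarray) -> tuple[float, float, float]:
    """Coefficients (c2, c1, c0) of det(lam*I - J) = lam^3 + c2 lam^2 + c1 lam + c0."""
    c2 = -float(np.trace(J))
    c1 = float(
        J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
        + J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]
    )
    c0 = -float(np.linalg.det(J))
    return c2, c1, c0


def hopf_test(J: np.ndarray) -> float:
    """Routh-Hurwitz Hopf test function c2*c1 - c0.

    Vanishes when a purely imaginary eigenvalue pair exists (valid where
    c1 > 0); positive for a stable spectrum.
    """
    c2, c1, c0 = char_coeffs(J)
    return c2 * c1 - c0


def sn_test(J: np.ndarray) -> float:
    """Saddle-node test function det(J) (zero eigenvalue)."""
    return float(np.linalg.det(J))


def find_equilibrium(
    p: MePDParams,
    guess: Sequence[float],
    tol: float = 1e-12,
    max_iter: int = 50,
) -> np.ndarray:
    """Newton solve of ``mepd_rhs = 0`` with analytic Jacobian and damping.

    Raises :class:`ContinuationError` (carrying the final residual) on
    non-convergence.
    """
    x = np.asarray(guess, dtype=float).copy()
    r = _rhs(x, p)
    for _ in range(max_iter):
        nr = np.linalg.norm(r)
        if nr < tol:
            return x
        try:
            dx = np.linalg.solve(mepd_jacobian(x, p), -r)
        except np.linalg.LinAlgError as exc:
            raise ContinuationError(f"singular Jacobian at {x} ({exc})") from exc
        lam = 1.0
        for _ls in range(20):
            xn = x + lam * dx
            rn = _rhs(xn, p)
            if np.linalg.norm(rn) < (1.0 - 0.25 * lam) * nr or np.linalg.norm(rn) < tol:
                break
            lam *= 0.5
        else:
            # Newton convergence is often non-monotone here; take the full
            # step and let max_iter/the final residual check guard failure.
            xn = x + dx
            rn = _rhs(xn, p)
        x, r = xn, rn
    nr = np.linalg.norm(r)
    if nr < tol:
        return x
    raise ContinuationError(f"Newton did not converge, residual {nr:.3e}")


def _pair_eigs(ev: np.ndarray, prev: np.ndarray | None) -> np.ndarray:
    """Order eigenvalues; match to the previous point's ordering if given."""
    ev = np.asarray(ev)
    if prev is None:
        return ev[np.lexsort((ev.imag, ev.real))]
    out = np.empty_like(ev)
    used = [False] * len(ev)
    for i, pv in enumerate(prev):
        j = int(
            np.argmin([np.inf if used[k] else abs(ev[k] - pv) for k in range(len(ev))])
        )
        out[i] = ev[j]
        used[j] = True
    return out


@dataclass
class EquilibriumBranch:
    """Ordered equilibrium continuation output in one free parameter."""

    free_param: str
    params: np.ndarray          # (n,)
    states: np.ndarray          # (n, 3)
    eigenvalues: np.ndarray     # (n, 3) complex, pairing-consistent
    stable: np.ndarray          # (n,) bool
    arclength: np.ndarray       # (n,)
    base: MePDParams = field(default_factory=MePDParams)
    status: str = "ok"          # 'ok' | 'truncated'

    def __len__(self) -> int:
        return len(self.params)

    def param_at(self, i: int) -> MePDParams:
        return _set(self.base, self.free_param, self.params[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                self.free_param: self.params,
                "Gl": self.states[:, 0],
                "Gi": self.states[:, 1],
                "Ge": self.states[:, 2],
                "stable": self.stable,
                "arclength": self.arclength,
            }
        )
        for k in range(3):
            df[f"eig{k}_re"] = self.eigenvalues[:, k].real
            df[f"eig{k}_im"] = self.eigenvalues[:, k].imag
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class BifurcationPoint:
    """A located bifurcation with its defining diagnostics.

    ``kind`` is one of HB, SN, HC, BT, CP, TR.  ``params`` maps free
    parameter name(s) to their critical value(s).
    """

    kind: str
    params: dict[str, float]
    state: np.ndarray
    eigenvalues: np.ndarray | None = None
    info: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "params": {k: float(v) for k, v in self.params.items()},
            "state": np.asarray(self.state).tolist(),
            "eigenvalues": (
                None
                if self.eigenvalues is None
                else [[float(e.real), float(e.imag)] for e in self.eigenvalues]
            ),
            "info": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.info.items()
            },
        }


def continue_equilibria(
    p: MePDParams,
    free_param: str,
    prange: tuple[float, float],
    guess: Sequence[float] | None = None,
    ds0: float = 0.01,
    ds_min: float = 1e-5,
    ds_max: float = 0.05,
    max_steps: int = 20000,
    residual_tol: float = 1e-10,
) -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium branch.

    Starts from a Newton-corrected equilibrium at ``prange[0]`` (guess
    defaults to the origin) and traverses folds.  Steps are halved on
    corrector failure and grown by 1.3x after three consecutive successes,
    capped to ``[ds_min, ds_max]``.  Eigenvalues are recorded at every
    accepted point with pairing kept consistent along the branch.
    """
    lo, hi = prange
    if not hi > lo:
        raise ValueError("prange must satisfy hi > lo")
    p0 = _set(p, free_param, lo)
    x = find_equilibrium(p0, guess if guess is not None else np.zeros(3))

    pts_x: list[np.ndarray] = []
    pts_l: list[float] = []
    eigs: list[np.ndarray] = []
    arcs: list[float] = []
    status = "ok"

    def record(x: np.ndarray, lam: float, s: float) -> None:
        pe = _set(p, free_param, lam)
        ev = np.linalg.eigvals(mepd_jacobian(x, pe))
        prev = eigs[-1] if eigs else None
        eigs.append(_pair_eigs(ev, prev))
        pts_x.append(x.copy())
        pts_l.append(float(lam))
        arcs.append(s)

    record(x, lo, 0.0)
    u = np.concatenate([x, [lo]])
    tangent = None
    ds = ds0
    successes = 0
    s_acc = 0.0

    def ext_jac(u: np.ndarray) -> np.ndarray:
        """3x4 Jacobian [J | dF/dlam] of the rhs in (x, lam)."""
        pe = _set(p, free_param, u[3])
        J = mepd_jacobian(u[:3], pe)
        Fl = _dF_dparam(u[:3], pe, free_param)
        return np.hstack([J, Fl[:, None]])

    for _ in range(max_steps):
        A = ext_jac(u)
        # Tangent: unit null vector of the 3x4 extended Jacobian.
        _, _, vt = np.linalg.svd(A)
        t_new = vt[-1]
        if tangent is not None and np.dot(t_new, tangent) < 0:
            t_new = -t_new
        elif tangent is None and t_new[3] < 0:
            t_new = -t_new  # start moving towards increasing parameter
        tangent = t_new

        converged = False
        while ds >= ds_min:
            u_pred = u + ds * tangent
            un = u_pred.copy()
            ok = False
            for _n in range(12):
                pe = _set(p, free_param, un[3])
                F = _rhs(un[:3], pe)
                g = np.dot(tangent, un - u_pred)
                res = np.concatenate([F, [g]])
                if np.linalg.norm(res) < 1e-12:
                    ok = True
                    break
                Aug = np.vstack([ext_jac(un), tangent])
                try:
                    dun = np.linalg.solve(Aug, -res)
                except np.linalg.LinAlgError:
                    break
                un = un + dun
                if not np.all(np.isfinite(un)):
                    break
            if ok and np.linalg.norm(_rhs(un[:3], _set(p, free_param, un[3]))) < residual_tol:
                converged = True
                break
            ds *= 0.5
            successes = 0
        if not converged:
            status = "truncated"
            break

        u = un
        s_acc += ds
        record(u[:3], u[3], s_acc)
        successes += 1
        if successes >= 3:
            ds = min(ds * 1.3, ds_max)
            successes = 0
        if u[3] > hi + 1e-12 or u[3] < lo - 1e-12:
            break
    else:
        status = "truncated"

    eig_arr = np.array(eigs)
    return EquilibriumBranch(
        free_param=free_param,
        params=np.array(pts_l),
        states=np.array(pts_x),
        eigenvalues=eig_arr,
        stable=(eig_arr.real < 0).all(axis=1),
        arclength=np.array(arcs),
        base=p,
        status=status,
    )


def _refine_between(
    branch: EquilibriumBranch,
    i: int,
    testfn,
    accept,
    max_bisect: int = 80,
) -> tuple[np.ndarray, float] | None:
    """Bisect a test-function sign change between branch points i and i+1.

    The intermediate point at fraction s is obtained by Newton correction
    in the hyperplane orthogonal to the secant through the linear
    interpolant, so folds are handled.
    """
    p = branch.base
    name = branch.free_param
    u0 = np.concatenate([branch.states[i], [branch.params[i]]])
    u1 = np.concatenate([branch.states[i + 1], [branch.params[i + 1]]])
    sec = u1 - u0
    nsec = np.linalg.norm(sec)
    if nsec == 0:
        return None
    sec = sec / nsec

    def solve_at(s: float) -> np.ndarray | None:
        anchor = u0 + s * (u1 - u0)
        un = anchor.copy()
        for _ in range(30):
            pe = _set(p, name, un[3])
            F = _rhs(un[:3], pe)
            g = np.dot(sec, un - anchor)
            res = np.concatenate([F, [g]])
            if np.linalg.norm(res) < 1e-13:
                return un
            J = mepd_jacobian(un[:3], pe)
            Fl = _dF_dparam(un[:3], pe, name)
            Aug = np.vstack([np.hstack([J, Fl[:, None]]), sec])
            try:
                dun = np.linalg.solve(Aug, -res)
            except np.linalg.LinAlgError:
                return None
            un = un + dun
        return None

    def tval(u: np.ndarray) -> float:
        return testfn(mepd_jacobian(u[:3], _set(p, name, u[3])))

    ta, tb = tval(u0), tval(u1)
    if not np.isfinite(ta) or not np.isfinite(tb) or ta * tb > 0:
        return None
    sa, sb = 0.0, 1.0
    ua = u0
    for _ in range(max_bisect):
        sm = 0.5 * (sa + sb)
        um = solve_at(sm)
        if um is None:
            return None
        if accept(um):
            return um[:3], float(um[3])
        tm = tval(um)
        if ta * tm <= 0:
            sb, tb = sm, tm
        else:
            sa, ta, ua = sm, tm, um
    return (ua[:3], float(ua[3])) if accept(ua) else None


def detect_codim1(
    branch: EquilibriumBranch,
    hb_tol: float = 1e-8,
    sn_tol: float = 1e-8,
) -> list[BifurcationPoint]:
    """Locate Hopf and saddle-node points along an equilibrium branch.

    Hopf points are sign changes of the Routh-Hurwitz test function
    (refined until the complex pair satisfies ``|Re| < hb_tol``); folds are
    sign changes of ``det(J)`` (refined until ``|lam_min| < sn_tol``).
    """
    if len(branch) < 2:
        return []
    p = branch.base
    name = branch.free_param
    out: list[BifurcationPoint] = []

    def eigs_at(x: np.ndarray, lam: float) -> np.ndarray:
        return np.linalg.eigvals(mepd_jacobian(x, _set(p, name, lam)))

    def hb_accept(u: np.ndarray) -> bool:
        ev = eigs_at(u[:3], u[3])
        pair = ev[np.abs(ev.imag) > 1e-6]
        return pair.size >= 2 and float(np.max(np.abs(pair.real))) < hb_tol

    def sn_accept(u: np.ndarray) -> bool:
        ev = eigs_at(u[:3], u[3])
        return float(np.min(np.abs(ev))) < sn_tol

    J_list = [
        mepd_jacobian(branch.states[i], branch.param_at(i)) for i in range(len(branch))
    ]
    hb_vals = np.array([hopf_test(J) for J in J_list])
    sn_vals = np.array([sn_test(J) for J in J_list])
    c1_vals = np.array([char_coeffs(J)[1] for J in J_list])

    for i in range(len(branch) - 1):
        if hb_vals[i] * hb_vals[i + 1] < 0 and (c1_vals[i] > 0 or c1_vals[i + 1] > 0):
            res = _refine_between(branch, i, hopf_test, hb_accept)
            if res is not None:
                x, lam = res
                ev = eigs_at(x, lam)
                pair = ev[np.abs(ev.imag) > 1e-6]
                if pair.size >= 2:
                    freq = float(np.max(np.abs(pair.imag)))
                    out.append(
                        BifurcationPoint(
                            kind="HB",
                            params={name: lam},
                            state=x,
                            eigenvalues=ev,
                            info={"hopf_frequency": freq, "period": 2 * np.pi / freq},
                        )
                    )
        if sn_vals[i] * sn_vals[i + 1] < 0:
            res = _refine_between(branch, i, sn_test, sn_accept)
            if res is not None:
                x, lam = res
                ev = eigs_at(x, lam)
                out.append(
                    BifurcationPoint(
                        kind="SN",
                        params={name: lam},
                        state=x,
                        eigenvalues=ev,
                        info={"min_abs_eig": float(np.min(np.abs(ev)))},
                    )
                )
    out.sort(key=lambda bp: bp.params[name])
    return out
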