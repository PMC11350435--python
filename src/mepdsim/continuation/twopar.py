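"""Two-parameter continuation of codim-1 bifurcation loci, codim-2 point
detection (Bogdanov-Takens, cusp) and the large-period homoclinic proxy.

The loci are tracked as zero curves of a minimally augmented system:
the three equilibrium equations plus one scalar test function (det(J) for
saddle-nodes, the Routh-Hurwitz combination c2*c1 - c0 for Hopf), with
pseudo-arclength stepping in (state, param1, param2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..models import mepd_jacobian, mepd_rhs
from ..params import MePDParams, unchecked_replace
from .equilibria import (
    BifurcationPoint,
    ContinuationError,
    char_coeffs,
    continue_equilibria,
    detect_codim1,
    hopf_test,
    sn_test,
)
from .cycles import continue_limit_cycle

__all__ = [
    "TwoParamCurve",
    "continue_codim1_locus",
    "detect_codim2",
    "approximate_homoclinic",
]


def _setp(p: MePDParams, names: tuple[str, str], vals) -> MePDParams:
    return unchecked_replace(p, **{names[0]: float(vals[0]), names[1]: float(vals[1])})


@dataclass
class TwoParamCurve:
    """Ordered locus of a codim-1 bifurcation in a two-parameter plane."""

    kind: str                 # 'HB' | 'SN' | 'HC'
    param_names: tuple[str, str]
    params: np.ndarray        # (n, 2)
    states: np.ndarray        # (n, 3)
    aux: np.ndarray | None = None  # HB: omega^2 along the curve; HC: period
    codim2: list[BifurcationPoint] = field(default_factory=list)
    base: MePDParams = field(default_factory=MePDParams)
    status: str = "ok"

    def __len__(self) -> int:
        return len(self.params)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                self.param_names[0]: self.params[:, 0],
                self.param_names[1]: self.params[:, 1],
                "Gl": self.states[:, 0],
                "Gi": self.states[:, 1],
                "Ge": self.states[:, 2],
            }
        )
        if self.aux is not None:
            df["aux"] = self.aux
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def _test_fn(kind: str):
    if kind == "HB":
        return hopf_test
    if kind == "SN":
        return sn_test
    raise ValueError(f"cannot continue locus of kind {kind!r}")


def _G(u: np.ndarray, p: MePDParams, names, test) -> np.ndarray:
    """Augmented system: [rhs(x); test(J)] at u = (x, p1, p2)."""
    pe = _setp(p, names, u[3:])
    x = u[:3]
    J = mepd_jacobian(x, pe)
    return np.concatenate([mepd_rhs(0.0, x, pe), [test(J)]])


def _G_jac(u: np.ndarray, p: MePDParams, names, test, h: float = 1e-6) -> np.ndarray:
    """4x5 finite-difference Jacobian of the augmented system."""
    A = np.empty((4, 5))
    for j in range(5):
        hp = h * max(1.0, abs(u[j]))
        up, um = u.copy(), u.copy()
        up[j] += hp
        um[j] -= hp
        A[:, j] = (_G(up, p, names, test) - _G(um, p, names, test)) / (2 * hp)
    return A


def continue_codim1_locus(
    point: BifurcationPoint,
    p: MePDParams,
    param_pair: tuple[str, str],
    box: tuple[tuple[float, float], tuple[float, float]],
    ds0: float = 0.01,
    ds_min: float = 1e-6,
    ds_max: float = 0.1,
    max_steps: int = 5000,
    bidirectional: bool = True,
) -> TwoParamCurve:
    """Continue an HB or SN point as a curve in two parameters.

    The starting point must be a codim-1 point detected with
    ``param_pair[0]`` free and ``param_pair[1]`` at its value in ``p``.
    Stops at the box boundary, on step underflow (status ``truncated``) or
    after ``max_steps``.  Every accepted point satisfies ``|rhs| < 1e-10``
    and ``|test| < 1e-8``.
    """
    kind = point.kind
    test = _test_fn(kind)
    (lo1, hi1), (lo2, hi2) = box
    n1, n2 = param_pair
    v1 = point.params.get(n1, getattr(p, n1))
    v2 = point.params.get(n2, getattr(p, n2))
    u0 = np.concatenate([np.asarray(point.state, float), [v1, v2]])

    # polish the seed on the augmented system
    u0 = _newton_aug(u0, p, param_pair, test)
    if u0 is None:
        raise ContinuationError(f"could not polish {kind} seed on augmented system")

    halves = []
    for sign in (1.0, -1.0) if bidirectional else (1.0,):
        halves.append(
            _march(u0, p, param_pair, test, (lo1, hi1, lo2, hi2), sign, ds0, ds_min, ds_max, max_steps)
        )
    if bidirectional:
        fwd, bwd = halves
        params = np.vstack([bwd["params"][::-1], [u0[3:]], fwd["params"]])
        states = np.vstack([bwd["states"][::-1], [u0[:3]], fwd["states"]])
        status = "ok" if (fwd["status"] == "ok" and bwd["status"] == "ok") else "truncated"
    else:
        fwd = halves[0]
        params = np.vstack([[u0[3:]], fwd["params"]])
        states = np.vstack([[u0[:3]], fwd["states"]])
        status = fwd["status"]

    aux = None
    if kind == "HB":
        aux = np.array(
            [
                char_coeffs(mepd_jacobian(states[i], _setp(p, param_pair, params[i])))[1]
                for i in range(len(params))
            ]
        )
    return TwoParamCurve(
        kind=kind,
        param_names=param_pair,
        params=params,
        states=states,
        aux=aux,
        base=p,
        status=status,
    )


def _newton_aug(u, p, names, test, tol=1e-11, max_iter=30):
    u = np.asarray(u, float).copy()
    for _ in range(max_iter):
        g = _G(u, p, names, test)
        if np.linalg.norm(g) < tol:
            return u
        A = _G_jac(u, p, names, test)
        du, *_ = np.linalg.lstsq(A, -g, rcond=None)  # minimum-norm step
        u = u + du
        if not np.all(np.isfinite(u)):
            return None
    return u if np.linalg.norm(_G(u, p, names, test)) < 1e-8 else None


def _march(u0, p, names, test, bounds, sign, ds0, ds_min, ds_max, max_steps):
    lo1, hi1, lo2, hi2 = bounds
    params, states = [], []
    u = u0.copy()
    tangent = None
    ds = ds0
    successes = 0
    status = "ok"
    for _ in range(max_steps):
        A = _G_jac(u, p, names, test)
        _, _, vt = np.linalg.svd(A)
        t_new = vt[-1]
        if tangent is None:
            if sign * t_new[3] < 0 and abs(t_new[3]) > 1e-8:
                t_new = -t_new
            elif abs(t_new[3]) <= 1e-8 and sign * t_new[4] < 0:
                t_new = -t_new
        elif np.dot(t_new, tangent) < 0:
            t_new = -t_new
        tangent = t_new

        converged = False
        while ds >= ds_min:
            u_pred = u + ds * tangent
            un = u_pred.copy()
            ok = False
            for _n in range(15):
                g = _G(un, p, names, test)
                res = np.concatenate([g, [np.dot(tangent, un - u_pred)]])
                if np.linalg.norm(res) < 1e-11:
                    ok = True
                    break
                Aug = np.vstack([_G_jac(un, p, names, test), tangent])
                try:
                    dun = np.linalg.solve(Aug, -res)
                except np.linalg.LinAlgError:
                    break
                un = un + dun
                if not np.all(np.isfinite(un)):
                    break
            gn = _G(un, p, names, test) if ok else None
            if ok and np.linalg.norm(gn[:3]) < 1e-10 and abs(gn[3]) < 1e-8:
                converged = True
                break
            ds *= 0.5
            successes = 0
        if not converged:
            status = "truncated"
            break
        u = un
        params.append(u[3:].copy())
        states.append(u[:3].copy())
        successes += 1
        if successes >= 3:
            ds = min(ds * 1.3, ds_max)
            successes = 0
        if not (lo1 - 1e-9 <= u[3] <= hi1 + 1e-9 and lo2 - 1e-9 <= u[4] <= hi2 + 1e-9):
            break
    else:
        status = "truncated"
    return {
        "params": np.array(params).reshape(-1, 2),
        "states": np.array(states).reshape(-1, 3),
        "status": status,
    }


def _fold_normal_form_b(
    x, pe: MePDParams, v_prev: np.ndarray | None = None, h: float = 1e-5
) -> tuple[float, np.ndarray]:
    """Quadratic coefficient w . D2f[v, v] of the fold normal form.

    Both null vectors are unit-normalised with sign fixed by continuity
    against the previous curve point (eigenvector orientation is otherwise
    arbitrary and would inject spurious sign changes), and the left vector
    is NOT rescaled by 1/(w.v): that rescaling has poles where w and v
    turn orthogonal, which read as fake sign changes of the test function.
    """
    J = mepd_jacobian(x, pe)
    w_eig, W = np.linalg.eig(J.T)
    v_eig, V = np.linalg.eig(J)
    iw = int(np.argmin(np.abs(w_eig)))
    iv = int(np.argmin(np.abs(v_eig)))
    w = np.real(W[:, iw])
    v = np.real(V[:, iv])
    v = v / np.linalg.norm(v)
    w = w / np.linalg.norm(w)
    if v_prev is not None:
        if np.dot(v, v_prev[0]) < 0:
            v = -v
        if np.dot(w, v_prev[1]) < 0:
            w = -w
    else:
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
    f0 = mepd_rhs(0.0, x, pe)
    fp = mepd_rhs(0.0, x + h * v, pe)
    fm = mepd_rhs(0.0, x - h * v, pe)
    d2 = (fp - 2 * f0 + fm) / (h * h)
    return float(np.dot(w, d2)), (v, w)


def _polish_bt(u0: np.ndarray, p: MePDParams, names, tol=1e-10, max_iter=40):
    """Newton solve of the Bogdanov-Takens defining system.

    ``[rhs(x); c0(J); c1(J)] = 0`` in ``(x, p1, p2)`` — at the solution the
    Jacobian has an exact double-zero eigenvalue.
    """

    def F(u):
        pe = _setp(p, names, u[3:])
        J = mepd_jacobian(u[:3], pe)
        _, c1, c0 = char_coeffs(J)
        return np.concatenate([mepd_rhs(0.0, u[:3], pe), [c0, c1]])

    u = np.asarray(u0, float).copy()
    for _ in range(max_iter):
        g = F(u)
        if np.linalg.norm(g) < tol:
            return u
        A = np.empty((5, 5))
        for j in range(5):
            h = 1e-6 * max(1.0, abs(u[j]))
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            A[:, j] = (F(up) - F(um)) / (2 * h)
        try:
            du = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError:
            return None
        u = u + du
        if not np.all(np.isfinite(u)):
            return None
    return u if np.linalg.norm(F(u)) < 1e-7 else None


def detect_codim2(
    curves: list[TwoParamCurve],
    bt_omega_tol: float = 1e-4,
) -> list[BifurcationPoint]:
    """Find Bogdanov-Takens points on HB curves and cusps on SN curves.

    BT: the squared Hopf frequency (c1 along the HB locus) crosses zero or
    falls below ``bt_omega_tol``; cross-checked against proximity to any
    SN curve in the set.  CP: the fold normal-form quadratic coefficient
    changes sign along an SN locus.
    """
    out: list[BifurcationPoint] = []
    sn_points = np.vstack(
        [c.params for c in curves if c.kind == "SN"]
    ) if any(c.kind == "SN" for c in curves) else None

    for c in curves:
        names = c.param_names
        if c.kind == "HB" and c.aux is not None and len(c) >= 2:
            om2 = c.aux
            for i in range(len(c) - 1):
                crossing = om2[i] * om2[i + 1] < 0
                touching = min(abs(om2[i]), abs(om2[i + 1])) < bt_omega_tol and not crossing
                if not (crossing or touching):
                    continue
                # linear interpolation to the omega^2 = 0 crossing, then a
                # Newton polish on the BT defining system
                if crossing:
                    s = om2[i] / (om2[i] - om2[i + 1])
                else:
                    s = 0.0 if abs(om2[i]) < abs(om2[i + 1]) else 1.0
                u0 = np.concatenate(
                    [
                        c.states[i] + s * (c.states[i + 1] - c.states[i]),
                        c.params[i] + s * (c.params[i + 1] - c.params[i]),
                    ]
                )
                u = _polish_bt(u0, c.base, names)
                if u is None:
                    u = u0
                pe = _setp(c.base, names, u[3:])
                ev = np.linalg.eigvals(mepd_jacobian(u[:3], pe))
                mods = np.sort(np.abs(ev))
                info = {
                    "omega_sq": float(char_coeffs(mepd_jacobian(u[:3], pe))[1]),
                    "two_smallest_eig_mods": mods[:2].tolist(),
                }
                if sn_points is not None:
                    d = np.min(np.linalg.norm(sn_points - u[3:], axis=1))
                    info["distance_to_SN_curve"] = float(d)
                out.append(
                    BifurcationPoint(
                        kind="BT",
                        params={names[0]: float(u[3]), names[1]: float(u[4])},
                        state=u[:3],
                        eigenvalues=ev,
                        info=info,
                    )
                )
        if c.kind == "SN" and len(c) >= 3:
            bvals = np.empty(len(c))
            v_prev = None
            for i in range(len(c)):
                bvals[i], v_prev = _fold_normal_form_b(
                    c.states[i], _setp(c.base, names, c.params[i]), v_prev
                )
            for i in range(len(c) - 1):
                if bvals[i] * bvals[i + 1] < 0:
                    j = i if abs(bvals[i]) < abs(bvals[i + 1]) else i + 1
                    pe = _setp(c.base, names, c.params[j])
                    ev = np.linalg.eigvals(mepd_jacobian(c.states[j], pe))
                    out.append(
                        BifurcationPoint(
                            kind="CP",
                            params={names[0]: c.params[j, 0], names[1]: c.params[j, 1]},
                            state=c.states[j],
                            eigenvalues=ev,
                            info={"fold_coefficient": float(bvals[j])},
                        )
                    )
    return out


def approximate_homoclinic(
    p: MePDParams,
    param_pair: tuple[str, str],
    box: tuple[tuple[float, float], tuple[float, float]],
    n_grid: int = 8,
    period_ratio: float = 50.0,
    eq_guess=None,
    lc_kwargs: dict | None = None,
) -> TwoParamCurve:
    """Approximate the homoclinic locus by period blow-up of the cycle.

    For each value of ``param_pair[1]`` on a grid, the Hopf point in
    ``param_pair[0]`` is located and the emerging cycle is continued until
    its period reaches ``period_ratio`` times the onset period; the
    parameter pair at which that happens is one point of the approximate
    HC curve.  Grid lines without a Hopf point, or where no cycle reaches
    the threshold inside the box, are skipped (recorded in ``status``).
    """
    n1, n2 = param_pair
    (lo1, hi1), (lo2, hi2) = box
    grid2 = np.linspace(lo2, hi2, n_grid)
    pts, states, periods = [], [], []
    skipped: list[float] = []
    kw = dict(dp0=0.05, dp_max=0.5)
    if lc_kwargs:
        kw.update(lc_kwargs)
    for v2 in grid2:
        pe = unchecked_replace(p, **{n2: float(v2)})
        try:
            br = continue_equilibria(pe, n1, (lo1, hi1), guess=eq_guess)
            hbs = [b for b in detect_codim1(br) if b.kind == "HB"]
            if not hbs:
                skipped.append(float(v2))
                continue
            lc = continue_limit_cycle(
                hbs[0], pe, n1, (hbs[0].params[n1], hi1),
                period_blowup_ratio=period_ratio, **kw,
            )
        except ContinuationError:
            skipped.append(float(v2))
            continue
        if lc.status != "period_blowup" or len(lc) == 0:
            skipped.append(float(v2))
            continue
        pts.append([lc.params[-1], v2])
        states.append(lc.section_states[-1])
        periods.append(lc.periods[-1])
    return TwoParamCurve(
        kind="HC",
        param_names=param_pair,
        params=np.array(pts).reshape(-1, 2),
        states=np.array(states).reshape(-1, 3),
        aux=np.array(periods) if periods else None,
        base=p,
        status="ok" if not skipped else f"skipped {len(skipped)} grid lines: {skipped}",
    )
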