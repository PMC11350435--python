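"""In-silico experiment drivers: kisspeptin stimulation, receptor-antagonism
sweeps, projection-stimulation IPI curves, mean-output heat maps and the
GABA-efferent gain-switch analysis.

All drivers are deterministic: sweeps warm-start each run from the end
state of the previous grid point so statistics are collected on the
attracting branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .params import COUPLING_PRESETS, CouplingParams, KNDyParams, MePDParams, update
from .pulses import PulseStats, detect_pulses
from .simulate import OutputSummary, Trajectory, integrate, mean_outputs

__all__ = [
    "SweepResult",
    "HeatMap",
    "sweep_kisspeptin",
    "sweep_projection_stimulation",
    "sweep_antagonism",
    "heatmap_mean_output",
    "find_gain_switch",
    "classify_mepd",
]

#: Peak-to-peak threshold on post-transient Gl below which the MePD block
#: counts as stationary.
OSC_RANGE_TOL = 1e-3

#: Pulse-detection options for coupled v traces.  A genuine pulse swings v
#: by ~v0/d_v (2500); the fast MePD forcing alone produces a ripple of up
#: to a few hundred at the MePD cycle period (~2 min).  The floor (15% of
#: v0/d_v) and the 5-min separation reject ripple-only traces that the
#: generic 1% floor would misread as pulsatile.
COUPLED_PULSE_OPTS: dict[str, float] = {
    "amplitude_floor": 0.15 * 25000.0 / 10.0,
    "min_distance": 5.0,
}


def classify_mepd(traj: Trajectory) -> str:
    """'oscillatory' or 'stationary' from the post-transient Gl range."""
    gl = traj.post_component("Gl")
    return "oscillatory" if gl.max() - gl.min() > OSC_RANGE_TOL else "stationary"


@dataclass
class SweepResult:
    """Per-grid-point outputs of a one-parameter scenario sweep."""

    param_names: tuple[str, ...]
    grid: np.ndarray
    summaries: list[OutputSummary]
    pulses: list[PulseStats | None]
    labels: list[str]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.grid)
        if not (len(self.summaries) == len(self.pulses) == len(self.labels) == n):
            raise ValueError("grid and per-point result lengths must match")

    @property
    def mean_ipi(self) -> np.ndarray:
        return np.array(
            [p.mean_ipi if p is not None else np.nan for p in self.pulses]
        )

    @property
    def mean_mepd(self) -> np.ndarray:
        return np.array([s.mean_mepd for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        g = np.atleast_2d(np.asarray(self.grid, float).T).T
        data = {name: g[:, i] for i, name in enumerate(self.param_names)}
        data["mean_glut"] = [s.mean_glut for s in self.summaries]
        data["mean_gaba"] = [s.mean_gaba for s in self.summaries]
        data["mean_mepd"] = [s.mean_mepd for s in self.summaries]
        data["label"] = self.labels
        data["mean_ipi"] = self.mean_ipi
        data["n_pulses"] = [
            p.n_pulses if p is not None else -1 for p in self.pulses
        ]
        data["pulse_class"] = [
            p.classification if p is not None else "" for p in self.pulses
        ]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass
class HeatMap:
    """Mean-output matrix over a two-parameter grid with oscillation mask.

    ``matrix[i, j]`` is the selected mean output at ``(axis1[i], axis2[j])``;
    ``oscillatory[i, j]`` marks cells where the MePD block oscillates
    (elsewhere the value is the stationary-state mean).
    """

    param_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    matrix: np.ndarray
    oscillatory: np.ndarray
    output: str = "mepd"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError("matrix dims must match axes")
        if self.oscillatory.shape != self.matrix.shape:
            raise ValueError("mask dims must match matrix")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.axis1, columns=self.axis2)
        df.index.name = self.param_names[0]
        df.columns.name = self.param_names[1]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.12g")


def _coupled_point(
    mp: MePDParams,
    kp: KNDyParams,
    cp: CouplingParams,
    init,
    window: float,
    rtol: float,
    atol: float,
) -> tuple[Trajectory, OutputSummary, PulseStats, str]:
    traj = integrate(
        "coupled", mepd=mp, kndy=kp, coupling=cp,
        init=init, t_span=(0.0, window), rtol=rtol, atol=atol,
    )
    summ = mean_outputs(traj)
    ps = detect_pulses(traj.post_times, traj.post_component("v"), **COUPLED_PULSE_OPTS)
    label = classify_mepd(traj)
    if ps.classification != "pulsatile":
        label += "+quiescent-KNDy"
    return traj, summ, ps, label


def _coupled_sweep(
    mp: MePDParams,
    kp: KNDyParams,
    cp: CouplingParams,
    kp_grid: Sequence[float],
    window: float,
    warm_start: bool,
    rtol: float,
    atol: float,
    meta: dict[str, Any],
) -> SweepResult:
    summaries, pulses, labels = [], [], []
    init = None
    for kval in kp_grid:
        mpe = update(mp, Kp=float(kval))
        traj, summ, ps, label = _coupled_point(mpe, kp, cp, init, window, rtol, atol)
        summaries.append(summ)
        pulses.append(ps)
        labels.append(label)
        if warm_start:
            init = traj.states[-1]
    return SweepResult(
        param_names=("Kp",),
        grid=np.asarray(kp_grid, float),
        summaries=summaries,
        pulses=pulses,
        labels=labels,
        meta=meta,
    )


def sweep_kisspeptin(
    mepd: MePDParams,
    kndy: KNDyParams,
    kp_grid: Sequence[float],
    coupling: CouplingParams | None = None,
    window: float = 600.0,
    warm_start: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SweepResult:
    """Coupled-system response to increasing kisspeptin drive.

    Baseline coupling (equal projection weights) unless overridden.  Per
    grid point: mean MePD outputs and KNDy pulse statistics (IPI on the
    firing-rate component v).
    """
    cp = coupling if coupling is not None else COUPLING_PRESETS["baseline"]
    return _coupled_sweep(
        mepd, kndy, cp, kp_grid, window, warm_start, rtol, atol,
        meta={"scenario": "kisspeptin", "coupling": cp.to_dict(), "window": window},
    )


def sweep_projection_stimulation(
    mepd: MePDParams,
    kndy: KNDyParams,
    preset: str,
    kp_grid: Sequence[float],
    window: float = 600.0,
    warm_start: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SweepResult:
    """IPI-versus-stimulation curve for a projection-stimulation preset.

    ``preset`` selects the coupling weights: ``glut_stim`` (j_l=1.5,
    j_e=0.5), ``gaba_stim`` (j_l=0.5, j_e=1.5) or ``baseline``.  Pulse
    cessation shows up as a non-pulsatile classification in the results.
    """
    if preset not in COUPLING_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; use one of {list(COUPLING_PRESETS)}")
    cp = COUPLING_PRESETS[preset]
    return _coupled_sweep(
        mepd, kndy, cp, kp_grid, window, warm_start, rtol, atol,
        meta={"scenario": "projection", "preset": preset,
              "coupling": cp.to_dict(), "window": window},
    )


def sweep_antagonism(
    mepd: MePDParams,
    kndy: KNDyParams,
    which: str,
    beta_grid: Sequence[float],
    kp_grid: Sequence[float],
    coupled_cells: Sequence[tuple[float, float]] = (),
    window: float = 240.0,
    coupled_window: float = 600.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[HeatMap, list[dict[str, Any]]]:
    """Receptor-antagonism sweep over (beta, Kp).

    ``which`` is ``'beta1'`` (GABAergic suppression) or ``'beta2'``
    (glutamatergic suppression).  Every cell gets a MePD-only run (mean
    output + dynamics label, arranged as a heat map); cells listed in
    ``coupled_cells`` as ``(beta, Kp)`` pairs additionally get a full
    coupled run with KNDy IPI.
    """
    if which not in ("beta1", "beta2"):
        raise ValueError("which must be 'beta1' or 'beta2'")
    bg = np.asarray(beta_grid, float)
    kg = np.asarray(kp_grid, float)
    if bg.min() < 0 or bg.max() > 1:
        raise ValueError("beta grid must lie within [0, 1]")
    mat = np.empty((len(bg), len(kg)))
    osc = np.zeros((len(bg), len(kg)), dtype=bool)
    for i, b in enumerate(bg):
        init = None
        for j, kv in enumerate(kg):
            mpe = update(mepd, **{which: float(b), "Kp": float(kv)})
            traj = integrate(
                "mepd", mepd=mpe, init=init, t_span=(0.0, window),
                step=0.01, rtol=rtol, atol=atol,
            )
            summ = mean_outputs(traj)
            mat[i, j] = summ.mean_mepd
            osc[i, j] = classify_mepd(traj) == "oscillatory"
            init = traj.states[-1]
    heat = HeatMap(
        param_names=(which, "Kp"),
        axis1=bg,
        axis2=kg,
        matrix=mat,
        oscillatory=osc,
        output="mepd",
        meta={"scenario": "antagonism", "which": which, "window": window},
    )
    details: list[dict[str, Any]] = []
    for b, kv in coupled_cells:
        mpe = update(mepd, **{which: float(b), "Kp": float(kv)})
        _, summ, ps, label = _coupled_point(
            mpe, kndy, COUPLING_PRESETS["baseline"], None, coupled_window, rtol, atol
        )
        details.append(
            {
                which: float(b),
                "Kp": float(kv),
                "summary": summ.to_dict(),
                "pulses": ps.to_dict(),
                "label": label,
            }
        )
    return heat, details


def heatmap_mean_output(
    mepd: MePDParams,
    param_pair: tuple[str, str],
    grid1: Sequence[float],
    grid2: Sequence[float],
    output: str = "mepd",
    window: float = 240.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> HeatMap:
    """Mean-output heat map of the MePD block over any two parameters.

    ``output`` selects the functional: ``'glut'`` (mean Gl), ``'gaba'``
    (mean Ge) or ``'mepd'`` (mean Gl - Ge).  Rows are warm-started along
    the second axis.
    """
    if output not in ("glut", "gaba", "mepd"):
        raise ValueError("output must be 'glut', 'gaba' or 'mepd'")
    g1 = np.asarray(grid1, float)
    g2 = np.asarray(grid2, float)
    mat = np.empty((len(g1), len(g2)))
    osc = np.zeros((len(g1), len(g2)), dtype=bool)
    for i, v1 in enumerate(g1):
        init = None
        for j, v2 in enumerate(g2):
            mpe = update(mepd, **{param_pair[0]: float(v1), param_pair[1]: float(v2)})
            traj = integrate(
                "mepd", mepd=mpe, init=init, t_span=(0.0, window),
                step=0.01, rtol=rtol, atol=atol,
            )
            summ = mean_outputs(traj)
            mat[i, j] = {
                "glut": summ.mean_glut,
                "gaba": summ.mean_gaba,
                "mepd": summ.mean_mepd,
            }[output]
            osc[i, j] = classify_mepd(traj) == "oscillatory"
            init = traj.states[-1]
    return HeatMap(
        param_names=param_pair,
        axis1=g1,
        axis2=g2,
        matrix=mat,
        oscillatory=osc,
        output=output,
        meta={"scenario": "heatmap", "window": window},
    )


def find_gain_switch(
    mepd: MePDParams,
    kp_band: tuple[float, float] = (1.42, 2.2),
    n_grid: int = 24,
    statistic: str = "max",
    window: float = 240.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, Any]:
    """Kisspeptin level where the GABA-efferent gain flips sign.

    Sweeps Kp across the oscillatory band (warm-started long simulations),
    computes the per-cycle statistic of Ge — ``'max'``: the upper envelope
    of the limit cycle (the quantity whose rise-then-fall marks the gain
    switch), or ``'mean'``: the cycle average — and returns the location
    of its interior maximum, refined by golden-section search on the cubic
    interpolant of the grid values.

    Raises ``ValueError`` when the statistic has no interior maximum on
    the band.
    """
    if statistic not in ("max", "mean"):
        raise ValueError("statistic must be 'max' or 'mean'")
    grid = np.linspace(kp_band[0], kp_band[1], n_grid)
    vals = np.empty(n_grid)
    init = None
    for i, kv in enumerate(grid):
        mpe = update(mepd, Kp=float(kv))
        traj = integrate(
            "mepd", mepd=mpe, init=init, t_span=(0.0, window),
            step=0.005, rtol=rtol, atol=atol,
        )
        ge = traj.post_component("Ge")
        t = traj.post_times
        if statistic == "max":
            vals[i] = ge.max()
        else:
            vals[i] = np.trapezoid(ge, t) / (t[-1] - t[0])
        init = traj.states[-1]
    i_max = int(np.argmax(vals))
    if i_max in (0, n_grid - 1):
        raise ValueError(
            f"no interior maximum of cycle-{statistic} Ge on Kp band {kp_band}"
        )
    spline = CubicSpline(grid, vals)
    res = minimize_scalar(
        lambda x: -spline(x),
        bounds=(grid[max(0, i_max - 2)], grid[min(n_grid - 1, i_max + 2)]),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return {
        "Kp": float(res.x),
        "statistic": statistic,
        "value": float(spline(res.x)),
        "grid": grid.tolist(),
        "values": vals.tolist(),
    }
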