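"""Time integration of the model systems and mean-output functionals."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import make_coupled_rhs, make_kndy_rhs, make_mepd_rhs
from .params import CouplingParams, KNDyParams, MePDParams

__all__ = [
    "Trajectory",
    "OutputSummary",
    "IntegrationError",
    "integrate",
    "mean_outputs",
    "MODEL_COMPONENTS",
]

MODEL_COMPONENTS: dict[str, tuple[str, ...]] = {
    "mepd": ("Gl", "Gi", "Ge"),
    "kndy": ("D", "N", "v"),
    "coupled": ("Gl", "Gi", "Ge", "D", "N", "v"),
}

#: Default uniform output steps (min) and integration windows (min).
DEFAULT_STEP = {"mepd": 0.002, "kndy": 0.01, "coupled": 0.01}
DEFAULT_WINDOW = {"mepd": 30.0, "kndy": 600.0, "coupled": 600.0}
DEFAULT_INIT = {
    "mepd": (0.1, 0.1, 0.1),
    "kndy": (0.1, 0.1, 1.0),
    "coupled": (0.1, 0.1, 0.1, 0.1, 0.1, 1.0),
}
_SOLVER = {"mepd": "RK45", "kndy": "LSODA", "coupled": "LSODA"}


class IntegrationError(RuntimeError):
    """Solver failure, carrying the offending parameter snapshot."""


@dataclass
class Trajectory:
    """Uniformly resampled solution of one integration run.

    ``transient_end`` is the index of the first sample included in
    post-transient statistics.
    """

    times: np.ndarray
    states: np.ndarray
    components: tuple[str, ...]
    transient_end: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states row count must equal time count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.transient_end < len(self.times):
            raise ValueError("transient_end out of range")

    def component(self, name: str) -> np.ndarray:
        return self.states[:, self.components.index(name)]

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.transient_end :]

    @property
    def post_states(self) -> np.ndarray:
        return self.states[self.transient_end :]

    def post_component(self, name: str) -> np.ndarray:
        return self.post_states[:, self.components.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.components))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class OutputSummary:
    """Time-averaged circuit outputs over the post-transient window.

    ``mean_mepd = mean_glut - mean_gaba`` holds exactly (linearity of the
    trapezoidal integral).
    """

    mean_glut: float
    mean_gaba: float
    mean_mepd: float
    window: float

    def to_dict(self) -> dict[str, float]:
        return {
            "mean_glut": self.mean_glut,
            "mean_gaba": self.mean_gaba,
            "mean_mepd": self.mean_mepd,
            "window": self.window,
        }


def _rhs_for(
    model: str,
    mepd: MePDParams | None,
    kndy: KNDyParams | None,
    coupling: CouplingParams | None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    if model == "mepd":
        return make_mepd_rhs(mepd or MePDParams())
    if model == "kndy":
        return make_kndy_rhs(kndy or KNDyParams())
    if model == "coupled":
        return make_coupled_rhs(
            mepd or MePDParams(), kndy or KNDyParams(), coupling or CouplingParams()
        )
    raise ValueError(f"unknown model {model!r}")


def default_transient(t0: float, t1: float) -> float:
    """Length of the discarded transient: min(half the window, 200 min)."""
    return min(0.5 * (t1 - t0), 200.0)


def integrate(
    model: str,
    mepd: MePDParams | None = None,
    kndy: KNDyParams | None = None,
    coupling: CouplingParams | None = None,
    init: Sequence[float] | None = None,
    t_span: tuple[float, float] | None = None,
    step: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    transient: float | None = None,
    method: str | None = None,
) -> Trajectory:
    """Integrate one of the model systems and resample on a uniform grid.

    Parameters
    ----------
    model
        ``"mepd"``, ``"kndy"`` (free-running pulse generator) or
        ``"coupled"``.
    init, t_span, step
        Initial state, time window (min) and output step (min); defaults
        per model.  The run is fully deterministic.
    transient
        Length (min) of the initial segment excluded from statistics;
        default ``min(window/2, 200)``.

    Raises
    ------
    IntegrationError
        If the solver fails (e.g. step-size underflow); the message names
        the parameter set.
    """
    if model not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model!r}")
    t0, t1 = t_span if t_span is not None else (0.0, DEFAULT_WINDOW[model])
    if not t1 > t0:
        raise ValueError("t_span must satisfy t1 > t0")
    y0 = np.asarray(init if init is not None else DEFAULT_INIT[model], dtype=float)
    h = step if step is not None else DEFAULT_STEP[model]
    rhs = _rhs_for(model, mepd, kndy, coupling)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method=method or _SOLVER[model],
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        p = mepd if model == "mepd" else (mepd, kndy, coupling)
        raise IntegrationError(f"solver failed ({sol.message}) for params={p!r}")
    n = int(round((t1 - t0) / h)) + 1
    times = t0 + h * np.arange(n)
    times[-1] = min(times[-1], t1)
    states = sol.sol(times).T
    tr = transient if transient is not None else default_transient(t0, t1)
    transient_end = int(np.searchsorted(times, t0 + tr))
    transient_end = min(transient_end, len(times) - 1)
    meta = {
        "model": model,
        "t_span": (t0, t1),
        "step": h,
        "rtol": rtol,
        "atol": atol,
        "init": y0.tolist(),
        "mepd": (mepd or MePDParams()).to_dict() if model != "kndy" else None,
        "kndy": (kndy or KNDyParams()).to_dict() if model != "mepd" else None,
        "coupling": (coupling or CouplingParams()).to_dict() if model == "coupled" else None,
    }
    return Trajectory(times, states, MODEL_COMPONENTS[model], transient_end, meta)


def mean_outputs(traj: Trajectory) -> OutputSummary:
    """Trapezoidal time averages of Gl, Ge and their difference.

    Uses the post-transient window only; requires at least 2 samples and
    the MePD components to be present.
    """
    for name in ("Gl", "Ge"):
        if name not in traj.components:
            raise ValueError(f"trajectory lacks component {name!r}")
    t = traj.post_times
    if t.size < 2:
        raise ValueError("post-transient window shorter than 2 samples")
    span = t[-1] - t[0]
    gl = traj.post_component("Gl")
    ge = traj.post_component("Ge")
    mean_glut = float(np.trapezoid(gl, t) / span)
    mean_gaba = float(np.trapezoid(ge, t) / span)
    return OutputSummary(
        mean_glut=mean_glut,
        mean_gaba=mean_gaba,
        mean_mepd=mean_glut - mean_gaba,
        window=float(span),
    )
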