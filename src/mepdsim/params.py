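"""Parameter sets for the MePD circuit, the KNDy pulse generator and their coupling.

All defaults correspond to the published calibration of the two models.
Parameter sets are immutable dataclasses; use :func:`dataclasses.replace`
(re-exported here as :func:`update`) to derive modified copies.  Each set
serialises to and from a flat ASCII-keyed mapping suitable for YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields, replace as update
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "MePDParams",
    "KNDyParams",
    "CouplingParams",
    "COUPLING_PRESETS",
    "update",
    "unchecked_replace",
    "params_from_mapping",
    "load_params",
    "dump_params",
]


def unchecked_replace(obj, **changes):
    """Copy a parameter set without invariant validation.

    Continuation correctors need to evaluate the vector field at parameter
    values marginally outside the declared ranges (e.g. alpha = 1 + 1e-9
    while converging onto a boundary); the model equations remain well
    defined there.  Not part of the user-facing API.
    """
    new = object.__new__(type(obj))
    for f in fields(obj):
        object.__setattr__(new, f.name, changes.get(f.name, getattr(obj, f.name)))
    return new


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class MePDParams:
    """Parameters of the three-population GABA-glutamate circuit.

    Populations: glutamatergic neurons (Gl), GABA interneurons (Gi) and
    GABA efferent neurons (Ge).  ``Kp`` is the kisspeptin drive, split
    between Gl and Gi by the ratio ``alpha``.  ``beta1``/``beta2`` scale
    down GABAergic/glutamatergic interaction strengths to mimic receptor
    antagonism.
    """

    delta: float = 3.0      # time scaling, min^-1
    alpha: float = 0.9      # fraction of Kp routed to the glutamatergic population
    Kp: float = 0.0         # kisspeptin excitatory input, a.u.
    c_ll: float = 18.0      # Glu -> Glu self-excitation
    c_li: float = 16.0      # Glu -> GABAint excitation
    c_il: float = 35.0      # GABAint -> Glu inhibition
    c_le: float = 40.0      # Glu -> GABAeff excitation
    c_ie: float = 25.0      # GABAint -> GABAeff inhibition
    a_l: float = 1.3        # sigmoid max slopes
    a_i: float = 2.0
    a_e: float = 2.0
    theta_l: float = 4.0    # half-maximum firing thresholds
    theta_i: float = 3.7
    theta_e: float = 3.7
    beta1: float = 0.0      # GABAergic interaction suppression, [0, 1]
    beta2: float = 0.0      # glutamatergic interaction suppression, [0, 1]

    def __post_init__(self) -> None:
        _require(self.delta > 0, "delta must be > 0")
        _require(0.0 <= self.alpha <= 1.0, "alpha must lie in [0, 1]")
        _require(0.0 <= self.beta1 <= 1.0, "beta1 must lie in [0, 1]")
        _require(0.0 <= self.beta2 <= 1.0, "beta2 must lie in [0, 1]")
        _require(self.Kp >= 0.0, "Kp must be >= 0")
        for name in ("a_l", "a_i", "a_e", "theta_l", "theta_i", "theta_e"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class KNDyParams:
    """Parameters of the arcuate KNDy pulse-generator model.

    State variables are dynorphin (D, nM), neurokinin B (N, nM) and the
    population firing rate (v, spikes/min).
    """

    d_D: float = 0.2        # dynorphin degradation, min^-1
    d_N: float = 1.0        # NKB degradation, min^-1
    d_v: float = 10.0       # firing-rate reset rate, min^-1
    k_D: float = 4.0        # dynorphin secretion strength, nM/min
    k_N: float = 40.0       # NKB secretion strength, nM/min
    p_v: float = 0.006      # effective synaptic strength
    v0: float = 25000.0     # maximum firing-rate increase, spikes/min^2
    K_D: float = 0.3        # dynorphin half-inhibition, nM
    K_N: float = 4.0        # NKB half-effect, nM
    K_v1: float = 600.0     # half-maximal dynorphin secretion rate, spikes/min
    K_v2: float = 200.0     # half-maximal NKB secretion rate, spikes/min
    k: float = 10.0         # sigmoid steepness
    m: float = 0.5          # half-maximal synaptic input
    I0: float = 0.14        # basal input

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CouplingParams:
    """Weights converting MePD population activity into KNDy synaptic input.

    ``j_l`` scales the excitatory glutamatergic contribution (+j_l*Gl),
    ``j_e`` the inhibitory GABA-efferent contribution (-j_e*Ge).
    """

    j_l: float = 1.0
    j_e: float = 1.0

    def __post_init__(self) -> None:
        _require(self.j_l >= 0, "j_l must be >= 0")
        _require(self.j_e >= 0, "j_e must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: Named coupling presets: equal weighting, glutamatergic-projection
#: stimulation and GABAergic-projection stimulation.
COUPLING_PRESETS: dict[str, CouplingParams] = {
    "baseline": CouplingParams(1.0, 1.0),
    "glut_stim": CouplingParams(1.5, 0.5),
    "gaba_stim": CouplingParams(0.5, 1.5),
}

_CLASSES = (MePDParams, KNDyParams, CouplingParams)
_FIELD_OWNER: dict[str, type] = {}
for _cls in _CLASSES:
    for _f in fields(_cls):
        _FIELD_OWNER[_f.name] = _cls


def params_from_mapping(
    mapping: Mapping[str, Any],
) -> tuple[MePDParams, KNDyParams, CouplingParams]:
    """Build the three parameter sets from one flat symbol->value mapping.

    Unknown keys raise :class:`ParameterError`; missing keys take their
    defaults.
    """
    groups: dict[type, dict[str, float]] = {cls: {} for cls in _CLASSES}
    for key, value in mapping.items():
        owner = _FIELD_OWNER.get(key)
        if owner is None:
            raise ParameterError(f"unknown parameter {key!r}")
        try:
            groups[owner][key] = float(value)
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"parameter {key!r}: {exc}") from exc
    return (
        MePDParams(**groups[MePDParams]),
        KNDyParams(**groups[KNDyParams]),
        CouplingParams(**groups[CouplingParams]),
    )


def load_params(path: str | Path) -> tuple[MePDParams, KNDyParams, CouplingParams]:
    """Read a flat YAML or JSON parameter mapping from *path*."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ParameterError(f"{path}: expected a flat mapping")
    return params_from_mapping(data)


def dump_params(
    path: str | Path,
    mepd: MePDParams | None = None,
    kndy: KNDyParams | None = None,
    coupling: CouplingParams | None = None,
) -> None:
    """Write the given parameter sets as one flat mapping (YAML or JSON by suffix)."""
    flat: dict[str, float] = {}
    for obj in (mepd, kndy, coupling):
        if obj is not None:
            flat.update(obj.to_dict())
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(flat, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=True))
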