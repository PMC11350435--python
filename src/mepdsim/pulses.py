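"""Pulse-peak detection and inter-pulse-interval statistics on model traces.

The detector is a model-trace analogue of LH-pulse counting: local maxima
with a prominence floor relative to the trace range, a minimum peak
separation and an absolute amplitude floor below which the trace counts as
non-pulsatile.  A deterministic fixture generator produces synthetic
pulsatile traces with known ground-truth peak times for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = ["PulseStats", "detect_pulses", "make_pulse_fixture"]

#: 1% of the maximal sustainable firing rate v0/d_v of the KNDy model.
DEFAULT_AMPLITUDE_FLOOR = 0.01 * 25000.0 / 10.0
#: Mean level above which a non-pulsatile trace counts as saturated
#: (depolarisation block) rather than quiescent.
DEFAULT_SATURATION_LEVEL = 0.5 * 25000.0 / 10.0


@dataclass(frozen=True)
class PulseStats:
    """Detected peaks and IPI statistics of one uniformly sampled trace."""

    peak_times: np.ndarray
    ipis: np.ndarray
    mean_ipi: float
    n_pulses: int
    classification: str  # 'pulsatile' | 'quiescent' | 'saturated'
    amplitude: float     # trace max - min
    ipi_cv: float        # coefficient of variation of the IPIs (0 if < 2 IPIs)

    def to_dict(self) -> dict[str, Any]:
        return {
            "peak_times": self.peak_times.tolist(),
            "ipis": self.ipis.tolist(),
            "mean_ipi": self.mean_ipi,
            "n_pulses": self.n_pulses,
            "classification": self.classification,
            "amplitude": self.amplitude,
            "ipi_cv": self.ipi_cv,
        }


def detect_pulses(
    times: Sequence[float],
    values: Sequence[float],
    prominence_fraction: float = 0.2,
    min_distance: float = 2.0,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
    saturation_level: float = DEFAULT_SATURATION_LEVEL,
) -> PulseStats:
    """Find pulse peaks in a uniformly sampled trace and summarise IPIs.

    Peaks are local maxima with prominence at least
    ``prominence_fraction * (max - min)`` separated by at least
    ``min_distance`` minutes.  A trace is ``pulsatile`` if it has >= 3 such
    peaks and its range exceeds ``amplitude_floor``; otherwise it is
    ``saturated`` when its mean exceeds ``saturation_level`` and
    ``quiescent`` when not.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0 or v.size == 0:
        raise ValueError("empty trace")
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    if np.any(~np.isfinite(v)) or np.any(~np.isfinite(t)):
        raise ValueError("trace contains non-finite values")
    dt = float(np.median(np.diff(t)))
    rng = float(v.max() - v.min())
    if rng > 0:
        idx, _ = find_peaks(
            v,
            prominence=prominence_fraction * rng,
            distance=max(1, int(round(min_distance / dt))),
        )
    else:
        idx = np.array([], dtype=int)
    peak_times = t[idx]
    ipis = np.diff(peak_times)
    n = len(peak_times)
    if n >= 3 and rng >= amplitude_floor:
        cls = "pulsatile"
    elif float(v.mean()) >= saturation_level:
        cls = "saturated"
    else:
        cls = "quiescent"
        if rng < amplitude_floor:
            peak_times = np.array([])
            ipis = np.array([])
            n = 0
    mean_ipi = float(ipis.mean()) if ipis.size else float("nan")
    cv = float(ipis.std() / ipis.mean()) if ipis.size >= 2 and ipis.mean() > 0 else 0.0
    return PulseStats(
        peak_times=peak_times,
        ipis=ipis,
        mean_ipi=mean_ipi,
        n_pulses=n,
        classification=cls,
        amplitude=rng,
        ipi_cv=cv,
    )


def make_pulse_fixture(
    peak_times: Sequence[float],
    widths: float | Sequence[float] = 1.0,
    amplitudes: float | Sequence[float] = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    step: float = 0.05,
    pad: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Generate a synthetic pulsatile trace of Gaussian bumps plus noise.

    Returns ``(times, values, truth)`` where ``truth`` records the
    generating peak times, bump parameters and seed.  Deterministic for a
    fixed seed.  Bumps closer than one width apart are flagged with a
    warning entry in the truth metadata (their maxima may merge).
    """
    centres = np.asarray(peak_times, dtype=float)
    if centres.size == 0:
        raise ValueError("need at least one peak time")
    if np.any(np.diff(centres) <= 0):
        raise ValueError("peak times must be strictly increasing")
    w = np.broadcast_to(np.asarray(widths, dtype=float), centres.shape).copy()
    amp = np.broadcast_to(np.asarray(amplitudes, dtype=float), centres.shape).copy()
    warnings: list[str] = []
    gaps = np.diff(centres)
    too_close = gaps < np.maximum(w[:-1], w[1:])
    for i in np.flatnonzero(too_close):
        warnings.append(
            f"bumps at t={centres[i]:g} and t={centres[i + 1]:g} overlap "
            f"(gap {gaps[i]:g} < width)"
        )
    t0 = max(0.0, centres[0] - pad)
    t1 = centres[-1] + pad
    times = t0 + step * np.arange(int(round((t1 - t0) / step)) + 1)
    values = np.zeros_like(times)
    for c, wi, ai in zip(centres, w, amp):
        values += ai * np.exp(-0.5 * ((times - c) / wi) ** 2)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    truth = {
        "peak_times": centres.tolist(),
        "widths": w.tolist(),
        "amplitudes": amp.tolist(),
        "noise_sd": noise_sd,
        "seed": seed,
        "step": step,
        "warnings": warnings,
    }
    return times, values, truth
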