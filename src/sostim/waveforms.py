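"""Stimulation waveform families and their time-bin representation.

Four parametric families are supported, all defined on the one-second
stimulation window t ∈ [0, 1] s:

- ``W1``: single sinusoid            A·sin(2πft − φ) + O
- ``W2``: sum of three sinusoids     Σᵢ Aᵢ·sin(2πfᵢt − φᵢ) + O
- ``W3``: square wave with duty D    A·square(2πft − φ, D) + O
- ``W4``: cubic polynomial           p₁(t−φ)³ + p₂(t−φ)² + p₃(t−φ) + p₄

Waveforms are evaluated on a fine 0.1 ms grid and reduced to per-bin
average amplitudes at one of the supported bin widths Δt ∈ {20, 50, 100,
200} ms; that binned vector is what the linear forward model scales into
a region-by-time current-density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

VALID_DT_MS = (20, 50, 100, 200)

#: encoding resolution of the waveform time grid, seconds
TIME_STEP = 1e-4

#: parameter names per family, in canonical order
PARAM_NAMES = {
    "W1": ("A", "f", "phi", "O"),
    "W2": ("A1", "A2", "A3", "f1", "f2", "f3", "phi1", "phi2", "phi3", "O"),
    "W3": ("A", "f", "phi", "D", "O"),
    "W4": ("p1", "p2", "p3", "p4", "phi"),
}

_AMP_B = (0.0, 1.0)
_FREQ_B = (0.01, 4.0)
_PHASE_B = (-np.pi, np.pi)
_OFFSET_B = (0.0, 1.0)
_DUTY_B = (0.0, 100.0)
_POLY_B = (-1.0, 1.0)

_DEFAULT_BOUNDS = {
    "W1": (_AMP_B, _FREQ_B, _PHASE_B, _OFFSET_B),
    "W2": (_AMP_B, _AMP_B, _AMP_B, _FREQ_B, _FREQ_B, _FREQ_B,
           _PHASE_B, _PHASE_B, _PHASE_B, _OFFSET_B),
    "W3": (_AMP_B, _FREQ_B, _PHASE_B, _DUTY_B, _OFFSET_B),
    "W4": (_POLY_B, _POLY_B, _POLY_B, _POLY_B, _PHASE_B),
}


def default_bounds(kind: str) -> tuple[tuple[float, float], ...]:
    """Per-parameter (lo, hi) search bounds for a waveform family.

    Amplitudes and offsets span [0, 1] (dimensionless scaling of the
    unit-amplitude transfer vector), frequencies [0.01, 4] Hz, phases
    [−π, π] rad, the square-wave duty cycle [0, 100] % and polynomial
    coefficients [−1, 1].
    """
    if kind not in _DEFAULT_BOUNDS:
        raise ValueError(f"unknown waveform kind {kind!r}")
    return _DEFAULT_BOUNDS[kind]


def eval_many(kind: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a batch of parameter vectors of one family on a time grid.

    Parameters
    ----------
    kind : one of ``W1``..``W4``.
    params : array (k, n_params); each row a full parameter vector.
    t : array (nt,), seconds, inside [0, 1].

    Returns
    -------
    array (k, nt) of amplitudes.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    t = np.asarray(t, dtype=float)
    if t.size and (t.min() < 0 or t.max() > 1):
        raise ValueError("time points must lie in [0, 1] s")
    n_expected = len(PARAM_NAMES.get(kind, ()))
    if n_expected == 0:
        raise ValueError(f"unknown waveform kind {kind!r}")
    if params.shape[1] != n_expected:
        raise ValueError(
            f"{kind} takes {n_expected} parameters, got {params.shape[1]}"
        )
    tt = t[None, :]
    if kind == "W1":
        A, f, phi, O = (params[:, i, None] for i in range(4))
        return A * np.sin(2 * np.pi * f * tt - phi) + O
    if kind == "W2":
        out = params[:, 9, None] * np.ones_like(tt)
        for i in range(3):
            A = params[:, i, None]
            f = params[:, 3 + i, None]
            phi = params[:, 6 + i, None]
            out = out + A * np.sin(2 * np.pi * f * tt - phi)
        return out
    if kind == "W3":
        A, f, phi, D, O = (params[:, i, None] for i in range(5))
        # scipy's square() is +1 for the first `duty` fraction of each period
        out = signal.square(2 * np.pi * f * tt - phi, duty=D / 100.0)
        return A * out + O
    # W4: cubic polynomial in (t − phi)
    p1, p2, p3, p4, phi = (params[:, i, None] for i in range(5))
    x = tt - phi
    return ((p1 * x + p2) * x + p3) * x + p4


@dataclass(frozen=True)
class Waveform:
    """One member of a waveform family: a kind plus a full parameter vector."""

    kind: str
    params: tuple[float, ...]
    bounds: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = PARAM_NAMES.get(self.kind)
        if names is None:
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != len(names):
            raise ValueError(
                f"{self.kind} takes {len(names)} parameters "
                f"({', '.join(names)}), got {len(self.params)}"
            )
        if self.bounds is None:
            object.__setattr__(self, "bounds", default_bounds(self.kind))

    @property
    def n_params(self) -> int:
        return len(self.params)

    def __call__(self, t) -> np.ndarray | float:
        return eval_waveform(self, t)


def eval_waveform(w: Waveform, t) -> np.ndarray | float:
    """Amplitude of waveform ``w`` at time(s) ``t`` (seconds in [0, 1])."""
    t_arr = np.asarray(t, dtype=float)
    out = eval_many(w.kind, np.asarray(w.params)[None, :], np.atleast_1d(t_arr))[0]
    return float(out[0]) if t_arr.ndim == 0 else out


@dataclass(frozen=True)
class BinnedWaveform:
    """Average amplitude of a waveform within each Δt bin of [0, 1] s."""

    dt: int
    means: np.ndarray

    def __post_init__(self) -> None:
        if self.dt not in VALID_DT_MS:
            raise ValueError(f"dt must be one of {VALID_DT_MS}, got {self.dt}")
        means = np.asarray(self.means, dtype=float)
        if means.shape != (1000 // self.dt,):
            raise ValueError(
                f"expected {1000 // self.dt} bins for dt={self.dt} ms, "
                f"got shape {means.shape}"
            )
        object.__setattr__(self, "means", means)

    @property
    def n_bins(self) -> int:
        return len(self.means)


def time_grid() -> np.ndarray:
    """Midpoints of the 0.1 ms encoding grid over [0, 1] s."""
    n = int(round(1.0 / TIME_STEP))
    return (np.arange(n) + 0.5) * TIME_STEP


def bin_many(kind: str, params: np.ndarray, dt: int) -> np.ndarray:
    """Bin-average a batch of waveforms: (k, n_params) → (k, 1000/dt)."""
    if dt not in VALID_DT_MS:
        raise ValueError(f"dt must be one of {VALID_DT_MS}, got {dt}")
    grid = time_grid()
    vals = eval_many(kind, params, grid)
    m = 1000 // dt
    return vals.reshape(vals.shape[0], m, -1).mean(axis=2)


def bin_waveform(w: Waveform, dt: int) -> BinnedWaveform:
    """Reduce a waveform to per-bin average amplitudes at bin width ``dt`` ms."""
    means = bin_many(w.kind, np.asarray(w.params)[None, :], dt)[0]
    return BinnedWaveform(dt=dt, means=means)
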