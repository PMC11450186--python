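"""Shunting-inhibition divisive-normalization circuit model of Tm1/Tm9.

A transmedullary neuron receives a main lamina input I(t) (L2 for Tm1, L3
for Tm9) and is divisively normalized by a wide-field neuron that pools
lamina responses from several medulla columns:

    R(t) = I(t) / (g_l + J(t)^p),    J(t) = sum over columns of I_i(t)

with leak conductance g_l and an integer normalization exponent p (1 for
Tm1, 2 for Tm9).  Columns sit on a 1-D row at the 5-degree medulla-column
pitch within the pooling diameter (a 15-degree pool spans three columns).

The contrast read-out simulates many sinusoidal gratings with random spatial
phase, computes the F1 amplitude of the response at each mean luminance, and
summarizes the luminance dependence by the slope of the max-normalized F1
curve against log10 luminance.  Divisive normalization with p = 1 makes this
slope nearly vanish (luminance invariance); p = 2 turns it negative
(low-luminance enhancement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DivisionDegenerateError, InvalidSpecError
from .lmc_model import MembraneParams, membrane_calcium_response
from .natural_scenes import COLUMN_PITCH_DEG
from .stimuli import GratingSpec

__all__ = [
    "NormalizationParams",
    "CircuitResponseCurve",
    "PROTOCOL_LUMINANCES_PHOTONS",
    "pool_inputs",
    "tm_response",
    "column_offsets",
    "simulate_contrast_curves",
    "calibrate_leak_conductance",
]

#: Grating mean luminances as printed, photons s^-1 photoreceptor^-1.
PROTOCOL_LUMINANCES_PHOTONS = (1.2e4, 2.6e4, 5.3e4, 7.9e4, 10.6e4)


@dataclass(frozen=True)
class NormalizationParams:
    """Leak conductance, pooling extent and exponent of the Tm circuit."""

    g_l: float = 1.0
    p: int = 1
    pooling_diameter: float = 15.0
    input_cell: str = "L2"
    input_params: MembraneParams = field(default_factory=MembraneParams)

    def __post_init__(self) -> None:
        if self.g_l <= 0:
            raise InvalidSpecError("leak conductance must be positive")
        if int(self.p) != self.p:
            raise InvalidSpecError("normalization exponent must be an integer")


def pool_inputs(input_responses: np.ndarray) -> np.ndarray:
    """Pooled wide-field signal J(t): sum of column responses.

    ``input_responses`` has columns on the leading axis; a single series
    passes through unchanged.
    """
    arr = np.asarray(input_responses, dtype=np.float64)
    if arr.size == 0:
        raise InvalidSpecError("empty pooling region")
    if arr.ndim == 1:
        return arr.copy()
    return arr.sum(axis=0)


def tm_response(I: np.ndarray, J: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Elementwise shunting normalization I / (g_l + J^p)."""
    I = np.asarray(I, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    if I.shape != J.shape:
        raise InvalidSpecError("main and pooled inputs must share a shape")
    div = params.g_l + J ** params.p
    if np.any(div == 0):
        raise DivisionDegenerateError("g_l + J^p vanishes")
    return I / div


def column_offsets(pooling_diameter: float, pitch: float = COLUMN_PITCH_DEG) -> np.ndarray:
    """Azimuthal positions (degrees) of columns on a 1-D row within the pool.

    Columns at integer multiples of the pitch whose centers lie within
    pooling_diameter / 2 of the central column; 15 degrees -> three columns.
    """
    k = int(np.floor(pooling_diameter / 2.0 / pitch + 1e-9))
    return np.arange(-k, k + 1, dtype=np.float64) * pitch


@dataclass
class CircuitResponseCurve:
    """Mean F1 amplitude per luminance with the log-luminance slope."""

    luminances: np.ndarray
    f1: np.ndarray
    slope: float
    n_traces: int
    seed: int | None
    params: NormalizationParams | None = None

    def to_csv(self, path) -> None:
        pd.DataFrame({"mean_luminance": self.luminances, "f1_amplitude": self.f1}).to_csv(
            path, index=False
        )


def _normalized_slope(luminances: np.ndarray, f1: np.ndarray) -> float:
    """Slope of F1/max(F1) versus log10 luminance (recordings are normalized per fly)."""
    peak = f1.max()
    y = f1 / peak if peak > 0 else f1
    return float(np.polyfit(np.log10(luminances), y, 1)[0])


def _simulate_f1(
    params: NormalizationParams | None,
    grating: GratingSpec,
    luminances: np.ndarray,
    phases: np.ndarray,
    n_samples: int = 200,
) -> np.ndarray:
    """Mean F1 across traces for each luminance.

    ``params=None`` simulates the un-normalized lamina input itself.
    One period of the grating is simulated per trace; columns see the same
    temporal phase shifted by their spatial offset along the grating.
    """
    membrane = params.input_params if params is not None else MembraneParams()
    offs = (
        column_offsets(params.pooling_diameter)
        if params is not None
        else np.array([0.0])
    )
    spatial_phase = 2 * np.pi * offs / grating.spatial_wavelength
    t = np.arange(n_samples) / n_samples  # one temporal period
    # angle: (trace, column, time)
    theta = (
        phases[:, None, None]
        + spatial_phase[None, :, None]
        + 2 * np.pi * t[None, None, :]
    )
    f1_per_lum = np.empty(len(luminances))
    for i, L in enumerate(luminances):
        s = L * (1.0 + grating.michelson_contrast * np.sin(theta))
        resp = membrane_calcium_response(s, membrane)
        center = resp[:, len(offs) // 2, :]
        if params is None:
            out = center
        else:
            J = resp.sum(axis=1)
            out = tm_response(center, J, params)
        spec = np.fft.rfft(out, axis=-1)
        f1_per_lum[i] = float(np.mean(2.0 * np.abs(spec[..., 1]) / n_samples))
    return f1_per_lum


def simulate_contrast_curves(
    params: NormalizationParams | None,
    grating: GratingSpec | None = None,
    n_traces: int = 1000,
    seed: int = 0,
    luminances=PROTOCOL_LUMINANCES_PHOTONS,
    phases: np.ndarray | None = None,
) -> CircuitResponseCurve:
    """F1-vs-luminance curve of the normalized (or raw lamina) model.

    Draws ``n_traces`` uniform random spatial phases (shared across columns
    up to the per-column offset), simulates one grating period per trace,
    averages F1 amplitudes, and fits the slope of the max-normalized curve
    against log10 luminance.  ``params=None`` yields the un-normalized
    lamina control.  Luminances default to the five printed photon rates.
    """
    if n_traces < 1:
        raise InvalidSpecError("need at least one trace")
    grating = grating or GratingSpec()
    luminances = np.asarray(luminances, dtype=np.float64)
    if phases is None:
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0.0, 2 * np.pi, size=n_traces)
    else:
        phases = np.asarray(phases, dtype=np.float64)
    f1 = _simulate_f1(params, grating, luminances, phases)
    return CircuitResponseCurve(
        luminances=luminances,
        f1=f1,
        slope=_normalized_slope(luminances, f1),
        n_traces=len(phases),
        seed=seed,
        params=params,
    )


@lru_cache(maxsize=8)
def calibrate_leak_conductance(
    pooling_diameter: float = 15.0,
    seed: int = 0,
    n_phases: int = 64,
) -> float:
    """Leak conductance g_l making the p=1 circuit maximally luminance-invariant.

    One-dimensional minimization of |slope| of the p=1 model at the given
    pooling diameter over log10 g_l, with evenly spaced phases for a smooth
    objective.  g_l is not experimentally constrained; this provides the default.
    """
    phases = np.linspace(0.0, 2 * np.pi, n_phases, endpoint=False)
    grating = GratingSpec()
    lum = np.asarray(PROTOCOL_LUMINANCES_PHOTONS)

    def objective(log_gl: float) -> float:
        p = NormalizationParams(g_l=10.0**log_gl, p=1, pooling_diameter=pooling_diameter)
        f1 = _simulate_f1(p, grating, lum, phases)
        return abs(_normalized_slope(lum, f1))

    res = minimize_scalar(objective, bounds=(-3.0, 8.0), method="bounded")
    return float(10.0**res.x)
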