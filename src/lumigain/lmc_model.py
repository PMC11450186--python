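"""Effective membrane / calcium model of lamina monopolar cells (L2/L3).

The model is a single-compartment membrane whose voltage relaxes towards a
leak value ``v_L`` plus a conductance-scaled stimulus ``g^-1 s(t)``.  Because
the membrane integrates much faster than the stimulus changes, the
pseudo-stationary voltage v = v_L + g^-1 s(t) is used throughout; an explicit
Euler integrator of the relaxation dynamics is provided for validation only.
The calcium-proxy output passes the voltage through a ramp rectifier and a
square: response = alpha * max(v_L + g^-1 s, 0)^2.

Gauge note: whenever the rectifier never engages (v stays positive, which
holds for every non-negative stimulus when v_L > 0), the response is exactly
invariant under (g^-1, v_L, alpha) -> (k g^-1, k v_L, alpha / k^2).  Only two
parameter combinations are then identifiable from response data, and fits are
reported in the gauge where v_L equals a caller-chosen reference value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateFitWarning, FitDegenerateError, InvalidSpecError
from .stimuli import GratingSpec

__all__ = [
    "MembraneParams",
    "L3_DEFAULT_PARAMS",
    "ContrastResponseTable",
    "membrane_calcium_response",
    "membrane_voltage_euler",
    "respond_to_scene",
    "simulate_grating_f1",
    "fit_membrane_params",
    "MembraneFit",
]


@dataclass(frozen=True)
class MembraneParams:
    """Inverse conductance, leak voltage and output gain of the LMC model."""

    g_inv: float = 0.05
    v_l: float = 0.3
    alpha: float = 4.0

    def __post_init__(self) -> None:
        if self.g_inv < 0 or self.alpha < 0:
            raise InvalidSpecError("g_inv and alpha must be non-negative")


#: Parameters reproducing L3 calcium contrast responses to 1 Hz gratings.
L3_DEFAULT_PARAMS = MembraneParams(g_inv=0.05, v_l=0.3, alpha=4.0)


@dataclass
class ContrastResponseTable:
    """Fit target: rows of (luminance, michelson_contrast, response)."""

    luminance: np.ndarray
    contrast: np.ndarray
    response: np.ndarray
    cell_type: str = ""
    signal: str = ""

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=np.float64)
        if not (len(self.luminance) == len(self.contrast) == len(self.response)):
            raise InvalidSpecError("table columns must share a length")
        if np.any(self.luminance <= 0):
            raise InvalidSpecError("luminances must be positive")
        if np.any(self.response < 0):
            raise InvalidSpecError("responses must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "ContrastResponseTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            luminance=df["luminance"].to_numpy(),
            contrast=df["contrast"].to_numpy(),
            response=df["response"].to_numpy(),
            cell_type=str(df["cell_type"].iloc[0]) if "cell_type" in df else "",
            signal=str(df["signal"].iloc[0]) if "signal" in df else "",
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "luminance": self.luminance,
                "contrast": self.contrast,
                "response": self.response,
                "cell_type": self.cell_type,
                "signal": self.signal,
            }
        ).to_csv(path, index=False)


def membrane_calcium_response(s, params: MembraneParams) -> np.ndarray:
    """Calcium proxy alpha * max(v_L + g^-1 s, 0)^2, elementwise."""
    s = np.asarray(s, dtype=np.float64)
    v = params.v_l + params.g_inv * s
    return params.alpha * np.square(np.clip(v, 0.0, None))


def membrane_voltage_euler(
    s: np.ndarray, params: MembraneParams, dt: float, tau: float = 0.01
) -> np.ndarray:
    """Explicit-Euler integration of dv/dt = (-(v - v_L) + g^-1 s) / tau.

    Validation-only path: with tau much smaller than the stimulus timescale
    the trajectory converges to the pseudo-stationary voltage.
    """
    s = np.asarray(s, dtype=np.float64)
    v = np.empty_like(s)
    v0 = params.v_l + params.g_inv * s[0]
    v[0] = v0
    for i in range(1, len(s)):
        v[i] = v[i - 1] + dt / tau * (-(v[i - 1] - params.v_l) + params.g_inv * s[i])
    return v


def respond_to_scene(scene: np.ndarray, params: MembraneParams) -> np.ndarray:
    """Pixelwise calcium-proxy response to a luminance image."""
    scene = np.asarray(scene, dtype=np.float64)
    if np.any(scene < 0) or not np.all(np.isfinite(scene)):
        raise InvalidSpecError("scene luminance must be finite and non-negative")
    return membrane_calcium_response(scene, params)


def simulate_grating_f1(
    params: MembraneParams,
    luminance,
    contrast,
    temporal_frequency: float = 1.0,
    n_samples: int = 256,
) -> np.ndarray:
    """F1 amplitude of the model response to full-field sinusoidal gratings.

    The stimulus at one retinal point is s(t) = L (1 + C sin(2 pi f t)); the
    response is evaluated over exactly one period so the Fourier amplitude at
    f is exact to quadrature accuracy.
    """
    L = np.atleast_1d(np.asarray(luminance, dtype=np.float64))
    C = np.atleast_1d(np.asarray(contrast, dtype=np.float64))
    L, C = np.broadcast_arrays(L, C)
    t = np.arange(n_samples) / n_samples  # one period, f*t in [0, 1)
    s = L[..., None] * (1.0 + C[..., None] * np.sin(2 * np.pi * t))
    r = membrane_calcium_response(s, params)
    spec = np.fft.rfft(r, axis=-1)
    return 2.0 * np.abs(spec[..., 1]) / n_samples


@dataclass
class MembraneFit:
    """Fitted parameters with optimization diagnostics."""

    params: MembraneParams
    residual_norm: float
    n_restarts: int
    restart_costs: list
    gauge_normalized: bool


_BOUNDS = (np.array([0.0, -1.0, 0.0]), np.array([1.0, 1.0, 100.0]))


def fit_membrane_params(
    data: ContrastResponseTable,
    stimulus_model: GratingSpec | None = None,
    n_restarts: int = 8,
    seed: int = 0,
    v_l_reference: float = 0.3,
) -> MembraneFit:
    """Least-squares fit of simulated grating F1 amplitudes to measured ones.

    Bounded nonlinear least squares (g^-1 in [0,1], v_L in [-1,1], alpha in
    [0,100]) with seeded random restarts.  When the best solution lies on the
    rectifier-inactive gauge ridge, it is rescaled so v_L equals
    ``v_l_reference`` (the rescaling is accepted only if it does not increase
    the cost).
    """
    if len(np.unique(data.luminance)) < 3:
        raise FitDegenerateError("need at least 3 distinct luminances to fit")
    if np.all(data.response == 0):
        # null data: the canonical degenerate solution is zero output gain
        warnings.warn(
            "fit is degenerate: responses are identically zero",
            DegenerateFitWarning,
            stacklevel=2,
        )
        return MembraneFit(
            params=MembraneParams(g_inv=0.05, v_l=v_l_reference, alpha=0.0),
            residual_norm=0.0,
            n_restarts=0,
            restart_costs=[],
            gauge_normalized=False,
        )
    tf = stimulus_model.temporal_frequency if stimulus_model is not None else 1.0

    L, C, y = data.luminance, data.contrast, data.response

    def residuals(theta):
        p = MembraneParams(*theta)
        return simulate_grating_f1(p, L, C, temporal_frequency=tf) - y

    rng = np.random.default_rng(seed)
    lo, hi = _BOUNDS
    starts = [np.array([0.05, 0.3, 4.0])]
    starts += [lo + rng.random(3) * (hi - lo) for _ in range(n_restarts)]

    best, costs = None, []
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=_BOUNDS)
        costs.append(float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol

    theta = best.x.copy()
    gauge = False
    if theta[1] != 0 and v_l_reference != 0 and np.sign(theta[1]) == np.sign(v_l_reference):
        k = v_l_reference / theta[1]
        cand = np.array([theta[0] * k, v_l_reference, theta[2] / k**2])
        if np.all(cand >= lo) and np.all(cand <= hi):
            c_cand = 0.5 * float(np.sum(residuals(cand) ** 2))
            if c_cand <= best.cost * (1 + 1e-9) + 1e-15:
                theta, gauge = cand, True

    params = MembraneParams(*theta)
    if params.alpha < 1e-8 or np.all(y == 0):
        warnings.warn(
            "fit is degenerate: output gain indistinguishable from zero",
            DegenerateFitWarning,
            stacklevel=2,
        )
    return MembraneFit(
        params=params,
        residual_norm=float(np.sqrt(2 * best.cost)),
        n_restarts=len(starts),
        restart_costs=costs,
        gauge_normalized=gauge,
    )
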