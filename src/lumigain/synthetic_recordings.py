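"""Ground-truth synthetic ROI recordings.

Generates GCaMP-like fluorescence traces from linear-nonlinear model neurons
with known Gaussian receptive fields, known temporal kernels and known
luminance-gain laws, so every stage of the imaging-analysis pipeline can be
validated against closed-form ground truth without any recorded data.

Gain laws (P = slow full-field background luminance of the stimulus):
``luminance_scaling`` leaves the contrast drive untouched, so response
amplitude grows with luminance (lamina-like); ``luminance_invariant``
divides by (g0 + P) (Tm1-like); ``low_luminance_enhancing`` divides by
(g0 + P^2) (Tm9-like).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidSpecError
from .imaging_analysis import RoiTraceSet
from .stimuli import StimulusMovie

__all__ = [
    "GroundTruthNeuron",
    "RecordingManifest",
    "generate_recording",
    "biexponential_kernel",
]

GAIN_LAWS = ("luminance_scaling", "luminance_invariant", "low_luminance_enhancing")


@dataclass(frozen=True)
class GroundTruthNeuron:
    """Planted linear-nonlinear neuron."""

    rf_center: tuple[float, float] = (0.0, 0.0)  # (azimuth, elevation) degrees
    rf_sigma: float = 4.0
    gain_law: str = "luminance_scaling"
    polarity: str = "OFF"
    noise_sd: float = 0.0
    temporal_kernel: str | tuple = "biexponential"  # or "delta" or sample tuple

    def __post_init__(self) -> None:
        if self.rf_sigma <= 0:
            raise InvalidSpecError("rf_sigma must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.gain_law not in GAIN_LAWS:
            raise InvalidSpecError(f"unknown gain law {self.gain_law!r}")
        if self.polarity not in ("ON", "OFF"):
            raise InvalidSpecError("polarity must be 'ON' or 'OFF'")


@dataclass(frozen=True)
class RecordingManifest:
    """Recording-session description: neurons, scan rate, trials, seed."""

    neurons: tuple
    frame_rate: float = 12.0  # two-photon scan rate, typically 10-15 Hz
    n_trials: int = 3
    seed: int = 0
    response_amplitude: float = 0.3  # peak |dF/F| of the noiseless response
    baseline_fluorescence: float = 100.0
    g0: float = 1e-3  # leak of the divisive gain laws, normalized units

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.n_trials < 1:
            raise InvalidSpecError("frame rate and trial count must be positive")


def biexponential_kernel(
    frame_rate: float, rise: float = 0.05, decay: float = 0.4, duration: float = 2.0
) -> np.ndarray:
    """Unit-area calcium-indicator kernel (1 - e^-t/rise) e^-t/decay."""
    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    h = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return h / h.sum()


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def generate_recording(
    manifest: RecordingManifest,
    movie: StimulusMovie,
    background_smoothing: float = 0.0,
) -> tuple[RoiTraceSet, dict]:
    """Simulate fluorescence traces of the manifest's neurons to a movie.

    Per neuron: the movie is weighted by a Gaussian receptive field, the
    slow full-field luminance is subtracted to form a contrast drive, the
    gain law is applied, the result is convolved with the temporal kernel,
    rescaled to the target dF/F amplitude, sampled at the scan rate, and
    repeated over trials with fresh seeded Gaussian noise.  Returns the
    trace set plus a ground-truth sidecar holding every internal signal.
    """
    nT, ny, nx = movie.frames.shape
    half_w = nx * movie.degrees_per_pixel / 2.0
    half_h = ny * movie.degrees_per_pixel / 2.0
    x = (np.arange(nx) + 0.5) * movie.degrees_per_pixel - half_w
    y = (np.arange(ny) + 0.5) * movie.degrees_per_pixel - half_h

    flat = movie.frames.reshape(nT, -1)
    # full-field background luminance: the spatial mean of each frame (exact
    # for full-field gratings spanning whole wavelengths; optionally smoothed)
    P = _moving_average(
        flat.mean(axis=1),
        max(1, int(round(background_smoothing * movie.frame_rate))),
    )

    t_movie = np.arange(nT) / movie.frame_rate
    duration = nT / movie.frame_rate
    n_scan = int(np.floor(duration * manifest.frame_rate))
    t_scan = np.arange(n_scan) / manifest.frame_rate

    rng = np.random.default_rng(manifest.seed)
    traces, gt_neurons = [], []
    for neuron in manifest.neurons:
        cx, cy = neuron.rf_center
        if not (-half_w <= cx <= half_w and -half_h <= cy <= half_h):
            raise GeometryError("receptive-field center outside the movie")
        xx, yy = np.meshgrid(x, y)
        w = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * neuron.rf_sigma**2)))
        w = (w / w.sum()).ravel()

        drive = flat @ w
        contrast = drive - P
        if neuron.polarity == "OFF":
            contrast = -contrast
        if neuron.gain_law == "luminance_invariant":
            contrast = contrast / (manifest.g0 + P)
        elif neuron.gain_law == "low_luminance_enhancing":
            contrast = contrast / (manifest.g0 + P**2)

        if neuron.temporal_kernel == "biexponential":
            h = biexponential_kernel(movie.frame_rate)
        elif neuron.temporal_kernel == "delta":
            h = np.array([1.0])
        else:
            h = np.asarray(neuron.temporal_kernel, dtype=np.float64)
        r = np.convolve(contrast, h)[:nT]

        peak = np.max(np.abs(r))
        scale = manifest.response_amplitude / peak if peak > 0 else 1.0
        r_rel = scale * r
        r_scan = np.interp(t_scan, t_movie, r_rel)

        sd = float(r_scan.std())
        trial_traces = [
            manifest.baseline_fluorescence
            * (1.0 + r_scan + neuron.noise_sd * sd * rng.standard_normal(n_scan))
            for _ in range(manifest.n_trials)
        ]
        traces.append(np.concatenate(trial_traces))
        gt_neurons.append(
            {
                "rf_center": list(neuron.rf_center),
                "rf_sigma": neuron.rf_sigma,
                "gain_law": neuron.gain_law,
                "polarity": neuron.polarity,
                "noise_sd": neuron.noise_sd,
                "amplitude_scale": float(scale),
                "response": r_scan,
            }
        )

    trial_bounds = [
        (i * n_scan, (i + 1) * n_scan) for i in range(manifest.n_trials)
    ]
    labels_scan = movie.epoch_labels[
        np.clip((t_scan * movie.frame_rate).astype(int), 0, nT - 1)
    ]
    recording = RoiTraceSet(
        traces=np.vstack(traces),
        frame_rate=manifest.frame_rate,
        trial_bounds=trial_bounds,
        epoch_labels=np.tile(labels_scan, manifest.n_trials),
    )
    sidecar = {
        "seed": manifest.seed,
        "frame_rate": manifest.frame_rate,
        "n_trials": manifest.n_trials,
        "neurons": gt_neurons,
    }
    return recording, sidecar


def save_sidecar(sidecar: dict, path) -> None:
    """Write the ground-truth sidecar as JSON (arrays become lists)."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as f:
        json.dump(sidecar, f, default=default)
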