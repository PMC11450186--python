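"""Natural-scene ensembles, trajectory sampling and the pooling-size loss.

A scene ensemble renders one underlying reflectance field under several
illumination conditions ("sunny" = brighter mean with stronger spatially
structured illumination, "shaded" = dimmer and more diffuse).  LMC responses
to each condition are normalized by a spatially pooled background, sampled
along stochastic forward-wave trajectories, and the resulting contrast
distributions are compared between conditions with 1-D Wasserstein
distances.  The pooling loss trades off convergence of the distributions
across conditions against preservation of contrast structure, and scanning
it over pooling diameters exposes the optimal local pooling extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gaussian_kde, wasserstein_distance

from .errors import DivisionDegenerateError, InvalidSpecError
from .lmc_model import MembraneParams, respond_to_scene

__all__ = [
    "Scene",
    "SceneEnsemble",
    "EnsembleParams",
    "Trajectory",
    "ContrastDistribution",
    "PoolingScanResult",
    "COLUMN_PITCH_DEG",
    "synthesize_scene_ensemble",
    "simulate_trajectory",
    "sample_contrast_responses",
    "disc_pooled_mean",
    "normalize_by_pooled_luminance",
    "normalize_by_pooled_response",
    "wasserstein_1d",
    "pooling_loss",
    "scan_pooling_sizes",
]

#: Angular pitch of one medulla column (degrees of visual space).
COLUMN_PITCH_DEG = 5.0


@dataclass
class Scene:
    """One luminance rendering of a scene under a given illumination."""

    luminance: np.ndarray
    degrees_per_pixel: float
    condition_label: str = ""
    seed: int | None = None
    mean_gain: float = 1.0

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance, dtype=np.float64)
        if np.any(self.luminance < 0) or not np.all(np.isfinite(self.luminance)):
            raise InvalidSpecError("scene luminance must be finite and non-negative")

    def to_tiff(self, path) -> None:
        import json
        import tifffile

        tifffile.imwrite(path, self.luminance.astype(np.float32))
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as f:
            json.dump(
                {
                    "degrees_per_pixel": self.degrees_per_pixel,
                    "condition_label": self.condition_label,
                    "seed": self.seed,
                },
                f,
            )


@dataclass(frozen=True)
class EnsembleParams:
    """Generator settings for a synthetic scene ensemble.

    The reflectance field has an isotropic power-law amplitude spectrum
    (exponent ``spectral_exponent``) in log space with standard deviation
    ``log_reflectance_sd``; each condition multiplies it by a smooth
    log-normal illumination field (correlation scale
    ``illumination_scale_deg``, strength per condition) and rescales to an
    exact target mean.  Conditions are (label, mean, illumination strength,
    illumination substream) tuples; the default four conditions realize two
    global gains x two illumination fields.
    """

    size: int = 256
    degrees_per_pixel: float = 0.25
    spectral_exponent: float = 1.0
    log_reflectance_sd: float = 0.8
    illumination_scale_deg: float = 8.0
    conditions: tuple = (
        ("shaded-a", 0.1, 0.15, 0),
        ("shaded-b", 0.1, 0.15, 1),
        ("sunny-a", 0.4, 0.5, 0),
        ("sunny-b", 0.4, 0.5, 1),
    )

    def __post_init__(self) -> None:
        if self.size < 16:
            raise InvalidSpecError("scene side must be at least 16 pixels")
        if self.spectral_exponent <= 0:
            raise InvalidSpecError("spectral exponent must be positive")


@dataclass
class SceneEnsemble:
    """>= 2 renderings of one reflectance field under different illumination."""

    scenes: list
    params: EnsembleParams
    seed: int

    def __post_init__(self) -> None:
        shapes = {s.luminance.shape for s in self.scenes}
        dpps = {s.degrees_per_pixel for s in self.scenes}
        if len(shapes) != 1 or len(dpps) != 1:
            raise InvalidSpecError("ensemble scenes must share geometry")

    @property
    def width_deg(self) -> float:
        return self.scenes[0].luminance.shape[1] * self.scenes[0].degrees_per_pixel


def _power_law_field(shape, exponent, rng) -> np.ndarray:
    """Zero-mean Gaussian field with amplitude spectrum ~ 1/|k|^exponent."""
    ny, nx = shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    k = np.hypot(ky, kx)
    amp = np.zeros_like(k)
    amp[k > 0] = k[k > 0] ** (-exponent)
    noise = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    fld = np.fft.ifft2(amp * noise).real
    return (fld - fld.mean()) / fld.std()


def _smooth_field(shape, scale_px, rng) -> np.ndarray:
    from scipy import ndimage

    fld = ndimage.gaussian_filter(rng.standard_normal(shape), scale_px, mode="wrap")
    return (fld - fld.mean()) / fld.std()


def synthesize_scene_ensemble(
    params: EnsembleParams | None = None, seed: int = 0
) -> SceneEnsemble:
    """Draw a reflectance field and render it under each condition."""
    params = params or EnsembleParams()
    root = np.random.SeedSequence(seed)
    refl_ss, illum_ss = root.spawn(2)
    shape = (params.size, params.size)

    rng = np.random.default_rng(refl_ss)
    log_refl = params.log_reflectance_sd * _power_law_field(
        shape, params.spectral_exponent, rng
    )
    reflectance = np.exp(log_refl)

    illum_streams = illum_ss.spawn(
        max(c[3] for c in params.conditions) + 1
    )
    scale_px = params.illumination_scale_deg / params.degrees_per_pixel
    illum_fields = {}

    scenes = []
    for label, target_mean, strength, stream in params.conditions:
        if stream not in illum_fields:
            illum_fields[stream] = _smooth_field(
                shape, scale_px, np.random.default_rng(illum_streams[stream])
            )
        illum = np.exp(strength * illum_fields[stream])
        lum = reflectance * illum
        lum *= target_mean / lum.mean()  # exact target mean by construction
        scenes.append(
            Scene(
                luminance=lum,
                degrees_per_pixel=params.degrees_per_pixel,
                condition_label=label,
                seed=seed,
                mean_gain=target_mean,
            )
        )
    return SceneEnsemble(scenes=scenes, params=params, seed=seed)


@dataclass
class Trajectory:
    """Forward-wave gaze trajectory over a scene.

    T(z) = amplitude * sin(2 pi * freq_mult * omega_z * z) + gamma z
    + noise_scale * N(0, 1), with z sweeping the horizontal extent at pixel
    resolution and omega_z the inverse horizontal length.  Units are pixels;
    vertical positions are clipped to the image.
    """

    z: np.ndarray
    t: np.ndarray
    rows: np.ndarray
    gamma: float
    seed: int | None = None


def simulate_trajectory(
    scene: Scene,
    gamma: float = 1.0 / 3.0,
    seed: int | None = None,
    amplitude: float = 30.0,
    freq_mult: float = 3.0,
    noise_scale: float = 60.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Draw one stochastic trajectory across the scene."""
    n_rows, n_cols = scene.luminance.shape
    if n_cols == 0 or n_rows == 0:
        raise InvalidSpecError("scene is empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    z = np.arange(n_cols, dtype=np.float64)
    omega_z = 1.0 / n_cols
    t = (
        amplitude * np.sin(2 * np.pi * freq_mult * omega_z * z)
        + gamma * z
        + noise_scale * rng.standard_normal(n_cols)
    )
    rows = np.clip(np.rint(t), 0, n_rows - 1).astype(int)
    return Trajectory(z=z, t=t, rows=rows, gamma=gamma, seed=seed)


@dataclass
class ContrastDistribution:
    """Pooled response samples with a Gaussian KDE on a fixed grid."""

    samples: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    condition_label: str = ""

    @property
    def mean(self) -> float:
        return float(self.samples.mean())


def _kde_on_grid(samples: np.ndarray, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    sd = samples.std()
    if sd == 0:  # degenerate: all samples identical
        center = samples[0]
        half = max(abs(center), 1.0) * 1e-3
        grid = np.linspace(center - half, center + half, n_grid)
        bw = half / 10
        density = np.exp(-0.5 * ((grid - center) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
        return grid, density
    kde = gaussian_kde(samples)  # Scott's rule
    bw = kde.factor * sd
    grid = np.linspace(samples.min() - 3 * bw, samples.max() + 3 * bw, n_grid)
    return grid, kde(grid)


def sample_contrast_responses(
    response_image: np.ndarray,
    trajectories: list[Trajectory],
    condition_label: str = "",
) -> ContrastDistribution:
    """Pool response values along trajectories and estimate their density."""
    if not trajectories:
        raise InvalidSpecError("at least one trajectory required")
    response_image = np.asarray(response_image, dtype=np.float64)
    samples = np.concatenate(
        [response_image[tr.rows, tr.z.astype(int)] for tr in trajectories]
    )
    if samples.size == 0:
        raise InvalidSpecError("pooled sample is empty")
    grid, density = _kde_on_grid(samples)
    return ContrastDistribution(
        samples=samples, grid=grid, density=density, condition_label=condition_label
    )


def _disc_kernel(diameter_px: float) -> np.ndarray:
    r = diameter_px / 2.0
    n = max(int(np.ceil(diameter_px)), 1)
    if n % 2 == 0:
        n += 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    return ((yy - c) ** 2 + (xx - c) ** 2 <= r**2).astype(np.float64)


def disc_pooled_mean(image: np.ndarray, diameter_deg: float, degrees_per_pixel: float) -> np.ndarray:
    """Mean of ``image`` over a centered disc at every pixel.

    Uniform weights over pixels whose centers fall inside the disc;
    at image boundaries the mean renormalizes over in-bounds pixels.
    """
    image = np.asarray(image, dtype=np.float64)
    diameter_px = diameter_deg / degrees_per_pixel
    kern = _disc_kernel(diameter_px)
    if kern.sum() <= 1:
        return image.copy()
    num = signal.fftconvolve(image, kern, mode="same")
    den = signal.fftconvolve(np.ones_like(image), kern, mode="same")
    return num / den


def normalize_by_pooled_luminance(
    response_image: np.ndarray,
    scene: Scene,
    pooling_diameter: float,
    g_l: float = 0.05,
) -> np.ndarray:
    """response / (g_l + disc-mean of the raw scene luminance)."""
    pooled = disc_pooled_mean(scene.luminance, pooling_diameter, scene.degrees_per_pixel)
    div = g_l + pooled
    if np.any(div <= 0):
        raise DivisionDegenerateError("zero pooled luminance with non-positive leak")
    return np.asarray(response_image, dtype=np.float64) / div


def normalize_by_pooled_response(
    response_image: np.ndarray,
    degrees_per_pixel: float,
    pooling_diameter: float,
    g_l: float = 0.05,
    column_pitch: float = COLUMN_PITCH_DEG,
) -> np.ndarray:
    """Divisive normalization by the pooled lamina-neuron signal.

    The divisor is g_l plus the summed response over the pooling disc
    expressed in medulla-column units (disc mean x number of columns the
    disc covers, hexagonal column area = sqrt(3)/2 * pitch^2), mirroring the
    circuit model where a wide-field neuron sums lamina inputs over columns.
    """
    response_image = np.asarray(response_image, dtype=np.float64)
    pooled_mean = disc_pooled_mean(response_image, pooling_diameter, degrees_per_pixel)
    column_area = np.sqrt(3.0) / 2.0 * column_pitch**2
    n_columns = np.pi * (pooling_diameter / 2.0) ** 2 / column_area
    div = g_l + pooled_mean * n_columns
    if np.any(div <= 0):
        raise DivisionDegenerateError("non-positive divisor in pooled normalization")
    return response_image / div


def wasserstein_1d(p, q) -> float:
    """Order-1 Wasserstein distance between two empirical sample sets."""
    a = p.samples if isinstance(p, ContrastDistribution) else np.asarray(p, float)
    b = q.samples if isinstance(q, ContrastDistribution) else np.asarray(q, float)
    if a.size == 0 or b.size == 0:
        raise InvalidSpecError("empty sample set")
    return float(wasserstein_distance(a, b))


def pooling_loss(
    sunny_norm,
    shaded_raw,
    shaded_norm,
    return_terms: bool = False,
):
    """Two-term pooling loss, L = sqrt(term1 + term2).

    term1: squared Wasserstein distance between the normalized contrast
    distributions of the two conditions (stability across illumination).
    term2: squared distance between the dimmer condition's mean-centered
    raw and mean-centered normalized distributions (penalizes normalization
    that collapses contrast structure).
    """
    def _s(d):
        return d.samples if isinstance(d, ContrastDistribution) else np.asarray(d, float)

    s_sun, s_raw, s_norm = _s(sunny_norm), _s(shaded_raw), _s(shaded_norm)
    term1 = wasserstein_1d(s_sun, s_norm) ** 2
    term2 = wasserstein_1d(s_raw - s_raw.mean(), s_norm - s_norm.mean()) ** 2
    loss = float(np.sqrt(term1 + term2))
    if return_terms:
        return loss, float(term1), float(term2)
    return loss


@dataclass
class PoolingScanResult:
    """Loss versus pooling diameter, aggregated over condition pairs."""

    table: pd.DataFrame  # columns: pooling_diameter, loss_mean, loss_std, ...
    pair_losses: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def diameters(self) -> np.ndarray:
        return self.table["pooling_diameter"].to_numpy()

    @property
    def loss_mean(self) -> np.ndarray:
        return self.table["loss_mean"].to_numpy()

    @property
    def loss_std(self) -> np.ndarray:
        return self.table["loss_std"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def scan_pooling_sizes(
    ensemble: SceneEnsemble,
    params: MembraneParams | None = None,
    diameters=(0.5, 1.0, 2.0, 4.0, 8.0, 15.0, 24.0, 32.0),
    n_trajectories: int = 15,
    seed: int = 0,
    g_l: float = 0.05,
    background: str = "response",
) -> PoolingScanResult:
    """Pooling-loss scan over diameters and all ordered condition pairs.

    Per condition: LMC responses per pixel, divisive normalization with the
    given pooling diameter, response samples along seeded stochastic
    trajectories.  Per (brighter, dimmer) condition pair the two-term loss is
    evaluated; rows report mean +- std across pairs.  ``background`` selects
    the divisor: pooled lamina response in column units ("response",
    circuit-consistent default) or pooled raw scene luminance ("luminance").
    """
    params = params or MembraneParams()
    if len(ensemble.scenes) < 2 or len(diameters) < 2:
        raise InvalidSpecError("need >= 2 conditions and >= 2 diameters")

    root = np.random.SeedSequence(seed)
    cond_streams = root.spawn(len(ensemble.scenes))

    responses, raw_samples, traj_sets = [], [], []
    for scene, ss in zip(ensemble.scenes, cond_streams):
        resp = respond_to_scene(scene.luminance, params)
        rng = np.random.default_rng(ss)
        trajs = [
            simulate_trajectory(scene, rng=rng) for _ in range(n_trajectories)
        ]
        responses.append(resp)
        traj_sets.append(trajs)
        raw_samples.append(sample_contrast_responses(resp, trajs, scene.condition_label))

    means = [s.luminance.mean() for s in ensemble.scenes]
    pairs = [
        (i, j) if means[i] >= means[j] else (j, i)
        for i in range(len(means))
        for j in range(i + 1, len(means))
    ]

    rows, pair_losses = [], {}
    for d in diameters:
        norm_samples = []
        for k, (scene, resp) in enumerate(zip(ensemble.scenes, responses)):
            if background == "response":
                norm = normalize_by_pooled_response(
                    resp, scene.degrees_per_pixel, d, g_l=g_l
                )
            elif background == "luminance":
                norm = normalize_by_pooled_luminance(resp, scene, d, g_l=g_l)
            else:
                raise InvalidSpecError(f"unknown background mode {background!r}")
            norm_samples.append(
                sample_contrast_responses(norm, traj_sets[k], scene.condition_label)
            )
        losses = []
        per_pair = {}
        for bright, dim in pairs:
            loss = pooling_loss(
                norm_samples[bright], raw_samples[dim], norm_samples[dim]
            )
            losses.append(loss)
            key = (
                ensemble.scenes[bright].condition_label,
                ensemble.scenes[dim].condition_label,
            )
            per_pair[key] = loss
        pair_losses[float(d)] = per_pair
        rows.append(
            {
                "pooling_diameter": float(d),
                "loss_mean": float(np.mean(losses)),
                "loss_std": float(np.std(losses)),
            }
        )
    return PoolingScanResult(table=pd.DataFrame(rows), pair_losses=pair_losses, seed=seed)
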