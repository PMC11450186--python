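"""Visual stimulus generation.

Stimuli are luminance movies sampled on a flat screen: drifting sinusoidal
gratings at several mean luminances, OFF edges moving over uniform
backgrounds, and ternary white noise (squares or stripes) used for reverse
correlation.  All luminance values are kept in normalized units L/I_max in
[0, 1]; the physical maximum photon rate of the projector is metadata only.

Coordinates are degrees of visual angle, x = azimuth and y = elevation, with
the origin at the screen center and pixel centers at half-integer multiples
of the pixel pitch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .errors import (
    DivisionDegenerateError,
    GeometryError,
    InvalidSpecError,
    UndefinedContrastError,
)

__all__ = [
    "PROTOCOL_MEAN_LUMINANCES",
    "I_MAX_PHOTONS",
    "ScreenGeometry",
    "FullField",
    "Disc",
    "DiscWithAnnulus",
    "GratingSpec",
    "EdgeSpec",
    "WhiteNoiseSpec",
    "StimulusMovie",
    "make_drifting_grating",
    "make_off_edge",
    "make_ternary_noise",
    "michelson_contrast",
    "weber_contrast",
    "contrast_metrics",
]

#: Maximum luminance at the fly's position (photons s^-1 photoreceptor^-1),
#: metadata for converting normalized units back to physical ones.
I_MAX_PHOTONS = 2.17e5

#: The five grating mean luminances used throughout, in normalized units
#: (1.2, 2.6, 5.3, 7.9, 10.6 x 10^4 photons s^-1 photoreceptor^-1 / I_max).
PROTOCOL_MEAN_LUMINANCES = tuple(
    float(v) for v in np.array([1.2, 2.6, 5.3, 7.9, 10.6]) * 1e4 / I_MAX_PHOTONS
)


@dataclass(frozen=True)
class ScreenGeometry:
    """Flat projection screen: extent (degrees), pixel pitch and frame rate."""

    width_deg: float = 60.0
    height_deg: float = 60.0
    degrees_per_pixel: float = 0.5
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.degrees_per_pixel <= 0 or self.frame_rate <= 0:
            raise InvalidSpecError("pixel pitch and frame rate must be positive")
        if self.width_deg <= 0 or self.height_deg <= 0:
            raise InvalidSpecError("screen extent must be positive")

    @property
    def n_x(self) -> int:
        return int(round(self.width_deg / self.degrees_per_pixel))

    @property
    def n_y(self) -> int:
        return int(round(self.height_deg / self.degrees_per_pixel))

    @property
    def x_centers(self) -> np.ndarray:
        """Azimuth of pixel centers (degrees), origin at screen center."""
        return (np.arange(self.n_x) + 0.5) * self.degrees_per_pixel - self.width_deg / 2

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.n_y) + 0.5) * self.degrees_per_pixel - self.height_deg / 2


@dataclass(frozen=True)
class FullField:
    """Aperture covering the whole screen."""


@dataclass(frozen=True)
class Disc:
    diameter: float
    center: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class DiscWithAnnulus:
    inner: float
    outer: float
    annulus_luminance: float
    center: tuple[float, float] = (0.0, 0.0)


Aperture = FullField | Disc | DiscWithAnnulus


@dataclass(frozen=True)
class GratingSpec:
    """Drifting sinusoidal grating protocol.

    One epoch per mean luminance, each ``epoch_duration`` seconds of drift at
    full ``michelson_contrast``, interleaved with full-field frames at the
    epoch's mean luminance.  Temporal frequency = speed / wavelength.
    """

    temporal_frequency: float = 1.0
    spatial_wavelength: float = 30.0
    michelson_contrast: float = 1.0
    mean_luminances: tuple[float, ...] = PROTOCOL_MEAN_LUMINANCES
    epoch_duration: float = 4.0
    interleave_duration: float = 4.0
    aperture: Aperture = FullField()
    direction: tuple[float, float] = (1.0, 0.0)
    randomize_epochs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_wavelength <= 0:
            raise InvalidSpecError("spatial wavelength must be positive")
        if self.temporal_frequency <= 0:
            raise InvalidSpecError("temporal frequency must be positive")
        if not 0.0 <= self.michelson_contrast <= 1.0:
            raise InvalidSpecError("Michelson contrast must lie in [0, 1]")
        if any(l < 0 for l in self.mean_luminances):
            raise InvalidSpecError("luminances must be non-negative")
        n = float(np.hypot(*self.direction))
        if n == 0:
            raise InvalidSpecError("direction must be a non-zero vector")

    @classmethod
    def from_speed(cls, speed: float, spatial_wavelength: float, **kwargs) -> "GratingSpec":
        """Construct from drift speed (deg/s); f = speed / wavelength."""
        return cls(
            temporal_frequency=speed / spatial_wavelength,
            spatial_wavelength=spatial_wavelength,
            **kwargs,
        )


@dataclass(frozen=True)
class EdgeSpec:
    """OFF moving edge protocol: uniform field, then a dark edge sweeping by."""

    background_luminances: tuple[float, ...] = tuple(
        float(v) for v in np.array([1.2, 2.6, 5.3, 10.6, 16.0, 21.4]) * 1e4 / I_MAX_PHOTONS
    )
    edge_speed: float = 30.0
    weber_contrast: float = -1.0
    pre_duration: float = 1.0
    inter_epoch_dark: float = 4.0
    randomize_epochs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_speed <= 0:
            raise InvalidSpecError("edge speed must be positive")
        if any(l <= 0 for l in self.background_luminances):
            raise InvalidSpecError("background luminances must be positive")


@dataclass(frozen=True)
class WhiteNoiseSpec:
    """Ternary white noise: elements drawn i.i.d. from {0, 0.5, 1} x I_max.

    ``element`` is ``("square", size_deg)`` or ``("stripe", width_deg)``;
    stripes span the full screen height.  A mid-luminance full-field prelude
    precedes the noise to provide the baseline for dF/F.
    """

    element: tuple[str, float] = ("stripe", 5.0)
    update_rate: float = 20.0
    levels: tuple[float, float, float] = (0.0, 0.5, 1.0)
    duration: float = 60.0
    baseline_prelude: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        kind, size = self.element
        if kind not in ("square", "stripe"):
            raise InvalidSpecError(f"unknown noise element kind {kind!r}")
        if size <= 0:
            raise InvalidSpecError("element size must be positive")
        if len(self.levels) != 3:
            raise InvalidSpecError("ternary noise requires exactly three levels")
        if self.duration < 1.0 / self.update_rate:
            raise InvalidSpecError("duration shorter than one update interval")


@dataclass
class StimulusMovie:
    """Luminance movie: frames indexed (time, elevation, azimuth).

    ``epoch_labels`` carries one integer per frame (-1 marks interleave /
    prelude / darkness frames, >= 0 indexes the stimulus epoch).
    """

    frames: np.ndarray
    frame_rate: float
    degrees_per_pixel: float
    epoch_labels: np.ndarray
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.epoch_labels = np.asarray(self.epoch_labels)
        if self.frames.ndim != 3:
            raise InvalidSpecError("frames must be a (time, y, x) array")
        if np.any(self.frames < 0):
            raise InvalidSpecError("luminance values must be non-negative")
        if len(self.epoch_labels) != len(self.frames):
            raise InvalidSpecError("epoch_labels must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            # track_times=False keeps file bytes reproducible run-to-run
            f.create_dataset(
                "frames", data=self.frames.astype(np.float32), track_times=False
            )
            f.create_dataset(
                "epoch_labels", data=self.epoch_labels.astype(np.int64), track_times=False
            )
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["degrees_per_pixel"] = self.degrees_per_pixel
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, path) -> "StimulusMovie":
        with h5py.File(path, "r") as f:
            return cls(
                frames=f["frames"][...].astype(np.float64),
                epoch_labels=f["epoch_labels"][...],
                frame_rate=float(f.attrs["frame_rate"]),
                degrees_per_pixel=float(f.attrs["degrees_per_pixel"]),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.float32))


def _aperture_mask(aperture: Aperture, screen: ScreenGeometry) -> np.ndarray | None:
    """Boolean mask of pixels inside the stimulated region (None = all)."""
    if isinstance(aperture, FullField):
        return None
    xx, yy = np.meshgrid(screen.x_centers, screen.y_centers)
    if isinstance(aperture, Disc):
        diam = aperture.diameter
        cx, cy = aperture.center
    else:
        diam = aperture.inner
        cx, cy = aperture.center
    if diam > min(screen.width_deg, screen.height_deg) or (
        isinstance(aperture, DiscWithAnnulus)
        and aperture.outer > min(screen.width_deg, screen.height_deg)
    ):
        raise GeometryError("aperture exceeds the screen extent")
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= (diam / 2) ** 2


def make_drifting_grating(spec: GratingSpec, screen: ScreenGeometry | None = None) -> StimulusMovie:
    """Render the drifting-grating protocol as a :class:`StimulusMovie`.

    Each epoch shows L * (1 + C sin(2 pi (x'/lambda - f t))) where x' is the
    position along the drift direction, followed by a full-field interleave at
    the epoch's mean luminance.  Epoch order is drawn once from the seeded
    generator when ``randomize_epochs`` is set.
    """
    screen = screen or ScreenGeometry()
    if screen.frame_rate < 2 * spec.temporal_frequency:
        raise InvalidSpecError("frame rate below Nyquist for the temporal frequency")

    xx, yy = np.meshgrid(screen.x_centers, screen.y_centers)
    dx, dy = spec.direction
    norm = float(np.hypot(dx, dy))
    proj = (xx * dx + yy * dy) / norm  # degrees along drift direction

    mask = _aperture_mask(spec.aperture, screen)

    n_epoch = int(round(spec.epoch_duration * screen.frame_rate))
    n_inter = int(round(spec.interleave_duration * screen.frame_rate))
    t = np.arange(n_epoch) / screen.frame_rate

    rng = np.random.default_rng(spec.seed)
    order = np.arange(len(spec.mean_luminances))
    if spec.randomize_epochs:
        order = rng.permutation(order)

    # phase referenced so the central pixel sits at the luminance peak at
    # stimulus onset: generated extremes (hence Michelson contrast) are exact
    p0 = proj[screen.n_y // 2, screen.n_x // 2]
    phi0 = np.pi / 2 - 2 * np.pi * p0 / spec.spatial_wavelength
    phase = phi0 + 2 * np.pi * (
        proj[None] / spec.spatial_wavelength - spec.temporal_frequency * t[:, None, None]
    )
    modulation = np.sin(phase)  # shared across epochs

    frames, labels = [], []
    for idx in order:
        mean = spec.mean_luminances[idx]
        epoch = mean * (1.0 + spec.michelson_contrast * modulation)
        if mask is not None:
            epoch = np.where(mask[None], epoch, mean)
            if isinstance(spec.aperture, DiscWithAnnulus):
                ap = spec.aperture
                cx, cy = ap.center
                r2 = (xx - cx) ** 2 + (yy - cy) ** 2
                ring = (r2 > (ap.inner / 2) ** 2) & (r2 <= (ap.outer / 2) ** 2)
                epoch = np.where(ring[None], ap.annulus_luminance, epoch)
        frames.append(epoch)
        labels.append(np.full(n_epoch, idx))
        frames.append(np.full((n_inter, screen.n_y, screen.n_x), mean))
        labels.append(np.full(n_inter, -1))

    return StimulusMovie(
        frames=np.concatenate(frames),
        frame_rate=screen.frame_rate,
        degrees_per_pixel=screen.degrees_per_pixel,
        epoch_labels=np.concatenate(labels),
        seed=spec.seed,
        extras={"epoch_order": order, "mean_luminances": spec.mean_luminances},
    )


def make_off_edge(spec: EdgeSpec, screen: ScreenGeometry | None = None) -> StimulusMovie:
    """Render the OFF-edge protocol.

    Per background luminance: ``pre_duration`` seconds of uniform field, then
    a dark edge (luminance = background * (1 + Weber contrast)) whose front
    sweeps across azimuth at ``edge_speed``; epochs are separated by darkness.
    """
    screen = screen or ScreenGeometry()
    if spec.weber_contrast <= -1.0 and any(
        l * (1 + spec.weber_contrast) < 0 for l in spec.background_luminances
    ):
        raise InvalidSpecError("edge luminance would be negative")

    n_pre = int(round(spec.pre_duration * screen.frame_rate))
    n_dark = int(round(spec.inter_epoch_dark * screen.frame_rate))
    traversal = screen.width_deg / spec.edge_speed
    n_sweep = int(round(traversal * screen.frame_rate))
    x = screen.x_centers

    rng = np.random.default_rng(spec.seed)
    order = np.arange(len(spec.background_luminances))
    if spec.randomize_epochs:
        order = rng.permutation(order)

    frames, labels = [], []
    for idx in order:
        bg = spec.background_luminances[idx]
        edge_lum = bg * (1.0 + spec.weber_contrast)
        frames.append(np.full((n_pre, screen.n_y, screen.n_x), bg))
        labels.append(np.full(n_pre, idx))
        # edge front position over time, entering from the left screen edge
        front = -screen.width_deg / 2 + spec.edge_speed * (
            np.arange(1, n_sweep + 1) / screen.frame_rate
        )
        covered = x[None, :] <= front[:, None]  # (t, x)
        sweep = np.where(covered[:, None, :], edge_lum, bg)
        sweep = np.broadcast_to(sweep, (n_sweep, screen.n_y, screen.n_x)).copy()
        frames.append(sweep)
        labels.append(np.full(n_sweep, idx))
        frames.append(np.zeros((n_dark, screen.n_y, screen.n_x)))
        labels.append(np.full(n_dark, -1))

    return StimulusMovie(
        frames=np.concatenate(frames),
        frame_rate=screen.frame_rate,
        degrees_per_pixel=screen.degrees_per_pixel,
        epoch_labels=np.concatenate(labels),
        seed=spec.seed,
        extras={"epoch_order": order, "background_luminances": spec.background_luminances},
    )


def _element_grid(spec: WhiteNoiseSpec, screen: ScreenGeometry) -> tuple[int, int, int]:
    """Number of elements (ny, nx) and rendered pixels per element.

    Elements are snapped to a whole pixel count; a warning is issued when
    snapping changes the requested size by more than 5%.
    """
    kind, size = spec.element
    px = max(1, int(round(size / screen.degrees_per_pixel)))
    snapped = px * screen.degrees_per_pixel
    if abs(snapped - size) / size > 0.05:
        warnings.warn(
            f"noise element snapped from {size}deg to {snapped:.3g}deg",
            stacklevel=3,
        )
    n_x = max(1, int(round(screen.width_deg / snapped)))
    n_y = n_x if kind == "square" else 1
    return n_y, n_x, px


def make_ternary_noise(
    spec: WhiteNoiseSpec,
    screen: ScreenGeometry | None = None,
    render: str = "full",
) -> StimulusMovie:
    """Render ternary white noise.

    Each element independently takes one of the three levels with probability
    1/3 at every update; a mid-level full-field prelude precedes the noise.
    ``render="full"`` rasterizes to screen pixels at the screen frame rate;
    ``render="updates"`` returns the movie at element/update resolution (one
    pixel per element, frame rate = update rate), which is exact for all
    estimators and cheap for long stimuli.
    """
    screen = screen or ScreenGeometry()
    n_el_y, n_el_x, px = _element_grid(spec, screen)
    n_updates = int(round(spec.duration * spec.update_rate))
    rng = np.random.default_rng(spec.seed)
    levels = np.asarray(spec.levels, dtype=np.float64)
    draws = rng.integers(0, 3, size=(n_updates, n_el_y, n_el_x))
    noise = levels[draws]

    mid = spec.levels[1]
    if render == "updates":
        n_pre = int(round(spec.baseline_prelude * spec.update_rate))
        frames = np.concatenate(
            [np.full((n_pre, n_el_y, n_el_x), mid), noise]
        )
        labels = np.concatenate([np.full(n_pre, -1), np.zeros(n_updates, dtype=int)])
        dpp = px * screen.degrees_per_pixel
        return StimulusMovie(
            frames=frames,
            frame_rate=spec.update_rate,
            degrees_per_pixel=dpp,
            epoch_labels=labels,
            seed=spec.seed,
            extras={"update_rate": spec.update_rate, "levels": spec.levels},
        )
    if render != "full":
        raise InvalidSpecError(f"unknown render mode {render!r}")

    reps = int(round(screen.frame_rate / spec.update_rate))
    if reps < 1:
        raise InvalidSpecError("screen frame rate below the noise update rate")
    full_y = noise.repeat(px, axis=1) if n_el_y > 1 else np.broadcast_to(
        noise, (n_updates, screen.n_y, n_el_x)
    )
    full = np.asarray(full_y).repeat(px, axis=2)
    # pad/crop to exact screen pixel counts (snapping can leave a remainder)
    full = full[:, : screen.n_y, : screen.n_x]
    if full.shape[1] < screen.n_y or full.shape[2] < screen.n_x:
        full = np.pad(
            full,
            ((0, 0), (0, screen.n_y - full.shape[1]), (0, screen.n_x - full.shape[2])),
            mode="edge",
        )
    full = full.repeat(reps, axis=0)
    n_pre = int(round(spec.baseline_prelude * screen.frame_rate))
    frames = np.concatenate([np.full((n_pre, screen.n_y, screen.n_x), mid), full])
    labels = np.concatenate(
        [np.full(n_pre, -1), np.zeros(n_updates * reps, dtype=int)]
    )
    return StimulusMovie(
        frames=frames,
        frame_rate=screen.frame_rate,
        degrees_per_pixel=screen.degrees_per_pixel,
        epoch_labels=labels,
        seed=spec.seed,
        extras={"update_rate": spec.update_rate, "levels": spec.levels},
    )


def michelson_contrast(frames: np.ndarray) -> float:
    """(max - min) / (max + min) over the given luminance values."""
    frames = np.asarray(frames, dtype=np.float64)
    if np.any(frames < 0):
        raise InvalidSpecError("luminance values must be non-negative")
    hi, lo = frames.max(), frames.min()
    if hi + lo == 0:
        raise UndefinedContrastError("Michelson contrast undefined for an all-zero field")
    return float((hi - lo) / (hi + lo))


def weber_contrast(i_edge: float, i_background: float) -> float:
    """(I_edge - I_background) / I_background."""
    if i_background <= 0:
        raise DivisionDegenerateError("Weber contrast undefined for zero background")
    return float((i_edge - i_background) / i_background)


def contrast_metrics(
    frames: np.ndarray | None = None,
    pair: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Michelson contrast of a field and/or Weber contrast of an (edge, bg) pair."""
    out: dict[str, float] = {}
    if frames is not None:
        out["michelson"] = michelson_contrast(frames)
    if pair is not None:
        out["weber"] = weber_contrast(*pair)
    if not out:
        raise InvalidSpecError("provide frames and/or an (edge, background) pair")
    return out
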