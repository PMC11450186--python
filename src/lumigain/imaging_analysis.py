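"""Calcium-imaging response analysis.

Implements the recording-analysis pipeline applied to ROI fluorescence
traces: dF/F normalization, trial-reliability filtering, F1 amplitudes of
grating responses, response-vs-log-luminance slopes, OFF-edge response
metrics, contrast-luminance heatmaps, reverse-correlation spatiotemporal
receptive fields (STRFs) from ternary white noise, Gaussian receptive-field
fits with FWHM, and online RF-center mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .errors import DivisionDegenerateError, InvalidSpecError
from .stimuli import StimulusMovie

__all__ = [
    "RoiTraceSet",
    "STRF",
    "Gaussian1DFit",
    "Gaussian2DFit",
    "ContrastLuminanceMap",
    "FWHM_PER_SIGMA",
    "dff",
    "roi_reliability",
    "f1_amplitude",
    "luminance_slope",
    "edge_response",
    "contrast_luminance_map",
    "compute_strf",
    "filter_strfs",
    "extract_filters",
    "map_rf_center",
]

#: Exact FWHM of a Gaussian per unit sigma, 2 sqrt(2 ln 2) = 2.3548...
FWHM_PER_SIGMA = float(2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RoiTraceSet:
    """ROI x time fluorescence traces with trial structure.

    ``trial_bounds`` is a list of (start, stop) sample indices delimiting
    repeats of the same stimulus; trials must not overlap.
    """

    traces: np.ndarray
    frame_rate: float
    trial_bounds: list = field(default_factory=list)
    epoch_labels: np.ndarray | None = None
    background_subtracted: bool = True

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=np.float64))
        if self.frame_rate <= 0:
            raise InvalidSpecError("frame rate must be positive")
        prev_stop = -1
        for start, stop in sorted(self.trial_bounds):
            if start < prev_stop:
                raise InvalidSpecError("trial windows overlap")
            prev_stop = stop

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    def trials(self, roi: int) -> list[np.ndarray]:
        return [self.traces[roi, a:b] for a, b in self.trial_bounds]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=self.traces, track_times=False)
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["background_subtracted"] = self.background_subtracted
            if self.trial_bounds:
                f.create_dataset(
                    "trial_bounds", data=np.asarray(self.trial_bounds), track_times=False
                )
            if self.epoch_labels is not None:
                f.create_dataset(
                    "epoch_labels", data=np.asarray(self.epoch_labels), track_times=False
                )

    @classmethod
    def from_hdf5(cls, path) -> "RoiTraceSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                traces=f["traces"][...],
                frame_rate=float(f.attrs["frame_rate"]),
                trial_bounds=[tuple(b) for b in f["trial_bounds"][...]]
                if "trial_bounds" in f
                else [],
                epoch_labels=f["epoch_labels"][...] if "epoch_labels" in f else None,
                background_subtracted=bool(f.attrs.get("background_subtracted", True)),
            )


def dff(
    traces: np.ndarray,
    baseline_mode: str = "trace_mean",
    frame_rate: float | None = None,
    prelude_duration: float = 4.0,
) -> np.ndarray:
    """Relative fluorescence change (F - F0) / F0 per ROI.

    ``baseline_mode="trace_mean"`` uses the mean of each trace as F0;
    ``"prelude_mean"`` (white-noise protocol) uses the mean of the first
    ``prelude_duration`` seconds, which requires ``frame_rate``.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    if baseline_mode == "trace_mean":
        f0 = traces.mean(axis=1)
    elif baseline_mode == "prelude_mean":
        if frame_rate is None:
            raise InvalidSpecError("prelude_mean baseline requires frame_rate")
        n = int(round(prelude_duration * frame_rate))
        f0 = traces[:, :n].mean(axis=1)
    else:
        raise InvalidSpecError(f"unknown baseline mode {baseline_mode!r}")
    bad = np.where(f0 <= 0)[0]
    if bad.size:
        raise DivisionDegenerateError(
            f"non-positive baseline for ROI(s) {bad.tolist()}"
        )
    out = (traces - f0[:, None]) / f0[:, None]
    return out[0] if out.shape[0] == 1 and np.asarray(traces).ndim == 1 else out


def roi_reliability(trials, threshold: float = 0.6) -> tuple[float, bool]:
    """Mean pairwise Pearson correlation across trials, and a keep flag.

    Raises on fewer than two trials; a zero-variance trial makes the
    correlation undefined and yields (nan, False).
    """
    trials = [np.asarray(t, dtype=np.float64) for t in trials]
    if len(trials) < 2:
        raise InvalidSpecError("reliability requires at least two trials")
    n = len(trials[0])
    if any(len(t) != n for t in trials):
        raise InvalidSpecError("trials must have equal length")
    if any(np.std(t) == 0 for t in trials):
        return float("nan"), False
    mat = np.corrcoef(np.vstack(trials))
    iu = np.triu_indices(len(trials), k=1)
    value = float(mat[iu].mean())
    return value, value >= threshold


def f1_amplitude(trace: np.ndarray, stimulus_frequency: float, frame_rate: float) -> float:
    """Fourier amplitude of the trace at the stimulus temporal frequency.

    Convention: a pure sinusoid of amplitude A returns A.  The transform is
    evaluated on the largest whole number of stimulus periods; the requested
    frequency must land within half a frequency bin of a DFT bin.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if stimulus_frequency > frame_rate / 2:
        raise InvalidSpecError("stimulus frequency above Nyquist")
    n_periods = int(np.floor(len(trace) * stimulus_frequency / frame_rate))
    if n_periods < 2:
        raise InvalidSpecError("trace shorter than two stimulus periods")
    n_used = int(round(n_periods * frame_rate / stimulus_frequency))
    seg = trace[:n_used]
    spec = np.fft.rfft(seg)
    k_exact = stimulus_frequency * n_used / frame_rate
    k = int(round(k_exact))
    if abs(k_exact - k) > 0.5:
        raise InvalidSpecError("stimulus frequency does not align with a DFT bin")
    return float(2.0 * np.abs(spec[k]) / n_used)


def luminance_slope(luminances, responses) -> float:
    """OLS slope of response versus log10(luminance)."""
    L = np.asarray(luminances, dtype=np.float64)
    y = np.asarray(responses, dtype=np.float64)
    if len(np.unique(L)) < 2:
        raise InvalidSpecError("slope requires at least two distinct luminances")
    if np.any(L <= 0):
        raise InvalidSpecError("luminances must be positive for the log scale")
    return float(np.polyfit(np.log10(L), y, 1)[0])


def edge_response(
    trace: np.ndarray,
    frame_rate: float,
    edge_start: float,
    edge_end: float | None = None,
    pre_window: float = 1.0,
) -> float:
    """Peak within the edge window minus the mean over the preceding window."""
    trace = np.asarray(trace, dtype=np.float64)
    i_start = int(round(edge_start * frame_rate))
    i_pre = int(round((edge_start - pre_window) * frame_rate))
    i_end = len(trace) if edge_end is None else int(round(edge_end * frame_rate))
    if i_pre < 0 or i_start <= i_pre or i_end <= i_start or i_end > len(trace):
        raise InvalidSpecError("edge/pre windows fall outside the trace")
    return float(trace[i_start:i_end].max() - trace[i_pre:i_start].mean())


def epoch_f1_amplitudes(
    trace: np.ndarray,
    epoch_labels: np.ndarray,
    frame_rate: float,
    stimulus_frequency: float,
) -> dict[int, float]:
    """F1 amplitude per stimulus epoch of a labelled trace.

    Contiguous runs sharing a non-negative label are treated as repeats of
    that epoch; F1 amplitudes are computed per run and averaged per label.
    """
    trace = np.asarray(trace, dtype=np.float64)
    labels = np.asarray(epoch_labels)
    if len(labels) != len(trace):
        raise InvalidSpecError("labels must match the trace length")
    runs: dict[int, list[float]] = {}
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            lab = int(labels[start])
            if lab >= 0:
                runs.setdefault(lab, []).append(
                    f1_amplitude(trace[start:i], stimulus_frequency, frame_rate)
                )
            start = i
    return {lab: float(np.mean(v)) for lab, v in sorted(runs.items())}


@dataclass
class ContrastLuminanceMap:
    """Contrast x luminance response grid and its interpolated heatmap."""

    base: np.ndarray
    interpolated: np.ndarray
    smoothing_sigma: float
    contour_levels: np.ndarray
    degenerate: bool = False


def contrast_luminance_map(
    grid: np.ndarray,
    zoom: int = 5,
    smoothing_sigma: float = 10.0,
    n_contours: int = 8,
) -> ContrastLuminanceMap:
    """Order-1 spline zoom of the mean-response grid, then Gaussian smoothing.

    A 5x5 grid becomes 25x25 at the default zoom.  ``smoothing_sigma`` is in
    zoomed-grid pixels; contour levels are evenly spaced strictly between the
    smoothed map's extrema.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2 or np.any(~np.isfinite(grid)):
        raise InvalidSpecError("grid must be a complete finite 2-D array")
    interp = ndimage.zoom(grid, zoom, order=1)
    smoothed = ndimage.gaussian_filter(interp, smoothing_sigma)
    lo, hi = smoothed.min(), smoothed.max()
    degenerate = hi == lo
    levels = (
        np.full(n_contours, lo)
        if degenerate
        else np.linspace(lo, hi, n_contours + 2)[1:-1]
    )
    return ContrastLuminanceMap(
        base=grid,
        interpolated=smoothed,
        smoothing_sigma=smoothing_sigma,
        contour_levels=levels,
        degenerate=degenerate,
    )


@dataclass
class STRF:
    """Reverse-correlation kernel, lag x space, plus extraction metadata."""

    kernel: np.ndarray  # (n_lags, *spatial_shape)
    update_rate: float
    window: float
    amplitude: float = 0.0
    snr: float = float("nan")
    accepted: bool = False

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        self.amplitude = float(np.max(np.abs(self.kernel)))
        mean_abs = float(np.mean(np.abs(self.kernel)))
        self.snr = self.amplitude / mean_abs if mean_abs > 0 else float("nan")

    @property
    def n_lags(self) -> int:
        return self.kernel.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.kernel.shape[1:]


def _movie_to_design(movie: StimulusMovie) -> tuple[np.ndarray, float, np.ndarray]:
    """Centered stimulus values per noise update from a ternary movie.

    Levels {0, mid, max} map to {-1, 0, +1}.  Works for update-resolution
    movies directly; full renderings are decimated to the update rate.
    """
    update_rate = float(movie.extras.get("update_rate", movie.frame_rate))
    step = int(round(movie.frame_rate / update_rate))
    frames = movie.frames[::step] if step > 1 else movie.frames
    labels = movie.epoch_labels[::step] if step > 1 else movie.epoch_labels
    i_max = float(movie.frames.max())
    if i_max <= 0:
        raise InvalidSpecError("movie carries no light")
    design = 2.0 * frames / i_max - 1.0
    return design, update_rate, np.asarray(labels)


def compute_strf(
    trace: np.ndarray,
    trace_rate: float,
    stimulus: StimulusMovie | np.ndarray,
    window: float = 2.0,
    prelude_duration: float = 4.0,
    update_rate: float = 20.0,
) -> STRF:
    """Reverse-correlation STRF from a ternary-noise recording.

    The trace is linearly interpolated to the noise update rate, converted to
    dF/F against the prelude baseline, and mean-centered; stimulus levels are
    centered to {-1, 0, +1}.  A backward window of ``window`` seconds then
    yields kernel[lag] = sum_t r_t s(t - lag) / (T - tau), with the sum over
    all times with a complete window.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if isinstance(stimulus, StimulusMovie):
        design, update_rate, s_labels = _movie_to_design(stimulus)
    else:
        design = np.asarray(stimulus, dtype=np.float64)
        s_labels = None

    spatial_shape = design.shape[1:]
    S = design.reshape(len(design), -1)

    # resample the recorded trace onto the stimulus update grid
    t_trace = np.arange(len(trace)) / trace_rate
    t_stim = np.arange(len(S)) / update_rate
    r = np.interp(t_stim, t_trace, trace)

    n_pre = int(round(prelude_duration * update_rate))
    if n_pre > 0:
        f0 = r[:n_pre].mean()
        if f0 <= 0:
            raise DivisionDegenerateError("non-positive prelude baseline")
        r = (r - f0) / f0
    r = r - r.mean()

    if s_labels is not None:  # correlate over the noise portion only
        keep = s_labels >= 0
        first = int(np.argmax(keep))
        S, r = S[first:], r[first:]

    n_lags = int(round(window * update_rate))
    T = len(S)
    if T <= n_lags:
        raise InvalidSpecError("stimulus shorter than the correlation window")

    kernel = np.empty((n_lags, S.shape[1]))
    norm = T - n_lags
    for lag in range(n_lags):
        kernel[lag] = r[n_lags - 1 :] @ S[n_lags - 1 - lag : T - lag] / norm
    return STRF(
        kernel=kernel.reshape(n_lags, *spatial_shape),
        update_rate=update_rate,
        window=window,
    )


def filter_strfs(
    strfs: list[STRF],
    mode: str = "default",
    amplitude_threshold: float | None = None,
    snr_threshold: float = 10.0,
) -> list[STRF]:
    """Quality filter: keep STRFs whose peak amplitude (and SNR) pass.

    ``default``: max |kernel| >= 0.005.  ``low_snr`` (noisier recordings):
    amplitude >= 0.003 and peak-to-background SNR >= 10, where SNR is
    max|kernel| / mean|kernel| (see package docs for why the absolute-value
    background is used).  Accepted flags are set in place; the accepted
    subset is returned.
    """
    if mode == "default":
        amp = 0.005 if amplitude_threshold is None else amplitude_threshold
        use_snr = False
    elif mode == "low_snr":
        amp = 0.003 if amplitude_threshold is None else amplitude_threshold
        use_snr = True
    else:
        raise InvalidSpecError(f"unknown filter mode {mode!r}")
    kept = []
    for strf in strfs:
        ok = strf.amplitude >= amp
        if use_snr:
            ok = ok and strf.snr >= snr_threshold
        strf.accepted = bool(ok)
        if ok:
            kept.append(strf)
    return kept


@dataclass
class Gaussian1DFit:
    a: float
    mu: float
    sigma: float
    fwhm: float
    residual: float
    converged: bool = True


@dataclass
class Gaussian2DFit:
    h: float
    center_x: float
    center_y: float
    width_x: float
    width_y: float
    residual: float
    converged: bool = True


def _gauss1d(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_1d(x: np.ndarray, y: np.ndarray, max_sigma: float | None = None) -> Gaussian1DFit:
    """Nonlinear LSQ fit of a single Gaussian; FWHM = 2 sqrt(2 ln 2) sigma."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    i0 = int(np.argmax(y))
    a0, mu0 = float(y[i0]), float(x[i0])
    w = np.clip(y, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w))) if w.sum() > 0 else 1.0
    sigma0 = max(sigma0, np.min(np.diff(np.sort(x))) / 2 if len(x) > 1 else 1e-3)
    hi = max_sigma if max_sigma is not None else (x.max() - x.min()) or 1.0
    try:
        popt, _ = curve_fit(
            _gauss1d,
            x,
            y,
            p0=[a0, mu0, min(sigma0, hi)],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, hi * 10]),
            maxfev=10000,
        )
        resid = float(np.sqrt(np.mean((_gauss1d(x, *popt) - y) ** 2)))
        a, mu, sigma = popt
        return Gaussian1DFit(
            a=float(a), mu=float(mu), sigma=float(sigma),
            fwhm=FWHM_PER_SIGMA * float(sigma), residual=resid,
        )
    except RuntimeError:
        return Gaussian1DFit(
            a=a0, mu=mu0, sigma=sigma0, fwhm=FWHM_PER_SIGMA * sigma0,
            residual=float("nan"), converged=False,
        )


def extract_filters(
    strf: STRF, degrees_per_pixel: float = 1.0
) -> tuple[np.ndarray, np.ndarray, Gaussian1DFit]:
    """Spatial and temporal profiles of a 1-D-space STRF plus a Gaussian fit.

    The temporal profile is the lag trace at the spatial location of the
    kernel's minimum; the spatial profile is the spatial slice at the lag of
    the minimum (minima, because OFF-cell STRF amplitudes are negative; ties
    break to the first occurrence in row-major order).  The Gaussian is fit
    to the absolute spatial profile, in degrees.
    """
    kernel = strf.kernel
    if kernel.ndim == 3 and 1 in kernel.shape[1:]:  # stripes: drop unit axis
        kernel = kernel.reshape(kernel.shape[0], -1)
    if kernel.ndim != 2:
        raise InvalidSpecError("extract_filters expects a lag x space kernel")
    strf = STRF(kernel=kernel, update_rate=strf.update_rate, window=strf.window,
                accepted=strf.accepted)
    lag_min, x_min = np.unravel_index(int(np.argmin(strf.kernel)), strf.kernel.shape)
    temporal = strf.kernel[:, x_min]
    spatial = strf.kernel[lag_min, :]
    x = np.arange(len(spatial)) * degrees_per_pixel
    fit = fit_gaussian_1d(x, np.abs(spatial))
    return spatial, temporal, fit


def _gauss2d(xy, h, cx, cy, wx, wy):
    x, y = xy
    return h * np.exp(-(((cx - x) / wx) ** 2 + ((cy - y) / wy) ** 2) / 2.0)


def map_rf_center(
    rf: np.ndarray | STRF,
    x_deg: np.ndarray | None = None,
    y_deg: np.ndarray | None = None,
) -> Gaussian2DFit:
    """2-D Gaussian fit to the spatial receptive field for stimulus placement.

    Accepts either a 2-D spatial response grid or a lag x y x x STRF (the
    frame at the lag of the kernel minimum is fitted).  Axes default to pixel
    indices when no degree coordinates are given.
    """
    if isinstance(rf, STRF):
        if rf.kernel.ndim != 3:
            raise InvalidSpecError("STRF must have two spatial dimensions")
        per_lag_min = rf.kernel.reshape(rf.n_lags, -1).min(axis=1)
        frame = rf.kernel[int(np.argmin(per_lag_min))]
    else:
        frame = np.asarray(rf, dtype=np.float64)
    if frame.ndim != 2:
        raise InvalidSpecError("spatial RF must be 2-D")
    ny, nx = frame.shape
    x = np.arange(nx, dtype=np.float64) if x_deg is None else np.asarray(x_deg, float)
    y = np.arange(ny, dtype=np.float64) if y_deg is None else np.asarray(y_deg, float)
    xx, yy = np.meshgrid(x, y)

    iy, ix = np.unravel_index(int(np.argmax(np.abs(frame))), frame.shape)
    h0 = float(frame[iy, ix])
    w = np.abs(frame).ravel()
    wsum = w.sum()
    if wsum == 0:
        return Gaussian2DFit(0.0, float(x[ix]), float(y[iy]), 1.0, 1.0,
                             float("nan"), converged=False)
    wx0 = float(np.sqrt(np.sum(w * (xx.ravel() - x[ix]) ** 2) / wsum)) or 1.0
    wy0 = float(np.sqrt(np.sum(w * (yy.ravel() - y[iy]) ** 2) / wsum)) or 1.0
    try:
        popt, _ = curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            frame.ravel(),
            p0=[h0, float(x[ix]), float(y[iy]), wx0, wy0],
            maxfev=20000,
        )
        resid = float(np.sqrt(np.mean((_gauss2d((xx.ravel(), yy.ravel()), *popt) - frame.ravel()) ** 2)))
        h, cx, cy, wx, wy = popt
        return Gaussian2DFit(
            h=float(h), center_x=float(cx), center_y=float(cy),
            width_x=abs(float(wx)), width_y=abs(float(wy)), residual=resid,
        )
    except RuntimeError:
        return Gaussian2DFit(
            h=h0, center_x=float(x[ix]), center_y=float(y[iy]),
            width_x=wx0, width_y=wy0, residual=float("nan"), converged=False,
        )
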