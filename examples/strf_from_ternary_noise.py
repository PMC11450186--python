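"""Estimate a spatiotemporal receptive field by reverse correlation.

A model OFF neuron with a known 4-degree Gaussian receptive field responds
to two minutes of ternary white-noise stripes.  Reverse-correlating its
dF/F trace against the centered stimulus recovers the planted spatial
profile (negative, because the cell is OFF) and a Gaussian fit reports its
width as a FWHM.
"""

import numpy as np

from lumigain.imaging_analysis import compute_strf, extract_filters, filter_strfs
from lumigain.stimuli import WhiteNoiseSpec, make_ternary_noise
from lumigain.synthetic_recordings import (
    GroundTruthNeuron,
    RecordingManifest,
    generate_recording,
)

movie = make_ternary_noise(
    WhiteNoiseSpec(element=("stripe", 5.0), duration=120.0, seed=0),
    render="updates",
)
neuron = GroundTruthNeuron(
    rf_center=(5.0, 0.0), rf_sigma=4.0, polarity="OFF",
    noise_sd=0.2, temporal_kernel="delta",
)
rec, truth = generate_recording(
    RecordingManifest(neurons=(neuron,), frame_rate=20.0, n_trials=1, seed=1), movie
)

strf = compute_strf(rec.traces[0], rec.frame_rate, movie)
kept = filter_strfs([strf])
print(f"STRF kernel: {strf.n_lags} lags x {strf.spatial_shape} stripes, "
      f"peak amplitude {strf.amplitude:.4f}, "
      f"{'accepted' if kept else 'rejected'} by the amplitude filter")

spatial, temporal, fit = extract_filters(strf, degrees_per_pixel=movie.degrees_per_pixel)
x = (np.arange(len(spatial)) + 0.5) * movie.degrees_per_pixel - 30.0
planted = -np.exp(-((x - 5.0) ** 2) / (2 * 4.0**2))
corr = np.corrcoef(spatial, planted)[0, 1]
print(f"spatial profile correlation with the planted OFF filter: {corr:.3f}")
print(f"Gaussian fit: center {fit.mu - 30.0:+.1f} deg (planted +5.0), "
      f"sigma {fit.sigma:.2f} deg (planted 4.0), FWHM {fit.fwhm:.2f} deg")
print("the estimator recovers the OFF polarity and the filter location to "
      "within a stripe width; width estimates sharpen with longer noise "
      "presentations (the protocols use ~10 min).")
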