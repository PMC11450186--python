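"""Classify luminance-gain laws from synthetic recordings.

Three model neurons watch the same five-luminance drifting grating: one
whose contrast response scales with luminance (lamina-like), one divisively
normalized by the background luminance (Tm1-like, invariant) and one
normalized by its square (Tm9-like, low-luminance enhancing).  Running the
analysis pipeline (trial averaging, dF/F, F1 amplitude per epoch, slope
against log luminance) recovers each law from the slope's sign and size.
"""

import numpy as np

from lumigain.imaging_analysis import (
    dff,
    epoch_f1_amplitudes,
    luminance_slope,
    roi_reliability,
)
from lumigain.stimuli import (
    PROTOCOL_MEAN_LUMINANCES,
    GratingSpec,
    ScreenGeometry,
    make_drifting_grating,
)
from lumigain.synthetic_recordings import (
    GroundTruthNeuron,
    RecordingManifest,
    generate_recording,
)

movie = make_drifting_grating(GratingSpec(seed=5), ScreenGeometry(degrees_per_pixel=2.0))
laws = ("luminance_scaling", "luminance_invariant", "low_luminance_enhancing")
neurons = tuple(
    GroundTruthNeuron(gain_law=law, polarity="ON", noise_sd=0.1, rf_sigma=6.0)
    for law in laws
)
rec, _ = generate_recording(
    RecordingManifest(neurons=neurons, frame_rate=12.0, n_trials=3, seed=2), movie
)

lums = np.array(PROTOCOL_MEAN_LUMINANCES)
for i, law in enumerate(laws):
    trials = rec.trials(i)
    reliability, kept = roi_reliability(trials)
    trace = dff(np.mean(trials, axis=0)[None])[0]
    f1 = epoch_f1_amplitudes(trace, rec.epoch_labels[: len(trace)], rec.frame_rate, 1.0)
    resp = np.array([f1[k] for k in range(5)])
    slope = luminance_slope(lums, resp / resp.max())
    print(f"{law:>26}: reliability {reliability:.2f} "
          f"({'kept' if kept else 'rejected'}), slope {slope:+.3f}")
print("positive / near-zero / negative slopes classify the three gain "
      "laws exactly as constructed.")
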