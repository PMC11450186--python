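"""Scan the spatial pooling size of divisive normalization on natural scenes.

One synthetic reflectance field is rendered under four illumination
conditions (two mean levels x two shadow patterns).  Lamina responses to
each condition are divisively normalized by the pooled lamina signal over
discs of increasing diameter, sampled along stochastic gaze trajectories,
and condition pairs are compared with a two-term Wasserstein loss: term 1
penalizes contrast distributions that differ between illumination
conditions, term 2 penalizes normalization that destroys contrast
structure.  The loss is large for sub-degree pooling (responses collapse),
large again for near-global pooling (local illumination differences
survive), and minimal at an intermediate, local pooling extent.
"""

from lumigain.lmc_model import MembraneParams
from lumigain.natural_scenes import (
    EnsembleParams,
    scan_pooling_sizes,
    synthesize_scene_ensemble,
)

# scaled-down ensemble so the example runs in a couple of seconds
ens = synthesize_scene_ensemble(EnsembleParams(size=128, degrees_per_pixel=0.5), seed=0)
print("conditions:", ", ".join(
    f"{s.condition_label} (mean {s.luminance.mean():.2f})" for s in ens.scenes
))

result = scan_pooling_sizes(ens, MembraneParams(), n_trajectories=10, seed=0)
print(f"{'diameter (deg)':>15} {'loss mean':>10} {'loss std':>10}")
for _, row in result.table.iterrows():
    print(f"{row.pooling_diameter:>15.1f} {row.loss_mean:>10.4f} {row.loss_std:>10.4f}")

best = result.table.loc[result.table.loss_mean.idxmin()]
print(f"minimum loss at {best.pooling_diameter:g} degrees: local spatial "
      "pooling balances stable contrast coding across illumination against "
      "preserving contrast structure.")
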