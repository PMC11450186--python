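"""Area and column span of a presynaptic partner from synapse coordinates.

A columnar neuron's axis is the leading principal component of its
presynaptic-site cloud; a partner's synapses are projected onto the
perpendicular plane, where the convex-hull area and the maximal extent in
11.2-um column units quantify how many columns the partner innervates.
"""

import numpy as np

from lumigain.anatomy_geometry import SynapseCloud, hull_metrics, projection_plane

rng = np.random.default_rng(0)

# columnar reference neuron: sites along a vertical axis with ~1 um jitter
axis_sites = np.column_stack([
    rng.normal(0, 1.0, 300), rng.normal(0, 1.0, 300), rng.uniform(0, 40, 300)
])
plane = projection_plane(SynapseCloud(points=axis_sites))
print(f"projection axis: {np.round(plane.axis, 3)} (close to the z unit vector)")

# wide-field partner: synapses spread over ~3 column diameters in the plane
partner_xy = rng.normal(0, 11.2, size=(120, 2))
partner = SynapseCloud(points=plane.centroid + partner_xy @ plane.basis)
m = hull_metrics(partner, plane)
print(f"projected hull area: {m.area:.1f} um^2 over {m.n_points} synapses")
print(f"max extent {m.max_extent:.1f} um -> column span {m.column_span:.2f} "
      "(multiples of the 11.2 um column pitch)")
print("a span of ~3 or more columns marks a wide-field, multi-column input.")
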