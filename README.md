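# lumigain

Rapid luminance gain control in the fly visual system, as a tested,
reusable Python library. Natural scenes change their illumination on fast
timescales (sun to shade within a saccade), yet downstream vision needs
contrast representations that stay put. `lumigain` implements the
computational machinery used to study how *Drosophila* medulla neurons
(Tm1/Tm9) achieve this: visual stimulus generation, an effective membrane
model of lamina monopolar cells (LMCs, L2/L3), natural-scene contrast
sampling with a spatial-pooling loss, a shunting-inhibition
divisive-normalization circuit model, the calcium-imaging analysis pipeline
(ΔF/F, trial reliability, F1 amplitudes, reverse-correlation receptive
fields), and connectome point-cloud geometry — all exercisable end to end
on synthetic data with known ground truth. It is aimed at visual-circuits
researchers who want to reuse these analyses or probe the models without
any recorded data.

## The models

**LMC membrane model.** A lamina neuron's calcium-proxy response to a
luminance stimulus s(t) is the pseudo-stationary

    R(s) = α · max(v_L + g⁻¹ s, 0)²

with leak voltage v_L, inverse conductance g⁻¹ and output gain α
(L3 values: g⁻¹ = 0.05, v_L = 0.3, α = 4).

**Divisive normalization by shunting inhibition.** A Tm neuron's response
to its main lamina input I(t) is divided by a wide-field signal that pools
lamina responses I_i over columns within a pooling diameter:

    R = I / (g_l + Jᵖ),   J = Σ_{i∈ℛ} I_i

with leak conductance g_l and integer exponent p. With p = 1 (Tm1) the F1
contrast response becomes nearly independent of mean luminance; with p = 2
(Tm9) low-luminance responses are enhanced (negative slope against log
luminance).

**Pooling loss on natural scenes.** For one scene under sunny (S) and
shaded (D) illumination, with ρ(c) the contrast-response distribution along
stochastic gaze trajectories and P(c−c̄) its mean-centered version,

    𝓛² = 𝓓[ρ(c)_S | ρ(c)_D]² + 𝓓[P(c−c̄)_D | P(c−c̄)_{D−norm}]²

where 𝓓 is the order-1 Wasserstein distance. The first term penalizes
contrast codes that differ between illumination conditions, the second
penalizes normalization that collapses contrast structure. Scanning the
pooling diameter traces a U-shaped loss whose minimum sits at local,
multi-column pooling.

## Worked example

```bash
python examples/circuit_luminance_invariance.py
```

prints (abridged):

```
calibrated leak conductance g_l = 0.001
 luminance (photons/s)   input F1     Tm1 F1       Tm9 F1
              1.2e+04   2.88e+06     0.2407     1.57e-08
              ...
              1.06e+05   2.25e+08     0.2408     2.02e-10
slope of max-normalized F1 vs log10 luminance: input +0.939, Tm1 +0.00024, Tm9 -0.986
Tm1 slope is 0.026% of its input's
```

The un-normalized lamina input's contrast response grows steeply with mean
luminance (slope ≈ +0.94 per decade after normalizing each curve to its
maximum). Passing the same input through the p = 1 normalization circuit
with a 15° pool flattens that dependence by four orders of magnitude —
luminance invariance — while the p = 2 circuit inverts it, the two
cell-type-specific signatures the models are built to explain.

Other short, narrative scripts in `examples/` cover stimulus contrast
calibration, the membrane-model fit, the scene pooling scan,
reverse-correlation receptive-field estimation, gain-law classification
through the imaging pipeline, and synapse-cloud geometry. The `lumigain`
CLI exposes the same stages (`lumigain stim|lmc-fit|scene-scan|circuit-sim|
synth|analyze|run`) for scripted pipelines.

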