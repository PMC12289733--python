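"""Ventriloquism in the two-layer firing-rate network.

Auditory and visual layers of spatially tuned neurons interact through
Gaussian cross-modal synapses.  A visual bump 6 deg away drags the auditory
activity bump — and hence its barycenter readout — toward the visual
position.  With the synapses cut, the shift disappears.
"""

from msimodels import AVNetParams, Stimulus, barycenter_readout, simulate_av

stimuli = {
    "auditory": Stimulus(modality="auditory", position=45.0, duration=400.0),
    "visual": Stimulus(modality="visual", position=51.0, duration=400.0),
}

for label, params in [
    ("coupled  ", AVNetParams(n_neurons=90)),
    ("decoupled", AVNetParams(n_neurons=90, W0_av=0.0, W0_va=0.0)),
]:
    result = simulate_av(stimuli, params, duration=400.0, seed=0)
    positions = result.activity.coords["x"].values
    estimate = barycenter_readout(result.get_mode("auditory").values[-1], positions)
    print(f"{label}: auditory estimate = {estimate:6.2f} deg "
          f"(bias {(estimate - 45.0) / 6.0:+.2f})")
print()
print("The coupled network mislocalizes the sound toward the light; severing")
print("the cross-modal synapses abolishes the effect entirely.")
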