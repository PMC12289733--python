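"""Temporal unity judgments from the three-layer network.

Brief (50 ms) co-located flashes and beeps are presented at increasing
onset asynchronies.  The multisensory layer only fires strongly when the
filtered feedforward drive from both unisensory layers overlaps in time, so
the causal readout (peak multisensory activation) falls off with asynchrony
— the network's version of the temporal binding window.
"""

from msimodels import STCIParams, Stimulus, simulate_stci

params = STCIParams()  # full 180-neuron ring; the feedforward drive that
# gates the multisensory layer scales with neuron density
print("onset asynchrony (ms)   common-source readout")
for delta in (0.0, 20.0, 80.0, 150.0, 250.0):
    stimuli = {
        "auditory": Stimulus(modality="auditory", position=90.0,
                             onset=160.0 + delta, duration=50.0),
        "visual": Stimulus(modality="visual", position=90.0,
                           onset=160.0, duration=50.0),
    }
    result = simulate_stci(stimuli, params, duration=500.0, seed=0)
    print(f"{delta:>20.0f}   {float(result.causes.values.max()):.3f}")
print()
print("Synchronous stimuli are judged to share a cause; beyond ~80 ms the")
print("readout collapses to the unisensory baseline.")
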