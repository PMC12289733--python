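"""Bayesian causal inference across spatial disparities.

The observer weighs 'one common source' against 'two independent sources'.
Small audio-visual conflicts look like sensory noise (high posterior of a
common cause, strong ventriloquism); large conflicts look like separate
events (posterior drops, the auditory estimate snaps back to the truth).
"""

from msimodels import default_task, get_contract, run_task

contract = get_contract("bci")
table = run_task(contract, default_task("implicit_spatial"), {"p_common": 0.5})

print("disparity  posterior(common)  auditory bias")
for _, row in table.sort_values("disparity").iterrows():
    print(f"{row['disparity']:+9.0f}  {row['unity']:>16.3f}  {row['bias']:>13.3f}")
print()
print("Bias decays toward 0 as the disparity grows — the signature that")
print("distinguishes causal inference from plain reliability weighting,")
print("whose bias would stay constant at every disparity.")
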