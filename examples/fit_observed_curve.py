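"""Recovering a generative parameter from a behavioral unity curve.

A temporal unity curve is generated by the causal-inference observer with
p_common = 0.7, then treated as 'observed data': a seeded differential-
evolution search over p_common in [0, 1] minimizes the squared error
between model and data.  Self-recovery validates the fitting loop before
it is pointed at real response tables (CSV with columns disparity, value).
"""

import pandas as pd

from msimodels import default_task, fit_model, get_contract, run_task

contract = get_contract("bci", dimension="time")
task = default_task("explicit_temporal")

generated = run_task(contract, task, {"p_common": 0.7})
observed = pd.DataFrame(
    {"disparity": generated["disparity"], "value": generated["unity"]}
)

fit = fit_model(contract, observed, {"p_common": (0.0, 1.0)}, task,
                budget=1000, seed=42)
print(f"true p_common      : 0.70")
print(f"recovered p_common : {fit.params['p_common']:.3f}")
print(f"final SSE          : {fit.loss:.2e}  ({fit.n_evaluations} evaluations)")
print()
print("The search lands on the generating value with near-zero loss — the")
print("fitting machinery is unbiased on data the model can represent.")
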