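"""Near-optimal bimodal integrator (maximum-likelihood cue combination).

Two unisensory position estimates with Gaussian noise are fused by
reliability weighting:

    w_a = sigma_v^2 / (sigma_a^2 + sigma_v^2),   w_v = 1 - w_a
    s_hat = w_a * s_hat_a + w_v * s_hat_v
    sigma_fused^2 = sigma_a^2 sigma_v^2 / (sigma_a^2 + sigma_v^2)

The fused percept aligns with the more reliable cue and is always less
variable than either unisensory estimate.  The model is static (one time
step) and emits no causal-inference readout: reliability weighting has no
notion of a common versus separate cause, which is why its auditory bias is
the disparity-independent constant ``w_v``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .contract import ModelContract, ParameterError, ParameterSpec, register_model
from .results import MULTISENSORY, UNISENSORY, build_result
from .stimulus import Stimulus


def mle_weights(sigma_a: float, sigma_v: float) -> tuple[float, float]:
    """Reliability weights (w_a, w_v); precisions normalized to sum to 1."""
    if sigma_a <= 0 or sigma_v <= 0:
        raise ParameterError("sigmas must be > 0")
    va, vv = sigma_a**2, sigma_v**2
    w_a = vv / (va + vv)
    return w_a, 1.0 - w_a


def mle_estimate(
    s_hat_a: float, s_hat_v: float, sigma_a: float, sigma_v: float
) -> tuple[float, float]:
    """Fused position estimate and fused SD."""
    if not (np.isfinite(s_hat_a) and np.isfinite(s_hat_v)):
        raise ValueError("estimates must be finite")
    w_a, w_v = mle_weights(sigma_a, sigma_v)
    fused = w_a * s_hat_a + w_v * s_hat_v
    fused_sd = np.sqrt(sigma_a**2 * sigma_v**2 / (sigma_a**2 + sigma_v**2))
    return float(fused), float(fused_sd)


def _normal_density(grid: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    d = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    total = d.sum()
    if total == 0:
        raise ValueError(
            f"grid does not cover estimate {mu} (density underflow)"
        )
    return d / total


def mle_run(
    stimuli: Mapping[str, Stimulus],
    params: Mapping[str, float],
    seed: int | None = None,
    grid: np.ndarray | None = None,
):
    """Run the integrator on validated AV stimuli.

    Noiseless mode (stimulus ``noise`` = 0) takes the true positions as the
    unisensory estimates; otherwise estimates are drawn from
    ``N(position, sigma)`` with the run seed.  Each mode holds a normal
    density over the spatial grid, renormalized to sum to 1.
    """
    (mod_a, mod_v) = list(stimuli)
    stim_a, stim_v = stimuli[mod_a], stimuli[mod_v]
    sigma_a = params[f"{mod_a}_sigma"]
    sigma_v = params[f"{mod_v}_sigma"]
    if grid is None:
        grid = np.arange(0.0, 180.0, 1.0)
    rng = np.random.default_rng(seed)
    s_hat_a, s_hat_v = stim_a.position, stim_v.position
    if stim_a.noise > 0:
        s_hat_a = rng.normal(s_hat_a, sigma_a)
    if stim_v.noise > 0:
        s_hat_v = rng.normal(s_hat_v, sigma_v)
    fused, fused_sd = mle_estimate(s_hat_a, s_hat_v, sigma_a, sigma_v)
    act = {
        mod_a: _normal_density(grid, s_hat_a, sigma_a)[None, :],
        mod_v: _normal_density(grid, s_hat_v, sigma_v)[None, :],
        "multi": _normal_density(grid, fused, fused_sd)[None, :],
    }
    return build_result(
        per_mode_activity=act,
        coords={"time": [0.0], "x": grid},
        mode_roles={mod_a: UNISENSORY, mod_v: UNISENSORY, "multi": MULTISENSORY},
        causes=None,
        metadata={
            "measurements": {mod_a: float(s_hat_a), mod_v: float(s_hat_v)},
            # the integrator reports one fused percept for either modality
            "estimates": {mod_a: fused, mod_v: fused},
            "fused_estimate": fused,
            "fused_sd": fused_sd,
        },
    )


@register_model("mle")
def mle_contract(
    modalities: tuple[str, str] = ("auditory", "visual"),
    sigma_defaults: tuple[float, float] = (4.0, 3.0),
) -> ModelContract:
    """Contract for the bimodal integrator, modality-adaptive.

    Parameter template is ``{mod}_sigma`` per modality; the defaults follow
    the usual regime of spatial ventriloquism (audition less reliable than
    vision).
    """
    params = tuple(
        ParameterSpec(name=f"{m}_sigma", default=d, lower=1e-9)
        for m, d in zip(modalities, sigma_defaults)
    )
    return ModelContract(
        name="mle",
        modalities=tuple(modalities),
        multisensory_label="multi",
        n_spatial_dims=1,
        parameters=params,
        runner=mle_run,
        temporal=False,
        description="near-optimal bimodal integrator (reliability weighting)",
    )
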