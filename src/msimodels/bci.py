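"""Bayesian causal inference over one stimulus dimension.

The observer receives two noisy measurements ``x_a`` and ``x_v`` (positions
in degrees, or onsets in ms) and entertains two generative hypotheses:

* C = 1 — one source ``s ~ N(mu_p, sigma_p)`` produced both measurements,
  ``x_m ~ N(s, sigma_m)``;
* C = 2 — two independent sources, one per modality, each drawn from the
  same prior.

The posterior probability of a common cause follows from Bayes' rule with
prior ``p_common``, and the final per-modality estimates combine the fused
(C=1) and segregated (C=2) conditional estimates according to a readout
strategy (model averaging by default).

All closed forms below are exact marginalizations of this Gaussian
generative model; the test suite checks them against brute-force numerical
integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .contract import ModelContract, ParameterError, ParameterSpec, register_model
from .results import MULTISENSORY, UNISENSORY, build_result
from .stimulus import Stimulus

STRATEGIES = ("averaging", "selection", "matching")


@dataclass(frozen=True)
class BCIParams:
    """Generative-model parameters for one run."""

    p_common: float
    sigma_a: float
    sigma_v: float
    sigma_p: float
    mu_p: float
    strategy: str = "averaging"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_common <= 1.0:
            raise ParameterError("p_common must lie in [0, 1]")
        for name in ("sigma_a", "sigma_v", "sigma_p"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.strategy not in STRATEGIES:
            raise ParameterError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )


def likelihood_common(x_v: float, x_a: float, p: BCIParams) -> float:
    """p(x_v, x_a | C=1): both measurements from one prior-drawn source.

    Equals ``integral N(x_v; s, sigma_v) N(x_a; s, sigma_a) N(s; mu_p,
    sigma_p) ds`` in closed form.
    """
    va, vv, vp = p.sigma_a**2, p.sigma_v**2, p.sigma_p**2
    V = vv * va + vv * vp + va * vp
    expo = (
        (x_v - x_a) ** 2 * vp
        + (x_v - p.mu_p) ** 2 * va
        + (x_a - p.mu_p) ** 2 * vv
    ) / (2.0 * V)
    return math.exp(-expo) / (2.0 * math.pi * math.sqrt(V))


def likelihood_independent(x_v: float, x_a: float, p: BCIParams) -> float:
    """p(x_v, x_a | C=2): independent sources, factorized marginals
    ``N(x_v; mu_p, sigma_v^2 + sigma_p^2) * N(x_a; mu_p, sigma_a^2 + sigma_p^2)``.
    """
    vv = p.sigma_v**2 + p.sigma_p**2
    va = p.sigma_a**2 + p.sigma_p**2
    lv = math.exp(-((x_v - p.mu_p) ** 2) / (2 * vv)) / math.sqrt(2 * math.pi * vv)
    la = math.exp(-((x_a - p.mu_p) ** 2) / (2 * va)) / math.sqrt(2 * math.pi * va)
    return lv * la


def posterior_common(x_v: float, x_a: float, p: BCIParams) -> float:
    """Posterior probability of a common cause, pi = p(C=1 | x_v, x_a)."""
    l1 = likelihood_common(x_v, x_a, p)
    l2 = likelihood_independent(x_v, x_a, p)
    num = l1 * p.p_common
    den = num + l2 * (1.0 - p.p_common)
    if den == 0.0:
        raise ZeroDivisionError(
            "degenerate posterior: both likelihoods underflowed to zero"
        )
    return num / den


def conditional_estimates(x_v: float, x_a: float, p: BCIParams) -> dict[str, float]:
    """Posterior-mean estimates under each causal structure.

    Returns the fused estimate (shared by both modalities under C=1) and the
    per-modality segregated estimates under C=2, each a precision-weighted
    mean of measurement(s) and prior.
    """
    pa, pv, pp = 1 / p.sigma_a**2, 1 / p.sigma_v**2, 1 / p.sigma_p**2
    fused = (x_a * pa + x_v * pv + p.mu_p * pp) / (pa + pv + pp)
    seg_a = (x_a * pa + p.mu_p * pp) / (pa + pp)
    seg_v = (x_v * pv + p.mu_p * pp) / (pv + pp)
    return {
        "fused": fused,
        "seg_a": seg_a,
        "seg_v": seg_v,
        "fused_sd": math.sqrt(1 / (pa + pv + pp)),
        "seg_a_sd": math.sqrt(1 / (pa + pp)),
        "seg_v_sd": math.sqrt(1 / (pv + pp)),
    }


def final_estimates(
    x_v: float,
    x_a: float,
    p: BCIParams,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Strategy-combined per-modality estimates plus the posterior.

    * averaging — posterior-weighted mix of fused and segregated estimates;
    * selection — the more probable causal structure's estimate;
    * matching — structure sampled with probability ``pi`` (needs ``rng``).
    """
    pi = posterior_common(x_v, x_a, p)
    est = conditional_estimates(x_v, x_a, p)
    if p.strategy == "averaging":
        s_a = pi * est["fused"] + (1 - pi) * est["seg_a"]
        s_v = pi * est["fused"] + (1 - pi) * est["seg_v"]
    elif p.strategy == "selection":
        common = pi >= 0.5
        s_a = est["fused"] if common else est["seg_a"]
        s_v = est["fused"] if common else est["seg_v"]
    else:  # matching
        if rng is None:
            rng = np.random.default_rng(0)
        common = rng.uniform() < pi
        s_a = est["fused"] if common else est["seg_a"]
        s_v = est["fused"] if common else est["seg_v"]
    return {"posterior_common": pi, "est_a": s_a, "est_v": s_v, **est}


def _mixture_density(
    grid: np.ndarray, w1: float, mu1: float, sd1: float, mu2: float, sd2: float
) -> np.ndarray:
    d = w1 * np.exp(-0.5 * ((grid - mu1) / sd1) ** 2) / sd1
    d = d + (1 - w1) * np.exp(-0.5 * ((grid - mu2) / sd2) ** 2) / sd2
    total = d.sum()
    if total == 0:
        raise ValueError("grid does not cover the posterior mass")
    return d / total


def bci_run(
    stimuli: Mapping[str, Stimulus],
    params: Mapping[str, float],
    seed: int | None = None,
    grid: np.ndarray | None = None,
    dimension: str = "space",
    strategy: str = "averaging",
):
    """Run causal inference on validated AV stimuli.

    ``dimension="space"`` feeds stimulus positions (deg) to the generative
    model, ``dimension="time"`` feeds onsets (ms) — the same equations apply
    with ms units.  Noiseless stimuli (noise = 0) set the measurements to
    the true values; otherwise measurements are drawn from
    ``N(value, sigma_m)`` using the run seed.

    The unisensory modes carry each modality's full posterior marginal (the
    fused/segregated mixture), the multisensory mode the fused (C=1)
    posterior density, and ``causes`` the scalar posterior probability of a
    common cause.
    """
    (mod_a, mod_v) = list(stimuli)
    stim_a, stim_v = stimuli[mod_a], stimuli[mod_v]
    p = BCIParams(
        p_common=params["p_common"],
        sigma_a=params[f"{mod_a}_sigma"],
        sigma_v=params[f"{mod_v}_sigma"],
        sigma_p=params["sigma_p"],
        mu_p=params["mu_p"],
        strategy=strategy,
    )
    if dimension == "space":
        true_a, true_v = stim_a.position, stim_v.position
        if grid is None:
            grid = np.arange(0.0, 180.0, 1.0)
    elif dimension == "time":
        true_a, true_v = stim_a.onset, stim_v.onset
        if grid is None:
            grid = np.arange(0.0, 500.0, 2.0)
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    rng = np.random.default_rng(seed)
    x_a, x_v = float(true_a), float(true_v)
    if stim_a.noise > 0:
        x_a = float(rng.normal(x_a, p.sigma_a))
    if stim_v.noise > 0:
        x_v = float(rng.normal(x_v, p.sigma_v))
    out = final_estimates(x_v, x_a, p, rng=rng)
    pi = out["posterior_common"]
    act = {
        mod_a: _mixture_density(
            grid, pi, out["fused"], out["fused_sd"], out["seg_a"], out["seg_a_sd"]
        )[None, :],
        mod_v: _mixture_density(
            grid, pi, out["fused"], out["fused_sd"], out["seg_v"], out["seg_v_sd"]
        )[None, :],
        "multi": _mixture_density(
            grid, 1.0, out["fused"], out["fused_sd"], out["fused"], out["fused_sd"]
        )[None, :],
    }
    return build_result(
        per_mode_activity=act,
        coords={"time": [0.0], "x": np.asarray(grid, dtype=float)},
        mode_roles={mod_a: UNISENSORY, mod_v: UNISENSORY, "multi": MULTISENSORY},
        causes=pi,
        metadata={
            "dimension": dimension,
            "strategy": strategy,
            "measurements": {mod_a: x_a, mod_v: x_v},
            "estimates": {mod_a: out["est_a"], mod_v: out["est_v"]},
            "posterior_common": pi,
        },
    )


@register_model("bci")
def bci_contract(
    modalities: tuple[str, str] = ("auditory", "visual"),
    dimension: str = "space",
    strategy: str = "averaging",
) -> ModelContract:
    """Contract factory for the causal-inference observer.

    Spatial defaults put audition slightly less reliable than vision (deg
    units); temporal defaults use ms-scale noise.  ``mu_p`` defaults to the
    middle of the stimulus range each task uses (45 deg / 160 ms) and should
    be set explicitly for other setups.
    """
    mod_a, mod_v = modalities
    if dimension == "space":
        sig_a, sig_v, sig_p, mu_p = 4.0, 3.0, 15.0, 45.0
    elif dimension == "time":
        sig_a, sig_v, sig_p, mu_p = 50.0, 50.0, 150.0, 160.0
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    params = (
        ParameterSpec("p_common", 0.5, 0.0, 1.0),
        ParameterSpec(f"{mod_a}_sigma", sig_a, 1e-9),
        ParameterSpec(f"{mod_v}_sigma", sig_v, 1e-9),
        ParameterSpec("sigma_p", sig_p, 1e-9),
        ParameterSpec("mu_p", mu_p),
    )

    def runner(stimuli, resolved, seed):
        return bci_run(
            stimuli, resolved, seed, dimension=dimension, strategy=strategy
        )

    return ModelContract(
        name="bci" if dimension == "space" else "bci_time",
        modalities=tuple(modalities),
        multisensory_label="multi",
        n_spatial_dims=1,
        parameters=params,
        runner=runner,
        temporal=(dimension == "time"),
        description="Bayesian causal inference (common vs independent cause)",
    )
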