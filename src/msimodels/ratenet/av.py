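"""Two-layer audio-visual firing-rate network.

Two unisensory layers (auditory, visual) of rate-coded neurons on a ring,
each with Mexican-hat lateral connectivity, coupled by non-negative Gaussian
cross-modal synapses.  External stimuli are Gaussian bumps gated by
onset/duration.  The perceived position of each modality is the barycenter
of its layer's activity; cross-modal coupling makes one modality's
barycenter shift toward a concurrent stimulus in the other modality — the
network account of the ventriloquist effect.

This model has no multisensory layer: the ``multi`` mode of its result is
the mean of the two layer activities, a documented surrogate kept so the
output satisfies the uniform result contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ..contract import ModelContract, ParameterSpec, register_model
from ..results import MULTISENSORY, UNISENSORY, build_result
from ..stimulus import Stimulus
from .dynamics import check_finite, sigmoid
from .kernels import (
    gaussian_input_profile,
    gaussian_weights,
    mexican_hat_weights,
    preferred_positions,
)


@dataclass(frozen=True)
class AVNetParams:
    """Structural and dynamical constants of the two-layer network.

    Defaults place the network in the classic regime of this model family:
    narrow strong lateral excitation with broad inhibition (bump attractor),
    a broad auditory and narrow visual input kernel (vision dominates
    spatially), and suprathreshold stimulus drive.
    """

    n_neurons: int = 180  # 1 deg / neuron on a 180-deg ring
    extent: float = 180.0
    # lateral Mexican hat
    L_ex: float = 5.0
    sigma_ex: float = 3.0
    L_in: float = 4.0
    sigma_in: float = 24.0
    # cross-modal Gaussian synapses
    W0_av: float = 3.5  # visual -> auditory amplitude
    W0_va: float = 3.5  # auditory -> visual amplitude
    sigma_c: float = 10.0
    # neuron nonlinearity
    slope: float = 0.6
    theta: float = 20.0
    # time constants (ms)
    tau_a: float = 15.0
    tau_v: float = 15.0
    dt: float = 0.1
    # external input
    E0_a: float = 28.0
    E0_v: float = 27.0
    sigma_stim_a: float = 15.0
    sigma_stim_v: float = 4.0
    noise_frac: float = 0.0  # SD of per-neuron multiplicative perturbation

    def __post_init__(self) -> None:
        if self.n_neurons < 3:
            raise ValueError("n_neurons must be >= 3")
        for name in (
            "sigma_ex",
            "sigma_in",
            "sigma_c",
            "tau_a",
            "tau_v",
            "dt",
            "sigma_stim_a",
            "sigma_stim_v",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt > min(self.tau_a, self.tau_v) / 10.0:
            raise ValueError("dt must be <= min(tau)/10 for stable Euler steps")


def build_lateral_weights(params: AVNetParams) -> np.ndarray:
    """Mexican-hat lateral kernel shared by both unisensory layers."""
    return mexican_hat_weights(
        params.n_neurons,
        params.L_ex,
        params.sigma_ex,
        params.L_in,
        params.sigma_in,
        params.extent,
    )


def build_crossmodal_weights(params: AVNetParams) -> tuple[np.ndarray, np.ndarray]:
    """(W_av, W_va): Gaussian synapses into auditory from visual and vice versa."""
    w_av = gaussian_weights(params.n_neurons, params.W0_av, params.sigma_c, params.extent)
    w_va = gaussian_weights(params.n_neurons, params.W0_va, params.sigma_c, params.extent)
    return w_av, w_va


def external_input(
    stimulus: Stimulus,
    params: AVNetParams,
    t: float,
    noise_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Input vector at time ``t``: Gaussian bump during the stimulus window.

    ``noise_factors`` is the per-neuron multiplicative perturbation
    ``1 + eta`` drawn once per trial (see :func:`trial_noise_factors`).
    """
    if not 0.0 <= stimulus.position < params.extent:
        raise ValueError(
            f"position {stimulus.position} outside [0, {params.extent})"
        )
    if not (stimulus.onset <= t < stimulus.onset + stimulus.duration):
        return np.zeros(params.n_neurons)
    e0, sig = _modality_input_constants(stimulus.modality, params)
    profile = gaussian_input_profile(
        params.n_neurons, stimulus.position, stimulus.intensity * e0, sig, params.extent
    )
    if noise_factors is not None:
        profile = profile * noise_factors
    return profile


def trial_noise_factors(
    params: AVNetParams, rng: np.random.Generator
) -> np.ndarray | None:
    """Per-neuron factors ``1 + eta``, eta ~ N(0, noise_frac); None if 0."""
    if params.noise_frac == 0:
        return None
    return 1.0 + rng.normal(0.0, params.noise_frac, params.n_neurons)


def _modality_input_constants(modality: str, params: AVNetParams) -> tuple[float, float]:
    if modality == "auditory":
        return params.E0_a, params.sigma_stim_a
    if modality == "visual":
        return params.E0_v, params.sigma_stim_v
    raise ValueError(f"network has no input channel for modality {modality!r}")


def simulate_av(
    stimuli: Mapping[str, Stimulus],
    params: AVNetParams,
    duration: float = 500.0,
    seed: int | None = None,
    record_every: int = 10,
):
    """Euler-integrate the two-layer network and package an NDResult.

    Rates start at zero; trajectories are recorded every ``record_every``
    steps (default 1 ms at dt = 0.1).  The result's ``multi`` mode is the
    mean of the two layers (surrogate, see module docstring); ``causes`` is
    absent because this model computes no causal readout.
    """
    stim_a, stim_v = stimuli["auditory"], stimuli["visual"]
    n = params.n_neurons
    lat = build_lateral_weights(params)
    w_av, w_va = build_crossmodal_weights(params)
    rng = np.random.default_rng(seed)
    nf_a = trial_noise_factors(params, rng)
    nf_v = trial_noise_factors(params, rng)

    prof_a = external_input(
        replace_onset_zero(stim_a), params, 0.0, noise_factors=nf_a
    )
    prof_v = external_input(
        replace_onset_zero(stim_v), params, 0.0, noise_factors=nf_v
    )

    dt = params.dt
    n_steps = int(round(duration / dt))
    n_rec = n_steps // record_every + 1
    traj_a = np.zeros((n_rec, n))
    traj_v = np.zeros((n_rec, n))
    rec_t = np.zeros(n_rec)

    z_a = np.zeros(n)
    z_v = np.zeros(n)
    k = 1
    for i in range(n_steps):
        t = i * dt
        e_a = prof_a if stim_a.onset <= t < stim_a.onset + stim_a.duration else 0.0
        e_v = prof_v if stim_v.onset <= t < stim_v.onset + stim_v.duration else 0.0
        q_a = e_a + lat @ z_a + w_av @ z_v
        q_v = e_v + lat @ z_v + w_va @ z_a
        z_a = z_a + (dt / params.tau_a) * (-z_a + sigmoid(q_a, params.slope, params.theta))
        z_v = z_v + (dt / params.tau_v) * (-z_v + sigmoid(q_v, params.slope, params.theta))
        if (i + 1) % record_every == 0 and k < n_rec:
            check_finite(z_a, t, "auditory")
            check_finite(z_v, t, "visual")
            traj_a[k] = z_a
            traj_v[k] = z_v
            rec_t[k] = (i + 1) * dt
            k += 1

    positions = preferred_positions(n, params.extent)
    return build_result(
        per_mode_activity={
            "auditory": traj_a,
            "visual": traj_v,
            "multi": 0.5 * (traj_a + traj_v),
        },
        coords={"time": rec_t, "x": positions},
        mode_roles={
            "auditory": UNISENSORY,
            "visual": UNISENSORY,
            "multi": MULTISENSORY,
        },
        causes=None,
        metadata={"network": "av", "duration": duration},
    )


def replace_onset_zero(stim: Stimulus) -> Stimulus:
    """Copy of the stimulus with the window open at t=0 (profile probe)."""
    return stim.model_copy(update={"onset": 0.0})


_SCHEMA_FIELDS = (
    ("L_ex", 0.0, 50.0),
    ("sigma_ex", 1e-6, 90.0),
    ("L_in", 0.0, 50.0),
    ("sigma_in", 1e-6, 90.0),
    ("W0_av", 0.0, 50.0),
    ("W0_va", 0.0, 50.0),
    ("sigma_c", 1e-6, 90.0),
    ("slope", 1e-6, 10.0),
    ("theta", 0.0, 100.0),
    ("tau_a", 1.0, 200.0),
    ("tau_v", 1.0, 200.0),
    ("E0_a", 0.0, 200.0),
    ("E0_v", 0.0, 200.0),
    ("sigma_stim_a", 1e-6, 90.0),
    ("sigma_stim_v", 1e-6, 90.0),
    ("noise_frac", 0.0, 1.0),
)


@register_model("net_av")
def av_contract(
    n_neurons: int = 180,
    dt: float = 0.1,
    duration: float = 500.0,
    record_every: int = 10,
) -> ModelContract:
    """Contract for the two-layer network (audio-visual only)."""
    base = AVNetParams()
    specs = tuple(
        ParameterSpec(name, getattr(base, name), lo, hi)
        for name, lo, hi in _SCHEMA_FIELDS
    )

    def runner(stimuli, resolved, seed):
        p = AVNetParams(n_neurons=n_neurons, dt=dt, **resolved)
        return simulate_av(
            stimuli, p, duration=duration, seed=seed, record_every=record_every
        )

    return ModelContract(
        name="net_av",
        modalities=("auditory", "visual"),
        multisensory_label="multi",
        n_spatial_dims=1,
        parameters=specs,
        runner=runner,
        temporal=True,
        description="two-layer audio-visual rate network (Mexican-hat ring)",
    )
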