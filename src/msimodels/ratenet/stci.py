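"""Three-layer multisensory spatiotemporal causal-inference network.

Extends the two-layer audio-visual network with a multisensory layer joined
to both unisensory layers by feedforward (unisensory -> multisensory) and
feedback (multisensory -> unisensory) Gaussian synapses.  Pathways carry
latencies (cross-modal, feedforward, feedback) implemented as ring buffers
of past rates, and first-order low-pass temporal filters per neuron
population shape the temporal progression of the synaptic drive.

Dual readout:

* implicit — barycenter of each unisensory layer (spatial estimate, deg);
* explicit — the maximal multisensory activation normalized by
  ``causes_norm`` gives a value in [0, 1] per time step interpreted as the
  proportion of common-source reports; the trial-level value is its peak
  over time, so transient multisensory responses under temporal disparity
  are not missed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ..contract import ModelContract, ParameterSpec, register_model
from ..results import MULTISENSORY, UNISENSORY, build_result
from ..stimulus import Stimulus
from .av import (
    AVNetParams,
    _SCHEMA_FIELDS,
    build_crossmodal_weights,
    build_lateral_weights,
    external_input,
    replace_onset_zero,
    trial_noise_factors,
)
from .dynamics import DelayBuffer, barycenter_readout, check_finite, sigmoid
from .kernels import gaussian_weights, mexican_hat_weights, preferred_positions


@dataclass(frozen=True)
class STCIParams(AVNetParams):
    """Two-layer constants plus the multisensory layer's connectivity,
    temporal filters and pathway latencies (ms)."""

    # weaker direct cross-modal coupling than the two-layer model: part of
    # the interaction is carried by the feedback loop through the
    # multisensory layer instead
    W0_av: float = 1.5
    W0_va: float = 1.5
    # feedforward / feedback interlayer synapses
    W0_mc: float = 2.2
    sigma_mc: float = 3.0
    W0_cm: float = 4.0
    sigma_cm: float = 3.0
    # multisensory lateral Mexican hat
    L0_ex_c: float = 3.0
    sigma_ex_c: float = 3.0
    L0_in_c: float = 2.6
    sigma_in_c: float = 24.0
    tau_c: float = 15.0
    # temporal filters (0 = off)
    tau_filt_a: float = 20.0
    tau_filt_v: float = 20.0
    tau_filt_c: float = 10.0
    # pathway latencies
    delta_cm: float = 5.0
    delta_ff: float = 10.0
    delta_fb: float = 10.0
    # causal readout normalization (sigmoid ceiling by default)
    causes_norm: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("W0_mc", "W0_cm", "L0_ex_c", "L0_in_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("delta_cm", "delta_ff", "delta_fb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_filt_a", "tau_filt_v", "tau_filt_c"):
            tf = getattr(self, name)
            if tf != 0 and tf < self.dt:
                raise ValueError(f"{name} must be 0 (off) or >= dt")
        if self.tau_c <= 0 or self.dt > self.tau_c / 10.0:
            raise ValueError("tau_c must be > 0 with dt <= tau_c/10")
        if self.causes_norm <= 0:
            raise ValueError("causes_norm must be > 0")


def build_interlayer_weights(
    params: STCIParams,
) -> tuple[np.ndarray, np.ndarray]:
    """(W_mc, W_cm): Gaussian feedforward and feedback kernels.

    The same kernel serves both modalities on each pathway (the layers share
    the spatial grid), so scaling an amplitude scales every entry linearly.
    """
    w_mc = gaussian_weights(params.n_neurons, params.W0_mc, params.sigma_mc, params.extent)
    w_cm = gaussian_weights(params.n_neurons, params.W0_cm, params.sigma_cm, params.extent)
    return w_mc, w_cm


def causal_readout(multi_activity: np.ndarray, causes_norm: float) -> np.ndarray:
    """Per-time causal-inference value: max multisensory rate / norm, in [0,1].

    ``multi_activity`` is (time, neurons); pointwise-larger activity never
    lowers the readout (monotone).
    """
    if causes_norm <= 0:
        raise ValueError("causes_norm must be > 0")
    arr = np.atleast_2d(np.asarray(multi_activity, dtype=float))
    return np.clip(arr.max(axis=-1) / causes_norm, 0.0, 1.0)


def implicit_readout(result) -> dict[str, float]:
    """Barycenter (deg) of each unisensory layer at the final time step."""
    positions = result.activity.coords["x"].values
    out = {}
    for mode in result.unisensory_modes:
        final = result.get_mode(mode).values[-1]
        out[mode] = barycenter_readout(final, positions)
    return out


class _Lowpass:
    """Online first-order low-pass; tau = 0 passes the input through."""

    def __init__(self, tau: float, dt: float, n: int):
        self.tau = tau
        self.a = dt / tau if tau > 0 else None
        self.g = np.zeros(n)

    def step(self, x: np.ndarray) -> np.ndarray:
        if self.a is None:
            return x
        self.g = self.g + self.a * (x - self.g)
        return self.g


def simulate_stci(
    stimuli: Mapping[str, Stimulus],
    params: STCIParams,
    duration: float = 500.0,
    seed: int | None = None,
    record_every: int = 10,
):
    """Euler-integrate the three-layer network and package an NDResult.

    Net inputs per step (pre-update rates throughout):

    * unisensory m: external + lateral + delayed cross-modal + delayed,
      filtered feedback from the multisensory layer;
    * multisensory: lateral + delayed, filtered feedforward from both
      unisensory layers.

    ``causes`` is the per-recorded-time causal readout series.
    """
    stim_a, stim_v = stimuli["auditory"], stimuli["visual"]
    n = params.n_neurons
    lat = build_lateral_weights(params)
    lat_c = mexican_hat_weights(
        n, params.L0_ex_c, params.sigma_ex_c, params.L0_in_c, params.sigma_in_c,
        params.extent,
    )
    w_av, w_va = build_crossmodal_weights(params)
    w_mc, w_cm = build_interlayer_weights(params)
    rng = np.random.default_rng(seed)
    nf_a = trial_noise_factors(params, rng)
    nf_v = trial_noise_factors(params, rng)
    prof_a = external_input(replace_onset_zero(stim_a), params, 0.0, noise_factors=nf_a)
    prof_v = external_input(replace_onset_zero(stim_v), params, 0.0, noise_factors=nf_v)

    dt = params.dt
    n_steps = int(round(duration / dt))
    k_cm = int(round(params.delta_cm / dt))
    k_ff = int(round(params.delta_ff / dt))
    k_fb = int(round(params.delta_fb / dt))
    buf_len = max(k_cm, k_ff, k_fb, 1)
    hist_a = DelayBuffer(buf_len, (n,))
    hist_v = DelayBuffer(buf_len, (n,))
    hist_c = DelayBuffer(buf_len, (n,))
    lp_fb_a = _Lowpass(params.tau_filt_a, dt, n)
    lp_fb_v = _Lowpass(params.tau_filt_v, dt, n)
    lp_ff = _Lowpass(params.tau_filt_c, dt, n)

    n_rec = n_steps // record_every + 1
    traj_a = np.zeros((n_rec, n))
    traj_v = np.zeros((n_rec, n))
    traj_c = np.zeros((n_rec, n))
    rec_t = np.zeros(n_rec)

    z_a = np.zeros(n)
    z_v = np.zeros(n)
    z_c = np.zeros(n)
    k = 1
    for i in range(n_steps):
        t = i * dt
        e_a = prof_a if stim_a.onset <= t < stim_a.onset + stim_a.duration else 0.0
        e_v = prof_v if stim_v.onset <= t < stim_v.onset + stim_v.duration else 0.0

        z_a_del = z_a if k_cm == 0 else hist_a.read(k_cm)
        z_v_del = z_v if k_cm == 0 else hist_v.read(k_cm)
        z_a_ff = z_a if k_ff == 0 else hist_a.read(k_ff)
        z_v_ff = z_v if k_ff == 0 else hist_v.read(k_ff)
        z_c_fb = z_c if k_fb == 0 else hist_c.read(k_fb)

        fb = w_cm @ z_c_fb
        fb_a = lp_fb_a.step(fb)
        fb_v = lp_fb_v.step(fb)
        ff = lp_ff.step(w_mc @ z_a_ff + w_mc @ z_v_ff)

        q_a = e_a + lat @ z_a + w_av @ z_v_del + fb_a
        q_v = e_v + lat @ z_v + w_va @ z_a_del + fb_v
        q_c = lat_c @ z_c + ff

        hist_a.push(z_a)
        hist_v.push(z_v)
        hist_c.push(z_c)

        z_a = z_a + (dt / params.tau_a) * (-z_a + sigmoid(q_a, params.slope, params.theta))
        z_v = z_v + (dt / params.tau_v) * (-z_v + sigmoid(q_v, params.slope, params.theta))
        z_c = z_c + (dt / params.tau_c) * (-z_c + sigmoid(q_c, params.slope, params.theta))
        if (i + 1) % record_every == 0 and k < n_rec:
            check_finite(z_a, t, "auditory")
            check_finite(z_v, t, "visual")
            check_finite(z_c, t, "multisensory")
            traj_a[k] = z_a
            traj_v[k] = z_v
            traj_c[k] = z_c
            rec_t[k] = (i + 1) * dt
            k += 1

    positions = preferred_positions(n, params.extent)
    causes = causal_readout(traj_c, params.causes_norm)
    return build_result(
        per_mode_activity={
            "auditory": traj_a,
            "visual": traj_v,
            "multi": traj_c,
        },
        coords={"time": rec_t, "x": positions},
        mode_roles={
            "auditory": UNISENSORY,
            "visual": UNISENSORY,
            "multi": MULTISENSORY,
        },
        causes=causes,
        metadata={"network": "stci", "duration": duration},
    )


_STCI_EXTRA_FIELDS = (
    ("W0_mc", 0.0, 50.0),
    ("sigma_mc", 1e-6, 90.0),
    ("W0_cm", 0.0, 50.0),
    ("sigma_cm", 1e-6, 90.0),
    ("L0_ex_c", 0.0, 50.0),
    ("sigma_ex_c", 1e-6, 90.0),
    ("L0_in_c", 0.0, 50.0),
    ("sigma_in_c", 1e-6, 90.0),
    ("tau_c", 1.0, 200.0),
    ("tau_filt_a", 0.0, 500.0),
    ("tau_filt_v", 0.0, 500.0),
    ("tau_filt_c", 0.0, 500.0),
    ("delta_cm", 0.0, 100.0),
    ("delta_ff", 0.0, 100.0),
    ("delta_fb", 0.0, 100.0),
    ("causes_norm", 1e-6, 100.0),
)


@register_model("net_stci")
def stci_contract(
    n_neurons: int = 180,
    dt: float = 0.1,
    duration: float = 500.0,
    record_every: int = 10,
) -> ModelContract:
    """Contract for the three-layer spatiotemporal network."""
    base = STCIParams()
    specs = tuple(
        ParameterSpec(name, getattr(base, name), lo, hi)
        for name, lo, hi in _SCHEMA_FIELDS + _STCI_EXTRA_FIELDS
    )

    def runner(stimuli, resolved, seed):
        p = STCIParams(n_neurons=n_neurons, dt=dt, **resolved)
        return simulate_stci(
            stimuli, p, duration=duration, seed=seed, record_every=record_every
        )

    return ModelContract(
        name="net_stci",
        modalities=("auditory", "visual"),
        multisensory_label="multi",
        n_spatial_dims=1,
        parameters=specs,
        runner=runner,
        temporal=True,
        description="three-layer spatiotemporal causal-inference network",
    )
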