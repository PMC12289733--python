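"""Shared pieces of the rate dynamics.

Each neuron's rate follows a first-order equation driven through a sigmoid:

    tau dz/dt = -z + F(q),     F(q) = 1 / (1 + exp(-s (q - theta)))

integrated with forward Euler at fixed ``dt`` (dt <= min(tau)/10 enforced by
the parameter containers).  With z(0) in [0, 1) the rates stay in [0, 1)
for all time because F is bounded in (0, 1) and the Euler update is a convex
combination for dt < tau.
"""

from __future__ import annotations

import numpy as np


def sigmoid(q: np.ndarray, slope: float, theta: float) -> np.ndarray:
    """Static neuron nonlinearity F(q); F(theta) = 0.5."""
    return 1.0 / (1.0 + np.exp(-slope * (q - theta)))


def euler_step(
    z: np.ndarray, q: np.ndarray, dt: float, tau: float, slope: float, theta: float
) -> np.ndarray:
    """One forward-Euler update of a layer."""
    return z + (dt / tau) * (-z + sigmoid(q, slope, theta))


def check_finite(z: np.ndarray, t: float, layer: str) -> None:
    if not np.all(np.isfinite(z)):
        bad = int(np.argmax(~np.isfinite(z)))
        raise FloatingPointError(
            f"non-finite rate in layer {layer!r} at t={t:.2f} ms, neuron {bad}"
        )


def barycenter_readout(activity: np.ndarray, positions: np.ndarray) -> float:
    """Activity-weighted mean preferred position (deg).

    Arithmetic (non-circular) mean: valid for task stimuli that sit
    mid-grid, far from the ring's wrap point.  All-zero activity has no
    defined barycenter and raises.
    """
    activity = np.asarray(activity, dtype=float)
    total = activity.sum()
    if total <= 0 or not np.any(activity > 0):
        raise ValueError("no activity to read out")
    return float((positions * activity).sum() / total)


def temporal_filter_series(series: np.ndarray, tau_filt: float, dt: float) -> np.ndarray:
    """First-order low-pass over the leading (time) axis; tau = 0 is identity.

    g <- g + (dt / tau)(-g + x), g(0) = 0.  A bounded input yields a bounded
    output within the same bounds.
    """
    if tau_filt == 0:
        return np.array(series, copy=True)
    out = np.zeros_like(series, dtype=float)
    g = np.zeros(series.shape[1:], dtype=float)
    a = dt / tau_filt
    for i in range(series.shape[0]):
        g = g + a * (series[i] - g)
        out[i] = g
    return out


def delayed_series(series: np.ndarray, latency: float, dt: float) -> np.ndarray:
    """Shift a time series by ``latency`` ms (zero before the delay elapses).

    Latencies that are not a multiple of ``dt`` round to the nearest step;
    composing two delays equals the summed delay up to that rounding.
    """
    if latency < 0:
        raise ValueError("latency must be >= 0")
    k = int(round(latency / dt))
    if k == 0:
        return np.array(series, copy=True)
    out = np.zeros_like(series, dtype=float)
    if k < series.shape[0]:
        out[k:] = series[:-k]
    return out


class DelayBuffer:
    """Fixed-length ring buffer of past layer states for online delays."""

    def __init__(self, n_steps: int, shape: tuple[int, ...]):
        self.n = max(n_steps, 1)
        self.buf = np.zeros((self.n,) + shape, dtype=float)
        self.idx = 0
        self.filled = 0

    def push(self, value: np.ndarray) -> None:
        self.buf[self.idx] = value
        self.idx = (self.idx + 1) % self.n
        self.filled = min(self.filled + 1, self.n)

    def read(self, k: int) -> np.ndarray:
        """Value pushed ``k`` steps ago (k >= 1); zeros if not yet filled."""
        if k > self.filled:
            return np.zeros(self.buf.shape[1:], dtype=float)
        return self.buf[(self.idx - k) % self.n]
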