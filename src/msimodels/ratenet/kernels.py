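"""Spatial connectivity kernels on the neuron ring.

Neurons are laid out on a ring with uniform preferred-position spacing
(default 180 neurons at 1 deg/neuron, period 180 deg).  Distances are
circular so the layer has no boundary.
"""

from __future__ import annotations

import warnings

import numpy as np


def preferred_positions(n_neurons: int, extent: float = 180.0) -> np.ndarray:
    """Preferred position (deg) of each neuron."""
    return np.arange(n_neurons) * (extent / n_neurons)


def circular_distance(n_neurons: int, extent: float = 180.0) -> np.ndarray:
    """Pairwise circular distance matrix (deg) on the ring."""
    pos = preferred_positions(n_neurons, extent)
    diff = np.abs(pos[:, None] - pos[None, :])
    return np.minimum(diff, extent - diff)


def mexican_hat_weights(
    n_neurons: int,
    l_ex: float,
    sigma_ex: float,
    l_in: float,
    sigma_in: float,
    extent: float = 180.0,
) -> np.ndarray:
    """Difference-of-Gaussians lateral kernel with zero self-connection.

    Short-range excitation minus longer-range inhibition; a pure-inhibition
    parameterization (inhibition at least as strong and at least as narrow
    as excitation) is allowed but warned about, since no bump can form.
    """
    if sigma_in <= sigma_ex and l_in >= l_ex:
        warnings.warn(
            "inhibition dominates excitation everywhere; no Mexican hat",
            stacklevel=2,
        )
    d = circular_distance(n_neurons, extent)
    w = l_ex * np.exp(-(d**2) / (2 * sigma_ex**2)) - l_in * np.exp(
        -(d**2) / (2 * sigma_in**2)
    )
    np.fill_diagonal(w, 0.0)
    return w


def gaussian_weights(
    n_neurons: int, w0: float, sigma: float, extent: float = 180.0
) -> np.ndarray:
    """Non-negative Gaussian kernel (cross-modal / interlayer synapses)."""
    d = circular_distance(n_neurons, extent)
    return w0 * np.exp(-(d**2) / (2 * sigma**2))


def gaussian_input_profile(
    n_neurons: int,
    position: float,
    amplitude: float,
    sigma: float,
    extent: float = 180.0,
) -> np.ndarray:
    """Spatial profile of an external stimulus centered at ``position``."""
    pos = preferred_positions(n_neurons, extent)
    diff = np.abs(pos - position)
    d = np.minimum(diff, extent - diff)
    return amplitude * np.exp(-(d**2) / (2 * sigma**2))
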