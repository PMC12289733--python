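"""Shared fixtures: stimulus builders and fast (reduced-size) network params."""

import pytest

from msimodels import AVNetParams, STCIParams, Stimulus


def av_pair(
    pos_a=45.0,
    pos_v=51.0,
    onset_a=0.0,
    onset_v=0.0,
    duration=500.0,
    intensity_a=1.0,
    intensity_v=1.0,
    noise=0.0,
):
    """Auditory/visual stimulus pair as a list (contract order)."""
    return [
        Stimulus(
            modality="auditory",
            position=pos_a,
            onset=onset_a,
            duration=duration,
            intensity=intensity_a,
            noise=noise,
        ),
        Stimulus(
            modality="visual",
            position=pos_v,
            onset=onset_v,
            duration=duration,
            intensity=intensity_v,
            noise=noise,
        ),
    ]


def av_dict(**kwargs):
    stims = av_pair(**kwargs)
    return {s.modality: s for s in stims}


@pytest.fixture
def fast_av_params():
    """Full-resolution dynamics on a smaller ring for fast unit tests."""
    return AVNetParams(n_neurons=90)


@pytest.fixture
def fast_stci_params():
    return STCIParams(n_neurons=90)
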