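"""Declarative stimulus descriptions.

A :class:`Stimulus` is one modality's physical description — where it is
(degrees), when it happens (onset/duration in ms), how strong it is
(dimensionless intensity) and how unreliable it is (noise SD).  Models decide
how to consume these attributes; validation against a model's contract
happens in :func:`validate_stimuli`.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, field_validator


class Stimulus(BaseModel):
    """Physical description of a single-modality stimulus."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    modality: str
    position: float = 0.0  # degrees
    onset: float = 0.0  # ms
    duration: float = 1.0  # ms
    intensity: float = 1.0  # dimensionless amplitude
    noise: float = 0.0  # SD of stimulus perturbation

    @field_validator("duration")
    @classmethod
    def _duration_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("duration must be > 0")
        return v

    @field_validator("onset", "intensity", "noise")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v


class StimulusError(ValueError):
    """Raised when stimuli do not satisfy a model contract."""


def validate_stimuli(stimuli, contract) -> dict[str, Stimulus]:
    """Check one stimulus per declared unisensory modality, in contract order.

    Returns a normalized mapping modality -> Stimulus.  Rejects missing or
    duplicate modalities and positions outside the contract's spatial domain.
    """
    by_modality: dict[str, Stimulus] = {}
    for stim in stimuli:
        if not isinstance(stim, Stimulus):
            stim = Stimulus(**dict(stim))
        if stim.modality in by_modality:
            raise StimulusError(f"duplicate modality: {stim.modality}")
        by_modality[stim.modality] = stim
    missing = [m for m in contract.modalities if m not in by_modality]
    if missing:
        raise StimulusError(f"missing modality: {', '.join(missing)}")
    extra = set(by_modality) - set(contract.modalities)
    if extra:
        raise StimulusError(
            f"unknown modality for {contract.name}: {', '.join(sorted(extra))}"
        )
    lo, hi = contract.spatial_domain
    for stim in by_modality.values():
        if not (lo <= stim.position <= hi):
            raise StimulusError(
                f"{stim.modality} position {stim.position} outside spatial "
                f"domain [{lo}, {hi}]"
            )
    return {m: by_modality[m] for m in contract.modalities}
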