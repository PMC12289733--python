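"""The uniform model contract.

Every model exposes a :class:`ModelContract`: its modality slots, spatial
dimensionality, parameter schema (names, bounds, defaults) and a run entry
point that always returns a validated :class:`~msimodels.results.NDResult`.
Because the contract is uniform, any processing function (task harness,
sweep engine, metrics) consumes any model's output interchangeably.

Parameter names are *modality-adaptive*: a model written against generic
slots (``{mod1}``, ``{mod2}``) is instantiated for concrete modalities, so
an audio-visual setup exposes ``auditory_position`` while a visual-tactile
setup exposes ``tactile_position`` with the core logic untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .results import NDResult
from .stimulus import Stimulus, validate_stimuli

_PLACEHOLDER = re.compile(r"\{(mod\d+)\}")


class ParameterError(ValueError):
    """Raised on parameter-schema violations (unknown name, out of bounds)."""


@dataclass(frozen=True)
class ParameterSpec:
    """One named model parameter with bounds and a default."""

    name: str
    default: float
    lower: float = float("-inf")
    upper: float = float("inf")

    def check(self, value: float) -> float:
        value = float(value)
        if not (self.lower <= value <= self.upper):
            raise ParameterError(
                f"parameter {self.name!r}={value} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )
        return value


def resolve_parameter_names(
    template_params: Sequence[str], modalities: Sequence[str]
) -> list[str]:
    """Substitute modality placeholders (``{mod1}``, ``{mod2}``, ...) with
    concrete modality labels.

    ``modalities[i]`` fills ``{mod(i+1)}``.  Raises if a template references
    a slot the modality tuple does not provide, or if more modalities are
    supplied than the template has slots.
    """
    slots = {f"mod{i + 1}": m for i, m in enumerate(modalities)}
    used: set[str] = set()
    resolved = []
    for name in template_params:
        def _sub(match: re.Match) -> str:
            slot = match.group(1)
            if slot not in slots:
                raise ParameterError(
                    f"template {name!r} references slot {slot!r} but only "
                    f"{len(slots)} modalities were given"
                )
            used.add(slot)
            return slots[slot]

        resolved.append(_PLACEHOLDER.sub(_sub, name))
    unused = set(slots) - used
    if unused and any(_PLACEHOLDER.search(n) for n in template_params):
        raise ParameterError(
            f"modality count mismatch: slots {sorted(unused)} have no "
            f"placeholder in the template"
        )
    return resolved


@dataclass(frozen=True)
class ModelContract:
    """Uniform description of a model: modalities, schema, run entry point.

    ``runner(stimuli, params, seed) -> NDResult`` receives validated stimuli
    (mapping modality -> Stimulus) and a fully-populated, bounds-checked
    parameter dict.
    """

    name: str
    modalities: tuple[str, ...]
    multisensory_label: str
    n_spatial_dims: int
    parameters: tuple[ParameterSpec, ...]
    runner: Callable[[Mapping[str, Stimulus], Mapping[str, float], int | None], NDResult]
    spatial_domain: tuple[float, float] = (0.0, 180.0)
    temporal: bool = False  # supports onset-disparity (temporal) tasks
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.modalities) < 2:
            raise ValueError("a contract needs >= 2 unisensory modalities")
        if not 1 <= self.n_spatial_dims <= 3:
            raise ValueError("n_spatial_dims must be 1..3")

    @property
    def mode_labels(self) -> tuple[str, ...]:
        return self.modalities + (self.multisensory_label,)

    @property
    def schema(self) -> dict[str, ParameterSpec]:
        return {p.name: p for p in self.parameters}

    def defaults(self) -> dict[str, float]:
        return {p.name: p.default for p in self.parameters}

    def resolve_params(self, params: Mapping[str, float] | None) -> dict[str, float]:
        """Merge user params over defaults, rejecting unknown names and
        bound violations."""
        schema = self.schema
        merged = self.defaults()
        for name, value in (params or {}).items():
            if name not in schema:
                raise ParameterError(
                    f"unknown parameter {name!r} for model {self.name!r}; "
                    f"known: {sorted(schema)}"
                )
            merged[name] = schema[name].check(value)
        return merged


def run_model(
    contract: ModelContract,
    stimuli: Sequence[Stimulus],
    params: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> NDResult:
    """Validate inputs and dispatch to the contract's runner.

    Identical ``(stimuli, params, seed)`` always produce identical output;
    every source of randomness inside a runner flows through one generator
    seeded with ``seed``.
    """
    normalized = validate_stimuli(stimuli, contract)
    resolved = contract.resolve_params(params)
    result = contract.runner(normalized, resolved, seed)
    # stamp provenance
    result.metadata.update(  # type: ignore[union-attr]
        model=contract.name, seed=seed, params=dict(resolved)
    )
    return result


# --- registry ------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., ModelContract]] = {}


def register_model(name: str):
    """Decorator registering a contract factory under ``name``."""

    def deco(factory):
        _REGISTRY[name] = factory
        return factory

    return deco


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def get_contract(name: str, **kwargs) -> ModelContract:
    """Instantiate a registered model contract by name."""
    # ensure built-ins are registered
    from . import mle, bci  # noqa: F401
    from .ratenet import av, stci  # noqa: F401

    if name not in _REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; registered: {available_models()}"
        )
    return _REGISTRY[name](**kwargs)
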