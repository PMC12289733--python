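"""Parameter-sweep engine over any conforming model.

Two result-processing strategies:

* ``collect_all`` — every run's NDResult is kept and stacked into an
  :class:`~msimodels.results.NDResultCollection`;
* ``reduce_on_the_fly`` — a scalar metric is applied as each run finishes
  and the full result is released, so peak memory does not grow with the
  number of sweep values.

Child seeds are pre-assigned from a stable hash of ``(base_seed, value
index, repeat)``, so sequential and process-parallel execution give
identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .contract import ModelContract, ParameterError, run_model
from .results import NDResult, NDResultCollection, stack_collection
from .stimulus import Stimulus


def child_seed(base_seed: int | None, value_index: int, repeat: int) -> int:
    """Deterministic, process-stable child seed below 2**31."""
    key = f"{base_seed}|{value_index}|{repeat}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SweepConfig:
    """What to sweep and how to process the runs."""

    target_parameter: str
    values: tuple
    repeats: int = 1
    base_seed: int | None = None
    strategy: str = "collect_all"  # or "reduce_on_the_fly"
    metric: Callable[[NDResult], float] | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("sweep values must be non-empty")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.strategy not in ("collect_all", "reduce_on_the_fly"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "reduce_on_the_fly" and self.metric is None:
            raise ValueError("reduce_on_the_fly requires a metric")


class SweepRunError(RuntimeError):
    """A member run failed; coordinates of the failure are attached."""


def _single_run(model, stimuli, params, seed):
    if isinstance(model, ModelContract):
        return run_model(model, stimuli, params, seed)
    # duck-typed callable model: f(stimuli, params, seed) -> NDResult
    return model(stimuli, params, seed)


def run_sweep(
    model: ModelContract,
    stimuli: Sequence[Stimulus],
    fixed_params: Mapping[str, float] | None,
    config: SweepConfig,
    n_jobs: int = 1,
) -> NDResultCollection | pd.DataFrame:
    """Sweep one parameter; return a collection or a reduced table.

    Runs are ordered by (value, repeat).  Any member failure raises
    :class:`SweepRunError` naming the (value, repeat) coordinates — partial
    results are never returned silently.
    """
    if config.target_parameter not in model.schema:
        raise ParameterError(
            f"parameter {config.target_parameter!r} not in schema of "
            f"model {model.name!r}"
        )
    fixed = dict(fixed_params or {})

    jobs = []
    for i, value in enumerate(config.values):
        model.schema[config.target_parameter].check(value)
        for r in range(config.repeats):
            params = {**fixed, config.target_parameter: value}
            jobs.append((i, value, r, params, child_seed(config.base_seed, i, r)))

    def _execute(job):
        i, value, r, params, seed = job
        try:
            return _single_run(model, stimuli, params, seed)
        except Exception as exc:  # noqa: BLE001 - annotate location
            raise SweepRunError(
                f"run failed at {config.target_parameter}={value!r}, "
                f"repeat {r}: {exc}"
            ) from exc

    if config.strategy == "collect_all":
        if n_jobs != 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=n_jobs)(delayed(_execute)(j) for j in jobs)
        else:
            results = [_execute(j) for j in jobs]
        return stack_collection(
            results, config.target_parameter, list(config.values)
        )

    # reduce on the fly: result released after each reduction
    rows = []
    for job in jobs:
        i, value, r, _, _ = job
        result = _execute(job)
        try:
            m = config.metric(result)
        except Exception as exc:  # noqa: BLE001
            raise SweepRunError(
                f"metric failed at {config.target_parameter}={value!r}, "
                f"repeat {r}: {exc}"
            ) from exc
        rows.append(
            {config.target_parameter: value, "repeat": r, "metric": float(m)}
        )
        del result
    return pd.DataFrame(rows)


def cross_sweep(
    model: ModelContract,
    stimuli_for_disparity: Callable[[float], Sequence[Stimulus]],
    fixed_params: Mapping[str, float] | None,
    config: SweepConfig,
    disparities: Sequence[float],
) -> pd.DataFrame:
    """For each parameter value, run a full disparity curve.

    ``stimuli_for_disparity(d)`` builds the stimulus pair for disparity
    ``d``.  Output rows are ordered (parameter value, disparity, repeat) and
    carry the reduced metric (``config.metric`` mandatory here: a full
    nested collection of network runs rarely fits a laptop, and the curve is
    what the analyses consume).
    """
    if config.metric is None:
        raise ValueError("cross_sweep requires a metric")
    if not disparities:
        raise ValueError("disparities must be non-empty")
    rows = []
    for i, value in enumerate(config.values):
        model.schema[config.target_parameter].check(value)
        for j, d in enumerate(sorted(disparities)):
            for r in range(config.repeats):
                params = {**dict(fixed_params or {}), config.target_parameter: value}
                seed = child_seed(config.base_seed, i * len(disparities) + j, r)
                try:
                    result = _single_run(
                        model, stimuli_for_disparity(d), params, seed
                    )
                    m = config.metric(result)
                except Exception as exc:  # noqa: BLE001
                    raise SweepRunError(
                        f"run failed at {config.target_parameter}={value!r}, "
                        f"disparity {d!r}, repeat {r}: {exc}"
                    ) from exc
                rows.append(
                    {
                        config.target_parameter: value,
                        "disparity": d,
                        "repeat": r,
                        "metric": float(m),
                    }
                )
    return pd.DataFrame(rows)
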