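"""Causal-inference task harness.

Three protocols around audio-visual disparity:

* ``implicit_spatial`` — auditory stimulus fixed at 45 deg, visual at
  disparities of +/-3, +/-6, +/-12, +/-24 deg; readout is the auditory
  position estimate, summarized as the *auditory bias*
  ``(estimate - true_a) / (true_v - true_a)`` (0 = no ventriloquism,
  1 = full visual capture).
* ``explicit_spatial`` — same stimuli; readout is the unity judgment
  (proportion of common-source reports).
* ``explicit_temporal`` — visual onset fixed at 160 ms, auditory onsets at
  0, +/-20, +/-80, +/-150 and +250 ms relative to it; readout is unity.

Each condition is presented once with all noise sources eliminated, so a
model's curve is its deterministic prediction.  Unity curves are summarized
by a Gaussian fit (amplitude, mean, width) and models can be fitted to
observed curves with a seeded differential-evolution search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .contract import ModelContract, run_model
from .results import NDResult
from .ratenet.dynamics import barycenter_readout
from .ratenet.stci import causal_readout
from .stimulus import Stimulus
from .sweep import child_seed

SPATIAL_DISPARITIES = (-24.0, -12.0, -6.0, -3.0, 3.0, 6.0, 12.0, 24.0)
TEMPORAL_DISPARITIES = (-150.0, -80.0, -20.0, 0.0, 20.0, 80.0, 150.0, 250.0)

TASK_KINDS = ("implicit_spatial", "explicit_spatial", "explicit_temporal")


@dataclass(frozen=True)
class TaskSpec:
    """One experiment's stimulus protocol."""

    kind: str
    anchor: float  # deg (spatial: auditory position) or ms (temporal: visual onset)
    disparities: tuple[float, ...]
    duration: float = 500.0  # spatial stimulus duration, ms
    stim_duration: float = 50.0  # temporal-task stimulus duration, ms
    intensity: float = 1.0
    noise: float = 0.0
    position: float = 90.0  # co-located position for the temporal task

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.kind!r}")
        if not self.disparities:
            raise ValueError("disparities must be non-empty")

    @property
    def is_temporal(self) -> bool:
        return self.kind == "explicit_temporal"

    def stimuli(self, disparity: float) -> list[Stimulus]:
        """Build the AV stimulus pair for one disparity condition."""
        if self.is_temporal:
            return [
                Stimulus(
                    modality="auditory",
                    position=self.position,
                    onset=self.anchor + disparity,
                    duration=self.stim_duration,
                    intensity=self.intensity,
                    noise=self.noise,
                ),
                Stimulus(
                    modality="visual",
                    position=self.position,
                    onset=self.anchor,
                    duration=self.stim_duration,
                    intensity=self.intensity,
                    noise=self.noise,
                ),
            ]
        return [
            Stimulus(
                modality="auditory",
                position=self.anchor,
                onset=0.0,
                duration=self.duration,
                intensity=self.intensity,
                noise=self.noise,
            ),
            Stimulus(
                modality="visual",
                position=self.anchor + disparity,
                onset=0.0,
                duration=self.duration,
                intensity=self.intensity,
                noise=self.noise,
            ),
        ]


def default_task(kind: str) -> TaskSpec:
    """The three standard protocols with their canonical disparity sets."""
    if kind in ("implicit_spatial", "explicit_spatial"):
        return TaskSpec(kind=kind, anchor=45.0, disparities=SPATIAL_DISPARITIES)
    if kind == "explicit_temporal":
        return TaskSpec(kind=kind, anchor=160.0, disparities=TEMPORAL_DISPARITIES)
    raise ValueError(f"unknown task kind {kind!r}")


def auditory_bias(estimated_a: float, true_a: float, true_v: float) -> float:
    """Normalized shift of the auditory estimate toward the visual stimulus."""
    if true_v == true_a:
        raise ZeroDivisionError("auditory bias undefined at zero disparity")
    return (estimated_a - true_a) / (true_v - true_a)


# --- per-model readouts ---------------------------------------------------


def implicit_estimate(result: NDResult, modality: str = "auditory") -> float:
    """Position estimate for one modality from any conforming result.

    Closed-form models publish their estimates in metadata; network results
    are decoded by the barycenter of the modality's layer at the final
    recorded time.
    """
    meta = result.metadata
    if "estimates" in meta and modality in meta["estimates"]:
        return float(meta["estimates"][modality])
    if "fused_estimate" in meta:
        return float(meta["fused_estimate"])
    positions = result.activity.coords["x"].values
    final = result.get_mode(modality).values[-1]
    return barycenter_readout(final, positions)


def unity_readout(result: NDResult, causes_norm: float = 1.0) -> float:
    """Common-source report value in [0, 1] from any conforming result.

    Models that compute a causal readout expose it through ``causes``
    (scalar posterior or time series, whose trial value is its peak).  For
    network results without one (the two-layer model), the maximal
    multisensory activation over the trial serves as the readout.  Returns
    NaN when neither is available (the reliability-weighted integrator has
    no notion of causes unless a threshold rule is configured).
    """
    c = result.causes_scalar()
    if c is not None:
        return c
    multi = result.get_mode(result.multisensory_mode).values
    if multi.ndim == 2 and multi.shape[0] > 1:  # a genuine time course
        return float(causal_readout(multi, causes_norm).max())
    return float("nan")


def run_task(
    model: ModelContract,
    task: TaskSpec,
    params: Mapping[str, float] | None = None,
    base_seed: int | None = None,
    mle_unity_threshold: float | None = None,
) -> pd.DataFrame:
    """Run every condition of a task; one row per disparity.

    Columns: disparity, est_auditory, est_visual, bias (NaN at zero
    disparity or for temporal tasks), unity.  ``mle_unity_threshold``
    optionally turns the integrator's fused-vs-unisensory discrepancy into
    a unity rule; by default its unity is NaN.
    """
    if task.is_temporal and not model.temporal:
        raise ValueError(
            f"model {model.name!r} is static and cannot run the temporal task"
        )
    rows = []
    for i, d in enumerate(task.disparities):
        seed = child_seed(base_seed, i, 0)
        result = run_model(model, task.stimuli(d), params, seed)
        if task.is_temporal:
            est_a = est_v = bias = float("nan")
            if "estimates" in result.metadata:
                est = result.metadata["estimates"]
                est_a = float(est.get("auditory", float("nan")))
                est_v = float(est.get("visual", float("nan")))
        else:
            est_a = implicit_estimate(result, "auditory")
            est_v = implicit_estimate(result, "visual")
            true_a, true_v = task.anchor, task.anchor + d
            bias = auditory_bias(est_a, true_a, true_v) if d != 0 else float("nan")
        unity = unity_readout(result)
        if math.isnan(unity) and mle_unity_threshold is not None:
            # threshold rule: report "one cause" when the discrepancy between
            # the unisensory estimates is below the configured threshold
            disc = abs(est_a - est_v) if not task.is_temporal else abs(d)
            unity = 1.0 if disc <= mle_unity_threshold else 0.0
        rows.append(
            {
                "disparity": d,
                "est_auditory": est_a,
                "est_visual": est_v,
                "bias": bias,
                "unity": unity,
            }
        )
    return pd.DataFrame(rows)


# --- Gaussian summaries ---------------------------------------------------


@dataclass(frozen=True)
class GaussianFit:
    """Summary of a unity-vs-disparity curve.

    amplitude — maximum proportion of common-source reports; mean — the
    disparity of that maximum; width — SD of the fitted Gaussian, the range
    of disparities over which the model reports a common source.
    """

    amplitude: float
    mean: float
    width: float
    rss: float
    degenerate: bool = False


def _gauss(d, a, mu, w):
    return a * np.exp(-((d - mu) ** 2) / (2 * w**2))


def fit_gaussian(
    disparities: Sequence[float], proportions: Sequence[float]
) -> GaussianFit:
    """Least-squares Gaussian fit of a unity curve, multi-start.

    Starts from 5 deterministic initializations (data-driven peak plus
    spread combinations); bounds A in [0, 1], mu within the disparity span,
    w in (0, 2 * span].  Raises only if every start fails to converge;
    a constant curve is returned flagged degenerate (width unidentifiable).
    """
    d = np.asarray(disparities, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if d.shape != p.shape or d.size < 4:
        raise ValueError("need >= 4 (disparity, proportion) points")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("proportions must lie in [0, 1]")
    order = np.argsort(d)
    d, p = d[order], p[order]
    span = float(d.max() - d.min())
    if np.ptp(p) < 1e-12:
        return GaussianFit(
            amplitude=float(p[0]),
            mean=float(d.mean()),
            width=float("nan"),
            rss=0.0,
            degenerate=True,
        )
    lo = [0.0, d.min(), 1e-6]
    hi = [1.0, d.max(), 2 * span]
    peak_mu = float(d[np.argmax(p)])
    starts = [
        (min(p.max(), 1.0), peak_mu, span / 4),
        (min(p.max(), 1.0), peak_mu, span / 2),
        (0.5, 0.0 if d.min() <= 0 <= d.max() else peak_mu, span / 3),
        (min(p.max(), 1.0), float(d.mean()), span / 8),
        (0.9, peak_mu, span),
    ]
    best = None
    last_err = None
    for a0, mu0, w0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _gauss, d, p, p0=[a0, mu0, w0], bounds=(lo, hi), maxfev=10000
            )
        except RuntimeError as exc:
            last_err = exc
            continue
        rss = float(np.sum((p - _gauss(d, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError(f"Gaussian fit failed from every start: {last_err}")
    (a, mu, w), rss = best
    return GaussianFit(
        amplitude=float(a), mean=float(mu), width=abs(float(w)), rss=rss
    )


# --- sweeps over task metrics --------------------------------------------


def sweep_metric(
    model: ModelContract,
    task: TaskSpec,
    parameter: str,
    values: Sequence[float],
    fixed_params: Mapping[str, float] | None = None,
    base_seed: int | None = None,
    bias_at: float = -6.0,
) -> pd.DataFrame:
    """Task-level summary per parameter value.

    Implicit tasks: the auditory bias at the ``bias_at`` disparity point.
    Explicit tasks: the Gaussian fit of the unity curve (amplitude, mean,
    width, rss columns).
    """
    rows = []
    for i, value in enumerate(values):
        params = {**dict(fixed_params or {}), parameter: value}
        table = run_task(model, task, params, base_seed=child_seed(base_seed, i, 0))
        if task.kind == "implicit_spatial":
            if bias_at not in task.disparities:
                raise ValueError(
                    f"bias point {bias_at} not among task disparities"
                )
            row = table.loc[table["disparity"] == bias_at].iloc[0]
            rows.append({parameter: value, "bias": float(row["bias"])})
        else:
            fit = fit_gaussian(table["disparity"], table["unity"])
            rows.append(
                {
                    parameter: value,
                    "amplitude": fit.amplitude,
                    "mean": fit.mean,
                    "width": fit.width,
                    "rss": fit.rss,
                }
            )
    return pd.DataFrame(rows)


# --- model-to-data fitting ------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    params: dict[str, float]
    loss: float
    n_evaluations: int
    converged: bool
    message: str = ""


def fit_model(
    model: ModelContract,
    observed: pd.DataFrame,
    free_params: Mapping[str, tuple[float, float]],
    task: TaskSpec,
    fixed_params: Mapping[str, float] | None = None,
    budget: int = 2000,
    seed: int | None = None,
    target_column: str | None = None,
) -> FitResult:
    """Fit free parameters to an observed (disparity, value) curve by
    seeded differential evolution minimizing the sum of squared errors.

    ``observed`` needs columns ``disparity`` and ``value``; the model
    quantity compared against it is the bias for implicit tasks and the
    unity proportion for explicit tasks (override with ``target_column``).
    The search is population-based (mutation + crossover), capped so total
    objective evaluations stay within ``budget``.
    """
    missing = set(observed["disparity"]) - set(task.disparities)
    if missing:
        raise ValueError(f"observed disparities {sorted(missing)} not in task")
    names = list(free_params)
    col = target_column or ("bias" if task.kind == "implicit_spatial" else "unity")
    obs = observed.set_index("disparity")["value"]
    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        params = {**dict(fixed_params or {}), **dict(zip(names, x))}
        table = run_task(model, task, params, base_seed=seed).set_index("disparity")
        pred = table.loc[obs.index, col]
        return float(np.sum((pred.values - obs.values) ** 2))

    if not names:
        loss = objective(np.array([]))
        return FitResult(
            params=dict(fixed_params or {}),
            loss=loss,
            n_evaluations=n_evals,
            converged=True,
            message="no free parameters; returning model loss unchanged",
        )

    bounds = [free_params[n] for n in names]
    popsize = 15
    maxiter = max(budget // (popsize * len(names)) - 2, 1)
    res = optimize.differential_evolution(
        objective,
        bounds=bounds,
        seed=seed,
        popsize=popsize,
        maxiter=maxiter,
        tol=1e-10,
        polish=False,
        updating="immediate",
    )
    return FitResult(
        params={**dict(fixed_params or {}), **dict(zip(names, res.x))},
        loss=float(res.fun),
        n_evaluations=n_evals,
        converged=bool(res.success) or res.fun < 1e-12,
        message=str(res.message),
    )
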