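"""Standardized multidimensional result containers.

Every model in this package returns an :class:`NDResult`: a labeled activity
array over ``(mode, time[, x[, y[, z]]])`` plus an optional causal-inference
readout (``causes``) and a run-metadata record.  Because the container is
identical across models, every analysis tool (task harness, sweeps, metrics)
works on every model's output unchanged.

Axis conventions
----------------
* ``mode`` — sensory modality of the activity slice.  At least two modes must
  be tagged *unisensory* and exactly one *multisensory*.
* ``time`` — milliseconds, explicit coordinate table.
* ``x``, ``y``, ``z`` — spatial axes in degrees; absent axes are dropped from
  the right, so the canonical layout is ``(mode, time, x, y, z)`` truncated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

AXIS_ORDER = ("mode", "time", "x", "y", "z")
SPATIAL_AXES = ("x", "y", "z")

UNISENSORY = "unisensory"
MULTISENSORY = "multisensory"


class ResultValidationError(ValueError):
    """Raised when an activity block violates the result contract."""


@dataclass(frozen=True)
class NDResult:
    """Labeled model output: activity over (mode, time, space) + causes.

    Parameters
    ----------
    activity:
        ``xarray.DataArray`` with dims a prefix-ordered subset of
        ``(mode, time, x, y, z)`` always containing ``mode`` and ``time``.
    mode_roles:
        Mapping mode label -> ``"unisensory"`` | ``"multisensory"``.
    causes:
        Optional causal-inference readout in [0, 1]; either a scalar
        (closed-form models) or a time series aligned with the time axis
        (network models).
    metadata:
        Run provenance: model name, parameter record, seed, anything
        JSON-serializable.
    """

    activity: xr.DataArray
    mode_roles: Mapping[str, str]
    causes: float | xr.DataArray | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    # -- validation -------------------------------------------------------
    def __post_init__(self) -> None:
        dims = tuple(self.activity.dims)
        if not set(dims) <= set(AXIS_ORDER):
            raise ResultValidationError(
                f"axis names must be drawn from {AXIS_ORDER}, got {dims}"
            )
        if "mode" not in dims or "time" not in dims:
            raise ResultValidationError("mode and time axes are mandatory")
        expected = tuple(a for a in AXIS_ORDER if a in dims)
        if dims != expected:
            raise ResultValidationError(
                f"axes must follow canonical order {expected}, got {dims}"
            )
        if len(dims) > 5:
            raise ResultValidationError("at most 5 axes are supported")

        labels = [str(m) for m in self.activity.coords["mode"].values]
        roles = dict(self.mode_roles)
        if set(roles) != set(labels):
            raise ResultValidationError(
                "mode_roles labels must match the mode coordinate"
            )
        n_uni = sum(1 for r in roles.values() if r == UNISENSORY)
        n_multi = sum(1 for r in roles.values() if r == MULTISENSORY)
        if len(labels) < 3 or n_uni < 2:
            raise ResultValidationError(
                "insufficient unisensory modes: need >= 2 unisensory plus "
                "one multisensory mode"
            )
        if n_multi != 1:
            raise ResultValidationError("exactly one multisensory mode required")
        if n_uni + n_multi != len(labels):
            raise ResultValidationError(
                f"unknown mode role among {sorted(set(roles.values()))}"
            )

        if not np.all(np.isfinite(self.activity.values)):
            raise ResultValidationError("activity contains non-finite values")

        if self.causes is not None:
            cvals = np.asarray(
                self.causes.values
                if isinstance(self.causes, xr.DataArray)
                else self.causes,
                dtype=float,
            )
            if not np.all(np.isfinite(cvals)):
                raise ResultValidationError("causes contains non-finite values")
            if cvals.min() < 0.0 or cvals.max() > 1.0:
                raise ResultValidationError("causes must lie in [0, 1]")

    # -- accessors --------------------------------------------------------
    @property
    def modes(self) -> list[str]:
        return [str(m) for m in self.activity.coords["mode"].values]

    @property
    def unisensory_modes(self) -> list[str]:
        return [m for m in self.modes if self.mode_roles[m] == UNISENSORY]

    @property
    def multisensory_mode(self) -> str:
        return next(m for m in self.modes if self.mode_roles[m] == MULTISENSORY)

    @property
    def time_coords(self) -> np.ndarray:
        return self.activity.coords["time"].values

    @property
    def spatial_axes(self) -> tuple[str, ...]:
        return tuple(a for a in SPATIAL_AXES if a in self.activity.dims)

    def get_mode(self, label: str) -> xr.DataArray:
        """Read-only view of one mode's activity over the remaining axes."""
        if label not in self.modes:
            raise KeyError(
                f"unknown mode {label!r}; available: {self.modes}"
            )
        view = self.activity.sel(mode=label)
        view.values.flags.writeable = False
        return view

    def causes_scalar(self) -> float | None:
        """Trial-level causal readout: the scalar itself, or the peak of the
        time series (transients under temporal disparity are kept)."""
        if self.causes is None:
            return None
        if isinstance(self.causes, xr.DataArray):
            return float(self.causes.values.max())
        return float(self.causes)

    # -- io ---------------------------------------------------------------
    def to_netcdf(self, path) -> None:
        """Write a self-describing NetCDF (classic format) file."""
        ds = xr.Dataset({"activity": self.activity})
        if isinstance(self.causes, xr.DataArray):
            ds["causes"] = self.causes
            ds.attrs["causes_kind"] = "series"
        elif self.causes is not None:
            ds.attrs["causes_kind"] = "scalar"
            ds.attrs["causes_value"] = float(self.causes)
        else:
            ds.attrs["causes_kind"] = "none"
        ds.attrs["mode_roles"] = json.dumps(dict(self.mode_roles))
        ds.attrs["metadata"] = json.dumps(dict(self.metadata), default=str)
        # mode labels must be fixed-width strings for the classic backend
        ds = ds.assign_coords(mode=np.array(self.modes, dtype="S32"))
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "NDResult":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        labels = [
            m.decode() if isinstance(m, bytes) else str(m)
            for m in ds.coords["mode"].values
        ]
        activity = ds["activity"].assign_coords(mode=labels)
        kind = ds.attrs.get("causes_kind", "none")
        causes: float | xr.DataArray | None
        if kind == "series":
            causes = ds["causes"]
        elif kind == "scalar":
            causes = float(ds.attrs["causes_value"])
        else:
            causes = None
        return cls(
            activity=activity,
            mode_roles=json.loads(ds.attrs["mode_roles"]),
            causes=causes,
            metadata=json.loads(ds.attrs["metadata"]),
        )


def build_result(
    per_mode_activity: Mapping[str, np.ndarray],
    coords: Mapping[str, Sequence[float]],
    mode_roles: Mapping[str, str],
    causes: float | np.ndarray | None = None,
    metadata: Mapping[str, object] | None = None,
) -> NDResult:
    """Assemble a validated :class:`NDResult` from per-mode arrays.

    ``coords`` holds the shared coordinate tables for every non-mode axis
    (``time`` mandatory, spatial axes optional).  Every per-mode array must
    conform to those tables; nothing invalid is ever stored.
    """
    if not per_mode_activity:
        raise ResultValidationError("no modes supplied")
    axis_names = tuple(a for a in AXIS_ORDER[1:] if a in coords)
    if set(coords) - set(axis_names):
        raise ResultValidationError(
            f"unknown coordinate axes {set(coords) - set(axis_names)}"
        )
    if "time" not in coords:
        raise ResultValidationError("time coordinates are mandatory")
    shape = tuple(len(np.asarray(coords[a])) for a in axis_names)
    blocks = []
    labels = list(per_mode_activity)
    for label in labels:
        arr = np.asarray(per_mode_activity[label], dtype=float)
        if arr.shape != shape:
            raise ResultValidationError(
                f"mode {label!r} has shape {arr.shape}, expected {shape} "
                f"from coordinate tables"
            )
        blocks.append(arr)
    stacked = np.stack(blocks, axis=0)
    activity = xr.DataArray(
        stacked,
        dims=("mode",) + axis_names,
        coords={"mode": labels, **{a: np.asarray(coords[a]) for a in axis_names}},
    )
    causes_obj: float | xr.DataArray | None = None
    if causes is not None:
        carr = np.asarray(causes, dtype=float)
        if carr.ndim == 0:
            causes_obj = float(carr)
        else:
            if carr.shape != (len(np.asarray(coords["time"])),):
                raise ResultValidationError(
                    "causes series must align with the time axis"
                )
            causes_obj = xr.DataArray(
                carr, dims=("time",), coords={"time": np.asarray(coords["time"])}
            )
    return NDResult(
        activity=activity,
        mode_roles=dict(mode_roles),
        causes=causes_obj,
        metadata=dict(metadata or {}),
    )


def get_mode(result: NDResult, label: str) -> xr.DataArray:
    """Functional alias for :meth:`NDResult.get_mode`."""
    return result.get_mode(label)


@dataclass(frozen=True)
class NDResultCollection:
    """Ordered, homogeneous set of results from a sweep.

    All members share identical axis names and coordinate tables (checked at
    construction); the shared tables are stored once (``compressed``).
    """

    results: tuple[NDResult, ...]
    sweep_axis: str
    sweep_values: tuple
    compressed: bool = True

    def __post_init__(self) -> None:
        if not self.results:
            raise ResultValidationError("empty collection")
        if len(self.results) % len(self.sweep_values) != 0:
            raise ResultValidationError(
                f"{len(self.results)} results do not divide into "
                f"{len(self.sweep_values)} sweep values"
            )
        ref = self.results[0]
        for r in self.results[1:]:
            if r.activity.dims != ref.activity.dims:
                raise ResultValidationError("heterogeneous axes in collection")
            for d in ref.activity.dims:
                if not np.array_equal(
                    r.activity.coords[d].values, ref.activity.coords[d].values
                ):
                    raise ResultValidationError(
                        f"coordinate table mismatch on axis {d!r}"
                    )

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, i: int) -> NDResult:
        return self.results[i]

    @property
    def repeats(self) -> int:
        return len(self.results) // len(self.sweep_values)

    def coords(self) -> dict[str, np.ndarray]:
        ref = self.results[0]
        return {d: ref.activity.coords[d].values for d in ref.activity.dims}

    def metric(self, fn: Callable[[NDResult], float]) -> pd.DataFrame:
        return collection_metric(self, fn)

    def to_netcdf(self, path) -> None:
        """Write the whole collection as one NetCDF file along a sweep axis."""
        rep = self.repeats
        stacked = xr.concat(
            [r.activity for r in self.results], dim="member"
        ).assign_coords(
            member=np.arange(len(self.results)),
        )
        ds = xr.Dataset({"activity": stacked})
        ds.attrs["sweep_axis"] = self.sweep_axis
        ds.attrs["sweep_values"] = json.dumps(list(self.sweep_values))
        ds.attrs["repeats"] = rep
        ds.attrs["mode_roles"] = json.dumps(dict(self.results[0].mode_roles))
        ds.attrs["metadata"] = json.dumps(
            [dict(r.metadata) for r in self.results], default=str
        )
        ds = ds.assign_coords(
            mode=np.array(self.results[0].modes, dtype="S32")
        )
        ds.to_netcdf(path, engine="scipy")


def stack_collection(
    results: Sequence[NDResult],
    sweep_axis: str,
    sweep_values: Sequence,
) -> NDResultCollection:
    """Aggregate homogeneous results into an ordered collection."""
    return NDResultCollection(
        results=tuple(results),
        sweep_axis=sweep_axis,
        sweep_values=tuple(sweep_values),
    )


def collection_metric(
    coll: NDResultCollection, metric: Callable[[NDResult], float]
) -> pd.DataFrame:
    """Apply a scalar metric member-by-member; one row per member.

    A metric failure is re-raised with the offending member's sweep value
    attached so sweep debugging does not require bisection.
    """
    rows = []
    rep = coll.repeats
    for i, result in enumerate(coll):
        value = coll.sweep_values[i // rep]
        try:
            m = metric(result)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise type(exc)(
                f"metric failed at {coll.sweep_axis}={value!r}: {exc}"
            ) from exc
        rows.append({coll.sweep_axis: value, "repeat": i % rep, "metric": m})
    return pd.DataFrame(rows)
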