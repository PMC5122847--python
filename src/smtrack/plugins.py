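"""Declarative plugin system.

Every algorithm stage (detection, refinement, tracking) is described by a
:class:`PluginDescriptor`: a name, a stage, a mandatory description, a typed
parameter list (each with default, optional range/choices, and a mandatory
tooltip), an entry point, and a flag saying whether frames can be processed
independently.  From this single object the command-line/config interface is
generated automatically, and :func:`run_stage` executes the plugin with a
per-frame parallelization contract: if ``frame_independent`` is true the
output is identical whether frames are processed sequentially, in any order,
or concurrently (results are sorted by ``(frame, x, y)`` before return).

Stochastic plugins must declare an explicit ``seed`` parameter; the
framework itself never draws randomness.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import MANDATORY_COLUMNS, MovieStack, ResultTable

__all__ = [
    "ParameterSpec",
    "PluginDescriptor",
    "PluginRegistry",
    "registry",
    "register_plugin",
    "build_cli_schema",
    "run_stage",
    "PluginValidationError",
    "StageError",
]

_KINDS = ("int", "float", "bool", "string", "list", "filepath")
STAGES = ("detection", "refinement", "tracking")


class PluginValidationError(ValueError):
    """A descriptor or parameter value violates the plugin contract."""


class StageError(RuntimeError):
    """A plugin raised during stage execution; carries frame and plugin name."""


@dataclass(frozen=True)
class ParameterSpec:
    """One typed plugin parameter.

    ``range`` is ``(min, max)`` for numeric kinds or the choice sequence for
    ``list`` kind.  The tooltip is mandatory -- a parameter nobody can
    understand is a parameter nobody can tune.
    """

    name: str
    kind: str
    default: object
    tooltip: str
    range: Optional[Sequence] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise PluginValidationError(
                f"parameter {self.name!r}: unknown kind {self.kind!r}"
            )
        if not self.tooltip or not str(self.tooltip).strip():
            raise PluginValidationError(
                f"parameter {self.name!r}: tooltip is mandatory"
            )
        if self.range is not None:
            self.validate(self.default)

    def validate(self, value):
        """Coerce and range-check a value; raises on violation."""
        if self.kind == "int":
            value = int(value)
        elif self.kind == "float":
            value = float(value)
        elif self.kind == "bool":
            if isinstance(value, str):
                value = value.lower() in ("1", "true", "yes", "on")
            value = bool(value)
        elif self.kind in ("string", "filepath"):
            value = str(value)
        if self.range is not None:
            if self.kind == "list":
                if value not in self.range:
                    raise PluginValidationError(
                        f"parameter {self.name!r}: {value!r} not among "
                        f"choices {list(self.range)}"
                    )
            elif self.kind in ("int", "float"):
                lo, hi = self.range
                if (lo is not None and value < lo) or (hi is not None and value > hi):
                    raise PluginValidationError(
                        f"parameter {self.name!r}: {value} outside range "
                        f"[{lo}, {hi}]"
                    )
        return value


@dataclass(frozen=True)
class PluginDescriptor:
    """Declarative description of one algorithm plugin.

    ``main`` is called once per frame for detection/refinement plugins with
    ``frame_independent=True`` (signature ``main(frame_image, frame_index,
    params, upstream_rows)``), or once with the whole upstream table for
    tracking (``main(movie, params, upstream)``); it returns a DataFrame
    with at least the stage's mandatory columns.
    """

    name: str
    stage: str
    description: str
    params: tuple
    main: Callable
    frame_independent: bool = True

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise PluginValidationError(f"unknown stage {self.stage!r}")
        if not self.description or not self.description.strip():
            raise PluginValidationError(
                f"plugin {self.name!r}: description is mandatory"
            )
        names = [p.name for p in self.params]
        if len(names) != len(set(names)):
            raise PluginValidationError(
                f"plugin {self.name!r}: duplicate parameter names"
            )

    def resolve_params(self, values: Optional[dict] = None) -> dict:
        """Fill defaults and validate user-supplied parameter values."""
        values = dict(values or {})
        unknown = set(values) - {p.name for p in self.params}
        if unknown:
            raise PluginValidationError(
                f"plugin {self.name!r}: unknown parameters {sorted(unknown)}"
            )
        return {
            p.name: p.validate(values.get(p.name, p.default))
            for p in self.params
        }


class PluginRegistry:
    """Plugins namespaced by (stage, name)."""

    def __init__(self) -> None:
        self._plugins: dict = {}

    def register(self, descriptor: PluginDescriptor) -> PluginDescriptor:
        key = (descriptor.stage, descriptor.name)
        if key in self._plugins:
            raise PluginValidationError(
                f"plugin {descriptor.name!r} already registered for stage "
                f"{descriptor.stage!r}"
            )
        self._plugins[key] = descriptor
        return descriptor

    def get(self, stage: str, name: str) -> PluginDescriptor:
        try:
            return self._plugins[(stage, name)]
        except KeyError:
            raise KeyError(f"no plugin {name!r} for stage {stage!r}") from None

    def list(self, stage: Optional[str] = None) -> list:
        return sorted(
            (d for (s, _), d in self._plugins.items() if stage is None or s == stage),
            key=lambda d: (d.stage, d.name),
        )

    def __contains__(self, key) -> bool:
        return key in self._plugins


#: Global default registry; built-in plugins register here on import.
registry = PluginRegistry()


def register_plugin(descriptor: PluginDescriptor,
                    into: Optional[PluginRegistry] = None) -> PluginDescriptor:
    """Validate and register a plugin descriptor (default: global registry)."""
    return (into or registry).register(descriptor)


def build_cli_schema(descriptor: PluginDescriptor) -> list:
    """Command-line/config schema for one plugin: one entry per parameter.

    Each entry carries the flag name, kind, default, range/choices and the
    tooltip as help text; parsers built from it must reject out-of-range
    values.
    """
    schema = []
    for p in descriptor.params:
        schema.append({
            "flag": f"--{p.name.replace('_', '-')}",
            "dest": p.name,
            "kind": p.kind,
            "default": p.default,
            "range": None if p.range is None else list(p.range),
            "help": p.tooltip,
        })
    return schema


def run_stage(
    descriptor: PluginDescriptor,
    movie: MovieStack,
    params: Optional[dict] = None,
    upstream: Optional[ResultTable] = None,
    frame_order: Optional[Sequence[int]] = None,
    n_workers: int = 1,
) -> ResultTable:
    """Execute one pipeline stage under the plugin contract.

    For frame-independent plugins, frames are processed in ``frame_order``
    (default: ascending) with ``n_workers`` threads; the result table is
    sorted by ``(frame, x, y)`` and is therefore identical for any order or
    worker count.  Refinement and tracking require the upstream table.
    """
    values = descriptor.resolve_params(params)
    if descriptor.stage in ("refinement", "tracking") and upstream is None:
        raise ValueError(f"stage {descriptor.stage!r} requires an upstream table")

    if not descriptor.frame_independent:
        try:
            df = descriptor.main(movie, values, upstream)
        except Exception as exc:
            raise StageError(
                f"plugin {descriptor.name!r} failed on whole-movie pass: {exc}"
            ) from exc
        return _finalize(df, descriptor)

    frames = list(frame_order) if frame_order is not None else list(range(movie.n_frames))
    up_df = upstream.df if upstream is not None else None

    def one(f: int) -> pd.DataFrame:
        rows = None
        if up_df is not None:
            rows = up_df[up_df["frame"] == f]
        try:
            return descriptor.main(movie.data[f], f, values, rows)
        except Exception as exc:
            raise StageError(
                f"plugin {descriptor.name!r} failed on frame {f}: {exc}"
            ) from exc

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            parts = list(pool.map(one, frames))
    else:
        parts = [one(f) for f in frames]
    parts = [p for p in parts if p is not None and len(p)]
    if parts:
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(MANDATORY_COLUMNS[descriptor.stage]))
    return _finalize(df, descriptor)


def _finalize(df: pd.DataFrame, descriptor: PluginDescriptor) -> ResultTable:
    mandatory = MANDATORY_COLUMNS[descriptor.stage]
    for col in mandatory:
        if col not in df.columns:
            if len(df) == 0:
                df[col] = pd.Series(dtype=float)
            else:
                raise StageError(
                    f"plugin {descriptor.name!r} output lacks mandatory "
                    f"column {col!r}"
                )
    ordered = list(mandatory) + [c for c in df.columns if c not in mandatory]
    df = df[ordered]
    sort_cols = ["frame", "x", "y"]
    if descriptor.stage == "tracking":
        sort_cols = ["track_id", "frame"]
    if len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    return ResultTable(df, stage_tag=descriptor.stage)
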