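"""Signed errors against reference values and their MAE/RMSE aggregations.

The benchmark quantifies each (functional f, basis b) combination by the
signed error eps_{f,b} = X_{f,b} - X_ref of every property X against its
reference, deliberately without taking the modulus so that under- and
overestimation remain distinguishable.  Aggregation then averages |eps| over
basis sets (per-functional MAE) or over functionals (per-basis MAE), using
whatever combinations are actually present.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import round_half_up

__all__ = [
    "ReferenceValue",
    "ReferenceSet",
    "ErrorRecord",
    "UnitMismatchError",
    "relative_error",
    "mae_by_functional",
    "mae_by_basis",
    "mae_tables",
    "validation_stats",
    "ValidationStats",
    "default_references",
]

log = logging.getLogger(__name__)

_PROVENANCES = frozenset({"experimental", "high_level_theory"})


class UnitMismatchError(ValueError):
    """Calculated and reference values carry different declared units."""


@dataclass(frozen=True)
class ReferenceValue:
    value: float
    units: str
    provenance: str
    sources: tuple[float, ...] = ()
    uncertainty: float | None = None
    synthetic: bool = False

    def __post_init__(self) -> None:
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"provenance must be one of {sorted(_PROVENANCES)}, got {self.provenance!r}")
        if not math.isfinite(self.value):
            raise ValueError("reference value must be finite")


class ReferenceSet(Mapping[str, ReferenceValue]):
    """Property -> reference map; exactly one reference per scored property."""

    def __init__(self, entries: Mapping[str, ReferenceValue]):
        self._entries = dict(entries)

    def __getitem__(self, key: str) -> ReferenceValue:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def values_by_property(self) -> dict[str, float]:
        return {k: v.value for k, v in self._entries.items()}

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "ReferenceSet":
        entries = {}
        for prop, spec in doc["properties"].items():
            spec = dict(spec)
            if "sources" in spec:
                spec["sources"] = tuple(spec["sources"])
            entries[prop] = ReferenceValue(**spec)
        return cls(entries)

    @classmethod
    def from_file(cls, path) -> "ReferenceSet":
        text = open(path, "r", encoding="utf-8").read()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(doc)


def default_references() -> ReferenceSet:
    """Packaged reference configuration for the caffeic acid benchmark."""
    ref = importlib.resources.files("dftbench.data").joinpath("references.yaml")
    return ReferenceSet.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ErrorRecord:
    """Signed error of one property for one combination, in property units."""

    functional: str
    basis: str
    property: str
    epsilon: float


def relative_error(x: float, x_ref: float, units: str | None = None, ref_units: str | None = None) -> float:
    """Signed error x - x_ref (modulus deliberately not applied).

    If both unit declarations are given they must agree.
    """
    if units is not None and ref_units is not None and units != ref_units:
        raise UnitMismatchError(f"value in {units!r} but reference in {ref_units!r}")
    return x - x_ref


def _records_frame(errors: Iterable[ErrorRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(errors, pd.DataFrame):
        return errors
    return pd.DataFrame([e.__dict__ for e in errors])


def mae_by_functional(errors: Iterable[ErrorRecord] | pd.DataFrame, functional: str) -> float:
    """Mean |eps| over the basis sets present for one functional."""
    df = _records_frame(errors)
    sel = df[df["functional"] == functional]
    if sel.empty:
        raise ValueError(f"no error records for functional {functional!r}")
    return float(sel["epsilon"].abs().mean())


def mae_by_basis(errors: Iterable[ErrorRecord] | pd.DataFrame, basis: str) -> float:
    """Mean |eps| over the functionals present for one basis set."""
    df = _records_frame(errors)
    sel = df[df["basis"] == basis]
    if sel.empty:
        raise ValueError(f"no error records for basis {basis!r}")
    return float(sel["epsilon"].abs().mean())


def mae_tables(errors: Iterable[ErrorRecord] | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-functional and per-basis MAE tables (property columns), with counts.

    Only combinations present in the input enter the averages; the number of
    records behind each cell is logged so sparse grids are visible.
    """
    df = _records_frame(errors)
    if df.empty:
        raise ValueError("no error records")
    by_f = df.groupby(["functional", "property"])["epsilon"].agg(lambda s: s.abs().mean()).unstack("property")
    by_b = df.groupby(["basis", "property"])["epsilon"].agg(lambda s: s.abs().mean()).unstack("property")
    n_f = df.groupby(["functional", "property"]).size()
    log.info("MAE aggregation over %d records; cells per functional/property: %s", len(df), n_f.to_dict())
    return by_f, by_b


@dataclass(frozen=True)
class ValidationStats:
    """Calc-vs-experiment summary for an external validation set."""

    deltas: tuple[float, ...]
    mae: float
    rmse: float

    @property
    def display(self) -> tuple[float, float]:
        """(MAE, RMSE) rounded half-up to one decimal for table output."""
        return round_half_up(self.mae, 1), round_half_up(self.rmse, 1)


def validation_stats(pairs: Sequence[tuple[float, float]]) -> ValidationStats:
    """Per-item Delta = calc - exp, MAE = mean|Delta|, RMSE = sqrt(mean Delta^2)."""
    if len(pairs) == 0:
        raise ValueError("validation set is empty")
    deltas = np.array([calc - exp for calc, exp in pairs], dtype=float)
    return ValidationStats(
        deltas=tuple(deltas),
        mae=float(np.mean(np.abs(deltas))),
        rmse=float(np.sqrt(np.mean(deltas**2))),
    )
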