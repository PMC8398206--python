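"""Readers/writers for the tabular schemas and the end-to-end pipeline.

Three CSV schemas travel between stages (UTF-8, comma separated, ``.``
decimal, mandatory header; en-dashes in method names are normalized on
read):

* energetics — one row per (functional, basis, species, site):
  ``functional, basis, species_kind, site, enthalpy_hartree,
  eps_homo_hartree, eps_lumo_hartree``
* timings — ``functional, basis, stage, total_cpu_time_s, n_instances,
  n_cores``
* geometry/property values — ``functional, basis, property, value``
  (pre-computed scored properties whose calculation is outside this
  package's scope, e.g. bond lengths)

``run_pipeline`` composes everything: indices, signed errors, MAE tables,
reduced regression models, normalized timings, the score matrix and the flat
ranking.  Outputs are deterministic functions of the inputs; every emitted
file set carries a config hash in ``run.json`` and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .descriptors import Catalog, CatalogLookupError, default_catalog, feature_table
from .error_metrics import ErrorRecord, ReferenceSet, default_references, mae_tables, relative_error
from .performance import PerformanceRecord, stage_summary
from .regression import RegressionModel, fit_reduced, model_report
from .scoring import ScoringConfig, janak_points, performance_points, property_points, rank_combinations, total_score
from .thermochem import SpeciesEnergetics, compute_indices

__all__ = [
    "SchemaError",
    "PipelineError",
    "PipelineConfig",
    "read_energetics",
    "write_energetics",
    "read_timings",
    "write_timings",
    "read_property_values",
    "write_property_values",
    "energetics_to_errors",
    "run_pipeline",
]

log = logging.getLogger(__name__)

SPECIES_KINDS = ("parent", "radical", "cation_radical", "anion_radical", "anion", "h_atom")

ENERGETICS_COLUMNS = (
    "functional",
    "basis",
    "species_kind",
    "site",
    "enthalpy_hartree",
    "eps_homo_hartree",
    "eps_lumo_hartree",
)
TIMINGS_COLUMNS = ("functional", "basis", "stage", "total_cpu_time_s", "n_instances", "n_cores")


class SchemaError(ValueError):
    """Input file violates a declared schema; messages carry the row number."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _normalize_text(s: str) -> str:
    return s.replace("–", "-").replace("—", "-").strip()


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")


def _check_names(df: pd.DataFrame, catalog: Catalog, path, allow_unknown: bool) -> None:
    if allow_unknown:
        return
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            catalog.functional(row.functional)
            catalog.basis(row.basis)
        except CatalogLookupError as exc:
            raise SchemaError(f"{path}: row {i}: {exc.args[0]}") from exc


# -- energetics -----------------------------------------------------------


def read_energetics(path, catalog: Catalog | None = None, allow_unknown: bool = False) -> list[SpeciesEnergetics]:
    """Parse an energetics CSV into validated species records.

    Unknown functional/basis names are rejected against the catalog unless
    ``allow_unknown``; duplicate (combination, species, site) rows and bad
    species kinds raise :class:`SchemaError` with the offending row number.
    """
    catalog = catalog or default_catalog()
    df = _read_csv(path)
    _require_columns(df, ENERGETICS_COLUMNS, path)
    for col in ("functional", "basis", "species_kind", "site"):
        df[col] = df[col].map(_normalize_text)
    _check_names(df, catalog, path, allow_unknown)

    seen: set[tuple] = set()
    groups: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.species_kind not in SPECIES_KINDS:
            raise SchemaError(
                f"{path}: row {i}: unknown species_kind {row.species_kind!r}; expected one of {SPECIES_KINDS}"
            )
        key = (row.functional, row.basis, row.species_kind, row.site)
        if key in seen:
            raise SchemaError(f"{path}: row {i}: duplicate record for {key}")
        seen.add(key)
        try:
            h = float(row.enthalpy_hartree)
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: bad enthalpy {row.enthalpy_hartree!r}") from exc
        g = groups.setdefault((row.functional, row.basis), {"radical": {}, "anion": {}})
        if row.species_kind == "parent":
            g["parent"] = h
            for attr, col in (("eps_homo", row.eps_homo_hartree), ("eps_lumo", row.eps_lumo_hartree)):
                if col != "":
                    try:
                        g[attr] = float(col)
                    except ValueError as exc:
                        raise SchemaError(f"{path}: row {i}: bad {attr} {col!r}") from exc
        elif row.species_kind == "radical":
            g["radical"][row.site] = h
        elif row.species_kind == "anion":
            g["anion"][row.site] = h
        elif row.species_kind == "cation_radical":
            g["cation_radical"] = h
        elif row.species_kind == "anion_radical":
            g["anion_radical"] = h
        elif row.species_kind == "h_atom":
            g["h_atom"] = h

    records = []
    for (f, b), g in sorted(groups.items()):
        if "parent" not in g:
            raise SchemaError(f"{path}: combination ({f}, {b}) has no parent species row")
        records.append(
            SpeciesEnergetics(
                combination=(f, b),
                h_parent=g["parent"],
                h_radical_by_site=g["radical"] or None,
                h_cation_radical=g.get("cation_radical"),
                h_anion_radical=g.get("anion_radical"),
                h_anion_by_site=g["anion"] or None,
                h_hydrogen_atom=g.get("h_atom"),
                eps_homo=g.get("eps_homo"),
                eps_lumo=g.get("eps_lumo"),
            )
        )
    return records


def write_energetics(records: Iterable[SpeciesEnergetics], path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: r.combination):
        f, b = r.combination
        def add(kind, site, h, homo="", lumo=""):
            rows.append(
                {
                    "functional": f,
                    "basis": b,
                    "species_kind": kind,
                    "site": site,
                    "enthalpy_hartree": repr(float(h)),
                    "eps_homo_hartree": homo,
                    "eps_lumo_hartree": lumo,
                }
            )

        add(
            "parent",
            "",
            r.h_parent,
            "" if r.eps_homo is None else repr(float(r.eps_homo)),
            "" if r.eps_lumo is None else repr(float(r.eps_lumo)),
        )
        for site, h in sorted((r.h_radical_by_site or {}).items()):
            add("radical", site, h)
        if r.h_cation_radical is not None:
            add("cation_radical", "", r.h_cation_radical)
        if r.h_anion_radical is not None:
            add("anion_radical", "", r.h_anion_radical)
        for site, h in sorted((r.h_anion_by_site or {}).items()):
            add("anion", site, h)
        if r.h_hydrogen_atom is not None:
            add("h_atom", "", r.h_hydrogen_atom)
    pd.DataFrame(rows, columns=list(ENERGETICS_COLUMNS)).to_csv(path, index=False)


# -- timings and property values ------------------------------------------


def read_timings(path, catalog: Catalog | None = None, allow_unknown: bool = False) -> list[PerformanceRecord]:
    catalog = catalog or default_catalog()
    df = _read_csv(path)
    _require_columns(df, TIMINGS_COLUMNS, path)
    for col in ("functional", "basis", "stage"):
        df[col] = df[col].map(_normalize_text)
    _check_names(df, catalog, path, allow_unknown)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                PerformanceRecord(
                    combination=(row.functional, row.basis),
                    stage=row.stage.lower(),
                    total_cpu_time=float(row.total_cpu_time_s),
                    n_instances=int(row.n_instances),
                    n_cores=int(row.n_cores),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return records


def write_timings(records: Iterable[PerformanceRecord], path) -> None:
    rows = [
        {
            "functional": r.combination[0],
            "basis": r.combination[1],
            "stage": r.stage,
            "total_cpu_time_s": repr(float(r.total_cpu_time)),
            "n_instances": r.n_instances,
            "n_cores": r.n_cores,
        }
        for r in sorted(records, key=lambda r: (r.stage, r.combination))
    ]
    pd.DataFrame(rows, columns=list(TIMINGS_COLUMNS)).to_csv(path, index=False)


def read_property_values(path) -> pd.DataFrame:
    """Pre-computed scored property values: functional, basis, property, value."""
    df = _read_csv(path)
    _require_columns(df, ("functional", "basis", "property", "value"), path)
    for col in ("functional", "basis", "property"):
        df[col] = df[col].map(_normalize_text)
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric value column: {exc}") from exc
    return df


def write_property_values(df: pd.DataFrame, path) -> None:
    out = df.loc[:, ["functional", "basis", "property", "value"]].sort_values(
        ["property", "functional", "basis"], kind="stable"
    )
    out.to_csv(path, index=False)


# -- pipeline --------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and knobs for one full benchmark analysis run."""

    energetics: str
    timings: str
    out_dir: str
    geometry: str | None = None
    references: str | None = None
    alpha: float = 0.05
    scoring: ScoringConfig = ScoringConfig()
    allow_unknown: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")  # output location does not influence results
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def energetics_to_errors(
    records: Iterable[SpeciesEnergetics],
    references: ReferenceSet,
) -> pd.DataFrame:
    """Signed errors of every computable index against its reference."""
    refs = references.values_by_property()
    rows = []
    for rec in records:
        indices = compute_indices(rec)
        for prop, value in indices.as_dict().items():
            if prop in refs:
                rows.append(
                    {
                        "functional": rec.combination[0],
                        "basis": rec.combination[1],
                        "property": prop,
                        "epsilon": relative_error(value, refs[prop]),
                    }
                )
    return pd.DataFrame(rows, columns=["functional", "basis", "property", "epsilon"])


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(cfg: PipelineConfig, catalog: Catalog | None = None) -> dict:
    """Run the full analysis and write the report bundle to ``cfg.out_dir``.

    Emits: errors.csv, mae_by_functional.csv, mae_by_basis.csv,
    regression_models.json/.txt, timings_normalized.csv, score_matrix.csv,
    ranking.csv and run.json (package version + config hash).  Returns the
    in-memory bundle.  Deterministic given identical inputs.
    """
    catalog = catalog or default_catalog()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    references = _stage("references")(
        lambda: ReferenceSet.from_file(cfg.references) if cfg.references else default_references()
    )
    records = _stage("read_energetics")(read_energetics, cfg.energetics, catalog, cfg.allow_unknown)
    errors = _stage("indices")(energetics_to_errors, records, references)
    if cfg.geometry:
        geo = _stage("read_geometry")(read_property_values, cfg.geometry)
        refs = references.values_by_property()
        unknown = sorted(set(geo["property"]) - set(refs))
        if unknown:
            raise PipelineError(f"stage 'read_geometry' failed: no reference for propert(ies) {', '.join(unknown)}")
        geo = geo.assign(epsilon=geo["value"] - geo["property"].map(refs)).drop(columns="value")
        errors = pd.concat([errors, geo], ignore_index=True)
    errors = errors.sort_values(["property", "functional", "basis"], kind="stable").reset_index(drop=True)
    errors.to_csv(out / "errors.csv", index=False)

    mae_f, mae_b = _stage("mae")(mae_tables, errors)
    mae_f.to_csv(out / "mae_by_functional.csv")
    mae_b.to_csv(out / "mae_by_basis.csv")

    features = feature_table(catalog)
    models: list[RegressionModel] = []
    for prop in sorted(errors["property"].unique()):
        sub = errors[errors["property"] == prop].merge(features, on=["functional", "basis"], how="inner")
        if len(sub) <= len(features.columns):  # too few rows to support inference
            log.warning("skipping regression for %s: only %d observations", prop, len(sub))
            continue
        model = _stage(f"regression[{prop}]")(
            fit_reduced, sub[list(features.columns[2:])], sub["epsilon"].to_numpy(), prop, cfg.alpha
        )
        models.append(model)
    (out / "regression_models.json").write_text(
        json.dumps({m.response: m.as_dict() for m in models}, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "regression_models.txt").write_text(model_report(models), encoding="utf-8")

    timing_records = _stage("read_timings")(read_timings, cfg.timings, catalog, cfg.allow_unknown)
    timings = _stage("performance")(stage_summary, timing_records, cfg.scoring.performance_stages)
    timings.to_csv(out / "timings_normalized.csv", index=False)

    cards = _stage("scoring")(_score_cards, errors, timings, references, cfg.scoring)
    matrix, ranking = _stage("ranking")(rank_combinations, cards)
    matrix.to_csv(out / "score_matrix.csv")
    ranking.to_csv(out / "ranking.csv", index=False)

    run_info = {"package": "dftbench", "version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    (out / "run.json").write_text(json.dumps(run_info, indent=2, sort_keys=True), encoding="utf-8")
    log.info("pipeline complete: %d combinations scored into %s", len(cards), out)
    return {
        "errors": errors,
        "mae_by_functional": mae_f,
        "mae_by_basis": mae_b,
        "models": models,
        "timings": timings,
        "score_matrix": matrix,
        "ranking": ranking,
        "run": run_info,
    }


def _score_cards(errors: pd.DataFrame, timings: pd.DataFrame, references: ReferenceSet, scoring: ScoringConfig):
    refs = references.values_by_property()
    eps = errors.pivot_table(index=["functional", "basis"], columns="property", values="epsilon", sort=True)
    tnorm = timings.pivot_table(index=["functional", "basis"], columns="stage", values="t_norm", sort=True)
    tmax = timings.groupby("stage")["t_max"].first()
    cards = []
    for combo in eps.index:
        row = eps.loc[combo]
        missing = [p for p in (*scoring.properties, *scoring.janak_entries) if p not in row.index or pd.isna(row[p])]
        if combo not in tnorm.index:
            missing += [f"timing:{s}" for s in scoring.performance_stages]
        if missing:
            raise ValueError(f"combination {combo} lacks entries: {', '.join(missing)}")
        pp = {p: property_points(float(row[p]), refs[p], scoring) for p in scoring.properties}
        jp = {j: janak_points(float(row[j]), refs[j], scoring) for j in scoring.janak_entries}
        cp = {
            s: performance_points(float(tnorm.loc[combo, s]), float(tmax[s]), scoring)
            for s in scoring.performance_stages
        }
        cards.append(total_score(tuple(combo), pp, cp, jp, scoring))
    return cards
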