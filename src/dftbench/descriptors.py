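"""Catalog of benchmarked density functionals and basis sets.

The benchmark grid pairs 11 exchange-correlation functionals with 14 basis
sets (154 combinations).  Each functional is described by the fraction of
exact Hartree-Fock exchange it applies at short (SR), middle (MR) and long
(LR) interelectronic range; each basis set by its size (number of basis
functions on the benchmark molecule), valence splitting (double- vs
triple-zeta) and the presence of diffuse functions.  These descriptors are
the regression features of the analysis layer.

The catalog itself is data (``data/catalog.yaml``), not code, so new methods
can be added without touching the package.
"""

from __future__ import annotations

import difflib
import importlib.resources
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FunctionalSpec",
    "BasisSpec",
    "Catalog",
    "CatalogLookupError",
    "FEATURE_NAMES",
    "default_catalog",
    "lookup_functional",
    "lookup_basis",
    "encode_features",
    "feature_table",
    "normalize_name",
]

#: Canonical order of the regression features.
FEATURE_NAMES: tuple[str, ...] = ("SR", "MR", "LR", "NBF", "zeta", "D")

_RUNGS = frozenset({"GGA", "GH", "RSH"})
_FAMILIES = frozenset({"Pople", "Dunning", "Ahlrich"})
_ZETAS = frozenset({"double", "triple"})


class CatalogLookupError(KeyError):
    """Unknown functional or basis-set name, with nearest-match suggestions."""


def normalize_name(name: str) -> str:
    """Collapse a method/basis name to a canonical lookup key.

    Hyphens, en-/em-dashes and whitespace are stripped, the name is
    case-folded, and the omega spellings of the wB97 family are mapped onto
    ``w`` — the literature mixes "WB97", "wB97" and "ωB97" freely.
    """
    key = name.replace("–", "-").replace("—", "-")
    key = key.replace("ω", "w").replace("Ω", "w")
    key = key.replace("-", "").replace(" ", "")
    return key.casefold()


@dataclass(frozen=True)
class FunctionalSpec:
    """Descriptor of one exchange-correlation functional.

    ``hf_sr``/``hf_mr``/``hf_lr`` are percentages of exact Hartree-Fock
    exchange at short, middle and long range; global hybrids (and the pure
    GGA) must apply one constant fraction at every range.
    """

    name: str
    rung: str  # GGA | GH | RSH
    meta: bool
    hf_sr: float
    hf_mr: float
    hf_lr: float

    def __post_init__(self) -> None:
        if self.rung not in _RUNGS:
            raise ValueError(f"unknown rung {self.rung!r}; expected one of {sorted(_RUNGS)}")
        for label, pct in (("hf_sr", self.hf_sr), ("hf_mr", self.hf_mr), ("hf_lr", self.hf_lr)):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{label}={pct} outside [0, 100] for {self.name}")
        if self.rung in ("GGA", "GH") and not (self.hf_sr == self.hf_mr == self.hf_lr):
            raise ValueError(
                f"{self.name}: a {self.rung} functional must use one exchange "
                f"fraction at every range, got {self.hf_sr}/{self.hf_mr}/{self.hf_lr}"
            )


@dataclass(frozen=True)
class BasisSpec:
    """Descriptor of one basis set: size, valence splitting, diffusion."""

    name: str
    family: str  # Pople | Dunning | Ahlrich
    nbf: int
    zeta: str  # double | triple
    diffuse: bool

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.zeta not in _ZETAS:
            raise ValueError(f"zeta must be 'double' or 'triple', got {self.zeta!r}")
        if self.nbf <= 0:
            raise ValueError(f"nbf must be positive, got {self.nbf}")


class Catalog:
    """Immutable lookup table of functionals and basis sets."""

    def __init__(self, functionals: Mapping[str, FunctionalSpec], basis_sets: Mapping[str, BasisSpec]):
        self._functionals = dict(functionals)
        self._basis_sets = dict(basis_sets)
        self._f_index = {normalize_name(k): k for k in self._functionals}
        self._b_index = {normalize_name(k): k for k in self._basis_sets}

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "Catalog":
        funcs = {f["name"]: FunctionalSpec(**f) for f in doc["functionals"]}
        bases = {b["name"]: BasisSpec(**b) for b in doc["basis_sets"]}
        return cls(funcs, bases)

    @classmethod
    def from_file(cls, path) -> "Catalog":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Catalog":
        ref = importlib.resources.files("dftbench.data").joinpath("catalog.yaml")
        return cls.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))

    # -- lookups ----------------------------------------------------------

    @property
    def functionals(self) -> tuple[FunctionalSpec, ...]:
        return tuple(self._functionals.values())

    @property
    def basis_sets(self) -> tuple[BasisSpec, ...]:
        return tuple(self._basis_sets.values())

    def functional(self, name: str) -> FunctionalSpec:
        return self._lookup(name, self._f_index, self._functionals, "functional")

    def basis(self, name: str) -> BasisSpec:
        return self._lookup(name, self._b_index, self._basis_sets, "basis set")

    def _lookup(self, name, index, table, kind):
        key = normalize_name(name)
        if key in index:
            return table[index[key]]
        close = difflib.get_close_matches(key, index.keys(), n=3, cutoff=0.4)
        suggestions = ", ".join(table[index[c]].name for c in close) or "none"
        raise CatalogLookupError(f"unknown {kind} {name!r}; nearest catalog matches: {suggestions}")

    def combinations(self) -> Iterator[tuple[FunctionalSpec, BasisSpec]]:
        """All functional x basis pairs, in catalog order."""
        for f in self._functionals.values():
            for b in self._basis_sets.values():
                yield f, b


def encode_features(functional: FunctionalSpec, basis: BasisSpec) -> np.ndarray:
    """Six-component feature vector (SR, MR, LR, NBF, zeta, D).

    SR/MR/LR are the raw exchange percentages in [0, 100]; NBF the basis-set
    size; zeta the double-zeta indicator (absence of double-zeta means
    triple-zeta, encoded 0); D the diffuse-function indicator, with no
    distinction between single and double diffusion.
    """
    return np.array(
        [
            functional.hf_sr,
            functional.hf_mr,
            functional.hf_lr,
            float(basis.nbf),
            1.0 if basis.zeta == "double" else 0.0,
            1.0 if basis.diffuse else 0.0,
        ]
    )


def feature_table(catalog: Catalog | None = None) -> pd.DataFrame:
    """Tidy feature matrix over the whole grid (one row per combination)."""
    catalog = catalog or default_catalog()
    rows = []
    for f, b in catalog.combinations():
        rows.append({"functional": f.name, "basis": b.name, **dict(zip(FEATURE_NAMES, encode_features(f, b)))})
    df = pd.DataFrame(rows)
    df["NBF"] = df["NBF"].astype(int)
    return df


_DEFAULT: Catalog | None = None


def default_catalog() -> Catalog:
    """The packaged catalog (11 functionals x 14 basis sets), cached."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Catalog.default()
    return _DEFAULT


def lookup_functional(name: str, catalog: Catalog | None = None) -> FunctionalSpec:
    """Resolve a functional name (case/hyphen/omega tolerant)."""
    return (catalog or default_catalog()).functional(name)


def lookup_basis(name: str, catalog: Catalog | None = None) -> BasisSpec:
    """Resolve a basis-set name (case/hyphen/en-dash tolerant)."""
    return (catalog or default_catalog()).basis(name)
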