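"""Reactivity indices of a phenolic antioxidant from species enthalpies.

The thermodynamic feasibility of the radical-scavenging channels is
summarized by four enthalpic indices, each a gas-phase reaction enthalpy of
the parent phenol ArOH:

* BDE  — homolytic O-H cleavage, ArOH -> ArO. + H.      (HAT channel)
* aIP  — adiabatic ionization, ArOH -> ArOH.+ + e-      (SET-PT channel)
* aEA  — adiabatic electron attachment, ArOH + e- -> ArOH.-
* PA   — heterolytic deprotonation, ArOH -> ArO- + H+   (SPLET channel)

plus two vertical counterparts obtained without geometry relaxation via
Janak's theorem, the DFT analogue of Koopmans' theorem: vIP = -eps(HOMO),
vEA = -eps(LUMO).

Conventions: the free electron carries zero enthalpy; the gas-phase proton
enthalpy defaults to 5/2 RT (~1.48 kcal/mol) and is configurable; the
hydrogen-atom enthalpy is always an input computed at the same level of
theory as the parent, never a constant.  aEA is reported as
Delta_H(anion - neutral), so a bound anion is negative.  All species
enthalpies are vacuum values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .constants import HARTREE_TO_EV, HARTREE_TO_KCAL, PROTON_ENTHALPY_KCAL

__all__ = [
    "SpeciesEnergetics",
    "ReactivityIndices",
    "MissingSpeciesError",
    "bde",
    "adiabatic_ip",
    "adiabatic_ea",
    "proton_affinity",
    "janak_vip",
    "janak_vea",
    "compute_indices",
]


class MissingSpeciesError(ValueError):
    """A requested index needs a species that the record does not carry."""


def _check_finite(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SpeciesEnergetics:
    """Enthalpies and frontier-orbital energies for one (functional, basis) pair.

    All enthalpies in Hartree.  Site maps (phenolic O-H positions, e.g. C3 and
    C4 of the catechol moiety) key the radical and deprotonated-anion species.
    Optional species may be absent; the corresponding indices are then simply
    not computed.
    """

    combination: tuple[str, str]
    h_parent: float
    h_radical_by_site: Mapping[str, float] | None = None
    h_cation_radical: float | None = None
    h_anion_radical: float | None = None
    h_anion_by_site: Mapping[str, float] | None = None
    h_hydrogen_atom: float | None = None
    eps_homo: float | None = None
    eps_lumo: float | None = None

    def __post_init__(self) -> None:
        _check_finite(h_parent=self.h_parent)
        for label, val in (
            ("h_cation_radical", self.h_cation_radical),
            ("h_anion_radical", self.h_anion_radical),
            ("h_hydrogen_atom", self.h_hydrogen_atom),
            ("eps_homo", self.eps_homo),
            ("eps_lumo", self.eps_lumo),
        ):
            if val is not None:
                _check_finite(**{label: val})
        for label, m in (("h_radical_by_site", self.h_radical_by_site), ("h_anion_by_site", self.h_anion_by_site)):
            if m is not None:
                for site, val in m.items():
                    _check_finite(**{f"{label}[{site}]": val})
        if self.eps_homo is not None and self.eps_lumo is not None and not self.eps_homo < self.eps_lumo:
            raise ValueError(
                f"eps_homo ({self.eps_homo}) must lie below eps_lumo ({self.eps_lumo}) "
                f"for {self.combination}"
            )


@dataclass(frozen=True)
class ReactivityIndices:
    """Computed indices; enthalpic ones in kcal/mol, vertical ones in eV."""

    combination: tuple[str, str]
    bde_by_site: Mapping[str, float] | None = None
    aip: float | None = None
    aea: float | None = None
    pa_by_site: Mapping[str, float] | None = None
    vip: float | None = None
    vea: float | None = None
    flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        """Flat property -> value map using site-suffixed keys (bde_c3, ...)."""
        out: dict[str, float] = {}
        if self.bde_by_site:
            out.update({f"bde_{s.lower()}": v for s, v in self.bde_by_site.items()})
        if self.pa_by_site:
            out.update({f"pa_{s.lower()}": v for s, v in self.pa_by_site.items()})
        for key in ("aip", "aea", "vip", "vea"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


def bde(h_parent: float, h_radical: float, h_hydrogen_atom: float) -> float:
    """O-H bond dissociation enthalpy, kcal/mol.

    ArOH -> ArO. + H. ; Delta_H = H(ArO.) + H(H.) - H(ArOH).  A negative
    value (exothermic cleavage) is physically unusual but not an error.
    """
    _check_finite(h_parent=h_parent, h_radical=h_radical, h_hydrogen_atom=h_hydrogen_atom)
    return (h_radical + h_hydrogen_atom - h_parent) * HARTREE_TO_KCAL


def adiabatic_ip(h_parent: float, h_cation_radical: float) -> float:
    """Adiabatic ionization potential, kcal/mol (free electron at zero enthalpy)."""
    _check_finite(h_parent=h_parent, h_cation_radical=h_cation_radical)
    value = (h_cation_radical - h_parent) * HARTREE_TO_KCAL
    if value < 0.0:
        warnings.warn("negative adiabatic ionization potential: cation below neutral", stacklevel=2)
    return value


def adiabatic_ea(h_parent: float, h_anion_radical: float) -> float:
    """Adiabatic electron affinity as Delta_H(anion - neutral), kcal/mol.

    Negative means the anion is bound (electron attachment releases enthalpy).
    """
    _check_finite(h_parent=h_parent, h_anion_radical=h_anion_radical)
    return (h_anion_radical - h_parent) * HARTREE_TO_KCAL


def proton_affinity(h_parent: float, h_anion: float, h_proton: float = PROTON_ENTHALPY_KCAL) -> float:
    """Deprotonation enthalpy ArOH -> ArO- + H+, kcal/mol.

    ``h_proton`` is the gas-phase proton enthalpy in kcal/mol (default
    5/2 RT at 298.15 K, ~1.48).
    """
    _check_finite(h_parent=h_parent, h_anion=h_anion, h_proton=h_proton)
    return (h_anion - h_parent) * HARTREE_TO_KCAL + h_proton


def janak_vip(eps_homo: float) -> float:
    """Vertical ionization potential from the HOMO eigenvalue, eV."""
    _check_finite(eps_homo=eps_homo)
    return -eps_homo * HARTREE_TO_EV


def janak_vea(eps_lumo: float) -> float:
    """Vertical electron affinity from the LUMO eigenvalue, eV (may be negative)."""
    _check_finite(eps_lumo=eps_lumo)
    return -eps_lumo * HARTREE_TO_EV


def compute_indices(
    s: SpeciesEnergetics,
    require: tuple[str, ...] | None = None,
    h_proton: float = PROTON_ENTHALPY_KCAL,
) -> ReactivityIndices:
    """All available reactivity indices for one species record.

    Missing optional species simply leave the corresponding index absent.
    ``require`` names index groups ('bde', 'aip', 'aea', 'pa', 'vip', 'vea')
    that must be computable; a missing prerequisite then raises
    :class:`MissingSpeciesError` naming the absent species.
    """
    require = tuple(require or ())
    flags: list[str] = []

    needs = {
        "bde": [("h_radical_by_site", s.h_radical_by_site), ("h_hydrogen_atom", s.h_hydrogen_atom)],
        "aip": [("h_cation_radical", s.h_cation_radical)],
        "aea": [("h_anion_radical", s.h_anion_radical)],
        "pa": [("h_anion_by_site", s.h_anion_by_site)],
        "vip": [("eps_homo", s.eps_homo)],
        "vea": [("eps_lumo", s.eps_lumo)],
    }
    for idx in require:
        if idx not in needs:
            raise ValueError(f"unknown index {idx!r}; expected one of {sorted(needs)}")
        missing = [name for name, val in needs[idx] if val is None]
        if missing:
            raise MissingSpeciesError(
                f"index {idx!r} for {s.combination} requires missing species field(s): {', '.join(missing)}"
            )

    bde_by_site = None
    if s.h_radical_by_site is not None and s.h_hydrogen_atom is not None:
        bde_by_site = {site: bde(s.h_parent, h_rad, s.h_hydrogen_atom) for site, h_rad in s.h_radical_by_site.items()}

    aip = None
    if s.h_cation_radical is not None:
        aip = (s.h_cation_radical - s.h_parent) * HARTREE_TO_KCAL
        if aip < 0.0:
            flags.append("negative_aip")

    aea = adiabatic_ea(s.h_parent, s.h_anion_radical) if s.h_anion_radical is not None else None
    pa_by_site = (
        {site: proton_affinity(s.h_parent, h_an, h_proton) for site, h_an in s.h_anion_by_site.items()}
        if s.h_anion_by_site is not None
        else None
    )
    vip = janak_vip(s.eps_homo) if s.eps_homo is not None else None
    vea = janak_vea(s.eps_lumo) if s.eps_lumo is not None else None

    return ReactivityIndices(
        combination=s.combination,
        bde_by_site=bde_by_site,
        aip=aip,
        aea=aea,
        pa_by_site=pa_by_site,
        vip=vip,
        vea=vea,
        flags=tuple(flags),
    )
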