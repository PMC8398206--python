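"""Reactivity-index arithmetic, unit conventions and record composition."""

import math

import pytest

from dftbench.constants import EV_TO_KCAL, HARTREE_TO_KCAL, PROTON_ENTHALPY_KCAL
from dftbench.thermochem import (
    MissingSpeciesError,
    SpeciesEnergetics,
    adiabatic_ea,
    adiabatic_ip,
    bde,
    compute_indices,
    janak_vea,
    janak_vip,
    proton_affinity,
)


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        # hand-arithmetic oracles: delta-H in Hartree times 627.5095
        (bde, (-500.0, -499.4, -0.497912), 0.102088 * HARTREE_TO_KCAL),
        (bde, (-500.0, -499.502088, -0.497912), 0.0),  # closed cycle
        (adiabatic_ip, (-500.0, -499.70665), 0.29335 * HARTREE_TO_KCAL),
        (adiabatic_ip, (-500.0, -500.0), 0.0),
        (adiabatic_ea, (-500.0, -500.0204), -0.0204 * HARTREE_TO_KCAL),
        (adiabatic_ea, (-500.0, -499.99), 0.01 * HARTREE_TO_KCAL),  # unbound anion
        (proton_affinity, (-500.0, -499.487, 1.48), 0.513 * HARTREE_TO_KCAL + 1.48),
        (proton_affinity, (-500.0, -500.0, 0.0), 0.0),
        (janak_vip, (-0.263125,), 0.263125 * 27.2114),
        (janak_vip, (0.0,), 0.0),
        (janak_vip, (-1.0,), 27.2114),
        (janak_vea, (-0.024622,), 0.024622 * 27.2114),
        (janak_vea, (0.036752,), -0.036752 * 27.2114),
    ],
)
def test_index_arithmetic(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=1e-9)


def test_reference_scale_checks():
    """The worked conversions land on the benchmark's reference magnitudes."""
    assert adiabatic_ip(-500.0, -499.70665) == pytest.approx(184.08, abs=0.005)
    assert adiabatic_ea(-500.0, -500.0204) == pytest.approx(-12.80, abs=0.005)
    assert proton_affinity(-500.0, -499.487, 1.48) == pytest.approx(323.39, abs=0.005)
    assert janak_vip(-0.263125) == pytest.approx(7.16, abs=0.001)
    assert janak_vea(-0.024622) == pytest.approx(0.67, abs=0.001)


def test_exothermic_cleavage_allowed():
    assert bde(-500.0, -499.9, -0.5) < 0.0


def test_negative_aip_warns():
    with pytest.warns(UserWarning, match="negative"):
        assert adiabatic_ip(-500.0, -500.1) < 0


def test_nonfinite_inputs_rejected():
    for bad in (math.nan, math.inf):
        with pytest.raises(ValueError):
            bde(bad, -499.4, -0.5)
        with pytest.raises(ValueError):
            adiabatic_ea(-500.0, bad)


def test_proton_enthalpy_default_is_ideal_gas_5half_rt():
    assert PROTON_ENTHALPY_KCAL == pytest.approx(2.5 * 0.0019872 * 298.15, rel=1e-3)
    assert PROTON_ENTHALPY_KCAL == pytest.approx(1.48, abs=0.01)


def test_ev_kcal_consistency():
    # the field's round value of 23.0 kcal/mol per eV holds within 0.3%
    assert abs(EV_TO_KCAL - 23.0) / 23.0 < 0.003


def _full_record():
    return SpeciesEnergetics(
        combination=("M06-2X", "6-311G(d,p)"),
        h_parent=-647.0,
        h_radical_by_site={"C3": -646.37, "C4": -646.39},
        h_cation_radical=-646.71,
        h_anion_radical=-647.02,
        h_anion_by_site={"C3": -646.46, "C4": -646.49},
        h_hydrogen_atom=-0.497912,
        eps_homo=-0.26,
        eps_lumo=-0.02,
    )


def test_compute_indices_full_record():
    idx = compute_indices(_full_record())
    flat = idx.as_dict()
    assert set(flat) == {"bde_c3", "bde_c4", "pa_c3", "pa_c4", "aip", "aea", "vip", "vea"}
    assert flat["bde_c3"] == pytest.approx(bde(-647.0, -646.37, -0.497912))
    assert flat["vea"] == pytest.approx(janak_vea(-0.02))


def test_compute_indices_partial_record():
    rec = SpeciesEnergetics(combination=("BLYP", "cc-pVDZ"), h_parent=-647.0, h_cation_radical=-646.7)
    idx = compute_indices(rec)
    assert idx.aip is not None
    assert idx.pa_by_site is None and idx.bde_by_site is None and idx.vip is None


def test_compute_indices_required_missing_species():
    rec = SpeciesEnergetics(combination=("BLYP", "cc-pVDZ"), h_parent=-647.0)
    with pytest.raises(MissingSpeciesError, match="h_anion_by_site"):
        compute_indices(rec, require=("pa",))


def test_unit_invariance_of_indices():
    """Pre-converting every enthalpy to kcal/mol changes nothing beyond 1e-9."""
    rec = _full_record()
    idx_hartree = compute_indices(rec).as_dict()
    k = HARTREE_TO_KCAL

    def direct_kcal(prop):
        if prop.startswith("bde_"):
            site = prop[-2:].upper()
            return rec.h_radical_by_site[site] * k + rec.h_hydrogen_atom * k - rec.h_parent * k
        if prop.startswith("pa_"):
            site = prop[-2:].upper()
            return rec.h_anion_by_site[site] * k - rec.h_parent * k + PROTON_ENTHALPY_KCAL
        if prop == "aip":
            return rec.h_cation_radical * k - rec.h_parent * k
        if prop == "aea":
            return rec.h_anion_radical * k - rec.h_parent * k
        raise KeyError(prop)

    for prop in ("bde_c3", "bde_c4", "pa_c3", "pa_c4", "aip", "aea"):
        assert idx_hartree[prop] == pytest.approx(direct_kcal(prop), abs=1e-9)


def test_homo_above_lumo_rejected():
    with pytest.raises(ValueError, match="eps_homo"):
        SpeciesEnergetics(combination=("x", "y"), h_parent=-1.0, eps_homo=-0.1, eps_lumo=-0.2)
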