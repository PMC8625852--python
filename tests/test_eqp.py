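import dataclasses
import math

import pytest

from invitrodist import (
    ChemicalRecord,
    IonClass,
    SystemSpec,
    bulk_medium_ratio,
    naproxen_like,
    simulate,
    solve_eqp,
)
from invitrodist.eqp import plastic_equivalent_volume_ul
from invitrodist.partitioning import PartitionSet
from invitrodist.test_system import PhaseVolumes

from conftest import brute_force_cw, capacities_of


def make_parts(**overrides) -> PartitionSet:
    """Minimal all-unity PartitionSet for hand-built mass-balance checks."""
    base = dict(
        chemical_id="manual",
        ion_class=IonClass.NEUTRAL,
        f_n_medium=1.0,
        f_n_cytosol=1.0,
        f_n_lysosome=1.0,
        k_aw=0.0, d_aw=0.0,
        k_saw=0.0, d_saw=0.0,
        k_slw=0.0, d_slw=0.0,
        k_dsw=0.0, d_dsw=0.0,
        k_mw=1.0, d_mw=1.0,
        k_pw=1.0, d_pw=1.0,
        k_cw=1.0, d_cw=1.0, d_cw_adj=1.0,
        k_plw=0.0, d_plw=0.0,
        k_bw=1.0, d_bw=1.0,
        k_pl_bw=1.0, d_pl_bw=1.0,
        log_kow_t=0.0, log_kaw_t=-10.0,
    )
    base.update(overrides)
    return PartitionSet(**base)


def make_vols(**overrides) -> PhaseVolumes:
    base = dict(
        v_water=100.0, v_air=0.0, v_albumin=0.0, v_serum_lipid=0.0,
        v_other_dom=0.0, v_cells=0.0, a_plastic_m2=0.0,
    )
    base.update(overrides)
    return PhaseVolumes(**base)


WATER_CHEM = ChemicalRecord(id="tracer", mw=100.0, nominal_um=10.0, sw_mg_l=1e6)
WATER_SPEC = SystemSpec(fbs_fraction=0.0, medium_volume_ul=100.0, cell_count=0.0)


class TestClosedForm:
    def test_water_only_system_keeps_everything_dissolved(self):
        result = solve_eqp(WATER_CHEM, WATER_SPEC, make_parts(), make_vols())
        assert result.c_water_um == pytest.approx(10.0)
        assert result.free_ratio == pytest.approx(1.0)
        assert result.bulk_ratio == pytest.approx(1.0)

    def test_two_phase_albumin_free_fraction(self):
        """water 200 uL + albumin 0.338 uL at log D 5.21: 200/54,817 oracle."""
        parts = make_parts(d_saw=10**5.21)
        vols = make_vols(v_water=200.0, v_albumin=0.338)
        spec = dataclasses.replace(WATER_SPEC, medium_volume_ul=200.0)
        result = solve_eqp(WATER_CHEM, spec, parts, vols)
        expected = 200.0 / (200.0 + 10**5.21 * 0.338)
        assert expected == pytest.approx(0.00364, abs=2e-5)
        assert result.free_ratio == pytest.approx(expected, rel=1e-12)
        # all sorbed mass stays suspended in the medium
        bulk, free = bulk_medium_ratio(result)
        assert bulk == pytest.approx(1.0, rel=1e-12)
        assert free == pytest.approx(expected, rel=1e-12)

    def test_dose_is_nominal_times_medium_volume(self):
        result = solve_eqp(WATER_CHEM, WATER_SPEC, make_parts(), make_vols())
        assert result.total_umol == pytest.approx(10.0 * 100.0 * 1e-6)

    def test_plastic_unit_conversion(self):
        # 1e-4 m^3/m^2 over 1e-2 m^2 is 1e-6 m^3, i.e. 1000 uL of water
        assert plastic_equivalent_volume_ul(1e-4, 1e-2) == pytest.approx(1000.0)

    def test_membrane_concentration_mm(self):
        parts = make_parts(d_mw=2000.0)
        result = solve_eqp(WATER_CHEM, WATER_SPEC, parts, make_vols())
        assert result.c_membrane_mm == pytest.approx(2000.0 * 10.0 / 1000.0)

    def test_nonpositive_nominal_rejected(self):
        chem = ChemicalRecord(id="zero", mw=100.0, nominal_um=0.0)
        with pytest.raises(Exception, match="nominal"):
            solve_eqp(chem, WATER_SPEC, make_parts(), make_vols())


class TestNaproxenWorkedCase:
    """Ionizable acid with empirical biopartitioning in 96-well systems."""

    def test_free_ratio_at_10pct_fbs(self):
        result, _, _ = simulate(naproxen_like(), SystemSpec(fbs_fraction=0.10))
        assert 0.003 / 1.5 <= result.free_ratio <= 0.003 * 1.5

    def test_free_ratio_at_2pct_fbs(self):
        result, _, _ = simulate(naproxen_like(), SystemSpec(fbs_fraction=0.02))
        assert 0.02 / 1.5 <= result.free_ratio <= 0.02 * 1.5

    def test_less_serum_means_more_freely_dissolved(self):
        r10, _, _ = simulate(naproxen_like(), SystemSpec(fbs_fraction=0.10))
        r2, _, _ = simulate(naproxen_like(), SystemSpec(fbs_fraction=0.02))
        assert r2.free_ratio > r10.free_ratio


class TestConservationAndOracle:
    def test_mass_conservation_on_panel(self, panel_500):
        spec = SystemSpec()
        for chem in panel_500:
            result, _, _ = simulate(chem, spec)
            assert result.mass_total() == pytest.approx(result.total_umol, rel=1e-9)
            assert sum(result.mass_fractions.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(m >= 0 for m in result.masses_umol.values())

    def test_brute_force_oracle_equivalence(self, panel_500):
        """Root-finding the activity balance reproduces the closed form."""
        from invitrodist.eqp import simulate as run
        from invitrodist.partitioning import build_partition_set
        from invitrodist.test_system import derive_phase_volumes

        spec = SystemSpec()
        vols = derive_phase_volumes(spec)
        for chem in panel_500:
            result, parts, _ = run(chem, spec)
            caps = capacities_of(parts, vols)
            oracle = brute_force_cw(result.total_umol, caps)
            assert result.c_water_um == pytest.approx(oracle, rel=1e-9)


class TestMonotonicity:
    def test_cw_decreases_with_any_capacity(self):
        base = solve_eqp(WATER_CHEM, WATER_SPEC, make_parts(), make_vols())
        grown = [
            (make_parts(d_aw=1.0), make_vols(v_air=50.0)),
            (make_parts(d_saw=100.0), make_vols(v_albumin=1.0)),
            (make_parts(d_cw_adj=50.0), make_vols(v_cells=1.0)),
            (make_parts(d_plw=1e-5), make_vols(a_plastic_m2=1e-4)),
        ]
        for parts, vols in grown:
            result = solve_eqp(WATER_CHEM, WATER_SPEC, parts, vols)
            assert result.c_water_um < base.c_water_um

    def test_headspace_growth_never_raises_condensed_masses(self):
        chem = ChemicalRecord(
            id="volatile", mw=120.0, log_kow_n=2.5, log_kaw_n=-0.5,
            sw_mg_l=500.0, nominal_um=50.0,
        )
        small, _, _ = simulate(chem, SystemSpec(headspace_multiplier=1.0))
        large, _, _ = simulate(chem, SystemSpec(headspace_multiplier=100.0))
        for phase in ("water", "albumin", "serum_lipid", "other_dom", "cells", "plastic"):
            assert large.masses_umol[phase] <= small.masses_umol[phase]
        assert large.masses_umol["headspace"] > small.masses_umol["headspace"]


class TestBulkRatio:
    def test_serum_free_bulk_equals_free(self):
        chem = ChemicalRecord(id="x", mw=150.0, log_kow_n=2.0, log_kaw_n=-6.0)
        result, _, _ = simulate(chem, SystemSpec(fbs_fraction=0.0))
        bulk, free = bulk_medium_ratio(result)
        assert bulk == pytest.approx(free, rel=1e-12)

    def test_closed_water_only_both_unity(self):
        result = solve_eqp(WATER_CHEM, WATER_SPEC, make_parts(), make_vols())
        bulk, free = bulk_medium_ratio(result)
        assert bulk == pytest.approx(1.0)
        assert free == pytest.approx(1.0)
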