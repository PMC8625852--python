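import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from invitrodist import (
    ChemicalRecord,
    PartitionOptions,
    SystemSpec,
    ValidationError,
    build_partition_set,
    distribution_ratio,
    kplw_fischer,
    kplw_kramer,
)
from invitrodist.partitioning import (
    SpeciesPair,
    adjust_cell_water_ph,
    biopartition_neutral,
    blood_water_ratio,
    cell_water_ratio,
    lysosomal_trapping_multiplier,
    scale_to_charged,
    DEFAULT_BLOOD,
    PhaseComposition,
)
from invitrodist.test_system import CellComposition


class TestPlasticSpLfers:
    @pytest.mark.parametrize(
        "fn, log_kow, expected",
        [
            (kplw_kramer, 0.0, -6.94),
            (kplw_kramer, 4.0, -3.06),
            (kplw_kramer, 7.5, 0.335),
            (kplw_fischer, 0.0, -4.64),
            (kplw_fischer, 4.0, -2.40),
            (kplw_fischer, 7.5, -0.44),
        ],
    )
    def test_values(self, fn, log_kow, expected):
        assert fn(log_kow) == pytest.approx(expected, abs=1e-12)

    def test_difference_crosses_zero_once(self):
        """|Kramer - Fischer| = |0.41 logKow - 2.30|, one crossing on a grid."""
        grid = np.linspace(-4.0, 10.0, 200)
        diff = np.array([kplw_kramer(x) - kplw_fischer(x) for x in grid])
        assert np.allclose(np.abs(diff), np.abs(0.41 * grid - 2.30))
        assert np.sum(np.diff(np.sign(diff)) != 0) == 1


class TestBiopartitioning:
    @pytest.mark.parametrize(
        "log_kow, phase, expected",
        [
            (0.0, "membrane", 0.12),
            (3.0, "albumin", 2.55),
            (5.0, "storage_lipid", 5.0),
        ],
    )
    def test_splfer_defaults(self, log_kow, phase, expected):
        assert biopartition_neutral(log_kow, phase) == pytest.approx(expected)

    def test_unknown_phase(self):
        with pytest.raises(ValidationError):
            biopartition_neutral(2.0, "mitochondria")

    @pytest.mark.parametrize(
        "log_k_n, phase, expected",
        [(3.0, "membrane", 2.0), (3.0, "plastic", 1.0)],
    )
    def test_charged_scaling(self, log_k_n, phase, expected):
        assert scale_to_charged(log_k_n, phase) == pytest.approx(expected)

    def test_zero_offset_override(self):
        assert scale_to_charged(3.0, "membrane", {"membrane": 0.0}) == 3.0


class TestDistributionRatio:
    @pytest.mark.parametrize(
        "k_n, k_i, f_n, expected",
        [(100.0, 1.0, 1.0, 100.0), (100.0, 1.0, 0.0, 1.0), (100.0, 1.0, 0.5, 50.5)],
    )
    def test_weighted_average(self, k_n, k_i, f_n, expected):
        assert distribution_ratio(k_n, k_i, f_n) == pytest.approx(expected)

    @given(
        k_n=st.floats(1e-6, 1e8),
        k_i=st.floats(1e-6, 1e8),
        f_n=st.floats(0.0, 1.0),
    )
    def test_bounded_by_species_ratios(self, k_n, k_i, f_n):
        d = distribution_ratio(k_n, k_i, f_n)
        assert min(k_n, k_i) * (1 - 1e-12) <= d <= max(k_n, k_i) * (1 + 1e-12)


class TestCellWaterRatio:
    def test_pure_water_cell(self):
        comp = CellComposition(1.0, 0.0, 0.0, 0.0)
        pair = SpeciesPair(1.0, 1.0)
        assert cell_water_ratio(comp, pair, pair, pair, 1.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """0.03*1000 + 0.2*10 + 0.7 water = 32.7."""
        comp = CellComposition(
            f_water=0.7, f_bulk_protein=0.2, f_membrane_lipid=0.03, f_storage_lipid=0.0
        )
        k = cell_water_ratio(
            comp,
            SpeciesPair(1000.0, 1000.0),
            SpeciesPair(5.0, 5.0),  # zero volume fraction, value irrelevant
            SpeciesPair(10.0, 10.0),
            1.0,
        )
        assert k == pytest.approx(32.7)

    def test_anionic_option_no_effect_on_neutrals(self):
        comp = CellComposition()
        pairs = [SpeciesPair(100.0, 100.0)] * 3
        on = cell_water_ratio(
            comp, *pairs, 1.0, ion_sign=0,
            options=PartitionOptions(anionic_phospholipids=True),
        )
        off = cell_water_ratio(comp, *pairs, 1.0, ion_sign=0)
        assert on == off

    def test_anionic_option_raises_cation_sorption(self):
        comp = CellComposition()
        mem = SpeciesPair(1000.0, 100.0)
        other = SpeciesPair(1.0, 1.0)
        on = cell_water_ratio(
            comp, mem, other, other, 0.1, ion_sign=+1,
            options=PartitionOptions(anionic_phospholipids=True),
        )
        off = cell_water_ratio(comp, mem, other, other, 0.1, ion_sign=+1)
        assert on > off

    def test_invalid_composition(self):
        with pytest.raises(ValidationError):
            CellComposition(0.9, 0.3, 0.0, 0.0).validate()
        with pytest.raises(ValidationError):
            CellComposition(-0.1, 0.3, 0.0, 0.0).validate()


class TestPhAdjustment:
    def test_acid_factor(self):
        """Acid ratio shrinks ~0.4-fold for cytosol pH 7.0 under medium pH 7.4."""
        assert adjust_cell_water_ph(1.0, 7.4, 7.0, "acid") == pytest.approx(0.398, abs=1e-3)

    def test_base_factor(self):
        assert adjust_cell_water_ph(1.0, 7.4, 7.0, "base") == pytest.approx(2.512, abs=1e-3)

    @pytest.mark.parametrize("ion_class", ["acid", "base", "neutral"])
    def test_equal_ph_identity(self, ion_class):
        assert adjust_cell_water_ph(42.0, 7.4, 7.4, ion_class) == pytest.approx(42.0)


class TestLysosomalTrapping:
    def test_zero_for_non_bases(self):
        assert lysosomal_trapping_multiplier("neutral", None, 7.0, 4.8, 0.01) == 0.0
        assert lysosomal_trapping_multiplier("acid", 4.0, 7.0, 4.8, 0.01) == 0.0

    def test_no_gradient_no_accumulation(self):
        inc = lysosomal_trapping_multiplier("base", 9.0, 7.0, 7.0, 0.05)
        assert inc == pytest.approx(0.05)  # accumulation ratio exactly 1

    def test_accumulation_ratio(self):
        """(1+10^4.2)/(1+10^2.0) = 157.0 for pKa 9, cytosol 7.0, lysosome 4.8."""
        inc = lysosomal_trapping_multiplier("base", 9.0, 7.0, 4.8, 0.05)
        assert inc / 0.05 == pytest.approx(157.0, abs=0.5)


class TestCompositePhases:
    def test_pure_water_blood(self):
        comp = PhaseComposition(1.0, 0.0, 0.0, 0.0, 0.0)
        pair = SpeciesPair(1000.0, 1000.0)
        assert blood_water_ratio(comp, pair, pair, pair, pair, 1.0) == pytest.approx(1.0)

    def test_unit_ratio_limit(self):
        pair = SpeciesPair(1.0, 1.0)
        k = blood_water_ratio(DEFAULT_BLOOD, pair, pair, pair, pair, 1.0)
        total = (
            DEFAULT_BLOOD.f_water + DEFAULT_BLOOD.f_albumin + DEFAULT_BLOOD.f_storage_lipid
            + DEFAULT_BLOOD.f_membrane_lipid + DEFAULT_BLOOD.f_bulk_protein
        )
        assert k == pytest.approx(total)


class TestPartitionSetAssembly:
    def test_neutral_path_equals_ioc_path(self, neutral_panel_50):
        """For neutral chemicals every D must equal its K to 1e-12 relative."""
        spec = SystemSpec()
        for chem in neutral_panel_50:
            parts = build_partition_set(chem, spec)
            assert parts.d_aw == pytest.approx(parts.k_aw, rel=1e-12)
            assert parts.d_saw == pytest.approx(parts.k_saw, rel=1e-12)
            assert parts.d_slw == pytest.approx(parts.k_slw, rel=1e-12)
            assert parts.d_dsw == pytest.approx(parts.k_dsw, rel=1e-12)
            assert parts.d_plw == pytest.approx(parts.k_plw, rel=1e-12)
            assert parts.d_cw_adj == pytest.approx(parts.d_cw, rel=1e-12)

    def test_ion_is_nonvolatile(self):
        """A fully charged acid has a vanishing air-water distribution ratio."""
        chem = ChemicalRecord(
            id="strong_acid", mw=200, ion_class="acid", pka=2.0, log_kaw_n=-1.0
        )
        parts = build_partition_set(chem, SystemSpec())
        assert parts.d_aw / parts.k_aw == pytest.approx(parts.f_n_medium, rel=1e-9)

    def test_empirical_d_used_verbatim(self):
        chem = ChemicalRecord(
            id="emp", mw=230, ion_class="acid", pka=4.15,
            log_kow_n=3.18, log_dmw=2.17, log_dsaw=5.21,
        )
        parts = build_partition_set(chem, SystemSpec())
        assert parts.d_saw == pytest.approx(10**5.21)
        assert parts.d_mw == pytest.approx(10**2.17)

    def test_d_between_species_ratios(self, panel_500):
        spec = SystemSpec()
        for chem in panel_500[:100]:
            parts = build_partition_set(chem, spec)
            for k_attr, d_attr in [
                ("k_saw", "d_saw"), ("k_slw", "d_slw"),
                ("k_dsw", "d_dsw"), ("k_plw", "d_plw"),
            ]:
                k_n = getattr(parts, k_attr)
                d = getattr(parts, d_attr)
                # charged-form ratio is k_n scaled down, so d <= k_n always
                assert d <= k_n * (1 + 1e-12)
                assert d > 0

    def test_salting_out_scales_neutral_ratios(self):
        chem = ChemicalRecord(id="x", mw=100, log_kow_n=3.0, log_kaw_n=-2.0)
        fresh = build_partition_set(chem, SystemSpec(ionic_strength_m=0.0, temperature_c=25.0))
        salty = build_partition_set(chem, SystemSpec(ionic_strength_m=0.5, temperature_c=25.0))
        factor = 10 ** (0.3 * 0.5)
        assert salty.k_saw / fresh.k_saw == pytest.approx(factor, rel=1e-12)
        assert salty.k_aw / fresh.k_aw == pytest.approx(factor, rel=1e-12)
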