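"""Phase-water partition (K) and distribution (D) ratios.

All sorbing phases in the test system are referenced to water.  Neutral-form
ratios come from single-parameter linear free-energy relationships (spLFERs)
on log K_OW,N, or from user-supplied empirical values.  For ionizable
organic chemicals (IOCs) the charged-form ratio is scaled down from the
neutral-form ratio by a per-phase log-unit offset (ions sorb much less to
apolar phases and do not volatilize: K_AW of the ion is zero), and the two
species are combined into a pH-dependent distribution ratio

    D = f_N * K_N + (1 - f_N) * K_I

with the neutral fraction f_N from Henderson-Hasselbalch speciation.

Composite phases (cell, blood, plasma) are composition-weighted sums of the
constituent-phase ratios plus the water fraction.  The cell-water ratio is
built at cytosol pH and then corrected for the pH difference between medium
and cytosol; an optional lysosomal ion-trapping increment accumulates basic
IOCs in the acidic lysosomal sub-compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .chemistry import (
    AdjustedProperties,
    ChemicalRecord,
    IonClass,
    ValidationError,
    adjust_to_conditions,
    neutral_fraction,
)
from .test_system import CellComposition, SystemSpec

__all__ = [
    "PHASES",
    "SpLfer",
    "DEFAULT_SPLFERS",
    "DEFAULT_CHARGED_OFFSETS",
    "PhaseComposition",
    "DEFAULT_BLOOD",
    "DEFAULT_PLASMA",
    "PartitionOptions",
    "PartitionSet",
    "kplw_kramer",
    "kplw_fischer",
    "biopartition_neutral",
    "scale_to_charged",
    "distribution_ratio",
    "cell_water_ratio",
    "adjust_cell_water_ph",
    "lysosomal_trapping_multiplier",
    "blood_water_ratio",
    "build_partition_set",
]

PHASES = ("membrane", "albumin", "storage_lipid", "bulk_protein", "other_dom")


@dataclass(frozen=True)
class SpLfer:
    """log K_phase,N = slope * log K_OW,N + intercept."""

    slope: float
    intercept: float

    def __call__(self, log_kow_n: float) -> float:
        return self.slope * log_kow_n + self.intercept


# Literature-typical spLFER coefficients for neutral species; one editable
# table so measured alternatives can be swapped in.  Other dissolved organic
# matter is assumed to sorb like serum albumin.
DEFAULT_SPLFERS: dict[str, SpLfer] = {
    "membrane": SpLfer(1.01, 0.12),
    "albumin": SpLfer(0.71, 0.42),
    "storage_lipid": SpLfer(1.0, 0.0),
    "bulk_protein": SpLfer(0.74, -0.44),
    "other_dom": SpLfer(0.71, 0.42),
}

# log-unit reduction from the neutral-form to the charged-form ratio.
DEFAULT_CHARGED_OFFSETS: dict[str, float] = {
    "membrane": 1.0,
    "albumin": 0.7,
    "storage_lipid": 2.0,
    "bulk_protein": 1.0,
    "other_dom": 0.7,
    "plastic": 2.0,
}


def kplw_kramer(log_kow_n: float) -> float:
    """Plastic-water spLFER (long-contact sorption data); log K_PlW in m^3/m^2."""
    return 0.97 * log_kow_n - 6.94


def kplw_fischer(log_kow_n: float) -> float:
    """Alternative plastic-water spLFER; log K_PlW in m^3/m^2."""
    return 0.56 * log_kow_n - 4.64


def biopartition_neutral(
    log_kow_n: float, phase: str, splfers: Optional[dict[str, SpLfer]] = None
) -> float:
    """Neutral-form log K for one of the named biological phases."""
    table = splfers if splfers is not None else DEFAULT_SPLFERS
    if phase not in table:
        raise ValidationError(f"unknown phase {phase!r}; options: {sorted(table)}")
    return table[phase](log_kow_n)


def scale_to_charged(
    log_k_n: float, phase: str, offsets: Optional[dict[str, float]] = None
) -> float:
    """Charged-form log K scaled down from the neutral-form value."""
    table = offsets if offsets is not None else DEFAULT_CHARGED_OFFSETS
    if phase not in table:
        raise ValidationError(f"unknown phase {phase!r}; options: {sorted(table)}")
    return log_k_n - table[phase]


def distribution_ratio(k_n: float, k_i: float, f_n: float) -> float:
    """Speciation-weighted average of neutral- and charged-form ratios."""
    if not 0.0 <= f_n <= 1.0:
        raise ValidationError(f"neutral fraction {f_n} outside [0, 1]")
    if k_n < 0 or k_i < 0:
        raise ValidationError("partition ratios must be non-negative")
    return f_n * k_n + (1.0 - f_n) * k_i


def adjust_cell_water_ph(
    d_cw: float, bulk_ph: float, cell_ph: float, ion_class: IonClass | str
) -> float:
    """Correct the cell-water distribution ratio for the medium/cytosol pH gap.

    acids:  D_CW * 10^(cell_pH - bulk_pH); bases: D_CW * 10^(bulk_pH - cell_pH).
    Neutral chemicals pass through unchanged.
    """
    ion_class = IonClass(ion_class)
    if ion_class is IonClass.NEUTRAL:
        return d_cw
    if ion_class is IonClass.ACID:
        return d_cw * 10.0 ** (cell_ph - bulk_ph)
    return d_cw * 10.0 ** (bulk_ph - cell_ph)


def lysosomal_trapping_multiplier(
    ion_class: IonClass | str,
    pka: Optional[float],
    cytosol_ph: float,
    lysosome_ph: float,
    lysosome_volume_fraction: float,
) -> float:
    """Cell-ratio increment from ion trapping of bases in acidic lysosomes.

    The lysosomal aqueous sub-compartment holds total (neutral + ionized)
    base in excess of the cytosol by (1+10^(pKa-pH_lys))/(1+10^(pKa-pH_cyt));
    the increment is that accumulation ratio weighted by the lysosome volume
    fraction of the cell.  Acids and neutral chemicals get no increment.
    """
    ion_class = IonClass(ion_class)
    if not 0.0 <= lysosome_volume_fraction <= 0.1:
        raise ValidationError("lysosome volume fraction must be in [0, 0.1]")
    if ion_class is not IonClass.BASE:
        return 0.0
    if pka is None:
        raise ValidationError("pKa required for a basic IOC")
    accumulation = (1.0 + 10.0 ** (pka - lysosome_ph)) / (1.0 + 10.0 ** (pka - cytosol_ph))
    return lysosome_volume_fraction * accumulation


@dataclass(frozen=True)
class PhaseComposition:
    """Volume-fraction composition of a composite reference phase (blood, plasma)."""

    f_water: float
    f_albumin: float
    f_storage_lipid: float
    f_membrane_lipid: float
    f_bulk_protein: float

    def validate(self) -> None:
        fracs = (
            self.f_water,
            self.f_albumin,
            self.f_storage_lipid,
            self.f_membrane_lipid,
            self.f_bulk_protein,
        )
        if any(f < 0 for f in fracs):
            raise ValidationError("composition fractions must be non-negative")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValidationError(f"composition fractions sum to {sum(fracs)} > 1")


# Whole-blood and plasma proximate compositions (volume fractions).
# Documented placeholders in the representative physiological range;
# configurable wherever a PhaseComposition is accepted.
DEFAULT_BLOOD = PhaseComposition(
    f_water=0.80, f_albumin=0.030, f_storage_lipid=0.0033,
    f_membrane_lipid=0.0024, f_bulk_protein=0.155,
)
DEFAULT_PLASMA = PhaseComposition(
    f_water=0.92, f_albumin=0.040, f_storage_lipid=0.0040,
    f_membrane_lipid=0.0020, f_bulk_protein=0.025,
)


@dataclass(frozen=True)
class PartitionOptions:
    """Switches and coefficient tables governing ratio estimation."""

    plastic_model: str = "kramer"  # {"kramer", "fischer", "user"}
    user_plastic: Optional[SpLfer] = None
    splfers: dict[str, SpLfer] = field(default_factory=lambda: dict(DEFAULT_SPLFERS))
    charged_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGED_OFFSETS)
    )
    anionic_phospholipids: bool = False
    # electrostatic enhancement of charged-species sorption to the anionic
    # membrane-lipid sub-fraction: attraction for cations, repulsion for anions
    anionic_enhancement_cation: float = 10.0
    anionic_enhancement_anion: float = 0.05
    lysosomal_trapping: bool = False
    blood: PhaseComposition = DEFAULT_BLOOD
    plasma: PhaseComposition = DEFAULT_PLASMA
    blood_ph: float = 7.4

    def log_kplw(self, log_kow_n: float) -> float:
        if self.plastic_model == "kramer":
            return kplw_kramer(log_kow_n)
        if self.plastic_model == "fischer":
            return kplw_fischer(log_kow_n)
        if self.plastic_model == "user":
            if self.user_plastic is None:
                raise ValidationError("plastic_model='user' requires user_plastic coefficients")
            return self.user_plastic(log_kow_n)
        raise ValidationError(
            f"unknown plastic model {self.plastic_model!r}; options: kramer, fischer, user"
        )


@dataclass(frozen=True)
class SpeciesPair:
    """Neutral- and charged-form partition ratios for one phase."""

    k_n: float
    k_i: float

    def d(self, f_n: float) -> float:
        return distribution_ratio(self.k_n, self.k_i, f_n)


@dataclass
class PartitionSet:
    """All phase-water ratios for one chemical at system conditions.

    K-columns are neutral-form partition ratios; D-columns are pH-dependent
    distribution ratios.  For a neutral chemical D equals K in every phase.
    ``d_plw`` is in m^3/m^2; everything else is dimensionless (volume/volume).
    """

    chemical_id: str
    ion_class: IonClass
    f_n_medium: float
    f_n_cytosol: float
    f_n_lysosome: float
    k_aw: float
    d_aw: float
    k_saw: float
    d_saw: float
    k_slw: float
    d_slw: float
    k_dsw: float
    d_dsw: float
    k_mw: float
    d_mw: float          # membrane-water at cytosol pH (drives C_MEM)
    k_pw: float
    d_pw: float
    k_cw: float
    d_cw: float          # cell-water at cytosol pH, before the bulk/cell pH correction
    d_cw_adj: float      # after the bulk/cytosol pH correction (+ lysosome increment if enabled)
    k_plw: float
    d_plw: float
    k_bw: float
    d_bw: float
    k_pl_bw: float       # plasma-water, neutral form
    d_pl_bw: float
    log_kow_t: float     # inputs adjusted to system temperature / ionic strength
    log_kaw_t: float

    def as_dict(self) -> dict[str, float]:
        keys = (
            "f_n_medium f_n_cytosol f_n_lysosome k_aw d_aw k_saw d_saw k_slw d_slw "
            "k_dsw d_dsw k_mw d_mw k_pw d_pw k_cw d_cw d_cw_adj k_plw d_plw "
            "k_bw d_bw k_pl_bw d_pl_bw log_kow_t log_kaw_t"
        ).split()
        return {k: getattr(self, k) for k in keys}


def _ion_sign(ion_class: IonClass) -> int:
    return -1 if ion_class is IonClass.ACID else (+1 if ion_class is IonClass.BASE else 0)


def cell_water_ratio(
    composition: CellComposition,
    membrane: SpeciesPair,
    storage_lipid: SpeciesPair,
    bulk_protein: SpeciesPair,
    f_n: float,
    *,
    ion_sign: int = 0,
    options: Optional[PartitionOptions] = None,
) -> float:
    """Composition-weighted cell-water ratio at a single pH.

    K_CW (or D_CW) = sum over constituents of f_i * K_iW (or D_iW) + f_water.
    With the anionic-phospholipid option on, the anionic sub-fraction of
    membrane lipid sorbs the charged species with an electrostatic
    enhancement (attraction for cations, repulsion for anions); the option
    has no effect on neutral chemicals.
    """
    composition.validate()
    opts = options if options is not None else PartitionOptions()
    d_mem = membrane.d(f_n)
    if opts.anionic_phospholipids and ion_sign != 0:
        enh = (
            opts.anionic_enhancement_cation if ion_sign > 0 else opts.anionic_enhancement_anion
        )
        f_an = composition.anionic_membrane_fraction
        d_anionic = distribution_ratio(membrane.k_n, membrane.k_i * enh, f_n)
        d_mem = (1.0 - f_an) * d_mem + f_an * d_anionic
    return (
        composition.f_membrane_lipid * d_mem
        + composition.f_storage_lipid * storage_lipid.d(f_n)
        + composition.f_bulk_protein * bulk_protein.d(f_n)
        + composition.f_water
    )


def blood_water_ratio(
    composition: PhaseComposition,
    membrane: SpeciesPair,
    albumin: SpeciesPair,
    storage_lipid: SpeciesPair,
    bulk_protein: SpeciesPair,
    f_n: float,
) -> float:
    """Composition-weighted blood- (or plasma-) water ratio at blood pH."""
    composition.validate()
    return (
        composition.f_albumin * albumin.d(f_n)
        + composition.f_storage_lipid * storage_lipid.d(f_n)
        + composition.f_membrane_lipid * membrane.d(f_n)
        + composition.f_bulk_protein * bulk_protein.d(f_n)
        + composition.f_water
    )


def _species_pair(
    record: ChemicalRecord,
    phase: str,
    log_kow_t: float,
    log_salting: float,
    options: PartitionOptions,
) -> SpeciesPair:
    """Neutral/charged ratio pair for a biological phase, honoring empirical K."""
    empirical_kn = {
        "membrane": record.log_kmw_n,
        "albumin": record.log_ksaw_n,
    }.get(phase)
    if empirical_kn is not None:
        log_kn = empirical_kn + log_salting
    else:
        log_kn = biopartition_neutral(log_kow_t, phase, options.splfers) + log_salting
    k_n = 10.0 ** log_kn
    if record.is_ioc:
        k_i = 10.0 ** scale_to_charged(log_kn, phase, options.charged_offsets)
    else:
        k_i = k_n
    return SpeciesPair(k_n, k_i)


def build_partition_set(
    record: ChemicalRecord,
    spec: SystemSpec,
    options: Optional[PartitionOptions] = None,
) -> PartitionSet:
    """Assemble every phase-water K and D for one chemical in one system.

    Empirical distribution ratios supplied at assay pH (``log_dmw``,
    ``log_dsaw``) are used verbatim for every context and never
    re-speciated; empirical neutral-form K values enter the ordinary
    speciation path in place of the spLFER estimate.  All spLFER estimates
    use log K_OW,N adjusted to system temperature, and neutral-form ratios
    carry the Setschenow salting-out term.
    """
    opts = options if options is not None else PartitionOptions()
    adj = adjust_to_conditions(record, spec.temperature_c, spec.ionic_strength_m)
    sign = _ion_sign(record.ion_class)

    f_n_med = neutral_fraction(record.ion_class, record.pka, spec.medium_ph)
    f_n_cyt = neutral_fraction(record.ion_class, record.pka, spec.cytosol_ph)
    f_n_lys = neutral_fraction(record.ion_class, record.pka, spec.lysosome_ph)
    f_n_blood = neutral_fraction(record.ion_class, record.pka, opts.blood_ph)

    # air-water: the ion is non-volatile, K_AW,I = 0
    k_aw = 10.0 ** (adj.log_kaw_n + adj.log_salting)
    air = SpeciesPair(k_aw, 0.0 if record.is_ioc else k_aw)

    membrane = _species_pair(record, "membrane", adj.log_kow_n, adj.log_salting, opts)
    albumin = _species_pair(record, "albumin", adj.log_kow_n, adj.log_salting, opts)
    storage = _species_pair(record, "storage_lipid", adj.log_kow_n, adj.log_salting, opts)
    protein = _species_pair(record, "bulk_protein", adj.log_kow_n, adj.log_salting, opts)
    other = _species_pair(record, "other_dom", adj.log_kow_n, adj.log_salting, opts)

    log_kplw = opts.log_kplw(adj.log_kow_n) + adj.log_salting
    k_plw = 10.0 ** log_kplw
    plastic = SpeciesPair(
        k_plw,
        10.0 ** scale_to_charged(log_kplw, "plastic", opts.charged_offsets)
        if record.is_ioc
        else k_plw,
    )

    def d_or_empirical(pair: SpeciesPair, empirical_log_d: Optional[float], f_n: float) -> float:
        if empirical_log_d is not None:
            return 10.0 ** empirical_log_d
        return pair.d(f_n)

    d_saw = d_or_empirical(albumin, record.log_dsaw, f_n_med)
    d_mw_cyt = d_or_empirical(membrane, record.log_dmw, f_n_cyt)

    # cell-water ratio at cytosol pH
    comp = spec.cells.composition
    if record.log_dmw is not None:
        # empirical membrane D bypasses speciation (and the anionic option)
        d_cell_mem = 10.0 ** record.log_dmw
        d_cw = (
            comp.f_membrane_lipid * d_cell_mem
            + comp.f_storage_lipid * storage.d(f_n_cyt)
            + comp.f_bulk_protein * protein.d(f_n_cyt)
            + comp.f_water
        )
    else:
        d_cw = cell_water_ratio(
            comp, membrane, storage, protein, f_n_cyt, ion_sign=sign, options=opts
        )
    k_cw = cell_water_ratio(comp, membrane, storage, protein, 1.0, options=opts) if (
        record.log_dmw is None
    ) else (
        comp.f_membrane_lipid * 10.0 ** record.log_dmw
        + comp.f_storage_lipid * storage.k_n
        + comp.f_bulk_protein * protein.k_n
        + comp.f_water
    )

    # bulk/cytosol pH correction first, then the lysosome increment
    d_cw_adj = adjust_cell_water_ph(d_cw, spec.medium_ph, spec.cytosol_ph, record.ion_class)
    if opts.lysosomal_trapping:
        d_cw_adj += lysosomal_trapping_multiplier(
            record.ion_class,
            record.pka,
            spec.cytosol_ph,
            spec.lysosome_ph,
            spec.lysosome_volume_fraction,
        )

    def blood_like(composition: PhaseComposition, f_n: float, neutral: bool) -> float:
        fn = 1.0 if neutral else f_n
        mem = SpeciesPair(membrane.k_n, membrane.k_n) if neutral else membrane
        alb = SpeciesPair(albumin.k_n, albumin.k_n) if neutral else albumin
        if record.log_dmw is not None and not neutral:
            mem = SpeciesPair(10.0 ** record.log_dmw, 10.0 ** record.log_dmw)
        if record.log_dsaw is not None and not neutral:
            alb = SpeciesPair(10.0 ** record.log_dsaw, 10.0 ** record.log_dsaw)
        return blood_water_ratio(composition, mem, alb, storage, protein, fn)

    k_bw = blood_like(opts.blood, 1.0, neutral=True)
    d_bw = blood_like(opts.blood, f_n_blood, neutral=False)
    k_pl_bw = blood_like(opts.plasma, 1.0, neutral=True)
    d_pl_bw = blood_like(opts.plasma, f_n_blood, neutral=False)

    return PartitionSet(
        chemical_id=record.id,
        ion_class=record.ion_class,
        f_n_medium=f_n_med,
        f_n_cytosol=f_n_cyt,
        f_n_lysosome=f_n_lys,
        k_aw=air.k_n,
        d_aw=air.d(f_n_med),
        k_saw=albumin.k_n,
        d_saw=d_saw,
        k_slw=storage.k_n,
        d_slw=storage.d(f_n_med),
        k_dsw=other.k_n,
        d_dsw=other.d(f_n_med),
        k_mw=membrane.k_n,
        d_mw=d_mw_cyt,
        k_pw=protein.k_n,
        d_pw=protein.d(f_n_cyt),
        k_cw=k_cw,
        d_cw=d_cw,
        d_cw_adj=d_cw_adj,
        k_plw=plastic.k_n,
        d_plw=plastic.d(f_n_med),
        k_bw=k_bw,
        d_bw=d_bw,
        k_pl_bw=k_pl_bw,
        d_pl_bw=d_pl_bw,
        log_kow_t=adj.log_kow_n,
        log_kaw_t=adj.log_kaw_n,
    )
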