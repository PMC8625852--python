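"""In vitro test-system parameterization.

Translates a well-plate assay description — plate format, working volume of
medium, serum (FBS) content, headspace assumption, cell line and seeding
density, pH and temperature — into the phase volumes and plastic surface
area that enter the equilibrium mass balance.

Headspace: the minimum headspace volume is the difference between the total
well volume and the volume of medium added, which presumes a perfectly
sealed well.  A headspace multiplier > 1 enlarges this volume as a proxy for
gas exchange with surrounding air, leakage, and sorption to adhesive plate
covers — relevant for volatile chemicals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .chemistry import ValidationError

__all__ = [
    "PlateGeometry",
    "SerumComposition",
    "CellComposition",
    "CellParams",
    "SystemSpec",
    "PhaseVolumes",
    "PLATE_GEOMETRY",
    "CELL_LINE_PRESETS",
    "DEFAULT_SERUM",
    "derive_phase_volumes",
    "plastic_area",
]


@dataclass(frozen=True)
class PlateGeometry:
    total_well_volume_ul: float
    well_diameter_mm: float


# Vendor-typical flat-bottom plate dimensions, overridable via SystemSpec.
PLATE_GEOMETRY: dict[int, PlateGeometry] = {
    6: PlateGeometry(16800.0, 34.8),
    12: PlateGeometry(6900.0, 22.1),
    24: PlateGeometry(3400.0, 15.6),
    48: PlateGeometry(1600.0, 11.1),
    96: PlateGeometry(392.0, 6.4),
    384: PlateGeometry(112.0, 3.7),
    1536: PlateGeometry(12.5, 1.7),
}

# Typical cells per well at confluence-scale seeding, by plate format.
DEFAULT_CELLS_PER_WELL: dict[int, float] = {
    6: 1.0e6,
    12: 4.0e5,
    24: 2.0e5,
    48: 1.0e5,
    96: 2.0e4,
    384: 5.0e3,
    1536: 1.0e3,
}


@dataclass(frozen=True)
class SerumComposition:
    """Sorbing constituents of serum (FBS), g/L of serum, with densities.

    Albumin and "other dissolved organics" are distinct protein-like phases;
    total lipid is assigned to the storage-lipid phase.  Representative
    bovine-serum values; every number is user-overridable.
    """

    albumin_g_l: float = 25.0
    lipid_g_l: float = 2.0
    other_dom_g_l: float = 12.0
    albumin_density_g_ml: float = 1.36
    lipid_density_g_ml: float = 0.9
    other_dom_density_g_ml: float = 1.36


DEFAULT_SERUM = SerumComposition()


@dataclass(frozen=True)
class CellComposition:
    """Proximate composition of the cell as volume fractions.

    Fractions must sum to <= 1; any remainder is treated as inert.
    ``f_membrane_lipid`` covers all phospholipid; the anionic sub-fraction
    only matters when the anionic-phospholipid option is enabled for IOCs.
    """

    f_water: float = 0.70
    f_bulk_protein: float = 0.20
    f_membrane_lipid: float = 0.03
    f_storage_lipid: float = 0.02
    anionic_membrane_fraction: float = 0.10

    def validate(self) -> None:
        fracs = (self.f_water, self.f_bulk_protein, self.f_membrane_lipid, self.f_storage_lipid)
        if any(f < 0 for f in fracs):
            raise ValidationError("cell composition fractions must be non-negative")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValidationError(
                f"cell composition fractions sum to {sum(fracs)} > 1"
            )
        if not 0.0 <= self.anionic_membrane_fraction <= 1.0:
            raise ValidationError("anionic membrane fraction must be in [0, 1]")


@dataclass(frozen=True)
class CellParams:
    volume_per_cell_ul: float = 2.5e-6
    composition: CellComposition = field(default_factory=CellComposition)


# Published cellular volumes/compositions exist for only a handful of lines;
# these presets are editable starting points, not measurements.
CELL_LINE_PRESETS: dict[str, CellParams] = {
    "generic": CellParams(),
    "MCF7": CellParams(2.5e-6, CellComposition(0.70, 0.20, 0.03, 0.02)),
    "HCT116": CellParams(2.0e-6, CellComposition(0.72, 0.19, 0.03, 0.015)),
    "HEK293T": CellParams(2.0e-6, CellComposition(0.72, 0.19, 0.03, 0.015)),
    "HepG2": CellParams(3.0e-6, CellComposition(0.68, 0.20, 0.03, 0.04)),
}


@dataclass
class SystemSpec:
    """Full parameterization of one in vitro test system."""

    plate_format: int = 96
    medium_volume_ul: float = 100.0
    total_well_volume_ul: Optional[float] = None  # default: plate geometry table
    well_diameter_mm: Optional[float] = None
    headspace_multiplier: float = 1.0
    fbs_fraction: float = 0.10
    serum: SerumComposition = field(default_factory=SerumComposition)
    medium_ph: float = 7.4
    cytosol_ph: float = 7.0
    lysosome_ph: float = 4.8
    lysosome_volume_fraction: float = 0.01
    temperature_c: float = 37.0
    ionic_strength_m: float = 0.0
    cell_line: str = "generic"
    cell_count: Optional[float] = None  # default: per-plate seeding table
    cell_params: Optional[CellParams] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- resolved accessors -------------------------------------------------
    @property
    def geometry(self) -> PlateGeometry:
        total = self.total_well_volume_ul
        diam = self.well_diameter_mm
        if total is None or diam is None:
            if self.plate_format not in PLATE_GEOMETRY:
                raise ValidationError(
                    f"unknown plate format {self.plate_format}; supply total well "
                    "volume and diameter explicitly"
                )
            preset = PLATE_GEOMETRY[self.plate_format]
            total = total if total is not None else preset.total_well_volume_ul
            diam = diam if diam is not None else preset.well_diameter_mm
        return PlateGeometry(total, diam)

    @property
    def cells(self) -> CellParams:
        if self.cell_params is not None:
            return self.cell_params
        try:
            return CELL_LINE_PRESETS[self.cell_line]
        except KeyError:
            raise ValidationError(
                f"unknown cell line {self.cell_line!r}; options: "
                f"{sorted(CELL_LINE_PRESETS)}"
            ) from None

    @property
    def n_cells(self) -> float:
        if self.cell_count is not None:
            return self.cell_count
        return DEFAULT_CELLS_PER_WELL.get(self.plate_format, 2.0e4)

    def validate(self) -> None:
        geo = self.geometry
        if not self.medium_volume_ul > 0:
            raise ValidationError("medium volume must be > 0")
        if self.medium_volume_ul >= geo.total_well_volume_ul:
            raise ValidationError(
                f"medium volume {self.medium_volume_ul} uL must be below the total "
                f"well volume {geo.total_well_volume_ul} uL"
            )
        if self.headspace_multiplier < 1.0:
            raise ValidationError("headspace multiplier must be >= 1")
        if not 0.0 <= self.fbs_fraction <= 0.2:
            raise ValidationError("FBS volume fraction must be in [0, 0.2]")
        if not 0.0 <= self.lysosome_volume_fraction <= 0.1:
            raise ValidationError("lysosome volume fraction must be in [0, 0.1]")
        self.cells.composition.validate()
        if self.n_cells * self.cells.volume_per_cell_ul >= self.medium_volume_ul:
            raise ValidationError("cell volume must be below the medium volume")


def plastic_area(well_diameter_mm: float, medium_volume_ul: float) -> float:
    """Plastic surface area wetted by medium (m^2), flat-bottom cylinder.

    Bottom disc plus the wall up to the fill height medium_volume/(pi r^2).
    1 uL = 1 mm^3, so heights come out in mm and areas in mm^2.
    """
    if well_diameter_mm <= 0:
        raise ValidationError("well diameter must be > 0")
    r = well_diameter_mm / 2.0
    bottom_mm2 = math.pi * r * r
    height_mm = medium_volume_ul / bottom_mm2
    wall_mm2 = math.pi * well_diameter_mm * height_mm
    return (bottom_mm2 + wall_mm2) * 1e-6


@dataclass(frozen=True)
class PhaseVolumes:
    """Volumes (uL) of every phase plus plastic area (m^2)."""

    v_water: float
    v_air: float
    v_albumin: float
    v_serum_lipid: float
    v_other_dom: float
    v_cells: float
    a_plastic_m2: float


def derive_phase_volumes(spec: SystemSpec) -> PhaseVolumes:
    """Resolve a system spec into mass-balance phase volumes.

    Serum constituent volumes follow from the FBS volume fraction and the
    serum composition (g/L over density); they are subtracted from the
    aqueous volume so that medium = water + serum phases.  Cells are treated
    as submerged additions that do not displace the stated medium volume.
    """
    geo = spec.geometry
    v_air = spec.headspace_multiplier * (geo.total_well_volume_ul - spec.medium_volume_ul)

    def serum_volume(g_l: float, density_g_ml: float) -> float:
        # uL serum constituent = uL medium * FBS fraction * (g/L) / (g/mL) / 1000
        return spec.medium_volume_ul * spec.fbs_fraction * g_l / density_g_ml / 1000.0

    v_sa = serum_volume(spec.serum.albumin_g_l, spec.serum.albumin_density_g_ml)
    v_sl = serum_volume(spec.serum.lipid_g_l, spec.serum.lipid_density_g_ml)
    v_ds = serum_volume(spec.serum.other_dom_g_l, spec.serum.other_dom_density_g_ml)
    v_cells = spec.n_cells * spec.cells.volume_per_cell_ul
    v_water = spec.medium_volume_ul - v_sa - v_sl - v_ds
    if v_water <= 0:
        raise ValidationError("serum phases exceed medium volume")
    return PhaseVolumes(
        v_water=v_water,
        v_air=v_air,
        v_albumin=v_sa,
        v_serum_lipid=v_sl,
        v_other_dom=v_ds,
        v_cells=v_cells,
        a_plastic_m2=plastic_area(geo.well_diameter_mm, spec.medium_volume_ul),
    )
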