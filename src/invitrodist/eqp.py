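"""Closed-form equilibrium mass balance over all test-system phases.

The total dose M_T (umol) distributes instantaneously over water, headspace,
serum albumin, serum (storage) lipid, other dissolved organics, cells, and
the plastic vessel wall.  Equal chemical activity across phases means every
phase concentration is its phase-water ratio times the freely-dissolved
concentration C_W, so the balance closes in one division:

    C_W = M_T / (V_W + K_AW*V_A + K_SaW*V_Sa + K_SlW*V_Sl
                 + K_DsW*V_Ds + K_CW*V_C + K_PlW*A_Pl)

with pH-dependent distribution ratios (D) substituted for the partition
ratios (K) when the chemical is ionizable, and the cell term using the
medium/cytosol pH-corrected D_CW.  Units are uM, uL and umol throughout; the
plastic term K_PlW [m^3/m^2] * A_Pl [m^2] is converted to uL (x 1e9) so it
can join the volume sum.

No kinetics, degradation, biotransformation, or cell growth: one closed-form
evaluation per chemical, valid once the system has in fact equilibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .chemistry import ChemicalRecord, ValidationError
from .partitioning import PartitionOptions, PartitionSet, build_partition_set
from .test_system import PhaseVolumes, SystemSpec, derive_phase_volumes

__all__ = [
    "M3_PER_M2_TO_UL",
    "PHASE_NAMES",
    "DistributionResult",
    "plastic_equivalent_volume_ul",
    "solve_eqp",
    "bulk_medium_ratio",
    "simulate",
]

# K_PlW is an area-normalized sorption ratio in m^3 of water-equivalent per
# m^2 of plastic; m^3 -> uL is the single non-obvious unit conversion.
M3_PER_M2_TO_UL = 1e9

PHASE_NAMES = (
    "water",
    "headspace",
    "albumin",
    "serum_lipid",
    "other_dom",
    "cells",
    "plastic",
)


def plastic_equivalent_volume_ul(d_plw_m3_m2: float, area_m2: float) -> float:
    """Sorption capacity of the wetted plastic expressed as uL of water."""
    return d_plw_m3_m2 * area_m2 * M3_PER_M2_TO_UL


@dataclass
class DistributionResult:
    """Equilibrium distribution of one chemical in one test system."""

    chemical_id: str
    nominal_um: float            # C_N,I, initial nominal medium concentration
    total_umol: float            # M_T
    medium_volume_ul: float
    c_water_um: float            # C_W, freely dissolved
    c_cell_um: float             # C_C
    c_membrane_mm: float         # C_MEM, membrane-lipid concentration (mM)
    c_air_um: float
    masses_umol: dict[str, float]        # keyed by PHASE_NAMES
    mass_fractions: dict[str, float]
    free_ratio: float            # C_W / C_N,I
    bulk_ratio: float            # bulk-medium concentration / C_N,I

    def mass_total(self) -> float:
        return sum(self.masses_umol.values())


def solve_eqp(
    chem: ChemicalRecord,
    spec: SystemSpec,
    parts: PartitionSet,
    vols: PhaseVolumes,
) -> DistributionResult:
    """Solve the equilibrium partitioning mass balance for one chemical.

    The dose is the nominal concentration administered in the medium:
    M_T [umol] = C_N,I [uM] * medium volume [uL] * 1e-6.
    """
    if not chem.nominal_um > 0:
        raise ValidationError(f"chemical {chem.id!r}: nominal concentration must be > 0")

    # capacity of each phase expressed as uL of water-equivalent volume
    capacities = {
        "water": vols.v_water,
        "headspace": parts.d_aw * vols.v_air,
        "albumin": parts.d_saw * vols.v_albumin,
        "serum_lipid": parts.d_slw * vols.v_serum_lipid,
        "other_dom": parts.d_dsw * vols.v_other_dom,
        "cells": parts.d_cw_adj * vols.v_cells,
        "plastic": plastic_equivalent_volume_ul(parts.d_plw, vols.a_plastic_m2),
    }
    for phase, cap in capacities.items():
        if not math.isfinite(cap) or cap < 0:
            raise ValidationError(
                f"chemical {chem.id!r}: non-finite or negative capacity for phase {phase!r}"
            )

    m_t = chem.nominal_um * spec.medium_volume_ul * 1e-6  # umol
    denominator = sum(capacities.values())
    c_w = m_t / denominator * 1e6  # uM

    masses = {phase: c_w * cap * 1e-6 for phase, cap in capacities.items()}
    fractions = {phase: m / m_t for phase, m in masses.items()}

    c_cell = parts.d_cw_adj * c_w
    c_mem_mm = parts.d_mw * c_w / 1000.0
    c_air = parts.d_aw * c_w

    medium_mass = (
        masses["water"] + masses["albumin"] + masses["serum_lipid"] + masses["other_dom"]
    )
    bulk = (medium_mass / spec.medium_volume_ul * 1e6) / chem.nominal_um

    return DistributionResult(
        chemical_id=chem.id,
        nominal_um=chem.nominal_um,
        total_umol=m_t,
        medium_volume_ul=spec.medium_volume_ul,
        c_water_um=c_w,
        c_cell_um=c_cell,
        c_membrane_mm=c_mem_mm,
        c_air_um=c_air,
        masses_umol=masses,
        mass_fractions=fractions,
        free_ratio=c_w / chem.nominal_um,
        bulk_ratio=bulk,
    )


def bulk_medium_ratio(result: DistributionResult) -> tuple[float, float]:
    """(bulk-medium / nominal, freely-dissolved / nominal) concentration ratios.

    The bulk-medium concentration counts everything still suspended in the
    medium — water plus the serum phases — but not cells, plastic, or
    headspace; it is what a medium sample sent for chemical analysis would
    contain.
    """
    return result.bulk_ratio, result.free_ratio


def simulate(
    chem: ChemicalRecord,
    spec: SystemSpec,
    options: Optional[PartitionOptions] = None,
) -> tuple[DistributionResult, PartitionSet, PhaseVolumes]:
    """Full pipeline for one chemical: ratios, volumes, mass balance."""
    parts = build_partition_set(chem, spec, options)
    vols = derive_phase_volumes(spec)
    return solve_eqp(chem, spec, parts, vols), parts, vols
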