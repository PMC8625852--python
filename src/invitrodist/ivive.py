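"""In vitro-in vivo extrapolation (IVIVE) dose metrics.

Nominal in vitro effect concentrations (AC50, EC50, IC10) are routinely used
as direct surrogates for blood concentrations in reverse dosimetry, even
though assay media rarely resemble blood.  These metrics quantify the bias:

* DF, the depletion factor, nominal over freely-dissolved concentration —
  how much the bioavailable dose falls short of the administered one;
* EF, the enrichment factor, cell over nominal concentration;
* the equivalent blood concentration, the blood concentration at the same
  chemical activity as the predicted cell concentration,
  C_B = (K_BW/K_CW) * C_C (distribution ratios for ionizable chemicals);
* EF_B = C_B / C_N,I (and EF_P, the plasma analog);
* OED, the oral equivalent dose, an effect concentration divided by a
  toxicokinetic steady-state blood concentration per unit dose (C_SS).
  C_SS is an external input from a TK model and is never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .chemistry import ValidationError
from .eqp import DistributionResult
from .partitioning import PartitionSet

__all__ = [
    "IviveMetrics",
    "depletion_enrichment",
    "eqp_blood",
    "oed",
    "compute_metrics",
]


@dataclass
class IviveMetrics:
    chemical_id: str
    df: float                 # depletion factor, C_N,I / C_W
    ef: float                 # enrichment factor, C_C / C_N,I
    eqp_cb_um: float          # equivalent blood concentration (uM)
    ef_b: float               # EQP_CB / C_N,I
    eqp_cp_um: float          # plasma analog
    ef_p: float
    oed_nominal: Optional[float] = None   # mg/kg/d, from the nominal AC50
    oed_eqp: Optional[float] = None       # mg/kg/d, from the equivalent blood conc.


def depletion_enrichment(result: DistributionResult) -> tuple[float, float]:
    """(DF, EF) for one distribution result.

    DF = C_N,I / C_W; EF = C_C / C_N,I.  A system without cells has no cell
    concentration to enrich; EF is reported as 0 in that degenerate case.
    """
    if not result.c_water_um > 0:
        raise ValidationError("freely-dissolved concentration must be > 0")
    df = result.nominal_um / result.c_water_um
    if result.masses_umol.get("cells", 0.0) == 0.0:
        ef = 0.0
    else:
        ef = result.c_cell_um / result.nominal_um
    return df, ef


def eqp_blood(
    result: DistributionResult, parts: PartitionSet, *, plasma: bool = False
) -> tuple[float, float]:
    """(equivalent blood concentration uM, EF_B) at equal chemical activity.

    EQP_CB = (K_BW / K_CW) * C_C, with D-forms substituted for ionizable
    chemicals; EF_B = EQP_CB / C_N,I.  ``plasma=True`` uses the plasma
    composition instead of whole blood.
    """
    d_ref = parts.d_pl_bw if plasma else parts.d_bw
    if not parts.d_cw_adj > 0:
        raise ValidationError("cell-water ratio must be > 0")
    cb = d_ref / parts.d_cw_adj * result.c_cell_um
    return cb, cb / result.nominal_um


def oed(effect_um: float, c_ss_um_per_mgkgd: float) -> float:
    """Oral equivalent dose (mg/kg/d) by reverse dosimetry.

    OED = effect concentration / C_SS * 1 mg/kg/d, where C_SS is the
    TK-model steady-state blood concentration (uM) at a 1 mg/kg/d oral dose.
    Pass the nominal AC50 for the conventional estimate, or the equivalent
    blood concentration for the distribution-corrected variant.
    """
    if not c_ss_um_per_mgkgd > 0:
        raise ValidationError(f"C_SS must be > 0 (got {c_ss_um_per_mgkgd})")
    return effect_um / c_ss_um_per_mgkgd


def compute_metrics(
    result: DistributionResult,
    parts: PartitionSet,
    c_ss_um_per_mgkgd: Optional[float] = None,
) -> IviveMetrics:
    """All IVIVE metrics for one chemical; OEDs only when C_SS is supplied."""
    df, ef = depletion_enrichment(result)
    cb, ef_b = eqp_blood(result, parts)
    cp, ef_p = eqp_blood(result, parts, plasma=True)
    oed_nom = oed_corr = None
    if c_ss_um_per_mgkgd is not None:
        oed_nom = oed(result.nominal_um, c_ss_um_per_mgkgd)
        oed_corr = oed(cb, c_ss_um_per_mgkgd)
    return IviveMetrics(
        chemical_id=result.chemical_id,
        df=df,
        ef=ef,
        eqp_cb_um=cb,
        ef_b=ef_b,
        eqp_cp_um=cp,
        ef_p=ef_p,
        oed_nominal=oed_nom,
        oed_eqp=oed_corr,
    )
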