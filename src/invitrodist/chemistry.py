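"""Chemical data model, acid/base speciation, and condition adjustment.

A chemical is described by its minimal physical-chemical inputs: molecular
weight, melting point, ionization class (neutral, monoprotic acid or base)
with its pKa, the octanol-water and air-water partition ratios of the
neutral species at 25 degC, water solubility, and a nominal effect
concentration (e.g. an AC50 or EC50 on a medium basis, in uM).  Empirical
biopartitioning ratios (membrane-water, serum-albumin-water) may be supplied
either as single-species partition ratios (K, neutral form) or as
pH-dependent distribution ratios (D) measured at assay pH; D values are used
verbatim and never re-speciated.

Multiprotic chemicals must be entered with a single effective pKa — the
smallest acidic or the largest basic one — because speciation here considers
only the strongest ionizable group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "IonClass",
    "ChemicalRecord",
    "neutral_fraction",
    "adjust_to_conditions",
    "DEFAULT_DU_AW_KJ",
    "DEFAULT_DU_OW_KJ",
    "DEFAULT_SETSCHENOW",
]

R_GAS = 8.314  # J/mol/K
T_REF_K = 298.15

# Default internal energies of phase transfer (kJ/mol) for the van't Hoff
# temperature correction, and the Setschenow salting-out constant (L/mol).
# Representative literature magnitudes; override per chemical or per call.
DEFAULT_DU_AW_KJ = 60.0
DEFAULT_DU_OW_KJ = -20.0
DEFAULT_SETSCHENOW = 0.3


class IonClass(str, Enum):
    NEUTRAL = "neutral"
    ACID = "acid"
    BASE = "base"


class ValidationError(ValueError):
    """Raised when a chemical or system input violates its contract."""


@dataclass
class ChemicalRecord:
    """One chemical and its partitioning inputs.

    Required: ``id``, ``mw`` (g/mol), ``ion_class``, ``log_kow_n``,
    ``log_kaw_n`` (25 degC, neutral form), ``sw_mg_l`` (water solubility),
    ``nominal_um`` (effect concentration in the medium, uM).  ``pka`` is
    required for acids and bases.  Melting point ``mp_c`` only annotates
    solid-vs-liquid state on outputs; it does not enter the mass balance.
    """

    id: str
    mw: float
    ion_class: IonClass = IonClass.NEUTRAL
    name: str = ""
    mp_c: Optional[float] = None
    pka: Optional[float] = None
    log_kow_n: float = 0.0
    log_kaw_n: float = -10.0
    sw_mg_l: float = 1000.0
    nominal_um: float = 1.0
    # empirical biopartitioning (optional); K = neutral species, D = at assay pH
    log_kmw_n: Optional[float] = None
    log_dmw: Optional[float] = None
    log_ksaw_n: Optional[float] = None
    log_dsaw: Optional[float] = None
    # internal energies of phase transfer for temperature correction (kJ/mol)
    du_aw_kj: Optional[float] = None
    du_ow_kj: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.ion_class, str) and not isinstance(self.ion_class, IonClass):
            self.ion_class = IonClass(self.ion_class)
        self.validate()

    def validate(self) -> None:
        if self.mw is None or not self.mw > 0:
            raise ValidationError(f"chemical {self.id!r}: MW must be > 0 (got {self.mw})")
        if self.sw_mg_l is None or not self.sw_mg_l > 0:
            raise ValidationError(
                f"chemical {self.id!r}: water solubility must be > 0 (got {self.sw_mg_l})"
            )
        if self.ion_class is not IonClass.NEUTRAL:
            if self.pka is None:
                raise ValidationError(
                    f"chemical {self.id!r}: pKa is required for ion_class={self.ion_class.value}"
                )
            if not -5.0 <= self.pka <= 15.0:
                raise ValidationError(
                    f"chemical {self.id!r}: pKa {self.pka} outside [-5, 15]"
                )

    @property
    def is_ioc(self) -> bool:
        return self.ion_class is not IonClass.NEUTRAL

    def solubility_um(self) -> float:
        """Water solubility converted from mg/L to uM."""
        return self.sw_mg_l * 1000.0 / self.mw

    def is_solid_at(self, t_c: float) -> Optional[bool]:
        """Solid/liquid annotation from melting point; None if MP unknown."""
        if self.mp_c is None:
            return None
        return self.mp_c > t_c


def neutral_fraction(ion_class: IonClass | str, pka: Optional[float], ph: float) -> float:
    """Fraction of the chemical present as the neutral species at ``ph``.

    Henderson-Hasselbalch speciation for a monoprotic acid or base:
    acids  f_N = 1/(1+10^(pH-pKa)); bases f_N = 1/(1+10^(pKa-pH)).
    """
    ion_class = IonClass(ion_class)
    if not 0.0 <= ph <= 14.0:
        raise ValidationError(f"pH {ph} outside [0, 14]")
    if ion_class is IonClass.NEUTRAL:
        return 1.0
    if pka is None:
        raise ValidationError(f"pKa required for ion_class={ion_class.value}")
    if ion_class is IonClass.ACID:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def vant_hoff_delta(du_kj_mol: float, t_c: float) -> float:
    """Change in a log10 partition ratio from 25 degC to ``t_c``.

    log K(T) = log K(25) - (dU / (ln10 * R)) * (1/T - 1/298.15).
    """
    t_k = t_c + 273.15
    return -(du_kj_mol * 1000.0 / (math.log(10.0) * R_GAS)) * (1.0 / t_k - 1.0 / T_REF_K)


@dataclass(frozen=True)
class AdjustedProperties:
    """Partitioning inputs adjusted to system temperature and ionic strength."""

    log_kow_n: float
    log_kaw_n: float
    # additive log10 salting-out term applied to neutral-form phase-water ratios
    log_salting: float
    t_c: float
    ionic_strength: float


def adjust_to_conditions(
    record: ChemicalRecord,
    t_c: float = 25.0,
    ionic_strength: float = 0.0,
    *,
    du_aw_kj: Optional[float] = None,
    du_ow_kj: Optional[float] = None,
    setschenow: float = DEFAULT_SETSCHENOW,
) -> AdjustedProperties:
    """van't Hoff temperature correction plus Setschenow salting-out.

    The record's own internal energies take precedence over the call-site
    overrides, which in turn shadow the module defaults.  Salting-out scales
    the aqueous activity of the neutral species only, so every neutral-form
    phase-water ratio gains the same additive log10 term Ks*I; charged-form
    ratios are left unadjusted.
    """
    if not 0.0 <= t_c <= 50.0:
        raise ValidationError(f"temperature {t_c} degC outside [0, 50]")
    if ionic_strength < 0.0:
        raise ValidationError(f"ionic strength must be >= 0 (got {ionic_strength})")
    du_aw = record.du_aw_kj if record.du_aw_kj is not None else (
        du_aw_kj if du_aw_kj is not None else DEFAULT_DU_AW_KJ
    )
    du_ow = record.du_ow_kj if record.du_ow_kj is not None else (
        du_ow_kj if du_ow_kj is not None else DEFAULT_DU_OW_KJ
    )
    return AdjustedProperties(
        log_kow_n=record.log_kow_n + vant_hoff_delta(du_ow, t_c),
        log_kaw_n=record.log_kaw_n + vant_hoff_delta(du_aw, t_c),
        log_salting=setschenow * ionic_strength,
        t_c=t_c,
        ionic_strength=ionic_strength,
    )
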