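"""QA/QC flags on a predicted distribution.

Three screens mirror the checks a reviewer applies to nominal-dose in vitro
results: a volatility issue (most of the dose ends up in headspace), a
solubility issue (the freely-dissolved concentration still exceeds water
solubility after redistribution, so pure-phase chemical is expected in the
well), and a baseline-toxicity classification of the predicted membrane
concentration against the 20-60 mM narcosis range ("cytotoxic burst").

Tie-breaks the thresholds leave open are fixed here, once: both issue flags
use strict inequalities, and the baseline range is the closed interval
[20, 60] mM.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .chemistry import ChemicalRecord, ValidationError
from .eqp import DistributionResult

__all__ = [
    "VOLATILITY_MASS_FRACTION",
    "BASELINE_LOW_MM",
    "BASELINE_HIGH_MM",
    "BaselineClass",
    "QaqcFlags",
    "flag_volatility",
    "flag_solubility",
    "classify_baseline",
    "evaluate_flags",
    "batch_counts",
]

VOLATILITY_MASS_FRACTION = 2.0 / 3.0
BASELINE_LOW_MM = 20.0
BASELINE_HIGH_MM = 60.0


class BaselineClass(str, Enum):
    BELOW = "below_20mM"
    RANGE = "range_20_60mM"
    ABOVE = "above_60mM"


@dataclass(frozen=True)
class QaqcFlags:
    chemical_id: str
    volatility_issue: bool
    solubility_issue: bool
    baseline_class: BaselineClass
    solid_at_t: Optional[bool]  # melting-point annotation; None if MP unknown


def flag_volatility(result: DistributionResult) -> bool:
    """True iff more than 2/3 of the chemical mass sits in the headspace."""
    return result.mass_fractions["headspace"] > VOLATILITY_MASS_FRACTION


def flag_solubility(result: DistributionResult, sw_mg_l: float, mw: float) -> bool:
    """True iff C_W exceeds water solubility after distribution (uM basis)."""
    if not (sw_mg_l > 0 and mw > 0):
        raise ValidationError("water solubility and MW must be > 0")
    return result.c_water_um > sw_mg_l * 1000.0 / mw


def classify_baseline(c_mem_mm: float) -> BaselineClass:
    """Place a membrane concentration against the 20-60 mM baseline range."""
    if c_mem_mm < 0:
        raise ValidationError("membrane concentration must be >= 0")
    if c_mem_mm < BASELINE_LOW_MM:
        return BaselineClass.BELOW
    if c_mem_mm <= BASELINE_HIGH_MM:
        return BaselineClass.RANGE
    return BaselineClass.ABOVE


def evaluate_flags(
    chem: ChemicalRecord, result: DistributionResult, temperature_c: float = 37.0
) -> QaqcFlags:
    return QaqcFlags(
        chemical_id=chem.id,
        volatility_issue=flag_volatility(result),
        solubility_issue=flag_solubility(result, chem.sw_mg_l, chem.mw),
        baseline_class=classify_baseline(result.c_membrane_mm),
        solid_at_t=chem.is_solid_at(temperature_c),
    )


def batch_counts(flags: Iterable[QaqcFlags]) -> dict[str, int]:
    """Tabulated flag frequencies over a batch (pure aggregation of rows)."""
    flags = list(flags)
    return {
        "n_total": len(flags),
        "n_volatility_issue": sum(f.volatility_issue for f in flags),
        "n_solubility_issue": sum(f.solubility_issue for f in flags),
        "n_cmem_above_20mM": sum(
            f.baseline_class in (BaselineClass.RANGE, BaselineClass.ABOVE) for f in flags
        ),
        "n_cmem_above_60mM": sum(f.baseline_class is BaselineClass.ABOVE for f in flags),
    }
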