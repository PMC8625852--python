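"""Model-performance statistics and the scenario-comparison harness.

Predicted-vs-measured concentration ratios (e.g. the fraction of the
nominal dose remaining freely dissolved or in bulk medium after exposure)
are compared on a log10 scale:

    MB  = mean(log10(P/O))        model bias
    MAE = mean(|log10(P/O)|)      mean absolute error

both also expressed as Factors of Agreement, FoA = 10^MB and 10^MAE, i.e.
the geometric-mean fold error.  r^2 is the ordinary coefficient of
determination, by default on the log10-transformed ratios because observed
ratios span orders of magnitude (linear-space r^2 is available as an
option).

``scenario_sweep`` re-runs a dataset under a grid of headspace-multiplier x
plastic-model assumptions, separately for volatile and non-volatile subsets
(split at log K_AW or log D_AW = -4.0), and reports one statistics row per
cell.  The external datasets this harness was designed around live in other
publications' supporting information; the repository itself only carries
synthetic fixtures that exercise the machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chemistry import ChemicalRecord, ValidationError
from .eqp import simulate
from .partitioning import PartitionOptions
from .test_system import SystemSpec

__all__ = [
    "VOLATILE_LOG_KAW_CUTOFF",
    "EvalStats",
    "model_stats",
    "scenario_sweep",
]

# chemicals with log K_AW (or log D_AW) below this are "non-volatiles"
VOLATILE_LOG_KAW_CUTOFF = -4.0


@dataclass(frozen=True)
class EvalStats:
    n: int
    mb: float          # log10 units
    mae: float         # log10 units
    foa_mb: float      # 10**MB
    foa_mae: float     # 10**MAE
    r2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "MB": self.mb,
            "MAE": self.mae,
            "FoA_MB": self.foa_mb,
            "FoA_MAE": self.foa_mae,
            "r2": self.r2,
        }


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of y against x (identity-model residuals
    are not used; this is the squared Pearson correlation, the standard way
    scatter agreement is summarized for these comparisons)."""
    if len(x) < 2 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def model_stats(
    predicted: Sequence[float],
    observed: Sequence[float],
    *,
    log_space_r2: bool = True,
) -> EvalStats:
    """MB, MAE, Factors of Agreement and r^2 for paired positive ratios."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) < 2:
        raise ValidationError("predicted and observed must be equal-length 1-d, n >= 2")
    bad = np.where(~((p > 0) & (o > 0)))[0]
    if bad.size:
        raise ValidationError(f"nonpositive ratio at row(s) {bad.tolist()}")
    log_ratio = np.log10(p / o)
    mb = float(np.mean(log_ratio))
    mae = float(np.mean(np.abs(log_ratio)))
    if log_space_r2:
        r2 = _r_squared(np.log10(o), np.log10(p))
    else:
        r2 = _r_squared(o, p)
    return EvalStats(n=len(p), mb=mb, mae=mae, foa_mb=10.0**mb, foa_mae=10.0**mae, r2=r2)


def _predict_ratio(
    chem: ChemicalRecord, spec: SystemSpec, options: PartitionOptions, ratio_type: str
) -> tuple[float, float]:
    """(predicted ratio, log D_AW at medium pH) for one chemical/scenario."""
    result, parts, _ = simulate(chem, spec, options)
    if ratio_type == "bulk":
        ratio = result.bulk_ratio
    elif ratio_type == "free":
        ratio = result.free_ratio
    else:
        raise ValidationError(f"unknown ratio type {ratio_type!r}; use 'free' or 'bulk'")
    log_daw = math.log10(parts.d_aw) if parts.d_aw > 0 else -math.inf
    return ratio, log_daw


def scenario_sweep(
    dataset: pd.DataFrame,
    spec: SystemSpec,
    *,
    hs_multipliers: Sequence[float] = (1.0, 10.0, 50.0, 100.0),
    plastic_models: Sequence[str] = ("kramer", "fischer"),
    options: Optional[PartitionOptions] = None,
    log_space_r2: bool = True,
) -> pd.DataFrame:
    """Statistics grid over headspace and plastic-sorption assumptions.

    ``dataset`` needs the chemical CSV columns (see :mod:`invitrodist.io`)
    plus ``observed_ratio`` and ``ratio_type`` ('free' or 'bulk').  Rows
    with a missing observed ratio are skipped and counted.  Output is one
    row per (subset, HS multiplier, plastic model) with the EvalStats
    columns, subsets being 'all', 'non_volatile' and 'volatile' split at
    log K_AW/D_AW = -4.0.
    """
    from .io import record_from_row  # local import to avoid a cycle

    base_options = options if options is not None else PartitionOptions()
    rows: list[dict] = []
    n_skipped = int(dataset["observed_ratio"].isna().sum())
    usable = dataset[dataset["observed_ratio"].notna()]
    for hs in hs_multipliers:
        scenario_spec = replace(spec, headspace_multiplier=float(hs))
        for model in plastic_models:
            scenario_options = replace(base_options, plastic_model=model)
            preds, obs, volatile = [], [], []
            for _, row in usable.iterrows():
                chem = record_from_row(row)
                ratio_type = str(row.get("ratio_type", "bulk"))
                pred, log_daw = _predict_ratio(chem, scenario_spec, scenario_options, ratio_type)
                preds.append(pred)
                obs.append(float(row["observed_ratio"]))
                volatile.append(log_daw >= VOLATILE_LOG_KAW_CUTOFF)
            preds_a, obs_a = np.asarray(preds), np.asarray(obs)
            vol_a = np.asarray(volatile, dtype=bool)
            subsets = {
                "all": np.ones(len(preds_a), dtype=bool),
                "non_volatile": ~vol_a,
                "volatile": vol_a,
            }
            for name, mask in subsets.items():
                if mask.sum() < 2:
                    continue
                stats = model_stats(
                    preds_a[mask], obs_a[mask], log_space_r2=log_space_r2
                )
                rows.append(
                    {
                        "subset": name,
                        "hs_multiplier": hs,
                        "plastic_model": model,
                        "n_skipped": n_skipped,
                        **stats.as_dict(),
                    }
                )
    return pd.DataFrame(rows)
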