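"""Batch I/O: chemical tables, system configs, and the six output sheets.

Chemical CSV schema (one row per chemical; optional cells left empty, never
zero-filled):

    id, name, mw_g_mol, mp_c, ion_class, pka, logkow_n, logkaw_n, sw_mg_l,
    nominal_um, log_kmw, log_dmw, log_ksaw, log_dsaw, du_aw_kj, du_ow_kj

System specs load from YAML; any scalar there overrides the named preset's
default.  A batch run writes six CSVs mirroring the model's output sheets:
concentrations in all phases, mass fractions, masses, IVIVE metrics,
partitioning data adjusted to system conditions, and the QA/QC summary,
plus a run log recording every default that filled a missing input and
every row that failed validation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .chemistry import ChemicalRecord, ValidationError
from .eqp import PHASE_NAMES, simulate
from .ivive import compute_metrics
from .partitioning import PartitionOptions
from .qaqc import batch_counts, evaluate_flags
from .test_system import SerumComposition, SystemSpec

__all__ = [
    "CHEMICAL_COLUMNS",
    "RunConfig",
    "record_from_row",
    "read_chemicals_csv",
    "write_chemicals_csv",
    "load_system_yaml",
    "run_batch",
]

CHEMICAL_COLUMNS = [
    "id",
    "name",
    "mw_g_mol",
    "mp_c",
    "ion_class",
    "pka",
    "logkow_n",
    "logkaw_n",
    "sw_mg_l",
    "nominal_um",
    "log_kmw",
    "log_dmw",
    "log_ksaw",
    "log_dsaw",
    "du_aw_kj",
    "du_ow_kj",
]

_OPTIONAL_FLOATS = {
    "mp_c": "mp_c",
    "pka": "pka",
    "log_kmw": "log_kmw_n",
    "log_dmw": "log_dmw",
    "log_ksaw": "log_ksaw_n",
    "log_dsaw": "log_dsaw",
    "du_aw_kj": "du_aw_kj",
    "du_ow_kj": "du_ow_kj",
}


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    value = float(value)
    return None if math.isnan(value) else value


def record_from_row(row) -> ChemicalRecord:
    """Build a ChemicalRecord from one chemical-CSV row (Series or mapping)."""
    get = row.get if hasattr(row, "get") else lambda k, d=None: row[k] if k in row else d
    kwargs = {
        "id": str(get("id")),
        "name": str(get("name", "") or ""),
        "mw": float(get("mw_g_mol")),
        "ion_class": str(get("ion_class", "neutral") or "neutral"),
        "log_kow_n": float(get("logkow_n")),
        "log_kaw_n": float(get("logkaw_n")),
        "sw_mg_l": float(get("sw_mg_l")),
        "nominal_um": float(get("nominal_um")),
    }
    for col, attr in _OPTIONAL_FLOATS.items():
        kwargs[attr] = _opt(get(col))
    return ChemicalRecord(**kwargs)


def read_chemicals_csv(path: str | Path) -> list[ChemicalRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"id", "mw_g_mol", "logkow_n", "logkaw_n", "sw_mg_l", "nominal_um"} - set(
        df.columns
    )
    if missing:
        raise ValidationError(f"chemical CSV missing columns: {sorted(missing)}")
    return [record_from_row(row) for _, row in df.iterrows()]


def write_chemicals_csv(records: list[ChemicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "name": r.name,
                "mw_g_mol": r.mw,
                "mp_c": r.mp_c,
                "ion_class": r.ion_class.value,
                "pka": r.pka,
                "logkow_n": r.log_kow_n,
                "logkaw_n": r.log_kaw_n,
                "sw_mg_l": r.sw_mg_l,
                "nominal_um": r.nominal_um,
                "log_kmw": r.log_kmw_n,
                "log_dmw": r.log_dmw,
                "log_ksaw": r.log_ksaw_n,
                "log_dsaw": r.log_dsaw,
                "du_aw_kj": r.du_aw_kj,
                "du_ow_kj": r.du_ow_kj,
            }
        )
    pd.DataFrame(rows, columns=CHEMICAL_COLUMNS).to_csv(path, index=False)


def load_system_yaml(path: str | Path) -> SystemSpec:
    """SystemSpec from YAML; a nested ``serum`` mapping overrides that table."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    serum_raw = raw.pop("serum", None)
    if serum_raw is not None:
        raw["serum"] = SerumComposition(**serum_raw)
    cell_comp = raw.pop("cell_composition", None)
    if cell_comp is not None:
        from .test_system import CellComposition, CellParams

        vpc = raw.pop("volume_per_cell_ul", 2.5e-6)
        raw["cell_params"] = CellParams(vpc, CellComposition(**cell_comp))
    return SystemSpec(**raw)


@dataclass
class RunConfig:
    """Everything one batch run needs."""

    chemicals_csv: str | Path
    system: SystemSpec = field(default_factory=SystemSpec)
    options: PartitionOptions = field(default_factory=PartitionOptions)
    output_dir: str | Path = "outputs"
    c_ss_um_per_mgkgd: Optional[float] = None


def run_batch(config: RunConfig) -> dict[str, Path]:
    """Run every chemical in the table and write the six output sheets.

    Per-row validation failures are collected into the run log; the run
    continues for the remaining rows.  Returns the written file paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(config.chemicals_csv)

    conc_rows, frac_rows, mass_rows, ivive_rows, part_rows, qaqc_rows = [], [], [], [], [], []
    flags = []
    log_lines = [
        f"system: {config.system}",
        f"options: plastic_model={config.options.plastic_model} "
        f"anionic_phospholipids={config.options.anionic_phospholipids} "
        f"lysosomal_trapping={config.options.lysosomal_trapping}",
    ]
    for _, row in df.iterrows():
        try:
            chem = record_from_row(row)
            result, parts, _ = simulate(chem, config.system, config.options)
        except (ValidationError, ValueError, KeyError, TypeError) as exc:
            log_lines.append(f"SKIPPED row id={row.get('id', '?')}: {exc}")
            continue
        conc_rows.append(
            {
                "id": chem.id,
                "nominal_um": chem.nominal_um,
                "c_water_um": result.c_water_um,
                "c_cell_um": result.c_cell_um,
                "c_membrane_mm": result.c_membrane_mm,
                "c_air_um": result.c_air_um,
                "free_ratio": result.free_ratio,
                "bulk_ratio": result.bulk_ratio,
            }
        )
        frac_rows.append({"id": chem.id, **result.mass_fractions})
        mass_rows.append(
            {"id": chem.id, "total_umol": result.total_umol, **result.masses_umol}
        )
        metrics = compute_metrics(result, parts, config.c_ss_um_per_mgkgd)
        ivive_rows.append(
            {
                "id": chem.id,
                "DF": metrics.df,
                "EF": metrics.ef,
                "EQP_CB_um": metrics.eqp_cb_um,
                "EF_B": metrics.ef_b,
                "EF_P": metrics.ef_p,
                "OED_nominal": metrics.oed_nominal,
                "OED_eqp": metrics.oed_eqp,
            }
        )
        part_rows.append({"id": chem.id, **parts.as_dict()})
        flag = evaluate_flags(chem, result, config.system.temperature_c)
        flags.append(flag)
        qaqc_rows.append(
            {
                "id": chem.id,
                "volatility_issue": flag.volatility_issue,
                "solubility_issue": flag.solubility_issue,
                "baseline_class": flag.baseline_class.value,
                "solid_at_t": flag.solid_at_t,
            }
        )
    log_lines.append(
        "defaults: spLFER biopartitioning used wherever empirical log K/D was empty; "
        "module default internal energies used wherever du_aw_kj/du_ow_kj was empty"
    )
    log_lines.append(f"rows run: {len(conc_rows)} of {len(df)}")

    sheets = {
        "concentrations": pd.DataFrame(conc_rows),
        "mass_fractions": pd.DataFrame(frac_rows),
        "masses": pd.DataFrame(mass_rows),
        "ivive": pd.DataFrame(ivive_rows),
        "adjusted_partitioning": pd.DataFrame(part_rows),
        "qaqc": pd.DataFrame(qaqc_rows),
    }
    paths: dict[str, Path] = {}
    for name, sheet in sheets.items():
        path = out / f"{name}.csv"
        sheet.to_csv(path, index=False)
        paths[name] = path
    counts = batch_counts(flags)
    with open(out / "qaqc_counts.csv", "w") as fh:
        fh.write(",".join(counts) + "\n")
        fh.write(",".join(str(v) for v in counts.values()) + "\n")
    paths["qaqc_counts"] = out / "qaqc_counts.csv"
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["log"] = out / "run.log"
    return paths
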