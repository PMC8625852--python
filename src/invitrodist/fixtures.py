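"""Synthetic chemical panels and deterministic worked-case fixtures.

Real evaluation datasets for this kind of model live in the supporting
information of the experimental papers and are not redistributed here.
The generator instead produces (a) seeded random panels spanning the
property space the model is meant to cover — log K_OW,N from -4 to 8,
log K_AW,N from -14 to 0.5, neutral/acid/base ionization with pKa in
[2, 11] — and (b) a fixed set of hand-parameterized worked cases that pin
down limiting behaviors: a water-only inert tracer, an albumin-binder, a
naproxen-like ionizable acid with empirical biopartitioning ratios, a
volatile solvent-like chemical, and a supersaturating hydrophobe.

Everything is a function of the seed; the same seed gives byte-identical
CSVs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .chemistry import ChemicalRecord, IonClass
from .io import write_chemicals_csv

__all__ = [
    "LOGKOW_RANGE",
    "LOGKAW_RANGE",
    "PKA_RANGE",
    "random_panel",
    "worked_cases",
    "naproxen_like",
    "generate_fixtures",
]

LOGKOW_RANGE = (-4.0, 8.0)
LOGKAW_RANGE = (-14.0, 0.5)
PKA_RANGE = (2.0, 11.0)


def random_panel(
    seed: int,
    n: int,
    *,
    ion_classes: tuple[str, ...] = ("neutral", "acid", "base"),
) -> list[ChemicalRecord]:
    """Seeded random chemical panel spanning the declared property ranges."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        ion = ion_classes[int(rng.integers(len(ion_classes)))]
        log_kow = float(rng.uniform(*LOGKOW_RANGE))
        records.append(
            ChemicalRecord(
                id=f"syn{i:04d}",
                name=f"synthetic-{i}",
                mw=float(rng.uniform(80.0, 600.0)),
                mp_c=float(rng.uniform(-50.0, 250.0)),
                ion_class=IonClass(ion),
                pka=float(rng.uniform(*PKA_RANGE)) if ion != "neutral" else None,
                log_kow_n=log_kow,
                log_kaw_n=float(rng.uniform(*LOGKAW_RANGE)),
                # solubility loosely anti-correlated with hydrophobicity
                sw_mg_l=float(10.0 ** rng.uniform(3.0 - 0.5 * log_kow, 5.0 - 0.5 * log_kow)),
                nominal_um=float(10.0 ** rng.uniform(-1.0, 2.0)),
            )
        )
    return records


def naproxen_like() -> ChemicalRecord:
    """Ionizable acid with empirical membrane and albumin distribution ratios.

    Physical-chemical inputs are public literature values for naproxen;
    the empirical log D_MW = 2.17 and log D_SaW = 5.21 are measured at
    assay pH and are used verbatim by the partitioning layer.
    """
    return ChemicalRecord(
        id="naproxen_like",
        name="naproxen-like acid",
        mw=230.26,
        mp_c=153.0,
        ion_class=IonClass.ACID,
        pka=4.15,
        log_kow_n=3.18,
        log_kaw_n=-6.34,
        sw_mg_l=15.9,
        nominal_um=10.0,
        log_dmw=2.17,
        log_dsaw=5.21,
    )


def worked_cases() -> list[ChemicalRecord]:
    """Deterministic fixtures pinning down the model's limiting behaviors."""
    return [
        # inert hydrophilic tracer: nothing to sorb to, stays freely dissolved
        ChemicalRecord(
            id="water_only",
            name="inert tracer",
            mw=100.0,
            ion_class=IonClass.NEUTRAL,
            log_kow_n=-2.0,
            log_kaw_n=-12.0,
            sw_mg_l=1.0e5,
            nominal_um=10.0,
        ),
        # strong albumin binder, negligible volatility/plastic sorption
        ChemicalRecord(
            id="albumin_binder",
            name="albumin binder",
            mw=300.0,
            ion_class=IonClass.NEUTRAL,
            log_kow_n=1.0,
            log_kaw_n=-10.0,
            sw_mg_l=1.0e4,
            nominal_um=10.0,
            log_dsaw=5.21,
        ),
        naproxen_like(),
        # volatile, escapes to headspace
        ChemicalRecord(
            id="volatile",
            name="volatile solvent-like",
            mw=120.0,
            ion_class=IonClass.NEUTRAL,
            log_kow_n=2.5,
            log_kaw_n=-0.5,
            sw_mg_l=500.0,
            nominal_um=50.0,
        ),
        # hydrophobe dosed far above its water solubility
        ChemicalRecord(
            id="supersaturating",
            name="supersaturating hydrophobe",
            mw=390.0,
            mp_c=34.0,
            ion_class=IonClass.NEUTRAL,
            log_kow_n=6.5,
            log_kaw_n=-2.0,
            sw_mg_l=0.006,
            nominal_um=23.0,  # ~9 mg/L administered, >>  solubility
        ),
    ]


_SYSTEM_YAMLS = {
    "system_96well_fbs10.yaml": {
        "plate_format": 96,
        "medium_volume_ul": 100.0,
        "fbs_fraction": 0.10,
        "temperature_c": 37.0,
    },
    "system_96well_fbs2.yaml": {
        "plate_format": 96,
        "medium_volume_ul": 100.0,
        "fbs_fraction": 0.02,
        "temperature_c": 37.0,
    },
    "system_24well_serum_free.yaml": {
        "plate_format": 24,
        "medium_volume_ul": 1000.0,
        "fbs_fraction": 0.0,
        "temperature_c": 19.0,
        "cell_count": 2.0e5,
    },
}


def generate_fixtures(seed: int, n: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture file set: worked cases, a random panel, system YAMLs.

    ``n`` is the random-panel size; ``n = 0`` writes the worked cases only.
    Deterministic in ``seed``: identical seeds give byte-identical files.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cases_path = out / "worked_cases.csv"
    write_chemicals_csv(worked_cases(), cases_path)
    paths["worked_cases"] = cases_path

    if n > 0:
        panel_path = out / "random_panel.csv"
        write_chemicals_csv(random_panel(seed, n), panel_path)
        paths["random_panel"] = panel_path

    for name, payload in _SYSTEM_YAMLS.items():
        path = out / name
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        paths[name] = path
    return paths
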