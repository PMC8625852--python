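# Methods

## Model formulation

The package solves a closed-form equilibrium-partitioning (EQP) mass balance
for one chemical in one in vitro test system. Seven phases are carried:
medium water, headspace air, serum albumin, serum (storage) lipid, other
dissolved organic matter, cells, and the plastic vessel wall. Equal chemical
activity across phases means every phase concentration is a phase-water
ratio times the freely-dissolved concentration C_W, so

    C_W = M_T / Σ_i (K_iW · V_i)

with the water term being V_W itself and the plastic term an area (m²)
times an area-normalized sorption ratio (m³/m²), converted to µL by the
factor 1e9. The dose is M_T = C_N,I · V_medium · 1e-6 µmol: the nominal
concentration is defined in the medium as administered, not over the whole
well. All other concentrations, masses and mass fractions follow by
multiplication; no iteration is needed and the computation is exact to
floating-point.

Assumptions inherited from the EQP premise: instantaneous equilibrium,
single dose, no degradation or biotransformation, no cell growth, no
re-dissolution of precipitated chemical. Measurements on neutral organics
suggest equilibrium is approached within ~24 h, so short-duration tests and
slowly-permeating charged species are the main applicability-domain
caveats.

## Speciation and ionizable chemicals

Monoprotic acids and bases are speciated by Henderson–Hasselbalch:
f_N = 1/(1+10^(pH−pKa)) for acids and 1/(1+10^(pKa−pH)) for bases.
Multiprotic chemicals must be entered with one effective pKa (smallest
acidic or largest basic); only the strongest group is considered.

Each phase gets a distribution ratio D = f_N·K_N + (1−f_N)·K_I. Charged-form
ratios default to the neutral-form ratio scaled down by per-phase log-unit
offsets (membrane 1.0, albumin 0.7, storage lipid 2.0, bulk protein 1.0,
plastic 2.0); the charged form is treated as non-volatile (K_AW,I = 0).
These offsets are configurable; they encode the qualitative observation
that ions sorb much less to apolar phases, and are the weakest-constrained
numbers in the model.

The cell-water ratio is assembled at cytosol pH and then corrected for the
medium/cytosol pH difference: ×10^(pH_cell−pH_bulk) for acids,
×10^(pH_bulk−pH_cell) for bases (0.398-fold and 2.512-fold respectively for
medium pH 7.4 over cytosol pH 7.0). The optional lysosomal ion-trapping
increment for bases — the lysosome volume fraction times the total-species
accumulation ratio (1+10^(pKa−pH_lys))/(1+10^(pKa−pH_cyt)) — is added
*after* the pH correction; the order is a documented convention (the
increment is an additive aqueous-subcompartment term and should not be
re-scaled by the bulk/cytosol correction). Both the lysosome option and the
anionic-phospholipid option (10 % of membrane lipid anionic; charged-species
sorption to it enhanced 10× for cations, suppressed 20× for anions) are off
by default: they are preliminary, qualitative treatments.

## Partition-ratio estimation

Neutral-form ratios come from single-parameter LFERs on log K_OW,N, kept in
one editable table:

| phase | slope | intercept |
|---|---|---|
| membrane lipid | 1.01 | 0.12 |
| serum albumin | 0.71 | 0.42 |
| storage lipid | 1.00 | 0.00 |
| bulk protein | 0.74 | −0.44 |
| other dissolved organics | 0.71 | 0.42 |

Plastic-water sorption offers two published spLFERs — 0.97·logK_OW − 6.94
and 0.56·logK_OW − 4.64, both m³/m² — selectable per run, plus a user-coefficient
variant. The two differ most below log K_OW 2–4 and above 7.5, which is
where the choice can matter for serum-free systems.

Empirical biopartitioning inputs always take precedence over spLFER
estimates. Two forms are accepted: neutral-form K values (log_kmw, log_ksaw),
which enter the normal speciation path, and distribution ratios measured at
assay pH (log_dmw, log_dsaw), which are used verbatim and never
re-speciated — appropriate when the measurement already integrates the
speciation state.

Temperature is handled by van't Hoff correction of log K_OW and log K_AW
from 25 °C using internal energies of phase transfer (defaults
ΔU_AW = +60 kJ/mol, ΔU_OW = −20 kJ/mol — representative literature
magnitudes, per-chemical overridable; +60 kJ/mol gives +0.407 log units on
K_AW from 25→37 °C). Ionic strength applies a Setschenow term
10^(K_s·I), K_s = 0.3 L/mol, to neutral-form ratios only. Empirical K/D
inputs are assumed measured at assay conditions and are not re-adjusted.

## System parameterization

Plate geometry defaults (total well volume / diameter) cover 6–1536-well
formats with vendor-typical values; any geometry can be supplied explicitly.
The wetted plastic area is a flat-bottomed cylinder: bottom disc plus wall
up to the fill height.

Headspace is the total well volume minus the medium volume, times a
headspace multiplier ≥ 1. The minimum (multiplier 1) models a perfectly
sealed well; larger values are a deliberate proxy for gas exchange,
leakage, and sorption to adhesive covers, and the evaluation harness sweeps
multipliers {1, 10, 50, 100} because the appropriate value is
exposure-duration- and seal-dependent, not a property of the chemical.

Serum phases scale linearly with the FBS volume fraction. The default serum
composition is albumin 25 g/L, total lipid 2 g/L (assigned to the
storage-lipid phase), other dissolved organics 12 g/L, with densities
1.36 / 0.9 / 1.36 g/mL. These are representative bovine-serum values chosen
once as the package's reference serum — the albumin content sits inside the
reported 20–36 g/L span for FBS and reproduces the naproxen worked case
below — and every number is overridable per run. Serum constituent volumes
are subtracted from the aqueous volume (medium = water + serum phases), a
convention that only matters at high FBS; cells are booked as submerged
additions that do not displace medium.

Cell-line presets (generic, MCF7, HCT116, HEK293T, HepG2) carry
volume-per-cell and proximate composition (generic: 2.5e-6 µL/cell, water
0.70, bulk protein 0.20, membrane lipid 0.03, storage lipid 0.02). Published
compositions exist for only a handful of lines; the presets are editable
starting points. Blood (water 0.80, albumin 0.030, storage lipid 0.0033,
membrane lipid 0.0024, bulk protein 0.155) and plasma analogs are
configurable tables in the same representative spirit.

## IVIVE metrics and QA/QC

DF = C_N,I/C_W; EF = C_C/C_N,I (reported 0 when the system has no cell
phase); equivalent blood concentration C_B = (D_BW/D_CW)·C_C and
EF_B = C_B/C_N,I, with a plasma analog; OED = effect concentration / C_SS,
where C_SS (µM per 1 mg/kg/d) comes from an external toxicokinetic model —
this package never computes it.

QA/QC thresholds: volatility issue when the headspace mass fraction exceeds
2/3 (strictly); solubility issue when C_W exceeds the µM-converted water
solubility (strictly); membrane burden classified against the closed
interval [20, 60] mM. The boundary conventions are fixed here because the
thresholds themselves are conventionally quoted without tie-breaks. The
membrane concentration uses the membrane-lipid ratio at cytosol pH,
consistent with the baseline-toxicity framing of an in-membrane burden.

## Evaluation statistics

MB = mean(log10 P/O), MAE = mean(|log10 P/O|), Factors of Agreement 10^MB
and 10^MAE, and r² as the squared Pearson correlation of log10 ratios
(ratios span orders of magnitude; linear-space r² is an option). The
scenario sweep recomputes predictions per (headspace multiplier × plastic
model) cell and splits chemicals into non-volatile/volatile subsets at
log K_AW (or D_AW) = −4.0.

## Synthetic data

The fixture generator emulates the chemical-property space such models are
applied to: log K_OW,N uniform on [−4, 8], log K_AW,N on [−14, 0.5], ion
classes uniform over {neutral, acid, base} with pKa on [2, 11], molecular
weight 80–600 g/mol, solubility log-uniform and loosely anti-correlated
with hydrophobicity, nominal doses 0.1–100 µM. It does not emulate real
property covariance (e.g. the K_OW–K_AW relationship within chemical
families), measurement error, or mixtures; passing the property suite on
these panels demonstrates internal consistency (mass conservation, oracle
equivalence, monotonicity, speciation limits) across the full input domain,
not predictive accuracy against measurements — evaluating the latter
requires external datasets fed through the `evaluate` harness.

Five deterministic worked cases pin limiting behaviors: an inert tracer
(free ratio 1), a pure albumin binder, a naproxen-like ionizable acid with
empirical log D_MW = 2.17 and log D_SaW = 5.21 (free/nominal ratios 0.003
at 10 % FBS and 0.02 at 2 % FBS in 96-well systems — reproduced by the test
suite within a factor of 1.5 and reported by `scripts/acceptance.py` at one
significant figure), a volatile chemical, and a supersaturating hydrophobe
(dosed ~9 mg/L against 0.006 mg/L solubility; stays flagged after
redistribution).

## Numerical choices and problem sizes

The closed form is checked against an independent brute-force root-finding
solve of the activity balance to 1e-9 relative, and mass conservation to
1e-9 relative, on a seeded 500-chemical panel; neutral chemicals must give
identical results through the neutral-K and ionizable-D code paths to 1e-12
relative. These sizes make the whole suite run in seconds while covering
the input domain densely. Degenerate inputs are rejected with named
validation errors (non-positive MW/solubility/dose, missing pKa for an
ionizable class, serum volumes exceeding medium, composition fractions
summing above 1); a system with zero cells reports EF = 0 rather than a
hypothetical cell enrichment.

## Known limitations

Charged-form offsets, anionic-phospholipid and lysosome treatments are
order-of-magnitude heuristics; single-parameter LFERs are weak for charged
species, especially albumin binding, so empirical biopartitioning inputs
should be preferred for predominantly ionized chemicals. Serum, cell and
blood compositions are representative defaults, not measurements of any
specific lot or line. No cosolvent solubilization, no extracellular-matrix
or well-coating phases, no 3D culture geometry, no kinetics.
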