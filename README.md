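# invitrodist

Equilibrium-partitioning mass-balance model for predicting where an organic
chemical ends up once it is dosed into an in vitro test system — and what
that means for interpreting nominal effect concentrations.

## The problem

In vitro bioactivity and toxicity results (AC50, EC50, IC10) are almost
always reported against the *nominal* medium concentration, the amount
administered per volume of medium. But a chemical dosed into a well plate
does not stay freely dissolved: it volatilizes into headspace, binds serum
albumin and serum lipids, sorbs to the plastic vessel wall, and accumulates
in cells. For hydrophobic or volatile chemicals the freely-dissolved
concentration — the quantity that actually drives exposure — can be orders
of magnitude below nominal, and the cellular concentration orders of
magnitude above it. Anyone comparing potencies across assays, extrapolating
in vitro results to in vivo doses (IVIVE / reverse dosimetry), or designing
a dosing regime needs to know this distribution.

`invitrodist` computes it, per chemical and per test system, from a minimal
property set: molecular weight, melting point, ionization class and pKa,
log *K*<sub>OW,N</sub>, log *K*<sub>AW,N</sub>, and water solubility.

## The model

All phases are assumed to reach equal chemical activity instantly
("equilibrium partitioning"), so each phase concentration is its phase-water
partition ratio times the freely-dissolved concentration, and the mass
balance closes in a single division:

```
C_W = M_T / (V_W + K_AW·V_A + K_SaW·V_Sa + K_SlW·V_Sl + K_DsW·V_Ds + K_CW·V_C + K_PlW·A_Pl)
```

where *M*<sub>T</sub> (µmol) is the nominal concentration times the medium
volume, the *V* are phase volumes (µL), and *A*<sub>Pl</sub> is the wetted
plastic area (m², with *K*<sub>PlW</sub> in m³/m²). For ionizable organic
chemicals (monoprotic acids and bases) every *K* is replaced by a
pH-dependent distribution ratio *D* = *f*<sub>N</sub>·*K*<sub>N</sub> +
(1−*f*<sub>N</sub>)·*K*<sub>I</sub>, with the neutral fraction
*f*<sub>N</sub> from Henderson–Hasselbalch speciation, charged-form ratios
scaled down from the neutral form, and the cell-water ratio corrected for
the medium/cytosol pH difference (with an optional lysosomal ion-trapping
increment for bases).

Phase-water ratios come from single-parameter linear free-energy
relationships on log *K*<sub>OW,N</sub> (two published options for plastic),
or from user-supplied empirical values which always take precedence.

On top of the distribution the package derives:

* **IVIVE metrics** — depletion factor DF = *C*<sub>N,I</sub>/*C*<sub>W</sub>,
  cellular enrichment factor EF = *C*<sub>C</sub>/*C*<sub>N,I</sub>, the
  equivalent blood concentration at equal chemical activity with the cell
  (*C*<sub>B</sub> = (*K*<sub>BW</sub>/*K*<sub>CW</sub>)·*C*<sub>C</sub>),
  its ratio EF<sub>B</sub> to the nominal concentration, and oral equivalent
  doses OED = effect concentration / *C*<sub>SS</sub> (the toxicokinetic
  steady-state blood concentration per unit dose, an external input);
* **QA/QC flags** — volatility issue (> 2/3 of mass in headspace),
  solubility issue (*C*<sub>W</sub> above water solubility after
  distribution), and a baseline-toxicity classification of the predicted
  membrane concentration against the 20–60 mM narcosis range;
* **evaluation statistics** — model bias and mean absolute error on log10
  predicted/observed ratios, as Factors of Agreement 10^MB and 10^MAE, plus
  r², with a scenario sweep over headspace and plastic-sorption assumptions.

## Worked example

Naproxen (an acid, pKa 4.15) with measured membrane and albumin distribution
ratios, in a 96-well assay at 10 % fetal bovine serum:

```bash
invitrodist run --id naproxen --mw 230.26 --ion-class acid --pka 4.15 \
    --logkow 3.18 --logkaw -6.34 --sw 15.9 --nominal 10 \
    --log-dmw 2.17 --log-dsaw 5.21 --plate 96 --medium 100 --fbs 0.10
```

prints

```
chemical: naproxen
  freely dissolved C_W        0.03342 uM
  cell concentration C_C      0.08923 uM
  membrane concentration      0.004944 mM
  free / nominal ratio        0.003342
  bulk / nominal ratio        1
  mass fractions: water=0.00333, headspace=6.4e-12, albumin=0.996, serum_lipid=8.69e-06, other_dom=0.000225, cells=4.46e-06, plastic=3.44e-06
  DF=299.2  EF=0.008923  EQP_CB=162.7 uM  EF_B=16.27
  QA/QC: volatility_issue=False solubility_issue=False baseline=below_20mM
```

Reading: of a 10 µM nominal dose, 99.6 % is bound to serum albumin; only
0.3 % remains freely dissolved (free/nominal ratio 0.003, i.e. DF ≈ 300).
Because everything sorbed to serum stays suspended in the medium, a bulk
medium sample would still measure the full nominal concentration
(bulk ratio 1). At 2 % serum the free ratio rises to ≈ 0.02. The predicted
membrane burden (0.005 mM) is far below the 20–60 mM baseline-toxicity
range, so an effect at this dose would not be narcosis.

Batch mode and the evaluation harness:

```bash
invitrodist fixtures --seed 1 -n 50 --out fixtures/         # synthetic panel
invitrodist batch fixtures/random_panel.csv --out outputs/ --fbs 0.10
invitrodist evaluate dataset.csv --plate 24 --fbs 0 --temperature 19
```

`batch` writes six CSV sheets: concentrations in all phases, mass fractions,
masses, IVIVE metrics, partitioning adjusted to system conditions, and the
QA/QC summary with batch counts.

## Scope

The model is static: uptake kinetics, degradation, biotransformation, cell
growth, and re-dissolution of precipitated chemical are out of scope, and
results for chemicals flagged with the solubility issue should be read with
care. See `docs/methods.md` for assumptions, defaults and limitations.
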