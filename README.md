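# sprscreen

Triage and analysis for SPR-based fragment screening campaigns, with a
companion simulator so every stage of the pipeline is testable without
instrument data.

Fragment-based drug discovery (FBDD) screens libraries of very small
molecules (≲ 300 Da) for weak but efficient binding to a protein target —
here modeled on a screen against complement protease C1r, the initiating
enzyme of the classical complement pathway. Hits are typically in the
100 µM–mM affinity range, so the analysis lives or dies on careful signal
correction and normalization. This package implements that workflow for
surface plasmon resonance (SPR) data:

- **Library profiling** — rule-of-three fragment-likeness (MW ≤ 300 Da,
  H-bond donors ≤ 3, clogP ≤ 3), ligand efficiency
  LE = −RT·ln(K_D)/HAC (kcal·mol⁻¹ per heavy atom), atom-pair Tanimoto
  similarity and single-linkage clustering.
- **Sensorgram processing** — double referencing (reference-surface and
  buffer-blank subtraction), DMSO excluded-volume solvent correction from
  calibration cycles, report-point extraction (late-association binding
  point; residual point 10 s post injection).
- **Screening triage** — the clean screen (residual > 5.0 RU on a bare
  surface fails), hit calling against the theoretical maximal response

      R_max = immobilization (RU) × (MW_analyte / MW_ligand) × n

  with a hit requiring ≥ 60 % of R_max, and exclusion of
  superstoichiometric binders (> 2 × R_max) and injections outside the
  solvent-calibration range.
- **Affinity** — steady-state 1:1 fits of plateau responses,
  R_eq(C) = C·R_max/(C + K_D), with R_max *fixed* to its theoretical
  value so K_D stays estimable for weak binders; replicate aggregation as
  mean ± SD; stoichiometry-normalized domain mapping across surfaces.
- **Activity assays** — ELISA percent activity from per-column controls,
  unpaired t-tests for single-dose inhibition, constrained IC50 fits
  pct(C) = 100/(1 + (C/IC50)^h) with top/bottom fixed at 100/0, pathway
  selectivity profiles, and progress-curve initial rates.
- **Simulation** — closed-form 1:1 Langmuir cycles with DMSO bulk
  artifacts, drift, noise, sticky and superstoichiometric binders, full
  campaigns with planted ground truth, and dose-response plates.

## Worked example

Run a fully synthetic, seeded 200-compound campaign end to end
(simulate → double-reference → solvent-correct → triage → K_D fits):

```sh
sprscreen report --seed 3 --out results/
```

```
screening campaign summary
==========================
compounds screened: 200
insoluble: 0
clean-screen failures: 20
carried forward: 180
out of solvent calibration: 0
superstoichiometric: 10
hits: 10 (5.0%)
triage vs planted truth: hit_sensitivity=1.0000, hit_specificity=1.0000, clean_sensitivity=1.0000, clean_specificity=1.0000
KD CMP-6: 74 ± 1 µM (n=3)
KD CMP-87: 126 ± 2 µM (n=3)
```

The 20 clean-screen failures are the planted 10 % of non-specifically
sticky compounds; the 10 excluded superstoichiometric binders and the 10
called hits (5 %) match the planted class fractions, and each reported
K_D is the mean ± SD over three replicate 7-point dilution series
(7.8–500 µM, two-fold), fitted with the R_max-constrained steady-state
model against that compound's planted affinity.

The same machinery is available as a library:

```python
from sprscreen import (SurfaceDef, default_concentration_series,
                       fit_steady_state, steady_state_response,
                       theoretical_rmax, ligand_efficiency)

surface = SurfaceDef("C1r", ligand_mw=92000.0, immobilization=9200.0)
rmax = theoretical_rmax(surface, 276.0)        # 27.6 RU for a 276 Da fragment
concs = default_concentration_series()         # 7.8–500 µM, 7 points
responses = steady_state_response(concs, kd=480e-6, rmax=rmax)
fit = fit_steady_state(list(zip(concs, responses)), rmax)
print(f"KD = {fit.kd * 1e6:.0f} µM")           # KD = 480 µM
print(f"LE = {ligand_efficiency(fit.kd, 17):.2f}")  # LE = 0.27 kcal/mol/HA
```

Individual stages are exposed as CLI subcommands (`sprscreen simulate`,
`screen`, `fit-kd`, `fit-ic50`) that compose through plain CSV files.

## Layout

```
src/sprscreen/
  library.py      compounds, rule of three, ligand efficiency, similarity
  simulate.py     synthetic cycles, campaigns, dose series, ELISA plates
  processing.py   double referencing, solvent correction, report points
  triage.py       clean screen, Rmax hit calling, campaign bookkeeping
  affinity.py     constrained steady-state KD fits, domain mapping
  activity.py     percent activity, t-tests, IC50 fits, selectivity, rates
  pipeline.py     end-to-end orchestration, config, report rendering
  cli.py          click command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
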