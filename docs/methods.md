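# Methods

## Binding model

All SPR simulation and fitting assumes a 1:1 Langmuir interaction between
an injected analyte at concentration C and an immobilized ligand:

    dR/dt = ka·C·(Rmax − R) − kd·R

The simulator uses the closed-form solution — association
R(t) = R_eq·(1 − e^(−(ka·C + kd)·t)) with
R_eq = C·Rmax_theor·n/(C + K_D), dissociation R(t) = R(t_stop)·e^(−kd·t) —
rather than numerical integration, for speed and exactness; the ODE
integrator exists only in the test suite as an independent oracle. The
theoretical maximal response is

    Rmax_theor = immobilization (RU) × (MW_analyte / MW_ligand) × n

with n the binding stoichiometry (1 unless stated). Mass-transport
limitation, rebinding and surface heterogeneity are deliberately not
modeled: the analysis stage uses steady-state plateaus only, which these
effects do not shift.

Affinity fitting holds Rmax_theor *fixed* and fits K_D as the only free
parameter (optional constant offset, off by default). This constraint is
load-bearing: fragment affinities frequently exceed the top tested
concentration (max C = 500 µM vs K_D up to ~1.7 mM), where an
unconstrained two-parameter fit is unidentifiable. Fitting is unweighted
least squares in linear response space (SPR read noise is approximately
homoscedastic in RU), with K_D log10-parameterized internally, bounded to
[1e−9, 10] M, and initialized at the concentration nearest half the
maximum observed response. Replicate K_D values are aggregated as
arithmetic mean ± sample SD on the K_D scale (not log), matching the
mean ± SD convention used for reporting; at least three replicates are
required for a non-provisional result.

## Artifacts and their correction

Samples are prepared in DMSO-containing buffer; a per-cycle mismatch
between sample and running-buffer DMSO produces a bulk refractive-index
jump during the injection on every surface, plus a smaller
*excluded-volume* offset that survives reference subtraction because the
immobilized protein displaces solvent on the active surface. The
simulator models the bulk as `bulk_coeff` (default 100 RU per % v/v) times
the mismatch, and the surviving offset as a quadratic polynomial in the
bulk response (defaults 0.012·b + 2e−4·b², chosen to give offsets of a few
tenths of an RU at realistic mismatches — the same order as fragment
binding signals, which is precisely why screens correct for it).

Processing follows the standard excluded-volume procedure: solvent-only
calibration cycles spanning 4–5.5 % DMSO are collected at the start, end
and every 50 cycles; for each, the reference bulk response and the
active-minus-reference offset are measured, and a degree-2 polynomial
(configurable) of offset versus bulk is fitted. Calibrations apply
piecewise to the cycles they enclose (nearest span; no temporal
interpolation). Cycles whose bulk response falls outside the calibrated
range are flagged `out_of_calibration` and excluded from hit calling
rather than extrapolated. Double referencing subtracts the reference
surface and the nearest buffer blank; drift is common-mode and cancels
there.

Report points reduce each corrected trace to scalars: the *binding* point
is the mean over the last 2 s of the association phase, the *residual*
point the mean over a 1 s window centered 10 s after injection end.
A window (rather than the instantaneous sample a human analyst would
read) resists single-sample noise; this is the package's
operationalization of instrument-software baseline handling, which has no
published algorithm.

## Triage cascade

Order and inequality directions follow the screening protocol exactly:

1. **Insolubility** — an input flag (visual inspection upstream); consumed,
   never computed.
2. **Clean screen** — residual > 5.0 RU (strict) on a bare surface fails;
   exactly 5.0 RU passes.
3. **Solvent-calibration range** — out-of-range cycles are excluded.
4. **Abnormal shape** — no published definition exists; operationalized as
   the residual point exceeding the binding point by more than 3× baseline
   noise, or binding below −3× baseline noise. Configurable.
5. **Hit calling** — %Rmax = 100·binding/Rmax_theor; superstoichiometric
   (> 2 × Rmax, strict) excludes; hit requires no flags and
   %Rmax ≥ 60 (inclusive).

Hit rates are rounded half-up to one decimal (95/2000 = 4.75 % prints as
4.8 %).

## Synthetic campaigns

The generator emulates the study conditions: a 2000-compound-style library
split 1:1:1:1:4 across five subsets (2D/3D fragments, natural-product
scaffolds, serine-protease-inhibitor-like, PPI-inhibitor-like) with
subset-specific MW ranges; single-concentration screening at 500 µM with
30 s injections; 92 kDa ligand immobilized at 9200 RU; DMSO calibration
every 50 cycles over 4–5.5 %; per-cycle mismatch jitter of 0.15 % v/v.
Compound classes are planted with exact counts: clean binders
(K_D log-uniform 50–250 µM, so their plateau clears the 60 % Rmax cutoff
with margin), non-binders, sticky compounds (additive residual 8–15 RU
with slow decay, half-time ≫ 10 s, so the residual report point sees it),
and superstoichiometric binders (n ∈ [2.5, 4] with K_D 10–60 µM, so the
response clears 2 × Rmax). Dissociation rates are 0.5–2 s⁻¹, fast enough
that clean binders equilibrate within the injection and leave no residual.
Ground-truth labels are the noise-free closed-form outcomes of each
planted parameter set, which makes confusion-matrix tests exact rather
than heuristic.

What the simulator does **not** reproduce: mass-transport effects, slow
kinetics (where the plateau assumption fails), compound aggregation
dynamics, carry-over between cycles, and real instrument drift structure.
Passing tests therefore demonstrate the correctness of the *analysis*
under the stated noise model, not robustness to every pathology of real
sensor data.

ELISA plates are simulated as
A = neg + (pos − neg)·(1 − C^h/(C^h + IC50^h)) with multiplicative
Gaussian noise (5 % CV default) and one positive (full activity) and one
negative (no serum) control per column, mirroring per-column
normalization.

## Dose-response and statistics

Percent activity anchors each column to its own controls
(pos = 100 %, neg = 0 %), unclipped. IC50 fits use the inhibitor-versus-
response model with top/bottom constrained to 100/0; the fixed-slope
variant (h = 1) is the default, matching log(inhibitor)-vs-response
fitting of the campaign's dose-response data. IC50 is log-parameterized;
the 95 % CI is asymptotic on the log scale (t quantile, N − p degrees of
freedom) and back-transformed, so it is positive and brackets the
estimate by construction. Monte-Carlo checks in the test suite show
~93–95 % empirical coverage at 7 doses × 3 replicates × 5 % CV. Curves
spanning less than 10 percentage points are rejected as showing no dose
dependence rather than returning an unstable extrapolation. Fitted IC50s
outside the tested span are flagged `extrapolated` (the 520–660 µM lead
potencies sit just above a 500 µM top dose; the constrained model keeps
them estimable).

Single-dose comparisons use the two-sided unpaired Student's t-test
(equal variance; Welch by flag), significance at p < 0.05, with no
multiple-testing correction across a compound panel by default (a Holm
option exists in spirit via the returned p-values). Two identical
zero-variance groups return p = 1 by convention. Pathway selectivity
labels a compound `inactive` (no pathway inhibited), `<pathway>-specific`
(exactly one), or `multi-pathway`.

Ligand efficiency uses LE = −RT·ln(K_D)/HAC at 298.15 K in kcal·mol⁻¹
per heavy atom; the reporting convention for fragment campaigns. Published
LE tables rarely state T or the formula, so small reconciliation offsets
against external values are expected.

Similarity uses rdkit atom-pair count fingerprints; the Tanimoto
statistic (sum-min over sum-max on counts; set overlap on sets) is
computed in-package so it is testable independently of the fingerprint
backend. Clustering is single-linkage on 1 − Tanimoto via
scipy.cluster.hierarchy, verified against brute-force agglomeration for
small instances.

## Problem sizes and numerical choices

Default test/acceptance problem sizes — 200-compound campaigns, 3
replicate 7-point dilution series, 100–200 Monte-Carlo repetitions for
IC50 recovery — were chosen as the smallest sizes at which the recovery
statistics are stable; all complete in seconds. Solver tolerances are
1e−14 (xtol/ftol/gtol) for the 1–2 parameter least-squares problems,
where convergence is cheap. Degenerate inputs are rejected loudly:
all-zero response series, calibration sets without bulk spread,
degenerate plate controls, and windows outside a trace all raise with a
specific message rather than returning NaN.

## Known limitations

- Kinetic (ka/kd) fitting is out of scope; only steady-state affinities.
- The abnormal-shape heuristic is a stand-in for analyst judgment; it is
  conservative (3σ margins) and configurable.
- The insolubility flag must come from outside (no optical model).
- The asymptotic IC50 CI can undercover for strongly extrapolated fits;
  the extrapolation flag marks such results.
- Clustering ties (equal merge distances) follow scipy's deterministic
  ordering, which may differ from other implementations.
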