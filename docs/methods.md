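# Methods

## Model structure

The disposition model is a whole-body, perfusion-limited (flow-limited) PBPK
model for a 70-kg adult. Compartments are anatomical tissues connected by the
blood circulation: venous blood → lung → arterial blood → systemic tissues.
Muscle, adipose, skin, heart, brain, kidney and a lumped rest-of-body return
venous blood directly; spleen, stomach and the five intestinal wall segments
(duodenum, jejunum, ileum, cecum, colon) drain through the portal vein into
the liver, whose outflow (hepatic artery + portal vein) returns to venous
blood. The gut lumen is a first-order transit chain — stomach → duodenum →
jejunum → ileum → cecum → colon → feces — with first-order absorption from
the duodenum, jejunum and ileum lumen into the corresponding wall tissue;
the stomach lumen does not absorb. Dissolution is treated as instantaneous
(immediate-release formulations only).

Each perfusion-limited tissue obeys

    V_t dC_t/dt = Q_t (C_art − C_t / K_t:b),

with K_t:b = K_t:p / R_b the blood-referenced partition coefficient.
Elimination uses the venous-equilibrium (well-stirred) form: hepatic
f_u,b·CL_li,int·C_li/K_li:b, renal f_u,b·CL_k,int·C_k/K_k:b, and an optional
per-segment intestinal-wall clearance CL_Gw (default 0). Cumulative
elimination by route and fecal loss are carried as explicit states, so total
mass is checkable at every output time. All balances are linear in the state.

These right-hand sides are reconstructions of the standard flow-limited
balances consistent with the compartment graph; they are not transcribed
from any proprietary implementation.

## Heart-failure physiology

Heart failure is represented purely hemodynamically. The healthy baseline
tissue blood flows (summing to a cardiac output of 5600 mL/min) are scaled by
published per-class perfusion fractions: hepatic and splanchnic flow to
76% / 54% / 46% of baseline for NYHA classes II / III / IV, renal flow to
78% / 55% / 63%, and skin/adipose/muscle flow to 57% / 44% / 28%; heart,
brain and rest-of-body flows are unchanged, as are all tissue volumes and
intrinsic clearances. Pulmonary flow is always recomputed as the systemic
sum, so the circulation closes to machine precision. Note that the renal
fraction sequence is itself non-monotone in severity (class IV renal
perfusion partially recovers relative to class III); consequences are
discussed under Limitations.

Tissue volumes are a packaged synthetic stand-in assembled from standard
reference-man anatomy (rest-of-body closes total body volume at unit
density); they are overridable through config.

## Partition coefficients

Two composition-based K_t:p routes are implemented over a packaged tissue
composition table (fractional extracellular/intracellular water, neutral
lipid, neutral phospholipid, acidic phospholipid concentration, and
tissue:plasma albumin/lipoprotein ratios):

- **rodgers** — the Rodgers/Rowland mechanistic framework: ionization at
  intracellular (pH 7.0) versus plasma (pH 7.4) pH, octanol-calibrated
  neutral-lipid partitioning P = 10^logP with the membrane term 0.3P + 0.7,
  acidic-phospholipid association for moderate-to-strong bases (pKa ≥ 7)
  with the association constant recovered from the blood-cell partition
  implied by R_b (cell pH 7.22, hematocrit 0.45), and an albumin-type
  protein term for neutrals, acids, weak bases and zwitterions.
- **ruark** — a calibrated variant in which neutral-lipid affinity uses the
  vegetable-oil:water relation log K_vo:w = 1.115·logP − 1.35; ionization
  and protein terms are handled as above.

K_t:p prediction is deterministic and dose-free; a user-supplied partition
override bypasses prediction bit-exactly (used by the glycoside fixture,
whose muscle/skin/adipose affinity is transporter-driven and outside the
scope of composition-based prediction). f_u,b is always derived as
f_u,p / R_b; sampling perturbs f_u,p with R_b fixed.

## Absorption

Without an explicit absorption constant, per-segment k_a,i = 2·P_eff / r_i
with packaged segment radii (duodenum 1.6, jejunum 1.5, ileum 1.25 cm) and
P_eff in 1e-4 cm/s; an override applies one k_a uniformly to the three
absorbing segments. The fraction absorbed follows the cascade
F_a = 1 − Π_i K_t,i/(K_t,i + k_a,i). Default transit constants (gastric
emptying 2.5/h; duodenum 3.8, jejunum 0.66, ileum 0.62, cecum 0.23, colon
0.05 per hour) emulate typical human residence times and are config
overridable.

## Numerical integration

The system is x' = A x + u(t) with a constant compartmental matrix, so the
default engine propagates **exactly** with matrix exponentials between dose
boundaries (augmented-matrix form during infusions), restarting at every
dose event; boluses add their amount to venous blood (IV) or the stomach
lumen (oral). This gives machine-precision mass balance and is fast enough
for thousand-subject cohorts. An LSODA engine (rtol 1e-8, atol 1e-10 in
canonical mg/mL/min units, analytic Jacobian, per-event restarts) is kept as
an independent numerical route and is cross-checked against the exponential
engine in the tests. States are clipped at −1e-9 of administered mass;
larger negativity aborts.

Steady state under a repeating regimen is reached by cycling intervals until
the interval AUC changes by < 0.1% between successive intervals (cap 60
intervals; non-convergence raises — e.g. a zero-clearance drug). Output
sampling matters for IV boluses: the venous mixing spike decays on the scale
of V_ven/CO ≈ 0.6 min, so AUC-type analyses use early-dense (geometric)
grids.

## Non-compartmental analysis

AUC uses the linear-up/log-down trapezoid; λ_z is a log-linear fit on the
terminal window chosen by adjusted R² among the last k ≥ 3 positive points
after T_max (ties → more points); AUC_inf = AUC_0–t + C_last/λ_z, flagged
absent when λ_z is not estimable. Units: concentrations ng/mL, AUC
μg·h/mL. Exposure ratios (AUCR, CmaxR) are dose-normalized HF:healthy
ratios; fold errors are reported against the 0.5–2.0 acceptance window and
the stricter 0.8–1.25 window. Steady-state C_min is the trough over the
dosing interval on the dense grid.

## Virtual populations

Subjects share the physiology; five drug parameters (CL_li,int, CL_k,int,
f_u,p → f_u,b, P_eff, k_a) receive independent multiplicative draws, by
default uniform on 80–120% of baseline (the only quantitative statement
available about the variability model); a truncated lognormal alternative is
provided. When k_a is permeability-derived, its own draw is skipped — the
P_eff draw already perturbs absorption, and a second multiplier would
double-count it. Percentile bands (5th/50th/95th) pool all replicate cohorts
with linear interpolation of the empirical distribution. Residual
(intra-individual) error is applied only when generating synthetic
"observed" data, never inside cohort simulation; consequently the cohort
band quantifies parameter variability only, its half-width under the bounded
sampling is ~6–17% along the profile, and noisy observations with ≥10% CV
legitimately escape it at some times — the fold-error criterion is then the
operative acceptance route. Passing band checks here demonstrates the
pipeline's statistics under the generator's assumptions, not that real
patients vary by only ±20%.

## Sensitivity analysis

Local scans rescale one parameter over a fold range on a log-spaced 7-point
grid that always contains fold 1 (two-fold ranges for the intrinsic
clearances and hepatic/renal flows, three-fold for P_eff and the
muscle/skin/adipose flows, 0.7–1.3 for f_u,b). Blood-flow scans rescale a
single tissue's flow and recompute pulmonary flow for closure; f_u,b scans
move f_u,p with partitions held at baseline. The Sobol analysis reuses the
same fold bounds as independent uniform multipliers and delegates
Saltelli-type sampling and the first/total-order estimators to
`scipy.stats.sobol_indices`; correctness is anchored in tests by the
additive two-parameter function and the closed-form Ishigami indices. The
default metric is steady-state interval AUC (Cmax optional), evaluated at
0.25 mg qd of the glycoside fixture.

## Dose optimization

The optimizer returns the largest grid dose (step 0.005 mg, matching the
precision of clinically adjusted glycoside doses) at which **no** converged
subject's steady-state C_max reaches the toxic threshold (2.0 ng/mL), and
reports the fraction of subjects whose trough exceeds the minimum effective
concentration (0.5 ng/mL; the 0.5–0.9 ng/mL therapeutic band is reported
only). "All patients below threshold" means 0 of n sampled subjects, not a
population quantile. Ties resolve toward the higher dose. If no once-daily
dose can satisfy both window edges, the search moves to twice-daily dosing,
which lowers peak–trough fluctuation at equal daily dose. Because the model
is linear, each subject is simulated once at unit dose and the grid is
evaluated by exact dose scaling (dose proportionality is itself a tested
invariant).

## Synthetic fixtures

Three archetypes stand in for the drug classes the pipeline exercises (the
actual per-drug parameter files are not redistributable):
a renally cleared neutral glycoside analogue (CL_k,int 240 > CL_li,int 70
mL/min, f_u,p drawn from {0.61, 0.71, 0.95}, R_b 1, logP 1.26, P_eff 1e-4
cm/s, transporter-inflated muscle/skin/adipose partition override; terminal
half-life ≈ 56 h, F_a ≈ 0.7); an intermediate-extraction hepatically
cleared weak base (hepatic extraction ≈ 0.44); and a highly bound monoprotic
acid cleared by renal secretion. All fixture metadata is labelled synthetic.
Observations are generated from one cohort-drawn (or typical) subject,
subsampled to a sparse clinical schedule (0.25–24 h), with median-unbiased
multiplicative lognormal residual error.

## Problem sizes

Default analysis/test scales were chosen to keep the full pipeline
desk-runnable while preserving the statistics being demonstrated: cohorts of
200 subjects (3 replicates where bands are pooled), Sobol at 64 base samples
for the PBPK metric and 4096 for the analytic estimator checks, dose grids
of ~100 points. All are parameters and scale up directly.

## Limitations and known behaviors

- The published renal perfusion fractions are non-monotone in severity
  (78% → 55% → 63%). At steady state the interval AUC of an orally dosed,
  renally cleared drug is F·D/CL, and renal well-stirred clearance increases
  with renal flow while the hepatic-flow decrease cannot offset it under
  oral dosing (for a purely hepatically cleared drug, oral AUC is
  flow-independent; adding renal clearance makes the net hepatic-flow effect
  AUC-decreasing). Hence glycoside steady-state AUC rises from class II to
  III but dips ~1–3% from III to IV, while C_max rises strictly with
  severity (driven by the monotone muscle/skin/adipose flow loss) and the
  maximal safe dose is non-increasing. A claim that *both* AUC and C_max
  increase strictly across all classes is not structurally attainable under
  these fractions.
- Only hemodynamics change with disease: no age/sex/body-weight scaling, no
  altered gastric emptying or gut-wall thickening, no drug–drug
  interactions, no transporter kinetics, no enterohepatic recirculation, no
  saturable elimination, and no solubility/dissolution limitation.
- Tissue volumes, composition tables, transit constants and segment radii
  are packaged literature-typical stand-ins, clearly labelled, and
  overridable; they are not fitted to any dataset.
- The two-compartment and one-compartment analytic checks use degenerate
  physiologies (tiny lung/arterial volumes, uniform partitions); these are
  test constructions, not recommended configurations.
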