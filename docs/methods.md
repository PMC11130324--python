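# Methods

`her2qsp` is a mechanistic quantitative-systems-pharmacology (QSP) model of
HER2-positive breast cancer: an ODE model of ErbB receptor signaling and
tumor growth in a representative cell, coupled to mouse compartmental PK for
five therapeutics (lapatinib, pyrotinib, capecitabine, T-DM1, T-DXd), with
calibration, global sensitivity, synergy and resistance-phenotype tooling on
top. This note records the model, its assumptions, the numerical choices and
the known limitations.

## The cell-level signaling model

**Receptors and ligands.** Four ErbB receptors (EGFR, HER2, HER3, HER4) with
cell-line-specific copy numbers; the SKBR3 preset uses 150,000 / 1,500,000 /
40,000 / 2,000 molecules per cell, and generic IHC presets place 1.5, 0.5 and
0.1 million HER2 per cell for 3+/2+/1+ lines. Two ligands are modeled as
constant baths: EGF (binds EGFR) and NRG1 (binds HER3 and HER4), converted
from ng/mL using 6.2 kDa (EGF) and 7.5 kDa (NRG1 active domain).

**Dimer inventory.** Five dimer species, each paired with a phospho form:
EGF:EGFR–HER2, HER2–HER2 and the ligand-independent HER2–HER3 pair (the
constitutive drivers in HER2-overexpressing cells), plus the ligand-dependent
NRG1:HER3–HER2 and NRG1:HER4–HER2 pairs. HER3 homodimers are excluded (HER3
is kinase-dead). Binding and dimerization follow mass action; phosphorylation
and dephosphorylation cycle each dimer between active and inactive forms.
Active ligand-bound dimers are endocytosed (the classical receptor
down-regulation route), which is what makes NRG1 lower total HER3 and puts
the NRG1→HER3 axis in a genuine dynamic steady state.

**Cascades.** Two lumped two-tier cascades operate on normalized (0–1)
activities: a weighted phospho-receptor pool drives Raf (weight `w7`,
Hill constant `km7`; MEK is lumped into the Raf→ERK step, weight `w8`), and a
second HER3-weighted pool drives AKT through a lumped PI3K activation step
(`k_pi3k_act`/`k_pi3k_deact`). The Raf/ERK tier is deliberately operated in a
saturated regime (`km7` well below the baseline pool): this is what makes
partial receptor inhibition degrade signaling gracefully and produces graded
in vivo dose–response instead of all-or-nothing switching. The PI3K/AKT tier
is half-saturated at baseline so that ligand stimulation has headroom.

**FOXO feedback.** HER3 synthesis is multiplied by
`(1 + f_foxo·(1 − H(pAKT)))`, normalized at a reference pAKT, so any
perturbation that lowers pAKT (TKIs, pathway inhibition) raises HER3
synthesis — the resistance-relevant feedback.

**Growth and death.** With `S = (w11·H(pERK) + wAKT·H(pAKT))/(w11 + wAKT) + s_basal`,

```
dN/dt = N·[ umax·H(S; km13, n13)·(1 − V/Vmax)
          − dmax·(1 + w14·H(PL; km14, n14) + w15·H(FU; km10, n10)) ]
```

`PL` is intracellular ADC payload (nM), `FU` the 5-FU exposure; the logistic
factor applies in vivo only (`Vmax` = 2000 mm³, 1e6 cells/mm³). `s_basal` is
an ErbB-independent growth-signal offset, zero for SKBR3 and positive for the
lower-HER2 IHC presets (0.25 for 2+, 0.5 for 1+): those lines grow through
other drivers (e.g. ER signaling), which is also why HER2-targeted therapy is
progressively less effective in them. Growth/death rates are quoted per day;
the in vivo baseline (`umax` 0.38, `dmax` 0.11 per day) is deliberately
smaller in proliferative drive than the in vitro one, reflecting the
microenvironment shift seen when models of this kind are translated.

## Drug mechanisms

* **Lapatinib** — reversible EGFR/HER2 kinase binding (Kd 5 nM); bound
  receptors cannot dimerize or transphosphorylate and are degraded 3× faster.
* **Pyrotinib** — irreversible (covalent) EGFR/HER2/HER4 inactivation;
  recovery requires receptor resynthesis, giving deeper and longer pathway
  suppression per dose than lapatinib; bound receptors degrade 5× faster,
  reproducing the observed total-HER2 down-regulation with FOXO-driven HER3
  induction.
* **T-DM1 / T-DXd** — bind the HER2 ectodomain (also when the kinase site is
  TKI-occupied; kinase-site occupancy does not block ectodomain capture, a
  wiring detail that matters for TKI+ADC combinations), internalize
  (`kint_ADC`), and are processed in the lysosome (`kdeg_ADC_2`) in
  competition with a recycling/exocytosis branch (`k_recycle`) that clears
  complexes without payload release. Each processed complex releases `DAR`
  payload molecules (3.5 DM1, 8 DXd; molecules/cell → nM via a 2 pL cell
  volume). DM1 is effluxed (`kout_PL`) and cannot re-enter; DXd permeates the
  membrane in both directions (`kper_PL`), so extracellular DXd can re-load
  cells (bystander-capable).
* **Capecitabine** — prodrug; tumoricidal only as 5-FU after the sequential
  cap → 5'DFCR → 5'DFUR → 5-FU cascade (in vivo). In vitro assays use 5-FU
  directly.

## Pharmacokinetics

Standard one/two-compartment mouse models in nmol amounts (doses mg/kg at
20 g body weight): oral first-order absorption for the TKIs and capecitabine,
IV bolus for ADCs, with central/peripheral distribution and linear clearance.
ADCs additionally deconjugate in plasma into a payload disposition block
(starred volumes) — kept in the stand-alone PK module; in the combined tumor
model that block is omitted because plasma catabolites do not enter the tumor
(a stated assumption), which keeps the full system at 51 species and 74
reactions, inside the 60/80 budget. Tumor coupling: small molecules partition
instantaneously (`Kp`, interpreted as *free* tumor exposure — 0.007 for
lapatinib and 0.045 for pyrotinib, reflecting their very high protein
binding), while ADCs enter the tumor interstitium first-order in the central
amount (`k_tu`) with no back-flux and without depleting the central
compartment (the tumor dose is negligible against body burden; PK mass
balance is audited on the PK-only network, which carries explicit elimination
sinks). No primary mouse PK parameter values were available for these exact
formulations, so all PK parameters are provisional and chosen for
mouse-plausible shapes:
biexponential ADC decline over ~3 weeks, 1–2 h TKI half-lives with daily
trough escape, and ordered capecitabine metabolite peaks.

## Calibration

The loss is variance-weighted least squares on normalized readouts
(normalization per dataset flag: to series maximum, to control, or raw), with
a 10%-of-mean dispersion imputation when no SD is recorded. The optimizer is
a generalized pattern search (mesh/poll, opportunistic polling, expansion 2,
contraction 0.5, convergence at mesh < 1e-6 of the box) run multi-start over
log-scaled boxes — derivative-free, with a monotone incumbent trace and
deterministic given the seed. In vitro → in vivo translation is a hard
policy: only {umax, dmax, w14, w15, n14, km14} may be re-estimated, a
control-only dataset re-estimates umax alone, and signaling parameters are
returned bit-identical.

## Sensitivity, uncertainty, synergy

PRCC follows the standard recipe (rank transform, residualize each parameter
and the output on all others, correlate residuals; t-test p-values with
Bonferroni correction over parameters at p < 0.01, influence threshold
|PRCC| > 0.05). Samples are Latin hypercube over 0.5–2× baseline; the output
is tumor volume at day 20 under six input conditions (none, NRG1
overexpression, lapatinib+capecitabine, pyrotinib+capecitabine, T-DM1,
T-DXd). The NRG1-overexpression *sensitivity* condition uses a 2 ng/mL
autocrine-level bath — the receptor-binding-limited regime in which the
NRG1–HER3 association rate is rate-determining — whereas the resistance
*phenotype* simulations use a saturating 50 ng/mL exposure; at saturation all
HER3 titrates into ligand dimers and the binding rate cannot matter, which is
a structural fact of ligand–receptor systems, not a model artifact. At the
design size of 5000 samples the NRG1–HER3 binding rate clears the corrected
significance threshold; at the reduced 500-sample desk scale its |PRCC|
(≈0.06) passes the influence threshold but the significance test is
underpowered for it (power analysis: r = 0.06 needs n ≈ 5000 at the
Bonferroni-corrected level).

Sobol total-order indices use Saltelli sampling with the Jansen estimator
(base 512 by default, bootstrap CIs) and are cross-checked against PRCC for
rank agreement on analytic toys. Bootstrap uncertainty resamples datapoint
means from Normal(mean, sd) — explicit zero SDs resample exactly, missing SDs
get the 10% imputation — and refits the selected parameters within 0.1–10×
bounds.

Bliss independence uses `Yab = Ya + Yb − Ya·Yb` on fractional effects; in
vivo surfaces use TGI/100 clipped to [0, 1] (a documented choice — the
effect scale for in vivo Bliss is not uniquely defined), with a ±0.01
additive band.

## Phenotype presets

Override multipliers are reconstructions calibrated once so the qualitative
response patterns hold, and are configurable: `tdm1_resistant` kout_PL ×50;
`lapatinib_resistant` umax ×1.6, kon_Raf ×5; `pan_resistant` umax ×2.6,
kon_Raf ×6; `nrg1_over` constant 50 ng/mL NRG1; `her3_mab` k8on → 0;
`pi3k_inhibited` k_pi3k_act ×0.2; `pik3ca_dependent` wAKT ×4, w11 ×0.25 and
km_pi3k ×0.01 (constitutively active, receptor-independent PI3K — the reason
that phenotype resists lapatinib but responds to PI3K inhibition). The
optional exposure-driven potency-decay hook for acquired resistance is off by
default.

## Numerical choices

* Stiff integration with LSODA, rtol 1e-6 and per-species absolute tolerances
  scaled to each species' magnitude (receptor counts ~1e6, PK amounts ~1e3
  nmol, in vivo cell numbers ~1e7); dosing and stimulus events split the
  horizon into segments.
* States are clamped non-negative inside the rate kernel and on output
  (clamping at solver tolerance, not reflecting boundaries).
* Steady-state initialization integrates the ligand/drug-free system in
  growing chunks until the maximum relative derivative falls below 1e-8/h
  (default horizon 10,000 h); the tumor-size state is excluded from the
  criterion and reset afterwards.
* The packed right-hand side is a single numba-compiled interpreter over law
  codes; a naive per-reaction Python interpreter provides an independent
  evaluation path and the two are cross-checked at random states to ~1e-12.
* Reversible processes are single reactions with forward/reverse rates;
  stoichiometric coefficients may be non-integer (DAR, unit conversions).
* TGI is baseline-corrected, `100·(1 − (Vt − V0)/(Vc − V0))`, clipped at 100
  so regression below baseline reads as complete inhibition; the
  ratio-of-volumes form is available as an option.

## What the synthetic data emulate — and what they do not

The fixture generator reproduces the *structure* of the study's data:
immunoblot-style relative phospho series (n = 3 replicates, multiplicative
lognormal noise, normalized to max or control), dose–viability curves
normalized to untreated wells, plasma concentration samples with proportional
error, and tumor volumes measured every three days from an 80 mm³ start with
a 10% cv. Fixtures carry their generating truth, so recovery and coverage
tests are exact by construction. They do not emulate between-lab batch
effects, digitization error of literature curves, inter-animal growth-rate
heterogeneity, or censoring by humane endpoints — passing recovery tests
therefore demonstrates correctness of the estimation machinery, not
robustness to real-world measurement pathology.

## Problem sizes used by the test and acceptance runs

Desk-scale sizes, chosen as the package's own defaults: PRCC at n = 500
(5000-sample runs remain available through `SensitivitySpec(n=5000)`), Sobol
base 512 on toys, bootstrap coverage with 20 resamples of a three-arm
21-day xenograft design, pattern-search budgets of 150–220 polls, and
synergy/TGI grids of 3–4 doses per drug over 62 days.

## Known limitations

* One representative-cell tumor: no spatial structure, no subclonal
  evolution (acquired resistance is available only as the optional
  potency-decay hook), no immune compartment, no toxicity models.
* Human PK, allometric scaling and PK-level drug–drug interactions are out
  of scope; mouse PK parameters are provisional shape-calibrated values.
* STAT and PLC-γ branches and ER cross-talk are not modeled; the
  ErbB-independent growth of low-HER2 lines is summarized by a single basal
  signal offset.
* The ligand-saturation structure means ligand-binding rates are only
  informative (for sensitivity analysis) at sub-saturating concentrations.
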