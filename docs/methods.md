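# Methods

This note documents the models, algorithms and numerical choices behind
`vplung`, and what its synthetic experiments can and cannot show.

## 1. Steady-state multi-compartment gas exchange

The lung is modelled as `n_comp` parallel alveolar compartments (default
100 for physiology studies, 20 for patient matching) plus an anatomical
shunt and a serial dead space. Each compartment `i` receives alveolar
ventilation `V̇_i` and perfusion `Q̇_i`:

* total alveolar ventilation `V̇A = (VT/1000 − VD) · RR` (L/min) is split
  over *open* compartments in proportion to the inverse flow resistance;
* cardiac output `Q̇ = SV · HR / 1000` (L/min) is split over *all*
  compartments in proportion to the inverse vascular resistance, after
  removing the anatomical shunt fraction `f_s`.

Per-compartment resistances are deterministic log-normal quantiles
`exp(μ + σ · Φ⁻¹((i − ½)/n_comp))`. Quantiles, not random draws, keep
the simulator bit-reproducible: the distribution parameters (μ_fr, σ_fr,
μ_vr, σ_vr) are the fitted objects. The two marginal distributions are
paired through a fixed low-discrepancy (bit-reversal) permutation, so
ventilation and perfusion heterogeneity act as independent axes of V/Q
mismatch and a closed compartment carries an approximately proportional
perfusion share. ARDS-like deterioration is expressed by *closing* the
`n_cc` compartments of highest flow resistance: a closed compartment
keeps its perfusion but loses all ventilation (complete alveolar shunt).

Blood gas relations:

* O2 saturation: Severinghaus form `S(P) = 1/(1 + 23400/(P³ + 150P))`;
* O2 content: `C_O2 = 1.34 · Hb · S(P) + 0.003 · P` (mL/dL);
* CO2 content: linearization `C_CO2 = 0.45 · P_CO2 + 26.7` (mL/dL),
  adequate in the physiological range 25–80 mmHg;
* pH: Henderson–Hasselbalch with fixed bicarbonate 24 mmol/L
  (`pH = 6.1 + log10(24/(0.03 · PaCO2))`); metabolic acid–base is out of
  scope.

Steady state couples three balances: a per-compartment gas balance
`V̇_i·1000·(F_IO2 − P_A,i/(P_B − P_H2O)) = 10·Q̇_i·(C(P_A,i) − C_v)` for
O2 (and its CO2 analogue), flow-weighted mixing of end-capillary and
shunted venous blood into arterial blood, and the Fick updates
`C_vO2 = C_aO2 − V̇O2/(10 Q̇)`, `C_vCO2 = C_aCO2 + RQ·V̇O2/(10 Q̇)`.

Numerics: the CO2 system is linear in contents and is solved in closed
form. The O2 system is solved by fixed-point iteration on the
mixed-venous O2 content (relative tolerance 1e-6, max 200 iterations;
the map is a contraction because `dC_a/dC_v < 1`); each iteration solves
every compartment's monotone balance by 50-step bisection on
`P_A ∈ [0.5, F_IO2·(P_B − P_H2O)]` (resolution below 1e-9 of the
bracket). Content inversion (arterial and venous PO2 from content) uses
60-step bisection on [1e-3, 900] mmHg. A result is `converged` only if
the fixed point met tolerance *and* the ventilation-side O2 uptake
matches V̇O2 within 1%. Demand that cannot be met (venous content would
fall below 0.05 mL/dL) raises an error; `VT ≤ VD` (no alveolar
ventilation) and `n_cc ≥ n_comp` are rejected up front. With total shunt
and zero V̇O2 the arterial state equals the initial venous state (PO2 40,
PCO2 46 mmHg) — there is nothing to exchange.

PEEP, end-inspiratory pressure, I:E ratio and temperature are carried as
data but do not enter the gas-exchange core; airway/cardiovascular
mechanics and intra-breath dynamics are deliberately out of scope.
The numerical core is JIT-compiled (numba); one 20-compartment steady
state costs ~0.2 ms.

## 2. Matching the model to a patient

Each eligible patient is matched in two windows around the suspected
ARDS onset t0: window 1 = [t0−48 h, t0−24 h) (assumed steady pre-ARDS
state) and window 2 = [t0, t0+24 h) (assumed steady ARDS state); the day
in between is treated as transient and excluded.

The objective is the mean over charted timestamps of the squared scaled
residuals of PaO2, PaCO2, SaO2 and pH (scales 10 mmHg, 4 mmHg, 0.02,
0.04 — roughly twice a modern analyzer's repeatability, making the four
residuals commensurate); the simulator runs per timestamp with that
timestamp's charted FiO2, VT, RR and HR. Non-converged or infeasible
simulations add a fixed penalty of 1e3. Identical input tuples within a
window share one steady-state solve.

Window 1 fits all 11 parameters (f_s, RQ, VD, V̇O2, SV, I:E, μ_fr, σ_fr,
μ_vr, σ_vr, n_cc) over a physiological box (f_s 0.01–0.35, RQ 0.7–1.0,
VD 0.10–0.30 L, V̇O2 150–400 mL/min, SV 40–120 mL, I:E 0.25–1.0, μ ±1,
σ 0–0.8, n_cc 0–95 per 100) with a budget of 100 objective evaluations;
n_cc is relaxed to a continuous coordinate and rounded on evaluation.
Window 2 re-fits n_cc alone (exhaustive scan from the window-1 value to
n_comp−1) with everything else frozen, so progression is summarized by a
single interpretable parameter. A window's fit is *acceptable* when
every simulated gas mean lies within 2 sample SDs of the charted mean
(objective scales replace the SD when fewer than 3 rows are charted).
Patients acceptable in both windows contribute 18 model-derived
features: the 11 fitted parameters, n_cc of window 2, Δn_cc, total
alveolar ventilation and total shunt fraction per window, and
mixed-venous O2 saturation after onset.

### Identifiability

Arterial gases constrain only parameter combinations. Two structural
ridges matter: (i) V̇O2 and VD both enter through V̇O2/V̇A and are exactly
degenerate unless delivered tidal volume varies within the window (the
synthetic charts include ±8% per-8h-block VT fluctuation, which real
pressure-regulated ventilation produces, so this ridge is broken);
(ii) f_s and SV trade off through the mixed-venous content — the data
pin approximately `f_s·V̇O2/Q̇`, so f_s is recovered only up to the SV
search range. The I:E ratio does not influence a steady-state model at
all; its fitted value (and, weakly, the resistance-distribution
parameters) are noise-like coordinates. These are properties of
matching a steady-state model to arterial data, not implementation
artifacts; noise-free recovery experiments show median f_s errors right
at ~0.05 with low-stroke-volume (cardiac-failure-like) patients the
dominant error source.

### Surrogate optimizer

A compact RBF-surrogate global optimizer performs the window-1 search:
Latin-hypercube initialization (24 points in 11-D), thin-plate-spline
interpolation of the evaluated objective (clipped at its 90th percentile
so penalty plateaus do not warp the surface), and one new evaluation per
iteration chosen either from a scored candidate pool (1000 uniform + 500
local Gaussian candidates; the score blends predicted value with
distance to evaluated points, cycling weights 0.9/0.6/0.3 and local
spreads 0.15/0.05/0.015 of the box) or, every third iteration, by
L-BFGS-B descent on the surrogate from the incumbent. The final 10
evaluations exploit only. All randomness descends from one seed; fits
are exactly reproducible.

## 3. Synthetic multi-hospital cohorts

Real multi-center ICU extracts cannot be redistributed; the generator
produces cohorts with the structural features that drive the analysis,
with known ground truth.

**Hospitals.** Three profiles (70/65/65 patients by default) differing
in blood-gas analyzer offset (PaO2 +5/0/−5 mmHg), PEEP policy
(offset 0/+2/−2 cmH2O, each patient additionally ±1 cmH2O clinician
discretion), FiO2 charting grid (0.05), charting interval (2/4/8 h),
tidal-volume policy (6/7/8 mL/kg) and case mix. Measurement effects are
applied after simulation and never touch the random stream, so
zero-effect reruns are pointwise comparable (each charted PaO2 differs
by exactly the offset).

**Archetypes.** Each patient draws a latent configuration from one of
four libraries: *ards* (f_s 0.03–0.10, n_cc 0–10% before onset rising to
30–60% at onset), *cardiac* (SV 35–55 mL, HR 90–115, f_s 0.06–0.11, V̇O2
160–220; at onset SV falls to 45–60% — closed compartments unchanged),
*copd_like* (VD 0.22–0.30 L, strong flow-resistance heterogeneity
σ_fr 0.4–0.8, moderate n_cc increase 15–28%), *control* (mid-range
physiology with a moderate non-ARDS deterioration, e.g. post-operative
atelectasis, n_cc +15–28%). Remaining ranges are mid-range ICU values
(RQ 0.75–0.95, V̇O2 180–250 mL/min, SV 70–100 mL, HR 72–96). The free
ranges were fixed once, by direct steady-state calculation, so that
pre-onset P/F sits above 300 mmHg and post-onset P/F below it for the
large majority of deteriorating patients — the conditions the onset rule
presupposes. 60% of true-ARDS patients carry the J80 diagnosis code
(under-diagnosis); cardiac and copd_like patients carry I50/J44 with
probability 0.85; unrelated comorbidity codes are sprinkled in.

**Charts.** BGA and ventilator rows are emitted on the hospital's
charting grid over [t0−60 h, t0+36 h]. Settings change per 8-hour block
(FiO2 ±0.02, RR ±3, HR ±5, delivered VT ±8%), emulating routine
titration — which is also what makes the matching problem identifiable.
The deterioration completes within the last charting step before t0 (t0
is drawn on the charting grid): with any slower ramp the charted P/F
crosses 300 mmHg well before the full ARDS state (the dissociation-curve
plateau makes P/F fall early), and the operational onset would
systematically precede the modelled one; the window design still
excludes the full day before t0 as transient. Gaussian measurement
noise (PaO2 5 mmHg, PaCO2 2 mmHg, pH 0.02, SaO2 0.01, P_insp 1 cmH2O)
is added to charted values.

**Not emulated:** missing data, unit mismatches between hospitals,
drugs/fluids, imaging, multi-organ physiology, stays beyond the ±3-day
analysis window, time-varying parameters other than the onset step.
Passing tests on these cohorts therefore shows the pipeline's logic is
correct and that the bias/enrichment phenomena can be produced and
detected — not that real ICU data behave this way.

## 4. Preprocessing

Inclusion: adult age bin and cumulative invasive ventilation ≥ 24 h.
k-anonymity: an interval of any binned biometric with fewer than 8
patients is suppressed entirely; any patient whose 4-way bin combination
cell holds fewer than 10 patients is suppressed (empty cells are
ignored). Suspected onset: the first charted time with P/F < 300 mmHg
that stays below threshold for ≥ 24 h, judged on charted rows with
last-observation-carried-forward; a charting gap over 12 h breaks the
run. Windows are half-open; patients without blood gases in either
window are ineligible. Raw features are per-window means of the 10
charted variables (20 features).

## 5. Consensus clustering and statistics

Features are z-scored per column (mixed units would otherwise dominate
Euclidean distances). For each of `n_resamples` resamples (pipeline
default 200; 1000 at full scale) an 80% subsample is clustered once by
k-means (k-means++ seeding, one run — the resampling supplies the
perturbation; purely random seeding of single runs loses separable
structure). The consensus index of a pair is the fraction of co-sampled
resamples in which it co-clustered; never co-sampled pairs are stored as
0 and flagged. The final partition cuts an average-linkage hierarchy of
1 − D at k; the linkage is computed directly with Lance–Williams updates
and a deterministic tie rule (prefer the merge with the smaller combined
size, then lowest indices), which keeps the exactly-tied rational
distances of small consensus matrices reproducible (the partition agrees
with standard library linkage away from ties). An item whose mean
consensus with its own cluster's other members falls below τ = 0.5 is
labelled an outlier and excluded from cluster statistics. Cluster
consensus m(k) is the mean pairwise consensus within cluster k
(singletons: 1); clustering quality is the unweighted mean of m(k).
Quality versus k is assessed by repeating the whole procedure 100 times
on 80% subsamples (100 inner resamples per repeat), reporting mean ±
1.96·SE, and the raw/model arms are compared per k by a two-tailed
Welch t-test on the 100 quality samples.

Enrichment of each (cluster × diagnosis code) and (cluster × hospital)
pair uses the one-sided upper-tail hypergeometric probability, with
Benjamini–Hochberg correction applied within each family (all condition
tests together; all hospital tests together) at α = 0.05. Outliers are
excluded from both the population and the clusters. Both clustering
arms cover the same acceptably-fitted patients: the comparison contrasts
two representations of one population.

## 6. Pipeline defaults and problem sizes

The default study is 200 patients across 3 hospitals, 20 model
compartments for matching, a 100-evaluation fit budget, 200 consensus
resamples, k = 5 final clusters and a quality curve over k = 2…7 — a
desk-scale configuration that completes in roughly ten minutes on one
CPU while preserving every qualitative mechanism. All knobs live in the
YAML run configuration.

## 7. Known limitations

* f_s/SV (and the residual resistance-shape parameters) are only weakly
  identifiable from arterial gases; fitted values of I:E are
  uninformative by construction. Model-derived features therefore
  contain noise-like coordinates, which depresses the model arm's
  consensus.
* On synthetic cohorts the two arms' clustering stabilities are close
  (within ~0.05 of each other, order varying with the seed): the
  synthetic hospital fingerprint is low-dimensional and nearly
  categorical after window averaging, so hospital-driven raw clusters
  can be *stable as well as biased*. The robust synthetic findings are
  the bias-reduction ones: raw-arm clusters dominated by hospital
  enrichment, a diagnosed-ARDS-enriched model-arm cluster with the
  largest mean Δn_cc, and markedly weaker hospital enrichment in the
  model arm.
* The 2-SD acceptability rule depends on charting density; sparsely
  charted windows fall back to fixed scales.
* The CO2 content linearization and fixed-bicarbonate pH are first-order
  conveniences; they bound PaCO2-related conclusions to the normal
  acid-base range.
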