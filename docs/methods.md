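# Methods

This note documents the statistical models behind resistkit, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that affect results.

## RNAi screen scoring

**Model.** Each gene g is targeted by k siRNA reagents (default 3), each
measured in a drug arm and a vehicle arm of a plated viability assay.
Raw luminescence is normalized per plate and arm to the median of that
plate's negative-control wells, removing multiplicative plate effects.
The per-siRNA experimental value is

    x = log2(drug-arm fraction of control)          (default), or
    x = log2(drug-arm / vehicle-arm fraction of control)   (ratio mode).

Per-gene values aggregate the k siRNA x values (median by default;
mean and second-best selectable), and the screen statistic is
z = (x − μ)/σ with μ the **median** over all scored genes and σ the
ordinary standard deviation (ddof = 1), computed once over the whole
screen. The hybrid median/sd convention is deliberate: the median
center is robust to the hit tail, while σ keeps the familiar
standard-deviation scale. A MAD-based σ is intentionally not the
default. Scores are reported sensitivity-oriented (positive z =
knockdown sensitizes, i.e. stronger viability loss under drug), and the
sensitive/resistant lists are called at z ≥ +2.5 / z ≤ −2.5, both
inclusive. The partition sensitive + resistant + neutral always equals
the number of scored genes, and the median of all z is exactly 0.

**Why the drug arm is the default x.** In a paired-arm design the
vehicle arm measures reagent-intrinsic (drug-independent) viability
effects. When those are negligible — as in the generator's model, where
vehicle wells carry only technical noise — dividing by the vehicle arm
doubles Var(x) without removing any bias, and the screen's effective
signal-to-noise halves: at planted effects of 3× the assay noise, the
2.5σ threshold then cannot deliver both ≥90% recall and ≤10% empirical
FDR (the 40 planted hits inflate σ by ~1.24×, leaving a null tail of
~4–5 false calls against ~39 true ones; with the ratio the hit z drops
from ≈4.7 to ≈3.2 null-SDs and the operating point becomes infeasible
in expectation). Screens with appreciable off-target toxicity should
use `mode="ratio"`, which cancels reagent-intrinsic effects exactly.

**Aggregation.** The median of three siRNAs is the default because a
single off-target reagent cannot move it. With exactly three values
"second-best" (the second-strongest sensitizer) coincides with the
median.

**Enrichment.** Over-representation of a gene set in a hit list is the
upper tail of the hypergeometric distribution (scipy), after
intersecting the set with the screen universe; q-values are
Benjamini–Hochberg (statsmodels). On universes small enough to
enumerate, the p-value equals the exhaustive subset-count probability
to machine precision (tested).

## Screen generator

The generator emulates a genome-scale paired-arm library: 3 siRNA
copies per gene laid out as 3 replicate plate sets (copy k of every
gene at the same position of plate set k — the standard organisation of
multi-reagent libraries, which lets per-gene summaries average over
plate effects), with two control columns per 384-well plate
(control_fraction = 1/12). Planted sensitizers/resistors shift the
drug-arm log2 viability by a configured effect; noise is Gaussian on
the per-siRNA log2 viability ratio with SD `noise_sd` (each arm draws
noise_sd/√2 so the ratio carries exactly noise_sd). Defaults follow the
recovery conditions used throughout the tests: noise_sd = 0.5 log2
units, effects ±1.5 (= 3× noise), one well per arm per siRNA. The
drug-arm baseline sits at 70% control viability (an ~EC30 drug dose).
Hit placement is randomized so planted hits are not confounded with
plate position. What the generator does **not** model: off-target
(seed-sequence) effects, reagent-intrinsic toxicity, spatial
within-plate gradients, or edge effects — so passing recovery tests
demonstrate the statistics under clean technical noise, not robustness
to those artifacts (the ratio mode and robust aggregation exist for
real data precisely because of them).

## Dose-response analysis

**Model.** Viability as fraction of untreated control follows the
four-parameter logistic; fits minimize least squares (scipy
`curve_fit`, trust-region-reflective) with bounds 0 ≤ bottom ≤ top ≤
1.2 (CellTiter-Glo fractions can slightly exceed 1), hill ∈ [0.1, 10],
and log10 IC50 within ±3 decades of the tested range. The model is
parameterized as (bottom, span, hill, log10 IC50) so bottom ≤ top holds
by construction. Initialization is data-driven (top = max, bottom =
min, IC50 = dose nearest half-range); tolerances are tightened to
1e-15 so noise-free curves recover IC50 to ~1e-9 relative. Replicates
are averaged per dose before fitting (pooled fitting selectable). IC50
is the curve midpoint (relative IC50).

**Censoring.** A fit is censored when the curve never crosses its own
midpoint within the tested range (or the IC50 lands >10× outside it);
the stored IC50 is then the relevant dose-range bound. Flat fits
(span < 0.05) censor by overall level: above_max_dose when mean
viability > 0.5, else below_min_dose. Non-convergence produces a
censored fit with a diagnostic, never an exception.

**ECk.** The dose giving k% inhibition, by closed-form inversion of the
4PL. The default reference is absolute (v = 1 − k/100, the reading of
"sensitizer at its IC15"); a relative mode (k% of the top→bottom span,
for which ec_k(50) ≡ IC50 for any top/bottom) is available. Requests
outside the achievable span return a censored value.

**Fold-change classification.** Per drug: fold = IC50(resistant,
single)/IC50(parental, single); resistant iff fold > 5, strictly.
Folds involving one censored IC50 become one-sided bounds (qualifier
">" or "<") and are classified conservatively — a bound only triggers a
call if the bound itself clears the threshold. Both IC50s censored in
the same direction → category "indeterminate". Every drug receives
exactly one of {resistant, more_toxic_to_resistant (fold < 1/5),
unchanged, indeterminate}. Reversal (fold of resistant-line IC50,
single vs sensitizer combination, > 5) is evaluated only for resistant
drugs. Calls are invariant to dose units and monotone in upward
resistant-IC50 shifts (tested).

## Dose-response generator

Per drug: parental IC50 drawn log-uniformly from 30 nM–3 µM (or given),
resistance fold log-uniform 2–100×, reversal fold log-uniform 1–50×,
Hill slope 1, Gaussian noise SD 0.05 on the viability fraction, clipped
to [0, 1.2]. Wells are simulated in triplicate, the design used by the
assays this emulates. The dilution series is anchored per drug at 100×
the parental IC50 (panels titrate each compound around its own
potency); a common absolute top dose is available but leaves strongly
shifted resistant curves outside the tested range, where only censored
bounds are recoverable. Note the intrinsic precision limit: a fully
free 4PL on 7 single-replicate points at 5% noise has a median |log2
IC50| error of ≈0.27 regardless of optimizer (verified by multistart);
triplicates bring this to ≈0.15.

## Bliss synergy

Inhibition is E = clip(1 − v/control, 0, 1); clipping precedes the
Bliss formula because Additive = E1 + E2 − E1·E2 is a probability
statement and requires arguments in [0, 1]. The sensitizer's E2 is
dose-independent (it is given at one fixed concentration, its IC15).
Per-dose excess = E_obs − Additive ∈ [−1, 1]. A combination is called
synergistic when mean excess > 0.1 **and** excess > 0 at ≥50% of doses;
both thresholds are exposed because "synergistic" has no universal
numeric criterion — these defaults are this package's choice. The CI on
mean excess is a seeded percentile bootstrap over doses (default 1000
resamples). Under the generator's independent-action null
(multiplicative survival, 5% noise) the mean excess is unbiased to
within 0.002 at 10,000 replicates and the caller's false-call rate is
≈0 at defaults; the clipping-induced bias at extreme doses (where E ≈ 0
or v is clipped) stays well inside the ±0.02 budget. Loewe, ZIP, HSA
and checkerboard designs are out of scope.

## FRET imaging

Cells are segmented per frame by Otsu's global threshold (intensity-
scale invariant) with components < min_area_px (default 20) removed,
linked across frames by greedy nearest-centroid matching within
linking_max_dist_px (default 10; exact ties break toward the lower
label id, logged). The FRET ratio is mean YFP / mean CFP within the
cell mask, defined only where CFP > 0, and invariant to common channel
scaling. Activation is called at the first frame where the ratio falls
to ≤(1 − drop_fraction) of the cell's baseline (median of the first 3
frames) and stays there for ≥2 consecutive frames; drop_fraction
defaults to 0.3, a documented package choice rather than an established
cutoff. Because the call lands on the first frame at or after the true
switch, estimated times carry a positive bias of up to one frame
interval; the median absolute error on noisy synthetic movies is within
one frame. The movie generator renders cells as isotropic Gaussian
spots truncated at their 3σ support (so masks are exactly disjoint and
segmentation counts are exact on noise-free frames), placed by
rejection sampling with ≥6σ separation; on activation the YFP amplitude
scales by √(1 − ratio_drop) and CFP by its inverse, dropping the ratio
by exactly ratio_drop while approximately conserving total brightness.
Not modelled: bleed-through, photobleaching, cell movement, division,
or overlap — the tracking is therefore deliberately simple.

## Assay statistics

ΔRFU = (RFU2 − iRFU2) − (RFU1 − iRFU1) subtracts inhibitor-resistant
(non-proteasome) background proteolysis at each timepoint; it is
invariant to a common offset in all four reads and, on noise-free
simulated kinetics, equals signal_rate × (t2 − t1) exactly. Tumor
volume V = a²b/2 with a = width ≤ b = length; measurement pairs arriving
in the wrong order are swapped with a logged warning (calipers are
order-ambiguous), and non-positive inputs are rejected.

## Pipeline, formats, reproducibility

All tabular interchange is CSV with `# key: value` provenance headers
(config hash, seed, package version); gene sets are GMT; image stacks
multi-page TIFF per channel; run configuration YAML. Every generator
and every stochastic analysis step takes an explicit integer seed — no
global random state anywhere — and `run_pipeline` re-runs
byte-identically from the same config and seed. The pipeline's demo
configuration (500-gene screen, 12-drug panel, 10-cell movie) completes
in a few seconds on one CPU; the test suite and the acceptance script
use the same problem sizes as the documented recovery conditions
(2,000-gene screens, 30-drug panels, 12-cell movies, 10,000-replicate
Bliss nulls).
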