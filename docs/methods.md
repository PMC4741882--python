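# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic data do and do not establish.

## Relative quantification model

Each qRT-PCR reaction yields a 45-cycle fluorescence series. The curve is
modelled as a four-parameter logistic,

    F(c) = B + A / (1 + exp(-(c - m)/s)),

with baseline `B`, amplitude `A`, midpoint `m` and shape `s`. In the early
exponential phase the signal grows by `Eff = exp(1/s)` per cycle, so `s`
encodes the amplification efficiency. The crossing cycle is called at the
**second-derivative maximum (SDM)** of the curve, which for the logistic is
analytic:

    Ct = m - s * ln(2 + sqrt(3)),

the root of the third derivative. `sdm_ct` fits the logistic to all 45
cycles by least squares (`scipy.optimize.curve_fit`, initialized from the
half-maximum crossing) and evaluates this expression. We chose the model
fit over discrete second differences of a smoothed series deliberately:
on noise-free synthetic curves the discrete route carries a bias of about
a quarter of a cycle (the second-derivative peak is sharp and asymmetric
relative to the 1-cycle sampling grid), and under a few percent of
amplitude noise its argmax can jump to baseline noise spikes. The model
fit is exact on noise-free curves and degrades gracefully with noise
(98–99% of calls within 0.3 cycles at 2% amplitude noise). Curves whose
dynamic range stays below `min_amplitude` (default 0.05 fluorescence
units) or that admit no rising sigmoid in the cycle window are censored
(`NaN`).

**Efficiency.** `estimate_efficiency` regresses `log(F - B)` on cycle
number over the window where the baseline-subtracted signal lies between
1% and 15% of the amplitude. Even there the logistic is not perfectly
exponential: the log-slope at signal fraction `σ` is `(1/s)(1 - σ)`, so
the raw slope is divided by `1 - mean(σ)` before exponentiating. This
first-order curvature correction brings recovery on noise-free curves to
within ±0.03 of truth over Eff ∈ [1.6, 2.0]. Reactions without at least 3
usable window points fall back to Eff = 2.0 with a logged warning;
per-system efficiency is the median over reactions.

**Relative expression.** With per-cohort ceilings applied first (values
strictly greater than the ceiling are clamped to it and flagged censored;
a value exactly at the ceiling is kept), relative expression is

    RE = Eff^(Ct_min_series - Ct_sample),

so the sample with the lowest Ct per system has RE = 1. REs are divided by
the geometric mean of the three housekeeping REs (G6PD, GAPDH, HPRT);
samples with a censored or non-positive housekeeping value are excluded
with a log entry. Finally the whole batch is rescaled so its lowest
positive normalized value is exactly 1. The "series" for both the
per-system minimum and the final rescaling is the full input table;
callers wanting per-cohort batches simply quantify each cohort table
separately. Censored reactions keep their ceiling-derived RE (they form
the floor of the scale) rather than being dropped.

## Positivity calling

A sample is positive for a system when its scaled RE **strictly exceeds**
`mean + 3·SD` of the normal-tissue samples of that system. The SD is the
sample standard deviation (ddof = 1, configurable). Thresholds are
computed from normal colon tissue only, pooled across cohorts. When all
normals share one value (everything censored at the floor) the threshold
is nudged by 1e-9 so floor-valued tumors are never called positive. By
construction the false-positive rate on Gaussian-like normals approaches
the three-sigma tail, P(Z > 3) ≈ 0.135%.

## Group statistics

Group comparisons use Welch's unequal-variance t-test (Satterthwaite
degrees of freedom; Student's pooled form behind a flag). Stars follow
the usual strict coding (* p < 0.05, ** p < 0.01, *** p < 0.001). The
default test scale is the raw scaled RE; a `log2(RE + 1)` transform is
available and **recommended** whenever expression spans orders of
magnitude — on the synthetic cohorts, whose expressed REs are
log-uniform over ~2.5 decades, raw-scale tests have very little power
and the log scale restores it. No multiple-testing correction is applied
by default. The paired tumor/normal structure is not exploited by
default; a combined per-sample HERV-H value collapses the target systems
by `max` (default), `mean` or `sum`.

## Panels

Panels combine binary calls with the any-positive (OR) rule only.
Sensitivity and specificity are apparent (in-sample) proportions against
a case and a control tissue class, with Wilson 95% intervals
(statsmodels). `select_top_expressed` ranks target systems by positivity
frequency in the case class, breaking ties by mean scaled RE and then by
name.

## Insertion dating

A locus present in the human genome and in the orthologous position of
another primate predates their divergence, so its age is approximated by
the split age of the **most distant carrier species**. Presence is
`coverage ≥ 0.5` (boundary inclusive) of the human sequence by that
species' alignment; an optional flanking-sequence identity check
(ungapped, ≥ 0.7 over 500 bp, N positions excluded) guards against
non-orthologous alignments — random DNA scores ≈ 0.25 and fails it.
Non-contiguous presence rows (a gap below the defining species, e.g. a
lineage deletion) are still aged by the most distant carrier, with a
warning.

Split ages ship as a built-in table of approximate literature values
(Steiper & Young 2006; Locke et al. 2011), replaceable by a
species/split_age TSV or an ultrametric Newick tree. One caveat: the four
Old World monkeys of the panel share a single catarrhine node near 29–30
My; the built-in table staggers them by 0.3 My purely to satisfy the
strictly-ordered lineage model. Any analysis that treats those four ages
as distinct is over-reading the table.

Category age distributions are compared with the two-sided Mann–Whitney
rank-sum test, implemented in-package: exact enumeration of the null
distribution of U (standard counting recurrence) when both groups have
≤ 8 observations and no ties, otherwise the normal approximation with tie
and continuity corrections. The exact and approximate branches agree to
within 0.02 at 8-vs-8.

## Chromatin-mark overlap

Peak coordinates follow the BED convention (0-based, half-open,
strand-agnostic). The score of an LTR for one mark in one cell line is
the fraction of the LTR covered by the union of that experiment's peaks
(peaks are merged first, so bases are never double counted); the mark
score is the arithmetic mean over cell lines with data. Coverage fraction
was chosen over peak-signal averaging because it is reproducible without
peak score columns; a signal-weighted mode would need scored BED input.
Activating vs repressive mark sets default to
{H2az, H3k4me1/2/3, H3k9ac, H3k27ac} and {H3k9me3, H3k27me3} and are
configuration, not hard-coded. Category enrichment reuses the rank-sum
test above.

## Synthetic cohort generator

The generator emulates the *structure* of a two-center paired study, not
any real cohort's distributions (no per-sample clinical data exist to fit):

- 99 + 40 tumor/normal pairs in two cohorts with Ct ceilings 33 and 32;
- five target loci with tumor positivity probabilities 0.50, 0.33, 0.27,
  0.22, 0.17 (the observed frequency ordering), zero in normal colon;
- MSI prevalence 0.22; MSI boosts of +0.40/+0.45/+0.43 at the X, chr20
  and chr14 loci; node-status boosts of +0.30/+0.12 at the chr5 and chr20
  loci. These effect sizes were fixed by a design-time power analysis so
  that a 139-pair cohort detects the boosted associations with high
  probability, matching the strength of association such studies report;
- a constitutive family-level positive control (0.65 in tumor and
  normal), an essentially absent negative control (0.005), and tumor
  markers MMP7/OPN at 0.63/0.79 in tumors;
- expressed reactions draw Ct uniformly from 22–30; censored reactions
  sit exactly at their cohort ceiling; housekeeping Cts are N(20, 1);
- probability lookup is by decreasing specificity:
  (system, tissue, msi, n) → (…, msi, \*) → (…, \*, n) → (…, \*, \*);
  boosts are therefore overriding, not additive.

Amplification curves are noiseless or Gaussian-noise logistics with the
midpoint placed so the analytic SDM equals the requested Ct. Presence
matrices sample an insertion node per locus from a per-category
distribution (tumor-specific loci young — hominine nodes; silent and
constitutive loci older; gonadal in between) and are phylogenetically
consistent in clean mode; a dropout mode simulates orthology-check
failures. Peak simulation plants an LTR-covering peak with the
category/mark-dependent probability and records ground truth.

**What passing tests do not show.** Real amplification curves are not
logistic (drift, plateau slopes, competition), real normal tissue is not
exactly silent, real Ct distributions are not uniform, and real histone
peaks are not independent across cell lines. The tests establish that the
arithmetic, the calling rules and the statistics do what they claim on
data whose truth is known — not that the biological effect sizes are as
simulated.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 1,000 random Ct tables
for the quantification oracle; 500 + 500 synthetic curves for Ct
recovery; 5,000 fit / 50,000 held-out normals for threshold specificity;
one 139-pair cohort plus 200 replicate null cohorts for association
calibration; 10,000 samples for panel algebra; exhaustive enumeration up
to 8-vs-8 for rank-sum exactness; 1,000 loci for age recovery; and
10,000 random instances for the interval oracle. The whole suite runs in
well under a minute of compute plus the ~15 s null-replicate loop.
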