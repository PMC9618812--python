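# Methods

This note documents the statistical model behind `mirpredict`, the
choices made where the underlying clinical analysis left the design
open, and what the synthetic experiments do and do not establish.

## The prediction problem

The target outcome is binary: complete remission with bone-marrow
undetectable minimal residual disease (CR + BM uMRD) after first-line
FCR in B-CLL. The predictors are relative blood miRNA expression levels
at diagnosis on the 2^−ΔCt scale (ΔCt = assay Ct minus a per-sample
normalizer). Three facts shape the pipeline: responder status requires
two measurements (CR assessment and marrow flow cytometry), each of
which can be missing; miRNA expression is heavy-tailed and approximately
log-normal; and the clinical deliverable is a small decision tree a
laboratory can apply to a multiplex qPCR readout.

## Screening stage

Two arms of 8 samples each are compared over 384 assays. Ct values are
normalized per sample by the global mean over *detected* wells
(reference-assay normalization is available); relative expression is
2^−ΔCt, and the fold change between groups is the ratio of geometric
means, computed in the log domain, equal to 2 to the difference of mean
ΔCt. Ceiling-censored ("Undetermined") wells are stored at the
40-cycle ceiling with a flag; they are excluded from ΔCt statistics —
a censored well carries no expression value — but they still raise the
group's mean raw Ct, which is what the detection filter sees. The
default per-assay test is the two-sample t on ΔCt (Mann–Whitney and a
Shapiro–Wilk-gated automatic mode are options); assays are called
up/down at fold change ≥ 2.5 (or ≤ 1/2.5) with raw p < 0.05 — no
multiplicity correction at this stage, by design fidelity, with a
BH-FDR column available to users. The detection filter requires mean
raw Ct strictly below 30 cycles in *both* groups; failures are marked,
never deleted. Fold changes are always reported responder over
non-responder.

## Group comparison and ROC

`compare_groups` applies Shapiro–Wilk per group at α = 0.05 (when both
groups have ≥ 3 observations) and uses Student's t only when both
groups pass; otherwise Mann–Whitney. All tests are two-sided. ROC
curves sweep midpoints between consecutive sorted unique values plus
±∞ sentinels; with the default *high-positive* orientation a patient is
called positive when value > threshold, and equality routes negative —
the same boundary rule the decision tree uses, so a fixture threshold
behaves identically in both modules. AUC is the trapezoidal area under
the empirical sweep (tie segments enter as half-counts). The Youden
cutpoint maximizes J = Se + Sp − 1; ties break toward the smallest
threshold, which favors sensitivity under the high-positive convention.
The orientation default reflects the modeled finding that favorable
outcomes carried higher miRNA levels throughout.

Backward logistic selection drops, at each step, the candidate block
with the largest Wald p until all retained blocks are below α_stay
(default 0.05); "t-test on coefficients" is read as the Wald z, which
is what a logistic fit provides. Odds ratios carry Wald 95% intervals.
Perfect separation is flagged and reported as an infinite-OR marker
rather than a fitted number. With α_stay ≥ 1 the full model is
returned; with α_stay ≤ 0 the empty model.

## The decision tree

The root variable is supplied by the analyst (miR-125b by default —
chosen in the modeled analysis because it alone predicted blood uMRD —
with an `auto` mode selecting the overall most significant candidate).
The root always splits; every other node splits only if the most
significant unused candidate (Shapiro–Wilk-gated comparison of its
expression between responders and others *at that node*) reaches
p < α = 0.05 and both children keep at least `min_leaf` = 5 patients,
within `max_depth` = 4 splits per path. Thresholds are node-local
Youden cutpoints — recomputed on the node's patients, not inherited
from the cohort-level ROC. Ties on p break by larger AUC, then
lexicographic id; a variable is consumed along its path. Leaves carry
their empirical responder probability and an H/L path label. These
tie-break and boundary rules (strict > routes high) make construction
fully deterministic.

The published tree fixture stores the five published working
thresholds (miR-125b 0.0005; miR-15b 0.1710; miR-181c 0.0019; miR-193b
0.0113; miR-412 0.0003) and the two published leaf probabilities
(HHH 0.72, LL 0.04). The four middle-leaf probabilities were published
only graphically; the fixture stores placeholder values explicitly
marked `verified=False`, and per-node patient counts, which were never
published, are stored as None.

## Survival

Kaplan–Meier estimation and the k-sample log-rank test (hypergeometric
variance, df = k − 1) are delegated to lifelines; Cox regression uses
statsmodels' proportional-hazards fit with Breslow tie handling —
chosen over Efron because the Breslow partial likelihood is the one an
independent grid-search oracle can verify exactly. Monotone likelihoods
are flagged non-convergent with no fabricated hazard ratio. "Median not
reached" is a distinguished value (None), never an infinity stand-in;
fixed-time readouts use the left-continuous step value with Greenwood
standard errors available. The landmark filter drops subjects with
follow-up shorter than the landmark (default 9 months, the modeled
trial's MRD-assessment instant — stated both as "9 months" and as
"3 months after the end of treatment", reconciled here as one clinical
time point taken as an explicit parameter) and resets survivors'
clocks. Tree groups merge into three prognostic tiers — high {HHH},
intermediate {HHL, HLL, LH}, low {HLH, LL} — following the analysis's
own tier definition; one figure legend instead consolidates
HHL+HLH+HLL+LH, a discrepancy resolved in favor of the stated tiers.

## Cohort accounting

Responder = CR ∧ BM uMRD; no-CR alone suffices for non-responder (so a
no-CR patient without marrow data is still classifiable), while CR with
missing marrow data is unclassifiable. Each outcome is tabulated over
its own evaluable denominator, except CR/no-CR rates, which follow the
modeled study's printed arithmetic of dividing by the full cohort even
when a few patients lack a CR assessment — the one place where printed
percentages and strict evaluable-denominator logic disagree, documented
here and reproduced deliberately. Percentages round half-up to two
decimals; quartiles use linear interpolation (type 7, configurable in
principle via the underlying numpy call).

## Synthetic cohort generator

The generator is the package's test bed and defines its study
conditions. Defaults: 123 patients; 11-miRNA panel with log2-normal
expression (SD 1.5 log2 units, a realistic qPCR spread); a planted
six-leaf tree with the published topology whose split quantiles
reproduce the published high/low group sizes (e.g. 67/123
miR-125b-high) and whose thresholds therefore land exactly on the
published working cutpoints; per-leaf responder probabilities 0.72,
0.35, 0.30, 0.15, 0.20, 0.04 (the first and last published, the middle
four artifact defaults ordered so that each node's high side is the
favorable one); exponential event times with per-leaf hazards derived
from the reported 42.4-month PFS per group (the no-relapse group taken
at 0.99 so its hazard stays positive); administrative censoring at
42.4 months; outcome missingness 4% (CR), 12% (blood MRD), 23% (marrow
MRD), yielding distinct evaluable denominators. Leaf assignment
thresholds each patient's own expression against the planted tree, so
responder ⇔ CR ∧ BM uMRD holds exactly before missingness, and marrow
uMRD always implies blood uMRD. One RNG stream is consumed in the order
expression → outcomes → survival → missingness → covariates.
`path_separation_log2` optionally pushes each patient's path variables
away from their cutpoints (never across), widening the expression gap
around every planted threshold for separation experiments. The
screening generator plants log2 fold changes as Ct shifts on the
responder arm, with per-assay locations uniform on 22–33 cycles, noise
SD 1 cycle and 2% random dropout at the 40-cycle ceiling.

What the generator does *not* emulate: amplification-efficiency
variation, correlated miRNA co-regulation, informative (outcome-
dependent) missingness, non-exponential hazards, accrual-driven
censoring heterogeneity, and covariates genuinely associated with
outcome. Passing tests therefore demonstrate algorithmic correctness
and calibration under the assumed model, not clinical
transportability.

## Validation experiments and their limits

The test suite verifies every stage against independent oracles:
exhaustive cutpoint enumeration for ROC/Youden (1,000 random small
instances), hypergeometric enumeration for Fisher, permutation for
Spearman, hand product-limit and observed-minus-expected computations
for KM/log-rank, and a grid-search Breslow partial-likelihood maximizer
for Cox. Calibration runs check the screening null (significant
fraction ≈ 5% over 100 null cards), planted 4-fold detection at
0.5-cycle noise, logistic selection consistency, and Cox hazard-ratio
recovery (HR 2 within 10% at n = 2000).

Tree recovery is assessed on 20 cohorts of n = 2000: recovery means the
five planted internal nodes appear with the same variable at the same
position (extra data-driven splits below planted leaves are expected —
roughly forty residual null tests at α = 0.05 per cohort — and do not
count as failure). Measured recovery is ~80–85%, below a 90% target,
and the node-local Youden threshold at the two weak-contrast deep nodes
(responder probability 0.72 vs 0.35, and 0.30 vs 0.15) wanders beyond
0.1 marginal SD in a material fraction of runs. This is a property of
the estimator, not a bug: the Youden cutpoint's sampling error at a
~500-patient node shrinks to that tolerance only when the node's
responder-probability contrast is near-binary, and making deep
contrasts near-binary lets grandchild variables outcompete the child
variable at mid-level nodes, flipping the recovered order. The root and
strong-contrast nodes recover their thresholds within ~0.01–0.04 log2
units. These measurements are reported as-is by the acceptance test and
script rather than softened.

## Problem sizes

Default experiment sizes — n = 2000 × 20 seeds for tree recovery,
100 null + 100 planted screening cards, n = 2000 for Cox recovery,
n = 5000–6000 for distributional identities — were chosen as the
smallest sizes at which the asymptotic claims under test are cleanly
separated from sampling noise.
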