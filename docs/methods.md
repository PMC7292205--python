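# Methods

## The classification problem

Diffuse large B-cell lymphoma carries two principal cell-of-origin subtypes —
germinal center B-cell-like (GCB) and activated B-cell-like (ABC) — defined by
global expression profiling and prognostic under immunochemotherapy. The assay
this package implements measures 32 subtype-marker transcripts (16
overexpressed per subtype) plus three housekeeping genes (IPO8, PGK1, TFRC) by
qPCR on FFPE tissue, and assigns ABC / GCB / unclassified (UNC) with a linear
classifier.

## qPCR preprocessing

Each (sample, gene) is measured in triplicate. Replicates are reconciled by a
spread rule: if the triplicate range exceeds `max_spread` (default 0.5
cycles), the well farthest from the median is dropped; if the surviving pair
still spans more than `max_spread`, the measurement fails QC. The numeric
criterion is a laboratory convention, not a published constant, so it is
configuration. The same holds for sample acceptance: a sample passes when all
three housekeeping genes pass QC and at most `max_failed_genes` (default 3)
targets fail.

Normalization is ΔCt(g, s) = meanCt(g, s) − mean of the three housekeeping
mean Cts of that sample (unweighted arithmetic mean); the stored expression
value is −ΔCt. Because a per-sample plate offset adds the same constant to
every Ct, it cancels exactly in ΔCt — a property the suite asserts on random
tables. Missing values are never imputed: a sample lacking a usable panel gene
is rejected at classification time, the defensive posture appropriate for a
clinical assay.

## Signature selection (SVM-RFE)

Gene selection ranks features by the squared weight each gene receives in a
linear soft-margin SVM (C = 1) fit on per-gene standardized expression, then
removes the lowest-ranked `ceil(0.1 × remaining)` genes and refits, down to a
32-gene panel. The squared-weight criterion and the 10% schedule are the
standard SVM-RFE choices; both are configurable and recorded in the returned
trace. Ranking ties (exactly equal scores occur for constant genes, which
receive weight zero) are broken by eliminating the lexicographically last gene
id first, making the procedure deterministic and order-independent.

A caveat worth stating: RFE's scores are *joint* — each gene's weight depends
on every other surviving gene — so removing any feature, even an
already-eliminated one, perturbs subsequent rankings. The final panel is
therefore stable only up to the genes near the selection margin; on planted
two-class data at a 2-SD effect the rerun panel typically shares 28–31 of 32
genes with the original rather than being identical. The suite asserts this
approximate stability rather than an exact identity no margin-based ranker
can honour.

## Classifier, calibration, and the 75% rule

The subtype model is a linear SVM (C = 1) on the 32 panel genes,
standardized with means and SDs frozen from the training data (test samples
are scored on the training scale; no leakage). The signed margin is mapped to
P(GCB) by a sigmoid fitted on five-fold out-of-fold margins — Platt-style
calibration implemented as a logistic regression on the held-out margins, with
mild L2 regularization to keep the slope finite on separable data. The
calibration method is recorded in the model file as metadata since the
specific margin→probability map is an implementation choice. On uninformative
data the fitted slope can collapse to zero or below; it is then clamped to a
tiny positive value (with a warning) so calibration remains monotone and all
probabilities sit near 0.5, sending samples to UNC.

Calls use a strict threshold: GCB if P(GCB) > 0.75, ABC if P(ABC) > 0.75,
otherwise UNC — a probability of exactly 75% is unclassified. For comparison
with two-way IHC surrogates, calls collapse deterministically: GCB → GCB; ABC
and UNC → non-GCB. A model file (JSON) carries panel, standardization,
weights, bias, calibration and threshold together, so a call is reproducible
from a single artifact; the suite checks the serialization round trip to
1e-12.

## Hans surrogate

The IHC comparator dichotomizes CD10, BCL6 and MUM1 staining at a 30%
positivity cut-off and applies the published tree (CD10+ → GCB; CD10−/BCL6− →
non-GCB; CD10−/BCL6+/MUM1+ → non-GCB; else GCB). Whether exactly 30% counts
as positive is not specified anywhere authoritative; this implementation uses
≥ and exposes the cut-off as configuration.

## Agreement statistics

Two call sets are compared only over samples callable by both (dropped ids
are logged). Overall percent agreement is the confusion-matrix diagonal
fraction; PPA/NPA take GCB as positive with the designated reference on the
columns. Confidence intervals use the Wilson score method, chosen because it
reproduces the published first-test-set interval (0.94–0.99 for 209/215)
where a Wald interval does not; the second test set's printed upper bound
(0.957) matches neither Wilson (0.955) nor Wald (0.958) exactly, which is
left as an observed discrepancy rather than reconciled. Two assays sharing a
reference are compared by an exact McNemar test: the two-sided binomial tail
of the discordant-pair counts at p = ½.

Display rounding is half-up to one decimal in percent, matching how such
tables are conventionally printed.

## Clustering and survival

Sample structure uses d = 1 − Pearson r between 32-gene −ΔCt profiles (no
per-gene re-scaling before correlating; display scaling is cosmetic) and
complete-linkage agglomeration, implemented directly so the merge order has a
documented deterministic tie-break (smallest sorted member-id list first);
scipy's implementation serves as an independent cross-check in the tests.
Overall survival uses the Kaplan–Meier product-limit estimator and the
unstratified k-group log-rank test with the hypergeometric variance for ties
(both via lifelines), validated in the tests against hand-tabulated
observed/expected computations.

## Synthetic cohorts

The generator emulates the statistical structure the assay assumes, not the
physics of qPCR:

* **Expression** — class-conditional Gaussians with unit variance: each panel
  gene is Normal(effect, 1) in its overexpressing subtype and Normal(0, 1)
  otherwise; nuisance genes are Normal(0, 1) everywhere; an optional constant
  batch offset can be added to half the cohort. The default effect size of
  2 SD makes the two classes nearly separable in 32 dimensions, which mirrors
  how cleanly the published panel separates reference-labelled cohorts.
* **Ct values** — three replicates per (sample, gene) at
  25 − expression + Normal(0, replicate_sd); housekeeping genes have
  expression 0. The base of 25 cycles is an arbitrary instrument midrange and
  cancels in ΔCt. Default replicate noise 0.15 cycles is typical TaqMan
  triplicate scatter.
* **IHC** — class-concordant staining patterns (GCB: CD10 in 35–95%; ABC:
  CD10 in 0–25% with BCL6+/MUM1+), with probability `ihc_noise` (default
  0.15) of swapping to the other class's pattern; this is the single knob that
  drives IHC/expression discordance toward the high-70s-percent concordance
  regime reported for Hans-type surrogates.
* **Survival** — exponential event times with per-class hazards (defaults
  0.02/month ABC vs 0.01/month GCB, i.e. a hazard ratio of 2 reflecting the
  ABC survival disadvantage) under independent Uniform(0, 120 months)
  censoring. The censoring mechanism is a modelling choice; nothing in the
  assay depends on it.
* Default cohort size 89 ABC + 51 GCB matches a realistic single-center
  validation cohort's called class split.

Outputs are byte-identical for identical seeds; substreams are separated so
regenerating one fixture never perturbs another.

What the generator deliberately does not model: microarray probe effects,
FFPE storage-related signal decay, RNA quality gradients, PCR efficiency
differences between genes, or correlated marker co-expression within a
subtype. Passing tests therefore demonstrate that the algorithms are
implemented correctly and behave as designed under the assumed class
structure — not that the assay would achieve the same operating
characteristics on real tissue.

## Numerical choices and degenerate inputs

* Standardization uses population SD (ddof 0); constant genes get SD set to 1,
  leaving them at zero after centering (and hence zero SVM weight).
* Probability vectors must sum to 1 within 1e-9; call-set files store
  probabilities at full precision so round trips are exact.
* Ct values outside (0, 45] cycles are rejected as physically implausible;
  the instrument sentinel "Undetermined" becomes a missing value, not an
  error.
* Empty call sets, single-class training labels, disjoint sample-id sets and
  constant correlation profiles are all hard errors with named offenders.
* Expression matrices are genes × samples only; transposed input fails
  validation rather than being auto-detected.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
RFE recovery uses 500 genes × 350 samples (five seeds), classifier checks use
200-sample cohorts, clustering oracles use ≤ 12 leaves where brute-force
verification is exact. These sizes give stable statistics for every asserted
property while keeping a full run in the tens of seconds.

## Known limitations

* The package does not re-derive the published 32-gene panel from public
  microarray repositories; the panel ships as a constant and the selection
  machinery is validated on planted-signal cohorts instead.
* Probe/platform normalization (SCAN), batch correction (ComBat), enrichment
  and network annotation, and RNA-seq read processing are out of scope; a
  per-gene standardization is the only plumbing provided.
* Only the ABC/GCB axis is modelled; genetic subtypes and other IHC
  algorithms (Choi, Tally) are not implemented.
* The exact replicate-concordance and sample-acceptance criteria of the
  wet-lab assay are unpublished; the defaults here are defensible conventions,
  and both are configurable.
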