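# Methods

This note records the statistical procedures implemented in `sagarep`,
the conventions and defaults chosen where the design was open, and what
the synthetic-data generator does and does not emulate.

## Setting and notation

Two replicate chromatin-state annotations are compared on a shared
fixed-resolution binned genome: `G` bins of width `resolution` bp
(default 200 bp, the conventional ChromHMM bin width), laid out in
chromosome order with 0-based half-open coordinates. Each annotation
carries per-bin MAP labels `q_g ∈ {0..K−1}` and, optionally, a `G x K`
posterior matrix `P(Q_g = k | X)`. The *base* annotation is scored; the
*verification* annotation is the reference against which reproduction
is judged. The two roles are not symmetric; a symmetric mode runs both
directions and intersects the confident masks.

Bins not covered by any segment, or whose posterior row is all zero,
are flagged missing and excluded from every statistic (they are never
imputed). Segments that do not align to the bin grid contribute their
state to each bin whose midpoint they cover — a deterministic,
resolution-robust rule.

## State matching

Joint label frequencies over jointly annotated bins give
`P(B=k, V=l)`; marginals are genomic coverages. Correspondence uses the
intersection-over-union (Jaccard)

    IoU(k, l) = P(B=k, V=l) / (P(B=k) + P(V=l) − P(B=k, V=l)),

with `0/0 := 0`; each base state is matched to its maximum-IoU
verification state. The map may be many-to-one (it is a row argmax, not
a bipartite matching); argmax ties break to the lowest verification id
and are logged.

A spatial tolerance window `w` (bp, converted to whole bins by ceiling;
never crossing chromosome boundaries) relaxes exact-position agreement:
bin `g` with base state `k` is *reproduced* if the matched state occurs
anywhere in `g ± w`. Matching itself can be computed from the plain
(`w = 0`) joint or from the window-relaxed co-occurrence matrix; the
r-value pipeline defaults to windowed matching while the evaluation
report matches at `w = 0`, and both modes are exposed. The window-
relaxed matrix is not a joint distribution (one bin can see several
verification states), so only the plain matrix is used for information
measures.

## Information measures

Entropy and mutual information are computed from label frequencies in
bits (`log2`); `0·log 0 := 0`. `I(B;V) ≤ min(H(B), H(V))`, and the
ratio `I(B;V)/H(B)` is reported as the fraction of the base
annotation's information shared with the replicate.

The posterior-conditioned variant refines each base symbol into a
composite `(MAP state, posterior decile)`, with deciles equally spaced
on [0, 1] (not equal-count — deliberately different from the
calibration binning); empty cells contribute nothing. Since this is a
refinement of the label partition, it can only increase MI.

## Granularity

For one base state, verification states are ranked by IoU and
cumulatively merged; plotting the fraction of the base state covered
against the merged states' total coverage gives the state-merging
curve. The curve is anchored at (0, 0) with trapezoid integration; the
perfect-reproducibility reference rises to y = 1 at the first
verification state's coverage. The observed/perfect area ratio (auSMC)
is 1 exactly when the top-ranked verification state alone covers the
base state.

The merge trajectory coarsens both annotations: at each iteration the
within-annotation pair maximising `S(k,k′) = 1 − ΔI/ΔH` (changes from
summing the pair's joint rows and coverages) is merged on each side,
down to two states. Ties break to the smaller combined coverage, then
lowest ids. Merged posteriors are summed (states are mutually
exclusive) and merged labels are the *union* of the pair's bins — an
exact coarsening of the label partition, which guarantees entropy
strictly decreases and MI never increases along the trajectory. (A
summed posterior can overtake the old MAP state at scattered bins; we
do not re-argmax, keeping the trajectory a pure partition operation.)

## Calibration and r-values

Per base state, the calibration population is every bin where it is the
MAP label (the `map` population; scoring all bins with nonzero
posterior is a possible alternative we do not default to, since
r-values are assigned through the MAP state's curve). The population is
sorted by the state's posterior (stable sort, ties keep genome order),
split into `b` equal-count bins (default `b = 100`, automatically
reduced to keep ≥ 25 observations per bin), and the per-bin empirical
reproduced fraction is fit against the per-bin mean posterior by
unweighted least-squares isotonic regression (PAVA, via scikit-learn).
Goodness of fit is `r² = 1 − SS_res/SS_tot` (0 by convention for a
zero-variance target). Prediction is piecewise-constant on the bin
means, clamped to the boundary fitted values outside the support, so
r-values are globally nondecreasing in the posterior and bins with
identical (state, posterior) always get identical r.

States with too few usable bins to calibrate (< 50, i.e. fewer than two
25-observation bins) fall back to the state's windowed overlap fraction
as a constant r-value and are flagged in the output track.

Defaults `w = 1000` bp and `α = 0.9` are the standard operating point;
both are configurable. Thresholding `r ≥ α` yields the confident
subset; the confident fraction is nonincreasing in `α` by construction.

## Synthetic replicate pairs

The generator draws a "truth" segmentation with geometric segment
lengths (mean 25 bins = 5 kb at the default resolution, matching the
segment-length distribution implicit in HMM-based annotators) and
states uniform over `K` with adjacent segments forced to differ
(default `K = 16`, the state-count heuristic `floor(10 + 2·sqrt(d))`
for `d = 11` assays). The base annotation is the truth; its posterior
puts mass `p ∈ [sharpness, 1]` (default sharpness 0.95, emulating the
overconfidence of real SAGA posteriors) on the true state, the rest
spread with exponential noise. The verification annotation applies:

* **segment-level flips** (probability `flip_prob` per segment, default
  0.1, never landing on the same state) — whole-element disagreement,
  the dominant mode seen between real replicates;
* **boundary jitter** (rounded Gaussian, sd in bins) — boundary
  disagreement; a displaced boundary is clipped to stay between its
  original neighbours, keeping displacements of distinct edges local
  and independent;
* optional **state splitting** — a true state annotated as several
  interchangeable substates, emulating over-granularity.

The per-bin true reproduction probability `pi` is computed in closed
form by integrating over the joint visibility cases of the two edges
flanking each bin's segment, including the first-order rescue where a
flipped adjacent segment lands on the matched state (probability
`f/(K−1)`). Neglected are second-order events — edges crossing inside
short segments and contributions of next-nearest segments — which are
negligible when segments are much longer than the jitter sd; the
Monte-Carlo validation tests restrict themselves to this regime
(segment and neighbours ≥ 6x jitter sd).

Replicate-variability settings mirror the standard replicate designs:
S1 (independent model noise per replicate), S2 (one shared model-noise
draw, independent observation noise — more reproducible than S1 at
equal noise, as with a shared ("concatenated") model in practice), and
S3 (shared data noise, independent model draws).

What the generator does *not* emulate: realistic signal tracks,
correlated state-specific flip patterns, hypersegmentation beyond
jitter, or cross-cell-type verification. Passing recovery tests
therefore shows the estimator is correct under segment-level exchange
noise with known truth — not that any particular real replicate pair
reaches a given confident fraction.

## Problem sizes and test design

Parameter-recovery checks run at `G = 2·10⁵` bins with flip
probabilities 0.1/0.3/0.5, where the mean |r − pi| error is required to
stay within 0.03; at this size each state's calibration rests on
~12,000 bins. The calibration-consistency check (fitted curve vs the
identity when posteriors equal the true reproduction probability) uses
many short segments (mean 5 bins) and `K = 2`: flips act at segment
level, so segments — not bins — are the independent sampling units, and
this fixture places ~40,000 of them behind the curve, which is the
asymptotic regime the consistency claim presumes. Monte-Carlo
validation of `pi` uses 500+ verification redraws with empirical
standard errors computed from per-draw class means (bins within a draw
are correlated through shared segment flips).

## Known limitations

* The reproduction indicator is bin-level; segment-level overlap
  statistics are out of scope.
* Windowed matching uses window-relaxed co-occurrence with plain
  coverages in the IoU denominator; for large `w` this inflates IoU for
  all states and is only used for ranking.
* Isotonic calibration has the usual boundary bias of monotone
  regression at the support edges; with few calibration bins the
  piecewise-constant prediction is coarse.
* Enrichment validation reports natural-log observed/expected
  (configurable to log2); zero observed counts give −inf sentinels.
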