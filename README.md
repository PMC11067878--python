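# sagarep

Reproducibility assessment and confidence calibration for SAGA
chromatin-state genome annotations.

## The problem

Segmentation-and-genome-annotation (SAGA) methods such as ChromHMM and
Segway partition the genome into integer-labelled chromatin states
(promoter-like, enhancer-like, quiescent, ...) learned without
supervision from epigenomic tracks. Run the same method on a replicate
experiment and a substantial fraction of the annotation changes: state
definitions drift, labels switch, boundaries move. Unlike peak calling,
which has the IDR framework, chromatin-state annotations have lacked a
way to say *which parts of an annotation would survive replication*.

`sagarep` takes two replicate annotations — a **base** annotation to be
scored and a **verification** annotation as reference — each given as a
BED segmentation plus a `G x K` posterior matrix, and:

1. **matches states across replicates** by maximum intersection-over-union,
   `IoU(k, l) = P(B=k, V=l) / (P(B=k) + P(V=l) − P(B=k, V=l))`,
   which discounts genomic coverage so small well-matched states are not
   swamped by large ones;
2. **measures agreement** — naive (exact-position) and window-tolerant
   overlap, entropy `H(B)`, mutual information `I(B; V)` and its
   posterior-conditioned refinement, per-state state-merging curves
   (auSMC), and an iterative merge trajectory that maximises
   `S(k, k′) = 1 − ΔI(B;V) / ΔH(B)` at each step;
3. **calibrates posteriors into r-values**: per state, bins where it is
   the MAP label are sorted by posterior, split into equal-count bins,
   and the empirical fraction reproduced (matched state observed within
   `g ± w` bp) is fit by least-squares isotonic regression (PAVA). The
   fitted curve maps each bin's posterior to its **r-value** — the
   calibrated probability that the call would be reproduced in a
   replicate;
4. **extracts the confident subset**: bins with `r ≥ α` (0.9 or 0.95 in
   practice), written as browser-ready bedGraph/BED tracks.

A synthetic-data module generates replicate pairs with controllable
segment length, label-flip rate, boundary jitter, posterior sharpness
and state splitting, with a closed-form per-bin true reproduction
probability — so every pipeline stage is testable without external
data.

## Worked example

```python
import numpy as np
import sagarep as sr

# a synthetic replicate pair: 16 states, 200 bp bins, 15% of segments
# disagreeing between replicates, 1-bin boundary jitter
cfg = sr.GeneratorConfig(G=100_000, K=16, flip_prob=0.15, jitter_sd=1.0, seed=7)
truth = sr.generate_pair(cfg, w=1000)

res = sr.ReproducibilityModel(truth.base, truth.verif, w=1000, b=100).fit()

info = sr.info_summary(truth.base, truth.verif)
print(f"H(B) = {info.H_base:.3f} bits, I(B;V) = {info.MI:.3f} bits "
      f"(NMI = {info.NMI_base:.3f})")
for alpha in (0.8, 0.9):
    frac = res.confident(alpha).fraction_confident_overall
    print(f"fraction confident at alpha={alpha}: {frac:.3f}")
print(f"mean |r - true pi|: {np.nanmean(np.abs(res.rvalues.r - truth.pi)):.4f}")
```

prints

```
H(B) = 3.993 bits, I(B;V) = 2.710 bits (NMI = 0.679)
fraction confident at alpha=0.8: 0.855
fraction confident at alpha=0.9: 0.003
mean |r - true pi|: 0.0258
```

The base annotation carries ~4 bits of entropy of which 68% is shared
with the replicate. With 15% of segments flipped, the true per-bin
reproduction probability sits around 0.85: at `α = 0.8` most of the
genome is confidently annotated, while at `α = 0.9` almost nothing
passes — the calibrated r-values correctly refuse to certify a level of
reproducibility the replicates do not support. The last line checks the
r-values against the generator's known ground truth (mean error 0.026).

`res.summary()` returns a per-state table (coverage, matched state and
IoU, naive and windowed overlap, calibration fit, fraction confident),
and `sr.reproducibility_report` bundles the full evaluation, including
auSMC curves and the merge trajectory.

The same workflow is available from the shell:

```sh
sagarep simulate --g 100000 --k 16 --flip-prob 0.15 --seed 7 --out-prefix sim/pair
sagarep run  --base-seg sim/pair.base.bed  --base-post sim/pair.base.posterior.tsv \
             --verif-seg sim/pair.verif.bed --verif-post sim/pair.verif.posterior.tsv \
             --chrom-sizes sim/pair.chrom.sizes -w 1000 -b 100 --alpha 0.9 \
             --out-prefix out/run
sagarep eval ... ; sagarep merge-trajectory ...
```

`sagarep run` writes `out/run.rvalues.bedGraph`, `out/run.confident.bed`,
per-state summary TSVs and a provenance JSON.

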