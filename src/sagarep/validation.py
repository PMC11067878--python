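"""Biological sanity checks against external features.

Chromatin-state annotations have no gold standard; two classic
surrogates are used instead: promoter-like states should be enriched
near annotated TSSs, and transcribed-like states should coincide with
expressed regions (RNA-seq TPM).  Both checks here are computed as a
function of posterior rank, mirroring the calibration binning: if the
posterior carries confidence information, high-posterior bins should
show stronger enrichment / expression than low-posterior bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation, AnnotationError
from .genome import BinnedGenome


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSet:
    """Point features (TSS) or scored intervals (gene body + TPM) on a genome."""

    kind: str  # "points" | "scored_intervals"
    table: pd.DataFrame  # columns: chrom, start, end[, score]

    def __post_init__(self) -> None:
        if self.kind not in {"points", "scored_intervals"}:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.kind == "scored_intervals":
            if "score" not in self.table.columns:
                raise ValidationError("scored intervals need a score column")
            if (self.table["score"] < 0).any():
                raise ValidationError("TPM scores must be >= 0")


@dataclass(frozen=True)
class EnrichmentProfile:
    """Per posterior-rank-bin statistic for one state."""

    state: int
    bin_stat: pd.DataFrame


def read_features(path: str, kind: str) -> FeatureSet:
    """Read a BED3+ (points) or BED5 / BED+score (scored intervals) file."""
    ncols = 5 if kind == "scored_intervals" else 3
    names = ["chrom", "start", "end", "name", "score"][:ncols]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names, usecols=range(ncols))
    return FeatureSet(kind=kind, table=df)


def _feature_mask(features: FeatureSet, genome: BinnedGenome, flank: int) -> np.ndarray:
    """Boolean per bin: within ``flank`` bp of a point feature.

    A bin qualifies if its interval intersects ``[pos - flank, pos + flank]``
    for some feature position (the feature interval's start).
    """
    mask = np.zeros(genome.G, dtype=bool)
    slices = genome.chrom_slices()
    any_hit = False
    for row in features.table.itertuples(index=False):
        if row.chrom not in slices:
            continue
        any_hit = True
        ci = genome.chrom_index(row.chrom)
        size = genome.chrom_sizes[ci]
        pos = int(row.start)
        if pos < 0 or pos >= size:
            raise ValidationError(f"feature {row.chrom}:{pos} outside chromosome")
        lo = max(0, pos - flank) // genome.resolution
        hi = min(size - 1, pos + flank) // genome.resolution
        sl = slices[row.chrom]
        mask[sl.start + lo: sl.start + hi + 1] = True
    if not any_hit:
        raise ValidationError("no features on chromosomes shared with the genome")
    return mask


def _posterior_rank_chunks(base: Annotation, state: int, b: int) -> list[np.ndarray]:
    """Split all non-missing bins into ``b`` equal-count chunks by the
    posterior of ``state``, ascending (stable on ties)."""
    if base.posterior is None:
        raise AnnotationError("validation profiles require a posterior matrix")
    sel = np.flatnonzero(base.labels >= 0)
    if len(sel) < b:
        raise ValidationError(f"only {len(sel)} usable bins for b={b}")
    order = sel[np.argsort(base.posterior[sel, state], kind="stable")]
    return np.array_split(order, b)


def tss_enrichment(
    base: Annotation,
    tss: FeatureSet,
    state: int,
    b: int = 10,
    flank: int | None = None,
    log_base: str = "e",
) -> EnrichmentProfile:
    """log(observed/expected) TSS proximity per posterior-rank bin.

    ``observed`` is the number of bins in the posterior-rank bin lying
    within ``flank`` bp of a TSS; ``expected`` scales the bin's size by
    the genome-wide fraction of bins near a TSS.  Zero observed counts
    are reported as ``-inf``.  ``flank`` defaults to one bin width.
    """
    if tss.kind != "points":
        raise ValidationError("tss_enrichment needs point features")
    if flank is None:
        flank = base.genome.resolution
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    near = _feature_mask(tss, base.genome, flank)
    chunks = _posterior_rank_chunks(base, state, b)
    n_ok = sum(len(c) for c in chunks)
    frac_near = near[np.concatenate(chunks)].sum() / n_ok
    log = np.log if log_base == "e" else np.log2
    rows = []
    for i, c in enumerate(chunks):
        observed = int(near[c].sum())
        expected = len(c) * frac_near
        with np.errstate(divide="ignore"):
            enr = float(log(observed / expected)) if expected > 0 else np.nan
        rows.append({
            "bin": i,
            "mean_posterior": float(base.posterior[c, state].mean()),
            "observed": observed,
            "expected": float(expected),
            "enrichment": enr,
        })
    return EnrichmentProfile(state=int(state), bin_stat=pd.DataFrame(rows))


def _bin_tpm(genes: FeatureSet, genome: BinnedGenome) -> np.ndarray:
    """TPM of the gene covering each bin's midpoint (NaN outside genes)."""
    tpm = np.full(genome.G, np.nan)
    slices = genome.chrom_slices()
    for row in genes.table.itertuples(index=False):
        if row.chrom not in slices:
            continue
        ci = genome.chrom_index(row.chrom)
        size = genome.chrom_sizes[ci]
        res = genome.resolution
        sl = slices[row.chrom]
        n = genome.n_bins_per_chrom[ci]
        for local in range(max(0, int(row.start) // res),
                           min(n, -(-int(row.end) // res))):
            start = local * res
            mid = (start + min(start + res, size)) // 2
            if int(row.start) <= mid < int(row.end):
                tpm[sl.start + local] = row.score
    return tpm


def expression_by_posterior(
    base: Annotation,
    genes: FeatureSet,
    state: int,
    b: int = 10,
) -> EnrichmentProfile:
    """Mean +/- sd TPM per posterior-rank bin; bins outside genes are excluded."""
    if genes.kind != "scored_intervals":
        raise ValidationError("expression_by_posterior needs scored intervals")
    tpm = _bin_tpm(genes, base.genome)
    chunks = _posterior_rank_chunks(base, state, b)
    rows = []
    for i, c in enumerate(chunks):
        vals = tpm[c]
        vals = vals[~np.isnan(vals)]
        rows.append({
            "bin": i,
            "mean_posterior": float(base.posterior[c, state].mean()),
            "n_in_genes": len(vals),
            "mean_tpm": float(vals.mean()) if len(vals) else np.nan,
            "sd_tpm": float(vals.std()) if len(vals) else np.nan,
        })
    return EnrichmentProfile(state=int(state), bin_stat=pd.DataFrame(rows))


def expression_by_score(
    scores: np.ndarray,
    genes: FeatureSet,
    genome: BinnedGenome,
    b: int = 10,
) -> pd.DataFrame:
    """Mean TPM per rank bin of an arbitrary per-bin score (e.g. the r-value)."""
    tpm = _bin_tpm(genes, genome)
    ok = np.flatnonzero(~np.isnan(scores))
    if len(ok) < b:
        raise ValidationError(f"only {len(ok)} scored bins for b={b}")
    order = ok[np.argsort(scores[ok], kind="stable")]
    rows = []
    for i, c in enumerate(np.array_split(order, b)):
        vals = tpm[c]
        vals = vals[~np.isnan(vals)]
        rows.append({
            "bin": i,
            "mean_score": float(np.mean(scores[c])),
            "mean_tpm": float(vals.mean()) if len(vals) else np.nan,
        })
    return pd.DataFrame(rows)
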