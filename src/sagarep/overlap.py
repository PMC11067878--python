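"""Cross-replicate state overlap, IoU matching, and reproduction indicators.

Because SAGA methods are unsupervised, state ids carry no meaning across
two independently trained models.  The first step of any comparison is
therefore to measure, over all jointly annotated bins, the joint
frequency with which base state ``k`` and verification state ``l``
co-occur, and from it the intersection-over-union (Jaccard)

    IoU(k, l) = P(B=k, V=l) / (P(B=k) + P(V=l) - P(B=k, V=l)),

which discounts genomic coverage so that small, well-corresponding
states (promoters) are not swamped by large ones (quiescent).  Each base
state is then matched to the verification state maximising IoU.

A spatial tolerance window of ``w`` bp relaxes exact-position overlap:
a base bin is *reproduced* if its matched verification state occurs
anywhere within ``g ± w`` (windows never cross chromosome boundaries;
``w`` is converted to whole bins by ceiling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .annotation import Annotation

logger = logging.getLogger(__name__)


class OverlapError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapMatrix:
    """Joint and marginal state frequencies over jointly non-missing bins."""

    joint: np.ndarray          # (K_B, K_V), sums to 1
    marginal_base: np.ndarray  # (K_B,)
    marginal_verif: np.ndarray  # (K_V,)
    n_bins_used: int

    def __post_init__(self) -> None:
        j = self.joint
        if (j < 0).any():
            raise OverlapError("joint frequencies must be >= 0")
        if abs(j.sum() - 1.0) > 1e-9:
            raise OverlapError(f"joint must sum to 1, got {j.sum()!r}")
        if not np.allclose(j.sum(axis=1), self.marginal_base, atol=1e-9):
            raise OverlapError("row sums do not match base marginals")
        if not np.allclose(j.sum(axis=0), self.marginal_verif, atol=1e-9):
            raise OverlapError("column sums do not match verification marginals")

    def transpose(self) -> "OverlapMatrix":
        return OverlapMatrix(
            joint=self.joint.T.copy(),
            marginal_base=self.marginal_verif,
            marginal_verif=self.marginal_base,
            n_bins_used=self.n_bins_used,
        )


@dataclass(frozen=True)
class IoUMatrix:
    """Elementwise Jaccard similarity of base x verification state bin sets."""

    iou: np.ndarray  # (K_B, K_V) in [0, 1]


@dataclass(frozen=True)
class CorrespondenceMap:
    """Base state -> best-matching (max IoU) verification state.

    Many-to-one is allowed; this is a row argmax, not a bipartite matching.
    Ties break to the lowest verification id and are logged.
    """

    match: np.ndarray  # (K_B,) int
    score: np.ndarray  # (K_B,) matching IoU


@dataclass(frozen=True)
class ReproductionIndicator:
    """Per-bin boolean: matched verification state seen within ``g ± w``."""

    w: int  # bp
    reproduced: np.ndarray          # (G,) bool; False at missing base bins
    per_state_fraction: np.ndarray  # (K_B,)
    valid: np.ndarray               # (G,) bool: bins entering the statistics


def _usable(base: Annotation, verif: Annotation) -> np.ndarray:
    if base.genome is not verif.genome and base.genome != verif.genome:
        raise OverlapError("annotations must share one BinnedGenome")
    return (base.labels >= 0) & (verif.labels >= 0)


def joint_overlap(base: Annotation, verif: Annotation) -> OverlapMatrix:
    """Joint frequency P(B=k, V=l) over jointly non-missing bins."""
    ok = _usable(base, verif)
    n = int(ok.sum())
    if n == 0:
        raise OverlapError("no jointly annotated bins")
    flat = base.labels[ok] * verif.K + verif.labels[ok]
    counts = np.bincount(flat, minlength=base.K * verif.K).reshape(base.K, verif.K)
    joint = counts / n
    return OverlapMatrix(
        joint=joint,
        marginal_base=joint.sum(axis=1),
        marginal_verif=joint.sum(axis=0),
        n_bins_used=n,
    )


def iou_matrix(om: OverlapMatrix) -> IoUMatrix:
    """Elementwise Jaccard from joint/marginal frequencies; 0/0 := 0."""
    return IoUMatrix(iou=_iou_from_joint(om.joint))


def _iou_from_joint(joint: np.ndarray,
                    marginal_base: np.ndarray | None = None,
                    marginal_verif: np.ndarray | None = None) -> np.ndarray:
    if marginal_base is None:
        marginal_base = joint.sum(axis=1)
    if marginal_verif is None:
        marginal_verif = joint.sum(axis=0)
    denom = marginal_base[:, None] + marginal_verif[None, :] - joint
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(denom > 0, joint / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(iou, 0.0, 1.0)


def match_states(iou: IoUMatrix) -> CorrespondenceMap:
    """Match each base state to its maximum-IoU verification state."""
    m = iou.iou
    if m.ndim != 2 or m.shape[1] == 0:
        raise OverlapError("need at least one verification state")
    match = np.argmax(m, axis=1)  # lowest id wins ties
    score = m[np.arange(m.shape[0]), match]
    for k in range(m.shape[0]):
        row = m[k]
        if (row == score[k]).sum() > 1:
            logger.warning("IoU tie for base state %d; matched to lowest id %d",
                           k, int(match[k]))
        if score[k] == 0:
            logger.warning("base state %d has all-zero IoU row; matched to state 0", k)
    return CorrespondenceMap(match=match, score=score)


def state_presence_windows(verif: Annotation, w_bins: int) -> np.ndarray:
    """Boolean (G, K_V): is state l present within ``g ± w_bins`` of bin g?

    Windows are truncated at chromosome boundaries.  Missing bins carry
    no state and never contribute presence.
    """
    G, K = verif.G, verif.K
    present = np.zeros((G, K), dtype=bool)
    for sl in verif.genome.chrom_slices().values():
        lab = verif.labels[sl]
        for l in range(K):
            hit = (lab == l).astype(np.uint8)
            if w_bins == 0:
                present[sl, l] = hit.astype(bool)
            else:
                # maximum filter of size 2w+1 = windowed OR, edge-truncated
                present[sl, l] = maximum_filter1d(
                    hit, size=2 * w_bins + 1, mode="constant", cval=0
                ).astype(bool)
    return present


def reproduction_indicator(
    base: Annotation,
    verif: Annotation,
    corr: CorrespondenceMap,
    w: int,
) -> ReproductionIndicator:
    """Windowed reproduction: base bin g with state k is reproduced iff
    ``corr.match[k]`` is observed in the verification annotation within
    ``g ± w`` bp (ceil-converted to bins)."""
    ok = _usable(base, verif)
    w_bins = base.genome.bins_per_window(w)
    present = state_presence_windows(verif, w_bins)
    reproduced = np.zeros(base.G, dtype=bool)
    idx = np.flatnonzero(ok)
    target = corr.match[base.labels[idx]]
    reproduced[idx] = present[idx, target]
    per_state = np.zeros(base.K)
    counts = np.bincount(base.labels[idx], minlength=base.K)
    hits = np.bincount(base.labels[idx], weights=reproduced[idx].astype(float),
                       minlength=base.K)
    nz = counts > 0
    per_state[nz] = hits[nz] / counts[nz]
    return ReproductionIndicator(
        w=int(w), reproduced=reproduced, per_state_fraction=per_state, valid=ok
    )


def windowed_joint(base: Annotation, verif: Annotation, w: int) -> np.ndarray:
    """Window-relaxed co-occurrence matrix: entry (k, l) is the fraction of
    jointly annotated bins with base state k and verification state l present
    within ``g ± w``.

    Rows no longer sum to base marginals for ``w > 0`` (one bin can see
    several verification states), so this is returned as a raw matrix,
    not an :class:`OverlapMatrix`.  At ``w = 0`` it equals the plain joint.
    """
    ok = _usable(base, verif)
    n = int(ok.sum())
    if n == 0:
        raise OverlapError("no jointly annotated bins")
    w_bins = base.genome.bins_per_window(w)
    present = state_presence_windows(verif, w_bins)
    out = np.zeros((base.K, verif.K))
    lab = base.labels[ok]
    pres = present[ok]
    for k in range(base.K):
        sel = lab == k
        if sel.any():
            out[k] = pres[sel].sum(axis=0)
    return out / n


def match_states_windowed(base: Annotation, verif: Annotation, w: int) -> CorrespondenceMap:
    """State matching from the window-relaxed IoU (pipeline default mode)."""
    ok = _usable(base, verif)
    n = int(ok.sum())
    joint_w = windowed_joint(base, verif, w)
    mb = np.bincount(base.labels[ok], minlength=base.K) / n
    mv = np.bincount(verif.labels[ok], minlength=verif.K) / n
    return match_states(IoUMatrix(iou=_iou_from_joint(joint_w, mb, mv)))


def naive_overlap(
    base: Annotation, verif: Annotation, corr: CorrespondenceMap
) -> tuple[np.ndarray, float]:
    """Exact-position (w = 0) reproduction fractions.

    Returns (per-state fractions, overall fraction); the overall value
    weights states by their coverage, i.e. it is the plain fraction of
    jointly annotated bins that are reproduced.
    """
    ind = reproduction_indicator(base, verif, corr, w=0)
    n = int(ind.valid.sum())
    overall = float(ind.reproduced[ind.valid].sum() / n)
    return ind.per_state_fraction, overall
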