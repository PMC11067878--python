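"""Reproducibility as a function of chromatin-state granularity.

SAGA models run with many states tend to learn several near-duplicate
states (e.g. three enhancer flavours) that are not reproducible at that
resolution, yet their union is.  Two tools quantify this:

* the *state-merging curve* (SMC): for one base state, verification
  states are added in decreasing IoU order and the fraction of the base
  state covered is plotted against the added genomic coverage; the area
  ratio against the perfect one-state case (auSMC) summarises how much
  of the verification annotation must be pooled to recover the state;

* an iterative merge trajectory: within each annotation, the pair of
  states (k, k') whose merge loses the least mutual information per bit
  of entropy — maximising S = 1 - dI(B;V)/dH(B) — is merged, one pair
  per annotation per iteration, down to two states.  Merged posteriors
  are summed (states are mutually exclusive) and merged labels are the
  union of the pair's bins, so each step is an exact coarsening of the
  label partition: entropy strictly decreases and MI never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import MISSING, Annotation
from .information import _entropy_from_probs, mutual_information_from_joint
from .overlap import (
    OverlapError,
    OverlapMatrix,
    iou_matrix,
    joint_overlap,
    match_states,
    naive_overlap,
)


@dataclass(frozen=True)
class SMCCurve:
    """State-merging curve for one base state."""

    base_state: int
    order: np.ndarray   # verification states, IoU descending
    points: np.ndarray  # (K_V + 1, 2): (cumulative coverage, fraction overlapped)
    auSMC_ratio: float


@dataclass(frozen=True)
class MergeEvent:
    """One within-annotation merge of states (k, k')."""

    merged_pair: tuple[int, int]
    similarity: float   # S = 1 - dMI/dH
    delta_MI: float     # bits, >= 0
    delta_H: float      # bits, > 0 for any nontrivial merge
    resulting_K: int
    side: str = "base"  # which annotation was merged


@dataclass
class MergeTrajectory:
    """Ordered merge events and per-step summary snapshots."""

    events: list[MergeEvent]
    snapshots: list[dict] = field(default_factory=list)


def _trapezoid(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def smc_curve(base_state: int, om: OverlapMatrix) -> SMCCurve:
    """Build the SMC and auSMC ratio for one base state.

    Point i has x = summed coverage of the i highest-IoU verification
    states and y = the fraction of the base state's bins they jointly
    overlap; the curve is anchored at (0, 0) and integrated by the
    trapezoid rule.  The perfect-reproducibility reference jumps to
    y = 1 at the first verification state's coverage.
    """
    cov_k = om.marginal_base[base_state]
    if cov_k <= 0:
        raise OverlapError(f"base state {base_state} has zero coverage")
    iou_row = iou_matrix(om).iou[base_state]
    order = np.lexsort((np.arange(len(iou_row)), -iou_row))
    x = np.cumsum(om.marginal_verif[order])
    y = np.cumsum(om.joint[base_state, order]) / cov_k
    points = np.vstack([[0.0, 0.0], np.column_stack([x, y])])
    observed = _trapezoid(points)
    perfect_pts = np.array([[0.0, 0.0], [x[0], 1.0], [x[-1], 1.0]])
    perfect = _trapezoid(perfect_pts)
    return SMCCurve(
        base_state=int(base_state), order=order, points=points,
        auSMC_ratio=observed / perfect,
    )


def _merge_joint_rows(joint: np.ndarray, k: int, kp: int) -> np.ndarray:
    """Sum rows k and k' (result kept in row min(k, k'), other row dropped)."""
    lo, hi = min(k, kp), max(k, kp)
    out = joint.copy()
    out[lo] += out[hi]
    return np.delete(out, hi, axis=0)


def merge_similarity(om: OverlapMatrix, k: int, kp: int) -> MergeEvent:
    """Similarity S = 1 - dI(B;V)/dH(B) of merging base states k and k'.

    dI and dH are the drops in mutual information and base entropy when
    rows k and k' of the joint matrix (and the corresponding coverages)
    are summed.  Proportional rows give dI = 0, hence S = 1.
    """
    if k == kp:
        raise OverlapError("cannot merge a state with itself")
    before_I = mutual_information_from_joint(om.joint)
    before_H = _entropy_from_probs(om.marginal_base)
    merged = _merge_joint_rows(om.joint, k, kp)
    d_i = before_I - mutual_information_from_joint(merged)
    d_h = before_H - _entropy_from_probs(merged.sum(axis=1))
    sim = 1.0 - d_i / d_h if d_h > 0 else 1.0
    return MergeEvent(
        merged_pair=(min(k, kp), max(k, kp)),
        similarity=float(sim), delta_MI=float(max(d_i, 0.0)), delta_H=float(d_h),
        resulting_K=om.joint.shape[0] - 1,
    )


def _best_merge(joint: np.ndarray) -> MergeEvent:
    """Highest-S pair among all state pairs of the base side of ``joint``.

    Ties break to the smaller combined coverage, then to lowest ids.
    """
    om = OverlapMatrix(
        joint=joint, marginal_base=joint.sum(axis=1),
        marginal_verif=joint.sum(axis=0), n_bins_used=0,
    )
    K = joint.shape[0]
    best: MergeEvent | None = None
    best_key: tuple | None = None
    cov = om.marginal_base
    for k in range(K):
        for kp in range(k + 1, K):
            ev = merge_similarity(om, k, kp)
            key = (-ev.similarity, cov[k] + cov[kp], k, kp)
            if best_key is None or key < best_key:
                best, best_key = ev, key
    assert best is not None
    return best


def merge_states(ann: Annotation, k: int, kp: int) -> Annotation:
    """Merge states k and k' of one annotation.

    The merged state takes id min(k, k'); ids above max(k, k') shift
    down by one.  Labels are coarsened by union; posterior columns are
    summed (mutually exclusive states), so row sums are conserved.
    """
    lo, hi = min(k, kp), max(k, kp)
    remap = np.arange(ann.K, dtype=np.int64)
    remap[hi] = lo
    remap[hi + 1:] -= 1
    labels = np.where(ann.labels >= 0, remap[np.clip(ann.labels, 0, None)], MISSING)
    post = None
    if ann.posterior is not None:
        post = np.zeros((ann.G, ann.K - 1))
        for old in range(ann.K):
            post[:, remap[old]] += ann.posterior[:, old]
    mnem = []
    for new in range(ann.K - 1):
        parts = [ann.mnemonics[old] for old in range(ann.K) if remap[old] == new]
        mnem.append("+".join(parts))
    return Annotation(ann.genome, labels, post, K=ann.K - 1, mnemonics=mnem,
                      reconcile="keep")


def merge_trajectory(
    base: Annotation,
    verif: Annotation,
    w: int = 0,
    alpha: float | None = None,
    calibration_bins: int = 100,
) -> MergeTrajectory:
    """Iteratively merge the most-similar state pair in each annotation.

    At each iteration the maximum-S pair within the base annotation and
    the maximum-S pair within the verification annotation are merged
    (one merge per side), the state correspondence is re-derived, and a
    snapshot of (K, entropy, MI, naive overlap — and fraction confident
    at ``alpha`` if requested) is recorded, until both annotations are
    down to two states.
    """
    if base.K < 3 or verif.K < 3:
        raise OverlapError("merge trajectory needs at least 3 states per annotation")
    events: list[MergeEvent] = []
    snapshots: list[dict] = []
    b, v = base, verif

    def snapshot() -> None:
        om = joint_overlap(b, v)
        corr = match_states(iou_matrix(om))
        _, overall = naive_overlap(b, v, corr)
        snap = {
            "K_base": b.K, "K_verif": v.K,
            "entropy_base": _entropy_from_probs(om.marginal_base),
            "MI": mutual_information_from_joint(om.joint),
            "naive_overlap": overall,
        }
        if alpha is not None:
            from .model import ReproducibilityModel  # lazy: avoids import cycle

            res = ReproducibilityModel(b, v, w=w, b=calibration_bins).fit()
            snap["fraction_confident"] = res.confident(alpha).fraction_confident_overall
        snapshots.append(snap)

    snapshot()
    while b.K > 2 or v.K > 2:
        om = joint_overlap(b, v)
        if b.K > 2:
            ev = _best_merge(om.joint)
            b = merge_states(b, *ev.merged_pair)
            events.append(MergeEvent(**{**ev.__dict__, "side": "base"}))
        if v.K > 2:
            ev_t = _best_merge(om.joint.T)
            v = merge_states(v, *ev_t.merged_pair)
            events.append(MergeEvent(**{**ev_t.__dict__, "side": "verification"}))
        snapshot()
    return MergeTrajectory(events=events, snapshots=snapshots)
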