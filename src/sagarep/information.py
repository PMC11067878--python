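"""Entropy and mutual-information measures of annotation agreement.

Entropy H(B) = -sum_k P(B=k) log2 P(B=k) measures how much information an
annotation conveys given its label frequencies (16 evenly used labels =
4 bits).  Mutual information I(B;V) measures how much of that is shared
with the replicate.  A posterior-conditioned variant refines each base
label into (label, posterior decile) composite symbols before computing
MI against the verification labels; since refining a partition cannot
lose information, it is always >= the plain MI.  All values in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import Annotation, AnnotationError
from .overlap import OverlapMatrix, joint_overlap


def _entropy_from_probs(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=np.float64)
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def entropy(ann: Annotation) -> float:
    """Shannon entropy (bits) of the MAP-label distribution over non-missing bins."""
    return _entropy_from_probs(ann.coverages())


def mutual_information_from_joint(joint: np.ndarray) -> float:
    """I(B;V) in bits from a joint frequency matrix; zero cells contribute 0."""
    joint = np.asarray(joint, dtype=np.float64)
    pb = joint.sum(axis=1)
    pv = joint.sum(axis=0)
    prod = pb[:, None] * pv[None, :]
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / prod[nz])).sum())


def mutual_information(om: OverlapMatrix) -> float:
    """Mutual information (bits) between base and verification labels."""
    return mutual_information_from_joint(om.joint)


def posterior_conditioned_mi(
    base: Annotation, verif: Annotation, n_bins: int = 10
) -> float:
    """MI (bits) between (base label, posterior decile) and verification label.

    Each jointly annotated bin g is mapped to the composite symbol
    (MAP state k, i) where i indexes ``n_bins`` equally spaced intervals
    of [0, 1] containing the posterior of state k at g.  Empty composite
    cells contribute nothing.
    """
    if base.posterior is None:
        raise AnnotationError(
            "base annotation has no posterior matrix; use mutual_information instead"
        )
    ok = (base.labels >= 0) & (verif.labels >= 0)
    if not ok.any():
        raise AnnotationError("no jointly annotated bins")
    lab = base.labels[ok]
    post = base.posterior[np.flatnonzero(ok), lab]
    decile = np.minimum((post * n_bins).astype(np.int64), n_bins - 1)
    composite = lab * n_bins + decile
    flat = composite * verif.K + verif.labels[ok]
    counts = np.bincount(flat, minlength=base.K * n_bins * verif.K)
    joint = counts.reshape(base.K * n_bins, verif.K) / len(lab)
    return mutual_information_from_joint(joint)


@dataclass(frozen=True)
class InfoSummary:
    """Entropies and mutual-information summary of one replicate comparison."""

    H_base: float
    H_verif: float
    MI: float
    MI_posterior: float | None
    NMI_base: float  # MI / H_base

    def __post_init__(self) -> None:
        if self.MI < -1e-9 or self.MI > min(self.H_base, self.H_verif) + 1e-9:
            raise ValueError("MI must satisfy 0 <= MI <= min(H_B, H_V)")
        if self.MI_posterior is not None and self.MI_posterior < self.MI - 1e-9:
            raise ValueError("posterior-conditioned MI cannot be below plain MI")


def info_summary(base: Annotation, verif: Annotation, n_bins: int = 10) -> InfoSummary:
    """Compute H(B), H(V), I(B;V), posterior-conditioned MI and I/H(B)."""
    om = joint_overlap(base, verif)
    hb = _entropy_from_probs(om.marginal_base)
    hv = _entropy_from_probs(om.marginal_verif)
    mi = mutual_information(om)
    mip = (
        posterior_conditioned_mi(base, verif, n_bins)
        if base.posterior is not None
        else None
    )
    return InfoSummary(
        H_base=hb, H_verif=hv, MI=mi, MI_posterior=mip,
        NMI_base=mi / hb if hb > 0 else 0.0,
    )
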