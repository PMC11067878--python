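"""Binned chromatin-state annotations.

An :class:`Annotation` holds, for each of the ``G`` bins of a
:class:`~sagarep.genome.BinnedGenome`, the MAP state label ``q_g`` and
(optionally) the full posterior row ``P(Q_g = k | X)`` over the ``K``
states of the SAGA model that produced it.  Bins not covered by any
segment, or whose posterior row is all zero, are flagged missing and
excluded from every statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import BinnedGenome

logger = logging.getLogger(__name__)

MISSING = -1


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class StateInfo:
    """Metadata for one chromatin state: id, display mnemonic, genomic coverage.

    Mnemonics are display-only; no computation depends on them.
    """

    state_id: int
    mnemonic: str
    coverage: float


class Annotation:
    """Per-bin MAP labels plus optional G x K posterior matrix.

    Parameters
    ----------
    genome : BinnedGenome
    labels : array of int, length G
        MAP state ids in ``[0, K)``; ``-1`` marks missing bins.
    posterior : array (G, K) or None
        Per-bin state posteriors.  Rows of non-missing bins must sum to
        1 (tolerance 1e-6).  When given, labels are forced to the row
        argmax (ties broken by lowest state id); a disagreement with the
        supplied labels is logged.
    K : int, optional
        State count; inferred from labels/posterior if omitted.
    mnemonics : sequence of str, optional
    reconcile : {"argmax", "keep"}
        With ``"keep"``, supplied labels are trusted even when a
        posterior is present (all-zero rows still force missing).  Used
        for merged annotations, where labels are the union-coarsening of
        the original label partition and must stay so even if a summed
        posterior overtakes the old MAP state elsewhere.
    """

    def __init__(
        self,
        genome: BinnedGenome,
        labels: np.ndarray,
        posterior: np.ndarray | None = None,
        K: int | None = None,
        mnemonics: list[str] | None = None,
        reconcile: str = "argmax",
    ) -> None:
        labels = np.asarray(labels, dtype=np.int64).copy()
        if labels.shape != (genome.G,):
            raise AnnotationError(f"labels must have length G={genome.G}, got {labels.shape}")
        if posterior is not None:
            posterior = np.asarray(posterior, dtype=np.float64).copy()
            if posterior.ndim != 2 or posterior.shape[0] != genome.G:
                raise AnnotationError(
                    f"posterior must be (G, K) with G={genome.G}, got {posterior.shape}"
                )
            if posterior.min() < -1e-12 or posterior.max() > 1 + 1e-9:
                raise AnnotationError("posterior entries must lie in [0, 1]")
            if K is not None and posterior.shape[1] != K:
                raise AnnotationError(
                    f"posterior has {posterior.shape[1]} columns but K={K}"
                )
            K = posterior.shape[1]
            row_sums = posterior.sum(axis=1)
            # all-zero rows mark missing bins; other rows must be normalized
            zero_rows = row_sums <= 1e-12
            bad = ~zero_rows & (np.abs(row_sums - 1.0) > 1e-6)
            if bad.any():
                raise AnnotationError(
                    f"{int(bad.sum())} posterior rows do not sum to 1 (first at bin "
                    f"{int(np.flatnonzero(bad)[0])})"
                )
            if reconcile == "argmax":
                map_labels = np.argmax(posterior, axis=1)  # argmax takes lowest id on ties
                map_labels[zero_rows] = MISSING
                provided = labels >= 0
                disagree = provided & ~zero_rows & (labels != map_labels)
                if disagree.any():
                    logger.warning(
                        "labels disagree with posterior argmax at %d bins; using argmax",
                        int(disagree.sum()),
                    )
                labels = np.where(zero_rows, MISSING, map_labels)
            elif reconcile == "keep":
                labels = np.where(zero_rows, MISSING, labels)
            else:
                raise AnnotationError(f"unknown reconcile mode {reconcile!r}")
        if K is None:
            if labels.max() < 0:
                raise AnnotationError("annotation has no labelled bins and no K")
            K = int(labels.max()) + 1
        if labels.max() >= K:
            raise AnnotationError(f"label {int(labels.max())} >= K={K}")
        self.genome = genome
        self.K = int(K)
        self.labels = labels
        self.posterior = posterior
        if mnemonics is None:
            mnemonics = [str(k) for k in range(self.K)]
        if len(mnemonics) != self.K:
            raise AnnotationError("need one mnemonic per state")
        self.mnemonics = list(mnemonics)

    # ------------------------------------------------------------------
    @property
    def G(self) -> int:
        return self.genome.G

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing bins."""
        return self.labels == MISSING

    def coverages(self) -> np.ndarray:
        """Per-state fraction of non-missing bins carrying the state as MAP label."""
        ok = self.labels >= 0
        n = int(ok.sum())
        if n == 0:
            raise AnnotationError("annotation has no usable bins")
        return np.bincount(self.labels[ok], minlength=self.K) / n

    @property
    def states(self) -> list[StateInfo]:
        cov = self.coverages()
        return [
            StateInfo(state_id=k, mnemonic=self.mnemonics[k], coverage=float(cov[k]))
            for k in range(self.K)
        ]

    def map_posterior(self) -> np.ndarray:
        """Posterior of the MAP state per bin (NaN where missing)."""
        if self.posterior is None:
            raise AnnotationError("annotation has no posterior matrix")
        out = np.full(self.G, np.nan)
        ok = self.labels >= 0
        out[ok] = self.posterior[np.flatnonzero(ok), self.labels[ok]]
        return out

    def relabel(self, perm: np.ndarray) -> "Annotation":
        """Return a copy with state ids permuted: new id of state k is perm[k]."""
        perm = np.asarray(perm, dtype=np.int64)
        if sorted(perm.tolist()) != list(range(self.K)):
            raise AnnotationError("perm must be a permutation of 0..K-1")
        labels = np.where(self.labels >= 0, perm[np.clip(self.labels, 0, None)], MISSING)
        post = None
        if self.posterior is not None:
            post = np.empty_like(self.posterior)
            post[:, perm] = self.posterior
        mnem = [""] * self.K
        for k in range(self.K):
            mnem[perm[k]] = self.mnemonics[k]
        return Annotation(self.genome, labels, post, K=self.K, mnemonics=mnem)
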