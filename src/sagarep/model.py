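"""End-to-end reproducibility model: per-bin r-values and the confident subset.

The r-value of a genomic bin is the calibrated probability that its
chromatin-state call would be reproduced — its matched state observed
within ``g ± w`` bp — in a replicate annotation.  It is estimated by

1. matching base states to verification states by maximum IoU
   (window-relaxed by default),
2. computing the windowed reproduction indicator per bin,
3. per base state, binning its MAP bins by posterior (equal counts) and
   fitting an isotonic calibration curve of reproduced fraction against
   posterior,
4. evaluating each bin's MAP-state curve at its posterior.

Thresholding r >= alpha (0.9 or 0.95 in practice) yields the confident
annotation subset, analogous to an IDR cutoff for peak calling.

The public surface follows the model/results convention:
``ReproducibilityModel(base, verif, w=1000, b=100).fit()`` returns a
:class:`ReproducibilityResults` carrying the r-value track, the state
correspondence, the calibration curves and diagnostics, with
``.confident(alpha)`` and ``.summary()`` on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, AnnotationError
from .calibration import (
    CalibrationBins,
    CalibrationCurve,
    CalibrationError,
    bin_by_posterior,
    fit_isotonic,
    predict_rvalue,
)
from .genome import BinnedGenome
from .information import info_summary
from .overlap import (
    CorrespondenceMap,
    ReproductionIndicator,
    iou_matrix,
    joint_overlap,
    match_states,
    match_states_windowed,
    naive_overlap,
    reproduction_indicator,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RValueTrack:
    """Per-bin reproduction probabilities with full provenance."""

    genome: BinnedGenome
    r: np.ndarray                # (G,) in [0, 1]; NaN where missing
    state_of_record: np.ndarray  # (G,) MAP label used per bin; -1 missing
    mnemonics: list[str]
    w: int
    params: dict = field(default_factory=dict)
    flagged_states: tuple[int, ...] = ()  # states without a calibration curve


@dataclass(frozen=True)
class ConfidentAnnotation:
    """The alpha-thresholded confident subset of an r-value track."""

    track: RValueTrack
    alpha: float
    mask: np.ndarray  # (G,) bool; True implies r >= alpha
    fraction_confident_overall: float
    fraction_confident_per_state: np.ndarray


class ReproducibilityModel:
    """Reproducibility model for a (base, verification) annotation pair.

    Parameters
    ----------
    base, verif : Annotation
        Replicate annotations on one :class:`BinnedGenome`; the base
        must carry a posterior matrix.
    w : int
        Spatial tolerance in bp (default 1000).
    b : int
        Calibration bins per state (default 100); automatically reduced
        to keep at least ``min_per_bin`` observations per bin.
    matching : {"windowed", "plain"}
        Whether state correspondence uses the window-relaxed IoU
        (default) or the exact-position IoU.
    min_per_bin : int
        Floor on observations per calibration bin (default 25).
    """

    def __init__(
        self,
        base: Annotation,
        verif: Annotation,
        w: int = 1000,
        b: int = 100,
        matching: str = "windowed",
        min_per_bin: int = 25,
    ) -> None:
        if base.posterior is None:
            raise AnnotationError("base annotation needs a posterior matrix")
        if matching not in {"windowed", "plain"}:
            raise ValueError(f"unknown matching mode {matching!r}")
        self.base = base
        self.verif = verif
        self.w = int(w)
        self.b = int(b)
        self.matching = matching
        self.min_per_bin = int(min_per_bin)

    def fit(self) -> "ReproducibilityResults":
        """Run the full pipeline and return the results object."""
        base, verif, w = self.base, self.verif, self.w
        if self.matching == "windowed":
            corr = match_states_windowed(base, verif, w)
        else:
            corr = match_states(iou_matrix(joint_overlap(base, verif)))
        indicator = reproduction_indicator(base, verif, corr, w)

        curves: dict[int, CalibrationCurve] = {}
        bins: dict[int, CalibrationBins] = {}
        flagged: list[int] = []
        r = np.full(base.G, np.nan)
        ok = base.labels >= 0
        for k in range(base.K):
            sel = (base.labels == k) & indicator.valid
            n_k = int(sel.sum())
            b_k = min(self.b, n_k // self.min_per_bin)
            if b_k >= 2:
                cb = bin_by_posterior(base, indicator, k, b_k)
                curve = fit_isotonic(cb)
                bins[k], curves[k] = cb, curve
                where = np.flatnonzero(base.labels == k)
                r[where] = predict_rvalue(curve, base.posterior[where, k])
            else:
                # too few observations to calibrate: fall back to the
                # state's windowed overlap fraction and flag it
                flagged.append(k)
                r[base.labels == k] = indicator.per_state_fraction[k]
                if n_k > 0:
                    logger.warning(
                        "state %d has only %d usable bins; r set to its "
                        "windowed overlap fraction", k, n_k,
                    )
        r[~ok] = np.nan
        track = RValueTrack(
            genome=base.genome, r=r, state_of_record=base.labels.copy(),
            mnemonics=list(base.mnemonics), w=w,
            params={"b": self.b, "matching": self.matching,
                    "min_per_bin": self.min_per_bin},
            flagged_states=tuple(flagged),
        )
        return ReproducibilityResults(self, corr, indicator, bins, curves, track)


class ReproducibilityResults:
    """Fitted r-value track plus the intermediate objects that produced it."""

    def __init__(
        self,
        model: ReproducibilityModel,
        correspondence: CorrespondenceMap,
        indicator: ReproductionIndicator,
        calibration_bins: dict[int, CalibrationBins],
        calibration_curves: dict[int, CalibrationCurve],
        rvalues: RValueTrack,
    ) -> None:
        self.model = model
        self.correspondence = correspondence
        self.indicator = indicator
        self.calibration_bins = calibration_bins
        self.calibration_curves = calibration_curves
        self.rvalues = rvalues

    def confident(self, alpha: float = 0.9) -> ConfidentAnnotation:
        """Threshold the r-value track at ``alpha``."""
        return apply_threshold(self.rvalues, alpha)

    def summary(self) -> pd.DataFrame:
        """Per-state summary table: coverage, match, IoU, overlap, calibration r2."""
        base, verif = self.model.base, self.model.verif
        cov = base.coverages()
        per_state, _ = naive_overlap(base, verif, self.correspondence)
        conf = self.confident(0.9)
        rows = []
        for k in range(base.K):
            rows.append({
                "state": k,
                "mnemonic": base.mnemonics[k],
                "coverage": cov[k],
                "matched_state": int(self.correspondence.match[k]),
                "matched_iou": float(self.correspondence.score[k]),
                "naive_overlap": float(per_state[k]),
                f"overlap_w{self.model.w}": float(
                    self.indicator.per_state_fraction[k]
                ),
                "calibration_r2": (
                    self.calibration_curves[k].r2
                    if k in self.calibration_curves else np.nan
                ),
                "fraction_confident_0.9": float(
                    conf.fraction_confident_per_state[k]
                ),
            })
        return pd.DataFrame(rows)


def compute_rvalues(
    base: Annotation, verif: Annotation, w: int = 1000, b: int = 100, **kw
) -> RValueTrack:
    """Functional wrapper: fit the model and return just the r-value track."""
    return ReproducibilityModel(base, verif, w=w, b=b, **kw).fit().rvalues


def apply_threshold(track: RValueTrack, alpha: float = 0.9) -> ConfidentAnnotation:
    """Boolean confident mask (r >= alpha) and per-state confident fractions."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    ok = track.state_of_record >= 0
    mask = np.zeros(track.genome.G, dtype=bool)
    mask[ok] = track.r[ok] >= alpha
    n = int(ok.sum())
    overall = float(mask[ok].sum() / n) if n else 0.0
    K = len(track.mnemonics)
    counts = np.bincount(track.state_of_record[ok], minlength=K)
    hits = np.bincount(track.state_of_record[ok], weights=mask[ok].astype(float),
                       minlength=K)
    per_state = np.divide(hits, counts, out=np.zeros(K), where=counts > 0)
    return ConfidentAnnotation(
        track=track, alpha=float(alpha), mask=mask,
        fraction_confident_overall=overall,
        fraction_confident_per_state=per_state,
    )


def symmetric_confident_mask(
    base: Annotation, verif: Annotation, alpha: float = 0.9,
    w: int = 1000, b: int = 100, **kw
) -> np.ndarray:
    """Intersection of the confident masks of both scoring directions."""
    fwd = ReproducibilityModel(base, verif, w=w, b=b, **kw).fit().confident(alpha)
    rev = ReproducibilityModel(verif, base, w=w, b=b, **kw).fit().confident(alpha)
    return fwd.mask & rev.mask


def reproducibility_report(
    base: Annotation,
    verif: Annotation,
    w_values: tuple[int, ...] = (0, 200, 1000),
    alpha: float = 0.9,
    b: int = 100,
    merge: bool = False,
) -> dict:
    """Aggregate evaluation bundle for one replicate comparison.

    Contains the overlap/IoU matrices, naive and windowed overlap, the
    information summary, per-state auSMC ratios, the r-value pipeline
    outputs at the largest ``w``, and (optionally) the merge trajectory.
    Evaluation matching is done at w = 0.
    """
    from .granularity import merge_trajectory, smc_curve

    om = joint_overlap(base, verif)
    iou = iou_matrix(om)
    corr = match_states(iou)
    per_state, overall = naive_overlap(base, verif, corr)
    report: dict = {
        "overlap_matrix": om,
        "iou": iou,
        "correspondence": corr,
        "naive_overlap_per_state": per_state,
        "naive_overlap_overall": overall,
        "windowed_overlap": {},
        "info": info_summary(base, verif),
        "auSMC": {},
    }
    for w in w_values:
        ind = reproduction_indicator(base, verif, corr, w)
        nv = int(ind.valid.sum())
        report["windowed_overlap"][w] = {
            "per_state": ind.per_state_fraction,
            "overall": float(ind.reproduced[ind.valid].sum() / nv),
        }
    for k in range(base.K):
        if om.marginal_base[k] > 0:
            report["auSMC"][k] = smc_curve(k, om).auSMC_ratio
    if base.posterior is not None:
        try:
            res = ReproducibilityModel(base, verif, w=max(w_values), b=b).fit()
            report["rvalues"] = res.rvalues
            report["fraction_confident"] = res.confident(
                alpha
            ).fraction_confident_overall
        except (CalibrationError, AnnotationError) as exc:  # pragma: no cover
            logger.warning("r-value stage skipped: %s", exc)
    if merge and base.K >= 3 and verif.K >= 3:
        report["merge_trajectory"] = merge_trajectory(base, verif, w=0)
    return report
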