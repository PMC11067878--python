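"""Calibrating SAGA posteriors into reproduction probabilities.

SAGA posteriors are notoriously overconfident (most bins get > 0.99),
so the raw posterior is not a usable confidence score.  The observed
relationship between posterior and reproduction, however, is strongly
increasing, so it can be calibrated: for each base state, the bins where
it is the MAP label are sorted by its posterior, split into ``b``
equal-count bins, and the empirical reproduced fraction per bin is fit
with least-squares isotonic regression

    min sum_i (yhat_i - y_i)^2   s.t.  yhat_i <= yhat_j for b_i <= b_j,

solved exactly by the pool-adjacent-violators algorithm (PAVA, via
scikit-learn).  Prediction is piecewise-constant on the bin means with
clamped extrapolation outside the support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .annotation import Annotation, AnnotationError
from .overlap import ReproductionIndicator


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationBins:
    """Equal-count posterior bins of one state with empirical reproduced fractions."""

    state: int
    bin_edges: np.ndarray          # (b + 1,) posterior values delimiting the bins
    mean_posterior: np.ndarray     # (b,)
    reproduced_fraction: np.ndarray  # (b,)
    n_per_bin: np.ndarray          # (b,) counts, differing by at most 1

    @property
    def bin_count(self) -> int:
        return len(self.mean_posterior)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-constant map: posterior -> reproduction probability."""

    state: int
    x: np.ndarray       # bin mean posteriors (nondecreasing)
    fitted: np.ndarray  # fitted values, nondecreasing, in [0, 1]
    r2: float
    support: tuple[float, float]


def bin_by_posterior(
    base: Annotation,
    indicator: ReproductionIndicator,
    state: int,
    b: int,
) -> CalibrationBins:
    """Equal-count posterior binning of one state's MAP bins.

    The calibration population is every non-missing bin whose MAP label
    is ``state``, sorted ascending by that state's posterior (stable for
    ties, keeping genome order), then split into ``b`` contiguous
    subarrays whose sizes differ by at most one.
    """
    if base.posterior is None:
        raise AnnotationError("calibration requires a posterior matrix")
    if b < 1:
        raise CalibrationError(f"bin count must be >= 1, got {b}")
    sel = np.flatnonzero((base.labels == state) & indicator.valid)
    n = len(sel)
    if n < b:
        raise CalibrationError(
            f"state {state} has {n} usable bins but b={b}; use a smaller b"
        )
    post = base.posterior[sel, state]
    order = np.argsort(post, kind="stable")
    post_sorted = post[order]
    rep_sorted = indicator.reproduced[sel][order].astype(float)
    chunks = np.array_split(np.arange(n), b)
    mean_post = np.array([post_sorted[c].mean() for c in chunks])
    rep_frac = np.array([rep_sorted[c].mean() for c in chunks])
    counts = np.array([len(c) for c in chunks])
    edges = np.concatenate([[post_sorted[0]],
                            [post_sorted[c[-1]] for c in chunks]])
    return CalibrationBins(
        state=int(state), bin_edges=edges, mean_posterior=mean_post,
        reproduced_fraction=rep_frac, n_per_bin=counts,
    )


def fit_isotonic(bins: CalibrationBins) -> CalibrationCurve:
    """Least-squares monotone (PAVA) fit of reproduced fraction vs posterior.

    Unweighted over bins (equal-count bins carry near-equal weight
    anyway).  r2 is reported against the fitted curve; a zero-variance
    target gives r2 = 0 by convention.
    """
    if bins.bin_count < 2:
        raise CalibrationError("need at least 2 bins to fit a calibration curve")
    x, y = bins.mean_posterior, bins.reproduced_fraction
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = np.clip(iso.fit_transform(x, y), 0.0, 1.0)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CalibrationCurve(
        state=bins.state, x=x, fitted=fitted, r2=r2,
        support=(float(x[0]), float(x[-1])),
    )


def predict_rvalue(curve: CalibrationCurve, posterior: float | np.ndarray) -> np.ndarray:
    """Piecewise-constant prediction on the calibration curve.

    A posterior between two bin means takes the fitted value of the last
    bin mean not exceeding it; values outside the support clamp to the
    boundary fitted values.
    """
    p = np.atleast_1d(np.asarray(posterior, dtype=np.float64))
    if ((p < 0) | (p > 1)).any():
        raise CalibrationError("posterior values must lie in [0, 1]")
    idx = np.searchsorted(curve.x, p, side="right") - 1
    out = curve.fitted[np.clip(idx, 0, None)]
    out = np.where(idx < 0, curve.fitted[0], out)
    return out if np.ndim(posterior) else float(out[0])
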