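"""Synthetic replicate annotation pairs with known reproduction structure.

Real replicate pairs require trained SAGA models; for testing and
calibration studies this module generates pairs whose per-bin
probability of reproduction is known in closed form.  The base
annotation is a drawn "truth" segmentation (geometric segment lengths,
adjacent segments always differ); the verification annotation perturbs
it with the three noise processes seen between real replicates:

* segment-level label flips (whole elements called differently),
* Gaussian boundary jitter (segmentation disagreement at edges),
* optional state splitting (over-granularity: one true state annotated
  as several interchangeable substates).

With per-segment flip probability f and boundary jitter sd sigma, the
probability that bin g (in segment [a, b)) keeps its matched state
within a +/- w-bin window is

    pi_g = (1 - f) * P(left edge <= g + w) * P(right edge > g - w),

with the edge terms equal to rounded-Gaussian tail masses (1 at
chromosome ends, which are never jittered).  Second-order events — a
flipped neighbour landing on the same state, jittered edges crossing —
are excluded from the closed form and are negligible when segments are
much longer than sigma.

Replicate-variability settings mirror the replicate-design taxonomy:
S1 = independent model noise per replicate, S2 = one shared model-noise
draw with independent observation noise, S3 = shared observation (data)
noise with independent model-noise draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .annotation import Annotation
from .genome import BinnedGenome, bin_genome


class SimulationError(ValueError):
    pass


def default_state_count(n_assays: int) -> int:
    """Heuristic state count for a SAGA model trained on ``n_assays`` tracks:
    floor(10 + 2 * sqrt(n_assays)).  11 assays -> 16 states."""
    if n_assays < 1:
        raise SimulationError(f"need at least one assay, got {n_assays}")
    return int(math.floor(10 + 2 * math.sqrt(n_assays)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic replicate-pair generator.

    Defaults give a realistic desk-scale annotation: 200 bp bins,
    16 states (the heuristic for 11 assays), 5 kb mean segments, sharply
    peaked posteriors, 10% of segments disagreeing between replicates.
    """

    G: int = 50_000
    K: int = 16
    resolution: int = 200
    mean_segment_len: float = 25.0      # bins; geometric lengths
    posterior_sharpness: float = 0.95   # lower bound on the true state's posterior
    flip_prob: float = 0.1              # per-segment label-swap probability
    flip_prob_range: tuple[float, float] | None = None  # per-segment f ~ U(lo, hi)
    jitter_sd: float = 0.0              # boundary displacement sd, in bins
    split_states: dict[int, int] = field(default_factory=dict)
    calibrated_posteriors: bool = False  # true-state posterior = 1 - f_seg
    obs_flip_prob: float = 0.05         # observation noise for setting pairs
    n_chroms: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flip_prob", "posterior_sharpness", "obs_flip_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if self.jitter_sd < 0:
            raise SimulationError("jitter_sd must be >= 0")
        if self.G < self.n_chroms or self.K < 2 or self.mean_segment_len < 1:
            raise SimulationError("config would produce no usable segments")

    def genome(self) -> BinnedGenome:
        per = self.G // self.n_chroms
        sizes = {
            f"chrS{i + 1}": (per + (self.G % self.n_chroms if i == self.n_chroms - 1 else 0))
            * self.resolution
            for i in range(self.n_chroms)
        }
        return bin_genome(sizes, self.resolution)


# one segment: [start, end) in bin coordinates of its chromosome
@dataclass
class _Segment:
    start: int
    end: int
    state: int
    flip_p: float


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated replicate pair."""

    config: GeneratorConfig
    genome: BinnedGenome
    segments: dict[str, list[_Segment]]
    true_labels: np.ndarray
    pi: np.ndarray  # per-bin closed-form reproduction probability (at pi_window)
    pi_window: int  # bp window pi was evaluated at
    base: Annotation
    verif: Annotation

    @property
    def replicate_pair(self) -> tuple[Annotation, Annotation]:
        return self.base, self.verif


def _draw_segments(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, list[_Segment]]:
    genome = cfg.genome()
    p = min(1.0, 1.0 / cfg.mean_segment_len)
    out: dict[str, list[_Segment]] = {}
    for chrom, n in zip(genome.chrom_names, genome.n_bins_per_chrom):
        segs: list[_Segment] = []
        pos = 0
        prev = -1
        while pos < n:
            length = int(rng.geometric(p))
            end = min(pos + length, n)
            state = int(rng.integers(cfg.K - (prev >= 0)))
            if prev >= 0 and state >= prev:
                state += 1  # uniform over states != prev
            if cfg.flip_prob_range is not None:
                f = float(rng.uniform(*cfg.flip_prob_range))
            else:
                f = cfg.flip_prob
            segs.append(_Segment(pos, end, state, f))
            prev = state
            pos = end
        if not segs:
            raise SimulationError(f"no segments drawn on {chrom}")
        out[chrom] = segs
    return out


def _labels_from_segments(segments: dict[str, list[_Segment]],
                          genome: BinnedGenome) -> np.ndarray:
    labels = np.empty(genome.G, dtype=np.int64)
    for chrom, sl in genome.chrom_slices().items():
        for seg in segments[chrom]:
            labels[sl.start + seg.start: sl.start + seg.end] = seg.state
    return labels


def _perturb_segments(
    segments: dict[str, list[_Segment]],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    flip: bool = True,
    jitter: bool = True,
    flip_override: float | None = None,
) -> dict[str, list[_Segment]]:
    """Apply segment-level flips and boundary jitter; returns new segments."""
    out: dict[str, list[_Segment]] = {}
    for chrom, segs in segments.items():
        states = []
        for seg in segs:
            f = flip_override if flip_override is not None else seg.flip_p
            s = seg.state
            if flip and rng.random() < f:
                s = int(rng.integers(cfg.K - 1))
                if s >= seg.state:
                    s += 1  # never flips onto itself
            states.append(s)
        bounds = np.array([seg.end for seg in segs[:-1]], dtype=np.int64)
        if jitter and cfg.jitter_sd > 0 and len(bounds):
            n = segs[-1].end
            edges = np.concatenate([[0], bounds, [n]])
            moved = bounds + np.rint(
                rng.normal(0.0, cfg.jitter_sd, size=len(bounds))
            ).astype(np.int64)
            # jitter stays local: a boundary never crosses its original
            # neighbours, so displacements of distinct edges stay independent
            bounds = np.sort(np.clip(moved, edges[:-2], edges[2:]))
        edges = np.concatenate([[0], bounds, [segs[-1].end]])
        new = [
            _Segment(int(a), int(b), states[i], segs[i].flip_p)
            for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
            if b > a
        ]
        out[chrom] = new
    return out


def _make_posterior(
    labels: np.ndarray,
    K: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    p_true: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior rows: mass ``p_true`` on the true state, the remainder
    spread over the other states with exponential noise, renormalized."""
    G = len(labels)
    if p_true is None:
        # true-state posterior uniform on [sharpness, 1]
        p_true = 1.0 - (1.0 - cfg.posterior_sharpness) * rng.random(G)
    noise = rng.exponential(1.0, size=(G, K))
    noise[np.arange(G), labels] = 0.0
    denom = noise.sum(axis=1)
    denom[denom == 0] = 1.0
    post = noise / denom[:, None] * (1.0 - p_true)[:, None]
    post[np.arange(G), labels] = p_true
    return post


def _cdf_rounded(m: np.ndarray, sd: float) -> np.ndarray:
    """P(round(N(0, sd)) <= m) for integer thresholds m; step function at sd=0."""
    if sd == 0:
        return (m >= 0).astype(float)
    return norm.cdf((np.asarray(m, dtype=float) + 0.5) / sd)


def truth_pi(
    cfg: GeneratorConfig,
    segments: dict[str, list[_Segment]],
    genome: BinnedGenome,
    w: int = 0,
) -> np.ndarray:
    """Closed-form per-bin reproduction probability at window ``w`` bp.

    For bin g in segment [a, b) the matched state is seen in the window
    ``g +/- w`` if the segment itself is visible there and unflipped, or
    if a visible adjacent segment happens to flip onto the same state
    (probability f/(K-1) each).  The two jittered edges (a, b) are
    integrated jointly over the visibility cases they control; events
    involving more distant segments or crossing edges are neglected.
    """
    w_bins = genome.bins_per_window(w)
    sd = cfg.jitter_sd
    rescue = 1.0 / (cfg.K - 1)
    pi = np.empty(genome.G)
    for chrom, sl in genome.chrom_slices().items():
        segs = segments[chrom]
        n = segs[-1].end
        for i, seg in enumerate(segs):
            g = np.arange(seg.start, seg.end)
            m = len(g)
            # left edge a = seg.start: own segment needs delta_a <= g+w-a,
            # the left neighbour is in the window iff delta_a > g-w-a
            if seg.start > 0:
                own_l_ok = _cdf_rounded(g + w_bins - seg.start, sd)
                nbr_l_vis = 1.0 - _cdf_rounded(g - w_bins - seg.start, sd)
                f_l = segs[i - 1].flip_p
            else:
                own_l_ok, nbr_l_vis, f_l = np.ones(m), np.zeros(m), 0.0
            # right edge b = seg.end: own needs delta_b > g-w-b,
            # the right neighbour is in the window iff delta_b <= g+w-b
            if seg.end < n:
                own_r_ok = 1.0 - _cdf_rounded(g - w_bins - seg.end, sd)
                nbr_r_vis = _cdf_rounded(g + w_bins - seg.end, sd)
                f_r = segs[i + 1].flip_p
            else:
                own_r_ok, nbr_r_vis, f_r = np.ones(m), np.zeros(m), 0.0
            miss = _miss_probability(
                seg.flip_p, f_l * rescue, f_r * rescue,
                own_l_ok, own_r_ok, nbr_l_vis, nbr_r_vis,
            )
            pi[sl.start + seg.start: sl.start + seg.end] = 1.0 - miss
    return pi


def _miss_probability(f, rl, rr, own_l, own_r, nbr_l, nbr_r):
    """P(no visible segment shows the matched state), integrating the two
    edge displacements over their joint visibility cases.

    Left edge cases: delta small (own ok, neighbour out), middle (both
    visible), large (own out, neighbour in); analogously for the right
    edge.  Within a case, flips are independent across segments.
    """
    # joint case probabilities per edge (each edge has thresholds
    # own_ok and nbr_vis with own_ok + nbr_vis >= 1 pointwise)
    l_own_only = np.clip(1.0 - nbr_l, 0.0, 1.0)          # own ok, nbr out
    l_both = np.clip(own_l + nbr_l - 1.0, 0.0, 1.0)      # own ok, nbr in
    l_nbr_only = np.clip(1.0 - own_l, 0.0, 1.0)          # own out, nbr in
    r_own_only = np.clip(1.0 - nbr_r, 0.0, 1.0)
    r_both = np.clip(own_r + nbr_r - 1.0, 0.0, 1.0)
    r_nbr_only = np.clip(1.0 - own_r, 0.0, 1.0)
    miss = np.zeros_like(own_l)
    for pl, ol, nl in ((l_own_only, 1, 0), (l_both, 1, 1), (l_nbr_only, 0, 1)):
        for pr, orr, nr in ((r_own_only, 1, 0), (r_both, 1, 1), (r_nbr_only, 0, 1)):
            own_show = (1.0 - f) * ol * orr  # own needs both edges ok
            term = (1.0 - own_show) * (1.0 - rl * nl) * (1.0 - rr * nr)
            miss += pl * pr * term
    return miss


def _split_verif_states(
    segments: dict[str, list[_Segment]],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[_Segment]], int]:
    """Relabel each segment of a split state to a random substate.

    Substate 0 keeps the original id; extra substates get fresh ids
    K, K+1, ... in (state, part) order.
    """
    if not cfg.split_states:
        return segments, cfg.K
    extra_ids: dict[tuple[int, int], int] = {}
    next_id = cfg.K
    for k in sorted(cfg.split_states):
        for part in range(1, cfg.split_states[k]):
            extra_ids[(k, part)] = next_id
            next_id += 1
    out: dict[str, list[_Segment]] = {}
    for chrom, segs in segments.items():
        new = []
        for seg in segs:
            s = seg.state
            if s in cfg.split_states:
                part = int(rng.integers(cfg.split_states[s]))
                if part > 0:
                    s = extra_ids[(seg.state, part)]
            new.append(_Segment(seg.start, seg.end, s, seg.flip_p))
        out[chrom] = new
    return out, next_id


def generate_pair(cfg: GeneratorConfig, w: int = 0) -> SyntheticTruth:
    """Generate one (base, verification) pair with known truth.

    The base annotation's labels are the drawn truth; the verification
    applies segment flips, boundary jitter, and state splits.  ``w``
    only sets the window at which the returned ``pi`` is evaluated.
    Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.genome()
    segments = _draw_segments(cfg, rng)
    true_labels = _labels_from_segments(segments, genome)
    pi = truth_pi(cfg, segments, genome, w)

    p_true = None
    if cfg.calibrated_posteriors:
        p_true = np.empty(genome.G)
        for chrom, sl in genome.chrom_slices().items():
            for seg in segments[chrom]:
                p_true[sl.start + seg.start: sl.start + seg.end] = 1.0 - seg.flip_p
    base_post = _make_posterior(true_labels, cfg.K, cfg, rng, p_true=p_true)
    base = Annotation(genome, true_labels, base_post, K=cfg.K, reconcile="keep")

    verif_segments = _perturb_segments(segments, cfg, rng)
    verif_segments, K_v = _split_verif_states(verif_segments, cfg, rng)
    verif_labels = _labels_from_segments(verif_segments, genome)
    verif_post = _make_posterior(verif_labels, K_v, cfg, rng)
    verif = Annotation(genome, verif_labels, verif_post, K=K_v, reconcile="keep")
    return SyntheticTruth(
        config=cfg, genome=genome, segments=segments, true_labels=true_labels,
        pi=pi, pi_window=w, base=base, verif=verif,
    )


def redraw_verification(truth: SyntheticTruth, seed: int) -> np.ndarray:
    """Fresh verification labels from the same truth (for Monte-Carlo checks)."""
    rng = np.random.default_rng(seed)
    segs = _perturb_segments(truth.segments, truth.config, rng)
    return _labels_from_segments(segs, truth.genome)


def generate_setting_pair(
    cfg: GeneratorConfig, setting: str = "S1"
) -> tuple[Annotation, Annotation]:
    """Replicate pair under one of the variability settings.

    S1: each replicate gets an independent model-noise draw (flips +
    jitter at ``flip_prob``) and independent observation noise.
    S2: one shared model-noise draw; replicates differ only by
    observation noise (``obs_flip_prob``).
    S3: one shared observation-noise draw on the truth; replicates get
    independent model-noise draws.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.genome()
    truth = _draw_segments(cfg, rng)

    def model_noise(segs):
        return _perturb_segments(segs, cfg, rng)

    def obs_noise(segs):
        return _perturb_segments(segs, cfg, rng, jitter=False,
                                 flip_override=cfg.obs_flip_prob)

    if setting == "S1":
        a, b = obs_noise(model_noise(truth)), obs_noise(model_noise(truth))
    elif setting == "S2":
        shared = model_noise(truth)
        a, b = obs_noise(shared), obs_noise(shared)
    elif setting == "S3":
        shared = obs_noise(truth)
        a, b = model_noise(shared), model_noise(shared)
    else:
        raise SimulationError(f"unknown setting {setting!r}")
    out = []
    for segs in (a, b):
        labels = _labels_from_segments(segs, genome)
        post = _make_posterior(labels, cfg.K, cfg, rng)
        out.append(Annotation(genome, labels, post, K=cfg.K, reconcile="keep"))
    return out[0], out[1]
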