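"""Subclonal copy-number detection from binned read-depth tracks.

A minor clone present at fraction phi shifts the bulk copy number of an
amplified segment by only phi * (CN_sub - CN_base), too small for
segment-level callers tuned to the dominant clone.  The procedure here
projects segment boundaries obtained from a *reference* sample (one in
which the clone of interest is dominant, e.g. a cultured derivative) onto
the query sample's 1-kb binned copy-number track, then runs a Wilcoxon
rank-sum test between the bin values of each pair of adjacent segments.
A significant difference replicating the reference's up/down pattern is
evidence that the amplification exists subclonally in the query.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CNBinTrack",
    "SegmentSet",
    "AdjacentComparison",
    "GainLossCall",
    "segment_track",
    "project_segments",
    "compare_adjacent_segments",
    "detect_subclonal_pattern",
    "gain_pattern_from_means",
    "call_gain_loss",
    "stars",
]

LOSS_THRESHOLD = 1.5
GAIN_THRESHOLD = 2.5


@dataclass(frozen=True)
class CNBinTrack:
    """Binned copy-number values along one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    cn: np.ndarray
    bin_size: int = 1000

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        cn = np.asarray(self.cn, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "cn", cn)
        if not (len(starts) == len(ends) == len(cn)):
            raise ValueError("starts, ends, cn must have equal length")
        if len(starts) and ((np.diff(starts) <= 0).any() or (ends <= starts).any()):
            raise ValueError("bins must be sorted with end > start")
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            raise ValueError("bins must not overlap")
        if not np.isfinite(cn).all():
            raise ValueError("copy-number values must be finite")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass(frozen=True)
class SegmentSet:
    """Ordered, non-overlapping segments covering the analyzed interval."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    labels: tuple[str, ...]
    source_sample: str = ""

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if not (len(starts) == len(ends) == len(self.labels)):
            raise ValueError("starts, ends, labels must have equal length")
        if len(starts) == 0:
            raise ValueError("segment set must be non-empty")
        if (ends <= starts).any() or (len(starts) > 1 and (starts[1:] < ends[:-1]).any()):
            raise ValueError("segments must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class AdjacentComparison:
    pair: str               # "i to j", 1-based segment indices
    n_left: int
    n_right: int
    statistic: float        # Mann-Whitney U of the left side
    p_value: float
    significance: str       # ns / * / ** / ***
    direction: int          # sign of median(right) - median(left)


@dataclass(frozen=True)
class GainLossCall:
    label: str
    start: int
    end: int
    mean_cn: float
    call: str               # loss / neutral / gain


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# segmentation (stand-in for an external HMM segmenter)

def _gaussian_cost(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    # sum of squared deviations of x[i:j] around its mean
    n = j - i
    s = prefix[j] - prefix[i]
    return float(prefix_sq[j] - prefix_sq[i] - s * s / n)


def segment_track(track: CNBinTrack, penalty: float | None = None) -> SegmentSet:
    """Segment a binned track by binary segmentation with a Gaussian cost.

    Changepoints are accepted while the reduction in within-segment sum of
    squares exceeds ``penalty``.  The default penalty is BIC-style,
    ``2 * sigma^2 * log(n)``, with sigma estimated robustly from successive
    bin differences (median absolute difference / (0.6745 * sqrt(2))), so a
    flat noisy track yields a single segment while a step of a few noise
    SDs is split.  Fully deterministic.
    """
    x = track.cn
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 bins to segment")
    if penalty is None:
        diffs = np.abs(np.diff(x))
        sigma = np.median(diffs) / (0.6745 * np.sqrt(2.0)) if len(diffs) else 0.0
        sigma = max(sigma, 1e-12)
        penalty = 2.0 * sigma**2 * np.log(n)

    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(x * x)])

    breakpoints: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        base = _gaussian_cost(prefix, prefix_sq, i, j)
        # best single split of x[i:j]
        ks = np.arange(i + 1, j)
        ns_l = ks - i
        ns_r = j - ks
        s_l = prefix[ks] - prefix[i]
        s_r = prefix[j] - prefix[ks]
        cost = (
            prefix_sq[ks] - prefix_sq[i] - s_l * s_l / ns_l
            + prefix_sq[j] - prefix_sq[ks] - s_r * s_r / ns_r
        )
        k = int(ks[np.argmin(cost)])
        if base - float(cost.min()) > penalty:
            breakpoints.append(k)
            stack.append((i, k))
            stack.append((k, j))

    breakpoints.sort()
    bounds = [0, *breakpoints, n]
    seg_starts = track.starts[np.array(bounds[:-1])]
    seg_ends = np.array([track.ends[b - 1] for b in bounds[1:]])
    labels = tuple(str(i + 1) for i in range(len(seg_starts)))
    return SegmentSet(track.chrom, seg_starts, seg_ends, labels, source_sample="segmented")


# ---------------------------------------------------------------------------
# projection and adjacent-segment testing

def project_segments(reference: SegmentSet, query: CNBinTrack):
    """Assign each query bin to the reference segment containing its midpoint.

    Returns a list of ``(label, start, end, values)`` per segment plus the
    number of bins falling outside every segment (reported and excluded).
    Bin count is conserved: sum of per-segment counts + excluded = total.
    """
    if reference.chrom != query.chrom:
        raise ValueError(
            f"chromosome mismatch: segments on {reference.chrom}, track on {query.chrom}"
        )
    mids = query.midpoints
    idx = np.searchsorted(reference.starts, mids, side="right") - 1
    inside = (idx >= 0) & (mids < reference.ends[np.clip(idx, 0, len(reference) - 1)])
    n_excluded = int((~inside).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} bins fall outside all reference segments; excluded")
    projection = []
    for s in range(len(reference)):
        values = query.cn[inside & (idx == s)]
        projection.append(
            (reference.labels[s], int(reference.starts[s]), int(reference.ends[s]), values)
        )
    return projection, n_excluded


def rank_sum_test(a: np.ndarray, b: np.ndarray, alternative: str = "two-sided",
                  exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both samples have <= ``exact_max_n``
    observations and there are no ties; normal approximation with tie and
    continuity correction otherwise.  Two identical constant samples are
    maximally tied and return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(a) <= exact_max_n and len(b) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_adjacent_segments(projection, alternative: str = "two-sided",
                              exact_max_n: int = 25) -> list[AdjacentComparison]:
    """Rank-sum test between the bin values of each consecutive segment pair."""
    filled = [(lab, vals) for lab, _s, _e, vals in projection if len(vals) > 0]
    skipped = len(projection) - len(filled)
    if skipped:
        warnings.warn(f"{skipped} segments had no bins and were skipped")
    if len(filled) < 2:
        raise ValueError("need at least 2 segments with bins to compare")
    out = []
    for (lab_a, va), (lab_b, vb) in zip(filled[:-1], filled[1:]):
        u, p = rank_sum_test(va, vb, alternative=alternative, exact_max_n=exact_max_n)
        direction = int(np.sign(np.median(vb) - np.median(va)))
        out.append(
            AdjacentComparison(
                pair=f"{lab_a} to {lab_b}",
                n_left=len(va),
                n_right=len(vb),
                statistic=u,
                p_value=p,
                significance=stars(p),
                direction=direction,
            )
        )
    return out


def gain_pattern_from_means(segment_means: Sequence[float], tol: float = 0.25) -> list[str]:
    """Expected up/down/flat direction for each adjacent pair of a reference.

    A pair is "up" if the right segment's mean exceeds the left's by more
    than ``tol`` copies, "down" if lower by more than ``tol``, else "flat".
    """
    pattern = []
    for a, b in zip(segment_means[:-1], segment_means[1:]):
        if b - a > tol:
            pattern.append("up")
        elif a - b > tol:
            pattern.append("down")
        else:
            pattern.append("flat")
    return pattern


def detect_subclonal_pattern(
    comparisons: Sequence[AdjacentComparison],
    reference_gain_pattern: Sequence[str],
    alpha: float = 0.05,
    concordance_threshold: float = 0.75,
) -> dict:
    """Decide whether the reference's amplification ladder exists in the query.

    A non-flat adjacent pair is concordant if its query test is significant
    at ``alpha`` *and* steps in the reference's direction.  The region is
    called "detected" when the concordant fraction among non-flat pairs
    reaches ``concordance_threshold``.
    """
    if len(comparisons) != len(reference_gain_pattern):
        raise ValueError(
            f"{len(comparisons)} comparisons but {len(reference_gain_pattern)} pattern entries"
        )
    for d in reference_gain_pattern:
        if d not in ("up", "down", "flat"):
            raise ValueError(f"unknown direction {d!r}")
    informative = 0
    concordant = 0
    for comp, direction in zip(comparisons, reference_gain_pattern):
        if direction == "flat":
            continue
        informative += 1
        expected_sign = 1 if direction == "up" else -1
        if comp.p_value < alpha and comp.direction == expected_sign:
            concordant += 1
    fraction = concordant / informative if informative else float("nan")
    return {
        "n_pairs": len(comparisons),
        "n_informative": informative,
        "n_concordant": concordant,
        "concordance": fraction,
        "verdict": "detected"
        if informative and fraction >= concordance_threshold
        else "not_detected",
    }


def call_gain_loss(segments: SegmentSet, means: Sequence[float]) -> list[GainLossCall]:
    """Threshold segment mean CN: < 1.5 loss, > 2.5 gain, else neutral.

    Boundary values sit exactly on the threshold and are called neutral.
    """
    if len(means) != len(segments):
        raise ValueError("one mean per segment required")
    calls = []
    for lab, s, e, m in zip(segments.labels, segments.starts, segments.ends, means):
        if m < LOSS_THRESHOLD:
            call = "loss"
        elif m > GAIN_THRESHOLD:
            call = "gain"
        else:
            call = "neutral"
        calls.append(GainLossCall(lab, int(s), int(e), float(m), call))
    return calls
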