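"""CORE discovery and group discrimination from accessibility peak sets.

A CORE (cluster of cis-regulatory elements) is a genomic region where
accessible-chromatin peaks (CREs) are far more densely packed than chance
placement allows — the regulatory analogue of super-enhancer stitching.
COREs are called per sample from the sorted peak list, merged into a
cross-sample catalog, and each catalog CORE is then scored for how well
its presence/absence separates two sample groups (e.g. functionally
validated LSC+ vs LSC- AML fractions) via a predictability coefficient.

Coordinates are 0-based half-open internally; rendered CORE names are
1-based inclusive ("CORE-chr9-2014811-2032652" style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CRESet",
    "CORE",
    "CatalogCore",
    "DetectionMatrix",
    "PredictabilityResult",
    "call_cores",
    "build_catalog",
    "detection_matrix",
    "rank_predictability",
    "cre_accessibility_frequency",
]


@dataclass(frozen=True)
class CRESet:
    """One sample's accessible regions (peaks), sorted by (chrom, start)."""

    sample_id: str
    group: str
    peaks: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        peaks = tuple(sorted((str(c), int(s), int(e)) for c, s, e in self.peaks))
        object.__setattr__(self, "peaks", peaks)
        for c, s, e in peaks:
            if s < 0 or e <= s:
                raise ValueError(f"invalid peak {c}:{s}-{e}")

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[list, list]] = {}
        for c, s, e in self.peaks:
            out.setdefault(c, ([], []))
            out[c][0].append(s)
            out[c][1].append(e)
        return {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()}

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CORE:
    """A called cluster: a contiguous run of >= 2 peaks in one sample."""

    chrom: str
    start: int
    end: int
    members: tuple[tuple[int, int], ...]

    @property
    def order(self) -> int:
        return len(self.members)

    @property
    def name(self) -> str:
        return f"CORE-{self.chrom}-{self.start + 1}-{self.end}"


@dataclass
class CatalogCore:
    chrom: str
    start: int
    end: int
    contributors: set[str] = field(default_factory=set)

    @property
    def name(self) -> str:
        return f"CORE-{self.chrom}-{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class DetectionMatrix:
    """Catalog CORE x sample presence booleans, with group labels."""

    catalog: tuple[CatalogCore, ...]
    samples: tuple[str, ...]
    matrix: np.ndarray  # bool, shape (n_catalog, n_samples)
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.catalog), len(self.samples)):
            raise ValueError("matrix shape inconsistent with catalog/samples")


@dataclass(frozen=True)
class PredictabilityResult:
    core_name: str
    chrom: str
    start: int
    end: int
    freq_pos: float
    freq_neg: float
    pc: float
    rank: int


def _span_p_values(spans: np.ndarray, n_peaks: int, order: int, extent: int) -> np.ndarray:
    """Left-tail null probability of each run's start-to-start span.

    Under uniform peak placement, the span of ``order`` consecutive peaks
    out of ``n_peaks`` over an extent G is G * Beta(order-1, n_peaks-order+2)
    (a difference of uniform order statistics).  A tiny p-value marks a run
    packed far more tightly than chance placement allows.
    """
    with np.errstate(under="ignore"):
        return stats.beta.cdf(spans / extent, order - 1, n_peaks - order + 2)


def _knee_cut(spans: np.ndarray) -> float:
    """Elbow of the ascending sorted span curve: maximum vertical distance
    below the chord joining its endpoints.  On a pure uniform background the
    sorted span curve is convex and this rule is permissive; kept for
    comparison with elbow-style cluster callers."""
    m = len(spans)
    if m < 3:
        return -1.0
    y = np.sort(spans).astype(float)
    x = np.arange(m, dtype=float)
    chord = y[0] + (y[-1] - y[0]) * x / (m - 1)
    return float(y[int(np.argmax(chord - y))])


def call_cores(
    cres: CRESet,
    min_order: int = 2,
    max_order: int = 20,
    alpha: float = 0.05,
    threshold: str = "order-stat",
) -> list[CORE]:
    """Call COREs in one sample's peak set.

    Every run of k consecutive same-chromosome peaks (min_order <= k <=
    max_order) is a candidate window.  Under the default "order-stat" rule
    a run qualifies when its span p-value (see ``_span_p_values``) clears a
    Bonferroni-corrected ``alpha`` over the runs of its order; qualifying
    runs are then accepted greedily in ascending p-value (most improbably
    tight first, ties broken by larger order, smaller span, coordinate),
    skipping runs that overlap an accepted CORE.  Accepting by evidence
    rather than by order prevents a sloppy high-order window that merely
    contains a tight cluster plus stragglers from swallowing the cluster.

    The "knee" rule instead thresholds each order's spans at the elbow of
    the sorted span curve and accepts largest order first.  Deterministic
    either way; invariant to input peak order (peaks are sorted on entry).
    """
    if min_order < 2:
        raise ValueError("min_order must be >= 2")
    if threshold not in ("order-stat", "knee"):
        raise ValueError("threshold must be 'order-stat' or 'knee'")
    accepted: list[CORE] = []
    for chrom, (starts, ends) in sorted(cres.by_chrom().items()):
        n = len(starts)
        if n < min_order:
            continue
        extent = int(ends[-1] - starts[0])
        if extent <= 0:
            continue
        # (sort key..., run start index, order)
        candidates: list[tuple] = []
        for k in range(min(max_order, n), min_order - 1, -1):
            spans = starts[k - 1:] - starts[: n - k + 1]
            if threshold == "order-stat":
                p = _span_p_values(spans, n, k, extent)
                for i in np.flatnonzero(p <= alpha / len(spans)):
                    candidates.append((p[i], -k, spans[i], starts[i], int(i), k))
            else:
                cut = _knee_cut(spans)
                for i in np.flatnonzero(spans <= cut):
                    candidates.append((-k, spans[i], starts[i], 0.0, int(i), k))
        candidates.sort(key=lambda t: t[:4])
        taken: list[tuple[int, int]] = []
        for *_key, i, k in candidates:
            run_start = int(starts[i])
            run_end = int(ends[i + k - 1])
            if any(run_start < te and ts < run_end for ts, te in taken):
                continue
            taken.append((run_start, run_end))
            members = tuple((int(starts[j]), int(ends[j])) for j in range(i, i + k))
            accepted.append(CORE(chrom, run_start, run_end, members))
    accepted.sort(key=lambda c: (c.chrom, c.start, c.end))
    return accepted


def build_catalog(per_sample_cores: Mapping[str, Sequence[CORE]]) -> list[CatalogCore]:
    """Union-merge COREs across samples (single linkage on >= 1 bp overlap)."""
    if not per_sample_cores:
        raise ValueError("need at least one sample")
    intervals = []
    for sample, cores in per_sample_cores.items():
        for c in cores:
            intervals.append((c.chrom, c.start, c.end, sample))
    intervals.sort(key=lambda t: (t[0], t[1], t[2]))
    catalog: list[CatalogCore] = []
    for chrom, start, end, sample in intervals:
        if catalog and catalog[-1].chrom == chrom and start < catalog[-1].end:
            catalog[-1].end = max(catalog[-1].end, end)
            catalog[-1].contributors.add(sample)
        else:
            catalog.append(CatalogCore(chrom, start, end, {sample}))
    return catalog


def _overlaps(a_start, a_end, b_start, b_end, min_reciprocal: float) -> bool:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return False
    if min_reciprocal > 0:
        if ov < min_reciprocal * (a_end - a_start):
            return False
        if ov < min_reciprocal * (b_end - b_start):
            return False
    return True


def detection_matrix(
    catalog: Sequence[CatalogCore],
    per_sample_cores: Mapping[str, Sequence[CORE]],
    groups: Mapping[str, str],
    min_reciprocal_overlap: float = 0.0,
) -> DetectionMatrix:
    """Presence/absence of each catalog CORE per sample.

    A sample detects a catalog CORE iff one of its own called COREs
    overlaps it by >= 1 bp (optionally requiring a reciprocal overlap
    fraction of both intervals).
    """
    samples = tuple(per_sample_cores.keys())
    mat = np.zeros((len(catalog), len(samples)), dtype=bool)
    for j, sample in enumerate(samples):
        for core in per_sample_cores[sample]:
            for i, entry in enumerate(catalog):
                if entry.chrom != core.chrom:
                    continue
                if _overlaps(entry.start, entry.end, core.start, core.end,
                             min_reciprocal_overlap):
                    mat[i, j] = True
    return DetectionMatrix(tuple(catalog), samples, mat, dict(groups))


def rank_predictability(
    dm: DetectionMatrix, positive_group: str = "LSC+", negative_group: str = "LSC-"
) -> list[PredictabilityResult]:
    """Rank catalog COREs by how well presence predicts the positive group.

    The predictability coefficient is the balanced accuracy of the rule
    "detected => positive group":

        PC = (freq_pos + (1 - freq_neg)) / 2

    where freq_pos / freq_neg are per-group detection frequencies.  PC is
    0.5 for an uninformative CORE (equal frequencies) and 1 for perfect
    separation.  Ties in PC break by descending |freq_pos - freq_neg|,
    then genomic coordinate.
    """
    pos_idx = [j for j, s in enumerate(dm.samples) if dm.groups.get(s) == positive_group]
    neg_idx = [j for j, s in enumerate(dm.samples) if dm.groups.get(s) == negative_group]
    if not pos_idx or not neg_idx:
        raise ValueError(
            f"both groups must be non-empty (got {len(pos_idx)} {positive_group}, "
            f"{len(neg_idx)} {negative_group})"
        )
    rows = []
    for i, entry in enumerate(dm.catalog):
        freq_pos = float(dm.matrix[i, pos_idx].mean())
        freq_neg = float(dm.matrix[i, neg_idx].mean())
        pc = (freq_pos + (1.0 - freq_neg)) / 2.0
        rows.append((entry, freq_pos, freq_neg, pc))
    rows.sort(key=lambda t: (-t[3], -abs(t[1] - t[2]), t[0].chrom, t[0].start))
    return [
        PredictabilityResult(e.name, e.chrom, e.start, e.end, fp, fn, pc, rank)
        for rank, (e, fp, fn, pc) in enumerate(rows, start=1)
    ]


def cre_accessibility_frequency(
    entry: CatalogCore,
    per_sample_cores: Mapping[str, Sequence[CORE]],
    cre_sets: Mapping[str, CRESet],
    groups: Mapping[str, str],
) -> list[dict]:
    """Per-member-CRE accessibility fractions by group for one catalog CORE.

    Consensus member CREs are the union-merged member intervals of every
    contributing sample's COREs overlapping the entry.  A CRE counts as
    accessible in a sample iff any of that sample's peaks overlaps it by
    >= 1 bp.
    """
    member_intervals = []
    for sample, cores in per_sample_cores.items():
        for core in cores:
            if core.chrom == entry.chrom and _overlaps(
                entry.start, entry.end, core.start, core.end, 0.0
            ):
                member_intervals.extend(core.members)
    member_intervals.sort()
    consensus: list[list[int]] = []
    for s, e in member_intervals:
        if consensus and s < consensus[-1][1]:
            consensus[-1][1] = max(consensus[-1][1], e)
        else:
            consensus.append([s, e])

    group_levels = sorted(set(groups.values()))
    results = []
    for s, e in consensus:
        counts = {g: 0 for g in group_levels}
        totals = {g: 0 for g in group_levels}
        for sample, cres in cre_sets.items():
            g = groups.get(sample)
            if g is None:
                continue
            totals[g] += 1
            chrom_peaks = cres.by_chrom().get(entry.chrom)
            if chrom_peaks is None:
                continue
            ps, pe = chrom_peaks
            # any peak overlapping [s, e)
            lo = np.searchsorted(ps, e)
            if (pe[:lo] > s).any():
                counts[g] += 1
        results.append(
            {
                "cre_start": s,
                "cre_end": e,
                **{
                    f"frac_{g}": counts[g] / totals[g] if totals[g] else float("nan")
                    for g in group_levels
                },
            }
        )
    return results
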