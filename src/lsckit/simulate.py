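"""Synthetic inputs with the statistical structure the pipeline assumes.

The study data this pipeline was designed around (sorted AML fraction
ATAC-seq peak atlases, binned WGS copy-number tracks, limiting-dilution
xenograft tables, and a four-tier sorted-fraction expression matrix) are
access-restricted, so this module generates inputs with the same
statistical structure:

* limiting-dilution assays — per-animal Bernoulli responses under the
  single-hit model P(response) = 1 - exp(-f * dose);
* copy-number tracks — a reference sample in which the clone of interest
  is dominant (bin values Normal(subclone CN, sd)) and a query sample in
  which it is a phi-fraction mixture (Normal((1-phi)*base + phi*sub, sd));
* grouped peak atlases — Poisson uniform background peaks plus planted
  CRE clusters carried with group-specific probabilities;
* expression matrices — four hierarchy tiers with a signature-gene effect
  decreasing monotonically from stem to mature, plus Gaussian noise.

All randomness flows from one root seed through ``numpy``'s SeedSequence
spawning, with a fixed child index per stage, so each stage is
independently reproducible and identical (seed, config) pairs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv import CNBinTrack
from .cores import CRESet
from .lda import LDAssay
from .stemness import GeneSignature

__all__ = [
    "PlantedCore",
    "CNSegmentSpec",
    "ExpressionBlock",
    "SimConfig",
    "simulate_lda_assay",
    "simulate_cn_tracks",
    "simulate_peak_atlas",
    "simulate_expression",
]

# fixed child indices of the root SeedSequence, one per stage
_STAGE_LDA, _STAGE_CN, _STAGE_PEAKS, _STAGE_EXPR = 0, 1, 2, 3


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for one pipeline stage of a root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class PlantedCore:
    """A CRE cluster planted into the peak atlas with group-specific carriage."""

    chrom: str = "chrS"
    start: int = 2_000_000
    n_cres: int = 7
    cre_width: int = 300
    gap: int = 2_000
    presence_prob_pos: float = 0.75
    presence_prob_neg: float = 0.20

    def __post_init__(self) -> None:
        if self.n_cres < 2:
            raise ValueError("a cluster needs >= 2 CREs")
        for p in (self.presence_prob_pos, self.presence_prob_neg):
            if not 0.0 <= p <= 1.0:
                raise ValueError("presence probabilities must be in [0, 1]")
        if self.start < 0 or self.cre_width <= 0 or self.gap < 0:
            raise ValueError("invalid cluster geometry")

    @property
    def end(self) -> int:
        return self.start + self.n_cres * self.cre_width + (self.n_cres - 1) * self.gap

    def peak_intervals(self) -> list[tuple[int, int]]:
        step = self.cre_width + self.gap
        return [
            (self.start + i * step, self.start + i * step + self.cre_width)
            for i in range(self.n_cres)
        ]


@dataclass(frozen=True)
class CNSegmentSpec:
    """One segment of the simulated copy-number profile."""

    start: int
    end: int
    base_cn: float = 2.0
    subclone_cn: float = 2.0
    phi: float = 0.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ExpressionBlock:
    n_genes: int = 1000
    n_signature_genes: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.5
    samples_per_tier: int = 5

    def __post_init__(self) -> None:
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes must be <= n_genes")
        if min(self.n_genes, self.n_signature_genes, self.samples_per_tier) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_cn_profile() -> tuple[CNSegmentSpec, ...]:
    # an amplification ladder: alternating diploid / amplified (+3) segments
    # of 500 kb (500 bins at 1 kb), subclone fraction 0.3, read-depth noise 0.3
    segs = []
    pos = 0
    for i in range(8):
        amp = i % 2 == 1
        segs.append(
            CNSegmentSpec(
                start=pos,
                end=pos + 500_000,
                base_cn=2.0,
                subclone_cn=5.0 if amp else 2.0,
                phi=0.3,
                noise_sd=0.3,
            )
        )
        pos += 500_000
    return tuple(segs)


def _default_planted_cores() -> tuple[PlantedCore, ...]:
    # one discriminative cluster (carried by 75% of LSC+ vs 20% of LSC-,
    # echoing the detection contrast the discrimination stage must recover)
    # plus five group-balanced decoys
    cores = [PlantedCore(start=1_000_000, presence_prob_pos=0.75, presence_prob_neg=0.20)]
    for i in range(5):
        cores.append(
            PlantedCore(
                start=2_500_000 + i * 1_200_000,
                presence_prob_pos=0.5,
                presence_prob_neg=0.5,
            )
        )
    return tuple(cores)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for every synthetic input.

    Defaults mirror the analyzed cohort: 41 LSC+ and 52 LSC- fractions, an
    active-cell frequency of 1/286.4 for the dilution assay, a planted
    discriminative CRE cluster carried at 75% vs 20%, and a phi = 0.3
    amplification ladder for the subclone stage.
    """

    seed: int = 0
    n_lsc_pos: int = 41
    n_lsc_neg: int = 52
    genome_length: int = 10_000_000
    background_peak_rate: float = 5.0  # peaks per Mb
    peak_width: int = 300
    planted_cores: tuple[PlantedCore, ...] = field(default_factory=_default_planted_cores)
    cn_profile: tuple[CNSegmentSpec, ...] = field(default_factory=_default_cn_profile)
    lda_truth: float = 1.0 / 286.4
    lda_doses: tuple[float, ...] = (30_000, 7_500, 1_875, 469)
    lda_mice_per_dose: tuple[int, ...] = (3, 4, 6, 5)
    expression_block: ExpressionBlock = field(default_factory=ExpressionBlock)

    def __post_init__(self) -> None:
        if min(self.n_lsc_pos, self.n_lsc_neg) < 0:
            raise ValueError("sample counts must be >= 0")
        if self.lda_truth <= 0:
            raise ValueError("lda_truth frequency must be > 0")
        if self.background_peak_rate < 0:
            raise ValueError("background_peak_rate must be >= 0")
        ivs = sorted((c.chrom, c.start, c.end) for c in self.planted_cores)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs[:-1], ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("planted clusters must not overlap")
        for c in self.planted_cores:
            if c.end > self.genome_length:
                raise ValueError(f"planted cluster {c.chrom}:{c.start} exceeds genome bounds")


def simulate_lda_assay(
    f: float, doses: Sequence[float], mice_per_dose: Sequence[int], seed: int
) -> LDAssay:
    """Binomial dose-response draws under the single-hit model."""
    if f <= 0:
        raise ValueError("frequency f must be > 0")
    doses = tuple(float(d) for d in doses)
    mice = tuple(int(m) for m in mice_per_dose)
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be > 0")
    if len(doses) != len(mice):
        raise ValueError("doses and mice_per_dose must align")
    rng = stage_rng(seed, _STAGE_LDA)
    p = -np.expm1(-f * np.asarray(doses))
    responders = tuple(int(rng.binomial(m, pi)) for m, pi in zip(mice, p))
    return LDAssay(doses=doses, tested=mice, responders=responders)


def response_probability(f: float, dose: float) -> float:
    """Closed-form single-hit response probability 1 - exp(-f * dose)."""
    if f < 0 or dose < 0:
        raise ValueError("f and dose must be >= 0")
    return float(-np.expm1(-f * dose))


def simulate_cn_tracks(
    cn_profile: Sequence[CNSegmentSpec],
    bin_size: int = 1000,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[CNBinTrack, CNBinTrack]:
    """Reference (pure clone) and query (phi-mixture) binned CN tracks.

    Segments must tile an interval without overlap.  Reference bins are
    Normal(subclone_cn, sd): the clone of interest is dominant there.
    Query bins are Normal((1-phi)*base_cn + phi*subclone_cn, sd).
    """
    profile = sorted(cn_profile, key=lambda s: s.start)
    if not profile:
        raise ValueError("cn_profile must be non-empty")
    for a, b in zip(profile[:-1], profile[1:]):
        if b.start < a.end:
            raise ValueError(f"profile segments overlap at {b.start}")
    rng = stage_rng(seed, _STAGE_CN)
    starts, ends, ref_cn, query_cn = [], [], [], []
    for seg in profile:
        bs = np.arange(seg.start, seg.end, bin_size, dtype=np.int64)
        be = np.minimum(bs + bin_size, seg.end)
        n = len(bs)
        mixture = (1.0 - seg.phi) * seg.base_cn + seg.phi * seg.subclone_cn
        ref_cn.append(seg.subclone_cn + rng.normal(0.0, seg.noise_sd, n))
        query_cn.append(mixture + rng.normal(0.0, seg.noise_sd, n))
        starts.append(bs)
        ends.append(be)
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    ref = CNBinTrack(chrom, starts, ends, np.concatenate(ref_cn), bin_size)
    query = CNBinTrack(chrom, starts.copy(), ends.copy(), np.concatenate(query_cn), bin_size)
    return ref, query


def simulate_peak_atlas(config: SimConfig) -> tuple[dict[str, CRESet], dict[str, str]]:
    """Per-sample peak sets with planted clusters, plus group labels.

    Each sample receives Poisson(rate * genome_length) uniform-start
    fixed-width background peaks and, independently with its group's
    presence probability, every planted cluster's CREs.
    """
    rng = stage_rng(config.seed, _STAGE_PEAKS)
    mean_bg = config.background_peak_rate * config.genome_length / 1e6
    groups: dict[str, str] = {}
    atlas: dict[str, CRESet] = {}
    sample_specs = [(f"LSCpos_{i + 1:02d}", "LSC+") for i in range(config.n_lsc_pos)]
    sample_specs += [(f"LSCneg_{i + 1:02d}", "LSC-") for i in range(config.n_lsc_neg)]
    for sample_id, group in sample_specs:
        n_bg = rng.poisson(mean_bg)
        bg_starts = np.sort(
            rng.integers(0, max(config.genome_length - config.peak_width, 1), n_bg)
        )
        peaks = [("chrS", int(s), int(s + config.peak_width)) for s in bg_starts]
        for planted in config.planted_cores:
            p = planted.presence_prob_pos if group == "LSC+" else planted.presence_prob_neg
            if rng.random() < p:
                peaks.extend(
                    (planted.chrom, s, e) for s, e in planted.peak_intervals()
                )
        atlas[sample_id] = CRESet(sample_id, group, tuple(peaks))
        groups[sample_id] = group
    return atlas, groups


def simulate_expression(
    block: ExpressionBlock,
    n_fractions: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneSignature, pd.Series, dict[str, str]]:
    """Hierarchical expression matrix with graded stemness signal.

    Each signature gene i carries an additive effect ``delta_i`` whose
    magnitudes span 0.5x to 1.5x of ``effect_size`` (mean exactly
    ``effect_size``), scaled by a tier multiplier that decreases linearly
    and monotonically across tiers: 1 in tier 1 (stem) down to 0 in the
    last tier (mature).  Heterogeneous per-gene magnitudes make the
    stem-like *profile shape* — not just its level — resemble the
    reference, so rank-correlation scoring has signal as well.  All other
    genes are pure noise around their baselines.

    Returns (matrix, signature, reference profile, fraction labels); the
    reference profile is the noise-free tier-1 expectation of the
    signature genes, standing in for the mean over a stem-enriched
    reference cohort.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    rng = stage_rng(seed, _STAGE_EXPR)
    genes = [f"gene_{i + 1:04d}" for i in range(block.n_genes)]
    sig_genes = genes[: block.n_signature_genes]
    tiers = [f"tier{t + 1}" for t in range(n_fractions)]
    columns, fractions = [], {}
    values = []
    # per-gene baseline offsets so the reference ranking is non-trivial
    base = rng.normal(0.0, 1.0, block.n_genes)
    if block.n_signature_genes > 1:
        delta = block.effect_size * np.linspace(0.5, 1.5, block.n_signature_genes)
    else:
        delta = np.array([block.effect_size])
    for t, tier in enumerate(tiers):
        multiplier = (
            (n_fractions - 1 - t) / (n_fractions - 1) if n_fractions > 1 else 1.0
        )
        for k in range(block.samples_per_tier):
            col = f"{tier}_s{k + 1}"
            x = base + rng.normal(0.0, block.noise_sd, block.n_genes)
            x[: block.n_signature_genes] += multiplier * delta
            columns.append(col)
            fractions[col] = tier
            values.append(x)
    matrix = pd.DataFrame(np.column_stack(values), index=genes, columns=columns)
    signature = GeneSignature(
        name="synthetic_stemness",
        genes=tuple(sig_genes),
        weights=tuple(1.0 for _ in sig_genes),
    )
    reference = pd.Series(
        base[: block.n_signature_genes] + delta, index=sig_genes, name="reference"
    )
    return matrix, signature, reference, fractions
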