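"""Single-sample stemness scoring from expression signatures.

Three complementary scores, all computed per sample from a log-scale
genes x samples expression matrix:

* correlation score — Spearman rank correlation of the sample's signature-
  gene expression against a reference profile (the mean expression of the
  same genes across a reference set of stem-enriched fractions); the
  LSC104 procedure.
* weighted score — a fixed linear combination sum(w_i * x_i) over
  signature genes; the LSC17 procedure (weights supplied externally).
* enrichment score — a rank-based single-sample running-sum statistic
  (ssGSEA-style): genes are ranked by descending expression, the walk
  steps up at signature genes (increments proportional to rank^tau,
  normalized) and down by 1/(N - n) elsewhere, and the score is the sum of
  the running-sum values.  tau = 0 gives the unweighted walk.  Absolute
  values differ from GSVA's Kolmogorov-Smirnov-like score, but group
  contrasts — the quantity of interest — are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSignature",
    "signature_correlation_score",
    "weighted_signature_score",
    "enrichment_score",
    "score_hierarchy",
]


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.weights is not None:
            weights = tuple(float(w) for w in self.weights)
            object.__setattr__(self, "weights", weights)
            if len(weights) != len(genes):
                raise ValueError(
                    f"signature {self.name!r}: {len(weights)} weights for {len(genes)} genes"
                )

    def __len__(self) -> int:
        return len(self.genes)


def signature_correlation_score(sample: pd.Series, reference: pd.Series) -> float:
    """Spearman correlation of a sample to a signature reference profile.

    Computed over the genes shared between the sample column and the
    reference profile, with average-rank tie handling.  Requires >= 3
    shared genes.
    """
    shared = sample.index.intersection(reference.index)
    missing = reference.index.difference(sample.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared signature genes, have {len(shared)}; "
            f"missing from sample: {sorted(missing)}"
        )
    rho, _ = stats.spearmanr(sample.loc[shared].to_numpy(), reference.loc[shared].to_numpy())
    return float(rho)


def weighted_signature_score(
    sample: pd.Series, signature: GeneSignature, missing: str = "fail"
) -> float:
    """Weighted sum of signature-gene expression, sum(w_i * x_i).

    An unweighted signature scores with unit weights.  ``missing`` governs
    genes absent from the sample: "fail" raises, "drop" scores the genes
    that are present.
    """
    if missing not in ("fail", "drop"):
        raise ValueError("missing policy must be 'fail' or 'drop'")
    weights = signature.weights or tuple(1.0 for _ in signature.genes)
    absent = [g for g in signature.genes if g not in sample.index]
    if absent and missing == "fail":
        raise KeyError(f"signature genes missing from sample: {absent}")
    return float(
        sum(w * sample[g] for g, w in zip(signature.genes, weights) if g in sample.index)
    )


def enrichment_score(sample: pd.Series, signature: GeneSignature, tau: float = 0.25) -> float:
    """Single-sample running-sum enrichment of a gene set.

    Genes are ordered by descending expression (ties keep stable input
    order).  At the i-th gene (1-based from the top) the walk steps up by
    ``rank_i**tau`` (rank_i = N - i + 1, so the top gene carries the
    largest weight), normalized so up-steps over the signature sum to 1;
    non-signature genes step down by 1/(N - n).  The score is the sum of
    the N running-sum values; a set concentrated at the top of the ranking
    scores positive, at the bottom negative.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    n_total = len(sample)
    in_sig = sample.index.isin(signature.genes)
    n_sig = int(in_sig.sum())
    if n_sig == 0:
        raise ValueError("no signature genes present in the sample")
    if n_sig == n_total:
        raise ValueError("signature covers all genes; down-step undefined")
    order = np.argsort(-sample.to_numpy(), kind="stable")
    sig_sorted = in_sig[order]
    ranks = np.arange(n_total, 0, -1, dtype=float)  # N at the top, 1 at the bottom
    up = np.where(sig_sorted, ranks**tau, 0.0)
    up /= up[sig_sorted].sum()
    steps = np.where(sig_sorted, up, -1.0 / (n_total - n_sig))
    return float(np.cumsum(steps).sum())


def score_hierarchy(
    matrix: pd.DataFrame,
    fractions: Mapping[str, str],
    signature: GeneSignature,
    reference: pd.Series,
    hierarchy_order: Sequence[str],
    tau: float = 0.25,
    weighted_missing: str = "fail",
) -> tuple[pd.DataFrame, dict]:
    """Score every sample and check median monotonicity along a hierarchy.

    Parameters
    ----------
    matrix
        genes x samples expression (log scale expected).
    fractions
        sample id -> fraction/tier label; every sample column must map to
        a label appearing in ``hierarchy_order``.
    hierarchy_order
        Tier labels from most stem-like to most mature; medians of each
        score are checked for strict decrease along this order.

    Returns
    -------
    (scores, monotonicity)
        ``scores`` has one row per sample with the three scores and the
        fraction label; ``monotonicity`` maps score name -> bool (or None
        when fewer than 2 tiers are present).
    """
    unknown = [s for s in matrix.columns if s not in fractions]
    if unknown:
        raise ValueError(f"samples without a fraction label: {unknown}")
    bad = sorted(set(fractions[s] for s in matrix.columns) - set(hierarchy_order))
    if bad:
        raise ValueError(f"fraction labels not in hierarchy_order: {bad}")

    rows = []
    for s in matrix.columns:
        col = matrix[s]
        rows.append(
            {
                "sample": s,
                "fraction": fractions[s],
                "spearman_score": signature_correlation_score(col, reference),
                "weighted_score": weighted_signature_score(
                    col, signature, missing=weighted_missing
                ),
                "enrichment_score": enrichment_score(col, signature, tau=tau),
            }
        )
    scores = pd.DataFrame(rows).set_index("sample")

    present_tiers = [t for t in hierarchy_order if t in set(scores["fraction"])]
    monotonicity: dict[str, bool | None] = {}
    for name in ("spearman_score", "weighted_score", "enrichment_score"):
        if len(present_tiers) < 2:
            monotonicity[name] = None
            continue
        medians = [scores.loc[scores["fraction"] == t, name].median() for t in present_tiers]
        monotonicity[name] = all(a > b for a, b in zip(medians[:-1], medians[1:]))
    return scores, monotonicity
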