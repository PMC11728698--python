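"""Community-structure comparison through pairwise distance matrices.

Beyond per-sample distances to the truth, a profiler should preserve the
*relationships between samples*: if two communities are similar in the
ground truth they should look similar in the estimate.  This module
computes all-pairs sample distance matrices (Bray–Curtis, weighted
UniFrac or Aitchison) and compares the reference matrix with an estimated
one via the Jensen–Shannon divergence of their normalized upper triangles.
Lower divergence means the estimate preserves community structure better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .io import AbundanceTable, PhyloTree
from .metrics import multiplicative_replacement, _clr

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "jensen_shannon",
    "rank_tools",
]

METRIC_NAMES = ("bray_curtis", "weighted_unifrac", "aitchison")


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric within 1e-12")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)


def pairwise_distances(
    table: AbundanceTable,
    metric_name: str,
    tree: PhyloTree | None = None,
    delta: float | None = None,
) -> DistanceMatrix:
    """All sample-pair distances of a normalized table under one metric.

    Pairwise computation is vectorized but mathematically identical to the
    corresponding single-pair metric (equality is asserted in the test
    suite).  ``tree`` is required for weighted UniFrac.
    """
    if metric_name not in METRIC_NAMES:
        raise ValidationError(f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}")
    x = table.values  # features × samples
    sums = x.sum(axis=0)
    if (np.abs(sums - 1.0) > 1e-6).any():
        raise ValidationError("pairwise_distances requires a normalized table")

    if metric_name == "bray_curtis":
        cond = pdist(x.T, metric="braycurtis")
    elif metric_name == "weighted_unifrac":
        if tree is None:
            raise ValidationError("weighted_unifrac requires a tree")
        feats = tuple(table.feature_ids)
        in_tree = set(tree.leaf_names)
        keep = np.array([f in in_tree for f in feats])
        sub = x[keep]
        colsums = sub.sum(axis=0)
        if (colsums == 0).any():
            raise ValidationError("a sample carries no abundance on the tree")
        sub = sub / colsums
        lengths, membership = tree.branch_table(tuple(f for f, k in zip(feats, keep) if k))
        branch_mass = (membership @ sub) * lengths[:, None]
        # Σ b|u−v| / Σ b(u+v) is Bray–Curtis on the branch-length-weighted
        # branch-mass vectors.
        cond = pdist(branch_mass.T, metric="braycurtis")
    else:  # aitchison
        d = delta if delta is not None else 1.0 / x.shape[0] ** 2
        clr_cols = np.column_stack(
            [_clr(multiplicative_replacement(x[:, j], d)) for j in range(x.shape[1])]
        )
        cond = pdist(clr_cols.T, metric="euclidean")
    return DistanceMatrix(table.sample_ids, squareform(cond), metric_name)


def _normalized_triangle(m: DistanceMatrix) -> np.ndarray:
    tri = m.condensed()
    total = tri.sum()
    if total <= 0:
        raise ValidationError(
            f"{m.metric_name} matrix has no positive off-diagonal entry"
        )
    return tri / total


def jensen_shannon(p: DistanceMatrix, q: DistanceMatrix, literal_kl: bool = False) -> float:
    """Jensen–Shannon divergence between two distance matrices.

    The upper triangles are normalized to unit sum, forming discrete
    distributions p_ij and q_ij; with m = (p+q)/2,
    JSD = [D(p‖m) + D(q‖m)] / 2, natural log, terms with p_ij = 0
    contributing 0.  Result lies in [0, ln 2].

    ``literal_kl=True`` instead evaluates the symmetrized direct form
    [D(p‖q) + D(q‖p)] / 2 (which is unbounded and infinite whenever the
    supports differ); it exists for comparison only.
    """
    if p.sample_ids != q.sample_ids:
        raise ValidationError("distance matrices have mismatched sample ids")
    pi = _normalized_triangle(p)
    qi = _normalized_triangle(q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        if (b[mask] == 0).any():
            return float("inf")
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    if literal_kl:
        return 0.5 * (kl(pi, qi) + kl(qi, pi))
    m = 0.5 * (pi + qi)
    return 0.5 * (kl(pi, m) + kl(qi, m))


def rank_tools(jsd_by_tool: dict[str, float]) -> list[dict]:
    """Rank tools by ascending divergence (lower = closer to the truth).

    Ties share a rank; every tool at the minimal divergence is flagged
    ``best``.
    """
    if not jsd_by_tool:
        raise ValidationError("rank_tools: empty input")
    ordered = sorted(jsd_by_tool.items(), key=lambda kv: kv[1])
    out, rank = [], 0
    for i, (tool, val) in enumerate(ordered):
        if i == 0 or val > ordered[i - 1][1]:
            rank = i + 1
        out.append({"tool": tool, "jsd": float(val), "rank": rank,
                    "best": val == ordered[0][1]})
    return out
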