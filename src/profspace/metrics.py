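"""Per-sample evaluation metrics between reference and estimated profiles.

Presence/absence accuracy
    TP/FP/FN counts on the support sets (a feature "present" means
    abundance strictly greater than 0 — no detection threshold), giving
    sensitivity TP/(TP+FN) and precision TP/(TP+FP); FPRA (summed estimated
    abundance over false positives) and FNRA (summed reference abundance
    over false negatives) quantify how much *mass* the errors carry.

Alpha diversity
    Richness (nonzero-feature count) and Shannon entropy in nats,
    H = −Σ x ln x.

Beta-diversity style distances to the truth
    Bray–Curtis  d = Σ|u−v| / Σ(u+v);
    weighted UniFrac  d = Σ b_i |u_i − v_i| / Σ b_i (u_i + v_i) over the
    branches of a phylogeny, where a branch's u_i is the abundance mass of
    the leaves below it;
    Aitchison distance — Euclidean distance between clr-transformed
    compositions after multiplicative zero replacement.

A zero denominator makes a metric *undefined*; undefined values propagate
as NaN and are excluded from medians (with the exclusion count reported),
never silently coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AbundanceTable, PhyloTree

__all__ = [
    "ConfusionCounts",
    "SampleMetrics",
    "EvaluationReport",
    "confusion_counts",
    "sensitivity_precision",
    "fpra_fnra",
    "tpra",
    "richness_shannon",
    "bray_curtis",
    "weighted_unifrac",
    "aitchison",
    "evaluate_sample_set",
]

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int


@dataclass
class SampleMetrics:
    """All per-sample metrics; NaN marks an undefined value."""

    sample_id: str
    richness_diff: float
    shannon_diff: float
    bray_curtis: float
    unifrac: float
    aitchison: float
    sensitivity: float
    precision: float
    fpra: float
    fnra: float


_METRIC_FIELDS = [f.name for f in fields(SampleMetrics) if f.name != "sample_id"]


def _pair(u, v):
    """Align two abundance vectors; error on mismatched indices/lengths."""
    if isinstance(u, pd.Series) and isinstance(v, pd.Series):
        if not u.index.equals(v.index):
            if set(u.index) != set(v.index):
                raise ValidationError("abundance vectors have mismatched feature indices")
            v = v.reindex(u.index)
        return u.to_numpy(dtype=float), v.to_numpy(dtype=float)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError(
            f"abundance vectors have mismatched lengths {u.shape} vs {v.shape}"
        )
    return u, v


def confusion_counts(ref_col, est_col) -> ConfusionCounts:
    """TP/FP/FN on the support sets of one sample (zero means exactly 0)."""
    r, e = _pair(ref_col, est_col)
    rp, ep = r > 0, e > 0
    return ConfusionCounts(
        TP=int(np.sum(rp & ep)),
        FP=int(np.sum(~rp & ep)),
        FN=int(np.sum(rp & ~ep)),
    )


def sensitivity_precision(c: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, precision); NaN when a denominator is zero."""
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else float("nan")
    prec = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else float("nan")
    return sens, prec


def _check_normalized(x: np.ndarray, name: str) -> None:
    s = x.sum()
    if abs(s - 1.0) > _NORM_TOL:
        raise ValidationError(f"{name} column sums to {s!r}; expected a normalized column")


def fpra_fnra(ref_col, est_col) -> tuple[float, float]:
    """False-positive / false-negative relative abundance of one sample."""
    r, e = _pair(ref_col, est_col)
    _check_normalized(r, "reference")
    _check_normalized(e, "estimate")
    fpra = float(e[(r == 0) & (e > 0)].sum())
    fnra = float(r[(r > 0) & (e == 0)].sum())
    return fpra, fnra


def tpra(fpra: float) -> float:
    """True-positive relative abundance, 1 − FPRA."""
    return 1.0 - fpra


def richness_shannon(col) -> tuple[int, float]:
    """(richness, Shannon entropy in nats) of a normalized column."""
    x = col.to_numpy(dtype=float) if isinstance(col, pd.Series) else np.asarray(col, float)
    nz = x[x > 0]
    shannon = float(-(nz * np.log(nz)).sum()) if nz.size else 0.0
    return int(nz.size), shannon


def bray_curtis(u, v) -> float:
    """Σ|u−v| / Σ(u+v); NaN when both vectors are all-zero."""
    a, b = _pair(u, v)
    denom = (a + b).sum()
    if denom == 0:
        return float("nan")
    return float(np.abs(a - b).sum() / denom)


def _tree_vectors(u, v, tree: PhyloTree, strict: bool):
    """Align a vector pair to the tree leaves, dropping/renormalizing extras."""
    if isinstance(u, pd.Series):
        a, b = _pair(u, v)
        feats = list(u.index)
    else:
        a, b = _pair(u, v)
        feats = tree.leaf_names
        if len(a) != len(feats):
            raise ValidationError(
                "bare arrays must match the tree leaf count "
                f"({len(a)} values vs {len(feats)} leaves)"
            )
    in_tree = set(tree.leaf_names)
    keep = np.array([f in in_tree for f in feats])
    if not keep.all():
        missing = [f for f, k in zip(feats, keep) if not k]
        if strict:
            raise ValidationError(f"features absent from tree: {missing}")
        warnings.warn(
            f"{len(missing)} feature(s) absent from tree dropped and "
            "abundances renormalized",
            stacklevel=3,
        )
        a, b = a[keep], b[keep]
        feats = [f for f, k in zip(feats, keep) if k]
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        return None
    return a / sa, b / sb, feats


def weighted_unifrac(u, v, tree: PhyloTree, strict: bool = False) -> float:
    """Normalized weighted UniFrac distance between two profiles.

    For every branch, the abundance below it is the sum over descendant
    leaves; the distance is Σ b|u−v| / Σ b(u+v) ∈ [0, 1].  Features absent
    from the tree are dropped and the vectors re-closed (``strict=True``
    raises instead).  NaN when either profile carries no mass on the tree.
    """
    lengths_all = [n.length for n in tree.tree.traverse(include_self=False)]
    if lengths_all and all(l == 0 for l in lengths_all):
        raise ValidationError("tree has no (nonzero) branch lengths")
    aligned = _tree_vectors(u, v, tree, strict)
    if aligned is None:
        return float("nan")
    a, b, feats = aligned
    lengths, membership = tree.branch_table(tuple(feats))
    ub = membership @ a
    vb = membership @ b
    denom = float(lengths @ (ub + vb))
    if denom == 0:
        return float("nan")
    return float(lengths @ np.abs(ub - vb) / denom)


def multiplicative_replacement(x: np.ndarray, delta: float) -> np.ndarray:
    """Replace zeros of a composition by ``delta``, rescaling the rest.

    Each zero becomes ``delta`` and every nonzero entry is multiplied by
    (1 − z·delta), z the number of zeros, so the vector still sums to 1.
    """
    x = np.asarray(x, dtype=float)
    z = int(np.sum(x == 0))
    if z == 0:
        return x
    if z * delta >= 1:
        raise ValidationError(
            f"replacement exceeds unit mass: {z} zeros × delta {delta!r} ≥ 1"
        )
    return np.where(x == 0, delta, x * (1 - z * delta))


def _clr(x: np.ndarray) -> np.ndarray:
    lx = np.log(x)
    return lx - lx.mean()


def aitchison(u, v, delta: float | None = None) -> float:
    """Aitchison distance: ‖clr(u′) − clr(v′)‖₂ after zero replacement.

    ``delta`` defaults to 1/D², D the number of features in the shared
    space.
    """
    a, b = _pair(u, v)
    _check_normalized(a, "u")
    _check_normalized(b, "v")
    if delta is None:
        delta = 1.0 / len(a) ** 2
    if delta <= 0:
        raise ValidationError(f"delta must be positive, got {delta!r}")
    ar = multiplicative_replacement(a, delta)
    br = multiplicative_replacement(b, delta)
    return float(np.linalg.norm(_clr(ar) - _clr(br)))


@dataclass
class EvaluationReport:
    """Per-sample metrics plus median summaries for one (ref, est) pair."""

    samples: list[SampleMetrics]
    per_sample: pd.DataFrame          # rows = samples, columns = metrics
    medians: dict[str, float]         # NaN-excluded medians
    n_undefined: dict[str, int]       # how many samples were excluded per metric


def _union_align(ref: AbundanceTable, est: AbundanceTable):
    shared = [s for s in ref.sample_ids if s in set(est.sample_ids)]
    if not shared:
        raise ValidationError("reference and estimate share no samples")
    feats = list(ref.feature_ids)
    seen = set(feats)
    feats += [f for f in est.feature_ids if f not in seen]
    r = ref.data.reindex(index=feats, columns=shared, fill_value=0.0).fillna(0.0)
    e = est.data.reindex(index=feats, columns=shared, fill_value=0.0).fillna(0.0)
    return r, e, feats, shared


def evaluate_sample_set(
    ref: AbundanceTable,
    est: AbundanceTable,
    tree: PhyloTree | None = None,
    delta: float | None = None,
    strict_tree: bool = False,
) -> EvaluationReport:
    """Compute every metric for every shared sample.

    Features are unioned (absent ones imputed as exact 0).  The UniFrac
    column is NaN throughout when no tree is given.  Medians exclude
    undefined (NaN) values; the exclusion counts are reported alongside.
    """
    r, e, feats, shared = _union_align(ref, est)
    rows = []
    for s in shared:
        rc, ec = r[s], e[s]
        c = confusion_counts(rc, ec)
        sens, prec = sensitivity_precision(c)
        try:
            fp_ra, fn_ra = fpra_fnra(rc, ec)
        except ValidationError:
            fp_ra = fn_ra = float("nan")  # an all-zero column has no FPRA/FNRA
        rich_r, shan_r = richness_shannon(rc)
        rich_e, shan_e = richness_shannon(ec)
        uf = (
            weighted_unifrac(rc, ec, tree, strict=strict_tree)
            if tree is not None
            else float("nan")
        )
        try:
            ait = aitchison(rc, ec, delta=delta)
        except ValidationError:
            ait = float("nan")  # undefined for an all-zero column
        rows.append(
            SampleMetrics(
                sample_id=s,
                richness_diff=float(rich_e - rich_r),
                shannon_diff=shan_e - shan_r,
                bray_curtis=bray_curtis(rc, ec),
                unifrac=uf,
                aitchison=ait,
                sensitivity=sens,
                precision=prec,
                fpra=fp_ra,
                fnra=fn_ra,
            )
        )
    per_sample = pd.DataFrame(
        [{f: getattr(m, f) for f in ["sample_id", *_METRIC_FIELDS]} for m in rows]
    ).set_index("sample_id")
    medians, n_undef = {}, {}
    for col in _METRIC_FIELDS:
        vals = per_sample[col].to_numpy()
        defined = vals[~np.isnan(vals)]
        medians[col] = float(np.median(defined)) if defined.size else float("nan")
        n_undef[col] = int(np.isnan(vals).sum())
    return EvaluationReport(rows, per_sample, medians, n_undef)
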