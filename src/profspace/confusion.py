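"""Detection of systematically confused species pairs.

When a profiler's catalogue resolves taxa differently from the reference,
a species that is truly present (but missing from — or named differently
in — the catalogue) is often reported as a close relative instead.  Across
many samples this leaves a signature: the reference abundance of the
missed species (a false negative) correlates with the estimated abundance
of the spuriously reported one (a false positive).

A sample is *eligible* for a candidate pair (fn, fp) only when the pair is
simultaneously an FN and an FP there — ref[fn] > 0, est[fn] = 0,
ref[fp] = 0, est[fp] > 0; in any other sample at least one of the two is
not actually an error, so the sample carries no evidence of confusion.
Pairs with enough eligible samples and a Pearson correlation above the
threshold are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import AbundanceTable

__all__ = [
    "ConfusionPairRecord",
    "eligible_samples",
    "candidate_pairs",
    "find_confused_pairs",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SAMPLES = 25
DEFAULT_R_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionPairRecord:
    fn_feature: str
    fp_feature: str
    n_eligible: int
    pearson_r: float


def _aligned(ref: AbundanceTable, est: AbundanceTable):
    shared = [s for s in ref.sample_ids if s in set(est.sample_ids)]
    if not shared:
        raise ValidationError("reference and estimate share no samples")
    feats = list(ref.feature_ids)
    seen = set(feats)
    feats += [f for f in est.feature_ids if f not in seen]
    r = ref.data.reindex(index=feats, columns=shared, fill_value=0.0).fillna(0.0)
    e = est.data.reindex(index=feats, columns=shared, fill_value=0.0).fillna(0.0)
    return r.to_numpy(), e.to_numpy(), feats, shared


def eligible_samples(
    ref: AbundanceTable, est: AbundanceTable, fn_feature: str, fp_feature: str
) -> set[str]:
    """Samples where (fn, fp) is simultaneously a false negative and a false positive."""
    r, e, feats, shared = _aligned(ref, est)
    pos = {f: i for i, f in enumerate(feats)}
    for f in (fn_feature, fp_feature):
        if f not in pos:
            raise ValidationError(f"unknown feature id {f!r}")
    i, j = pos[fn_feature], pos[fp_feature]
    mask = (r[i] > 0) & (e[i] == 0) & (r[j] == 0) & (e[j] > 0)
    return {s for s, m in zip(shared, mask) if m}


def candidate_pairs(
    ref: AbundanceTable, est: AbundanceTable
) -> Iterator[tuple[str, str]]:
    """Candidate (fn, fp) pairs with at least one eligible sample.

    Per-sample FN and FP incidence is indexed first, so only pairs that
    actually co-occur as (FN, FP) in some sample are enumerated — pairs
    without any eligible sample cannot qualify anyway, and the full
    |features|² scan is avoided.
    """
    r, e, feats, _ = _aligned(ref, est)
    fn_mat = (r > 0) & (e == 0)
    fp_mat = (r == 0) & (e > 0)
    seen: set[tuple[int, int]] = set()
    for s in range(fn_mat.shape[1]):
        fns = np.flatnonzero(fn_mat[:, s])
        fps = np.flatnonzero(fp_mat[:, s])
        for i in fns:
            for j in fps:
                if i != j and (i, j) not in seen:
                    seen.add((i, j))
                    yield feats[i], feats[j]


def find_confused_pairs(
    ref: AbundanceTable,
    est: AbundanceTable,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> list[ConfusionPairRecord]:
    """All confused pairs with ≥ ``min_samples`` eligible samples and r > threshold.

    Pearson correlation is computed between the reference abundance of the
    FN feature and the estimated abundance of the FP feature over the
    eligible samples; the comparison is strict (r must *exceed* the
    threshold).  Pairs whose either series has fewer than 3 distinct values
    (correlation undefined or degenerate) are skipped with a logged note.
    Output is sorted by descending r, then by feature ids for determinism.
    """
    if min_samples < 3:
        raise ValidationError("min_samples must be at least 3")
    r, e, feats, _ = _aligned(ref, est)
    fn_mat = (r > 0) & (e == 0)
    fp_mat = (r == 0) & (e > 0)
    # eligible-sample counts for every (fn, fp) pair in one matmul
    counts = fn_mat.astype(np.int32) @ fp_mat.T.astype(np.int32)
    np.fill_diagonal(counts, 0)
    records: list[ConfusionPairRecord] = []
    for i, j in zip(*np.nonzero(counts >= min_samples)):
        mask = fn_mat[i] & fp_mat[j]
        x = r[i, mask]
        y = e[j, mask]
        if len(np.unique(x)) < 3 or len(np.unique(y)) < 3:
            logger.info(
                "skipping pair (%s, %s): fewer than 3 distinct values",
                feats[i], feats[j],
            )
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.info(
                "skipping pair (%s, %s): zero variance over eligible samples",
                feats[i], feats[j],
            )
            continue
        rho = float(stats.pearsonr(x, y).statistic)
        if rho > r_threshold:
            records.append(
                ConfusionPairRecord(feats[i], feats[j], int(mask.sum()), rho)
            )
    records.sort(key=lambda rec: (-rec.pearson_r, rec.fn_feature, rec.fp_feature))
    return records


def confusion_pairs_frame(records: list[ConfusionPairRecord]) -> pd.DataFrame:
    """Records as a DataFrame (columns fn_feature, fp_feature, n_eligible, pearson_r)."""
    return pd.DataFrame(
        [
            {
                "fn_feature": r.fn_feature,
                "fp_feature": r.fp_feature,
                "n_eligible": r.n_eligible,
                "pearson_r": r.pearson_r,
            }
            for r in records
        ],
        columns=["fn_feature", "fp_feature", "n_eligible", "pearson_r"],
    )
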