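"""Projection of abundance tables into a common feature space.

Different profilers report abundances against different catalogues, so
their outputs cannot be compared directly.  Given a weighted feature
mapping from a native catalogue to a common reference space, a table is
converted by four rules:

1. native features sharing a common target are **summed**;
2. a native feature with several weighted targets is **split**
   proportionally to the mapping weights;
3. native features without correspondence (and, optionally, features whose
   target is not resolved at species rank) are **omitted**;
4. the converted columns are **renormalized** to sum 1.

The mass omitted in step 3 is accounted per sample as *lost abundance*
(relative-abundance mass) and *lost features* (count of dropped native
features that were actually present in that sample), so the cost of moving
to the common space is itself a measurable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AbundanceTable, FeatureMapping

__all__ = ["ProjectionResult", "project", "loss_summary"]


@dataclass
class ProjectionResult:
    """Outcome of projecting one table through one mapping.

    ``projected`` holds the renormalized common-space table.  For every
    sample, the pre-normalization projected mass plus ``lost_abundance``
    equals the original column sum (mass conservation, within 1e-9).
    """

    projected: AbundanceTable
    lost_abundance: pd.Series
    lost_features: pd.Series
    dropped_feature_ids: set[str]
    projected_mass: pd.Series  # per-sample column sum before renormalization
    all_zero_samples: list[str] = field(default_factory=list)


def project(
    table: AbundanceTable,
    mapping: FeatureMapping,
    species_rank_filter: bool = False,
    common_rank_labels: dict[str, str] | None = None,
) -> ProjectionResult:
    """Convert ``table`` to the common feature space defined by ``mapping``.

    Order of operations: split → sum → drop → renormalize.  With
    ``species_rank_filter`` every entry whose common target carries a rank
    label other than ``"species"`` is treated as unmapped (rank labels are
    taken from ``common_rank_labels``, falling back to the native table's
    own labels; features without a label pass through).

    Raises ``ValidationError`` ("empty projection") when no feature of the
    table is mapped at all.
    """
    native_in_table = set(table.feature_ids)
    entries = mapping.entries
    if species_rank_filter:
        labels: dict[str, str] = {}
        if table.rank_labels is not None:
            labels.update({k: v for k, v in table.rank_labels.items() if pd.notna(v)})
        if common_rank_labels:
            labels.update(common_rank_labels)
        entries = [
            (n, c, w)
            for (n, c, w) in entries
            if labels.get(c, "species") == "species"
        ]

    mapped_natives = {n for n, _, _ in entries}
    used = [(n, c, w) for (n, c, w) in entries if n in native_in_table]
    if not used and native_in_table:
        raise ValidationError("empty projection: no table feature is mapped")

    common_ids: list[str] = []
    seen: set[str] = set()
    for _, c, _ in used:
        if c not in seen:
            seen.add(c)
            common_ids.append(c)

    values = table.values
    n_common, n_samples = len(common_ids), table.n_samples
    out = np.zeros((n_common, n_samples), dtype=float)
    cpos = {c: k for k, c in enumerate(common_ids)}
    fpos = {f: i for i, f in enumerate(table.feature_ids)}
    for n, c, w in used:
        out[cpos[c]] += w * values[fpos[n]]

    dropped = [f for f in table.feature_ids if f not in mapped_natives]
    drop_rows = values[[fpos[f] for f in dropped]] if dropped else np.zeros((0, n_samples))
    lost_abundance = drop_rows.sum(axis=0)
    lost_features = (drop_rows > 0).sum(axis=0).astype(int)

    projected_mass = out.sum(axis=0)
    all_zero = [s for s, m in zip(table.sample_ids, projected_mass) if m == 0]
    norm = np.where(projected_mass > 0, projected_mass, 1.0)
    normalized = out / norm

    proj_table = AbundanceTable(
        pd.DataFrame(normalized, index=common_ids, columns=table.sample_ids),
        normalized=not all_zero,
    )
    sidx = pd.Index(table.sample_ids)
    return ProjectionResult(
        projected=proj_table,
        lost_abundance=pd.Series(lost_abundance, index=sidx),
        lost_features=pd.Series(lost_features, index=sidx),
        dropped_feature_ids=set(dropped),
        projected_mass=pd.Series(projected_mass, index=sidx),
        all_zero_samples=all_zero,
    )


def loss_summary(results: dict[str, ProjectionResult] | list[ProjectionResult]) -> pd.DataFrame:
    """Median lost abundance and lost features per tool.

    ``results`` maps tool name → :class:`ProjectionResult` (a bare list gets
    positional names).  Medians across samples; even-length medians use the
    midpoint of the two central order statistics.
    """
    if not results:
        raise ValidationError("loss_summary: empty result list")
    if isinstance(results, list):
        results = {f"tool_{i}": r for i, r in enumerate(results)}
    rows = {
        tool: {
            "median_lost_abundance": float(np.median(r.lost_abundance)),
            "median_lost_features": float(np.median(r.lost_features)),
        }
        for tool, r in results.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
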