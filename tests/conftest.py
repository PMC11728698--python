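from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from profspace import AbundanceTable, FeatureMapping

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


def random_table(rng: np.random.Generator, n_features: int, n_samples: int,
                 density: float = 0.6, normalized: bool = True) -> AbundanceTable:
    """Random sparse relative-abundance table; every column has ≥1 nonzero."""
    x = rng.random((n_features, n_samples)) * (rng.random((n_features, n_samples)) < density)
    for j in range(n_samples):
        if x[:, j].sum() == 0:
            x[rng.integers(n_features), j] = rng.random() + 0.1
    feats = [f"F{i:03d}" for i in range(n_features)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    df = pd.DataFrame(x, index=feats, columns=samples)
    if normalized:
        df = df / df.sum(axis=0)
    return AbundanceTable(df, normalized=normalized)


def random_mapping(rng: np.random.Generator, feature_ids,
                   p_unmapped: float = 0.15, p_split: float = 0.25) -> FeatureMapping:
    """Random native→common mapping with unmapped, split and shared targets."""
    entries = []
    n_common = max(2, int(len(feature_ids) * 0.7))
    commons = [f"C{i:03d}" for i in range(n_common)]
    for f in feature_ids:
        u = rng.random()
        if u < p_unmapped:
            continue
        if u < p_unmapped + p_split:
            i, j = rng.choice(n_common, size=2, replace=False)
            w = 0.2 + 0.6 * rng.random()
            entries.append((f, commons[i], w))
            entries.append((f, commons[j], 1.0 - w))
        else:
            entries.append((f, commons[int(rng.integers(n_common))], 1.0))
    if not entries:  # ensure at least one mapped feature
        entries.append((feature_ids[0], commons[0], 1.0))
    return FeatureMapping(entries)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        {"S1": [0.5, 0.3, 0.2], "S2": [0.1, 0.0, 0.9]},
        index=["A", "B", "C"],
    )
    return AbundanceTable(df, normalized=True)
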