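"""Synthetic communities, profiler-error simulation, mappings and trees.

Profile-level stand-in for a full read-simulation benchmark: instead of
generating sequencing reads and re-profiling them, ground-truth
relative-abundance profiles are drawn directly (long-tailed log-normal
abundances over a random subset of the feature universe) and profiler
behaviour is emulated by injecting the error modes benchmarks actually
observe — sibling confusion, abundance-dependent dropout, false-positive
injection and multiplicative noise.  Companion generators produce random
feature mappings (unmapped / split / shared targets) and random
phylogenies, so the projection, metric, community and confusion modules
are all exercisable without any external download.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .errors import ValidationError
from .io import AbundanceTable, FeatureMapping, PhyloTree

__all__ = [
    "SimulationConfig",
    "generate_truth",
    "simulate_profiler",
    "generate_mapping",
    "generate_tree",
    "default_feature_ids",
]


@dataclass
class SimulationConfig:
    """All knobs of the simulator.

    Defaults emulate the study conditions of a gut-microbiome benchmark:
    343 samples over a universe of 1000 species, ~200 species per sample,
    log-normal relative abundances (σ = 1 on the log scale, a long-tailed
    community with Shannon diversity near ln(200) − σ²/2 ≈ 4.8 nats), and
    an error-free profiler unless error rates are switched on.
    """

    n_samples: int = 343
    n_features: int = 1000
    richness_mean: int = 200
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    # profiler error model
    dropout_rate_at_min: float = 0.0
    fp_injection_rate: float = 0.0
    confusion_pairs: tuple[tuple[str, str, float], ...] = ()
    noise_sigma: float = 0.0
    # mapping generator
    unmapped_fraction: float = 0.0
    split_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ValidationError("n_samples and n_features must be positive")
        if not (1 <= self.richness_mean <= self.n_features):
            raise ValidationError(
                f"richness_mean {self.richness_mean} outside [1, n_features={self.n_features}]"
            )
        if self.abundance_sigma < 0:
            raise ValidationError("abundance_sigma must be nonnegative")
        if not (0 <= self.dropout_rate_at_min <= 1):
            raise ValidationError("dropout_rate_at_min must lie in [0, 1]")
        if self.fp_injection_rate < 0 or self.noise_sigma < 0:
            raise ValidationError("rates must be nonnegative")
        for src, sink, frac in self.confusion_pairs:
            if not (0 <= frac <= 1):
                raise ValidationError(
                    f"confusion fraction {frac!r} for ({src!r}, {sink!r}) outside [0, 1]"
                )
        for name in ("unmapped_fraction", "split_fraction"):
            val = getattr(self, name)
            if not (0 <= val <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.unmapped_fraction + self.split_fraction > 1:
            raise ValidationError("unmapped_fraction + split_fraction exceeds 1")
        self.confusion_pairs = tuple(
            (str(s), str(t), float(f)) for s, t, f in self.confusion_pairs
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["confusion_pairs"] = [list(p) for p in self.confusion_pairs]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "confusion_pairs" in data:
            data["confusion_pairs"] = tuple(tuple(p) for p in data["confusion_pairs"])
        return cls(**data)


def default_feature_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"F{i:0{width}d}" for i in range(1, n + 1)]


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def generate_truth(config: SimulationConfig) -> AbundanceTable:
    """Draw ground-truth community profiles.

    Per sample: richness ~ round(Normal(richness_mean, richness_mean/10))
    clipped to [1, n_features]; that many features chosen uniformly without
    replacement; abundances i.i.d. LogNormal(μ, σ), closed to sum 1.
    """
    rng = _rng(config.seed, 1)
    feats = default_feature_ids(config.n_features)
    x = np.zeros((config.n_features, config.n_samples))
    for s in range(config.n_samples):
        rich = int(np.clip(
            round(rng.normal(config.richness_mean, config.richness_mean / 10)),
            1, config.n_features,
        ))
        chosen = rng.choice(config.n_features, size=rich, replace=False)
        ab = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=rich)
        x[chosen, s] = ab / ab.sum()
    samples = [f"S{s:04d}" for s in range(1, config.n_samples + 1)]
    return AbundanceTable(pd.DataFrame(x, index=feats, columns=samples), normalized=True)


def simulate_profiler(truth: AbundanceTable, config: SimulationConfig) -> AbundanceTable:
    """Apply the configured error model to a ground-truth table.

    Error modes in fixed order: (1) sibling confusion — each configured
    (source, sink, fraction) moves that fraction of the source's abundance
    to the sink, which may be a feature absent from the truth; (2) dropout —
    a present feature is dropped with probability decreasing linearly in
    log-abundance, from ``dropout_rate_at_min`` at the sample minimum to 0
    at the maximum; (3) false-positive injection — Poisson(rate) absent
    features appear at abundances drawn log-uniformly from the low tail
    (below the sample's median nonzero truth abundance); (4) multiplicative
    log-normal noise on surviving entries.  Columns are then re-closed.
    """
    if (
        not config.confusion_pairs
        and config.dropout_rate_at_min == 0
        and config.fp_injection_rate == 0
        and config.noise_sigma == 0
    ):
        # error-free profiler reproduces the truth bit-for-bit
        return AbundanceTable(truth.data.copy(), normalized=truth.normalized,
                              rank_labels=truth.rank_labels)
    feats = list(truth.feature_ids)
    universe = set(feats)
    for src, _, _ in config.confusion_pairs:
        if src not in universe:
            raise ValidationError(f"confusion source {src!r} absent from feature universe")
    extra = [
        sink for _, sink, _ in config.confusion_pairs if sink not in universe
    ]
    extra = list(dict.fromkeys(extra))
    all_feats = feats + extra
    pos = {f: i for i, f in enumerate(all_feats)}

    x = np.zeros((len(all_feats), truth.n_samples))
    x[: len(feats)] = truth.values.copy()
    rng = _rng(config.seed, 2)

    for src, sink, frac in config.confusion_pairs:
        i, j = pos[src], pos[sink]
        moved = x[i] * frac
        x[i] -= moved
        x[j] += moved

    n_feat, n_samp = x.shape
    for s in range(n_samp):
        col = x[:, s]
        # dropout, decreasing linearly in log-abundance
        if config.dropout_rate_at_min > 0:
            nz = np.flatnonzero(col)
            if nz.size:
                la = np.log(col[nz])
                span = la.max() - la.min()
                if span > 0:
                    p = config.dropout_rate_at_min * (la.max() - la) / span
                else:
                    p = np.zeros_like(la)
                drop = rng.random(nz.size) < p
                col[nz[drop]] = 0.0
        # false-positive injection from the low tail of the truth
        if config.fp_injection_rate > 0:
            truth_nz = truth.values[:, s][truth.values[:, s] > 0]
            absent = np.flatnonzero(col == 0)
            k = min(int(rng.poisson(config.fp_injection_rate)), absent.size)
            if k > 0 and truth_nz.size:
                lo = float(truth_nz.min())
                med = float(np.median(truth_nz))
                chosen = rng.choice(absent, size=k, replace=False)
                col[chosen] = np.exp(
                    rng.uniform(np.log(lo), np.log(max(med, lo)), size=k)
                )
        # multiplicative log-normal noise
        if config.noise_sigma > 0:
            nz = np.flatnonzero(col)
            col[nz] *= np.exp(rng.normal(0.0, config.noise_sigma, size=nz.size))
        total = col.sum()
        if total > 0:
            col /= total
        x[:, s] = col

    return AbundanceTable(
        pd.DataFrame(x, index=all_feats, columns=truth.sample_ids)
    ).normalize()


def generate_mapping(feature_ids, config: SimulationConfig) -> FeatureMapping:
    """Random native → common mapping with unmapped, split and shared targets.

    ``round(unmapped_fraction · n)`` features get no mapping;
    ``round(split_fraction · remainder)`` map to two common targets with
    equal 0.5 weights (their targets are drawn from the one-to-one pool, so
    distinct native features share a common target whenever splits exist);
    the rest map one-to-one.  With both fractions zero the mapping is a
    pure renaming bijection.
    """
    feats = list(feature_ids)
    n = len(feats)
    rng = _rng(config.seed, 3)
    order = rng.permutation(n)
    n_unmapped = round(config.unmapped_fraction * n)
    rest = order[n_unmapped:]
    n_split = round(config.split_fraction * rest.size)
    split_idx = rest[:n_split]
    one_idx = rest[n_split:]

    width = max(4, len(str(n)))
    entries: list[tuple[str, str, float]] = []
    one_targets = []
    for k, i in enumerate(sorted(one_idx)):
        target = f"C{k + 1:0{width}d}"
        one_targets.append(target)
        entries.append((feats[i], target, 1.0))
    for m, i in enumerate(sorted(split_idx)):
        if len(one_targets) >= 2:
            t1, t2 = rng.choice(len(one_targets), size=2, replace=False)
            targets = (one_targets[t1], one_targets[t2])
        else:
            targets = (f"X{2 * m + 1:0{width}d}", f"X{2 * m + 2:0{width}d}")
        entries.append((feats[i], targets[0], 0.5))
        entries.append((feats[i], targets[1], 0.5))
    return FeatureMapping(entries)


def generate_tree(feature_ids, seed: int) -> PhyloTree:
    """Random rooted binary tree over the features by successive joins.

    Branch lengths are i.i.d. Exponential(mean 0.1); the root carries no
    parent edge.  Deterministic given the seed.
    """
    feats = list(feature_ids)
    if len(feats) < 2:
        raise ValidationError("generate_tree requires at least 2 features")
    rng = _rng(seed, 4)
    nodes = [TreeNode(name=f) for f in feats]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.exponential(0.1))
        b.length = float(rng.exponential(0.1))
        parent = TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)
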