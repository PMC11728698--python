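"""Independent brute-force reference implementations used only by tests.

Deliberately naive (python loops, explicit set enumeration, textbook
formulas) and written against the definitions, not against the package
code, so they can serve as oracles for the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def bray_curtis_brute(u, v) -> float:
    num = den = 0.0
    for a, b in zip(u, v):
        num += abs(a - b)
        den += a + b
    return num / den


def weighted_unifrac_brute(u, v, skbio_tree, feature_ids) -> float:
    """Eq-style evaluation: per-edge descendant-leaf set enumeration."""
    pos = {f: i for i, f in enumerate(feature_ids)}
    su, sv = float(np.sum(u)), float(np.sum(v))
    num = den = 0.0
    for node in skbio_tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        ub = sum(u[pos[t]] / su for t in tips if t in pos)
        vb = sum(v[pos[t]] / sv for t in tips if t in pos)
        b = node.length or 0.0
        num += b * abs(ub - vb)
        den += b * (ub + vb)
    return num / den


def aitchison_brute(u, v, delta: float) -> float:
    def replace(x):
        z = sum(1 for a in x if a == 0)
        return [delta if a == 0 else a * (1 - z * delta) for a in x]

    def clr(x):
        g = math.exp(sum(math.log(a) for a in x) / len(x))
        return [math.log(a / g) for a in x]

    cu, cv = clr(replace(list(u))), clr(replace(list(v)))
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(cu, cv)))


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def confused_pairs_brute(ref_df, est_df, min_samples, r_threshold):
    """All-pairs direct rule application on aligned DataFrames.

    Returns {(fn, fp): (n_eligible, r)} for qualifying pairs.
    """
    feats = list(ref_df.index)
    samples = list(ref_df.columns)
    out = {}
    for fn in feats:
        for fp in feats:
            if fn == fp:
                continue
            eligible = [
                s
                for s in samples
                if ref_df.at[fn, s] > 0
                and est_df.at[fn, s] == 0
                and ref_df.at[fp, s] == 0
                and est_df.at[fp, s] > 0
            ]
            if len(eligible) < min_samples:
                continue
            x = [ref_df.at[fn, s] for s in eligible]
            y = [est_df.at[fp, s] for s in eligible]
            if len(set(x)) < 3 or len(set(y)) < 3:
                continue
            r = pearson_brute(x, y)
            if r > r_threshold:
                out[(fn, fp)] = (len(eligible), r)
    return out


def jsd_brute(p, q) -> float:
    """JSD of two normalized discrete distributions, natural log."""
    total = 0.0
    for a, b in zip(p, q):
        m = (a + b) / 2
        if a > 0:
            total += 0.5 * a * math.log(a / m)
        if b > 0:
            total += 0.5 * b * math.log(b / m)
    return total
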