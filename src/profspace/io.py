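"""Readers and writers for the framework's text formats.

Three kinds of objects circulate through the evaluation pipeline:

* :class:`AbundanceTable` — a features × samples matrix of relative
  abundances (TSV: first column feature id, header row sample ids);
* :class:`FeatureMapping` — a weighted many-to-many correspondence from a
  profiler's native feature identifiers to a common reference space (TSV
  with columns ``native_id``, ``common_id``, ``weight``; a weightless
  dialect splits each native id's mass equally over its rows);
* :class:`PhyloTree` — a rooted tree with branch lengths whose leaves are
  common-space features (newick), used by weighted UniFrac.

All formats round-trip bit-stably and never reorder features or samples.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "AbundanceTable",
    "FeatureMapping",
    "PhyloTree",
    "read_abundance_table",
    "write_abundance_table",
    "read_mapping",
    "write_mapping",
    "read_tree",
    "write_tree",
    "read_cami_profile",
]

_NORM_TOL_STRICT = 1e-9   # invariant check on a table flagged normalized
_NORM_TOL_READ = 1e-6     # drift accepted (and rescaled away) when reading


@dataclass
class AbundanceTable:
    """Relative-abundance matrix with features in rows, samples in columns.

    Parameters
    ----------
    data : pandas.DataFrame
        Nonnegative reals; index = feature ids, columns = sample ids.
    normalized : bool
        If True every column sums to 1 within 1e-9 and the invariant is
        enforced at construction.
    rank_labels : pandas.Series, optional
        Per-feature taxonomic-rank tag (e.g. ``"species"``), indexed like
        ``data``.
    """

    data: pd.DataFrame
    normalized: bool = False
    rank_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("abundance table contains NaN")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance {values[i, j]!r} at feature "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        if self.normalized:
            sums = values.sum(axis=0)
            bad = np.abs(sums - 1.0) > _NORM_TOL_STRICT
            if bad.any():
                j = int(np.argmax(bad))
                raise ValidationError(
                    f"column {self.data.columns[j]!r} sums to {sums[j]!r}, "
                    "not 1 within 1e-9 (all-zero columns are disallowed in "
                    "normalized tables)"
                )
        if self.rank_labels is not None:
            self.rank_labels = self.rank_labels.reindex(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def column(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def normalize(self) -> "AbundanceTable":
        """Close every column to sum 1; all-zero columns are left all-zero."""
        sums = self.data.sum(axis=0)
        nz = sums > 0
        out = self.data.copy()
        out.loc[:, nz[nz].index] = out.loc[:, nz[nz].index] / sums[nz]
        return AbundanceTable(out, normalized=bool(nz.all()),
                              rank_labels=self.rank_labels)


@dataclass
class FeatureMapping:
    """Weighted many-to-many map from native to common feature identifiers.

    Each native id's weights sum to 1 (its mass is fully distributed);
    native ids absent from the mapping are unmapped by definition.
    """

    entries: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        per_native: dict[str, float] = {}
        for native, common, w in self.entries:
            if (native, common) in seen:
                raise FormatError(f"duplicate mapping entry ({native!r}, {common!r})")
            seen.add((native, common))
            if not (w > 0 and w <= 1 + 1e-12):
                raise ValidationError(
                    f"weight {w!r} for ({native!r}, {common!r}) outside (0, 1]"
                )
            per_native[native] = per_native.get(native, 0.0) + w
        for native, total in per_native.items():
            if abs(total - 1.0) > _NORM_TOL_READ:
                raise ValidationError(
                    f"weights for native id {native!r} sum to {total!r}, not 1"
                )

    @property
    def native_ids(self) -> set[str]:
        return {n for n, _, _ in self.entries}

    @property
    def common_ids(self) -> set[str]:
        return {c for _, c, _ in self.entries}

    def targets(self, native_id: str) -> list[tuple[str, float]]:
        return [(c, w) for n, c, w in self.entries if n == native_id]

    @classmethod
    def identity(cls, feature_ids) -> "FeatureMapping":
        return cls([(f, f, 1.0) for f in feature_ids])


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths, leaves = feature ids.

    Thin wrapper over :class:`skbio.TreeNode` adding the invariants the
    evaluation pipeline relies on (unique leaf labels, a defined nonnegative
    length on every non-root edge) and a cached branch/leaf incidence table
    used by weighted UniFrac.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        labels = [leaf.name for leaf in tree.tips()]
        if len(labels) != len(set(labels)):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise FormatError(f"duplicate leaf labels: {dups}")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            elif node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length!r} on edge above "
                    f"{node.name or '<internal>'}"
                )
        self._branch_cache: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.tree.tips()]

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.tree.traverse(include_self=False))

    def branch_table(self, feature_ids) -> tuple[np.ndarray, np.ndarray]:
        """Branch lengths and branch × feature leaf-membership incidence.

        Returns ``(lengths, membership)`` where ``lengths[k]`` is the length
        of branch *k* and ``membership[k, i]`` is 1 when feature ``i``
        descends through branch *k*.  Features absent from the tree get an
        all-zero column.  Cached per feature-id tuple.
        """
        key = tuple(feature_ids)
        if key not in self._branch_cache:
            pos = {f: i for i, f in enumerate(key)}
            lengths: list[float] = []
            rows: list[np.ndarray] = []
            # postorder: children are visited before parents, so each node's
            # descendant-leaf indicator is the union of its children's.
            below: dict[int, np.ndarray] = {}
            for node in self.tree.postorder(include_self=True):
                if node.is_tip():
                    vec = np.zeros(len(key), dtype=np.float64)
                    if node.name in pos:
                        vec[pos[node.name]] = 1.0
                else:
                    vec = np.zeros(len(key), dtype=np.float64)
                    for child in node.children:
                        vec += below[id(child)]
                below[id(node)] = vec
                if node.parent is not None:
                    lengths.append(float(node.length))
                    rows.append(vec)
            self._branch_cache[key] = (
                np.asarray(lengths, dtype=float),
                np.vstack(rows) if rows else np.zeros((0, len(key))),
            )
        return self._branch_cache[key]


# ---------------------------------------------------------------------------
# abundance tables


def read_abundance_table(
    path,
    normalized_expected: bool = False,
    percent: bool = False,
) -> AbundanceTable:
    """Read a TSV abundance table (rows = features, header = sample ids).

    With ``normalized_expected`` column sums must lie within 1e-6 of 1 and
    residual drift is rescaled away so every column sums to exactly 1.
    ``percent`` divides all values by 100 first (tables stated on a 0–100
    scale); without it, column sums above 1 + 1e-6 are rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids: {dups}")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups}")

    rank_labels = None
    if "rank" in raw.columns:
        rank_labels = raw.pop("rank")
        rank_labels.name = None
    if raw.shape[1] == 0:
        raise FormatError("table has no sample columns")

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            i = int(np.argmax((bad | raw[col].isna()).to_numpy()))
            raise ParseError(
                f"non-numeric cell {raw[col].iloc[i]!r} at feature "
                f"{raw.index[i]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    df = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    df.index.name = None
    if percent:
        df = df / 100.0

    sums = df.sum(axis=0).to_numpy()
    if normalized_expected:
        if (np.abs(sums - 1.0) > _NORM_TOL_READ).any():
            j = int(np.argmax(np.abs(sums - 1.0) > _NORM_TOL_READ))
            raise ValidationError(
                f"column {df.columns[j]!r} sums to {sums[j]!r}; expected 1 "
                "within 1e-6"
            )
        df = df / sums
        return AbundanceTable(df, normalized=True, rank_labels=rank_labels)
    if (sums > 1.0 + _NORM_TOL_READ).any():
        j = int(np.argmax(sums > 1.0 + _NORM_TOL_READ))
        raise ValidationError(
            f"column {df.columns[j]!r} sums to {sums[j]!r} > 1; relative "
            "abundances are proportions (pass percent=True for 0-100 tables)"
        )
    return AbundanceTable(df, rank_labels=rank_labels)


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write a table as TSV with 12 significant digits (round-trip ≤ 1e-12)."""
    if table.n_samples == 0:
        raise FormatError("refusing to write a table with no samples")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_table_stream(table, fh)


def _write_table_stream(table: AbundanceTable, fh) -> None:
    has_ranks = table.rank_labels is not None
    header = ["feature_id"] + (["rank"] if has_ranks else []) + table.sample_ids
    fh.write("\t".join(map(str, header)) + "\n")
    vals = table.values
    for i, fid in enumerate(table.feature_ids):
        cells = [str(fid)]
        if has_ranks:
            cells.append(str(table.rank_labels.iloc[i]))
        cells.extend(f"{x:.12g}" for x in vals[i])
        fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# feature mappings


def read_mapping(path) -> FeatureMapping:
    """Read a feature-mapping TSV.

    Canonical dialect has a ``weight`` column; in the weightless dialect a
    native id appearing on k rows has its mass split equally, weight 1/k per
    row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["native_id", "common_id"]:
        raise FormatError(
            f"mapping header must start 'native_id<TAB>common_id', got {cols!r}"
        )
    if "weight" in cols:
        try:
            weights = df["weight"].astype(float).tolist()
        except ValueError as exc:
            raise ParseError(f"non-numeric weight in mapping: {exc}") from exc
    else:
        counts = df["native_id"].value_counts()
        weights = [1.0 / counts[n] for n in df["native_id"]]
    entries = [
        (str(n), str(c), float(w))
        for n, c, w in zip(df["native_id"], df["common_id"], weights)
    ]
    return FeatureMapping(entries)


def write_mapping(mapping: FeatureMapping, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("native_id\tcommon_id\tweight\n")
        for native, common, w in mapping.entries:
            fh.write(f"{native}\t{common}\t{w:.12g}\n")


# ---------------------------------------------------------------------------
# trees


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree; a missing branch length becomes 0 (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except FormatError:
        raise
    except Exception as exc:  # skbio raises its own parse errors
        raise ParseError(f"unparseable newick: {exc}") from exc
    missing = [
        n for n in tree.traverse(include_self=False) if n.length is None
    ]
    if missing:
        warnings.warn(
            f"{len(missing)} edge(s) without branch length; defaulting to 0",
            stacklevel=2,
        )
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def tree_from_newick(newick: str) -> PhyloTree:
    """Parse a newick string (convenience for tests and examples)."""
    try:
        t = TreeNode.read(_io.StringIO(newick), format="newick")
    except Exception as exc:
        raise ParseError(f"unparseable newick: {exc}") from exc
    return PhyloTree(t)


# ---------------------------------------------------------------------------
# CAMI profiling format (optional ground-truth import)


def read_cami_profile(path, rank: str | None = "species") -> AbundanceTable:
    """Read a (possibly multi-sample) CAMI taxonomic-profiling file.

    Percentages are divided by 100.  When ``rank`` is given only rows of
    that rank are kept; columns are then re-closed to sum 1.  The canonical
    TSV dialect remains the preferred input; this reader exists for
    ground-truth files published in the CAMI format.
    """
    samples: dict[str, dict[str, float]] = {}
    ranks: dict[str, str] = {}
    current = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("@@"):
                continue  # column header
            if line.startswith("@"):
                key, _, val = line[1:].partition(":")
                if key.strip().lower() == "sampleid":
                    current = val.strip()
                    samples.setdefault(current, {})
                continue
            if current is None:
                raise FormatError(f"data line {lineno} before any @SampleID")
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"line {lineno}: expected ≥5 columns, got {len(parts)}")
            taxid, row_rank, _taxpath, taxpathsn, pct = parts[:5]
            if rank is not None and row_rank != rank:
                continue
            name = taxpathsn.split("|")[-1] or taxid
            try:
                value = float(pct) / 100.0
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad percentage {pct!r}") from exc
            samples[current][name] = samples[current].get(name, 0.0) + value
            ranks[name] = row_rank
    if not samples:
        raise FormatError("no samples found in CAMI profile")
    df = pd.DataFrame(samples).fillna(0.0)
    rank_labels = pd.Series({f: ranks.get(f, "") for f in df.index})
    table = AbundanceTable(df, rank_labels=rank_labels)
    return table.normalize()
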