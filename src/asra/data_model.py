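"""Containers and text readers/writers for expression data.

The whole package operates on log2-normalized expression matrices
(genes x samples) with optional Affymetrix-style detection calls
(P = present, M = marginal, A = absent) and per-sample condition labels.
All on-disk formats are plain UTF-8 tab-delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CALLS = frozenset({"P", "M", "A"})


class DataError(ValueError):
    """Base class for malformed or inconsistent input data."""


class ParseError(DataError):
    """A cell could not be parsed (names the offending row/column)."""


class ValidationError(DataError):
    """An invariant of a domain object is violated."""


class AlignmentError(DataError):
    """Two objects that must share gene/sample identifiers do not."""


class InsufficientOverlapError(DataError):
    """Fewer than two gene identifiers are shared between two objects."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensity matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric log2 intensities, index = gene ids, columns = sample ids.
    calls : pandas.DataFrame, optional
        Detection calls, same shape/labels as ``values``; entries in
        ``{"P", "M", "A"}``.
    conditions : pandas.Series, optional
        Per-sample condition label (e.g. ``ASYM``, ``SYM``, ``p53SYM``),
        indexed by sample id.
    """

    values: pd.DataFrame
    calls: pd.DataFrame | None = None
    conditions: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.calls is not None:
            self._check_calls(self.calls)
        if self.conditions is not None:
            cond = pd.Series(self.conditions)
            if not cond.index.equals(v.columns):
                cond = cond.reindex(v.columns)
            if cond.isna().any():
                missing = cond.index[cond.isna()].tolist()
                raise ValidationError(f"samples without condition label: {missing[:5]}")
            self.conditions = cond.astype(str)

    def _check_calls(self, calls: pd.DataFrame) -> None:
        if not calls.index.equals(self.values.index) or not calls.columns.equals(
            self.values.columns
        ):
            raise AlignmentError("detection calls do not share the matrix's gene/sample ids")
        bad = ~calls.isin(VALID_CALLS)
        if bad.to_numpy().any():
            g, s = np.argwhere(bad.to_numpy())[0]
            raise ValidationError(
                f"illegal detection call {calls.iat[g, s]!r} at gene "
                f"{calls.index[g]!r}, sample {calls.columns[s]!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids carrying the given condition label."""
        if self.conditions is None:
            raise ValidationError("matrix has no condition labels")
        hit = self.conditions[self.conditions == condition]
        if hit.empty:
            known = sorted(self.conditions.unique())
            raise ValidationError(f"unknown condition {condition!r}; labels present: {known}")
        return list(hit.index)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to the given genes (order preserved as given)."""
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise AlignmentError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[gene_ids],
            calls=None if self.calls is None else self.calls.loc[gene_ids],
            conditions=self.conditions,
        )


@dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        members = list(self.members)
        if len(members) != len(set(members)):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")
        self.members = frozenset(str(m) for m in members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


# -- readers / writers ---------------------------------------------------------


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First row = sample ids, first column = gene ids, numeric body.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dups[:5]}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise ParseError(
                f"non-numeric cell in {path} at gene {gene!r}, sample {col!r}: "
                f"{raw.at[gene, col]!r}"
            )
        values[col] = converted
    return ExpressionMatrix(values=values)


def write_expression_tsv(m: ExpressionMatrix, path, float_format: str = "%.6f") -> None:
    m.values.to_csv(path, sep="\t", float_format=float_format, index_label="gene_id")


def read_detection_calls(path, m: ExpressionMatrix) -> ExpressionMatrix:
    """Attach a P/M/A detection-call grid sharing ``m``'s exact ids."""
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls.index = calls.index.astype(str)
    if list(calls.index) != m.gene_ids or list(calls.columns) != m.sample_ids:
        raise AlignmentError(f"call file {path} does not share the matrix's gene/sample ids")
    out = ExpressionMatrix(values=m.values, calls=calls, conditions=m.conditions)
    return out


def write_detection_calls(m: ExpressionMatrix, path) -> None:
    if m.calls is None:
        raise ValidationError("matrix carries no detection calls")
    m.calls.to_csv(path, sep="\t", index_label="gene_id")


def read_conditions_tsv(path, m: ExpressionMatrix) -> ExpressionMatrix:
    """Attach sample condition labels from a two-column TSV (sample_id, condition)."""
    anno = pd.read_csv(path, sep="\t", dtype=str)
    if anno.shape[1] < 2:
        raise ParseError(f"annotation file {path} needs two columns (sample_id, condition)")
    cond = pd.Series(
        anno.iloc[:, 1].values, index=anno.iloc[:, 0].astype(str).values
    )
    if cond.index.has_duplicates:
        raise ValidationError(f"duplicate sample ids in annotation {path}")
    missing = [s for s in m.sample_ids if s not in cond.index]
    if missing:
        raise AlignmentError(f"annotation {path} lacks samples: {missing[:5]}")
    return ExpressionMatrix(
        values=m.values, calls=m.calls, conditions=cond.reindex(m.sample_ids)
    )


def write_conditions_tsv(m: ExpressionMatrix, path) -> None:
    if m.conditions is None:
        raise ValidationError("matrix carries no condition labels")
    df = pd.DataFrame({"sample_id": m.sample_ids, "condition": m.conditions.values})
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One identifier per line; '#' starts a comment."""
    members: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.append(line)
    if len(members) != len(set(members)):
        raise ValidationError(f"duplicate identifiers in gene list {path}")
    return GeneSet(name=name or str(path), members=frozenset(members))


def write_gene_set(s: GeneSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# {s.name}\n")
        for m in s.sorted_members():
            fh.write(m + "\n")


def read_id_map(path) -> dict:
    """Two-column TSV mapping foreign ids -> this package's gene ids."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"id map {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def translate_ids(m: ExpressionMatrix, mapping: dict) -> ExpressionMatrix:
    """Rename genes through a user-supplied id mapping; unmapped genes kept as-is."""
    new_index = [mapping.get(g, g) for g in m.gene_ids]
    if len(set(new_index)) != len(new_index):
        raise ValidationError("id mapping produces duplicate gene ids")
    values = m.values.copy()
    values.index = new_index
    calls = None
    if m.calls is not None:
        calls = m.calls.copy()
        calls.index = new_index
    return ExpressionMatrix(values=values, calls=calls, conditions=m.conditions)


def match_genes(a: ExpressionMatrix, b):
    """Restrict two objects to their shared genes, identically ordered.

    ``b`` may be another :class:`ExpressionMatrix` or a :class:`GeneSet`.
    Returns ``(a_sub, b_sub, dropped)`` where ``dropped`` lists ids present in
    exactly one input; gene order follows ``a``.
    """
    a_ids = a.gene_ids
    if isinstance(b, GeneSet):
        b_ids = set(b.members)
    else:
        b_ids = set(b.gene_ids)
    shared = [g for g in a_ids if g in b_ids]
    if len(shared) < 2:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared gene id(s); at least 2 required"
        )
    dropped = sorted((set(a_ids) | b_ids) - set(shared))
    a_sub = a.subset_genes(shared)
    if isinstance(b, GeneSet):
        b_sub = GeneSet(name=b.name, members=frozenset(shared))
    else:
        b_sub = b.subset_genes(shared)
    return a_sub, b_sub, dropped
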