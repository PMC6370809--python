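"""Readers, writers and validated containers for every format the pipeline touches.

The whole analysis operates on three kinds of objects: a gene × sample
expression matrix (raw counts or log2 intensities), a per-sample annotation
(group labels and, for time courses, ordered time points), and named gene
sets (GMT files). All tabular exchange is tab-separated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_KINDS = ("counts", "log2")


class MatrixValidationError(ValueError):
    """Structural invariant of an expression matrix violated."""


class FormatError(ValueError):
    """Malformed input file (bad cell, short GMT line, ...)."""


@dataclass
class ExpressionMatrix:
    """Gene × sample numeric matrix with a declared value kind.

    ``values`` is a pandas DataFrame whose index holds gene identifiers and
    whose columns hold sample identifiers. ``value_kind`` is ``"counts"``
    (non-negative integers) or ``"log2"`` (reals). Identifiers are opaque,
    case-sensitive strings; duplicates are rejected.
    """

    values: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise MatrixValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise MatrixValidationError(f"duplicate gene id(s): {list(dup_genes)}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise MatrixValidationError(f"duplicate sample id(s): {list(dup_samples)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise MatrixValidationError("matrix contains non-numeric values")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise MatrixValidationError(
                "missing value at gene "
                f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}; "
                "missing values are not permitted"
            )
        if self.value_kind == "counts":
            if (arr < 0).any():
                g, s = np.argwhere(arr < 0)[0]
                raise MatrixValidationError(
                    f"negative count at gene {self.values.index[g]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise MatrixValidationError(
                    f"non-integer count at gene {self.values.index[g]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )

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

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.value_kind)


@dataclass
class SampleAnnotation:
    """Sample → (group, optional time point, replicate) mapping.

    ``table`` is indexed by sample_id with columns ``group``, ``time_point``
    (nullable) and ``replicate``. ``time_order`` declares the total order of
    time points when the annotation describes a series.
    """

    table: pd.DataFrame
    time_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.table.index = self.table.index.astype(str)
        if self.table.index.duplicated().any():
            raise MatrixValidationError("duplicate sample id in annotation")
        for col in ("group", "time_point", "replicate"):
            if col not in self.table.columns:
                self.table[col] = pd.NA if col != "replicate" else 0
        if self.time_order:
            declared = set(self.time_order)
            seen = set(self.table["time_point"].dropna().astype(str))
            unknown = seen - declared
            if unknown:
                raise MatrixValidationError(
                    f"time point(s) {sorted(unknown)} not in declared order {self.time_order}"
                )

    @classmethod
    def from_groups(cls, groups: Mapping[str, str]) -> "SampleAnnotation":
        """Build a two-group annotation from a sample_id → group_label dict."""
        tab = pd.DataFrame({"group": pd.Series(groups, dtype=str)})
        tab.index.name = "sample_id"
        return cls(tab)

    @classmethod
    def from_timepoints(
        cls,
        timepoints: Mapping[str, str],
        time_order: Sequence[str],
        groups: Mapping[str, str] | None = None,
    ) -> "SampleAnnotation":
        tab = pd.DataFrame({"time_point": pd.Series(timepoints, dtype=str)})
        tab["group"] = pd.Series(groups, dtype=str) if groups else "all"
        tab.index.name = "sample_id"
        return cls(tab, tuple(time_order))

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, grp in self.table["group"].items():
            out.setdefault(str(grp), []).append(sid)
        return out

    def two_groups(
        self, group_a: str | None = None, group_b: str | None = None
    ) -> tuple[str, list[str], str, list[str]]:
        """Resolve a two-group contrast; each group must have ≥ 2 samples."""
        grps = self.groups()
        if group_a is None or group_b is None:
            if len(grps) != 2:
                raise MatrixValidationError(
                    f"expected exactly 2 groups, found {sorted(grps)}; "
                    "pass group_a/group_b explicitly"
                )
            group_a, group_b = sorted(grps)
        for g in (group_a, group_b):
            if g not in grps:
                raise MatrixValidationError(f"group {g!r} not present in annotation")
            if len(grps[g]) < 2:
                raise MatrixValidationError(
                    f"group {g!r} has {len(grps[g])} sample(s); need at least 2"
                )
        return group_a, grps[group_a], group_b, grps[group_b]

    def check_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.table.index) - set(matrix.sample_ids)
        if missing:
            raise MatrixValidationError(
                f"annotated sample(s) absent from matrix: {sorted(missing)}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    description: str = ""
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set name must be non-empty")
        deduped = tuple(dict.fromkeys(self.members))
        if len(deduped) != len(self.members):
            logger.warning(
                "gene set %r: %d duplicate member(s) removed",
                self.name,
                len(self.members) - len(deduped),
            )
            object.__setattr__(self, "members", deduped)
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.members)


def read_expression_matrix(path, value_kind: str = "counts") -> ExpressionMatrix:
    """Read a tab-separated gene × sample matrix (first column = gene ids).

    Raises :class:`FormatError` with row/column coordinates for non-numeric
    cells and :class:`MatrixValidationError` for duplicate ids, negative or
    non-integer counts.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    parsed = raw.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {raw.iloc[g, s]!r} at row {raw.index[g]!r} "
            f"(data row {g + 1}), column {raw.columns[s]!r}"
        )
    if parsed.isna().to_numpy().any():
        g, s = np.argwhere(parsed.isna().to_numpy())[0]
        raise FormatError(
            f"empty cell at row {raw.index[g]!r}, column {raw.columns[s]!r}"
        )
    return ExpressionMatrix(parsed, value_kind=value_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path, precision: int = 6) -> None:
    if matrix.value_kind == "counts":
        matrix.values.astype(np.int64).to_csv(path, sep="\t")
    else:
        matrix.values.to_csv(path, sep="\t", float_format=f"%.{precision}g")


def read_sample_annotation(path, time_order: Sequence[str] = ()) -> SampleAnnotation:
    tab = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleAnnotation(tab, tuple(time_order))


def write_sample_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t")


def read_gene_sets_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated name, description, members.

    Duplicate members within a line are deduplicated (with a logged warning);
    a line with fewer than three fields or a repeated set name is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected name, description and at least "
                    f"one member, got {len(fields)} field(s)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in seen:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc, members=tuple(members)))
    return sets


def write_gene_sets_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def write_results_table(records: pd.DataFrame, path, precision: int = 6) -> None:
    """Write a result table as TSV with header; floats at fixed precision."""
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
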