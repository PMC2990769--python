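"""Input/output and domain containers for time-course pathway analysis.

The central objects are an :class:`ExpressionMatrix` (genes x samples) bound to
a :class:`TimeDesign` describing which sample column was measured at which time
point and replicate, and a :class:`PathwayCollection` of named gene sets read
from MSigDB-style GMT files.  Pathway submatrices are extracted by exact
identifier intersection; probe-to-gene annotation is deliberately out of scope
(a two-column mapping file can be applied with :func:`remap_gene_ids`).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Sampling grid (hours after lights-on) of the rat-liver time-course study:
#: nine light-period and nine dark-period points within one 24-h cycle.
RAT_LIVER_TIMEPOINTS: tuple[float, ...] = (
    0.25, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 11.0, 11.75,
    12.25, 13.0, 14.0, 16.0, 18.0, 20.0, 22.0, 23.0, 23.75,
)


class DataError(ValueError):
    """Malformed or inconsistent user input."""


class GMTParseError(DataError):
    pass


class PathwayTooSmallError(DataError):
    """Fewer mapped genes than ``min_size``; callers usually skip, not crash."""


@dataclass(frozen=True)
class TimeDesign:
    """Maps sample columns to (time point, replicate) pairs.

    Samples are assumed time-major by default: all replicates of the first
    time point, then all replicates of the second, and so on.  An explicit
    ``sample_order`` (one ``(time_index, replicate_index)`` pair per column)
    overrides this.
    """

    time_points: tuple[float, ...]
    replicates_per_time: int
    sample_order: tuple[tuple[int, int], ...] | None = None
    period_hint: float = 24.0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        object.__setattr__(self, "time_points", tp)
        if len(tp) < 1:
            raise DataError("design needs at least one time point")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise DataError("time_points must be strictly increasing")
        if tp[0] < 0 or tp[-1] >= self.period_hint:
            raise DataError(
                f"time_points must lie in [0, {self.period_hint}) hours"
            )
        if self.replicates_per_time < 1:
            raise DataError("replicates_per_time must be positive")
        if self.sample_order is not None:
            order = tuple((int(i), int(j)) for i, j in self.sample_order)
            object.__setattr__(self, "sample_order", order)
            seen = set(order)
            if len(seen) != len(order):
                raise DataError("sample_order maps two samples to one slot")
            for i, j in order:
                if not (0 <= i < len(tp)) or not (0 <= j < self.replicates_per_time):
                    raise DataError(f"sample_order entry {(i, j)} out of range")

    @property
    def n_samples(self) -> int:
        if self.sample_order is not None:
            return len(self.sample_order)
        return len(self.time_points) * self.replicates_per_time

    @property
    def is_complete(self) -> bool:
        return self.n_samples == len(self.time_points) * self.replicates_per_time

    def order(self) -> tuple[tuple[int, int], ...]:
        """Per-column (time_index, replicate_index), time-major by default."""
        if self.sample_order is not None:
            return self.sample_order
        return tuple(
            (i, j)
            for i in range(len(self.time_points))
            for j in range(self.replicates_per_time)
        )

    def sample_times(self) -> np.ndarray:
        """Hour of each sample column (replicated time points)."""
        tp = np.asarray(self.time_points)
        return tp[[i for i, _ in self.order()]]

    def time_index(self) -> np.ndarray:
        return np.array([i for i, _ in self.order()], dtype=int)


def rat_liver_design() -> TimeDesign:
    """The built-in 18-time-point x 3-replicate (54-sample) study design."""
    return TimeDesign(RAT_LIVER_TIMEPOINTS, replicates_per_time=3)


@dataclass(frozen=True)
class PathwayGeneSet:
    """A named gene set (one GMT record)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"pathway {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PathwayCollection:
    """Ordered collection of uniquely named pathways."""

    pathways: list[PathwayGeneSet]

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DataError(f"duplicate pathway names: {sorted(dupes)}")

    def __iter__(self) -> Iterator[PathwayGeneSet]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, key: int | str) -> PathwayGeneSet:
        if isinstance(key, str):
            for p in self.pathways:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.pathways[key]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a time-course design."""

    gene_ids: list[str]
    values: np.ndarray
    design: TimeDesign

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be 2-D (genes x samples)")
        if len(self.gene_ids) != self.values.shape[0]:
            raise DataError("gene_ids length does not match row count")
        if self.values.shape[1] != self.design.n_samples:
            raise DataError(
                f"matrix has {self.values.shape[1]} samples but the design "
                f"describes {self.design.n_samples}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise DataError(f"duplicate gene id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at gene {self.gene_ids[i]!r}, column {j}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PathwayExpressionMatrix:
    """The k x t submatrix of measured genes mapped onto one pathway."""

    pathway: PathwayGeneSet
    gene_ids: list[str]
    values: np.ndarray
    design: TimeDesign

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.gene_ids):
            raise DataError("gene_ids length does not match row count")
        if self.values.shape[1] != self.design.n_samples:
            raise DataError("column count does not match design")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> PathwayCollection:
    """Read an MSigDB-style GMT file (name, description, member genes...).

    Duplicate member tokens within a line are collapsed; empty tokens are
    dropped.  A line with fewer than three fields or a repeated pathway name
    is an error.
    """
    pathways: list[PathwayGeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1].strip()
            members = {tok.strip() for tok in fields[2:] if tok.strip()}
            if not members:
                raise GMTParseError(
                    f"{path}: line {lineno}: pathway {name!r} has no members"
                )
            pathways.append(PathwayGeneSet(name, description, frozenset(members)))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Write a collection back to GMT (members in sorted order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.description, *sorted(p.members)]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _strip_geo_quotes(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def read_expression(
    path: str | Path,
    design: TimeDesign,
    *,
    duplicate_policy: str = "error",
    sample_names: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples table.

    The first column holds gene identifiers, the header row sample names.
    Lines beginning with ``!`` or ``#`` are skipped, which makes the GEO
    Series Matrix dialect (metadata lines plus a quoted table) readable
    directly.  ``sample_names`` selects/reorders columns to match the design;
    by default the first ``design.n_samples`` columns are used in file order.

    ``duplicate_policy`` is ``"error"`` (default) or ``"mean"`` (collapse
    duplicate gene ids by averaging).
    """
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            rows.append([_strip_geo_quotes(tok) for tok in line.split("\t")])
    if len(rows) < 2:
        raise DataError(f"{path}: no data rows found")
    header, body = rows[0], rows[1:]
    columns = header[1:]
    width = len(header)
    for r, row in enumerate(body):
        if len(row) != width:
            raise DataError(
                f"{path}: row {r + 2} has {len(row)} fields, expected {width}"
            )

    gene_ids = [row[0] for row in body]
    try:
        values = np.array([row[1:] for row in body], dtype=float)
    except ValueError:
        for r, row in enumerate(body):
            for c, tok in enumerate(row[1:]):
                try:
                    float(tok)
                except ValueError:
                    raise DataError(
                        f"{path}: non-numeric value {tok!r} at gene "
                        f"{row[0]!r}, sample {columns[c]!r}"
                    ) from None
        raise

    if sample_names is not None:
        missing = [s for s in sample_names if s not in columns]
        if missing:
            raise DataError(f"{path}: samples missing from file: {missing}")
        idx = [columns.index(s) for s in sample_names]
        values = values[:, idx]
        columns = list(sample_names)
    if values.shape[1] < design.n_samples:
        raise DataError(
            f"{path}: file has {values.shape[1]} sample columns but the "
            f"design requires {design.n_samples}"
        )
    values = values[:, : design.n_samples]

    if len(set(gene_ids)) != len(gene_ids):
        if duplicate_policy == "mean":
            frame = pd.DataFrame(values, index=gene_ids)
            collapsed = frame.groupby(level=0, sort=False).mean()
            gene_ids = list(collapsed.index)
            values = collapsed.to_numpy()
        else:
            seen: set[str] = set()
            dup = next(g for g in gene_ids if g in seen or seen.add(g))
            raise DataError(f"{path}: duplicated gene id {dup!r}")

    return ExpressionMatrix(gene_ids, values, design)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    names = [
        f"T{expr.design.time_points[i]:g}_R{j + 1}" for i, j in expr.design.order()
    ]
    frame = pd.DataFrame(expr.values, index=expr.gene_ids, columns=names)
    frame.to_csv(path, sep="\t", index_label="gene_id")


def remap_gene_ids(
    expr: ExpressionMatrix,
    mapping: Mapping[str, str],
    *,
    collapse: str = "mean",
) -> ExpressionMatrix:
    """Apply a probe-to-gene mapping; unmapped rows are dropped.

    ``collapse`` handles several probes mapping to one gene: ``"mean"``
    averages them, ``"error"`` refuses.
    """
    keep = [i for i, g in enumerate(expr.gene_ids) if g in mapping]
    if not keep:
        raise DataError("mapping matches no gene ids")
    new_ids = [mapping[expr.gene_ids[i]] for i in keep]
    values = expr.values[keep]
    if len(set(new_ids)) != len(new_ids):
        if collapse != "mean":
            raise DataError("mapping collapses several probes onto one gene")
        frame = pd.DataFrame(values, index=new_ids)
        collapsed = frame.groupby(level=0, sort=False).mean()
        new_ids, values = list(collapsed.index), collapsed.to_numpy()
    return ExpressionMatrix(new_ids, values, expr.design)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Two-column (probe, gene) TSV/CSV mapping file."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        dialect = "excel-tab" if str(path).endswith((".tsv", ".txt")) else "excel"
        for row in csv.reader(fh, dialect=dialect):
            if len(row) >= 2 and row[0].strip():
                mapping[row[0].strip()] = row[1].strip()
    return mapping


def read_design(path: str | Path) -> TimeDesign:
    """Read a design from YAML (keys: time_points, replicates_per_time,
    optionally sample_order, period_hint)."""
    with open(path, encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    order = spec.get("sample_order")
    return TimeDesign(
        time_points=tuple(spec["time_points"]),
        replicates_per_time=int(spec["replicates_per_time"]),
        sample_order=tuple((int(i), int(j)) for i, j in order) if order else None,
        period_hint=float(spec.get("period_hint", 24.0)),
    )


# ---------------------------------------------------------------------------
# Pathway extraction
# ---------------------------------------------------------------------------

def extract_pathway_matrix(
    expr: ExpressionMatrix,
    pathway: PathwayGeneSet,
    *,
    min_size: int = 5,
    case_fold: bool = False,
) -> PathwayExpressionMatrix | None:
    """Select the rows of ``expr`` belonging to ``pathway``.

    Rows keep the expression matrix's order (stable).  Returns ``None`` with a
    logged status when fewer than ``min_size`` genes map — pathways that are
    too small are skipped, not fatal.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    members = pathway.members
    if case_fold:
        members = frozenset(m.casefold() for m in members)
        hits = [
            i for i, g in enumerate(expr.gene_ids) if g.casefold() in members
        ]
    else:
        hits = [i for i, g in enumerate(expr.gene_ids) if g in members]
    if len(hits) < min_size:
        logger.info(
            "pathway %s skipped: too few mapped genes (%d < %d)",
            pathway.name, len(hits), min_size,
        )
        return None
    return PathwayExpressionMatrix(
        pathway=pathway,
        gene_ids=[expr.gene_ids[i] for i in hits],
        values=expr.values[hits].copy(),
        design=expr.design,
    )
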