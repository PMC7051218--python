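"""Data model for protein x replicate abundance tables and the crossed replicate design.

The experimental unit emulated here is a set of ``n_bio * n_tech`` LC-MS/MS
runs per sample: each biological replicate (an independent cell-culture
passage) is split into several technical replicates (re-injections of the
same lysate).  Replicates carry positional labels ``R1..Rn``; two triad
groupings of the 3x3 design are in common use:

* TR (technical-replicate) groups: ``{R1,R2,R3}, {R4,R5,R6}, {R7,R8,R9}``
* BR (biological-replicate) groups: ``{R1,R4,R7}, {R2,R5,R8}, {R3,R6,R9}``

Two abundance flavors are handled: LFQ intensities (used downstream only as
a presence/absence signal) and APEX absolute abundances, which are placed on
an absolute scale by a multiplicative normalization constant ``C`` (default
1.0E8, an estimate of the total protein abundance in one sample).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Flavor",
    "Dialect",
    "Numbering",
    "Scheme",
    "AbundanceTable",
    "ReplicateDesign",
    "GroupingScheme",
    "TableParseError",
    "read_abundance_table",
    "build_design",
    "derive_grouping",
    "write_results",
    "DEFAULT_NORMALIZATION_CONSTANT",
]

DEFAULT_NORMALIZATION_CONSTANT = 1.0e8


class Flavor(str, enum.Enum):
    """Kind of value stored in an abundance table."""

    LFQ = "LFQ"
    APEX = "APEX"


class Dialect(str, enum.Enum):
    """Tabular file layouts accepted by :func:`read_abundance_table`."""

    CSV = "csv"
    TSV = "tsv"
    XLS_SUPPLEMENTARY = "xls_supplementary"


class Numbering(str, enum.Enum):
    """Convention mapping replicate labels R1..Rn onto the bio x tech crossing.

    ``TR_TRIADS_SAME_LYSATE``: consecutive labels are technical splits of one
    lysate (passage A -> R1,R2,R3).  ``BR_TRIADS_SAME_LYSATE``: strided labels
    share a lysate (passage A -> R1,R4,R7).  Both are legitimate readings of a
    3x3 layout; the former is the default.
    """

    TR_TRIADS_SAME_LYSATE = "tr_triads_same_lysate"
    BR_TRIADS_SAME_LYSATE = "br_triads_same_lysate"


class Scheme(str, enum.Enum):
    """Which triad grouping of the replicate labels to analyse."""

    TR = "TR"
    BR = "BR"


class TableParseError(ValueError):
    """Raised when an input table violates the format contract.

    Carries enough context (row / column) to locate the offending cell.
    """

    def __init__(self, message: str, row: object = None, column: object = None):
        detail = message
        if row is not None:
            detail += f" [row: {row}]"
        if column is not None:
            detail += f" [column: {column}]"
        super().__init__(detail)
        self.row = row
        self.column = column


@dataclass(frozen=True)
class AbundanceTable:
    """A protein x replicate matrix of non-negative values.

    Rows are proteins (unique accession or gene-symbol strings), columns are
    replicates.  Missing observations are canonicalized to 0 on construction;
    "identified / present" downstream means value > 0.
    """

    protein_ids: tuple[str, ...]
    replicate_ids: tuple[str, ...]
    values: np.ndarray
    flavor: Flavor
    normalization_constant: float = DEFAULT_NORMALIZATION_CONSTANT

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        values = np.nan_to_num(values, nan=0.0)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "protein_ids", tuple(str(p) for p in self.protein_ids))
        object.__setattr__(self, "replicate_ids", tuple(str(r) for r in self.replicate_ids))
        object.__setattr__(self, "flavor", Flavor(self.flavor))
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dupes = _duplicates(self.protein_ids)
            raise TableParseError(f"duplicate protein identifier(s): {sorted(dupes)}", row=sorted(dupes)[0])
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise TableParseError(f"duplicate replicate label(s): {sorted(_duplicates(self.replicate_ids))}")
        if values.shape != (len(self.protein_ids), len(self.replicate_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.replicate_ids)} replicates"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableParseError(
                f"negative value {values[i, j]!r}",
                row=self.protein_ids[i],
                column=self.replicate_ids[j],
            )
        if not self.normalization_constant > 0:
            raise ValueError("normalization_constant must be positive")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.protein_ids, name="protein"),
            columns=list(self.replicate_ids),
        )

    def column(self, replicate_id: str) -> np.ndarray:
        return self.values[:, self.replicate_ids.index(replicate_id)]

    def with_values(self, values: np.ndarray) -> "AbundanceTable":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    def write(self, path: str | Path, dialect: Dialect | str = Dialect.TSV) -> None:
        """Write the table back out (TSV or CSV); inverse of the reader."""
        dialect = Dialect(dialect)
        sep = "\t" if dialect is Dialect.TSV else ","
        if dialect is Dialect.XLS_SUPPLEMENTARY:
            raise ValueError("writing spreadsheet files is not supported; use tsv or csv")
        self.to_frame().to_csv(path, sep=sep, float_format="%.10g")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


@dataclass(frozen=True)
class ReplicateDesign:
    """Complete bio x tech crossing of replicate labels.

    ``assignments`` maps each replicate label to a ``(bio_label, tech_label)``
    pair; every pair of the ``n_bio x n_tech`` grid occurs exactly once.
    """

    assignments: Mapping[str, tuple[str, int]]
    n_bio: int
    n_tech: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        if len(self.assignments) != self.n_bio * self.n_tech:
            raise ValueError(
                f"{len(self.assignments)} assignments for a "
                f"{self.n_bio}x{self.n_tech} crossing"
            )
        pairs = set(self.assignments.values())
        if len(pairs) != self.n_bio * self.n_tech:
            raise ValueError("assignments do not form a complete crossing (repeated bio/tech pair)")
        bios = {b for b, _ in pairs}
        techs = {t for _, t in pairs}
        if len(bios) != self.n_bio or len(techs) != self.n_tech:
            raise ValueError("assignments do not cover the full bio x tech grid")

    @property
    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.assignments, key=_replicate_sort_key))

    @property
    def bio_labels(self) -> tuple[str, ...]:
        return tuple(sorted({b for b, _ in self.assignments.values()}))

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_bio": self.n_bio,
            "n_tech": self.n_tech,
            "assignments": {r: list(bt) for r, bt in self.assignments.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ReplicateDesign":
        return cls(
            assignments={r: (bt[0], int(bt[1])) for r, bt in d["assignments"].items()},
            n_bio=int(d["n_bio"]),
            n_tech=int(d["n_tech"]),
        )


def _replicate_sort_key(label: str) -> tuple:
    """Sort R2 before R10; fall back to plain string order."""
    if label.startswith("R") and label[1:].isdigit():
        return (0, int(label[1:]))
    return (1, label)


@dataclass(frozen=True)
class GroupingScheme:
    """An ordered partition of the replicate labels into analysis groups."""

    scheme: Scheme
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        object.__setattr__(
            self, "groups", tuple(tuple(str(m) for m in g) for g in self.groups)
        )
        flat = [m for g in self.groups for m in g]
        if len(set(flat)) != len(flat):
            raise ValueError("groups are not disjoint")

    @property
    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(m for g in self.groups for m in g)

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(f"{self.scheme.value}{i + 1}" for i in range(len(self.groups)))

    def to_dict(self) -> dict[str, Any]:
        return {"scheme": self.scheme.value, "groups": [list(g) for g in self.groups]}


# ---------------------------------------------------------------------------
# readers / builders


def read_abundance_table(
    path: str | Path,
    flavor: Flavor | str,
    dialect: Dialect | str | None = None,
    normalization_constant: float = DEFAULT_NORMALIZATION_CONSTANT,
) -> AbundanceTable:
    """Read a protein x replicate table from CSV/TSV or a supplementary-style
    spreadsheet (first column = protein identifier, one column per replicate).

    Blank and NaN cells are canonicalized to 0.  When the file has no usable
    header row, replicates are labelled ``R1..Rn`` by position.  Raises
    :class:`TableParseError` naming the offending row/column on duplicate
    protein identifiers, negative values or non-numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"abundance table not found: {path}")
    if dialect is None:
        dialect = _infer_dialect(path)
    dialect = Dialect(dialect)

    if dialect is Dialect.XLS_SUPPLEMENTARY:
        raw = pd.read_excel(path, sheet_name=0, header=0, index_col=0)
    else:
        sep = "\t" if dialect is Dialect.TSV else ","
        raw = pd.read_csv(path, sep=sep, header=0, index_col=0, skip_blank_lines=True)

    if raw.shape[0] < 1:
        raise TableParseError("table has no protein rows")
    if raw.shape[1] < 2:
        raise TableParseError("table must have at least 2 replicate columns")

    protein_ids = [str(p).strip() for p in raw.index]
    dup = _duplicates(protein_ids)
    if dup:
        raise TableParseError(f"duplicate protein identifier(s): {sorted(dup)}", row=sorted(dup)[0])

    if all(str(c).startswith("Unnamed") for c in raw.columns):
        replicate_ids = [f"R{i + 1}" for i in range(raw.shape[1])]
    else:
        replicate_ids = [str(c).strip() for c in raw.columns]

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        series = raw[col]
        numeric = pd.to_numeric(series, errors="coerce")
        # distinguish genuinely blank cells (-> 0) from unparseable text
        bad = numeric.isna() & series.notna() & (series.astype(str).str.strip() != "")
        if bad.any():
            row = protein_ids[int(np.argmax(bad.to_numpy()))]
            raise TableParseError(
                f"non-numeric cell {series[bad].iloc[0]!r}", row=row, column=replicate_ids[j]
            )
        values[:, j] = numeric.fillna(0.0).to_numpy(dtype=float)

    return AbundanceTable(
        protein_ids=tuple(protein_ids),
        replicate_ids=tuple(replicate_ids),
        values=values,
        flavor=Flavor(flavor),
        normalization_constant=normalization_constant,
    )


def _infer_dialect(path: Path) -> Dialect:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls", ".xlsm"}:
        return Dialect.XLS_SUPPLEMENTARY
    if suffix == ".csv":
        return Dialect.CSV
    return Dialect.TSV


def build_design(
    n_bio: int,
    n_tech: int,
    numbering: Numbering | str = Numbering.TR_TRIADS_SAME_LYSATE,
) -> ReplicateDesign:
    """Construct the complete crossing of ``n_bio`` passages x ``n_tech``
    injections with replicate labels ``R1..R(n_bio*n_tech)``.

    Under ``tr_triads_same_lysate`` consecutive labels share a passage
    (A -> R1..R3 for 3x3); under ``br_triads_same_lysate`` strided labels do
    (A -> R1, R4, R7).
    """
    if n_bio < 2 or n_tech < 2:
        raise ValueError("need at least 2 biological and 2 technical replicates")
    numbering = Numbering(numbering)
    bio_labels = _bio_labels(n_bio)
    assignments: dict[str, tuple[str, int]] = {}
    for b in range(n_bio):
        for t in range(n_tech):
            if numbering is Numbering.TR_TRIADS_SAME_LYSATE:
                idx = b * n_tech + t
            else:
                idx = t * n_bio + b
            assignments[f"R{idx + 1}"] = (bio_labels[b], t + 1)
    return ReplicateDesign(assignments=assignments, n_bio=n_bio, n_tech=n_tech)


def _bio_labels(n_bio: int) -> list[str]:
    import string

    if n_bio <= 26:
        return list(string.ascii_uppercase[:n_bio])
    return [f"P{i + 1}" for i in range(n_bio)]


def derive_grouping(design: ReplicateDesign, scheme: Scheme | str) -> GroupingScheme:
    """Partition the replicate labels into TR or BR groups.

    Grouping is positional (by label), not by passage: for any design the TR
    scheme is ``n_bio`` consecutive blocks of ``n_tech`` labels and the BR
    scheme is ``n_tech`` strided groups of ``n_bio`` labels (stride
    ``n_tech``).  For the 3x3 design this yields the canonical
    ``{R1,R2,R3}...`` and ``{R1,R4,R7}...`` triads whichever numbering
    convention built the design.
    """
    scheme = Scheme(scheme)
    labels = design.replicate_ids
    n_bio, n_tech = design.n_bio, design.n_tech
    if scheme is Scheme.TR:
        groups = tuple(
            tuple(labels[b * n_tech : (b + 1) * n_tech]) for b in range(n_bio)
        )
    else:
        groups = tuple(
            tuple(labels[t + i * n_tech] for i in range(n_bio)) for t in range(n_tech)
        )
    return GroupingScheme(scheme=scheme, groups=groups)


# ---------------------------------------------------------------------------
# result serialization


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _flatten(prefix: str, obj: Any, rows: list[tuple[str, Any]]) -> None:
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, (list, tuple)):
        if all(not isinstance(v, (Mapping, list, tuple)) for v in obj):
            rows.append((prefix, ";".join(_format_scalar(v) for v in obj)))
        else:
            for i, v in enumerate(obj):
                _flatten(f"{prefix}[{i}]", v, rows)
    else:
        rows.append((prefix, _format_scalar(obj)))


def _format_scalar(v: Any) -> str:
    if isinstance(v, float):
        return f"{v:.12g}"
    return str(v)


def write_results(results: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a result record (any of the pipeline's dataclasses, a dict,
    or a list of them) to JSON or a flat key/value TSV.

    JSON round-trips every numeric field at full precision; the TSV form is a
    two-column ``field<TAB>value`` flattening for human inspection.
    """
    path = Path(path)
    payload = _jsonable(results)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, allow_nan=False) + "\n")
    elif format == "tsv":
        rows: list[tuple[str, Any]] = []
        _flatten("", payload, rows)
        lines = ["field\tvalue"] + [f"{k}\t{v}" for k, v in rows]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")
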