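"""Expression-matrix and tissue-ontology I/O.

Reads and writes Expression Atlas style baseline-expression TSV files
(``Gene ID``, optional ``Gene Name``, one column per tissue), plus the
child→parent tissue tables used to roll fine-grained tissue calls up to
top-level anatomical terms (BTO-style, one level deep).

Conventions
-----------
* Empty / missing cells read as 0 — baseline Atlas exports omit values
  below their reporting cutoff, and keeping the zero-handling here means
  every downstream formula sees an explicit, dense, non-negative matrix.
* Genes are keyed on the stable gene id; symbols travel as metadata only.
* The unit tag (FPKM/TPM) is metadata: every cutoff in the method treats
  the two units identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousMappingError,
    DimensionError,
    DuplicateRecordError,
    MalformedInputError,
    MissingMappingError,
)

__all__ = [
    "ExpressionMatrix",
    "TissueOntologyMap",
    "GeneTissueAssignment",
    "read_expression_matrix",
    "write_expression_matrix",
    "load_tissue_map",
    "roll_up_assignments",
]

_GENE_ID_COL = "Gene ID"
_GENE_NAME_COL = "Gene Name"
_UNITS_RE = re.compile(r"#\s*units?\s*[:=]\s*(\w+)", re.IGNORECASE)


@dataclass
class ExpressionMatrix:
    """A non-negative gene × tissue expression table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per tissue.
    units
        ``"FPKM"`` or ``"TPM"``; informational only.
    gene_names
        Optional gene symbols aligned to ``values.index``.
    """

    values: pd.DataFrame
    units: str = "FPKM"
    gene_names: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.values
        if vals.shape[1] < 2:
            raise DimensionError(
                f"expression matrix needs >= 2 tissues, got {vals.shape[1]}"
            )
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise DuplicateRecordError(f"duplicate gene ids: {dups[:5]}")
        if vals.columns.has_duplicates:
            raise DuplicateRecordError("duplicate tissue labels")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise MalformedInputError("expression values must be finite")
        if (arr < 0).any():
            raise MalformedInputError("expression values must be non-negative")
        if self.gene_names is not None and not self.gene_names.index.equals(vals.index):
            self.gene_names = self.gene_names.reindex(vals.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_tissues} tissues, "
            f"units={self.units})"
        )


@dataclass
class TissueOntologyMap:
    """One-level child tissue → (parent tissue, ontology accession) lookup."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def parent(self, child: str) -> str:
        try:
            return self.entries[child][0]
        except KeyError:
            raise MissingMappingError(f"tissue {child!r} has no parent mapping") from None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, child: str) -> bool:
        return child in self.entries


#: Columns of the gene-tissue pair table, in output order.
PAIR_COLUMNS = [
    "gene_id",
    "gene_name",
    "tissue",
    "expression",
    "tau",
    "dist_ss",
    "x_max",
    "sigma",
    "is_argmax",
]


@dataclass
class GeneTissueAssignment:
    """Set of (gene, tissue) specificity calls with per-gene statistics.

    ``table`` has one row per assigned pair with columns :data:`PAIR_COLUMNS`.
    The ``is_argmax`` flag marks the pair(s) at each gene's maximum
    expression — restricting to those rows recovers the classic
    single-tissue tau assignment.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", "tissue") if c not in self.table.columns]
        if missing:
            raise MalformedInputError(f"assignment table lacks columns {missing}")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["gene_id"], self.table["tissue"]))

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene_id"])

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GeneTissueAssignment":
        """Build a minimal assignment from bare (gene, tissue) tuples."""
        rows = sorted(set(pairs))
        return cls(pd.DataFrame(rows, columns=["gene_id", "tissue"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneTissueAssignment":
        return cls(pd.read_csv(path, sep="\t"))


def _detect_units(path: Path) -> str:
    """Look for a '# units: TPM' comment in the file head; default FPKM."""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _UNITS_RE.search(line)
            if m:
                return m.group(1).upper()
    return "FPKM"


def read_expression_matrix(path: str | Path, units: str = "auto") -> ExpressionMatrix:
    """Read an Expression Atlas style TSV into an :class:`ExpressionMatrix`.

    The first column is the gene id; a second column named ``Gene Name``
    (any capitalisation) is treated as symbols; every remaining column is a
    tissue. Lines starting with ``#`` are skipped; empty cells become 0.

    Raises
    ------
    MalformedInputError
        On negative or non-numeric expression values.
    DuplicateRecordError
        If a gene id appears twice.
    DimensionError
        If fewer than two tissue columns remain.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 1:
        raise MalformedInputError(f"{path}: no columns found")
    gene_col = df.columns[0]
    name_col = None
    if df.shape[1] >= 2 and df.columns[1].strip().lower() in {"gene name", "gene_name"}:
        name_col = df.columns[1]
    tissue_cols = [c for c in df.columns if c not in (gene_col, name_col)]
    if len(tissue_cols) < 2:
        raise DimensionError(
            f"{path}: found {len(tissue_cols)} tissue columns, need >= 2"
        )
    if df[gene_col].duplicated().any():
        dups = df.loc[df[gene_col].duplicated(), gene_col].unique().tolist()
        raise DuplicateRecordError(f"{path}: duplicate gene ids {dups[:5]}")

    try:
        values = df[tissue_cols].apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise MalformedInputError(f"{path}: non-numeric expression cell ({exc})") from exc
    values = values.fillna(0.0).astype(float)
    values.index = pd.Index(df[gene_col].astype(str), name=_GENE_ID_COL)
    if (values.to_numpy() < 0).any():
        raise MalformedInputError(f"{path}: negative expression value")

    gene_names = None
    if name_col is not None:
        gene_names = pd.Series(
            df[name_col].astype(str).to_numpy(), index=values.index, name=_GENE_NAME_COL
        )
    resolved = _detect_units(path) if units == "auto" else units.upper()
    return ExpressionMatrix(values=values, units=resolved, gene_names=gene_names)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the same TSV dialect :func:`read_expression_matrix` reads."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = _GENE_ID_COL
    if matrix.gene_names is not None:
        out.insert(0, _GENE_NAME_COL, matrix.gene_names.to_numpy())
    with open(path, "w") as fh:
        fh.write(f"# units: {matrix.units}\n")
        out.to_csv(fh, sep="\t")


def load_tissue_map(path: str | Path) -> TissueOntologyMap:
    """Load a child/parent/accession TSV into a :class:`TissueOntologyMap`.

    A header row whose first cell is ``child`` (case-insensitive) is
    accepted and skipped; otherwise all rows are data. A child listed with
    two different parents raises :class:`AmbiguousMappingError`.
    """
    entries: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MalformedInputError(
                    f"{path}:{lineno}: expected child<TAB>parent[<TAB>accession]"
                )
            child, parent = parts[0].strip(), parts[1].strip()
            accession = parts[2].strip() if len(parts) > 2 else ""
            if lineno == 1 and child.lower() == "child":
                continue
            if child in entries and entries[child][0] != parent:
                raise AmbiguousMappingError(
                    f"tissue {child!r} mapped to both {entries[child][0]!r} and {parent!r}"
                )
            entries[child] = (parent, accession)
    return TissueOntologyMap(entries)


def roll_up_assignments(
    assignments: GeneTissueAssignment, tissue_map: TissueOntologyMap | Mapping[str, str]
) -> GeneTissueAssignment:
    """Map child-tissue pairs to parent tissues, collapsing sibling duplicates.

    The result is the set-image of the pairs under the child→parent map:
    ``(gene, child)`` becomes ``(gene, parent)`` and pairs that collide
    (two children of the same parent) collapse to one row. When per-pair
    statistics are present the surviving row is the one with the highest
    expression among the collapsed children, and ``is_argmax`` is true if
    any collapsed child was the argmax.
    """
    if isinstance(tissue_map, TissueOntologyMap):
        lookup = {c: p for c, (p, _) in tissue_map.entries.items()}
    else:
        lookup = dict(tissue_map)

    table = assignments.table.copy()
    unmapped = sorted(set(table["tissue"]) - set(lookup))
    if unmapped:
        raise MissingMappingError(f"tissues without parent mapping: {unmapped[:5]}")
    table["tissue"] = table["tissue"].map(lookup)

    if "expression" in table.columns:
        table = table.sort_values("expression", ascending=False, kind="stable")
    if "is_argmax" in table.columns:
        argmax = table.groupby(["gene_id", "tissue"])["is_argmax"].transform("any")
        table = table.assign(is_argmax=argmax)
    table = table.drop_duplicates(subset=["gene_id", "tissue"], keep="first")
    table = table.sort_values(["gene_id", "tissue"], kind="stable").reset_index(drop=True)
    return GeneTissueAssignment(table)
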