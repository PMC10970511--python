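"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular artifacts are TSV (gene-set descriptions may contain commas);
gene sets use the GMT dialect (set_id TAB description TAB member ...).
Gene identifiers are case-sensitive plain symbols — no aliasing or mapping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Treatment arms of the study design: vehicle control, low dose, high dose.
CONDITIONS = ("control", "low", "high")

#: Provenance labels a gene-set collection may carry.
CATEGORIES = ("injury_module", "pathway", "feature_set")


class ValidationError(ValueError):
    """A file or in-memory object violated a structural invariant."""


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """A log2 gene-expression matrix with per-sample design annotations.

    Parameters
    ----------
    expression
        genes x samples matrix of log2 expression; index holds gene symbols,
        columns hold sample ids.
    samples
        Sample sheet indexed by sample id with columns ``lot``, ``condition``
        (one of :data:`CONDITIONS`) and ``replicate`` (positive integer).
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        expr, sheet = self.expression, self.samples
        genes = expr.index
        if genes.has_duplicates:
            dups = genes[genes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if any(g == "" or not isinstance(g, str) for g in genes):
            raise ValidationError("gene symbols must be non-empty strings")
        if expr.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in matrix")
        if sheet.index.has_duplicates:
            raise ValidationError("duplicate sample ids in sample sheet")
        missing = {"lot", "condition", "replicate"} - set(sheet.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        in_matrix = set(expr.columns)
        in_sheet = set(sheet.index)
        if in_matrix != in_sheet:
            only_m = sorted(in_matrix - in_sheet)
            only_s = sorted(in_sheet - in_matrix)
            raise ValidationError(
                "matrix/sheet sample mismatch: "
                f"only in matrix {only_m[:5]}, only in sheet {only_s[:5]}"
            )
        bad = set(sheet["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition token(s): {sorted(bad)}")
        reps = sheet["replicate"]
        if not np.issubdtype(np.asarray(reps).dtype, np.integer) or (reps <= 0).any():
            raise ValidationError("replicate must be a positive integer")
        vals = expr.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("non-numeric expression cell")
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite expression value")

    # -- conveniences ------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def lots(self) -> list[str]:
        return sorted(self.samples["lot"].unique())

    def arm(self, lot: str, condition: str) -> pd.DataFrame:
        """Expression submatrix (genes x replicates) of one lot/condition arm."""
        if lot not in set(self.samples["lot"]):
            raise KeyError(f"unknown lot {lot!r}")
        if condition not in CONDITIONS:
            raise KeyError(f"unknown condition {condition!r}")
        ids = self.samples.index[
            (self.samples["lot"] == lot) & (self.samples["condition"] == condition)
        ]
        return self.expression[list(ids)]


def read_expression_study(matrix_path, sample_sheet_path) -> ExpressionStudy:
    """Load a log2 expression TSV plus its sample sheet and validate them.

    The matrix has a first column ``gene`` and one column per sample id; the
    sheet has columns ``sample_id``, ``lot``, ``condition``, ``replicate``.
    """
    expr = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if expr.columns[0] != "gene":
        raise ValidationError(
            f"{matrix_path}: first matrix column must be 'gene', got {expr.columns[0]!r}"
        )
    expr = expr.set_index("gene")
    non_num = [c for c in expr.columns if not np.issubdtype(expr[c].dtype, np.number)]
    if non_num:
        raise ValidationError(f"{matrix_path}: non-numeric cells in column(s) {non_num[:5]}")
    sheet = pd.read_csv(
        sample_sheet_path,
        sep="\t",
        dtype={"sample_id": str, "lot": str, "condition": str},
    )
    required = {"sample_id", "lot", "condition", "replicate"}
    if missing := required - set(sheet.columns):
        raise ValidationError(f"{sample_sheet_path}: missing columns {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    return ExpressionStudy(expression=expr, samples=sheet)


def write_expression_study(study: ExpressionStudy, matrix_path, sample_sheet_path) -> None:
    """Write the matrix and sheet in the canonical TSV layout (full precision)."""
    out = study.expression.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    sheet = study.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sample_sheet_path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]
    category: str

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValidationError("empty set_id")
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} is empty")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets (injury modules, pathways or toxicity feature sets)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.set_id in self.sets:
            raise ValidationError(f"duplicate set_id {gs.set_id!r}")
        self.sets[gs.set_id] = gs

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def ids(self) -> list[str]:
        return list(self.sets)


def read_gene_sets(gmt_path, category: str) -> GeneSetCollection:
    """Parse a GMT file, tagging every set with *category*.

    Duplicate members within a line are deduplicated with a logged warning;
    a line with fewer than three fields or a repeated set id is an error.
    """
    coll = GeneSetCollection()
    with open(gmt_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{gmt_path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            set_id, desc, *members = fields
            members = [m for m in members if m != ""]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r has %d duplicate member(s); deduplicated",
                    gmt_path, lineno, set_id, len(members) - len(unique),
                )
            coll.add(GeneSet(set_id, desc, frozenset(unique), category))
    return coll


def write_gene_sets(coll: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Result tables and config files
# ---------------------------------------------------------------------------


def write_table(
    rows: Sequence[Mapping], path, float_decimals: int = 4,
    columns: Sequence[str] | None = None,
) -> None:
    """Write homogeneous records as a TSV with header, in the supplied order.

    Floats are formatted to *float_decimals* decimals. An empty record list
    yields a header-only file (pass *columns* to name the header; otherwise
    the header is empty).
    """
    rows = list(rows)
    if not rows:
        Path(path).write_text("\t".join(columns or []) + "\n")
        return
    schema = list(columns) if columns is not None else list(rows[0].keys())
    if columns is not None and list(rows[0].keys()) != schema:
        raise ValidationError(f"record 1 schema {list(rows[0].keys())} != {schema}")
    for i, r in enumerate(rows[1:], start=2):
        if list(r.keys()) != schema:
            raise ValidationError(f"record {i} schema {list(r.keys())} != {schema}")
    df = pd.DataFrame(rows, columns=schema)
    write_frame(df, path, float_decimals=float_decimals)


def write_frame(df: pd.DataFrame, path, float_decimals: int = 4, index: bool = False) -> None:
    """TSV writer used for all report tables (fixed float formatting)."""
    df.to_csv(path, sep="\t", float_format=f"%.{float_decimals}f", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config_file(path) -> dict:
    """Read a YAML or JSON config mapping (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data


def dump_config_file(data: Mapping, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(dict(data), indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(dict(data), sort_keys=True))
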