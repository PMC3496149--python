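"""Readers and writers for expression matrices, clinical tables and signed gene sets.

The on-disk formats are deliberately plain text: tab-separated expression
matrices (optionally in the GEO Series Matrix dialect), CSV clinical tables
and GMT-like gene-set files whose members may carry explicit ``:+1`` /
``:-1`` weights.  Everything is held in memory as pandas objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("substrata")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gene_sets",
    "write_gene_sets",
    "normalize_symbol",
]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


def normalize_symbol(symbol: str) -> str:
    """Canonical join key for gene symbols: trimmed, upper-cased.

    Symbols are the join key between expression matrices, gene sets and
    centroid tables, and annotation sources disagree on case.
    """
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 expression values, features (probes/genes) x samples.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        All entries must be finite; missing values are rejected.
    feature_annot
        Optional per-feature annotation (e.g. gene symbol, annotation
        quality), indexed by feature id.
    sample_annot
        Optional per-sample annotation (e.g. hybridization batch), indexed
        by sample id; its index must be a subset of the sample ids.
    """

    values: pd.DataFrame
    feature_annot: pd.DataFrame | None = None
    sample_annot: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise FormatError(
                "non-finite expression value at feature "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.sample_annot is not None:
            extra = self.sample_annot.index.difference(self.values.columns)
            if len(extra):
                raise FormatError(f"sample annotation for unknown sample(s): {list(extra)[:3]}")

    # -- convenience -------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_by_features(self) -> pd.DataFrame:
        """The scikit-learn orientation (samples as rows)."""
        return self.values.T

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        annot = None
        if self.sample_annot is not None:
            keep = [s for s in sample_ids if s in self.sample_annot.index]
            annot = self.sample_annot.loc[keep]
        return ExpressionMatrix(self.values[list(sample_ids)], self.feature_annot, annot)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        annot = None
        if self.feature_annot is not None:
            keep = [f for f in feature_ids if f in self.feature_annot.index]
            annot = self.feature_annot.loc[keep]
        return ExpressionMatrix(self.values.loc[list(feature_ids)], annot, self.sample_annot)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same annotations, new value matrix (used by transforms)."""
        fa = self.feature_annot
        if fa is not None:
            fa = fa.loc[fa.index.intersection(values.index)]
        sa = self.sample_annot
        if sa is not None:
            sa = sa.loc[sa.index.intersection(values.columns)]
        return ExpressionMatrix(values, fa, sa)

    def symbols(self) -> pd.Series:
        """Normalized gene symbol per feature (falls back to the feature id)."""
        if self.feature_annot is not None and "symbol" in self.feature_annot.columns:
            sym = self.feature_annot["symbol"].reindex(self.values.index)
            sym = sym.fillna(pd.Series(self.values.index, index=self.values.index))
        else:
            sym = pd.Series(self.values.index, index=self.values.index)
        return sym.map(normalize_symbol)


CATEGORICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "tumor_size": ("T1", "T2"),
    "node_status": ("N0", "N+"),
    "nhg": ("1", "2", "3"),
    "er": ("pos", "neg"),
    "pr": ("pos", "neg"),
    "her2": ("pos", "neg"),
    "chemotherapy": ("yes", "no"),
    "endocrine_therapy": ("yes", "no"),
    "radiotherapy": ("yes", "no"),
    "nat1": ("pos", "neg"),
    "hla": ("pos", "moderate", "neg"),
}


@dataclass
class ClinicalTable:
    """Per-sample clinical follow-up and covariates.

    ``data`` is indexed by sample id and carries at least ``dmfs_time``
    (years, >= 0) and ``dmfs_event`` (0/1).  Categorical covariates are
    restricted to the enumerations in :data:`CATEGORICAL_LEVELS`; anything
    else is coerced to NA with a warning.  Missing values stay NA and are
    dropped per-analysis (complete-case).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample id in clinical table: {dup!r}")
        if "dmfs_time" in df.columns:
            t = pd.to_numeric(df["dmfs_time"], errors="coerce")
            if (t.dropna() < 0).any():
                bad = t.index[t < 0][0]
                raise ValueError(f"negative dmfs_time for sample {bad!r}")
            df["dmfs_time"] = t
        if "dmfs_event" in df.columns:
            e = pd.to_numeric(df["dmfs_event"], errors="coerce")
            if not e.dropna().isin([0, 1]).all():
                bad = e.index[~e.isin([0, 1]) & e.notna()][0]
                raise ValueError(f"dmfs_event must be 0/1, offending sample {bad!r}")
            df["dmfs_event"] = e
        for col, levels in CATEGORICAL_LEVELS.items():
            if col not in df.columns:
                continue
            vals = df[col].astype("string").str.strip()
            vals = vals.where(~vals.isin(["", "NA", "N/A", "nan", "None"]), pd.NA)
            bad = vals.notna() & ~vals.isin(levels)
            if bad.any():
                for sample, tok in vals[bad].items():
                    logger.warning(
                        "clinical: %s=%r for sample %r outside %s; set to NA",
                        col, tok, sample, levels,
                    )
                vals = vals.where(~bad, pd.NA)
            df[col] = vals
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def complete_cases(self, columns: list[str]) -> pd.DataFrame:
        """Rows with no NA in ``columns`` (per-analysis complete-case rule)."""
        return self.data.dropna(subset=[c for c in columns if c in self.data.columns])


@dataclass
class GeneSetCollection:
    """Named signed gene sets: set name -> {normalized symbol: weight in {+1, -1}}."""

    sets: dict[str, dict[str, int]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            for sym, w in members.items():
                if w not in (1, -1):
                    raise FormatError(f"gene set {name!r}: weight for {sym!r} must be +1/-1, got {w}")

    def __getitem__(self, name: str) -> dict[str, int]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

_GEO_TABLE_BEGIN = "!series_matrix_table_begin"
_GEO_TABLE_END = "!series_matrix_table_end"


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a features x samples log2 expression matrix.

    ``dialect="tsv"`` expects a header row of sample ids and feature ids in
    the first column.  ``dialect="geo_series_matrix"`` additionally strips
    ``!``-prefixed metadata lines, the ``!series_matrix_table_begin/end``
    fences and surrounding double quotes on identifiers.
    """
    path = Path(path)
    if dialect not in ("tsv", "geo_series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = path.read_text().splitlines()
    if dialect == "geo_series_matrix":
        inside = _GEO_TABLE_BEGIN not in {ln.strip() for ln in lines}
        table = []
        for ln in lines:
            s = ln.strip()
            if s == _GEO_TABLE_BEGIN:
                inside = True
                continue
            if s == _GEO_TABLE_END:
                inside = False
                continue
            if not inside or s.startswith("!") or not s:
                continue
            table.append(ln)
        lines = table
    else:
        lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: no table found")

    def _unquote(tok: str) -> str:
        tok = tok.strip()
        if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
            tok = tok[1:-1]
        return tok

    header = [_unquote(t) for t in lines[0].split("\t")]
    sample_ids = header[1:]
    feature_ids = []
    rows = []
    for r, ln in enumerate(lines[1:], start=2):
        toks = ln.split("\t")
        if len(toks) != len(header):
            raise FormatError(f"{path}: row {r} has {len(toks)} fields, expected {len(header)}")
        feature_ids.append(_unquote(toks[0]))
        row = []
        for c, tok in enumerate(toks[1:], start=2):
            try:
                row.append(float(_unquote(tok)))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {tok!r}"
                ) from None
        rows.append(row)
    values = pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids)
    return ExpressionMatrix(values)


def write_expression(matrix: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write a matrix in either dialect; inverse of :func:`read_expression`."""
    path = Path(path)
    df = matrix.values
    if dialect == "tsv":
        out = ["\t".join(["feature_id", *map(str, df.columns)])]
        for fid, row in df.iterrows():
            out.append("\t".join([str(fid), *(repr(float(v)) for v in row)]))
        path.write_text("\n".join(out) + "\n")
    elif dialect == "geo_series_matrix":
        out = [
            "!Series_title\t\"synthetic series\"",
            _GEO_TABLE_BEGIN,
            "\t".join(['"ID_REF"', *(f'"{c}"' for c in df.columns)]),
        ]
        for fid, row in df.iterrows():
            out.append("\t".join([f'"{fid}"', *(repr(float(v)) for v in row)]))
        out.append(_GEO_TABLE_END)
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def read_clinical(path) -> ClinicalTable:
    """Read a clinical CSV keyed by a ``sample_id`` column."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required 'sample_id' column")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT-like, optionally signed)
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> GeneSetCollection:
    """Read GMT-like lines: ``name<TAB>description<TAB>SYMBOL[:+1|:-1]...``.

    Members without an explicit weight default to +1; duplicate symbols
    within a set collapse to the first occurrence with a warning.
    """
    path = Path(path)
    sets: dict[str, dict[str, int]] = {}
    descriptions: dict[str, str] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        toks = ln.rstrip("\n").split("\t")
        if len(toks) < 3:
            raise FormatError(f"{path}:{lineno}: expected name, description and >= 1 member")
        name, desc = toks[0].strip(), toks[1]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        members: dict[str, int] = {}
        for tok in toks[2:]:
            tok = tok.strip()
            if not tok:
                continue
            if ":" in tok:
                sym, wtok = tok.rsplit(":", 1)
                if wtok not in ("+1", "1", "-1"):
                    raise FormatError(
                        f"{path}:{lineno}: invalid weight {wtok!r} for member {sym!r} (must be +1 or -1)"
                    )
                weight = 1 if wtok in ("+1", "1") else -1
            else:
                sym, weight = tok, 1
            sym = normalize_symbol(sym)
            if sym in members:
                logger.warning("gene set %r: duplicate member %r collapsed to first occurrence", name, sym)
                continue
            members[sym] = weight
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    out = []
    for name in collection:
        desc = collection.descriptions.get(name, "")
        members = [f"{sym}:{w:+d}" for sym, w in collection[name].items()]
        out.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(out) + "\n")
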