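"""In-memory containers for expression data and sample metadata, with TSV I/O.

Expression values are log2 sample/universal-reference ratios arranged as a
spots x samples matrix. Missingness is carried as NaN in the value matrix;
``mask`` exposes it as a boolean DataFrame (True = missing). Spot ids are
unique; gene symbols are annotation and may repeat across spots (duplicate
spots are deliberately kept as separate rows throughout the pipeline).

File format: tab-separated, UTF-8, LF line endings. First column ``spot_id``,
optional ``gene_symbol`` and ``mean_log_intensity`` columns, then one column
per sample. Empty cells or the token ``NA`` mean missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

MISSING_TOKEN = "NA"

#: canonical group labels used by the simulator and the pipeline
GROUP_CASE = "case"
GROUP_CONTROL = "control"

_RESERVED_COLUMNS = ("spot_id", "gene_symbol", "mean_log_intensity")


@dataclass
class ExpressionMatrix:
    """Spots x samples log2-ratio matrix with missing mask and optional intensities.

    Parameters
    ----------
    values : DataFrame
        Float matrix indexed by spot id with sample-id columns; NaN = missing.
    gene_symbols : Series, optional
        Gene symbol per spot (index aligned with ``values``); symbols may repeat.
    intensity : DataFrame, optional
        Mean log2 spot intensity, same shape as ``values``; the covariate for
        intensity-dependent (lowess) centering.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None
    intensity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "spot_id"
        self.values.columns.name = None
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate spot id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values.to_numpy()).any():
                raise FormatError("non-finite (inf) expression value")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)
        if self.intensity is not None:
            self.intensity = self.intensity.astype(float)
            if self.intensity.shape != self.values.shape:
                raise FormatError(
                    "intensity matrix shape "
                    f"{self.intensity.shape} != values shape {self.values.shape}"
                )
            self.intensity.index = self.values.index
            self.intensity.columns = self.values.columns

    # -- basic accessors -------------------------------------------------
    @property
    def spot_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing mask (True where the value is absent)."""
        return self.values.isna()

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_spots(self, spot_ids) -> "ExpressionMatrix":
        """Row-subset (order follows ``spot_ids``)."""
        idx = pd.Index(spot_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown spot ids: {list(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[idx],
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[idx],
            intensity=None if self.intensity is None else self.intensity.loc[idx],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown sample ids: {list(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values[idx],
            gene_symbols=self.gene_symbols,
            intensity=None if self.intensity is None else self.intensity[idx],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.copy(),
            intensity=None if self.intensity is None else self.intensity.copy(),
        )


@dataclass
class SampleTable:
    """Sample -> subject -> group mapping with optional clinical covariates.

    ``table`` is indexed by sample id and must contain ``subject_id`` and
    ``group`` columns; additional columns are treated as covariates (e.g.
    surgical status, chemotherapy status, diabetes history, tumor location,
    stage class). Every sample has exactly one subject and one group, and all
    samples of a subject share one group (the design is case/control at the
    subject level with repeated samples per subject).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        for col in ("subject_id", "group"):
            if col not in self.table.columns:
                raise FormatError(f"sample table missing required column {col!r}")
            if self.table[col].isna().any():
                bad = self.table.index[self.table[col].isna()][0]
                raise FormatError(f"sample {bad!r} has missing {col}")
        per_subject = self.table.groupby("subject_id")["group"].nunique()
        mixed = per_subject[per_subject > 1]
        if len(mixed):
            raise FormatError(
                f"subject {mixed.index[0]!r} has samples in more than one group"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def subjects(self) -> pd.Series:
        return self.table["subject_id"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table.drop(columns=["subject_id", "group"])

    def group_levels(self) -> list[str]:
        return sorted(self.table["group"].unique().tolist())

    def samples_in_group(self, group: str) -> pd.Index:
        return self.table.index[self.table["group"] == group]


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_strict(path) -> pd.DataFrame:
    """Read a TSV rejecting ragged rows; '' and 'NA' map to NaN."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    width = lines[0].count("\t")
    for i, ln in enumerate(lines[1:], start=2):
        if ln.count("\t") != width:
            raise FormatError(f"{path}: ragged row at line {i}")
    return pd.read_csv(
        io.StringIO(text),
        sep="\t",
        dtype=str,
        na_values=[MISSING_TOKEN, ""],
        keep_default_na=False,
    )


def read_expression_matrix(path, expect_log2: bool = True) -> ExpressionMatrix:
    """Read an expression TSV (header of sample ids, first column spot id).

    Optional ``gene_symbol`` and ``mean_log_intensity`` columns are honored;
    the per-spot intensity column is broadcast across samples. Empty cells or
    ``NA`` are missing. ``expect_log2=False`` marks the values as raw ratios
    which the caller must pass through :func:`pbmcsig.preprocess.log2_transform`
    (the flag is advisory; the container does not transform).
    """
    raw = _read_tsv_strict(path)
    if raw.columns[0] != "spot_id":
        raise FormatError(f"{path}: first column must be 'spot_id', got {raw.columns[0]!r}")
    raw = raw.set_index("spot_id")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate spot id {dup!r}")
    gene_symbols = None
    if "gene_symbol" in raw.columns:
        gene_symbols = raw.pop("gene_symbol")
    intensity_col = None
    if "mean_log_intensity" in raw.columns:
        intensity_col = raw.pop("mean_log_intensity")
    sample_cols = [c for c in raw.columns if c not in _RESERVED_COLUMNS]
    try:
        values = raw[sample_cols].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    intensity = None
    if intensity_col is not None:
        try:
            icol = intensity_col.astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric intensity cell ({exc})") from exc
        intensity = pd.DataFrame(
            np.repeat(icol.to_numpy()[:, None], values.shape[1], axis=1),
            index=values.index,
            columns=values.columns,
        )
    return ExpressionMatrix(values=values, gene_symbols=gene_symbols, intensity=intensity)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the TSV that :func:`read_expression_matrix` reads back.

    A spots x samples intensity matrix is written as a per-spot
    ``mean_log_intensity`` column when it is constant across samples (the
    simulator's convention); otherwise it is dropped with the data intact.
    """
    out = pd.DataFrame(index=matrix.values.index)
    out.index.name = "spot_id"
    if matrix.gene_symbols is not None:
        out["gene_symbol"] = matrix.gene_symbols
    if matrix.intensity is not None:
        arr = matrix.intensity.to_numpy()
        if np.allclose(arr, arr[:, :1], equal_nan=True):
            out["mean_log_intensity"] = arr[:, 0]
    full = pd.concat([out, matrix.values], axis=1)
    full.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, lineterminator="\n")


def read_sample_table(path) -> SampleTable:
    raw = _read_tsv_strict(path)
    if raw.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id', got {raw.columns[0]!r}")
    return SampleTable(raw.set_index("sample_id"))


def write_sample_table(samples: SampleTable, path) -> None:
    out = samples.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, lineterminator="\n")
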