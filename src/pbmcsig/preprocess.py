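"""Preprocessing of two-channel log-ratio data.

Three steps, in the order the pipeline applies them: log2 transform of raw
sample/reference ratios, per-array centering by a robust lowess fit of
log-ratio on mean spot log-intensity (removing additive offsets and smooth
intensity-dependent dye bias; median centering when no intensities exist),
and exclusion of spots whose missing fraction exceeds a threshold (default
50%, strictly greater than). Missing values stay missing throughout — no
imputation — and duplicate spots are never averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .data import (  # noqa: F401  (re-exported module surface)
    ExpressionMatrix,
    SampleTable,
    read_expression_matrix,
    read_sample_table,
    write_expression_matrix,
    write_sample_table,
)
from .exceptions import DomainError

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "log2_transform",
    "lowess_center_array",
    "center_arrays",
    "filter_genes_by_missingness",
]

#: minimum number of present spots for lowess smoothing; below this the
#: array falls back to median centering
MIN_POINTS_FOR_LOWESS = 10


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of every present raw ratio; the mask is untouched.

    Raises
    ------
    DomainError
        If any present value is <= 0, naming the offending spot and sample.
    """
    vals = matrix.values.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"nonpositive ratio {vals[i, j]!r} at spot "
            f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
        )
    out = matrix.copy()
    out.values.iloc[:, :] = np.log2(vals)
    return out


def lowess_center_array(
    log_ratios: np.ndarray,
    intensities: np.ndarray | None = None,
    frac: float = 0.3,
    iterations: int = 3,
) -> np.ndarray:
    """Center one array: subtract a robust lowess fit of log-ratio on intensity.

    With no intensity covariate (or fewer than MIN_POINTS_FOR_LOWESS present
    values) the array is median-centered instead. NaNs pass through.
    """
    y = np.asarray(log_ratios, dtype=float)
    if not 0.0 < frac <= 1.0:
        raise DomainError(f"lowess frac must be in (0, 1], got {frac}")
    if intensities is not None:
        x = np.asarray(intensities, dtype=float)
        if x.shape != y.shape:
            raise DomainError(
                f"length mismatch: {len(y)} log-ratios vs {len(x)} intensities")
    present = ~np.isnan(y)
    if intensities is not None:
        present &= ~np.isnan(np.asarray(intensities, dtype=float))
    out = y.copy()
    if intensities is None or present.sum() < MIN_POINTS_FOR_LOWESS:
        if present.sum() == 0:
            return out
        out[present] = y[present] - np.median(y[present])
        return out
    x = np.asarray(intensities, dtype=float)
    # return_sorted=False evaluates at the input points in input order (the
    # xvals path mishandles robustness weights when residuals vanish)
    fitted = _sm_lowess(
        y[present], x[present], frac=frac, it=iterations, return_sorted=False)
    out[present] = y[present] - fitted
    return out


def center_arrays(
    matrix: ExpressionMatrix, frac: float = 0.3, iterations: int = 3
) -> ExpressionMatrix:
    """Apply :func:`lowess_center_array` to every sample column."""
    out = matrix.copy()
    vals = out.values.to_numpy()
    intens = None if out.intensity is None else out.intensity.to_numpy()
    for j in range(vals.shape[1]):
        vals[:, j] = lowess_center_array(
            vals[:, j],
            None if intens is None else intens[:, j],
            frac=frac,
            iterations=iterations,
        )
    out.values.iloc[:, :] = vals
    return out


def filter_genes_by_missingness(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop spots whose missing fraction strictly exceeds the threshold.

    A spot missing exactly the threshold fraction is retained ("exceeded"
    read strictly). Columns are never dropped. Idempotent.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise DomainError(
            f"max_missing_fraction must be in [0, 1], got {max_missing_fraction}")
    frac_missing = matrix.mask.mean(axis=1)
    keep = matrix.spot_ids[frac_missing <= max_missing_fraction]
    return matrix.subset_spots(keep)
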