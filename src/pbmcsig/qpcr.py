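"""Relative qPCR quantification (2^-ddCt) and microarray concordance.

For a target gene and sample s, dCt_s = Ct_target,s - Ct_housekeeping,s;
referencing the calibrator sample (here the universal-reference RNA, the
same standard the arrays were normalized against) gives
ddCt_s = dCt_s - dCt_calibrator, and the fold change 2^(-ddCt_s) — one
cycle fewer means twice the expression, and the calibrator's fold is 1 by
construction. The housekeeping gene must be named explicitly: this assay's
usual default (GAPDH) is itself differentially expressed in the system the
pipeline targets, so no default is safe.

Concordance with the microarray compares, per gene, the qPCR cross-group
median fold-change ratio with the microarray ratio: the gene validates iff
both ratios fall strictly on the same side of 1 (a ratio exactly 1 is
"flat" and conservatively counts as non-agreement).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import GROUP_CASE, SampleTable
from .exceptions import DomainError
from .simulate import CtTable

__all__ = [
    "delta_delta_ct",
    "group_median_fold",
    "direction_concordance",
    "concordance_report",
]


def delta_delta_ct(ct: CtTable, target: str, housekeeping: str | None = None,
                   calibrator: str | None = None) -> pd.Series:
    """Per-sample fold changes 2^-ddCt for one target gene.

    ``housekeeping``/``calibrator`` default to the table's designations.
    Missing Ct values in used cells are an error naming the cell.
    """
    housekeeping = housekeeping or ct.housekeeping
    calibrator = calibrator or ct.calibrator
    if target == housekeeping:
        raise DomainError("target gene must differ from the housekeeping gene")
    for gene in (target, housekeeping):
        if gene not in ct.ct.columns:
            raise DomainError(f"gene {gene!r} not in Ct table")
    if calibrator not in ct.ct.index:
        raise DomainError(f"calibrator sample {calibrator!r} not in Ct table")
    t = ct.ct[target].astype(float)
    h = ct.ct[housekeeping].astype(float)
    for name, col in (("target", t), ("housekeeping", h)):
        if col.isna().any():
            s = col.index[col.isna()][0]
            raise DomainError(f"missing {name} Ct at sample {s!r}")
    dct = t - h
    ddct = dct - dct.loc[calibrator]
    folds = np.exp2(-ddct)
    folds.name = target
    return folds


def group_median_fold(folds: pd.Series, samples: SampleTable,
                      case_label: str = GROUP_CASE) -> tuple[float, str]:
    """Cross-group ratio of median fold changes, and its direction.

    ratio = median(case folds) / median(control folds); direction is "up"
    if ratio > 1, "down" if < 1, "flat" at exactly 1. Samples absent from
    the sample table (e.g. the calibrator) are ignored.
    """
    known = folds.index.intersection(samples.sample_ids)
    groups = samples.groups.loc[known]
    case_folds = folds.loc[known[groups == case_label]]
    ctrl_folds = folds.loc[known[groups != case_label]]
    if case_folds.empty or ctrl_folds.empty:
        raise DomainError("both groups must be represented among the samples")
    ratio = float(case_folds.median() / ctrl_folds.median())
    direction = "up" if ratio > 1 else ("down" if ratio < 1 else "flat")
    return ratio, direction


def _side(x: float) -> int:
    return 0 if x == 1.0 else (1 if x > 1.0 else -1)


def direction_concordance(microarray_fc, qpcr_fc) -> tuple[pd.Series, float]:
    """Per-gene direction agreement between two fold-change ratio sets.

    Both inputs map gene -> cross-group ratio over the same gene set. A gene
    agrees iff both ratios are strictly on the same side of 1; a ratio
    exactly 1 never agrees. Returns (per-gene boolean flags, agreeing
    fraction). Symmetric in its two arguments.
    """
    a = pd.Series(microarray_fc, dtype=float)
    b = pd.Series(qpcr_fc, dtype=float)
    if sorted(a.index) != sorted(b.index):
        raise DomainError("microarray and qPCR ratios must cover the same genes")
    b = b.loc[a.index]
    flags = pd.Series(
        [(_side(x) == _side(y) and _side(x) != 0) for x, y in zip(a, b)],
        index=a.index, name="concordant")
    return flags, float(flags.mean())


def concordance_report(microarray_fc, qpcr_fc) -> pd.DataFrame:
    """Tabular report: gene, microarray ratio, qPCR ratio, concordant flag."""
    flags, rate = direction_concordance(microarray_fc, qpcr_fc)
    out = pd.DataFrame({
        "microarray": pd.Series(microarray_fc, dtype=float),
        "qpcr": pd.Series(qpcr_fc, dtype=float).loc[flags.index],
        "concordant": flags,
    })
    out.index.name = "gene"
    out.attrs["validation_rate"] = rate
    return out
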