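"""Per-gene mixed-effects differential expression with FDR control.

Each gene is modelled as

    y_s = mu + beta * 1[group(s) = case] + b_subject(s) + eps_s,
    b ~ N(0, var_subject),  eps ~ N(0, var_residual),

a fixed diagnosis effect plus a random per-subject intercept accounting for
repeated samples per person. The fit is restricted maximum likelihood,
profiled over the variance ratio lambda = var_subject / var_residual: the
marginal covariance is block diagonal by subject, so for a given lambda the
GLS estimates, the profiled residual variance and the REML criterion all
reduce to sums over per-subject aggregates, and a single bounded scalar
optimisation over log(lambda) completes the fit. The boundary lambda = 0
collapses to ordinary least squares with pooled variance (equivalently the
pooled two-sample t-test, flagged as such); lambda -> infinity (zero residual
variance, e.g. exact within-subject duplicates) collapses to a two-sample
t-test on subject means. Inference is a two-sided Wald t with between-within
degrees of freedom (number of subjects - 2) while the random effect is
active, and n - 2 in the pooled fallback.

Fold changes are reported as 2^beta from the model estimate; multiplicity is
handled by Benjamini-Hochberg step-up adjustment (q-values) with discovery at
q <= 0.10 by default and an optional fold-change floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .data import GROUP_CASE, ExpressionMatrix, SampleTable
from .exceptions import DegenerateDataError, DomainError, FitError

__all__ = [
    "GeneFit",
    "fit_gene_mixed_model",
    "bh_fdr",
    "differential_expression",
    "select_genes",
    "DifferentialExpression",
    "DifferentialExpressionResults",
]

_LOG_LAMBDA_LO = -12.0
_LOG_LAMBDA_HI = 14.0  # lambda ~ 1.2e6; beyond this the fit collapses to subject means


@dataclass
class GeneFit:
    """Result of one per-gene fit."""

    beta: float            # log2 case - control difference
    se: float
    stat: float            # beta / se
    p: float               # two-sided
    df: float
    var_subject: float
    var_residual: float
    n_samples_used: int
    n_subjects_used: int
    method: str            # "mixed" or "two_sample_fallback"


def _pooled_t(y: np.ndarray, case: np.ndarray, df: int | None = None) -> tuple:
    """Pooled-variance two-sample t pieces: (beta, se, stat, p, df, s2)."""
    y1, y0 = y[case], y[~case]
    n1, n0 = len(y1), len(y0)
    beta = y1.mean() - y0.mean()
    ss = ((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum()
    dof = (n1 + n0 - 2) if df is None else df
    s2 = ss / (n1 + n0 - 2)
    if s2 <= 0:
        raise DegenerateDataError("zero pooled variance")
    se = math.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return beta, se, t, p, dof, s2


def fit_gene_mixed_model(y, group, subject, case_label: str | None = None) -> GeneFit:
    """REML fit of the random-subject-intercept model for one gene.

    Parameters
    ----------
    y : array-like
        Per-sample values; NaN = missing (those samples are dropped).
    group : array-like
        Two-level labels per sample.
    subject : array-like
        Subject id per sample.
    case_label : str, optional
        Which level is "case" (beta = case - control). Defaults to
        ``"case"`` when present, else the lexicographically larger level.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=object)
    subject = np.asarray(subject, dtype=object)
    if not (len(y) == len(group) == len(subject)):
        raise DomainError("y, group and subject must have equal length")
    present = ~np.isnan(y)
    y, group, subject = y[present], group[present], subject[present]

    levels = sorted(set(group))
    if len(levels) != 2:
        raise FitError(f"need exactly 2 group levels after dropping missing, got {levels}")
    if case_label is None:
        case_label = GROUP_CASE if GROUP_CASE in levels else levels[-1]
    if case_label not in levels:
        raise FitError(f"case label {case_label!r} not among levels {levels}")
    case = group == case_label
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n0 < 2:
        raise FitError(f"need >= 2 samples per group, got case={n1}, control={n0}")
    n = len(y)
    if np.ptp(y) == 0:
        raise DegenerateDataError("zero total variance")

    codes, uniq = pd.factorize(subject)
    n_subj = len(uniq)
    nj = np.bincount(codes).astype(float)
    Sj = np.bincount(codes, weights=y)
    gj = np.bincount(codes, weights=case.astype(float)) / nj  # 0/1 per subject
    sum_y2 = float((y * y).sum())

    if n_subj == n:
        # one sample per subject: the variance ratio is unidentified and the
        # REML criterion is flat -- the model IS the pooled two-sample t-test
        beta, se, t, p, dof, s2 = _pooled_t(y, case)
        return GeneFit(beta, se, t, p, dof, 0.0, s2, n, n_subj,
                       method="two_sample_fallback")

    def _gls(lam: float):
        d = 1.0 + lam * nj
        w = nj / d
        a = w.sum()
        b = (w * gj).sum()
        det = b * (a - b)
        if det <= 0:
            return None
        u = Sj / d
        t0, t1 = u.sum(), (u * gj).sum()
        # solve [[a, b], [b, b]] beta = [t0, t1]
        beta1 = (a * t1 - b * t0) / det
        beta0 = (t0 - b * beta1) / a
        yVy = sum_y2 - ((lam / d) * Sj * Sj).sum()
        rss = yVy - (beta0 * t0 + beta1 * t1)
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - 2)
        crit = (n - 2) * math.log(sigma2) + np.log(d).sum() + math.log(det)
        return crit, beta1, sigma2, a, det

    def _crit(log_lam: float) -> float:
        res = _gls(math.exp(log_lam))
        return math.inf if res is None else res[0]

    opt = optimize.minimize_scalar(
        _crit, bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI), method="bounded",
        options={"xatol": 1e-6})
    crit0 = _gls(0.0)[0]
    lam_hat = math.exp(opt.x)
    if crit0 <= opt.fun + 1e-8:
        lam_hat = 0.0

    if lam_hat == 0.0:
        # variance-component boundary: OLS with pooled variance
        beta, se, t, p, dof, s2 = _pooled_t(y, case)
        return GeneFit(beta, se, t, p, dof, 0.0, s2, n, n_subj,
                       method="two_sample_fallback")

    if opt.x >= _LOG_LAMBDA_HI - 0.5:
        # residual variance at (near) zero, e.g. exact within-subject
        # duplicates: the limit is a two-sample t-test on subject means
        ym = Sj / nj
        case_subj = gj > 0.5
        if case_subj.sum() < 2 or (~case_subj).sum() < 2:
            raise FitError("need >= 2 subjects per group for subject-mean collapse")
        beta, se, t, p, dof, s2 = _pooled_t(ym, case_subj)
        within_ms = (sum_y2 - (Sj * Sj / nj).sum()) / max(n - n_subj, 1)
        return GeneFit(beta, se, t, p, dof, s2, max(within_ms, 0.0), n, n_subj,
                       method="mixed")

    crit, beta1, sigma2, a, det = _gls(lam_hat)
    se = math.sqrt(sigma2 * a / det)
    t = beta1 / se
    dof = n_subj - 2
    p = 2.0 * stats.t.sf(abs(t), dof)
    return GeneFit(beta1, se, t, p, dof, lam_hat * sigma2, sigma2, n, n_subj,
                   method="mixed")


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    grouping: str = "group",
    case_label: str | None = None,
) -> pd.DataFrame:
    """Fit every spot independently and adjust across all fitted spots.

    ``grouping`` names either the design group column or any two-level
    covariate in the sample table (the latter serves the clinicopathologic
    subgroup comparisons, restricted by the caller to the relevant samples).
    Spots whose fit fails (all-missing group, zero variance) get NaN
    statistics and are excluded from the adjustment.

    Returns a DataFrame indexed by spot id with columns gene, beta, se, stat,
    p, df, var_subject, var_residual, n_samples_used, n_subjects_used,
    method, fold_change (= 2^beta), q, direction.
    """
    if grouping == "group":
        labels = samples.groups
    elif grouping in samples.table.columns:
        labels = samples.table[grouping]
    else:
        raise DomainError(f"unknown grouping {grouping!r}")
    keep = labels.notna()
    labels = labels[keep]
    levels = sorted(labels.unique().tolist())
    if len(levels) != 2:
        raise DomainError(f"grouping {grouping!r} must have 2 levels, got {levels}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise DomainError(f"each level of {grouping!r} needs >= 2 samples: {dict(counts)}")

    sample_ids = labels.index
    sub = matrix.subset_samples(sample_ids)
    grp = labels.to_numpy(dtype=object)
    subj = samples.subjects.loc[sample_ids].to_numpy(dtype=object)
    vals = sub.values.to_numpy()

    rows = []
    for i, spot in enumerate(sub.spot_ids):
        try:
            fit = fit_gene_mixed_model(vals[i], grp, subj, case_label=case_label)
            rows.append((spot, fit))
        except (FitError, DegenerateDataError):
            rows.append((spot, None))

    def _field(f, name):
        return getattr(f, name) if f is not None else np.nan

    table = pd.DataFrame({
        "gene": (matrix.gene_symbols.reindex(sub.spot_ids)
                 if matrix.gene_symbols is not None
                 else pd.Series(sub.spot_ids, index=sub.spot_ids)),
        "beta": [_field(f, "beta") for _, f in rows],
        "se": [_field(f, "se") for _, f in rows],
        "stat": [_field(f, "stat") for _, f in rows],
        "p": [_field(f, "p") for _, f in rows],
        "df": [_field(f, "df") for _, f in rows],
        "var_subject": [_field(f, "var_subject") for _, f in rows],
        "var_residual": [_field(f, "var_residual") for _, f in rows],
        "n_samples_used": [f.n_samples_used if f else 0 for _, f in rows],
        "n_subjects_used": [f.n_subjects_used if f else 0 for _, f in rows],
        "method": [f.method if f else "failed" for _, f in rows],
    }, index=pd.Index([s for s, _ in rows], name="spot_id"))
    table["fold_change"] = np.exp2(table["beta"])
    fitted = table["p"].notna()
    q = pd.Series(np.nan, index=table.index)
    if fitted.any():
        q[fitted] = bh_fdr(table.loc[fitted, "p"].to_numpy())
    table["q"] = q
    table["direction"] = np.where(table["beta"] >= 0, "up", "down")
    table.loc[~fitted, "direction"] = "NA"
    return table


def select_genes(de: pd.DataFrame, max_fdr: float = 0.10,
                 min_fold: float | None = 1.5) -> pd.Index:
    """Spots with q <= max_fdr and (optionally) |fold| >= min_fold either way."""
    if de.empty:
        raise DomainError("empty differential-expression table")
    ok = de["q"] <= max_fdr
    if min_fold is not None:
        fc = de["fold_change"]
        ok &= np.maximum(fc, 1.0 / fc) >= min_fold
    return de.index[ok.fillna(False)]


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class DifferentialExpression:
    """Per-gene mixed-model differential expression, statsmodels-style.

    Examples
    --------
    >>> model = DifferentialExpression(matrix, samples)      # doctest: +SKIP
    >>> res = model.fit()                                    # doctest: +SKIP
    >>> res.select(max_fdr=0.10, min_fold=1.5)               # doctest: +SKIP
    """

    def __init__(self, matrix: ExpressionMatrix, samples: SampleTable,
                 grouping: str = "group", case_label: str | None = None):
        self.matrix = matrix
        self.samples = samples
        self.grouping = grouping
        self.case_label = case_label

    def fit(self) -> "DifferentialExpressionResults":
        table = differential_expression(
            self.matrix, self.samples, self.grouping, self.case_label)
        return DifferentialExpressionResults(self, table)


class DifferentialExpressionResults:
    """Holds the per-spot DE table; selection, summary and TSV export."""

    def __init__(self, model: DifferentialExpression, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def n_fitted(self) -> int:
        return int(self.table["p"].notna().sum())

    def select(self, max_fdr: float = 0.10, min_fold: float | None = 1.5) -> pd.Index:
        return select_genes(self.table, max_fdr=max_fdr, min_fold=min_fold)

    def summary(self, max_fdr: float = 0.10, min_fold: float | None = 1.5) -> str:
        n_sig = len(select_genes(self.table, max_fdr=max_fdr, min_fold=None))
        n_fold = len(select_genes(self.table, max_fdr=max_fdr, min_fold=min_fold))
        lines = [
            "Differential expression (per-gene mixed model, REML)",
            f"  grouping:            {self.model.grouping}",
            f"  spots fitted:        {self.n_fitted} / {len(self.table)}",
            f"  significant (q<={max_fdr:g}):          {n_sig}",
        ]
        if min_fold is not None:
            lines.append(
                f"  of those, fold >= {min_fold:g} either way: {n_fold}")
        top = self.table.dropna(subset=["p"]).nsmallest(10, "q")
        lines.append("  top spots by q:")
        for spot, row in top.iterrows():
            lines.append(
                f"    {spot}\t{row['gene']}\tq={row['q']:.3g}"
                f"\tfold={row['fold_change']:.3f}\t{row['direction']}")
        return "\n".join(lines)

    def write_tsv(self, path, max_fdr: float | None = None,
                  min_fold: float | None = None) -> None:
        """Write the table (optionally only the selected spots), mirroring the
        gene/FDR/fold-change/direction report layout."""
        t = self.table
        if max_fdr is not None:
            t = t.loc[select_genes(t, max_fdr=max_fdr, min_fold=min_fold)]
        out = t[["gene", "q", "fold_change", "direction", "beta", "se", "p", "method"]]
        out = out.rename(columns={"q": "FDR"})
        out.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")
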