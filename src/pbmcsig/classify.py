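"""Compound covariate predictor (CCP) and companion classifiers.

The CCP is a linear rule for two-class expression data: each selected gene i
gets the weight w_i equal to its pooled-variance two-sample t-statistic
(case minus control) on the training data; a sample with log2 expression
values x_i scores c = sum_i w_i x_i, and is called case iff c is strictly
greater than a threshold set midway between the training class means of c.
Genes enter the predictor only if, on the training samples, their two-sample
p-value is <= p_max (default 1e-4) and their fold difference is >= min_fold
(default 1.5) in either direction.

Cross-validation is stratified k-fold (default k = 10, one repeat) with the
gene selection and all training redone from scratch inside every fold, so
the held-out fold never influences which genes are used — the unbiased
protocol; performing selection before splitting inflates accuracy on pure
noise (selection bias), which the test suite demonstrates.

Companion rules on the same selected genes: diagonal linear discriminant
analysis (per-gene pooled variances, equal priors), nearest centroid, and
1-/3-nearest neighbours on Euclidean distance with vote ties broken toward
the class of the single nearest neighbour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .data import GROUP_CASE, ExpressionMatrix, SampleTable
from .exceptions import DegenerateDataError, DomainError, FormatError

__all__ = [
    "CCPModel",
    "CVConfig",
    "Performance",
    "two_sample_t",
    "select_predictor_genes",
    "train_ccp",
    "ccp_classify",
    "companion_classify",
    "kfold_cross_validate",
    "evaluate_predictions",
    "CompoundCovariatePredictor",
    "CCPResults",
]

METHODS = ("ccp", "dlda", "nearest_centroid", "knn1", "knn3")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def two_sample_t(values, labels, case_label: str, welch: bool = False) -> float:
    """Two-sample t statistic, case mean minus control mean.

    Pooled-variance by default (the classical CCP weight); Welch behind a
    flag. NaNs are dropped per call.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=object)
    keep = ~np.isnan(v)
    v, lab = v[keep], lab[keep]
    x1 = v[lab == case_label]
    x0 = v[lab != case_label]
    if len(x1) < 2 or len(x0) < 2:
        raise DomainError("need >= 2 present samples per class")
    if welch:
        se = math.sqrt(x1.var(ddof=1) / len(x1) + x0.var(ddof=1) / len(x0))
    else:
        s2 = (((x1 - x1.mean()) ** 2).sum() + ((x0 - x0.mean()) ** 2).sum()) \
            / (len(x1) + len(x0) - 2)
        if s2 <= 0:
            raise DegenerateDataError("zero pooled variance")
        se = math.sqrt(s2 * (1.0 / len(x1) + 1.0 / len(x0)))
    if se == 0:
        raise DegenerateDataError("zero pooled variance")
    return (x1.mean() - x0.mean()) / se


def _t_and_p(values, labels, case_label):
    t = two_sample_t(values, labels, case_label)
    v = np.asarray(values, dtype=float)
    n = (~np.isnan(v)).sum()
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return t, p


def select_predictor_genes(
    train: ExpressionMatrix,
    labels,
    p_max: float = 1e-4,
    min_fold: float = 1.5,
    case_label: str = GROUP_CASE,
) -> pd.Index:
    """Training-data gene screen: two-sample p <= p_max and fold >= min_fold.

    Fold is 2^(case mean - control mean), compared in either direction.
    Degenerate (zero-variance) genes are excluded. May return an empty index;
    the caller decides the fallback.
    """
    lab = np.asarray(pd.Series(labels).loc[train.sample_ids], dtype=object)
    vals = train.values.to_numpy()
    keep = []
    for i, spot in enumerate(train.spot_ids):
        try:
            t, p = _t_and_p(vals[i], lab, case_label)
        except (DegenerateDataError, DomainError):
            continue
        v = vals[i]
        m = ~np.isnan(v)
        diff = v[m & (lab == case_label)].mean() - v[m & (lab != case_label)].mean()
        fc = 2.0 ** diff
        if p <= p_max and max(fc, 1.0 / fc) >= min_fold:
            keep.append(spot)
    return pd.Index(keep)


# ---------------------------------------------------------------------------
# CCP model
# ---------------------------------------------------------------------------

@dataclass
class CCPModel:
    """Fitted compound covariate predictor: genes, weights, decision threshold.

    The rule: score = sum_i weight_i * x_i over the model's genes (x = log2
    expression); predict ``positive_label`` iff score > threshold (strictly).
    """

    genes: list
    weights: np.ndarray
    threshold: float
    positive_label: str = GROUP_CASE
    negative_label: str = "non-" + GROUP_CASE
    impute_values: np.ndarray | None = None  # per-gene training means, optional

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.impute_values is not None:
            self.impute_values = np.asarray(self.impute_values, dtype=float)
        if len(self.genes) != len(self.weights):
            raise DomainError("genes and weights length mismatch")
        if not np.isfinite(self.weights).all() or not math.isfinite(self.threshold):
            raise DomainError("weights and threshold must be finite")

    def save(self, path) -> None:
        has_imp = self.impute_values is not None
        lines = [
            "#ccp_model\tv1",
            f"positive_label\t{self.positive_label}",
            f"negative_label\t{self.negative_label}",
            f"threshold\t{float(self.threshold)!r}",
            "gene\tweight" + ("\timpute_mean" if has_imp else ""),
        ]
        for i, (g, w) in enumerate(zip(self.genes, self.weights)):
            row = f"{g}\t{float(w)!r}"
            if has_imp:
                row += f"\t{float(self.impute_values[i])!r}"
            lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "CCPModel":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or not lines[0].startswith("#ccp_model"):
            raise FormatError(f"{path}: not a CCP model file")
        meta, genes, weights, imputes = {}, [], [], []
        in_genes = False
        for ln in lines[1:]:
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if parts[0] == "gene" and parts[1] == "weight":
                in_genes = True
                continue
            if in_genes:
                genes.append(parts[0])
                weights.append(float(parts[1]))
                if len(parts) > 2:
                    imputes.append(float(parts[2]))
            else:
                meta[parts[0]] = parts[1]
        return cls(
            genes=genes,
            weights=np.array(weights),
            threshold=float(meta["threshold"]),
            positive_label=meta.get("positive_label", GROUP_CASE),
            negative_label=meta.get("negative_label", "non-" + GROUP_CASE),
            impute_values=np.array(imputes) if imputes else None,
        )


def train_ccp(
    train: ExpressionMatrix,
    labels,
    genes,
    case_label: str = GROUP_CASE,
    impute: bool = False,
) -> CCPModel:
    """Fit the CCP on training data restricted to ``genes``.

    Weights are the per-gene two-sample t statistics; the threshold is the
    midpoint of the case and control means of the compound covariate.
    ``impute=True`` fills missing values with the gene's training mean (and
    stores those means in the model for prediction-time imputation); the
    default is to refuse missing values.
    """
    genes = list(genes)
    if not genes:
        raise DomainError("empty gene set")
    lab = pd.Series(labels).loc[train.sample_ids]
    sub = train.subset_spots(genes)
    vals = sub.values.to_numpy()
    impute_values = None
    if np.isnan(vals).any():
        if not impute:
            raise DomainError("missing training values for predictor genes "
                              "(pass impute=True or drop upstream)")
        impute_values = np.nanmean(vals, axis=1)
        vals = np.where(np.isnan(vals), impute_values[:, None], vals)
    elif impute:
        impute_values = vals.mean(axis=1)
    w = np.array([two_sample_t(vals[i], lab.to_numpy(dtype=object), case_label)
                  for i in range(len(genes))])
    scores = w @ vals   # compound covariate per sample
    is_case = (lab == case_label).to_numpy()
    threshold = (scores[is_case].mean() + scores[~is_case].mean()) / 2.0
    neg = sorted(set(lab) - {case_label})
    return CCPModel(genes=genes, weights=w, threshold=float(threshold),
                    positive_label=case_label,
                    negative_label=neg[0] if neg else "non-" + case_label,
                    impute_values=impute_values)


def ccp_classify(model: CCPModel, sample) -> tuple[float, str]:
    """Score one sample (mapping or Series of per-gene log2 values).

    Returns (score, label); label is the positive class iff score strictly
    exceeds the threshold. A missing model gene is an error unless the model
    carries training-mean imputation values.
    """
    s = pd.Series(sample)
    missing = [g for g in model.genes if g not in s.index or pd.isna(s[g])]
    if missing:
        if model.impute_values is None:
            raise DomainError(f"sample lacks values for model genes {missing[:5]}")
        fill = dict(zip(model.genes, model.impute_values))
        s = s.reindex(list(s.index) + [g for g in missing if g not in s.index])
        for g in missing:
            s[g] = fill[g]
    x = s.loc[model.genes].to_numpy(dtype=float)
    score = float(model.weights @ x)
    label = model.positive_label if score > model.threshold else model.negative_label
    return score, label


# ---------------------------------------------------------------------------
# companion classifiers
# ---------------------------------------------------------------------------

def companion_classify(method: str, train: ExpressionMatrix, labels,
                       test_sample, case_label: str = GROUP_CASE) -> str:
    """Classify one sample with DLDA, nearest centroid, or k-NN (k = 1 or 3).

    All operate on the genes (rows) of ``train``. DLDA uses per-gene pooled
    variances and equal priors (zero-variance genes are dropped with a
    warning); k-NN uses Euclidean distance with vote ties broken toward the
    class of the nearest neighbour.
    """
    if method not in ("dlda", "nearest_centroid", "knn1", "knn3"):
        raise DomainError(f"unknown companion method {method!r} (of {METHODS})")
    lab = pd.Series(labels).loc[train.sample_ids]
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise DomainError("companion classifiers need exactly 2 classes")
    X = train.values.to_numpy()               # genes x samples
    x = pd.Series(test_sample).loc[train.spot_ids].to_numpy(dtype=float)
    is_case = (lab == case_label).to_numpy()
    other = [c for c in classes if c != case_label][0]

    if method == "nearest_centroid":
        mu1 = np.nanmean(X[:, is_case], axis=1)
        mu0 = np.nanmean(X[:, ~is_case], axis=1)
        d1 = np.nansum((x - mu1) ** 2)
        d0 = np.nansum((x - mu0) ** 2)
        return case_label if d1 < d0 else other

    if method == "dlda":
        mu1 = np.nanmean(X[:, is_case], axis=1)
        mu0 = np.nanmean(X[:, ~is_case], axis=1)
        n1 = (~np.isnan(X[:, is_case])).sum(axis=1)
        n0 = (~np.isnan(X[:, ~is_case])).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = (np.nanvar(X[:, is_case], axis=1, ddof=1) * (n1 - 1)
                  + np.nanvar(X[:, ~is_case], axis=1, ddof=1) * (n0 - 1)) \
                / (n1 + n0 - 2)
        ok = np.nan_to_num(s2) > 0
        if not ok.all():
            import warnings
            warnings.warn(f"dlda: dropping {int((~ok).sum())} zero-variance gene(s)")
        if not ok.any():
            raise DegenerateDataError("all genes have zero pooled variance")
        d1 = np.nansum((x[ok] - mu1[ok]) ** 2 / s2[ok])
        d0 = np.nansum((x[ok] - mu0[ok]) ** 2 / s2[ok])
        return case_label if d1 < d0 else other

    k = 1 if method == "knn1" else 3
    dist = np.sqrt(np.nansum((X - x[:, None]) ** 2, axis=0))
    order = np.argsort(dist, kind="stable")[:k]
    votes = lab.iloc[order]
    counts = votes.value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        return votes.iloc[0]            # tie -> nearest neighbour's class
    return counts.index[0]


# ---------------------------------------------------------------------------
# cross-validation and evaluation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Cross-validation protocol parameters."""

    k: int = 10
    repeats: int = 1
    method: str = "ccp"
    p_max: float = 1e-4
    min_fold: float = 1.5
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if not 2 <= self.k <= n_samples:
            raise DomainError(f"k must be in [2, {n_samples}], got {self.k}")
        if self.repeats < 1:
            raise DomainError("repeats must be >= 1")
        if self.method not in METHODS:
            raise DomainError(f"method must be one of {METHODS}, got {self.method!r}")


@dataclass
class Performance:
    """Confusion counts with derived sensitivity / specificity / accuracy."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def sensitivity(self) -> float:
        denom = self.TP + self.FN
        if denom == 0:
            import warnings
            warnings.warn("no positive-class samples: sensitivity undefined")
            return math.nan
        return self.TP / denom

    @property
    def specificity(self) -> float:
        denom = self.TN + self.FP
        if denom == 0:
            import warnings
            warnings.warn("no negative-class samples: specificity undefined")
            return math.nan
        return self.TN / denom

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total

    def summary(self) -> str:
        return (
            f"TP={self.TP} FP={self.FP} TN={self.TN} FN={self.FN}  "
            f"sensitivity={self.sensitivity:.3f} "
            f"specificity={self.specificity:.3f} "
            f"accuracy={self.accuracy:.3f}"
        )


def evaluate_predictions(predicted, truth, positive_label: str = GROUP_CASE) -> Performance:
    """Confusion counts of predicted vs true labels."""
    pred = np.asarray(predicted, dtype=object)
    true = np.asarray(truth, dtype=object)
    if len(pred) != len(true):
        raise DomainError("predicted and true label vectors differ in length")
    pos_t = true == positive_label
    pos_p = pred == positive_label
    return Performance(
        TP=int((pos_t & pos_p).sum()),
        FP=int((~pos_t & pos_p).sum()),
        TN=int((~pos_t & ~pos_p).sum()),
        FN=int((pos_t & ~pos_p).sum()),
    )


def _classify_fold(method, train_m, train_lab, test_m, genes, case_label):
    """Predict every test sample with the requested rule."""
    preds = {}
    sub_train = train_m.subset_spots(genes)
    sub_test = test_m.subset_spots(genes)
    if method == "ccp":
        model = train_ccp(sub_train, train_lab, list(genes), case_label=case_label,
                          impute=True)
        for s in sub_test.sample_ids:
            _, preds[s] = ccp_classify(model, sub_test.values[s])
    else:
        for s in sub_test.sample_ids:
            preds[s] = companion_classify(
                method, sub_train, train_lab, sub_test.values[s], case_label)
    return preds


def kfold_cross_validate(
    matrix: ExpressionMatrix,
    labels,
    cv: CVConfig,
    case_label: str = GROUP_CASE,
) -> tuple[pd.DataFrame, Performance]:
    """Stratified k-fold CV with gene selection redone inside every fold.

    Returns (per-sample predictions as a DataFrame with one column per
    repeat, Performance aggregated over all held-out predictions). When a
    fold's selection comes back empty the fold falls back to the single
    smallest-p training gene so every sample still receives a prediction.
    """
    lab = pd.Series(labels).loc[matrix.sample_ids]
    cv.validate(len(lab))
    y = lab.to_numpy(dtype=object)
    neg = sorted(set(y) - {case_label})
    if case_label not in set(y) or not neg:
        raise DomainError("labels must contain the positive class and one other")

    pred_cols = {}
    all_pred, all_true = [], []
    for rep in range(cv.repeats):
        if cv.k == len(y):
            # leave-one-out: stratification is moot, folds are the samples
            folds = [(np.delete(np.arange(len(y)), i), np.array([i]))
                     for i in range(len(y))]
        else:
            skf = StratifiedKFold(n_splits=cv.k, shuffle=True,
                                  random_state=(cv.seed + rep) % (2 ** 31))
            folds = list(skf.split(np.zeros(len(y)), y.astype(str)))
        preds = pd.Series(index=lab.index, dtype=object)
        for tr_idx, te_idx in folds:
            tr_samples = lab.index[tr_idx]
            te_samples = lab.index[te_idx]
            tr_lab = lab.loc[tr_samples]
            if tr_lab.nunique() < 2:
                raise DomainError("a training fold lacks one of the classes")
            train_m = matrix.subset_samples(tr_samples)
            test_m = matrix.subset_samples(te_samples)
            genes = select_predictor_genes(
                train_m, tr_lab, p_max=cv.p_max, min_fold=cv.min_fold,
                case_label=case_label)
            if len(genes) == 0:
                genes = _best_gene_fallback(train_m, tr_lab, case_label)
            fold_preds = _classify_fold(
                cv.method, train_m, tr_lab, test_m, genes, case_label)
            for s, p in fold_preds.items():
                preds[s] = p
        pred_cols[f"repeat{rep + 1}"] = preds
        all_pred.extend(preds.to_numpy())
        all_true.extend(y)
    perf = evaluate_predictions(all_pred, all_true, positive_label=case_label)
    return pd.DataFrame(pred_cols), perf


def _best_gene_fallback(train_m, tr_lab, case_label) -> pd.Index:
    """Single smallest-p training gene (used when the screen selects none)."""
    lab = tr_lab.to_numpy(dtype=object)
    vals = train_m.values.to_numpy()
    best, best_p = None, np.inf
    for i, spot in enumerate(train_m.spot_ids):
        try:
            _, p = _t_and_p(vals[i], lab, case_label)
        except (DegenerateDataError, DomainError):
            continue
        if p < best_p:
            best, best_p = spot, p
    if best is None:
        raise DegenerateDataError("no usable gene for fallback selection")
    return pd.Index([best])


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class CompoundCovariatePredictor:
    """CCP with in-model gene screening, statsmodels-style.

    ``fit()`` screens genes on the full training data (p <= p_max, fold >=
    min_fold) unless an explicit gene list is given, then fits weights and
    threshold; ``cross_validate()`` runs the nested protocol.
    """

    def __init__(self, matrix: ExpressionMatrix, labels,
                 genes=None, p_max: float = 1e-4, min_fold: float = 1.5,
                 case_label: str = GROUP_CASE, impute: bool = False):
        self.matrix = matrix
        self.labels = pd.Series(labels).loc[matrix.sample_ids]
        self.genes = None if genes is None else list(genes)
        self.p_max = p_max
        self.min_fold = min_fold
        self.case_label = case_label
        self.impute = impute

    def fit(self) -> "CCPResults":
        genes = self.genes
        if genes is None:
            genes = list(select_predictor_genes(
                self.matrix, self.labels, p_max=self.p_max,
                min_fold=self.min_fold, case_label=self.case_label))
        if not genes:
            raise DomainError(
                f"no genes pass the screen (p <= {self.p_max}, "
                f"fold >= {self.min_fold})")
        model = train_ccp(self.matrix.subset_spots(genes), self.labels, genes,
                          case_label=self.case_label, impute=self.impute)
        return CCPResults(self, model)

    def cross_validate(self, cv: CVConfig | None = None):
        cv = cv or CVConfig(p_max=self.p_max, min_fold=self.min_fold)
        return kfold_cross_validate(self.matrix, self.labels, cv,
                                    case_label=self.case_label)


class CCPResults:
    """Fitted CCP: holds the model, predicts, and summarizes."""

    def __init__(self, parent: CompoundCovariatePredictor, model: CCPModel):
        self.parent = parent
        self.model = model

    def predict(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Score every sample column; returns DataFrame(score, label)."""
        sub = matrix.subset_spots(self.model.genes)
        out = []
        for s in sub.sample_ids:
            score, label = ccp_classify(self.model, sub.values[s])
            out.append((s, score, label))
        return pd.DataFrame(out, columns=["sample_id", "score", "label"]
                            ).set_index("sample_id")

    def evaluate(self, matrix: ExpressionMatrix, truth) -> Performance:
        pred = self.predict(matrix)["label"]
        t = pd.Series(truth).loc[pred.index]
        # the model's negative label need not equal the data's control label
        t = t.where(t == self.model.positive_label, self.model.negative_label)
        return evaluate_predictions(pred, t, positive_label=self.model.positive_label)

    def summary(self) -> str:
        lines = [
            "Compound covariate predictor",
            f"  positive label: {self.model.positive_label}",
            f"  threshold:      {self.model.threshold:.4f}",
            f"  genes ({len(self.model.genes)}):",
        ]
        for g, w in zip(self.model.genes, self.model.weights):
            lines.append(f"    {g}\t{w:+.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.model.save(path)
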