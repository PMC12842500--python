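"""Evaluation layer: inter-reader agreement, AUC against the volumetric
reference, logistic models and feature-combination search.

Cohen's kappa (unweighted and linearly weighted) quantifies chance-corrected
agreement between two categorical raters from a K x K contingency matrix;
confidence intervals come from a percentile bootstrap over the N paired
ratings.  Readers are scored against the volumetric reference one class at a
time (one-vs-rest); a purely categorical call is turned into a 0/1 score for
the target class.  Precision-recall AUC uses the step-wise average-precision
rule (no interpolation), which is the conservative convention for imbalanced
classes.  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY_ORDER = ("decreased", "increased", "stable")  # as printed


# ---------------------------------------------------------------------------
# agreement

@dataclass
class AgreementMatrix:
    """K x K contingency counts of two categorical raters."""

    counts: np.ndarray
    category_order: tuple[str, ...] = DEFAULT_CATEGORY_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.category_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} to match the categories")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("agreement matrix is empty")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, rater_a, rater_b,
                    category_order=DEFAULT_CATEGORY_ORDER) -> "AgreementMatrix":
        """Build the contingency table from two parallel label lists."""
        if len(rater_a) != len(rater_b):
            raise ValueError("raters must score the same measurements")
        idx = {c: i for i, c in enumerate(category_order)}
        unknown = (set(rater_a) | set(rater_b)) - set(category_order)
        if unknown:
            raise ValueError(f"labels outside the category order: {sorted(unknown)}")
        k = len(category_order)
        counts = np.zeros((k, k), dtype=np.int64)
        for a, b in zip(rater_a, rater_b):
            counts[idx[a], idx[b]] += 1
        return cls(counts, tuple(category_order))

    def reordered(self, category_order) -> "AgreementMatrix":
        perm = [self.category_order.index(c) for c in category_order]
        return AgreementMatrix(self.counts[np.ix_(perm, perm)], tuple(category_order))


@dataclass
class KappaResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    scheme: str


def _kappa_point(counts: np.ndarray, scheme: str) -> float:
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / n
    i, j = np.indices((k, k))
    if scheme == "unweighted":
        disagree = (i != j).astype(float)
    elif scheme == "linear":
        disagree = np.abs(i - j) / (k - 1)
    elif scheme == "quadratic":
        disagree = (np.abs(i - j) / (k - 1)) ** 2
    else:
        raise ValueError(f"unknown kappa scheme {scheme!r}")
    expected_dis = (disagree * expected).sum()
    if expected_dis == 0:
        raise ValueError("expected agreement is 1 (both raters constant); "
                         "kappa is undefined")
    return 1.0 - (disagree * counts).sum() / expected_dis


def cohen_kappa(m: AgreementMatrix, scheme: str = "unweighted",
                n_boot: int = 10_000, seed: int = 0,
                ci_level: float = 0.95) -> KappaResult:
    """Cohen's kappa with a percentile-bootstrap confidence interval.

    ``scheme`` is 'unweighted', 'linear' or 'quadratic'; disagreement
    weights for the weighted schemes are ``|i-j|/(K-1)`` (resp. squared)
    in the matrix's category order.
    """
    est = _kappa_point(m.counts, scheme)
    k = len(m.category_order)
    flat = np.repeat(np.arange(k * k), m.counts.ravel())
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        resampled = rng.choice(flat, size=flat.size, replace=True)
        counts = np.bincount(resampled, minlength=k * k).reshape(k, k)
        try:
            boots.append(_kappa_point(counts, scheme))
        except ValueError:
            continue  # degenerate resample
    if boots:
        alpha = (1 - ci_level) / 2
        lo, hi = np.quantile(boots, [alpha, 1 - alpha])
        lo, hi = min(lo, est), max(hi, est)
    else:
        lo = hi = est
    return KappaResult(estimate=float(est), ci_lower=float(lo),
                       ci_upper=float(hi), scheme=scheme)


# ---------------------------------------------------------------------------
# AUC against the reference

@dataclass
class BinaryEvalResult:
    auc_roc: float
    auc_prc: float
    positive_class: str
    n_pos: int
    n_neg: int


def reader_vs_reference_auc(reader_labels, reference_labels,
                            target_class: str) -> BinaryEvalResult:
    """One-vs-rest AUC of a categorical reader against the reference.

    The reference is binarized on `target_class`; the reader's call is the
    0/1 score "did the reader say the target class".  Ties are handled by
    the rank (Mann-Whitney) convention for ROC and grouped for PRC.
    """
    reader_labels = list(reader_labels)
    reference_labels = list(reference_labels)
    if len(reader_labels) != len(reference_labels):
        raise ValueError("reader and reference must have equal length")
    if len(reference_labels) < 2:
        raise ValueError("need at least two cases")
    y = np.array([ref == target_class for ref in reference_labels], dtype=int)
    if y.min() == y.max():
        raise ValueError(f"reference contains a single class for {target_class!r}")
    score = np.array([lab == target_class for lab in reader_labels], dtype=float)
    return BinaryEvalResult(
        auc_roc=float(roc_auc_score(y, score)),
        auc_prc=prc_auc(score, y),
        positive_class=target_class,
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
    )


def prc_auc(scores, labels) -> float:
    """Area under the precision-recall curve by the step-wise
    average-precision rule, with tied scores grouped.

    Constant scores give a single PR point at recall 1, so the area equals
    the prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("no positive cases; PRC AUC is undefined")
    return float(average_precision_score(labels, scores))


# ---------------------------------------------------------------------------
# logistic models

@dataclass
class LogisticFit:
    coefficients: pd.Series     # intercept + one per feature
    probabilities: np.ndarray   # in-sample fitted P(y = 1)
    converged: bool
    ridged: bool                # True if the separation fallback was used


def _irls_ridge(X: np.ndarray, y: np.ndarray, lam: float,
                max_iter: int = 200, tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Ridge-penalized IRLS for binomial regression (intercept unpenalized)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        beta_new = np.linalg.solve(X.T @ (w[:, None] * X) + pen,
                                   X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new, True
        beta = beta_new
    return beta, False


def logistic_score(features: pd.DataFrame, labels,
                   ridge_lambda: float = 1e-6,
                   max_iter: int = 200) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Fits ``P(y=1) = expit(b0 + X b)`` by iteratively reweighted least
    squares; on detected (quasi-)separation — diverging coefficients or
    non-convergence — refits with a tiny L2 ridge (intercept unpenalized).
    """
    features = pd.DataFrame(features)
    y = np.asarray(labels, dtype=float)
    n, p = features.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than features ({p})")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("labels are constant; nothing to fit")
    X = np.column_stack([np.ones(n), features.to_numpy(dtype=float)])
    if np.any(features.std(ddof=0).to_numpy() == 0):
        raise ValueError("constant feature column in the design")

    beta, converged = _irls_ridge(X, y, lam=0.0, max_iter=max_iter)
    ridged = False
    # separation shows up as non-convergence or exploding linear predictor
    if not converged or np.max(np.abs(X @ beta)) > 30:
        beta, converged = _irls_ridge(X, y, lam=ridge_lambda, max_iter=max_iter)
        ridged = True
        if not converged:
            raise RuntimeError("logistic fit failed to converge even with the "
                               "ridge fallback (suspected complete separation)")
    probs = 1.0 / (1.0 + np.exp(-(X @ beta)))
    names = ["intercept"] + [str(c) for c in features.columns]
    return LogisticFit(coefficients=pd.Series(beta, index=names),
                       probabilities=probs, converged=converged, ridged=ridged)


def best_feature_combination(features: pd.DataFrame, labels,
                             max_size: int = 3,
                             metric: str = "roc") -> list[tuple[tuple[str, ...], float]]:
    """Exhaustive search over feature subsets of size <= max_size.

    Each subset is scored by the in-sample AUC ('roc' or 'prc') of a
    logistic model; the ranking is by descending AUC with lexicographic
    feature-name tie-break.  Subsets whose fit fails are skipped with a
    warning.
    """
    features = pd.DataFrame(features)
    if features.shape[1] < 2:
        raise ValueError("need at least two candidate features")
    y = np.asarray(labels, dtype=int)
    names = sorted(str(c) for c in features.columns)
    results = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(names, size):
            try:
                fit = logistic_score(features[list(combo)], y)
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                logger.warning("skipping subset %s: %s", combo, exc)
                continue
            if metric == "roc":
                auc = float(roc_auc_score(y, fit.probabilities))
            elif metric == "prc":
                auc = prc_auc(fit.probabilities, y)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            results.append((combo, auc))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results


# ---------------------------------------------------------------------------
# commodity group comparisons

def group_compare(values_a, values_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided t-test (Student by default, Welch with equal_var=False)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def chisq_compare(counts_table) -> tuple[float, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    table = np.asarray(counts_table, dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
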