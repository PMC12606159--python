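"""Discriminant classification of call types.

The workflow mirrors the standard bioacoustic recipe: drop the SNR
column, prune correlated parameters (pairwise Pearson |r| > 0.7,
with a protected always-keep set), fit a linear discriminant analysis
on the retained parameters, and score classification with leave-one-out
cross-validation.  Reported statistics: confusion matrix (counts and
row-normalized percent), overall accuracy with an exact binomial
confidence interval, Cohen's kappa, per-class chance levels equal to
class proportions (priors are frequency-weighted), variance explained
per discriminant, and normalized absolute standardized-coefficient
"contributions" per discriminant.

The LDA eigenproblem, classification rule and LOOCV loop are
implemented here; scipy provides the generalized eigensolver and
statsmodels the binomial interval and Welch ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .util import round_half_up

__all__ = [
    "DFAModel",
    "DFAReport",
    "StabilityReport",
    "prune_correlated",
    "fit_lda",
    "predict_lda",
    "loocv_classify",
    "cohens_kappa",
    "accuracy_ci",
    "chance_levels",
    "variance_explained",
    "ld_contributions",
    "welch_anova",
    "parameter_stability",
]

#: Pearson correlation magnitude above which one of a parameter pair is pruned.
CORRELATION_THRESHOLD = 0.7
#: Parameters retained in the published analysis regardless of correlation.
ALWAYS_KEEP_DEFAULT = ("AE",)
#: Ridge scale applied to a singular pooled covariance: eps * trace / p.
RIDGE_EPS = 1e-8


def prune_correlated(
    X: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    always_keep: tuple[str, ...] = (),
) -> list[str]:
    """Iteratively drop one parameter from each |r| > threshold pair.

    From each offending pair, the parameter with the larger mean absolute
    correlation to all other retained parameters is removed, unless it is
    in ``always_keep``.  Raises on constant columns (correlation
    undefined).
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two parameters to prune")
    for col in X.columns:
        if np.isclose(X[col].std(ddof=1), 0.0):
            raise ValueError(f"constant column {col!r}: correlation undefined")
    keep = set(always_keep)
    retained = list(X.columns)
    while True:
        corr = X[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            (corr.loc[a, b], a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1:]
            if corr.loc[a, b] > threshold
        ]
        removable = []
        for r, a, b in sorted(pairs, reverse=True):
            mean_a, mean_b = corr.loc[a].mean(), corr.loc[b].mean()
            victim, other = (a, b) if mean_a >= mean_b else (b, a)
            if victim in keep:
                victim, other = other, victim
            if victim in keep:
                continue  # both protected
            removable.append(victim)
        if not removable:
            break
        retained.remove(removable[0])
    return retained


@dataclass
class DFAModel:
    """Fitted linear discriminant model.

    ``coefs`` has one column per discriminant, scaled to unit pooled
    within-class variance (a' Sw a = 1); ``eigenvalues`` are the
    between/within variance ratios along each axis, sorted descending.
    """

    feature_names: list[str]
    classes: list[str]
    class_means: pd.DataFrame  # classes x features
    pooled_cov: np.ndarray  # within-class, p x p
    coefs: np.ndarray  # p x n_discriminants
    eigenvalues: np.ndarray
    priors: pd.Series  # class proportions

    @property
    def n_discriminants(self) -> int:
        return self.coefs.shape[1]


def _pooled_cov(Xv: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    n, p = Xv.shape
    sw = np.zeros((p, p))
    for c in classes:
        xc = Xv[y == c]
        if xc.shape[0] >= 2:
            sw += (xc.shape[0] - 1) * np.cov(xc, rowvar=False)
    return sw / (n - len(classes))


def _regularize(sw: np.ndarray, ridge: float | None) -> np.ndarray:
    p = sw.shape[0]
    try:
        linalg.cholesky(sw)
        return sw
    except linalg.LinAlgError:
        if ridge is None:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular; enable ridge fallback"
            )
        warnings.warn("singular pooled covariance: applying ridge fallback",
                      stacklevel=3)
        return sw + ridge * np.trace(sw) / p * np.eye(p)


def fit_lda(
    X: pd.DataFrame, y: pd.Series, ridge: float | None = RIDGE_EPS
) -> DFAModel:
    """Fit the linear discriminant eigenproblem.

    Solves the generalized symmetric problem Sb a = λ Sw a (equivalently
    the eigendecomposition of Sw⁻¹ Sb), keeping the top
    min(K − 1, p) axes and scaling each so that a' Sw a = 1.  Priors are
    the class proportions.  A singular pooled covariance gets a ridge of
    ``ridge * trace/p`` with a warning (``ridge=None`` raises instead).
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    classes, counts = np.unique(yv, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two rows")
    if np.isnan(Xv).any():
        raise ValueError("feature matrix contains missing values")
    n, p = Xv.shape

    grand = Xv.mean(axis=0)
    means = np.vstack([Xv[yv == c].mean(axis=0) for c in classes])
    sb = np.zeros((p, p))
    for c_idx, c in enumerate(classes):
        d = (means[c_idx] - grand)[:, None]
        sb += counts[c_idx] * (d @ d.T)
    sb /= n
    sw = _regularize(_pooled_cov(Xv, yv, classes), ridge)

    evals, evecs = linalg.eigh(sb, sw)  # ascending; evecs already a'Sw a = 1
    order = np.argsort(evals)[::-1]
    r = min(len(classes) - 1, p)
    evals = np.clip(evals[order][:r], 0.0, None)
    coefs = evecs[:, order][:, :r]

    return DFAModel(
        feature_names=list(X.columns),
        classes=list(classes),
        class_means=pd.DataFrame(means, index=classes, columns=X.columns),
        pooled_cov=sw,
        coefs=coefs,
        eigenvalues=evals,
        priors=pd.Series(counts / n, index=classes),
    )


def predict_lda(model: DFAModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Classify rows with the Gaussian linear discriminant rule.

    Scores δ_c(x) = x'Σ⁻¹μ_c − ½ μ_c'Σ⁻¹μ_c + ln π_c with the pooled
    covariance; the highest-scoring class wins.
    """
    Xv = np.asarray(X, dtype=float)
    mu = model.class_means.to_numpy()
    siginv_mu = linalg.solve(model.pooled_cov, mu.T, assume_a="pos")  # p x K
    lin = Xv @ siginv_mu
    const = -0.5 * np.sum(mu.T * siginv_mu, axis=0) + np.log(
        model.priors.to_numpy()
    )
    return np.asarray(model.classes)[np.argmax(lin + const, axis=1)]


@dataclass
class DFAReport:
    """Leave-one-out classification report."""

    classes: list[str]
    confusion_counts: pd.DataFrame  # rows true, columns predicted
    confusion_percent: pd.DataFrame  # row-normalized, integer-rounded
    accuracy: float  # percent
    ci95: tuple[float, float]  # percent
    kappa: float
    chance: dict[str, int]  # percent per class
    per_class_correct: dict[str, float]  # percent per class
    variance_explained: list[float] = field(default_factory=list)
    contributions: pd.DataFrame | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "n": self.n,
            "confusion_counts": self.confusion_counts.to_dict(),
            "confusion_percent": self.confusion_percent.to_dict(),
            "accuracy_pct": self.accuracy,
            "ci95_pct": list(self.ci95),
            "kappa": self.kappa,
            "chance_pct": self.chance,
            "per_class_correct_pct": self.per_class_correct,
            "variance_explained_pct": self.variance_explained,
            "contributions_pct": (
                None if self.contributions is None else self.contributions.to_dict()
            ),
        }


def loocv_classify(
    X: pd.DataFrame, y: pd.Series, ridge: float | None = RIDGE_EPS
) -> DFAReport:
    """Leave-one-out cross-validated discriminant classification.

    Each row is classified by a model fitted on all the other rows
    (Gaussian rule, frequency priors).  The assembled report carries the
    confusion matrix, accuracy with its exact 95% binomial interval,
    Cohen's kappa, per-class chance levels and correct-classification
    rates, plus the variance-explained shares and parameter
    contributions of the non-cross-validated fit on the full data.
    """
    yv = np.asarray(y)
    n = len(yv)
    classes = sorted(np.unique(yv))
    predicted = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_lda(X.iloc[mask], pd.Series(yv[mask]), ridge=ridge)
        predicted[i] = predict_lda(model, X.iloc[[i]])[0]
        mask[i] = True

    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(yv, predicted):
        counts.loc[t, p] += 1
    row_sums = counts.sum(axis=1)
    percent = counts.div(row_sums, axis=0).mul(100.0)
    percent = percent.map(lambda v: round_half_up(v, 0))

    correct = int(np.trace(counts.to_numpy()))
    acc = 100.0 * correct / n
    full_model = fit_lda(X, y, ridge=ridge)
    return DFAReport(
        classes=classes,
        confusion_counts=counts,
        confusion_percent=percent,
        accuracy=acc,
        ci95=accuracy_ci(correct, n),
        kappa=cohens_kappa(counts.to_numpy()),
        chance=chance_levels(dict(zip(*np.unique(yv, return_counts=True)))),
        per_class_correct={
            c: 100.0 * counts.loc[c, c] / row_sums[c] for c in classes
        },
        variance_explained=variance_explained(full_model),
        contributions=ld_contributions(full_model),
        n=n,
    )


def cohens_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa from a square confusion-count matrix:
    (p_o − p_e) / (1 − p_e), with p_e from the row/column marginals."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain counts")
    po = np.trace(c) / total
    pe = float((c.sum(axis=1) / total) @ (c.sum(axis=0) / total))
    if np.isclose(pe, 1.0):
        raise ValueError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def accuracy_ci(
    correct: int, total: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval for accuracy, in percent."""
    if not 0 <= correct <= total or total <= 0:
        raise ValueError("need 0 <= correct <= total, total > 0")
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(correct, total, alpha=1 - level, method="beta")
    return 100.0 * float(lo), 100.0 * float(hi)


def chance_levels(class_sizes: dict[str, int]) -> dict[str, int]:
    """Chance correct-classification rates: class share of the sample,
    as integer percent (half-up)."""
    total = sum(class_sizes.values())
    if total <= 0 or any(v <= 0 for v in class_sizes.values()):
        raise ValueError("class sizes must be positive")
    return {
        c: int(round_half_up(100.0 * nc / total, 0))
        for c, nc in class_sizes.items()
    }


def variance_explained(model: DFAModel) -> list[float]:
    """Percent of between-class variance captured by each discriminant."""
    ev = model.eigenvalues
    total = ev.sum()
    if total <= 0:
        return [0.0 for _ in ev]
    return list(100.0 * ev / total)


def ld_contributions(model: DFAModel) -> pd.DataFrame:
    """Parameter contributions per discriminant, in percent.

    Coefficients are standardized by the pooled within-class standard
    deviations; each axis's contributions are the normalized absolute
    standardized coefficients.
    """
    sds = np.sqrt(np.diag(model.pooled_cov))
    std_coefs = np.abs(model.coefs * sds[:, None])
    shares = 100.0 * std_coefs / std_coefs.sum(axis=0, keepdims=True)
    return pd.DataFrame(
        shares,
        index=model.feature_names,
        columns=[f"LD{i + 1}" for i in range(model.n_discriminants)],
    )


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, p).

    Used to test whether discriminant scores differ across call types
    without assuming equal variances.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if all(np.isclose(np.var(g, ddof=1), 0.0) for g in groups):
        raise ValueError("all groups have zero variance; Welch F undefined")
    from statsmodels.stats.oneway import anova_oneway

    res = anova_oneway(groups, use_var="unequal", welch_correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StabilityReport:
    """Coefficient-of-variation stability of parameters across sites."""

    cv_table: pd.DataFrame  # columns: parameter, call_type, site, cv
    medians: pd.Series  # median CV per parameter


def parameter_stability(
    features: pd.DataFrame,
    parameters: list[str],
    type_col: str = "label",
    site_col: str = "site",
) -> StabilityReport:
    """Per-parameter CV = sd/mean by (call type, site); medians over cells.

    Cells with fewer than two measurements are skipped; cells with a
    non-positive mean are excluded with a warning (CV undefined).
    """
    rows = []
    n_undefined = 0
    for (ctype, site), grp in features.groupby([type_col, site_col]):
        for param in parameters:
            vals = grp[param].dropna().to_numpy(dtype=float)
            if vals.size < 2:
                continue
            m = vals.mean()
            if m <= 0:
                n_undefined += 1
                continue
            rows.append(
                {"parameter": param, "call_type": ctype, "site": site,
                 "cv": vals.std(ddof=1) / m}
            )
    if n_undefined:
        warnings.warn(
            f"{n_undefined} (type, site, parameter) cells had non-positive "
            "means; CV undefined and excluded",
            stacklevel=2,
        )
    cv_table = pd.DataFrame(rows, columns=["parameter", "call_type", "site", "cv"])
    medians = (
        cv_table.groupby("parameter")["cv"].median()
        if len(cv_table)
        else pd.Series(dtype=float)
    )
    return StabilityReport(cv_table=cv_table, medians=medians)
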