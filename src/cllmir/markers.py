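"""Two-class marker ranking, activation-signature derivation, and
clinical association testing.

The ranking metric is the signal-to-noise style score

    score = (mu1 - mu2) / sqrt(s1^2 + s2^2)

with class means mu and sample (n-1 denominator) standard deviations s.
A high score marks association with class 1. Significance per feature
comes from a Welch two-sample t-test with Benjamini-Hochberg control of
the false discovery rate across features.

The activation signature is derived by comparing resting to acutely
activated B cells: features with BH-adjusted Welch p below alpha are
assigned to the up set (higher mean in activated cells) or the down set
(lower mean).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .signature import MiRNASignature

__all__ = [
    "snr_score",
    "bh_adjust",
    "marker_selection",
    "derive_activation_signature",
    "clinical_association",
    "SNRMarkerRanker",
    "ActivationSignatureLearner",
]


def snr_score(class1, class2) -> float:
    """Signed marker score ``(mu1 - mu2) / sqrt(s1^2 + s2^2)``.

    Positive when the feature is higher in class 1. Standard deviations
    use the n-1 denominator. If both variances are zero the score is 0
    when the means agree and signed infinity (flagged by a warning)
    otherwise.
    """
    x1 = np.asarray(class1, dtype=float)
    x2 = np.asarray(class2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each class needs at least 2 values")
    mu1, mu2 = x1.mean(), x2.mean()
    denom = np.sqrt(x1.var(ddof=1) + x2.var(ddof=1))
    if denom == 0.0:
        if mu1 == mu2:
            return 0.0
        warnings.warn("zero within-class variance with unequal means")
        return float(np.sign(mu1 - mu2) * np.inf)
    return float((mu1 - mu2) / denom)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _snr_scores(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized :func:`snr_score` over the rows of two class matrices
    (features x samples each). Zero-variance ties score 0; unequal
    zero-variance means score signed infinity."""
    mu = a.mean(axis=1) - b.mean(axis=1)
    denom = np.sqrt(a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = mu / denom
    degenerate = denom == 0
    if degenerate.any():
        s[degenerate] = np.where(
            mu[degenerate] == 0, 0.0, np.sign(mu[degenerate]) * np.inf
        )
    return s


def _split_classes(labels: pd.Series, class1: str | None):
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if class1 is None:
        class1 = classes[0]
    if class1 not in classes:
        raise ValueError(f"class1={class1!r} not among labels {classes}")
    class2 = next(c for c in classes if c != class1)
    ids1 = labels.index[labels == class1]
    ids2 = labels.index[labels == class2]
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValueError("each class needs at least 2 samples")
    return class1, class2, ids1, ids2


class SNRMarkerRanker(BaseEstimator):
    """Rank features between two phenotypes by the signal-to-noise score.

    ``fit(X, y)`` with samples-x-features ``X`` and two-class labels
    ``y`` produces ``results_``: one row per feature with the score,
    Welch t statistic, p, BH q, and direction, sorted by descending
    score (ties broken by feature id).

    Parameters
    ----------
    class1 : str or None
        The label treated as class 1 (high score = up in class 1).
        ``None`` picks the alphabetically first label.
    """

    def __init__(self, class1: str | None = None):
        self.class1 = class1

    def fit(self, X, y):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        c1, c2, ids1, ids2 = _split_classes(y, self.class1)
        a = X.loc[ids1].to_numpy(dtype=float)
        b = X.loc[ids2].to_numpy(dtype=float)
        scores = _snr_scores(a.T, b.T)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties: no evidence
        t = np.where(np.isnan(t), 0.0, t)
        res = pd.DataFrame(
            {
                "feature": X.columns,
                "score": scores,
                "t": t,
                "p": p,
                "q": bh_adjust(p),
                "direction": np.where(
                    scores >= 0, f"up_in_{c1}", f"up_in_{c2}"
                ),
            }
        )
        res = res.sort_values(
            ["score", "feature"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        self.classes_ = (c1, c2)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.results_ = res
        return self

    @property
    def ranking_(self) -> list:
        check_is_fitted(self, "results_")
        return self.results_["feature"].tolist()


def marker_selection(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    class1: str | None = None,
) -> pd.DataFrame:
    """Rank the features of a features-x-samples matrix between two
    phenotypes; returns the sorted marker table (see SNRMarkerRanker)."""
    labels = pd.Series(labels)
    common = [s for s in matrix.columns if s in labels.index and pd.notna(labels[s])]
    ranker = SNRMarkerRanker(class1=class1).fit(
        matrix[common].T, labels.loc[common]
    )
    return ranker.results_


class ActivationSignatureLearner(BaseEstimator):
    """Derive an up/down miRNA signature from resting vs activated B cells.

    ``fit(X, y)``: samples-x-features ``X``; ``y`` labels containing
    ``control_label`` and ``activated_label``. Features with BH-adjusted
    Welch-t p below ``alpha`` enter ``signature_.up`` (activated mean >
    control mean) or ``signature_.down``. ``alpha >= 1`` disables the
    threshold and assigns every feature by mean-difference sign.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        control_label: str = "control_B",
        activated_label: str = "activated_B",
        name: str = "B_CELL_ACTIVATION",
    ):
        self.alpha = alpha
        self.control_label = control_label
        self.activated_label = activated_label
        self.name = name

    def fit(self, X, y):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        ids_act = y.index[y == self.activated_label]
        ids_ctl = y.index[y == self.control_label]
        if len(ids_act) < 2 or len(ids_ctl) < 2:
            raise ValueError("need >=2 samples in both control and activated groups")
        a = X.loc[ids_act].to_numpy(dtype=float)
        c = X.loc[ids_ctl].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(a, c, axis=0, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        q = bh_adjust(p)
        diff = a.mean(axis=0) - c.mean(axis=0)
        passed = np.ones_like(q, bool) if self.alpha >= 1.0 else q < self.alpha
        up = frozenset(X.columns[passed & (diff > 0)])
        down = frozenset(X.columns[passed & (diff < 0)])
        if not up and not down:
            warnings.warn("no feature passed the signature threshold; empty signature")
        self.tests_ = pd.DataFrame(
            {"feature": X.columns, "t": t, "p": p, "q": q, "mean_diff": diff}
        )
        self.signature_ = MiRNASignature(name=self.name, up=up, down=down)
        return self


def derive_activation_signature(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    control_label: str = "control_B",
    activated_label: str = "activated_B",
    name: str = "B_CELL_ACTIVATION",
) -> MiRNASignature:
    """Derive the activation signature from a features-x-samples matrix."""
    labels = pd.Series(labels)
    keep = [
        s
        for s in matrix.columns
        if labels.get(s) in (control_label, activated_label)
    ]
    learner = ActivationSignatureLearner(
        alpha=alpha,
        control_label=control_label,
        activated_label=activated_label,
        name=name,
    ).fit(matrix[keep].T, labels.loc[keep])
    return learner.signature_


def _wilcoxon_rank_sum(x, y, exact_limit: int):
    method = (
        "exact"
        if (len(x) <= exact_limit and len(y) <= exact_limit)
        else "asymptotic"
    )
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; midrank normal approximation instead
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
    return float(res.statistic), float(res.pvalue)


def clinical_association(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    covariate: str,
    features: Sequence[str] | None = None,
    test: str = "wilcoxon",
    exact_limit: int = 25,
    cutpoints: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Test each feature's expression against a clinical covariate.

    Binary covariates: Wilcoxon rank-sum on expression (``test=
    'wilcoxon'``, exact for small groups, midrank normal approximation
    otherwise) or Fisher's exact test on expression dichotomized at the
    per-feature median or a supplied cut-point (``test='fisher'``).
    Covariates with >=3 categories: Kruskal-Wallis. BH q across the
    features tested. Samples with missing covariate (``'NA'``/NaN) are
    dropped; requires >=4 informative samples and a non-constant
    covariate.
    """
    if covariate not in table.columns:
        raise KeyError(f"covariate {covariate!r} not in sample table")
    cov = table[covariate].replace("NA", np.nan).dropna()
    cov = cov[cov.index.isin(matrix.columns)]
    if len(cov) < 4:
        raise ValueError("fewer than 4 samples with a non-missing covariate")
    levels = sorted(cov.unique())
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    if features is None:
        features = list(matrix.index)

    rows = []
    for f in features:
        expr = matrix.loc[f, cov.index].astype(float)
        if len(levels) >= 3:
            groups = [expr[cov == lv].to_numpy() for lv in levels]
            res = stats.kruskal(*groups)
            stat, p, used = float(res.statistic), float(res.pvalue), "kruskal"
        elif test == "fisher":
            cut = (cutpoints or {}).get(f, float(expr.median()))
            tab = [
                [int(((expr <= cut) & (cov == lv)).sum()) for lv in levels],
                [int(((expr > cut) & (cov == lv)).sum()) for lv in levels],
            ]
            stat, p = stats.fisher_exact(tab)
            stat, p, used = float(stat), float(p), "fisher"
        else:
            x = expr[cov == levels[0]].to_numpy()
            y = expr[cov == levels[1]].to_numpy()
            stat, p = _wilcoxon_rank_sum(x, y, exact_limit)
            used = "wilcoxon"
        rows.append((f, used, stat, p))
    out = pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
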