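"""Running-sum set enrichment analysis (GSEA) with phenotype permutation.

Features are ranked by the signal-to-noise score between two phenotype
classes. For a candidate miRNA set the running sum walks the ranked
list, incrementing at set members by ``|metric|^weight`` (normalized to
sum to one over members) and decrementing at non-members by
``1/(N - N_hits)``. The enrichment score ES is the signed maximum
deviation from zero; ``weight=0`` gives the classic Kolmogorov-Smirnov
form whose running sum ends exactly at zero.

Significance comes from phenotype-label permutations with a signed-null
convention: the nominal p compares |ES| only against null scores of the
observed sign, and NES divides ES by the mean |null ES| of that sign —
up- and down-regulated sets are thereby tested independently. All
distinct label assignments are enumerated when few enough, otherwise
sampled without replacement. The permutation p carries a pseudocount
(add-one) so it is never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .markers import _snr_scores, _split_classes

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_features",
    "enrichment_score",
    "leading_edge",
    "gsea_permutation_test",
    "GSEAPermutationTest",
]


@dataclass(frozen=True)
class RankedList:
    """Feature ids ordered by descending ranking metric (ties broken by
    feature id, so the order is deterministic)."""

    features: tuple
    metric: tuple

    def __post_init__(self):
        if len(self.features) != len(self.metric):
            raise ValueError("features and metric lengths differ")
        if not all(np.isfinite(self.metric)):
            raise ValueError("ranking metric must be finite")

    def __len__(self):
        return len(self.features)


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    nominal_p: float
    leading_edge: list
    running_sum: np.ndarray
    n_permutations: int
    seed: int | None
    fdr_q: float | None = None
    ranked: RankedList | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "es": self.es,
            "nes": self.nes,
            "nominal_p": self.nominal_p,
            "fdr_q": self.fdr_q,
            "leading_edge": list(self.leading_edge),
            "running_sum": np.asarray(self.running_sum).tolist(),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def rank_features(
    matrix: pd.DataFrame, labels: pd.Series, class1: str | None = None
) -> RankedList:
    """Rank the features of a features-x-samples matrix by the
    signal-to-noise score (class 1 vs class 2), descending."""
    labels = pd.Series(labels)
    c1, c2, ids1, ids2 = _split_classes(
        labels[labels.index.isin(matrix.columns)], class1
    )
    a = matrix[ids1].to_numpy(dtype=float)
    b = matrix[ids2].to_numpy(dtype=float)
    scores = _snr_scores(a, b)
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], str(matrix.index[i]))
    )
    return RankedList(
        features=tuple(matrix.index[i] for i in order),
        metric=tuple(float(scores[i]) for i in order),
    )


def enrichment_score(ranked: RankedList, feature_set, weight: float = 1.0):
    """Running-sum enrichment score of *feature_set* in *ranked*.

    Returns ``(ES, running_sum)`` where the running sum has one entry
    per ranked feature. Requires the set to hit the list at least once
    and not cover it entirely; ``weight`` must be >= 0.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    members = set(feature_set)
    hits = np.array([f in members for f in ranked.features], dtype=bool)
    n_hits = int(hits.sum())
    n = len(ranked)
    if n_hits == 0:
        raise ValueError("feature set is disjoint from the ranked list")
    if n_hits == n:
        raise ValueError("feature set covers the entire ranked list")

    metric = np.abs(np.asarray(ranked.metric, dtype=float)) ** weight
    hit_weights = metric * hits
    total = hit_weights.sum()
    if total == 0.0:
        # all hit metrics zero (possible when weight>0): fall back to
        # equal weighting so the statistic stays defined
        hit_weights = hits.astype(float)
        total = hit_weights.sum()
    steps = np.where(hits, hit_weights / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def leading_edge(ranked: RankedList, feature_set, running_sum) -> list:
    """Set members at/before the running-sum peak (ES > 0) or at/after
    the trough (ES < 0), in ranked order."""
    members = set(feature_set)
    running = np.asarray(running_sum, dtype=float)
    idx = int(np.argmax(np.abs(running)))
    if running[idx] >= 0:
        span = range(0, idx + 1)
    else:
        span = range(idx, len(running))
    return [ranked.features[i] for i in span if ranked.features[i] in members]


def _distinct_assignments(n: int, k: int):
    """All distinct index subsets of size k from n samples."""
    return combinations(range(n), k)


def _sample_assignments(rng, n: int, k: int, count: int):
    """Sample *count* distinct size-k subsets of range(n) without
    replacement (count is far below C(n, k) when this path is taken)."""
    seen = set()
    out = []
    while len(out) < count:
        subset = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        if subset not in seen:
            seen.add(subset)
            out.append(subset)
    return out


def gsea_permutation_test(
    matrix: pd.DataFrame,
    labels,
    feature_set,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = 0,
    class1: str | None = None,
    permutation: str = "phenotype",
) -> EnrichmentResult:
    """Permutation significance of a set's enrichment score.

    ``permutation='phenotype'`` (default) permutes class labels over
    samples; ``'feature'`` draws random same-size feature sets instead
    (for designs with too few samples to permute).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(matrix.columns)].dropna()
    ranked = rank_features(matrix, labels, class1=class1)
    es, running = enrichment_score(ranked, feature_set, weight=weight)
    edge = leading_edge(ranked, feature_set, running)

    null_es = []
    if permutation == "phenotype":
        c1, c2, ids1, ids2 = _split_classes(labels, class1)
        samples = list(ids1) + list(ids2)
        sub = matrix[samples]
        n, k = len(samples), len(ids1)
        total = math.comb(n, k)
        if total < 2:
            raise ValueError("fewer than 2 distinct label permutations")
        if total <= n_perm:
            assignments = list(_distinct_assignments(n, k))
        else:
            rng = np.random.default_rng(seed)
            assignments = _sample_assignments(rng, n, k, n_perm)
        for subset in assignments:
            perm_labels = pd.Series(c2, index=samples, dtype=object)
            perm_labels.iloc[list(subset)] = c1
            perm_ranked = rank_features(sub, perm_labels, class1=c1)
            null_es.append(enrichment_score(perm_ranked, feature_set, weight)[0])
    elif permutation == "feature":
        rng = np.random.default_rng(seed)
        members = [f for f in ranked.features if f in set(feature_set)]
        size = len(members)
        pool = np.asarray(ranked.features, dtype=object)
        for _ in range(n_perm):
            rand_set = rng.choice(pool, size=size, replace=False)
            null_es.append(enrichment_score(ranked, set(rand_set), weight)[0])
    else:
        raise ValueError("permutation must be 'phenotype' or 'feature'")

    null_es = np.asarray(null_es, dtype=float)
    sign = 1.0 if es >= 0 else -1.0
    same_sign = null_es[np.sign(null_es) == sign] if es != 0 else null_es
    extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
    nominal_p = (1.0 + extreme) / (1.0 + len(same_sign))
    mean_null = np.mean(np.abs(same_sign)) if len(same_sign) else np.nan
    nes = es / mean_null if mean_null and np.isfinite(mean_null) else float("nan")
    return EnrichmentResult(
        es=es,
        nes=float(nes),
        nominal_p=float(nominal_p),
        leading_edge=edge,
        running_sum=running,
        n_permutations=len(null_es),
        seed=seed,
        ranked=ranked,
    )


class GSEAPermutationTest(BaseEstimator):
    """scikit-learn-style wrapper: ``fit(X, y)`` with samples-x-features
    ``X`` and two-class ``y`` runs the permutation test for
    ``feature_set`` and exposes ``es_``, ``nes_``, ``p_value_``,
    ``leading_edge_``, ``running_sum_``, ``result_``."""

    def __init__(
        self,
        feature_set=(),
        n_perm: int = 1000,
        weight: float = 1.0,
        seed: int | None = 0,
        class1: str | None = None,
        permutation: str = "phenotype",
    ):
        self.feature_set = feature_set
        self.n_perm = n_perm
        self.weight = weight
        self.seed = seed
        self.class1 = class1
        self.permutation = permutation

    def fit(self, X, y):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        result = gsea_permutation_test(
            X.T,
            y,
            self.feature_set,
            n_perm=self.n_perm,
            weight=self.weight,
            seed=self.seed,
            class1=self.class1,
            permutation=self.permutation,
        )
        self.result_ = result
        self.es_ = result.es
        self.nes_ = result.nes
        self.p_value_ = result.nominal_p
        self.leading_edge_ = result.leading_edge
        self.running_sum_ = result.running_sum
        return self
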