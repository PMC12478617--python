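"""Per-pair conditional covariance statistics for monotone homogeneity testing.

For every item pair (i, j) the data are stratified into conditioning groups
(by default, deciles of a regression-weighted score on the remaining items,
with the regression weights estimated in a training sample).  Within each
group the sample covariance of the pair is computed; the group-size-weighted
mean of these covariances is the mean conditional covariance (MCC).
Monotone homogeneity implies that the population value of every such
conditional covariance is nonnegative, so a clearly negative MCC is evidence
against unidimensionality.

The MCC is standardized by the stratified hypergeometric (Mantel-Haenszel)
variance, giving a Z statistic whose left tail measures evidence against the
model.  A continuity correction of +0.5 in the numerator is applied by
default and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import ndtr

from .data import ItemResponseMatrix

__all__ = [
    "SampleSplit",
    "PairIndex",
    "PairPredictor",
    "ConditioningGroups",
    "PairStatistic",
    "PairStatsVector",
    "CarpModel",
    "pair_count",
    "pair_indices",
    "split_sample",
    "fit_pair_predictor",
    "conditioning_groups",
    "group_covariance",
    "mcc_statistic",
    "mh_variance",
    "z_statistic",
    "fit_carp_model",
    "all_pair_stats",
]

Conditioning = Literal["carp", "restscore"]


def pair_count(J: int) -> int:
    """Number of unordered item pairs, K = J(J-1)/2."""
    if J < 2:
        raise ValueError("pair_count requires at least 2 items")
    return J * (J - 1) // 2


def pair_indices(J: int) -> np.ndarray:
    """Canonical (K, 2) array of pairs (i, j), i < j, lexicographic order.

    The linear position k of pair (i, j) in this array is the fixed vector
    index used by every aggregation.
    """
    i, j = np.triu_indices(J, k=1)
    return np.column_stack([i, j])


@dataclass(frozen=True)
class PairIndex:
    """An item pair (i, j) with its linear position k in canonical order."""

    i: int
    j: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise ValueError("pair requires 0 <= i < j")


def _pair_index(i: int, j: int, J: int) -> PairIndex:
    if not 0 <= i < j < J:
        raise ValueError(f"invalid pair ({i}, {j}) for {J} items")
    k = i * J - i * (i + 1) // 2 + (j - i - 1)
    return PairIndex(i, j, k)


@dataclass(frozen=True)
class SampleSplit:
    """Disjoint training/test partition of the subject rows."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    fraction: float
    seed: int


def split_sample(X: ItemResponseMatrix, fraction: float = 0.3, seed: int = 0) -> SampleSplit:
    """Randomly partition subjects into a training and a test sample.

    ``round(fraction * N)`` subjects form the training sample used to
    estimate the conditioning-score weights; the remainder form the test
    sample on which the statistics are evaluated.  Deterministic for a
    fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("training fraction must lie strictly between 0 and 1")
    N = X.n_subjects
    n_train = int(round(fraction * N))
    if n_train in (0, N):
        raise ValueError(
            f"degenerate split: fraction {fraction} of {N} subjects leaves an empty sample"
        )
    perm = np.random.default_rng(seed).permutation(N)
    return SampleSplit(
        train_rows=np.sort(perm[:n_train]),
        test_rows=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
    )


@dataclass(frozen=True)
class PairPredictor:
    """OLS conditioning-score weights for one pair.

    The score of a subject is ``intercept + weights . x_rest`` where
    ``x_rest`` are the subject's scores on the J-2 items other than the
    pair.  The regression target is the pair sum X_i + X_j, fitted in the
    training sample (a minimum-norm solution when the design is
    rank-deficient).
    """

    pair: PairIndex
    intercept: float
    weights: np.ndarray  # length J - 2, ordered by remaining-item column

    def scores(self, X: ItemResponseMatrix) -> np.ndarray:
        rest = np.delete(np.arange(X.n_items), [self.pair.i, self.pair.j])
        return self.intercept + X.values[:, rest].astype(float) @ self.weights


def _gram_ols(G: np.ndarray, rhs: np.ndarray, cols: np.ndarray) -> np.ndarray:
    # Minimum-norm least-squares solution from the Gram matrix:
    # pinv(A'A) A'y equals pinv(A) y for any design A.
    sub = G[np.ix_(cols, cols)]
    return np.linalg.pinv(sub, hermitian=True) @ rhs[cols]


def fit_pair_predictor(train: ItemResponseMatrix, pair: PairIndex | tuple) -> PairPredictor:
    """Fit the conditioning-score regression for one pair on training rows."""
    if not isinstance(pair, PairIndex):
        pair = _pair_index(pair[0], pair[1], train.n_items)
    if train.n_subjects < 2:
        raise ValueError("insufficient data: at least 2 training rows are required")
    A = np.column_stack([np.ones(train.n_subjects), train.values.astype(float)])
    G = A.T @ A
    y_cols = G[:, pair.i + 1] + G[:, pair.j + 1]  # A'y with y = X_i + X_j
    cols = np.array([0] + [c + 1 for c in range(train.n_items) if c not in (pair.i, pair.j)])
    beta = _gram_ols(G, y_cols, cols)
    return PairPredictor(pair=pair, intercept=float(beta[0]), weights=beta[1:])


@dataclass(frozen=True)
class ConditioningGroups:
    """Assignment of test subjects to quantile groups of a conditioning score.

    Tied scores always share a group, so the achieved number of groups
    ``n_groups`` may fall below the target C (degenerate case: one group).
    """

    pair: PairIndex
    labels: np.ndarray  # group label in {0, ..., n_groups - 1} per subject
    group_sizes: np.ndarray
    target_groups: int
    cut_points: np.ndarray  # interior quantile edges of the score

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def degenerate(self) -> bool:
        return self.n_groups == 1


def _quantile_edges(scores: np.ndarray, C: int) -> np.ndarray:
    return np.quantile(scores, np.arange(1, C) / C)


def _labels_from_edges(scores: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # label = number of cut points strictly below the score; a pure function
    # of the score value, so ties share a bin and duplicate edges merge bins
    return np.searchsorted(edges, scores, side="left")


def conditioning_groups(
    test: ItemResponseMatrix, predictor: PairPredictor, C: int = 10
) -> ConditioningGroups:
    """Assign test subjects to (at most) C quantile groups of the CARP score."""
    if C < 2:
        raise ValueError("the number of conditioning groups C must be at least 2")
    scores = predictor.scores(test)
    edges = _quantile_edges(scores, C)
    raw = _labels_from_edges(scores, edges)
    _, labels = np.unique(raw, return_inverse=True)
    return ConditioningGroups(
        pair=predictor.pair,
        labels=labels,
        group_sizes=np.bincount(labels),
        target_groups=C,
        cut_points=edges,
    )


def group_covariance(xi: np.ndarray, xj: np.ndarray) -> float:
    """Maximum-likelihood sample covariance of a pair within one group."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.ndim != 1:
        raise ValueError("group_covariance expects two equal-length vectors")
    if xi.size == 0:
        raise ValueError("group_covariance is undefined for an empty group")
    return float(np.mean(xi * xj) - np.mean(xi) * np.mean(xj))


def _group_sums(labels: np.ndarray, xi: np.ndarray, xj: np.ndarray):
    # empty bins (possible when labels come from fixed cut points) are dropped
    n_c = np.bincount(labels).astype(float)
    si = np.bincount(labels, weights=xi).astype(float)
    sj = np.bincount(labels, weights=xj).astype(float)
    sij = np.bincount(labels, weights=xi * xj).astype(float)
    occupied = n_c > 0
    return n_c[occupied], si[occupied], sj[occupied], sij[occupied]


def mcc_statistic(
    groups: ConditioningGroups, xi: np.ndarray, xj: np.ndarray
) -> tuple[float, float]:
    """Weighted-mean conditional covariance: numerator T = sum_c n_c cov_c and
    MCC = T / N_test.  Groups of size 1 contribute zero."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    n_c, si, sj, sij = _group_sums(groups.labels, xi, xj)
    T = float(np.sum(sij - si * sj / n_c))
    return T, T / xi.size


def mh_variance(groups: ConditioningGroups, xi: np.ndarray, xj: np.ndarray) -> float:
    """Stratified hypergeometric (Mantel-Haenszel) variance of the numerator.

    V = sum_c m_ic (n_c - m_ic) m_jc (n_c - m_jc) / (n_c^2 (n_c - 1)),
    with m_ic, m_jc the within-group counts of ones.  Groups with fewer than
    two subjects contribute zero.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    n_c, si, sj, _ = _group_sums(groups.labels, xi, xj)
    ok = n_c >= 2
    n_c, si, sj = n_c[ok], si[ok], sj[ok]
    return float(np.sum(si * (n_c - si) * sj * (n_c - sj) / (n_c**2 * (n_c - 1.0))))


def z_statistic(
    numerator: float, variance: float, continuity: bool = True
) -> tuple[float, float]:
    """Standardized statistic Z = (T + 0.5 [continuity]) / sqrt(V) and its
    left-tail standard-normal p-value.

    Small p corresponds to a clearly negative mean conditional covariance.
    A zero variance means every group is degenerate; the statistic is then
    undefined (NaN) and the pair must be excluded from aggregation.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if variance == 0:
        return float("nan"), float("nan")
    z = (numerator + (0.5 if continuity else 0.0)) / np.sqrt(variance)
    return float(z), float(ndtr(z))


@dataclass(frozen=True)
class PairStatistic:
    """All per-pair quantities on one sample."""

    pair: PairIndex
    numerator: float
    mcc: float
    variance: float
    z: float
    p: float
    continuity: bool

    @property
    def degenerate(self) -> bool:
        return self.variance == 0.0


@dataclass(frozen=True)
class PairStatsVector:
    """Stacked per-pair statistics in canonical pair order (vector in R^K)."""

    pairs: np.ndarray  # (K, 2)
    numerator: np.ndarray
    mcc: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_subjects: int
    sample: str  # "train" or "test"
    continuity: bool

    @property
    def K(self) -> int:
        return len(self.pairs)

    @property
    def degenerate(self) -> np.ndarray:
        return self.variance == 0.0

    def vector(self, kind: str) -> np.ndarray:
        """The K-vector consumed by aggregations: MCCs or Z statistics."""
        if kind == "MCC":
            return self.mcc
        if kind == "Z":
            return self.z
        raise ValueError("kind must be 'MCC' or 'Z'")

    def stats(self) -> list[PairStatistic]:
        J = int(self.pairs.max()) + 1 if len(self.pairs) else 0
        return [
            PairStatistic(
                pair=_pair_index(int(i), int(j), J),
                numerator=float(self.numerator[k]),
                mcc=float(self.mcc[k]),
                variance=float(self.variance[k]),
                z=float(self.z[k]),
                p=float(self.p[k]),
                continuity=self.continuity,
            )
            for k, (i, j) in enumerate(self.pairs)
        ]


@dataclass(frozen=True)
class CarpModel:
    """Fitted conditioning rule for all pairs, frozen for resampling.

    ``weight_matrix`` has one column per pair; row 0 is the intercept and
    row m+1 the weight on item m (zero for the pair's own items).  The decile
    cut points of the test-sample scores are part of the statistic's
    definition and are held fixed when the test rows are bootstrapped.
    """

    pairs: np.ndarray
    weight_matrix: np.ndarray  # (J + 1, K)
    test_cut_points: list[np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]
    target_groups: int = 10
    conditioning: str = "carp"

    def scores(self, values: np.ndarray) -> np.ndarray:
        """(n, K) matrix of conditioning scores for a raw 0/1 value matrix."""
        A = np.column_stack([np.ones(len(values)), values.astype(float)])
        return A @ self.weight_matrix


def _fit_weight_matrix(train_values: np.ndarray, pairs: np.ndarray, conditioning: str) -> np.ndarray:
    J = train_values.shape[1]
    W = np.zeros((J + 1, len(pairs)))
    if conditioning == "restscore":
        # Rosenbaum Case-5 conditioning: unweighted pairwise rest score
        W[1:, :] = 1.0
        for k, (i, j) in enumerate(pairs):
            W[i + 1, k] = 0.0
            W[j + 1, k] = 0.0
        return W
    if conditioning != "carp":
        raise ValueError("conditioning must be 'carp' or 'restscore'")
    A = np.column_stack([np.ones(len(train_values)), train_values.astype(float)])
    G = A.T @ A
    for k, (i, j) in enumerate(pairs):
        cols = np.array([0] + [c + 1 for c in range(J) if c not in (i, j)])
        beta = _gram_ols(G, G[:, i + 1] + G[:, j + 1], cols)
        W[cols, k] = beta
    return W


def _stats_from_labels(
    labels_per_pair: list[np.ndarray],
    values: np.ndarray,
    pairs: np.ndarray,
    continuity: bool,
    sample: str,
) -> PairStatsVector:
    n = len(values)
    K = len(pairs)
    numerator = np.empty(K)
    variance = np.empty(K)
    vals = values.astype(float)
    for k, (i, j) in enumerate(pairs):
        lab = labels_per_pair[k]
        xi, xj = vals[:, i], vals[:, j]
        n_c, si, sj, sij = _group_sums(lab, xi, xj)
        numerator[k] = np.sum(sij - si * sj / n_c)
        ok = n_c >= 2
        nc2, si2, sj2 = n_c[ok], si[ok], sj[ok]
        variance[k] = np.sum(si2 * (nc2 - si2) * sj2 * (nc2 - sj2) / (nc2**2 * (nc2 - 1.0)))
    mcc = numerator / n
    z = np.full(K, np.nan)
    p = np.full(K, np.nan)
    pos = variance > 0
    z[pos] = (numerator[pos] + (0.5 if continuity else 0.0)) / np.sqrt(variance[pos])
    p[pos] = ndtr(z[pos])
    return PairStatsVector(
        pairs=pairs,
        numerator=numerator,
        mcc=mcc,
        variance=variance,
        z=z,
        p=p,
        n_subjects=n,
        sample=sample,
        continuity=continuity,
    )


def fit_carp_model(
    X: ItemResponseMatrix,
    split: SampleSplit,
    C: int = 10,
    conditioning: Conditioning = "carp",
) -> CarpModel:
    """Fit the conditioning rule (weights on training rows, decile cut points
    on test-sample scores) for every pair."""
    pairs = pair_indices(X.n_items)
    train_values = X.values[split.train_rows]
    W = _fit_weight_matrix(train_values, pairs, conditioning)
    model = CarpModel(pairs=pairs, weight_matrix=W, target_groups=C, conditioning=conditioning)
    test_scores = model.scores(X.values[split.test_rows])
    cuts = [_quantile_edges(test_scores[:, k], C) for k in range(len(pairs))]
    return CarpModel(
        pairs=pairs,
        weight_matrix=W,
        test_cut_points=cuts,
        target_groups=C,
        conditioning=conditioning,
    )


def stats_with_fixed_cuts(
    model: CarpModel, values: np.ndarray, continuity: bool, sample: str = "test"
) -> PairStatsVector:
    """Statistics on a raw value matrix using the model's frozen cut points
    (the bootstrap path: resampled rows, original conditioning rule)."""
    scores = model.scores(values)
    labels = [
        _labels_from_edges(scores[:, k], model.test_cut_points[k])
        for k in range(len(model.pairs))
    ]
    return _stats_from_labels(labels, values, model.pairs, continuity, sample)


def all_pair_stats(
    X: ItemResponseMatrix,
    split: SampleSplit,
    C: int = 10,
    continuity: bool = True,
    conditioning: Conditioning = "carp",
) -> tuple[PairStatsVector, PairStatsVector]:
    """Compute all per-pair statistics on a train/test split.

    Returns ``(train_stats, test_stats)`` in canonical pair order.  Test
    statistics use conditioning scores from weights fitted on the training
    rows, binned at the test-sample deciles.  Training statistics (used for
    preselection) use the same self-fitted weights binned at the
    training-sample deciles.
    """
    if X.n_items < 3:
        raise ValueError("at least 3 items are needed to condition on a remaining item")
    model = fit_carp_model(X, split, C=C, conditioning=conditioning)
    test_stats = stats_with_fixed_cuts(model, X.values[split.test_rows], continuity, "test")
    train_values = X.values[split.train_rows]
    train_scores = model.scores(train_values)
    train_labels = [
        _labels_from_edges(train_scores[:, k], _quantile_edges(train_scores[:, k], C))
        for k in range(len(model.pairs))
    ]
    train_stats = _stats_from_labels(train_labels, train_values, model.pairs, continuity, "train")
    return train_stats, test_stats


def pair_stats_frame(train: PairStatsVector, test: PairStatsVector):
    """Tabular (pandas) view of the per-pair statistics, ready for CSV."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pair_i": test.pairs[:, 0],
            "pair_j": test.pairs[:, 1],
            "k": np.arange(test.K),
            "train_mcc": train.mcc,
            "test_mcc": test.mcc,
            "numerator": test.numerator,
            "variance": test.variance,
            "z": test.z,
            "p": test.p,
            "degenerate_flag": test.degenerate,
        }
    )
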