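"""Omnibus aggregation of the pairwise statistics.

The K per-pair statistics (MCCs or Zs) are combined into a single test of
monotone homogeneity in eight ways:

* LR -- likelihood-ratio-type chi-bar-square test: squared Mahalanobis
  distance from the statistic vector to the nonnegative cone, referred to a
  Monte-Carlo-weighted mixture of chi-square distributions;
* CL -- conditional likelihood ratio (Wollan-Dykstra): the same distance
  referred to a chi-square whose degrees of freedom equal the number of
  binding nonnegativity constraints;
* PS -- preselected standardized partial sum: the sum of test statistics
  over pairs with a negative training-sample MCC, standardized by the
  summed covariance submatrix;
* CS / CP / CB -- conditionalized sum / product / Bonferroni: p-values below
  a threshold t are divided by t and combined by Stouffer's sum, Fisher's
  product, or the minimum with a Bonferroni correction;
* PP / PB -- preselected product / Bonferroni: raw test p-values over the
  training-preselected pairs, combined by Fisher's product or Bonferroni.

A four-letter registry names the 20 supported tests: first letter the
pairwise statistic (M = MCC, Z = Z), second the covariance estimator
(B = bootstrap, M = moments, I = identity), last two the aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import nnls
from scipy.special import ndtr, ndtri

from . import covest, pairstats
from .covest import BootstrapPlan, CovMatrix, cov_identity, repair_psd
from .data import ItemResponseMatrix
from .pairstats import PairStatsVector

log = logging.getLogger(__name__)

__all__ = [
    "ConeProjection",
    "ChiBarWeights",
    "SelectionSet",
    "OmnibusResult",
    "TestConfig",
    "project_nonneg_cone",
    "chibar_weights",
    "chibar_weights_identity",
    "lr_pvalue",
    "cl_pvalue",
    "preselect",
    "conditional_select",
    "ps_test",
    "cs_test",
    "cp_test",
    "cb_test",
    "pp_test",
    "pb_test",
    "valid_test_names",
    "run_named_test",
    "run_all_tests",
]

P_FLOOR = 1e-300
_BIND_TOL = 1e-9


@dataclass(frozen=True)
class ConeProjection:
    """Projection of a statistic vector onto the nonnegative cone.

    ``chibar_sq`` is the squared Mahalanobis distance between the vector and
    its projection; ``n_active`` counts the coordinates pinned to zero by a
    binding constraint (under the identity metric, the number of negative
    statistics).
    """

    theta_star: np.ndarray
    chibar_sq: float
    n_active: int


def project_nonneg_cone(x: np.ndarray, sigma: CovMatrix) -> ConeProjection:
    """Solve min (x - theta)' Sigma^-1 (x - theta) subject to theta >= 0.

    The problem is whitened with the Cholesky factor of Sigma and solved as
    a nonnegative least-squares program; with the identity matrix the
    solution reduces to coordinatewise clipping at zero.
    """
    x = np.asarray(x, dtype=float)
    if sigma.method == "identity":
        theta = np.maximum(x, 0.0)
        chibar = float(np.sum(np.minimum(x, 0.0) ** 2))
        n_active = int(np.sum(x < -_BIND_TOL))
        return ConeProjection(theta, chibar, n_active)
    try:
        L = cholesky(sigma.matrix, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by repair_psd
        raise ValueError("sigma is not positive definite; repair it first") from exc
    A = solve_triangular(L, np.eye(len(x)), lower=True)  # A = L^-1
    theta, _ = nnls(A, A @ x)
    resid = A @ (x - theta)
    chibar = float(resid @ resid)
    # Lagrange multipliers of the nonnegativity constraints
    lam = A.T @ (A @ (theta - x))
    scale = max(1.0, float(np.abs(x).max(initial=0.0)))
    n_active = int(np.sum((theta <= _BIND_TOL * scale) & (lam > _BIND_TOL * scale)))
    return ConeProjection(theta, chibar, n_active)


@dataclass(frozen=True)
class ChiBarWeights:
    """Mixture weights of the chi-bar-square null distribution."""

    weights: np.ndarray  # w_0 ... w_K, summing to 1
    n_draws: int
    seed: int


def chibar_weights(sigma: CovMatrix, n_draws: int = 10000, seed: int = 0) -> ChiBarWeights:
    """Monte-Carlo chi-bar weights: draw from N(0, Sigma) and count, for each
    draw, how many coordinates are negative; w_k is the proportion of draws
    with exactly k negative coordinates."""
    K = sigma.K
    rng = np.random.default_rng(seed)
    L = cholesky(repair_psd(sigma).matrix, lower=True)
    counts = np.zeros(K + 1)
    block = 200_000 // max(K, 1) + 1
    done = 0
    while done < n_draws:
        b = min(block, n_draws - done)
        draws = rng.standard_normal((b, K)) @ L.T
        neg = (draws < 0).sum(axis=1)
        counts += np.bincount(neg, minlength=K + 1)
        done += b
    return ChiBarWeights(counts / n_draws, n_draws=n_draws, seed=seed)


def chibar_weights_identity(K: int) -> ChiBarWeights:
    """Closed-form weights under the identity covariance: the number of
    negative coordinates of a standard normal vector is binomial(K, 1/2)."""
    w = sps.binom.pmf(np.arange(K + 1), K, 0.5)
    return ChiBarWeights(w, n_draws=0, seed=0)


def lr_pvalue(chibar_sq: float, weights: ChiBarWeights) -> float:
    """Chi-bar-square tail probability: p = sum_k w_k P(chi2_k >= c), with
    the k = 0 component contributing only at c = 0."""
    if chibar_sq < 0:
        raise ValueError("chibar_sq must be nonnegative")
    if chibar_sq == 0.0:
        return 1.0
    w = weights.weights
    k = np.arange(1, len(w))
    return float(np.sum(w[1:] * sps.chi2.sf(chibar_sq, k)))


def cl_pvalue(chibar_sq: float, n_active: int) -> float:
    """Conditional (Wollan-Dykstra) p-value: chi-square tail with degrees of
    freedom equal to the number of binding constraints.  With no binding
    constraint the statistic vector lies in the cone and the test never
    rejects (p = 1)."""
    if n_active == 0:
        return 1.0
    return float(sps.chi2.sf(chibar_sq, n_active))


@dataclass(frozen=True)
class SelectionSet:
    """A subset of pair positions entering an aggregation.

    ``preselected_train`` sets depend only on training-sample MCCs;
    ``conditionalized_test`` sets contain the test pairs with p below the
    threshold t, with corrected p-values p / t attached.
    """

    indices: np.ndarray
    provenance: str
    threshold: float | None = None
    corrected_p: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class OmnibusResult:
    """One named omnibus test: statistic, reference distribution, p, decision."""

    test_name: str
    statistic: float
    reference: str
    df_or_weights: object
    p: float
    reject: bool
    alpha: float
    n_selected: int | None = None
    n_pairs: int = 0
    excluded_pairs: int = 0


def preselect(train_stats: PairStatsVector | np.ndarray) -> SelectionSet:
    """Pairs with a negative training-sample MCC (independent of the test
    sample by construction)."""
    mcc = train_stats.mcc if isinstance(train_stats, PairStatsVector) else np.asarray(train_stats)
    return SelectionSet(np.flatnonzero(mcc < 0), provenance="preselected_train")


def conditional_select(test_stats: PairStatsVector | np.ndarray, t: float = 0.5) -> SelectionSet:
    """Test pairs with p < t, each p divided by t (conditionalization).

    At the default t = 0.5 this keeps the pairs whose standardized statistic
    is negative; under a true null the corrected p-values are uniform."""
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold t must lie in (0, 1]")
    p = test_stats.p if isinstance(test_stats, PairStatsVector) else np.asarray(test_stats)
    with np.errstate(invalid="ignore"):
        sel = np.flatnonzero(p < t)
    return SelectionSet(sel, provenance="conditionalized_test", threshold=t, corrected_p=p[sel] / t)


def _clamp_p(p: np.ndarray) -> np.ndarray:
    if (p < P_FLOOR).any():
        log.info("clamping %d p-values at the %g floor", int((p < P_FLOOR).sum()), P_FLOOR)
    return np.maximum(p, P_FLOOR)


def _empty(name: str, reference: str, alpha: float, n_pairs: int) -> OmnibusResult:
    return OmnibusResult(
        test_name=name,
        statistic=float("nan"),
        reference=reference,
        df_or_weights=None,
        p=1.0,
        reject=False,
        alpha=alpha,
        n_selected=0,
        n_pairs=n_pairs,
    )


def ps_test(
    x: np.ndarray,
    sigma: CovMatrix,
    selection: SelectionSet,
    alpha: float = 0.05,
    name: str = "PS",
) -> OmnibusResult:
    """Preselected standardized partial sum: the selected statistics are
    summed and divided by the square root of the summed covariance
    submatrix; the reference is standard normal (left tail)."""
    if selection.size == 0:
        return _empty(name, "normal", alpha, len(x))
    idx = selection.indices
    denom = float(sigma.submatrix(idx).sum())
    T = float(np.asarray(x)[idx].sum() / np.sqrt(denom))
    p = float(ndtr(T))
    return OmnibusResult(name, T, "normal", None, p, p <= alpha, alpha, selection.size, len(x))


def cs_test(selection: SelectionSet, alpha: float = 0.05, name: str = "CS") -> OmnibusResult:
    """Conditionalized sum (Stouffer): corrected p-values are mapped to
    normal quantiles, summed, and standardized by sqrt(K')."""
    if selection.size == 0:
        return _empty(name, "normal", alpha, 0)
    q = ndtri(_clamp_p(selection.corrected_p))
    Z = float(q.sum() / np.sqrt(selection.size))
    p = float(ndtr(Z))
    return OmnibusResult(name, Z, "normal", None, p, p <= alpha, alpha, selection.size)


def cp_test(selection: SelectionSet, alpha: float = 0.05, name: str = "CP") -> OmnibusResult:
    """Conditionalized product (Fisher): -2 sum log corrected p, referred to
    chi-square with 2 K' degrees of freedom."""
    if selection.size == 0:
        return _empty(name, "chi-square", alpha, 0)
    X = float(-2.0 * np.log(_clamp_p(selection.corrected_p)).sum())
    df = 2 * selection.size
    p = float(sps.chi2.sf(X, df))
    return OmnibusResult(name, X, "chi-square", df, p, p <= alpha, alpha, selection.size)


def cb_test(selection: SelectionSet, alpha: float = 0.05, name: str = "CB") -> OmnibusResult:
    """Conditionalized Bonferroni: K' times the smallest corrected p-value."""
    if selection.size == 0:
        return _empty(name, "Bonferroni", alpha, 0)
    pmin = float(selection.corrected_p.min())
    adj = min(1.0, selection.size * pmin)
    return OmnibusResult(name, pmin, "Bonferroni", selection.size, adj, adj <= alpha, alpha, selection.size)


def pp_test(
    p_values: np.ndarray, selection: SelectionSet, alpha: float = 0.05, name: str = "PP"
) -> OmnibusResult:
    """Preselected product (Fisher) of the raw test p-values over the pairs
    chosen from the training sample."""
    if selection.size == 0:
        return _empty(name, "chi-square", alpha, len(p_values))
    psel = _clamp_p(np.asarray(p_values)[selection.indices])
    X = float(-2.0 * np.log(psel).sum())
    df = 2 * selection.size
    p = float(sps.chi2.sf(X, df))
    return OmnibusResult(name, X, "chi-square", df, p, p <= alpha, alpha, selection.size, len(p_values))


def pb_test(
    p_values: np.ndarray, selection: SelectionSet, alpha: float = 0.05, name: str = "PB"
) -> OmnibusResult:
    """Preselected Bonferroni: K_S times the smallest raw test p-value over
    the training-preselected pairs."""
    if selection.size == 0:
        return _empty(name, "Bonferroni", alpha, len(p_values))
    psel = np.asarray(p_values)[selection.indices]
    pmin = float(psel.min())
    adj = min(1.0, selection.size * pmin)
    return OmnibusResult(name, pmin, "Bonferroni", selection.size, adj, adj <= alpha, alpha, selection.size, len(p_values))


_STAT_LETTERS = {"M": "MCC", "Z": "Z"}
_COV_LETTERS = {"B": "bootstrap", "M": "moments", "I": "identity"}
_AGGREGATIONS = ("LR", "CL", "PS", "CS", "CP", "CB", "PP", "PB")


def valid_test_names() -> list[str]:
    """The 20 supported four-letter test codes.

    Bootstrap and moments covariances are meaningful only for the
    Mahalanobis-type aggregations (LR, CL, PS); the identity matrix is only
    reasonable for standardized Z statistics, where it additionally supports
    the covariance-free combiners (CS, CP, CB, PP, PB).
    """
    names = [s + c + a for s in "MZ" for c in "BM" for a in ("LR", "CL", "PS")]
    names += ["ZI" + a for a in _AGGREGATIONS]
    return names


@dataclass(frozen=True)
class TestConfig:
    """Settings shared by every omnibus test run."""

    __test__ = False  # not a pytest class, despite the name

    alpha: float = 0.05
    train_fraction: float = 0.3
    n_groups: int = 10
    continuity: bool = True
    threshold: float = 0.5  # conditionalization threshold t
    conditioning: str = "carp"
    n_boot: int = 1000
    n_weight_draws: int = 10000
    recompute_cuts: bool = False
    jitter: float = 1e-10
    seed: int = 0


def _parse_name(name: str) -> tuple[str, str, str]:
    if name not in valid_test_names():
        raise KeyError(
            f"unknown test {name!r}; valid tests are: {', '.join(valid_test_names())}"
        )
    return _STAT_LETTERS[name[0]], _COV_LETTERS[name[1]], name[2:]


def run_named_test(name: str, X: ItemResponseMatrix, config: TestConfig = TestConfig()) -> OmnibusResult:
    """Run one named omnibus test end to end on an item-response matrix."""
    return run_all_tests([name], X, config)[name]


def run_all_tests(
    names: list[str],
    X: ItemResponseMatrix,
    config: TestConfig = TestConfig(),
) -> dict[str, OmnibusResult]:
    """Run several named tests, sharing the split, the pairwise statistics,
    and any covariance estimates across tests.

    Pairs whose Mantel-Haenszel variance is zero on the test sample are
    excluded from every aggregation (K is reduced accordingly).
    """
    parsed = {name: _parse_name(name) for name in names}
    split = pairstats.split_sample(X, config.train_fraction, config.seed)
    model = pairstats.fit_carp_model(X, split, C=config.n_groups, conditioning=config.conditioning)
    test_values = X.values[split.test_rows]
    test_stats = pairstats.stats_with_fixed_cuts(model, test_values, config.continuity, "test")
    train_values = X.values[split.train_rows]
    train_scores = model.scores(train_values)
    train_labels = [
        pairstats._labels_from_edges(
            train_scores[:, k], pairstats._quantile_edges(train_scores[:, k], config.n_groups)
        )
        for k in range(len(model.pairs))
    ]
    train_stats = pairstats._stats_from_labels(
        train_labels, train_values, model.pairs, config.continuity, "train"
    )

    active = ~test_stats.degenerate
    excluded = int((~active).sum())
    if excluded:
        log.info("excluding %d degenerate pair(s) from aggregation", excluded)
    if not active.any():
        raise ValueError("every pair is degenerate on the test sample; no aggregation possible")
    idx = np.flatnonzero(active)
    vectors = {"MCC": test_stats.mcc[idx], "Z": test_stats.z[idx]}
    p_raw = test_stats.p[idx]
    train_mcc = train_stats.mcc[idx]
    K = len(idx)

    sigma_cache: dict[tuple[str, str], CovMatrix] = {}

    def get_sigma(kind: str, method: str) -> CovMatrix:
        key = (kind, method)
        if key in sigma_cache:
            return sigma_cache[key]
        if method == "identity":
            sigma = cov_identity(K, kind="Z")
        elif method == "bootstrap":
            plan = BootstrapPlan(config.n_boot, seed=config.seed + 1, recompute_cuts=config.recompute_cuts)
            test_matrix = ItemResponseMatrix(test_values, X.item_names)
            full = covest.cov_bootstrap(
                test_matrix, model, kind=kind, plan=plan, continuity=config.continuity
            )
            sigma = CovMatrix(full.matrix[np.ix_(idx, idx)], "bootstrap", kind)
        elif method == "moments":
            test_matrix = ItemResponseMatrix(test_values, X.item_names)
            test_scores = model.scores(test_values)
            labels = [
                pairstats._labels_from_edges(test_scores[:, k], model.test_cut_points[k])
                for k in range(len(model.pairs))
            ]
            full = covest.cov_moments_mcc(test_matrix, labels)
            mcc_cov = CovMatrix(full.matrix[np.ix_(idx, idx)], "moments", "MCC")
            sigma_cache[("MCC", "moments")] = mcc_cov
            if kind == "Z":
                sigma = covest.cov_moments_z(
                    mcc_cov, test_stats.variance[idx], test_stats.n_subjects
                )
            else:
                sigma = mcc_cov
        else:  # pragma: no cover
            raise KeyError(method)
        sigma_cache[key] = sigma
        return sigma

    proj_cache: dict[tuple[str, str], ConeProjection] = {}
    weight_cache: dict[tuple[str, str], ChiBarWeights] = {}
    results: dict[str, OmnibusResult] = {}

    for name, (kind, method, agg) in parsed.items():
        x = vectors[kind]
        if agg in ("LR", "CL", "PS"):
            sigma = repair_psd(get_sigma(kind, method), config.jitter)
        if agg in ("LR", "CL"):
            key = (kind, method)
            if key not in proj_cache:
                proj_cache[key] = project_nonneg_cone(x, sigma)
            proj = proj_cache[key]
        if agg == "LR":
            key = (kind, method)
            if key not in weight_cache:
                if method == "identity":
                    weight_cache[key] = chibar_weights_identity(K)
                else:
                    weight_cache[key] = chibar_weights(sigma, config.n_weight_draws, config.seed + 2)
            w = weight_cache[key]
            p = lr_pvalue(proj.chibar_sq, w)
            results[name] = OmnibusResult(
                name, proj.chibar_sq, "chi-bar-square", w.weights, p, p <= config.alpha,
                config.alpha, None, K, excluded,
            )
        elif agg == "CL":
            p = cl_pvalue(proj.chibar_sq, proj.n_active)
            if proj.n_active == 0:
                reject = False
            else:
                reject = proj.chibar_sq > sps.chi2.isf(config.alpha, proj.n_active)
            results[name] = OmnibusResult(
                name, proj.chibar_sq, "chi-square (conditional)", proj.n_active, p, reject,
                config.alpha, None, K, excluded,
            )
        elif agg == "PS":
            sel = preselect(train_mcc)
            res = ps_test(x, sigma, sel, config.alpha, name)
            results[name] = replace(res, excluded_pairs=excluded)
        elif agg in ("CS", "CP", "CB"):
            sel = conditional_select(p_raw, config.threshold)
            fn = {"CS": cs_test, "CP": cp_test, "CB": cb_test}[agg]
            res = fn(sel, config.alpha, name)
            results[name] = replace(res, n_pairs=K, excluded_pairs=excluded)
        else:  # PP / PB
            sel = preselect(train_mcc)
            fn = {"PP": pp_test, "PB": pb_test}[agg]
            res = fn(p_raw, sel, config.alpha, name)
            results[name] = replace(res, excluded_pairs=excluded)
    return results
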