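"""Covariance matrices of the pairwise statistics.

Three estimators of the K x K covariance matrix of the per-pair statistics
are provided:

* ``cov_identity`` -- the identity matrix, justified for standardized Z
  statistics because near-independent Bernoulli variables yield
  asymptotically uncorrelated conditional covariances;
* ``cov_moments_mcc`` / ``cov_moments_z`` -- a plug-in moment estimate that
  treats the conditioning groups as fixed, built from the per-subject
  cross-moment contributions to each MCC;
* ``cov_bootstrap`` -- row resampling of the test matrix with the fitted
  conditioning rule held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ItemResponseMatrix
from .pairstats import CarpModel, stats_with_fixed_cuts

log = logging.getLogger(__name__)

__all__ = [
    "CovMatrix",
    "BootstrapPlan",
    "cov_identity",
    "cov_bootstrap",
    "cov_moments_mcc",
    "cov_moments_z",
    "repair_psd",
]


@dataclass(frozen=True)
class CovMatrix:
    """A symmetric K x K covariance estimate with provenance."""

    matrix: np.ndarray
    method: str  # "identity" | "moments" | "bootstrap"
    kind: str  # "MCC" | "Z"
    repaired: bool = False

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(idx, idx)]


@dataclass(frozen=True)
class BootstrapPlan:
    """Resampling plan: number of resamples B, seed, and whether decile cut
    points are recomputed in each resample (default: held fixed)."""

    n_resamples: int = 1000
    seed: int = 0
    recompute_cuts: bool = False

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("bootstrap requires at least 2 resamples")


def cov_identity(K: int, kind: str = "Z") -> CovMatrix:
    """Identity covariance; meaningful only for standardized Z statistics."""
    if K < 1:
        raise ValueError("K must be positive")
    if kind != "Z":
        raise ValueError("the identity covariance is only valid for Z statistics")
    return CovMatrix(np.eye(K), method="identity", kind="Z")


def cov_bootstrap(
    test: ItemResponseMatrix,
    model: CarpModel,
    kind: str = "MCC",
    plan: BootstrapPlan = BootstrapPlan(),
    continuity: bool = True,
) -> CovMatrix:
    """Bootstrap covariance of the per-pair MCCs or Z statistics.

    Rows of the test matrix are resampled with replacement B times and the
    chosen statistic is recomputed for every pair, holding the
    training-fitted weights (and, by default, the original test-sample cut
    points) fixed.  Resamples where a pair is degenerate contribute missing
    values, handled by pairwise-complete covariance.
    """
    if kind not in ("MCC", "Z"):
        raise ValueError("kind must be 'MCC' or 'Z'")
    rng = np.random.default_rng(plan.seed)
    n = test.n_subjects
    K = len(model.pairs)
    draws = np.empty((plan.n_resamples, K))
    for b in range(plan.n_resamples):
        rows = rng.integers(0, n, size=n)
        values = test.values[rows]
        if plan.recompute_cuts:
            from .pairstats import _labels_from_edges, _quantile_edges, _stats_from_labels

            scores = model.scores(values)
            labels = [
                _labels_from_edges(scores[:, k], _quantile_edges(scores[:, k], model.target_groups))
                for k in range(K)
            ]
            stats = _stats_from_labels(labels, values, model.pairs, continuity, "test")
        else:
            stats = stats_with_fixed_cuts(model, values, continuity)
        draws[b] = stats.mcc if kind == "MCC" else stats.z
    frac_missing = np.isnan(draws).mean(axis=0)
    if (frac_missing > 0.1).any():
        bad = np.flatnonzero(frac_missing > 0.1)
        log.warning(
            "bootstrap: pairs %s degenerate in >10%% of resamples; exclude them upstream",
            bad.tolist(),
        )
    cov = pd.DataFrame(draws).cov().to_numpy()  # pairwise-complete, B-1 denominator
    cov = (cov + cov.T) / 2.0
    return CovMatrix(cov, method="bootstrap", kind=kind)


def cov_moments_mcc(
    test: ItemResponseMatrix,
    labels_per_pair: list[np.ndarray],
) -> CovMatrix:
    """Moment estimate of Cov(MCC_p, MCC_q) with fixed conditioning groups.

    Within group c, sum_{n in c} (x_in - pbar_ic)(x_jn - pbar_jc) equals
    n_c cov_c, so each MCC is exactly the subject mean of the centred
    cross products u_n = (x_in - pbar_i,c(n))(x_jn - pbar_j,c(n)).  Treating
    the group assignment as fixed and subjects as i.i.d., the covariance of
    two MCCs is estimated by the sample covariance of the per-subject
    contributions divided by the number of test subjects.
    """
    vals = test.values.astype(float)
    n = len(vals)
    K = len(labels_per_pair)
    # u-matrix: per-subject contribution of each pair's MCC
    U = np.empty((n, K))
    pairs_missing = []
    from .pairstats import pair_indices

    pairs = pair_indices(test.n_items)
    if K != len(pairs):
        raise ValueError("labels_per_pair must cover every pair in canonical order")
    for k, (i, j) in enumerate(pairs):
        lab = labels_per_pair[k]
        if len(lab) != n:
            raise ValueError("group labels must cover every test subject")
        n_c = np.bincount(lab).astype(float)
        if (n_c == 0).any():
            pairs_missing.append(k)
        denom = np.where(n_c > 0, n_c, 1.0)  # empty bins are never indexed below
        pbar_i = np.bincount(lab, weights=vals[:, i]) / denom
        pbar_j = np.bincount(lab, weights=vals[:, j]) / denom
        U[:, k] = (vals[:, i] - pbar_i[lab]) * (vals[:, j] - pbar_j[lab])
    if pairs_missing:
        log.debug("moments covariance: empty conditioning bins for pairs %s", pairs_missing)
    cov = np.cov(U, rowvar=False) / n
    cov = np.atleast_2d((cov + cov.T) / 2.0)
    return CovMatrix(cov, method="moments", kind="MCC")


def cov_moments_z(mcc_cov: CovMatrix, variances: np.ndarray, n_test: int) -> CovMatrix:
    """Rescale an MCC covariance to the Z scale.

    Under the linear approximation Z ~= N * MCC / sqrt(V), entry (p, q) is
    multiplied by N^2 / sqrt(V_p V_q) -- a congruence transform, so symmetry
    and positive semidefiniteness are preserved.
    """
    if mcc_cov.kind != "MCC":
        raise ValueError("cov_moments_z expects an MCC covariance")
    variances = np.asarray(variances, dtype=float)
    if (variances <= 0).any():
        raise ValueError("all pair variances must be positive (exclude degenerate pairs first)")
    scale = n_test / np.sqrt(variances)
    return CovMatrix(
        mcc_cov.matrix * np.outer(scale, scale),
        method="moments",
        kind="Z",
        repaired=mcc_cov.repaired,
    )


def save_covariance(cov: CovMatrix, pairs: np.ndarray, path) -> None:
    """Write a covariance matrix to CSV with pair labels ("i-j") as headers
    and a JSON sidecar recording method, kind, and repair status."""
    import json
    from pathlib import Path

    labels = [f"{i}-{j}" for i, j in pairs]
    pd.DataFrame(cov.matrix, index=labels, columns=labels).to_csv(path)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps({"method": cov.method, "kind": cov.kind, "repaired": cov.repaired}) + "\n"
    )


def repair_psd(m: CovMatrix, jitter: float = 1e-10) -> CovMatrix:
    """Shift the spectrum so the smallest eigenvalue is at least ``jitter``.

    Guarantees a Cholesky factorization exists for the whitening step of the
    cone projection.  Matrices that are already sufficiently positive
    definite are returned unchanged.
    """
    eigmin = float(np.linalg.eigvalsh(m.matrix).min())
    if eigmin >= jitter:
        return m
    bumped = m.matrix + (jitter - eigmin) * np.eye(m.K)
    return CovMatrix(bumped, method=m.method, kind=m.kind, repaired=True)
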