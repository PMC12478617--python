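"""Monte-Carlo experiment harness: rejection-rate grids and diagnostics.

Runs a set of simulation designs against a set of named omnibus tests and
tabulates rejection proportions, with reproducible per-replication seed
substreams (results are identical regardless of execution order or worker
count).  Includes the Schweder-Spjotvoll p-value diagnostic (sorted
p-values against their ranks) and a stochastic-dominance check of rejection
counts against the nominal binomial reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .aggregate import TestConfig, run_all_tests, valid_test_names
from .simulate import SimulationDesign, make_parameters, simulate_design

log = logging.getLogger(__name__)

__all__ = [
    "RejectionTable",
    "run_rejection_grid",
    "pvalue_diagnostics",
    "summarize_binomial_dominance",
    "random_unidimensional_cases",
    "preset_designs",
    "PRESETS",
    "study_type1_dim0",
    "study_type1_dim1_grid",
    "study_type1_dim1_random",
    "study_power_medium",
]

FOCAL_TESTS = ("ZICL", "ZICS", "ZICP", "ZIPP")


@dataclass(frozen=True)
class RejectionTable:
    """Rejection proportions per test (rows) and design cell (columns)."""

    rates: pd.DataFrame
    counts: pd.DataFrame  # valid (non-degenerate) replications per cell
    alpha: float
    seed: int | None
    pvalues: dict[tuple[str, str], np.ndarray] | None = None

    def max_rate(self, tests=None) -> float:
        rates = self.rates if tests is None else self.rates.loc[list(tests)]
        return float(rates.max().max())


def _replication(design: SimulationDesign, tests: list[str], alpha: float, child) -> dict:
    rng = np.random.default_rng(child)
    X = simulate_design(design, rng)
    config = TestConfig(
        alpha=alpha,
        train_fraction=design.train_fraction,
        continuity=design.continuity,
        seed=int(child.generate_state(2)[1] & 0x7FFFFFFF),
    )
    try:
        results = run_all_tests(tests, X, config)
    except ValueError as exc:  # all pairs degenerate in this replication
        log.warning("replication skipped (%s) for %s", exc, design.label)
        return {t: (np.nan, np.nan) for t in tests}
    return {t: (float(results[t].reject), results[t].p) for t in tests}


def run_rejection_grid(
    designs: list[SimulationDesign],
    tests: list[str] | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    n_jobs: int = 1,
    collect_pvalues: bool = False,
) -> RejectionTable:
    """Run every design x replication, applying each named test, and return
    rejection proportions.

    ``seed`` overrides the designs' own seeds with a single master seed;
    every replication gets an independent substream derived from (seed,
    design index, replication index).  Replications whose tests cannot be
    computed (all pairs degenerate) are excluded from the denominator.
    """
    tests = list(tests) if tests is not None else list(FOCAL_TESTS)
    unknown = set(tests) - set(valid_test_names())
    if unknown:
        raise KeyError(f"unknown test codes: {sorted(unknown)}")
    labels = [d.label for d in designs]
    if len(set(labels)) != len(labels):
        raise ValueError("design labels must be unique")

    def run_design(d_idx: int, design: SimulationDesign):
        root = np.random.SeedSequence([design.seed if seed is None else seed, d_idx])
        children = root.spawn(design.n_reps)
        if n_jobs != 1:
            from joblib import Parallel, delayed

            reps = Parallel(n_jobs=n_jobs)(
                delayed(_replication)(design, tests, alpha, ch) for ch in children
            )
        else:
            reps = [_replication(design, tests, alpha, ch) for ch in children]
        return reps

    rates = pd.DataFrame(index=tests, columns=labels, dtype=float)
    counts = pd.DataFrame(index=tests, columns=labels, dtype=float)
    pvalues: dict[tuple[str, str], np.ndarray] = {}
    for d_idx, design in enumerate(designs):
        reps = run_design(d_idx, design)
        for t in tests:
            rejects = np.array([r[t][0] for r in reps])
            valid = ~np.isnan(rejects)
            counts.loc[t, design.label] = int(valid.sum())
            rates.loc[t, design.label] = float(rejects[valid].mean()) if valid.any() else np.nan
            if collect_pvalues:
                pvalues[(design.label, t)] = np.array([r[t][1] for r in reps])
    return RejectionTable(
        rates=rates,
        counts=counts,
        alpha=alpha,
        seed=seed,
        pvalues=pvalues if collect_pvalues else None,
    )


def pvalue_diagnostics(pvalues: np.ndarray, test: str = "", scenario: str = "") -> pd.DataFrame:
    """Schweder-Spjotvoll series: sorted p-values with ranks.

    Under a uniform null the points lie on the diagonal ``rank / (n + 1)``;
    points above the diagonal indicate supra-uniform p-values, as expected
    under monotone homogeneity with non-flat response functions.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("at least one p-value is required")
    n = p.size
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "p": p,
            "uniform_reference": np.arange(1, n + 1) / (n + 1),
            "test": test,
            "scenario": scenario,
        }
    )


def summarize_binomial_dominance(table: RejectionTable, alpha: float | None = None) -> pd.DataFrame:
    """Compare rejection counts across design cells with the binomial
    reference at the nominal level.

    For each test the empirical cumulative distribution of per-cell
    rejection counts is compared pointwise with the binomial(n_reps, alpha)
    CDF; dominance holds when the empirical CDF is at least the binomial CDF
    everywhere, i.e. rejections are stochastically smaller than nominal.
    """
    from scipy.stats import binom

    alpha = table.alpha if alpha is None else alpha
    rows = []
    for t in table.rates.index:
        rates = table.rates.loc[t].to_numpy(dtype=float)
        ns = table.counts.loc[t].to_numpy(dtype=float)
        ok = ~np.isnan(rates)
        rates, ns = rates[ok], ns[ok]
        if len(set(ns.astype(int))) != 1:
            raise ValueError("dominance summary requires equal replication counts per cell")
        n = int(ns[0])
        k_counts = np.rint(rates * n).astype(int)
        grid = np.arange(n + 1)
        emp_cdf = (k_counts[:, None] <= grid[None, :]).mean(axis=0)
        ref_cdf = binom.cdf(grid, n, alpha)
        margin = float((emp_cdf - ref_cdf).min())
        rows.append(
            {
                "test": t,
                "n_cells": len(k_counts),
                "n_reps": n,
                "max_rate": float(rates.max()),
                "dominance_holds": bool(margin >= -1e-12),
                "min_cdf_margin": margin,
            }
        )
    return pd.DataFrame(rows).set_index("test")


def random_unidimensional_cases(
    n_cases: int = 20,
    n_reps: int = 50,
    seed: int = 0,
    J_range: tuple[int, int] = (3, 30),
    N_range: tuple[int, int] = (250, 2500),
    a_range: tuple[float, float] = (0.5, 2.0),
    b_range: tuple[float, float] = (-1.0, 1.0),
    continuity: bool = True,
) -> list[SimulationDesign]:
    """Unidimensional parameter cases with J, N, discriminations, and
    intercepts drawn uniformly; parameters are drawn once per case and held
    fixed across its replications."""
    rng = np.random.default_rng(seed)
    designs = []
    for c in range(n_cases):
        J = int(rng.integers(J_range[0], J_range[1] + 1))
        N = int(rng.integers(N_range[0], N_range[1] + 1))
        base = SimulationDesign(
            J=J,
            N=N,
            scenario="dim1",
            random_params=True,
            a_range=a_range,
            b_range=b_range,
            n_reps=n_reps,
            seed=seed,
            continuity=continuity,
            label=f"case{c + 1}:J={J},N={N}",
        )
        params = make_parameters(base, rng)
        designs.append(replace(base, random_params=False, params=params))
    return designs


def _dim0_corner(n_reps=1000, seed=0, continuity=True):
    return [
        SimulationDesign(J=J, N=N, scenario="dim0", n_reps=n_reps, seed=seed, continuity=continuity)
        for J in (3, 4, 5)
        for N in (250, 500)
    ]


def _dim1_grid(n_reps=100, seed=0, continuity=True):
    return [
        SimulationDesign(
            J=J, N=N, scenario="dim1", a=1.0, b=0.0, n_reps=n_reps, seed=seed, continuity=continuity
        )
        for J in (3, 4, 5, 6, 7, 10)
        for N in (250, 500, 1000)
    ]


def _power_medium(n_reps=100, seed=0, continuity=False):
    return [
        SimulationDesign(
            J=J, N=500, scenario="dim2", a=1.7, b=0.0, n_reps=n_reps, seed=seed, continuity=continuity
        )
        for J in (10, 20, 30)
    ]


def _three_scenarios(n_reps=200, seed=0, continuity=True):
    return [
        SimulationDesign(
            J=10, N=1000, scenario=s, a=1.0, b=0.0, n_reps=n_reps, seed=seed, continuity=continuity
        )
        for s in ("dim0", "dim1", "dim2")
    ]


#: Named design presets.  The "-small" variants keep replication counts low
#: enough for quick runs; "table1-full" mirrors the 1000-replication scale.
PRESETS = {
    "dim0-corner": _dim0_corner,
    "dim1-grid": _dim1_grid,
    "dim1-random": random_unidimensional_cases,
    "power-medium": _power_medium,
    "table1-small": _three_scenarios,
    "table1-full": lambda seed=0, continuity=True: _three_scenarios(1000, seed, continuity),
}


def preset_designs(name: str, **kwargs) -> list[SimulationDesign]:
    """Instantiate one of the named design presets."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**kwargs)


# ---------------------------------------------------------------------------
# One-call study runners for the headline simulation studies.


def study_type1_dim0(n_reps: int = 1000, seed: int = 0, n_jobs: int = 1) -> RejectionTable:
    """Type I error under the zero-dimensional model at the small-J /
    small-N corner (J in {3,4,5}, N in {250,500}), continuity on."""
    designs = _dim0_corner(n_reps=n_reps, continuity=True)
    return run_rejection_grid(designs, list(FOCAL_TESTS), alpha=0.05, seed=seed, n_jobs=n_jobs)


def study_type1_dim1_grid(n_reps: int = 100, seed: int = 0, n_jobs: int = 1) -> RejectionTable:
    """Type I error under the unidimensional model with discriminations 1
    and intercepts 0 over J in {3..7,10} x N in {250,500,1000}."""
    designs = _dim1_grid(n_reps=n_reps, continuity=True)
    return run_rejection_grid(designs, list(FOCAL_TESTS), alpha=0.05, seed=seed, n_jobs=n_jobs)


def study_type1_dim1_random(
    n_cases: int = 20, n_reps: int = 50, seed: int = 0, n_jobs: int = 1
) -> RejectionTable:
    """Type I error across randomly drawn unidimensional parameter cases
    (J, N, discriminations, intercepts uniform), continuity on."""
    designs = random_unidimensional_cases(n_cases=n_cases, n_reps=n_reps, seed=seed)
    return run_rejection_grid(designs, list(FOCAL_TESTS), alpha=0.05, seed=seed, n_jobs=n_jobs)


def study_power_medium(n_reps: int = 100, seed: int = 0, n_jobs: int = 1) -> RejectionTable:
    """Power against the two-dimensional alternative with medium (1.7)
    discriminations, J in {10,20,30}, N = 500, continuity off."""
    designs = _power_medium(n_reps=n_reps, continuity=False)
    return run_rejection_grid(designs, list(FOCAL_TESTS), alpha=0.05, seed=seed, n_jobs=n_jobs)
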