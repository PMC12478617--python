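"""Multidimensional two-parameter-logistic response simulator.

Binary responses are generated from a compensatory two-dimensional logistic
model: P(X_j = 1 | theta) = logistic(a_j1 theta1 + a_j2 theta2 + b_j), with
theta drawn from a bivariate standard normal with correlation 0.  Note the
intercept parametrization (no 1.7 scaling constant, no a (theta - b)
difficulty form).

Three dimensionality scenarios drive the experiments:

* dim0 -- all discriminations zero: items are i.i.d. Bernoulli(logistic(b)),
  a degenerate unidimensional null;
* dim1 -- every item loads on dimension 1 only: the monotone homogeneity
  null with non-flat response functions;
* dim2 -- items split evenly over the two uncorrelated dimensions: the
  multidimensional alternative the tests are meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit

from .data import ItemResponseMatrix

__all__ = [
    "Scenario",
    "ItemParameters",
    "SimulationDesign",
    "scenario_loadings",
    "make_parameters",
    "response_probability",
    "generate_responses",
    "simulate_design",
]

Scenario = Literal["dim0", "dim1", "dim2"]


def scenario_loadings(J: int, scenario: Scenario) -> np.ndarray:
    """Dimension assignment per item: 0 = no loading, 1 or 2 = the loading
    dimension.  In the two-dimensional scenario the items are split evenly,
    dimension 1 taking the extra item when J is odd."""
    if J < 3:
        raise ValueError("at least 3 items are required")
    if scenario == "dim0":
        return np.zeros(J, dtype=int)
    if scenario == "dim1":
        return np.ones(J, dtype=int)
    if scenario == "dim2":
        if J < 4:
            raise ValueError("a two-dimensional design needs at least 4 items")
        J1 = (J + 1) // 2
        return np.array([1] * J1 + [2] * (J - J1))
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class ItemParameters:
    """Discriminations on the two dimensions and intercepts, one per item."""

    a1: np.ndarray
    a2: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a1 = np.asarray(self.a1, dtype=float)
        a2 = np.asarray(self.a2, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if not (a1.shape == a2.shape == b.shape) or a1.ndim != 1:
            raise ValueError("a1, a2, b must be equal-length 1-D arrays")
        if not np.isfinite(np.concatenate([a1, a2, b])).all():
            raise ValueError("item parameters must be finite")
        for name, arr in (("a1", a1), ("a2", a2), ("b", b)):
            object.__setattr__(self, name, arr)

    @property
    def n_items(self) -> int:
        return len(self.b)


@dataclass(frozen=True)
class SimulationDesign:
    """One simulation scenario: model, size, and test settings.

    ``a`` and ``b`` give the fixed discrimination (on the loading dimension)
    and intercept; with ``random_params`` they are redrawn per replication
    from ``a_range`` and ``b_range`` (uniform).  The default ranges stand in
    for typical low-to-high IRT discriminations and centred intercepts and
    are deliberately configurable.
    """

    J: int
    N: int
    scenario: Scenario
    a: float = 1.0
    b: float = 0.0
    random_params: bool = False
    a_range: tuple[float, float] = (0.5, 2.0)
    b_range: tuple[float, float] = (-1.0, 1.0)
    n_reps: int = 1
    seed: int = 0
    continuity: bool = True
    train_fraction: float = 0.3
    alpha: float = 0.05
    label: str | None = None
    params: ItemParameters | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.J < 3 or self.N < 10 or self.n_reps < 1:
            raise ValueError("design requires J >= 3, N >= 10, n_reps >= 1")
        if self.label is None:
            object.__setattr__(self, "label", f"{self.scenario},J={self.J},N={self.N}")


def make_parameters(design: SimulationDesign, seed: int | np.random.Generator = 0) -> ItemParameters:
    """Item parameters for a design: fixed constants, or uniform draws in
    random mode (discriminations must stay positive for monotonicity)."""
    loadings = scenario_loadings(design.J, design.scenario)
    if design.random_params:
        if design.a_range[0] < 0:
            raise ValueError("discrimination range must be nonnegative (monotone regressions)")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        a_vals = rng.uniform(*design.a_range, size=design.J)
        b = rng.uniform(*design.b_range, size=design.J)
    else:
        if design.a < 0:
            raise ValueError("discrimination must be nonnegative (monotone regressions)")
        a_vals = np.full(design.J, float(design.a))
        b = np.full(design.J, float(design.b))
    a1 = np.where(loadings == 1, a_vals, 0.0)
    a2 = np.where(loadings == 2, a_vals, 0.0)
    return ItemParameters(a1=a1, a2=a2, b=b)


def response_probability(theta: np.ndarray, params: ItemParameters) -> np.ndarray:
    """(n, J) success probabilities for latent positions theta (n, 2)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    return expit(theta[:, 0:1] * params.a1 + theta[:, 1:2] * params.a2 + params.b)


def generate_responses(
    params: ItemParameters, N: int, seed: int | np.random.Generator = 0
) -> ItemResponseMatrix:
    """Draw N subjects (theta bivariate standard normal, correlation 0) and
    independent Bernoulli responses per item."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.standard_normal((N, 2))
    probs = response_probability(theta, params)
    return ItemResponseMatrix((rng.random((N, params.n_items)) < probs).astype(np.int8))


def simulate_design(design: SimulationDesign, rng: np.random.Generator | None = None) -> ItemResponseMatrix:
    """One response matrix from a design (parameters redrawn if random)."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    params = design.params
    if params is None:
        params = make_parameters(design, rng)
    elif params.n_items != design.J:
        raise ValueError("fixed parameters do not match the design's number of items")
    return generate_responses(params, design.N, rng)
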