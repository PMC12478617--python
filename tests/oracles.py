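"""Independent brute-force oracles shared across test modules."""

from itertools import combinations

import numpy as np


def oracle_cone_projection(x, sigma):
    """Exhaustive active-set solver for the nonnegative-cone projection.

    Tries every subset of zeroed coordinates, solves the corresponding
    equality-constrained Mahalanobis projection, and keeps the feasible
    candidate with the smallest objective.  Exponential in K; only for
    small test instances.
    """
    x = np.asarray(x, dtype=float)
    W = np.linalg.inv(sigma)
    K = len(x)
    best = None
    for r in range(K + 1):
        for zero_set in combinations(range(K), r):
            free = [k for k in range(K) if k not in zero_set]
            theta = np.zeros(K)
            if free:
                if zero_set:
                    Wff = W[np.ix_(free, free)]
                    Wfz = W[np.ix_(free, list(zero_set))]
                    theta[free] = x[free] + np.linalg.solve(Wff, Wfz @ x[list(zero_set)])
                else:
                    theta[free] = x[free]
            if (theta >= -1e-12).all():
                d = x - theta
                obj = float(d @ W @ d)
                if best is None or obj < best:
                    best = obj
    return best
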