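"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they verify: FVA extrema come from
vertex enumeration of the flux polytope instead of an LP solver,
hypergeometric tails from exact rational enumeration, and BH adjustment
from the literal step-up formula.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product
from math import comb

import numpy as np


def fva_by_vertex_enumeration(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                              tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """FVA extrema of {v : S v = 0, lb <= v <= ub} by enumerating vertices.

    The polytope is bounded (finite bounds), so each coordinate's min/max is
    attained at a vertex; every vertex has at least n - rank(S) coordinates
    fixed at a bound, so trying all such fixings finds them all. Exponential
    in n — only for tiny networks.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    vertices = []
    for free in combinations(range(n), r):
        A = S[:, free]
        if r and np.linalg.matrix_rank(A) < r:
            continue
        fixed = [j for j in range(n) if j not in free]
        for vals in product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.array(vals) if fixed else np.zeros(m)
            if r:
                x_free, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            else:
                x_free = np.zeros(0)
            v = np.empty(n)
            v[list(free)] = x_free
            v[fixed] = vals
            if np.linalg.norm(S @ v, ord=np.inf) > 1e-8:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        raise ValueError("no feasible vertex found")
    V = np.array(vertices)
    return V.min(axis=0), V.max(axis=0)


def exact_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), in exact rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def brute_force_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def percentile_closest_ranks(values, q: float) -> float:
    """Linear interpolation between closest ranks: index = (n-1) * q / 100."""
    xs = np.sort(np.asarray(values, dtype=float))
    pos = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(xs[lo] * (1 - frac) + xs[hi] * frac)


def random_irreversible_network(rng: np.random.Generator,
                                max_reactions: int = 6
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A small random irreversible network (S, lb=0, random finite ub).

    Built as a random bipartite incidence with coefficients in {-2,-1,1,2},
    padded with exchange columns so nonzero flux is usually feasible.
    """
    n_mets = int(rng.integers(1, 4))
    n_internal = int(rng.integers(1, max_reactions - 1))
    cols = []
    for _ in range(n_internal):
        col = np.zeros(n_mets)
        picks = rng.choice(n_mets, size=min(n_mets, int(rng.integers(1, 3))), replace=False)
        for i in picks:
            col[i] = rng.choice([-2, -1, 1, 2])
        cols.append(col)
    # one uptake and one secretion exchange keep the polytope non-trivial
    for sign in (1.0, -1.0):
        col = np.zeros(n_mets)
        col[int(rng.integers(n_mets))] = sign
        cols.append(col)
    S = np.column_stack(cols)[:, :max_reactions]
    n = S.shape[1]
    lb = np.zeros(n)
    ub = rng.uniform(1.0, 10.0, size=n).round(2)
    return S, lb, ub
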