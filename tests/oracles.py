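"""Independent oracles used by the unit and acceptance tests.

These deliberately re-derive quantities through different algorithms and
data structures than the package: persistence by a naive set-based
boundary-matrix reduction, and Kullback–Leibler divergence by numerical
integration (Gauss–Hermite quadrature against density evaluations).
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.stats import multivariate_normal


def brute_force_rips_intervals(coords: np.ndarray, max_dim: int = 2
                               ) -> list[tuple[int, float, float]]:
    """Finite Rips persistence intervals (edge-length scale) by an
    explicit reduction over Python sets; no bitsets, no V matrix."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for d in range(min(max_dim + 1, n - 1) + 1):
        for s in itertools.combinations(range(n), d + 1):
            val = 0.0 if d == 0 else max(
                D[i, j] for i, j in itertools.combinations(s, 2))
            simplices.append((val, len(s), s))
    simplices.sort()
    index = {s: i for i, (_, _, s) in enumerate(simplices)}

    columns: list[set[int]] = []
    low_to_col: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j, (_, _, s) in enumerate(simplices):
        col: set[int] = set()
        if len(s) > 1:
            col = {index[s[:i] + s[i + 1:]] for i in range(len(s))}
        while col:
            low = max(col)
            if low not in low_to_col:
                break
            col = col ^ columns[low_to_col[low]]
        columns.append(col)
        if col:
            low_to_col[max(col)] = j
            pairs.append((max(col), j))

    out = []
    for i, j in pairs:
        birth, k, _ = simplices[i]
        death, _, _ = simplices[j]
        if death > birth and 1 <= k - 1 <= max_dim:
            out.append((k - 1, birth, death))
    return sorted(out)


def kl_by_quadrature(mu_p, sigma_p, mu_q, sigma_q, order: int = 24) -> float:
    """KL(p||q) for bivariate normals as E_p[log p - log q], evaluated by
    tensor-product Gauss–Hermite quadrature over the whitened space of p."""
    mu_p = np.asarray(mu_p, float)
    mu_q = np.asarray(mu_q, float)
    nodes, weights = hermgauss(order)
    z1, z2 = np.meshgrid(nodes, nodes, indexing="ij")
    z = np.sqrt(2.0) * np.column_stack([z1.ravel(), z2.ravel()])
    w = (np.outer(weights, weights) / np.pi).ravel()
    L = np.linalg.cholesky(np.asarray(sigma_p, float))
    x = mu_p + z @ L.T
    log_p = multivariate_normal(mu_p, sigma_p).logpdf(x)
    log_q = multivariate_normal(mu_q, sigma_q).logpdf(x)
    return float(np.sum(w * (log_p - log_q)))


def random_spd_2x2(rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    a = rng.normal(0.0, scale, size=(2, 2))
    return a @ a.T + 0.1 * scale ** 2 * np.eye(2)
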