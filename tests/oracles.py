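"""Independent oracle implementations used only by tests.

These deliberately avoid the package's own code paths: brute-force
enumeration for nonnegative least squares, dense numerical integration for
spectral overlap, and closed forms for the classical tests.
"""

import itertools

import numpy as np


def nnls_bruteforce(e: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exhaustive active-set search: try every support subset, solve the
    unconstrained LS on it, keep the feasible solution with the smallest
    residual. Exact for full-column-rank E."""
    k = e.shape[1]
    best_r, best_x = np.inf, np.zeros(k)
    for bits in itertools.product((0, 1), repeat=k):
        idx = [i for i in range(k) if bits[i]]
        x = np.zeros(k)
        if idx:
            sol, *_ = np.linalg.lstsq(e[:, idx], y, rcond=None)
            if (sol < -1e-9).any():
                continue
            x[idx] = np.clip(sol, 0.0, None)
        r = np.linalg.norm(e @ x - y)
        if r < best_r - 1e-12:
            best_r, best_x = r, x
    return best_x


def gaussian_cosine_continuous(delta_nm: float, width_nm: float) -> float:
    """Cosine similarity of two unit-height Gaussians a distance apart,
    evaluated by dense numerical integration."""
    x = np.linspace(-2000.0, 2000.0, 400001)
    a = np.exp(-(x**2) / (2 * width_nm**2))
    b = np.exp(-((x - delta_nm) ** 2) / (2 * width_nm**2))
    return float(np.trapezoid(a * b, x) / np.sqrt(np.trapezoid(a * a, x) * np.trapezoid(b * b, x)))


def chi2_2x2_closed_form(table: np.ndarray) -> float:
    """N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def kruskal_wallis_rank_form(groups: list[np.ndarray]) -> float:
    """12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    # average ties
    for v in np.unique(pooled):
        sel = pooled == v
        ranks[sel] = ranks[sel].mean()
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    return 12.0 / (n * (n + 1)) * h
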