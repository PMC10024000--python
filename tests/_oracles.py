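"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: dense-covariance
Gaussian conditioning for the Kalman smoother, a from-scratch
Fritsch-Carlson Hermite interpolant for PCHIP, and exhaustive-search IDW.
"""

from __future__ import annotations

import numpy as np


def dense_conditioning(values: np.ndarray, a: float, b: float, r: float,
                       mu0: float, p0: float) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean/variance of every latent AR(1) state by direct
    Gaussian conditioning on the observed entries (NaN = missing).

    Builds the full joint covariance of (x_1..x_n) from the recursion
    x_t = a x_{t-1} + b u_t with x_1 ~ N(mu0, p0), adds measurement noise on
    the observed coordinates, and conditions.  O(n^3); for n <= 50 only.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = np.empty(n)
    var = np.empty(n)
    mean[0], var[0] = mu0, p0
    for t in range(1, n):
        mean[t] = a * mean[t - 1]
        var[t] = a * a * var[t - 1] + b * b
    cov = np.zeros((n, n))
    for s in range(n):
        cov[s, s] = var[s]
        for t in range(s + 1, n):
            cov[s, t] = cov[t, s] = a ** (t - s) * var[s]
    obs = ~np.isnan(values)
    syy = cov[np.ix_(obs, obs)] + r * np.eye(int(obs.sum()))
    sxy = cov[:, obs]
    resid = values[obs] - mean[obs]
    post_mean = mean + sxy @ np.linalg.solve(syy, resid)
    post_var = np.diag(cov) - np.einsum(
        "ij,ji->i", sxy, np.linalg.solve(syy, sxy.T)
    )
    return post_mean, post_var


def fritsch_carlson_derivatives(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Knot derivatives of the shape-preserving cubic Hermite interpolant.

    Interior knots: zero where the secant slopes change sign or vanish,
    otherwise the weighted harmonic mean of the two slopes with weights
    w1 = 2 h_k + h_{k-1}, w2 = h_k + 2 h_{k-1}.  End knots: the one-sided
    three-point estimate, clipped to preserve shape.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h = np.diff(x)
    m = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)
    if n == 2:
        return np.array([m[0], m[0]])
    for k in range(1, n - 1):
        if m[k - 1] * m[k] <= 0:
            d[k] = 0.0
        else:
            w1 = 2 * h[k] + h[k - 1]
            w2 = h[k] + 2 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / m[k - 1] + w2 / m[k])

    def edge(h0, h1, m0, m1):
        val = ((2 * h0 + h1) * m0 - h0 * m1) / (h0 + h1)
        if np.sign(val) != np.sign(m0):
            return 0.0
        if np.sign(m0) != np.sign(m1) and abs(val) > 3 * abs(m0):
            return 3 * m0
        return val

    d[0] = edge(h[0], h[1], m[0], m[1])
    d[-1] = edge(h[-1], h[-2], m[-1], m[-2])
    return d


def hermite_eval(x: np.ndarray, y: np.ndarray, d: np.ndarray,
                 xq: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise cubic Hermite interpolant at query points."""
    x = np.asarray(x, dtype=float)
    xq = np.asarray(xq, dtype=float)
    out = np.empty(len(xq))
    for i, q in enumerate(xq):
        k = int(np.clip(np.searchsorted(x, q, side="right") - 1, 0, len(x) - 2))
        h = x[k + 1] - x[k]
        t = (q - x[k]) / h
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[i] = (h00 * y[k] + h10 * h * d[k]
                  + h01 * y[k + 1] + h11 * h * d[k + 1])
    return out


def pchip_oracle(x, y, xq) -> np.ndarray:
    """Shape-preserving interpolant values via the hand-coded route."""
    d = fritsch_carlson_derivatives(x, y)
    return hermite_eval(np.asarray(x, float), np.asarray(y, float), d, xq)


def idw_oracle(lat, lon, cell_lat, cell_lon, cell_values,
               n_neighbors: int = 4, power: float = 1.0) -> np.ndarray:
    """Exhaustive-search IDW: sort all cells by distance, combine the
    nearest ``n_neighbors`` with weights 1/d^power."""
    d = np.sqrt((cell_lat - lat) ** 2 + (cell_lon - lon) ** 2)
    order = np.lexsort((cell_lon, cell_lat, d))[:n_neighbors]
    dn = d[order]
    if dn[0] == 0:
        return np.asarray(cell_values)[:, order[0]]
    w = dn ** (-power)
    w = w / w.sum()
    return np.asarray(cell_values)[:, order] @ w


def simulate_ssm(n: int, a: float, b: float, seed: int,
                 missing_rate: float = 0.1) -> np.ndarray:
    """Draw one series from the AR(1)-plus-noise model with random gaps."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, b / np.sqrt(1 - a * a))
    shocks = rng.normal(0.0, b, n)
    for t in range(1, n):
        x[t] = a * x[t - 1] + shocks[t]
    y = x + rng.normal(0.0, 1.0, n)
    y[rng.uniform(size=n) < missing_rate] = np.nan
    return y
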