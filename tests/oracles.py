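"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (explicit loops, DFT
definitions, Floyd-Warshall, shortest-path enumeration) and deliberately
shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# WPLI

def analytic_signal_dft(x: np.ndarray) -> np.ndarray:
    """Analytic signal from the DFT definition (zero negative frequencies)."""
    n = len(x)
    spec = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1:n // 2] = 2.0
    else:
        h[1:(n + 1) // 2] = 2.0
    return np.fft.ifft(spec * h)


def wpli_brute(x: np.ndarray, y: np.ndarray) -> float:
    """WPLI by an explicit loop over time samples (5% edge trim per side)."""
    ax = analytic_signal_dft(np.asarray(x, dtype=float))
    ay = analytic_signal_dft(np.asarray(y, dtype=float))
    n = len(x)
    k = int(math.floor(0.05 * n))
    num = 0.0
    den = 0.0
    count = 0
    for t in range(k, n - k):
        im = (ax[t] * np.conj(ay[t])).imag
        num += im
        den += abs(im)
        count += 1
    if den / count < 1e-12:
        return 0.0
    return abs(num / count) / (den / count)


# ---------------------------------------------------------------------------
# graph metrics

def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def degree_brute(a: np.ndarray) -> np.ndarray:
    return np.array([int(sum(a[i])) for i in range(a.shape[0])])


def clustering_brute(a: np.ndarray) -> np.ndarray:
    """C_i by enumerating neighbour pairs and counting their edges."""
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        edges = sum(1 for u, v in itertools.combinations(nbrs, 2) if a[u, v])
        out[i] = 2.0 * edges / (k * (k - 1))
    return out


def global_efficiency_brute(a: np.ndarray) -> tuple[float, np.ndarray]:
    n = a.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    d = floyd_warshall(a)
    per = np.zeros(n)
    for i in range(n):
        per[i] = sum(1.0 / d[i, j] for j in range(n)
                     if j != i and np.isfinite(d[i, j])) / (n - 1)
    return float(per.mean()), per


def local_efficiency_brute(a: np.ndarray) -> tuple[float, np.ndarray]:
    n = a.shape[0]
    per = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        per[i] = global_efficiency_brute(sub)[0]
    return float(per.mean()), per


def betweenness_brute(a: np.ndarray) -> np.ndarray:
    """Normalized betweenness by explicit shortest-path counting.

    For every ordered pair (s, t), sigma(s, t) counts shortest paths via
    dynamic programming over the Floyd-Warshall distances; node v gains
    sigma(s, v) * sigma(v, t) / sigma(s, t) whenever it lies on a
    shortest s-t path.  Normalization: (N-1)(N-2)/2 for undirected graphs.
    """
    n = a.shape[0]
    d = floyd_warshall(a)

    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(range(n), key=lambda v: d[s, v])
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            sigma[s, v] = sum(sigma[s, u] for u in range(n)
                              if a[u, v] and d[s, u] + 1 == d[s, v])

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


# ---------------------------------------------------------------------------
# statistics

def mannwhitney_u_brute(x, y) -> float:
    """U statistic for the first sample, by direct pair counting."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    obs = mannwhitney_u_brute(x, y)
    mu = n1 * len(y) / 2.0
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        group1 = [pooled[i] for i in combo]
        group2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = mannwhitney_u_brute(group1, group2)
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
        total += 1
    return extreme / total
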