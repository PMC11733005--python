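"""Independent brute-force transcriptions of the feature definitions and
model quantities, written from their verbal definitions with plain loops.
Used only to cross-check the package implementation on small inputs.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def oracle_crossing_points(x) -> int:
    x = list(map(float, x))
    m = statistics.median(x)
    below = [xi <= m for xi in x]
    return sum(1 for i in range(len(x) - 1) if below[i] != below[i + 1])


def oracle_flat_spots(x) -> int:
    x = list(map(float, x))
    lo, hi = min(x), max(x)
    if hi == lo:
        return len(x)
    bins = []
    for xi in x:
        b = int((xi - lo) / (hi - lo) * 10)
        bins.append(min(b, 9))
    best, run = 1, 1
    for i in range(1, len(bins)):
        run = run + 1 if bins[i] == bins[i - 1] else 1
        best = max(best, run)
    return best


def oracle_spectral_entropy(x) -> float:
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    xd = [v - mean for v in x]
    m = n // 2
    powers = []
    for j in range(1, m + 1):
        re = sum(xd[t] * math.cos(2 * math.pi * j * t / n) for t in range(n))
        im = sum(xd[t] * math.sin(2 * math.pi * j * t / n) for t in range(n))
        powers.append(re * re + im * im)
    total = sum(powers)
    h = 0.0
    for p in powers:
        q = p / total
        if q > 0:
            h -= q * math.log(q)
    return h / math.log(m)


def oracle_lumpiness(x, w=10, standardize=True) -> float:
    x = [float(v) for v in x]
    if standardize:
        mu = statistics.mean(x)
        sd = statistics.stdev(x)
        if sd == 0:
            return 0.0
        x = [(v - mu) / sd for v in x]
    k = len(x) // w
    variances = [statistics.variance(x[i * w : (i + 1) * w]) for i in range(k)]
    return statistics.variance(variances)


def oracle_stability(x, w=10, standardize=True) -> float:
    x = [float(v) for v in x]
    if standardize:
        mu = statistics.mean(x)
        sd = statistics.stdev(x)
        if sd == 0:
            return 0.0
        x = [(v - mu) / sd for v in x]
    k = len(x) // w
    means = [statistics.mean(x[i * w : (i + 1) * w]) for i in range(k)]
    return statistics.variance(means)


def oracle_trend_strength(trend, remainder) -> float:
    vt = statistics.variance(list(map(float, trend)))
    vr = statistics.variance(list(map(float, remainder)))
    if vt + vr == 0:
        return 0.0
    return min(max(1.0 - vr / (vr + vt), 0.0), 1.0)


def gram_schmidt_poly(n: int, degree: int = 2) -> list[list[float]]:
    """Orthonormal polynomial columns of the index, by explicit Gram-Schmidt."""
    t = [float(i + 1) for i in range(n)]
    cols = [[ti**d for ti in t] for d in range(degree + 1)]
    out: list[list[float]] = []
    for c in cols:
        v = list(c)
        for u in out:
            proj = sum(a * b for a, b in zip(u, c))
            v = [vi - proj * ui for vi, ui in zip(v, u)]
        norm = math.sqrt(sum(vi * vi for vi in v))
        v = [vi / norm for vi in v]
        # orient positively with the raw power
        if sum(a * b for a, b in zip(v, c)) < 0:
            v = [-vi for vi in v]
        out.append(v)
    return out


def oracle_linearity_curvature(trend) -> tuple[float, float]:
    trend = list(map(float, trend))
    basis = gram_schmidt_poly(len(trend), 2)
    lin = sum(a * b for a, b in zip(basis[1], trend))
    curv = sum(a * b for a, b in zip(basis[2], trend))
    return lin, curv


def oracle_hurst(x) -> float:
    """Grid-plus-refine minimization of the Whittle objective, written with
    an explicit DFT."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    xd = [v - mean for v in x]
    m = (n - 1) // 2
    pg, freqs = [], []
    for j in range(1, m + 1):
        w = 2 * math.pi * j / n
        re = sum(xd[t] * math.cos(w * t) for t in range(n))
        im = sum(xd[t] * math.sin(w * t) for t in range(n))
        pg.append((re * re + im * im) / (2 * math.pi * n))
        freqs.append(w)

    def q(d):
        gs = [(2 * math.sin(w / 2)) ** (-2 * d) for w in freqs]
        return math.log(sum(p / g for p, g in zip(pg, gs)) / m) + sum(
            math.log(g) for g in gs
        ) / m

    lo, hi = -0.499, 0.499
    for _ in range(200):
        third = (hi - lo) / 3
        if q(lo + third) < q(hi - third):
            hi = hi - third
        else:
            lo = lo + third
    d = (lo + hi) / 2
    return min(max(0.5 + d, 0.0), 1.0)


def oracle_nonlinearity(x, lags=1) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    xs = (x - x.mean()) / x.std(ddof=1)
    y = xs[lags:]
    L = np.column_stack([xs[lags - k - 1 : n - k - 1] for k in range(lags)])
    ones = np.ones((y.size, 1))
    X0 = np.hstack([ones, L])
    powers = [L**2, L**3]
    X1 = np.hstack([X0] + powers)

    def sse(D):
        c = np.linalg.pinv(D.T @ D) @ D.T @ y
        r = y - D @ c
        return float(r @ r)

    s0, s1 = sse(X0), sse(X1)
    stat = y.size * max(s0 - s1, 0.0) / s0
    return 10.0 * stat / n


def oracle_cumlogit_loglik(theta, beta, X, y, categories) -> float:
    """Literal per-patient sum of log category probabilities."""
    total = 0.0
    cat_list = list(categories)
    K = len(theta)
    for xi, yi in zip(X, y):
        z = sum(b * v for b, v in zip(beta, xi))
        gammas = [1.0] + [1.0 / (1.0 + math.exp(-(t + z))) for t in theta] + [0.0]
        k = cat_list.index(yi)
        pi = gammas[k] - gammas[k + 1]
        total += math.log(pi)
    return total


def oracle_spearman(x, y) -> float:
    """Rank (average ties) then Pearson."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
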