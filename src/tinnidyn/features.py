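"""Ten time-series features per diary question, 100 predictors per patient.

Each feature operates on the observed values of one question in temporal
order with gaps closed (observed days concatenated and treated as equally
spaced); missing days are never imputed. The features:

========================  =====================================================
crossing-points           number of median crossings
curvature                 quadratic coefficient of an orthonormal polynomial
                          regression on the loess trend (convex > 0)
entropy                   normalized Shannon spectral entropy (1 = white-noise
                          like, near 0 = one dominant frequency/trend)
flat-spots                longest run within one of ten equal-width value bins
hurst                     long-memory index, 0.5 + fractional-differencing
                          order, clamped to [0, 1]
linearity                 linear coefficient of the same orthonormal
                          polynomial regression on the trend (declining < 0)
lumpiness                 variance of the variances of non-overlapping
                          10-point windows
nonlinearity              Terasvirta-style neural-network test statistic,
                          scaled as 10 * stat / n
stability                 variance of the means of non-overlapping 10-point
                          windows
trend                     trend strength 1 - Var(remainder) /
                          (Var(remainder) + Var(trend))
========================  =====================================================

Features whose length preconditions fail on a short series yield NaN
sentinels; the modelling stage refuses incomplete vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize

from .diary import QUESTION_CODES, PatientDiary

logger = logging.getLogger(__name__)

#: Canonical feature names, in fixed (alphabetical) order.
FEATURE_NAMES: tuple[str, ...] = (
    "crossing-points",
    "curvature",
    "entropy",
    "flat-spots",
    "hurst",
    "linearity",
    "lumpiness",
    "nonlinearity",
    "stability",
    "trend",
)

#: Window width for lumpiness / stability.
WINDOW = 10

#: All 100 predictor names "<question>_<feature>" in canonical order.
PREDICTOR_NAMES: tuple[str, ...] = tuple(
    f"{q}_{f}" for q in QUESTION_CODES for f in FEATURE_NAMES
)


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series values must be finite")
    return x


def crossing_points(x) -> int:
    """Number of times the series crosses its median."""
    x = _as_series(x)
    if x.size < 2:
        raise ValueError("crossing_points requires n >= 2")
    b = x <= np.median(x)
    return int(np.sum(b[1:] != b[:-1]))


def flat_spots(x) -> int:
    """Longest run of consecutive points in one of ten equal-width bins.

    A zero-range (constant) series sits in a single bin, so the run is the
    whole series: returns n.
    """
    x = _as_series(x)
    n = x.size
    if n < 2:
        raise ValueError("flat_spots requires n >= 2")
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return n
    bins = np.minimum((10 * (x - lo) / (hi - lo)).astype(int), 9)
    best = run = 1
    for i in range(1, n):
        run = run + 1 if bins[i] == bins[i - 1] else 1
        best = max(best, run)
    return best


def spectral_entropy(x) -> float:
    """Shannon entropy of the normalized periodogram, scaled to [0, 1].

    The series is demeaned; the periodogram is evaluated at the floor(n/2)
    positive Fourier frequencies and normalized to a probability
    distribution. Constant series are rejected (entropy undefined).
    """
    x = _as_series(x)
    n = x.size
    if n < 8:
        raise ValueError("spectral_entropy requires n >= 8")
    if x.max() - x.min() == 0:
        raise ValueError("spectral_entropy undefined for a constant series")
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    spec = spec[1 : n // 2 + 1]
    p = spec / spec.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(n // 2))


def _whittle_objective(d: float, pgram: np.ndarray, freqs: np.ndarray) -> float:
    g = (2.0 * np.sin(freqs / 2.0)) ** (-2.0 * d)
    return float(np.log(np.mean(pgram / g)) + np.mean(np.log(g)))


def hurst(x, method: str = "whittle") -> float:
    """Long-memory index in [0, 1]; 0.5 is memoryless.

    Default: 0.5 + d, with d the Whittle (frequency-domain maximum
    likelihood) estimate of the fractional-differencing order of the
    demeaned series, d constrained to [-0.5, 0.5]; the result is clamped to
    [0, 1]. ``method="rs"`` gives a rescaled-range estimate for
    cross-checking.
    """
    x = _as_series(x)
    n = x.size
    if n < 20:
        raise ValueError("hurst requires n >= 20")
    if x.max() - x.min() == 0:
        return 0.5
    if method == "rs":
        return _hurst_rs(x)
    if method != "whittle":
        raise ValueError(f"unknown hurst method {method!r}")
    xd = x - x.mean()
    m = (n - 1) // 2
    j = np.arange(1, m + 1)
    freqs = 2.0 * np.pi * j / n
    pgram = np.abs(np.fft.fft(xd)[1 : m + 1]) ** 2 / (2.0 * np.pi * n)
    res = optimize.minimize_scalar(
        _whittle_objective,
        bounds=(-0.499, 0.499),
        args=(pgram, freqs),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.clip(0.5 + res.x, 0.0, 1.0))


def _hurst_rs(x: np.ndarray) -> float:
    # classical rescaled-range slope over dyadic block sizes
    n = x.size
    sizes = [s for s in (10, 20, 40, 80, 160) if s <= n]
    if len(sizes) < 2:
        sizes = [max(10, n // 4), n]
    logs, logrs = [], []
    for s in sizes:
        rs_vals = []
        for start in range(0, n - s + 1, s):
            seg = x[start : start + s]
            dev = np.cumsum(seg - seg.mean())
            r = dev.max() - dev.min()
            sd = seg.std(ddof=1)
            if sd > 0:
                rs_vals.append(r / sd)
        if rs_vals:
            logs.append(np.log(s))
            logrs.append(np.log(np.mean(rs_vals)))
    slope = np.polyfit(logs, logrs, 1)[0]
    return float(np.clip(slope, 0.0, 1.0))


def _windowed(x: np.ndarray, w: int, standardize: bool) -> np.ndarray | None:
    n = x.size
    k = n // w
    if k < 2:
        return None
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            return np.zeros((k, w))
        x = (x - x.mean()) / sd
    return x[: k * w].reshape(k, w)


def lumpiness(x, w: int = WINDOW, standardize: bool = True) -> float:
    """Sample variance of the per-window sample variances.

    Windows are non-overlapping with a trailing partial window discarded;
    the series is optionally standardized to mean 0, sd 1 first (a constant
    series then yields 0 by convention). Returns NaN when fewer than two
    complete windows exist.
    """
    x = _as_series(x)
    tiles = _windowed(x, w, standardize)
    if tiles is None:
        return float("nan")
    return float(np.var(tiles.var(axis=1, ddof=1), ddof=1))


def stability(x, w: int = WINDOW, standardize: bool = True) -> float:
    """Sample variance of the per-window means; conventions as lumpiness."""
    x = _as_series(x)
    tiles = _windowed(x, w, standardize)
    if tiles is None:
        return float("nan")
    return float(np.var(tiles.mean(axis=1), ddof=1))


@lru_cache(maxsize=None)
def _loess_matrix(n: int, span: float, degree: int) -> np.ndarray:
    """Linear smoother matrix of a loess fit on the index 0..n-1.

    Local polynomial regression of the given degree with tricube weights
    over the ceil(span*n) nearest neighbours of each point. The fitted
    trend is linear in the data, so the whole smoother is one matrix.
    """
    q = min(max(int(np.ceil(span * n)), degree + 2), n)
    t = np.arange(n, dtype=float)
    L = np.zeros((n, n))
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        w = (1.0 - np.minimum(d[idx] / max(dmax, 1e-12), 1.0) ** 3) ** 3
        A = np.vander(t[idx] - t[i], degree + 1, increasing=True)
        AtW = A.T * w
        G = AtW @ A
        try:
            row = np.linalg.solve(G, AtW)[0]
        except np.linalg.LinAlgError:
            row = (np.linalg.pinv(G) @ AtW)[0]
        L[i, idx] = row
    return L


@dataclass(frozen=True)
class TrendDecomposition:
    """Additive trend/remainder split of a series (seasonal part is 0).

    Daily diary data has no modelled sub-daily periodicity, so the
    decomposition is trend + remainder = x exactly.
    """

    trend: np.ndarray
    remainder: np.ndarray

    @property
    def var_trend(self) -> float:
        return float(np.var(self.trend, ddof=1))

    @property
    def var_remainder(self) -> float:
        return float(np.var(self.remainder, ddof=1))


def decompose_trend(x, span: float = 0.75, degree: int = 2) -> TrendDecomposition:
    """Loess trend on the observation index; remainder = x - trend."""
    x = _as_series(x)
    if x.size < 10:
        raise ValueError("decompose_trend requires n >= 10")
    trend = _loess_matrix(x.size, span, degree) @ x
    return TrendDecomposition(trend=trend, remainder=x - trend)


def trend_strength(d: TrendDecomposition) -> float:
    """1 - Var(remainder) / (Var(remainder) + Var(trend)), clamped to [0, 1].

    Returns 0 when both variances vanish (constant series).
    """
    vr, vt = d.var_remainder, d.var_trend
    if vr + vt == 0:
        return 0.0
    return float(np.clip(1.0 - vr / (vr + vt), 0.0, 1.0))


@lru_cache(maxsize=None)
def _orthonormal_poly(n: int, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis (columns: const, linear, quadratic...).

    Signs fixed so each column correlates positively with the raw power it
    represents; the linear column is odd and the quadratic column even
    about the series midpoint.
    """
    t = np.arange(1.0, n + 1.0)
    M = np.vander(t, degree + 1, increasing=True)
    Q, R = np.linalg.qr(M)
    s = np.sign(np.diag(R))
    s[s == 0] = 1.0
    return Q * s


def trend_linearity_curvature(d: TrendDecomposition) -> tuple[float, float]:
    """Degree-1 and degree-2 coefficients of an orthonormal quadratic
    regression of the trend on the time index.

    Negative linearity = declining trend; positive curvature = convex.
    """
    trend = d.trend
    n = trend.size
    if n < 3:
        raise ValueError("trend_linearity_curvature requires n >= 3")
    Q = _orthonormal_poly(n, 2)
    coefs = Q.T @ trend
    return float(coefs[1]), float(coefs[2])


def nonlinearity(x, lags: int = 1) -> float:
    """Terasvirta-style neural-network nonlinearity statistic, 10 * stat / n.

    Regress x_t on its lags, then test whether the quadratic and cubic
    cross-terms of the lags explain the residual variance: the chi-square
    form stat = n_eff * (SSE0 - SSE1) / SSE0 from the auxiliary regression.
    Values near 0 indicate a linear series. Degenerate regressions return 0
    with a logged warning.
    """
    x = _as_series(x)
    n = x.size
    if n < 20:
        raise ValueError("nonlinearity requires n >= 20")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("nonlinearity: constant series, returning 0")
        return 0.0
    xs = (x - x.mean()) / sd
    y = xs[lags:]
    L = np.column_stack([xs[lags - k - 1 : n - k - 1] for k in range(lags)])
    n_eff = y.size

    def _sse(design: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ coef
        return float(r @ r)

    ones = np.ones((n_eff, 1))
    X0 = np.hstack([ones, L])
    # quadratic and cubic cross-terms of the lags
    quad = [L[:, i] * L[:, j] for i in range(lags) for j in range(i, lags)]
    cub = [
        L[:, i] * L[:, j] * L[:, k]
        for i in range(lags)
        for j in range(i, lags)
        for k in range(j, lags)
    ]
    X1 = np.hstack([X0, np.column_stack(quad + cub)])
    sse0, sse1 = _sse(X0), _sse(X1)
    if sse0 <= 0 or not np.isfinite(sse0) or not np.isfinite(sse1):
        logger.warning("nonlinearity: degenerate auxiliary regression, returning 0")
        return 0.0
    stat = n_eff * max(sse0 - sse1, 0.0) / sse0
    return float(10.0 * stat / n)


def extract_features(
    x, *, span: float = 0.75, degree: int = 2, window: int = WINDOW
) -> dict[str, float]:
    """All ten features of one observed series; NaN where preconditions fail."""
    x = _as_series(x)
    n = x.size
    out: dict[str, float] = {f: float("nan") for f in FEATURE_NAMES}
    if n >= 2:
        out["crossing-points"] = float(crossing_points(x))
        out["flat-spots"] = float(flat_spots(x))
    if n >= 8 and x.max() - x.min() > 0:
        out["entropy"] = spectral_entropy(x)
    if n >= 20:
        out["hurst"] = hurst(x)
        out["nonlinearity"] = nonlinearity(x)
    out["lumpiness"] = lumpiness(x, w=window)
    out["stability"] = stability(x, w=window)
    if n >= 10:
        d = decompose_trend(x, span=span, degree=degree)
        out["trend"] = trend_strength(d)
        lin, curv = trend_linearity_curvature(d)
        out["linearity"] = lin
        out["curvature"] = curv
    return out


def extract_all(p: PatientDiary, **kwargs) -> dict[str, float]:
    """100 named features for one patient: "<question>_<feature>".

    Each question's observed (day, value) pairs are taken in day order with
    gaps closed. Features whose preconditions fail carry NaN sentinels; the
    modelling stage accepts only complete vectors.
    """
    out: dict[str, float] = {}
    for q in QUESTION_CODES:
        feats = extract_features(p.values(q), **kwargs)
        for f in FEATURE_NAMES:
            out[f"{q}_{f}"] = feats[f]
    return out


def feature_matrix(
    diaries: list[PatientDiary], **kwargs
) -> tuple[pd.DataFrame, pd.Series]:
    """Patients x 100 feature frame plus per-patient sentinel (NaN) counts."""
    rows = {p.patient_id: extract_all(p, **kwargs) for p in diaries}
    F = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    F = F.reindex(columns=list(PREDICTOR_NAMES))
    F.index.name = "patient_id"
    sentinels = F.isna().sum(axis=1)
    sentinels.name = "n_sentinels"
    return F, sentinels
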