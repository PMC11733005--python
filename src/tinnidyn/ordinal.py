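"""Reversed cumulative-logit (proportional-odds) regression with an
elastic-net penalty, lambda path construction, and nested cross-validation.

Model: with ordered response categories c_1 < ... < c_C and thresholds
theta_2 >= ... >= theta_C,

    P(Y >= c_k | x) = logistic(theta_k + x' beta),   k = 2..C,

so a positive coefficient moves probability mass toward higher (clinically
worse) categories. The fit minimizes

    (1/n) * NLL(theta, beta) + lam * (alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2)

by accelerated proximal gradient descent with backtracking; soft
thresholding produces exact zeros in beta, and the thresholds are kept
ordered through the reparameterization theta_{k+1} = theta_k - exp(delta_k).
Thresholds are never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_ITER = 10_000
TOL_OBJ = 1e-8
TOL_PARAM = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when the proximal-gradient solver fails to converge."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class OrdinalNetFit:
    """One penalized cumulative-logit fit at a single (lambda, alpha)."""

    alpha: float
    lam: float
    beta: np.ndarray
    theta: np.ndarray  # decreasing thresholds for P(Y >= categories[1:])
    categories: np.ndarray  # observed category labels, ascending
    loglik: float  # unpenalized log-likelihood at the solution
    n_obs: int
    n_iter: int = 0
    feature_names: tuple[str, ...] | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    @property
    def aic(self) -> float:
        return aic(self)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _encode_y(y, categories=None) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    if categories is None:
        categories = np.unique(y)
    else:
        categories = np.asarray(categories)
    if categories.size < 2:
        raise ValueError("need at least 2 distinct response categories")
    idx = np.searchsorted(categories, y)
    if np.any(idx >= categories.size) or np.any(categories[idx] != y):
        raise ValueError("response contains labels outside the category set")
    return idx, categories


def _category_probs(theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """n x C matrix of category probabilities."""
    G = _sigmoid(theta[None, :] + z[:, None])  # P(Y >= c_k), k = 2..C
    n, K = G.shape
    Gamma = np.empty((n, K + 2))
    Gamma[:, 0] = 1.0
    Gamma[:, 1 : K + 1] = G
    Gamma[:, K + 1] = 0.0
    return Gamma[:, :-1] - Gamma[:, 1:]


def _loglik_and_score(
    theta: np.ndarray, z: np.ndarray, yi: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, its gradient wrt theta, and wrt z (per observation)."""
    n = z.size
    K = theta.size
    G = _sigmoid(theta[None, :] + z[:, None])
    g = G * (1.0 - G)
    rows = np.arange(n)
    upper = np.where(yi >= 1, G[rows, np.minimum(yi - 1, K - 1)], 1.0)
    lower = np.where(yi <= K - 1, G[rows, np.minimum(yi, K - 1)], 0.0)
    pi = upper - lower
    ll = float(np.sum(np.log(np.clip(pi, 1e-300, None))))
    pi_safe = np.clip(pi, 1e-12, None)
    # theta_j enters pi with + when yi == j+1 and with - when yi == j
    gplus = np.where(yi >= 1, g[rows, np.minimum(yi - 1, K - 1)], 0.0) / pi_safe
    gminus = np.where(yi <= K - 1, g[rows, np.minimum(yi, K - 1)], 0.0) / pi_safe
    grad_theta = np.zeros(K)
    np.add.at(grad_theta, yi[yi >= 1] - 1, gplus[yi >= 1])
    np.subtract.at(grad_theta, yi[yi <= K - 1], gminus[yi <= K - 1])
    score_z = gplus - gminus
    return ll, grad_theta, score_z


def model_loglik(fit: OrdinalNetFit, X, y) -> float:
    """Sum over observations of the log category probability at each y."""
    X = np.asarray(X, dtype=float)
    yi, _ = _encode_y(y, fit.categories)
    if np.any(np.diff(fit.theta) > 0):
        raise ValueError("thresholds must be non-increasing")
    z = X @ fit.beta if X.size else np.zeros(len(yi))
    pi = _category_probs(fit.theta, z)
    p = pi[np.arange(len(yi)), yi]
    if np.any(p <= 0):
        raise ValueError("non-positive category probability (unordered thresholds)")
    return float(np.sum(np.log(p)))


def predict_proba(fit: OrdinalNetFit, X) -> np.ndarray:
    """n x C category probabilities under the fitted model."""
    X = np.asarray(X, dtype=float)
    z = X @ fit.beta if X.size else np.zeros(X.shape[0])
    return _category_probs(fit.theta, z)


def penalized_objective(fit: OrdinalNetFit, X, y) -> float:
    """Mean negative log-likelihood plus the elastic-net penalty on beta."""
    n = len(np.asarray(y))
    pen = fit.lam * (
        fit.alpha * np.abs(fit.beta).sum()
        + 0.5 * (1.0 - fit.alpha) * float(fit.beta @ fit.beta)
    )
    return -model_loglik(fit, X, y) / n + pen


def aic(fit: OrdinalNetFit) -> float:
    """AIC with df = number of nonzero coefficients + number of thresholds."""
    df = fit.n_nonzero + fit.theta.size
    return 2.0 * df - 2.0 * fit.loglik


def mcfadden_r2(loglik_full: float, loglik_null: float) -> float:
    """McFadden pseudo R-squared, 1 - loglik_full / loglik_null."""
    if loglik_null == 0:
        raise ValueError("null log-likelihood must be negative")
    return 1.0 - loglik_full / loglik_null


def _intercept_theta(yi: np.ndarray, n_cat: int) -> np.ndarray:
    """Intercept-only MLE thresholds: empirical cumulative logits.

    Categories with zero count would push thresholds to infinity; all
    counts get +0.5 smoothing in that case so the thresholds stay finite
    and strictly ordered.
    """
    counts = np.bincount(yi, minlength=n_cat).astype(float)
    if np.any(counts == 0):
        counts += 0.5
    tail = np.cumsum(counts[::-1])[::-1] / counts.sum()  # P(Y >= c_k)
    q = tail[1:]
    return np.log(q) - np.log1p(-q)


def intercept_only_fit(y, categories=None) -> OrdinalNetFit:
    """Null (intercept-only) cumulative-logit model."""
    yi, categories = _encode_y(y, categories)
    theta = _intercept_theta(yi, categories.size)
    ll, _, _ = _loglik_and_score(theta, np.zeros(yi.size), yi)
    return OrdinalNetFit(
        alpha=0.5,
        lam=np.inf,
        beta=np.zeros(0),
        theta=theta,
        categories=categories,
        loglik=ll,
        n_obs=yi.size,
    )


def lambda_max(X, y, alpha: float = 0.5) -> float:
    """Smallest penalty that zeroes every coefficient (KKT bound).

    At the intercept-only solution the coefficient block stays at zero iff
    max_j |d(mean NLL)/d(beta_j)| <= alpha * lambda.
    """
    if alpha <= 0:
        raise ValueError("lambda_max requires alpha > 0 (no finite bound for ridge)")
    X = np.asarray(X, dtype=float)
    yi, categories = _encode_y(y)
    theta = _intercept_theta(yi, categories.size)
    _, _, score_z = _loglik_and_score(theta, np.zeros(yi.size), yi)
    grad = -(X.T @ score_z) / yi.size
    return float(np.max(np.abs(grad)) / alpha)


@dataclass(frozen=True)
class LambdaPath:
    """Decreasing 20-value penalty sequence from lambda_max downward."""

    lambdas: np.ndarray
    lambda_max: float
    min_ratio: float


def build_lambda_path(
    X, y, alpha: float = 0.5, n_lambda: int = 20, min_ratio: float = 0.01
) -> LambdaPath:
    lmax = lambda_max(X, y, alpha)
    lambdas = np.geomspace(lmax, lmax * min_ratio, n_lambda)
    return LambdaPath(lambdas=lambdas, lambda_max=lmax, min_ratio=min_ratio)


def _theta_to_params(theta: np.ndarray) -> tuple[float, np.ndarray]:
    gaps = np.maximum(-np.diff(theta), 1e-4)
    return float(np.clip(theta[0], -50.0, 50.0)), np.clip(np.log(gaps), -15.0, 5.0)


def _params_to_theta(a: float, delta: np.ndarray) -> np.ndarray:
    return np.concatenate([[a], a - np.cumsum(np.exp(delta))])


def fit_ordinal_net(
    X,
    y,
    lam: float,
    alpha: float = 0.5,
    *,
    categories=None,
    init: OrdinalNetFit | None = None,
    feature_names=None,
    max_iter: int = MAX_ITER,
    tol_obj: float = TOL_OBJ,
    tol_param: float = TOL_PARAM,
) -> OrdinalNetFit:
    """Fit the penalized cumulative-logit model at one (lambda, alpha).

    Accelerated proximal gradient with backtracking line search; beta is
    soft-thresholded (exact zeros), thresholds stay ordered through the
    exp-gap reparameterization and are unpenalized. ``init`` warm-starts
    from a previous fit on the same design (used along the lambda path).
    """
    X = np.asarray(X, dtype=float)
    yi, categories = _encode_y(y, categories)
    n, p = X.shape if X.ndim == 2 else (X.shape[0], 0)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    K = categories.size - 1

    if init is not None and init.beta.size == p:
        beta = init.beta.copy()
        a, delta = _theta_to_params(init.theta)
    else:
        beta = np.zeros(p)
        a, delta = _theta_to_params(_intercept_theta(yi, categories.size))

    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    def smooth_and_grad(a, delta, beta):
        theta = _params_to_theta(a, delta)
        z = X @ beta if p else np.zeros(n)
        ll, g_theta, score_z = _loglik_and_score(theta, z, yi)
        f = -ll / n + 0.5 * l2 * float(beta @ beta)
        # chain rule: theta_j = a - sum_{l<j} exp(delta_l)
        ga = -np.sum(g_theta) / n
        tail = np.cumsum(g_theta[::-1])[::-1]  # sum_{j>=l} g_theta_j
        gdelta = (np.exp(delta) * tail[1:]) / n if K > 1 else np.zeros(0)
        gbeta = -(X.T @ score_z) / n + l2 * beta if p else np.zeros(0)
        return f, ga, gdelta, gbeta

    def smooth_value(a, delta, beta):
        theta = _params_to_theta(a, delta)
        z = X @ beta if p else np.zeros(n)
        ll, _, _ = _loglik_and_score(theta, z, yi)
        return -ll / n + 0.5 * l2 * float(beta @ beta)

    def full_obj(a, delta, beta):
        return smooth_value(a, delta, beta) + l1 * np.abs(beta).sum()

    step = 1.0
    obj = full_obj(a, delta, beta)
    trace = [obj]
    stall = 0
    # Nesterov acceleration with restart on objective increase
    ya, ydelta, ybeta = a, delta.copy(), beta.copy()
    t_acc = 1.0

    for it in range(1, max_iter + 1):
        f_y, ga, gdelta, gbeta = smooth_and_grad(ya, ydelta, ybeta)
        while True:
            # box constraints stop boundary drift when a training sample has
            # an empty response category: a logit beyond +-50 or a threshold
            # gap outside [e^-15, e^5] is numerically indistinguishable from
            # the infinite-threshold optimum, so the iterates park there
            a_new = float(np.clip(ya - step * ga, -50.0, 50.0))
            delta_new = np.clip(ydelta - step * gdelta, -15.0, 5.0)
            b = ybeta - step * gbeta
            beta_new = np.sign(b) * np.maximum(np.abs(b) - step * l1, 0.0)
            f_new = smooth_value(a_new, delta_new, beta_new)
            da = a_new - ya
            dd = delta_new - ydelta
            db = beta_new - ybeta
            quad = (
                f_y
                + ga * da
                + float(gdelta @ dd)
                + float(gbeta @ db)
                + (da * da + float(dd @ dd) + float(db @ db)) / (2.0 * step)
            )
            if f_new <= quad + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        obj_new = f_new + l1 * np.abs(beta_new).sum()

        if obj_new > obj + 1e-12:
            # restart acceleration from the last accepted point
            ya, ydelta, ybeta = a, delta.copy(), beta.copy()
            t_acc = 1.0
            trace.append(obj)
            continue

        # parameter change measured on the natural scale (thresholds, beta):
        # a drifting log-gap of an effectively tied threshold must not stall
        # convergence
        dmax = max(
            float(np.max(np.abs(_params_to_theta(a_new, delta_new) - _params_to_theta(a, delta)))),
            float(np.max(np.abs(beta_new - beta), initial=0.0)),
        )
        stall = stall + 1 if abs(obj - obj_new) < tol_obj else 0
        # the stall rule covers boundary optima (a training sample with an
        # empty response category pushes a threshold to infinity): there the
        # objective flattens exponentially faster than the iterates settle
        converged = stall >= 1 and (dmax < tol_param or stall >= 25)

        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc))
        mom = (t_acc - 1.0) / t_next
        ya = a_new + mom * (a_new - a)
        ydelta = delta_new + mom * (delta_new - delta)
        ybeta = beta_new + mom * (beta_new - beta)
        t_acc = t_next
        a, delta, beta = a_new, delta_new, beta_new
        obj = obj_new
        trace.append(obj)
        step = min(step * 2.0, 1e6)
        if converged:
            break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations (objective {obj:.6g})",
            trace,
        )

    # soft-thresholding yields exact zeros; sub-epsilon residue from the
    # final gradient step is numerical noise, not a selected coefficient
    beta[np.abs(beta) < 1e-12] = 0.0
    theta = _params_to_theta(a, delta)
    z = X @ beta if p else np.zeros(n)
    ll, _, _ = _loglik_and_score(theta, z, yi)
    return OrdinalNetFit(
        alpha=alpha,
        lam=float(lam),
        beta=beta,
        theta=theta,
        categories=categories,
        loglik=ll,
        n_obs=n,
        n_iter=it,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def fit_path(
    X, y, lambdas, alpha: float = 0.5, *, categories=None, feature_names=None
) -> list[OrdinalNetFit]:
    """Fit every lambda on a decreasing path, warm-starting each fit."""
    fits: list[OrdinalNetFit] = []
    prev: OrdinalNetFit | None = None
    for lam in lambdas:
        prev = fit_ordinal_net(
            X,
            y,
            lam,
            alpha,
            categories=categories,
            init=prev,
            feature_names=feature_names,
        )
        fits.append(prev)
    return fits


def make_folds(y, n_folds: int, seed: int) -> np.ndarray:
    """Seeded fold assignment, stratified by response category.

    Within each category the members are shuffled and dealt round-robin
    across folds (one running pointer over categories), which stratifies
    frequent categories and spreads rare ones as evenly as possible.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    pointer = int(rng.integers(n_folds))
    for cat in np.unique(y):
        idx = np.flatnonzero(y == cat)
        rng.shuffle(idx)
        for i in idx:
            folds[i] = pointer % n_folds
            pointer += 1
    return folds


def _scale_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


@dataclass
class NestedCvResult:
    """Nested 5-fold cross-validation of the penalized ordinal model.

    Per fold, the elastic net is tuned over a fold-specific 20-value
    lambda path by AIC; each fold's selected model is scored on its
    held-out fold, and the lambda with the best held-out (per-observation)
    log-likelihood is refit on all data to give the final model.
    ``test_mcfadden`` is the mean of the five held-out McFadden values.
    """

    fold_assignments: np.ndarray
    per_fold: list[dict]
    chosen_lambda: float
    final_fit: OrdinalNetFit
    test_mcfadden: float
    seed: int
    per_fold_mcfadden: list[float] = field(default_factory=list)


def nested_cv(
    X,
    y,
    *,
    n_folds: int = 5,
    n_lambda: int = 20,
    alpha: float = 0.5,
    min_ratio: float = 0.01,
    seed: int = 0,
    scale_within_folds: bool = True,
    feature_names=None,
) -> NestedCvResult:
    """Tune lambda by nested cross-validation and refit on all data.

    With ``scale_within_folds`` (default) each training fold is re-scaled
    to column mean 0 / sd 1 and its scaling applied to the held-out fold,
    avoiding leakage; otherwise X is used as passed. The held-out null
    model (for McFadden) is the intercept-only model fit on the training
    fold and evaluated on the held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    yi, categories = _encode_y(y)
    folds = make_folds(y, n_folds, seed)
    per_fold: list[dict] = []

    for f in range(n_folds):
        tr, te = folds != f, folds == f
        X_tr, y_tr = X[tr], y[tr]
        X_te, y_te = X[te], y[te]
        if np.unique(y_te).size < 1 or np.unique(y_tr).size < 2:
            raise ValueError(
                f"fold {f} leaves too few response categories; "
                "use stratification or a larger sample"
            )
        if scale_within_folds:
            X_tr, mu, sd = _scale_columns(X_tr)
            X_te = (X_te - mu) / sd
        path = build_lambda_path(X_tr, y_tr, alpha, n_lambda, min_ratio)
        fits = fit_path(
            X_tr, y_tr, path.lambdas, alpha,
            categories=categories, feature_names=feature_names,
        )
        aics = np.array([aic(ft) for ft in fits])
        best = int(np.argmin(aics))
        sel = fits[best]
        ll_te = model_loglik(sel, X_te, y_te)
        null = intercept_only_fit(y_tr, categories)
        ll_null_te = model_loglik(null, np.zeros((X_te.shape[0], 0)), y_te)
        per_fold.append(
            {
                "fold": f,
                "lambda_path": path.lambdas,
                "selected_lambda": float(sel.lam),
                "selected_aic": float(aics[best]),
                "test_loglik": ll_te,
                "test_loglik_per_obs": ll_te / max(int(te.sum()), 1),
                "test_null_loglik": ll_null_te,
                "test_mcfadden": mcfadden_r2(ll_te, ll_null_te),
                "n_test": int(te.sum()),
                "n_nonzero": sel.n_nonzero,
            }
        )

    best_fold = max(per_fold, key=lambda d: d["test_loglik_per_obs"])
    chosen_lambda = best_fold["selected_lambda"]

    X_full = _scale_columns(X)[0] if scale_within_folds else X
    lmax_full = lambda_max(X_full, y, alpha)
    warm_lams = np.geomspace(lmax_full, chosen_lambda, 8)
    final = None
    for lam in warm_lams:
        final = fit_ordinal_net(
            X_full, y, lam, alpha,
            categories=categories, init=final, feature_names=feature_names,
        )
    per_fold_mcf = [d["test_mcfadden"] for d in per_fold]
    return NestedCvResult(
        fold_assignments=folds,
        per_fold=per_fold,
        chosen_lambda=float(chosen_lambda),
        final_fit=final,
        test_mcfadden=float(np.mean(per_fold_mcf)),
        seed=seed,
        per_fold_mcfadden=per_fold_mcf,
    )
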