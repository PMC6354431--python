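"""Likelihoods, ML fitting and AICc comparison of trait-evolution models.

Candidate models for a continuous trait x observed at the tips of a
phylogeny, with regimes (locomotor habits) painted on the branches:

* BM1 — single-rate Brownian motion: x ~ MVN(z0 1, sigma^2 C), C the
  shared-path-length matrix.
* BM3 / BM4 — multi-rate BM: V_ij = sum_k sigma_k^2 (shared time in regime
  k on the root-to-MRCA path).
* OU1 — single-optimum Ornstein-Uhlenbeck (Hansen) model with attraction
  strength alpha towards optimum theta.
* OU3 / OU4 — multi-optimum OU: one theta per regime, shared alpha and
  sigma^2 (the OUM convention); the root state equals the root regime's
  theta, so the tip mean is a weighted average of the optima visited on the
  root-to-tip path with exponentially decaying memory.
* EB — early burst: BM whose rate decays as sigma0^2 e^{r t}, r <= 0.

All likelihoods are exact multivariate-normal densities.  Fitting profiles
the linear parameters (optima / ancestral state) by GLS and the overall
scale analytically, leaving a 1-D bounded search over alpha (OU) or r (EB)
and a small-dimensional search over log rates for multi-rate BM.  Model
comparison uses AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1) and Akaike weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .trees import Phylogeny, RegimeMap, uniform_regime_map

__all__ = [
    "MODEL_NAMES",
    "ModelFitResult",
    "AlphaDiagnostics",
    "loglik_bm",
    "loglik_ou",
    "loglik_eb",
    "fit_model",
    "akaike_weights",
    "alpha_significance",
]

MODEL_NAMES = ("BM1", "BM3", "BM4", "OU1", "OU3", "OU4", "EB")

# free parameters: BM1 (sigma2, z0); BMk (k sigma2, z0); OU1 (alpha, sigma2,
# theta); OUm (alpha, sigma2, m theta); EB (sigma0^2, z0, r)
_N_REGIMES = {"BM1": 1, "BM3": 3, "BM4": 4, "OU1": 1, "OU3": 3, "OU4": 4, "EB": 1}


def _align(tree: Phylogeny, x) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = set(tree.tip_labels) - set(x.index)
        if missing:
            raise ValueError(f"trait values missing for tips: {sorted(missing)}")
        x = x.reindex(tree.tip_labels).to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_tips,):
        raise ValueError("trait vector length does not match tip count")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    return x


def _mvn_loglik(x: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    n = len(x)
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise linalg.LinAlgError(
            f"singular trait covariance (condition number {cond:.3g})"
        ) from exc
    r = x - mean
    q = r @ linalg.cho_solve((c, low), r, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + q))


# ------------------------------------------------------------- likelihoods

def loglik_bm(tree: Phylogeny, x, sigma2, z0: float,
              regime_map: RegimeMap | None = None) -> float:
    """Log-likelihood of (multi-rate) Brownian motion.

    ``sigma2`` is a scalar (single rate) or a state-keyed dict with
    ``regime_map`` painting the states; the covariance accumulates
    sigma_k^2 times the shared time spent in regime k.
    """
    x = _align(tree, x)
    if isinstance(sigma2, dict):
        if regime_map is None:
            raise ValueError("multi-rate BM requires a regime map")
        regime_map.validate()
        shared = regime_map.shared_times_by_state()
        unpainted = set(shared) - set(sigma2)
        if unpainted:
            raise ValueError(f"no rate for regime(s): {sorted(unpainted)}")
        V = sum(sigma2[s] * shared[s] for s in shared)
        if np.any(np.asarray(list(sigma2.values())) <= 0):
            raise ValueError("sigma2 must be positive")
    else:
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        C, _ = tree.vcv()
        V = sigma2 * C
    return _mvn_loglik(x, np.full(len(x), float(z0)), V)


def _ou_mean_weights(tree: Phylogeny, regime_map: RegimeMap, alpha: float,
                     states: list[str]) -> np.ndarray:
    """W with mean = W @ theta: per-tip exponentially-weighted regime shares.

    The root contributes e^{-alpha T_i} to its regime's column (root state
    = that regime's optimum); a path segment [t0, t1] in state s adds
    e^{-alpha (T_i - t1)} - e^{-alpha (T_i - t0)} to column s.  Rows sum
    to 1, so OU1 collapses to a constant mean at theta.
    """
    W = np.zeros((tree.n_tips, len(states)))
    T = tree.depths[tree.tip_indices]
    tip, t0, t1, sc = regime_map.tip_path_arrays(states)
    contrib = np.exp(-alpha * (T[tip] - t1)) - np.exp(-alpha * (T[tip] - t0))
    np.add.at(W, (tip, sc), contrib)
    W[:, states.index(regime_map.root_state)] += np.exp(-alpha * T)
    return W


def _ou_corr(C: np.ndarray, T: np.ndarray, alpha: float) -> np.ndarray:
    """OU tip covariance for sigma^2 = 1 (multiply by sigma^2 to scale)."""
    Ti = T[:, None]
    Tj = T[None, :]
    return np.exp(-alpha * (Ti + Tj - 2 * C)) * (1 - np.exp(-2 * alpha * C)) / (2 * alpha)


def loglik_ou(tree: Phylogeny, x, alpha: float, sigma2: float, theta,
              regime_map: RegimeMap | None = None) -> float:
    """Log-likelihood of the (multi-optimum) Hansen OU model.

    ``theta`` is a scalar (OU1) or a state-keyed dict.  The ancestral state
    is pinned to the root regime's optimum.  Covariance:
    V_ij = sigma^2/(2 alpha) e^{-alpha (T_i + T_j - 2 s_ij)} (1 - e^{-2 alpha s_ij}).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive (use loglik_bm for the BM limit)")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = _align(tree, x)
    if isinstance(theta, dict):
        if regime_map is None:
            raise ValueError("multi-optimum OU requires a regime map")
        regime_map.validate()
        states = sorted(theta)
        missing = set(regime_map.states) - set(theta)
        if missing:
            raise ValueError(f"no optimum for regime(s): {sorted(missing)}")
        theta_vec = np.array([theta[s] for s in states])
    else:
        states = [regime_map.root_state if regime_map is not None else "all"]
        regime_map = regime_map or uniform_regime_map(tree, states[0])
        theta_vec = np.array([float(theta)])
    C, T = tree.vcv()
    W = _ou_mean_weights(tree, regime_map, alpha, states)
    mean = W @ theta_vec
    V = sigma2 * _ou_corr(C, T, alpha)
    return _mvn_loglik(x, mean, V)


def _eb_vcv(tree: Phylogeny, r: float) -> np.ndarray:
    """Shared-path matrix under the early-burst branch-length transform."""
    below = tree.tips_below()
    C = np.zeros((tree.n_tips, tree.n_tips))
    d = tree.depths
    for i in range(1, tree.n_nodes):
        t1, t2 = d[tree.parent[i]], d[i]
        if r == 0:
            w = t2 - t1
        else:
            w = (np.exp(r * t2) - np.exp(r * t1)) / r
        b = below[i]
        C[np.ix_(b, b)] += w
    return C


def loglik_eb(tree: Phylogeny, x, sigma2: float, z0: float, r: float) -> float:
    """Log-likelihood of the early-burst model (rate sigma0^2 e^{r t})."""
    if r > 0:
        raise ValueError("early-burst exponent r must be <= 0")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = _align(tree, x)
    V = sigma2 * _eb_vcv(tree, r)
    return _mvn_loglik(x, np.full(len(x), float(z0)), V)


# ----------------------------------------------------------------- fitting

@dataclass
class ModelFitResult:
    """One maximum-likelihood fit of one model to one trait vector."""

    model: str
    lnL: float
    params: dict
    k: int
    n: int
    aicc: float
    converged: bool = True
    message: str = ""
    alpha_se: float | None = None
    alpha_ci: tuple[float, float] | None = None
    alpha_at_bound: bool = False

    @property
    def aic(self) -> float:
        return -2 * self.lnL + 2 * self.k


def _aicc(lnL: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2 * lnL + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _gls_profile(x: np.ndarray, W: np.ndarray, V0: np.ndarray):
    """Profile linear coefficients and scale for V = sigma^2 V0, mean W b.

    Returns (b_hat, sigma2_hat, concentrated lnL) or None if V0 is not PD.
    """
    n = len(x)
    try:
        c, low = linalg.cho_factor(V0, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    Wi = linalg.cho_solve((c, low), W, check_finite=False)
    xi = linalg.cho_solve((c, low), x, check_finite=False)
    A = W.T @ Wi
    try:
        with warnings.catch_warnings():
            # near the BM limit the design is nearly collinear; lstsq below
            # handles genuinely rank-deficient cases
            warnings.simplefilter("ignore", linalg.LinAlgWarning)
            b = linalg.solve(A, W.T @ xi, assume_a="pos")
    except linalg.LinAlgError:
        b = np.linalg.lstsq(A, W.T @ xi, rcond=None)[0]
    r = x - W @ b
    q = float(r @ linalg.cho_solve((c, low), r, check_finite=False))
    if q <= 0:
        q = 1e-300
    s2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
    return b, s2, float(lnL)


def _fit_bm1(tree, x) -> ModelFitResult:
    C, _ = tree.vcv()
    ones = np.ones((len(x), 1))
    b, s2, lnL = _gls_profile(x, ones, C)
    params = {"sigma2": s2, "z0": float(b[0])}
    return ModelFitResult("BM1", lnL, params, 2, len(x), _aicc(lnL, 2, len(x)))


def _fit_bm_multi(tree, x, regime_map, name, seed, n_starts) -> ModelFitResult:
    # the overall scale is profiled analytically, so only the log rate
    # *ratios* relative to the first regime are searched numerically
    regime_map.validate()
    states = sorted(regime_map.states)
    shared = regime_map.shared_times_by_state()
    mats = [shared[s] for s in states]
    ones = np.ones((len(x), 1))
    rng = np.random.default_rng(seed)
    m = len(states)

    def v0(rel):
        w = np.concatenate([[1.0], np.exp(rel)])
        return sum(wi * M for wi, M in zip(w, mats))

    def neg(rel):
        out = _gls_profile(x, ones, v0(rel))
        return 1e10 if out is None else -out[2]

    starts = [np.zeros(m - 1)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(0, 1.5, size=m - 1))
    best = None
    bounds = [(-23.0, 23.0)] * (m - 1)
    for s0 in starts:
        res = optimize.minimize(neg, s0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    w = np.concatenate([[1.0], np.exp(best.x)])
    b, s2, lnL = _gls_profile(x, ones, v0(best.x))
    sig = {s: float(s2 * wi) for s, wi in zip(states, w)}
    k = m + 1
    params = {"sigma2": sig, "z0": float(b[0])}
    return ModelFitResult(name, float(lnL), params, k, len(x),
                          _aicc(lnL, k, len(x)), converged=bool(best.success),
                          message="" if best.success else str(best.message))


def _fit_ou(tree, x, regime_map, name, seed, n_starts) -> ModelFitResult:
    h = tree.height
    C, T = tree.vcv()
    if regime_map is None:
        regime_map = uniform_regime_map(tree, "all")
    regime_map.validate()
    states = sorted(regime_map.states)
    lo, hi = 1e-9 / h, 50.0 / h

    def conc(log_a):
        a = np.exp(log_a)
        W = _ou_mean_weights(tree, regime_map, a, states)
        out = _gls_profile(x, W, _ou_corr(C, T, a))
        return 1e10 if out is None else -out[2]

    rng = np.random.default_rng(seed)
    grid = list(np.log(np.geomspace(lo, hi, 24)))
    grid += list(rng.uniform(np.log(lo), np.log(hi), size=max(0, n_starts)))
    vals = [conc(g) for g in grid]
    order = np.argsort(vals)
    best = None
    span = np.log(hi) - np.log(lo)
    for j in order[:3]:
        g = grid[j]
        res = optimize.minimize_scalar(
            conc, bounds=(max(np.log(lo), g - 0.2 * span), min(np.log(hi), g + 0.2 * span)),
            method="bounded", options={"xatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    a = float(np.exp(best.x))
    W = _ou_mean_weights(tree, regime_map, a, states)
    b, s2, lnL = _gls_profile(x, W, _ou_corr(C, T, a))
    if len(states) == 1:
        theta = float(b[0])
    else:
        theta = {s: float(v) for s, v in zip(states, b)}
    k = len(states) + 2
    params = {"alpha": a, "sigma2": float(s2), "theta": theta}
    at_bound = a <= lo * 3 or a >= hi / 1.5
    fit = ModelFitResult(name, float(lnL), params, k, len(x),
                         _aicc(lnL, k, len(x)), alpha_at_bound=at_bound)
    # Wald SE from the curvature of the profile log-likelihood in alpha;
    # the profile curvature equals the (alpha, alpha) entry of the inverse
    # full-Hessian covariance, so this is the full-model Wald interval
    if not at_bound:
        step = max(a * 1e-3, 1e-9)
        l0 = -best.fun
        lp = -conc(np.log(a + step))
        lm = -conc(np.log(a - step)) if a - step > 0 else None
        if lm is not None and np.isfinite(lp) and np.isfinite(lm):
            # second derivative in alpha via the log-parameterized evals
            d2 = (lp - 2 * l0 + lm) / (step**2)
            if d2 < 0:
                se = float(1.0 / np.sqrt(-d2))
                fit.alpha_se = se
                fit.alpha_ci = (a - 1.96 * se, a + 1.96 * se)
    return fit


def _ou_alpha_se(tree, x, regime_map, alpha, sigma2, theta) -> float | None:
    """Wald SE of alpha from the numerical Hessian of the full OU lnL."""
    states = sorted(theta) if isinstance(theta, dict) else None

    def pack():
        th = [theta[s] for s in states] if states else [theta]
        return np.array([alpha, sigma2, *th])

    def lnl(p):
        a, s2 = p[0], p[1]
        if a <= 0 or s2 <= 0:
            return -np.inf
        th = ({s: v for s, v in zip(states, p[2:])} if states else float(p[2]))
        try:
            return loglik_ou(tree, x, a, s2, th, regime_map)
        except linalg.LinAlgError:
            return -np.inf

    p0 = pack()
    steps = np.maximum(np.abs(p0) * 1e-4, 1e-7)
    m = len(p0)
    H = np.empty((m, m))
    f0 = lnl(p0)
    if not np.isfinite(f0):
        return None
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = steps[i]
            ej = np.zeros(m); ej[j] = steps[j]
            fpp = lnl(p0 + ei + ej)
            fpm = lnl(p0 + ei - ej)
            fmp = lnl(p0 - ei + ej)
            fmm = lnl(p0 - ei - ej)
            if not all(np.isfinite(v) for v in (fpp, fpm, fmp, fmm)):
                return None
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    var = cov[0, 0]
    return float(np.sqrt(var)) if var > 0 else None


def _fit_eb(tree, x, seed) -> ModelFitResult:
    h = tree.height
    ones = np.ones((len(x), 1))
    r_lo = -10.0 / h

    def conc(r):
        out = _gls_profile(x, ones, _eb_vcv(tree, r))
        return np.inf if out is None else -out[2]

    grid = np.linspace(r_lo, 0.0, 25)
    vals = [conc(r) for r in grid]
    j = int(np.argmin(vals))
    lo = grid[max(0, j - 1)]
    hi = grid[min(len(grid) - 1, j + 1)]
    res = optimize.minimize_scalar(conc, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    r = float(min(res.x, 0.0))
    b, s2, lnL = _gls_profile(x, ones, _eb_vcv(tree, r))
    params = {"sigma2": float(s2), "z0": float(b[0]), "r": r}
    return ModelFitResult("EB", float(lnL), params, 3, len(x), _aicc(lnL, 3, len(x)))


def fit_model(tree: Phylogeny, x, model: str,
              regime_map: RegimeMap | None = None,
              seed: int = 0, n_starts: int = 5) -> ModelFitResult:
    """Maximum-likelihood fit of one named model.

    Multi-regime models (BM3/BM4, OU3/OU4) require a regime map whose state
    count matches the model; single-regime models ignore the map.  Linear
    parameters are profiled by GLS, scale parameters analytically, and the
    remaining search (alpha for OU, r for EB, log rates for multi-rate BM)
    is bounded with grid + seeded multi-start.
    """
    model = model.upper()
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    x = _align(tree, x)
    need = _N_REGIMES[model]
    if need > 1:
        if regime_map is None:
            raise ValueError(f"{model} requires a regime map")
        got = len(regime_map.states)
        if got != need:
            raise ValueError(f"{model} needs {need} regimes, map has {got}")
    if model == "BM1":
        return _fit_bm1(tree, x)
    if model in ("BM3", "BM4"):
        return _fit_bm_multi(tree, x, regime_map, model, seed, n_starts)
    if model == "EB":
        return _fit_eb(tree, x, seed)
    return _fit_ou(tree, x, regime_map if need > 1 else None, model, seed, n_starts)


def akaike_weights(aicc) -> np.ndarray | dict[str, float] | pd.Series:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    if isinstance(aicc, dict):
        keys = list(aicc)
        w = akaike_weights(np.array([aicc[k] for k in keys]))
        return {k: float(v) for k, v in zip(keys, w)}
    if isinstance(aicc, pd.Series):
        return pd.Series(akaike_weights(aicc.to_numpy()), index=aicc.index)
    a = np.asarray(aicc, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two models to weight")
    d = a - np.nanmin(a)
    w = np.exp(-0.5 * d)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


@dataclass
class AlphaDiagnostics:
    """Is the OU attraction strength distinguishable from zero?"""

    significant: bool
    indeterminate: bool = False
    wide_ci: bool = False
    at_bound: bool = False
    lower: float | None = None
    upper: float | None = None


def alpha_significance(fit: ModelFitResult, tree_height: float = 1.0,
                       tol: float | None = None,
                       wide_ratio: float = 1e4) -> AlphaDiagnostics:
    """Screen an OU fit's alpha: Wald 95% CI lower bound above tolerance.

    An OU model whose alpha is statistically indistinguishable from zero is
    equivalent to BM, so its apparent support is discounted.  Fits at the
    optimizer bound or lacking a usable Hessian are never significant; CIs
    whose upper/lower ratio exceeds ``wide_ratio`` are flagged implausibly
    wide.
    """
    if not fit.model.startswith("OU"):
        raise ValueError("alpha screening applies to OU fits only")
    if tol is None:
        tol = 1e-6 / tree_height
    if fit.alpha_at_bound:
        return AlphaDiagnostics(False, at_bound=True,
                                lower=(fit.alpha_ci or (None, None))[0],
                                upper=(fit.alpha_ci or (None, None))[1])
    if fit.alpha_se is None or fit.alpha_ci is None:
        return AlphaDiagnostics(False, indeterminate=True)
    lo, hi = fit.alpha_ci
    wide = lo > 0 and hi / max(lo, 1e-300) > wide_ratio
    return AlphaDiagnostics(bool(lo > tol), wide_ci=bool(wide or lo <= 0),
                            lower=lo, upper=hi)
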