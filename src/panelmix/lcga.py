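"""Latent class growth analysis of the friendship-quality dimensions.

LCGA is a growth mixture model with zero within-class growth-factor
variance: every subject in class k follows the same quadratic mean curve
per dimension (support, negative interaction, power of the best friend;
time coded 0..4 so the intercept is the wave-1 level), plus independent
homoscedastic Gaussian residuals. A two-class solution splits subjects into
higher- and poorer-quality friendship groups; class 0 is always the class
with the higher mean support level. The class-enumeration test is a
parametric bootstrap likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

DIMS = ("sup", "neg", "pow")
T_WAVES = 5
_TIME = np.arange(T_WAVES, dtype=float)
_X = np.stack([np.ones(T_WAVES), _TIME, _TIME**2], axis=1)  # (T, 3)


class LcgaError(RuntimeError):
    pass


@dataclass
class GrowthMixtureModel:
    K: int
    weights: np.ndarray  # (K,)
    coef: np.ndarray  # (K, D, 3): intercept, linear, quadratic
    resid_var: np.ndarray  # (K, D)
    loglik: float
    bic: float
    entropy: float
    n: int
    assignment: np.ndarray  # (n,) modal class per subject
    posteriors: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    loglik_trace: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def curve(self, k: int, d: int) -> np.ndarray:
        """Fitted mean trajectory of dimension d for class k over waves."""
        return _X @ self.coef[k, d]

    @property
    def n_params(self) -> int:
        D = self.coef.shape[1]
        return (self.K - 1) + self.K * D * 4  # 3 curve coefs + residual var

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "coef": self.coef.tolist(),
            "resid_var": self.resid_var.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "entropy": self.entropy,
            "n": self.n,
        }


def _class_loglik(Y, coef, resid_var):
    """(n, K) log-likelihood over observed cells of (n, T, D) data."""
    n, T, D = Y.shape
    K = coef.shape[0]
    obs = ~np.isnan(Y)
    Y0 = np.where(obs, Y, 0.0)
    out = np.zeros((n, K))
    for k in range(K):
        mu = (_X @ coef[k].T)[None]  # (1, T, D)
        ll = -0.5 * (np.log(2 * np.pi * resid_var[k])[None, None] + (Y0 - mu) ** 2 / resid_var[k][None, None])
        out[:, k] = np.where(obs, ll, 0.0).sum(axis=(1, 2))
    return out


def _m_step(Y, resp, var_floor):
    n, T, D = Y.shape
    K = resp.shape[1]
    obs = ~np.isnan(Y)
    Y0 = np.where(obs, Y, 0.0)
    coef = np.empty((K, D, 3))
    resid = np.empty((K, D))
    for k in range(K):
        w_it = resp[:, k][:, None, None] * obs  # (n, T, D)
        for d in range(D):
            w = w_it[:, :, d]  # (n, T)
            XtWX = (_X.T * w.sum(axis=0)) @ _X
            XtWy = _X.T @ (w * Y0[:, :, d]).sum(axis=0)
            try:
                beta = np.linalg.solve(XtWX, XtWy)
            except np.linalg.LinAlgError as exc:
                raise LcgaError("singular design in weighted curve fit") from exc
            coef[k, d] = beta
            fitted = _X @ beta
            ss = (w * (Y0[:, :, d] - fitted[None, :]) ** 2).sum()
            resid[k, d] = max(ss / max(w.sum(), 1e-12), var_floor)
    return coef, resid


def fit_lcga(
    Y,
    K: int,
    *,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = 1e-8,
    seed=None,
) -> GrowthMixtureModel:
    """Fit a K-class LCGA to (n, 5, 3) trajectories with NaN for missing.

    Classes are relabelled so class 0 has the highest mean support curve
    (higher-quality friendship first). A class collapsing below weight 1/n
    triggers a restart; if every start fails an error is raised.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 10 * K:
        raise ValueError(f"need at least {10 * K} subjects for K={K}")
    rng = np.random.default_rng(seed)

    best = None
    for s in range(max(1, n_starts)):
        resp = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
        try:
            out = _em_lcga(Y, resp, tol, max_iter, var_floor)
        except LcgaError:
            continue
        if best is None or out[-2] > best[-2]:
            best = out
        if K == 1:
            break
    if best is None:
        raise LcgaError(f"all {n_starts} starts degenerated")
    weights, coef, resid, post, loglik, trace = best

    # order classes by mean support level, descending (class 0 = higher quality)
    sup_level = np.array([(_X @ coef[k, 0]).mean() for k in range(K)])
    order = np.argsort(-sup_level)
    weights, coef, resid, post = weights[order], coef[order], resid[order], post[:, order]

    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(post > 0, -post * np.log(post), 0.0).sum()
    entropy = float(1.0 - h / (n * np.log(K))) if K > 1 else 1.0
    p = (K - 1) + K * Y.shape[2] * 4
    return GrowthMixtureModel(
        K=K,
        weights=weights,
        coef=coef,
        resid_var=resid,
        loglik=loglik,
        bic=-2.0 * loglik + p * np.log(n),
        entropy=entropy,
        n=n,
        assignment=post.argmax(axis=1),
        posteriors=post,
        loglik_trace=trace,
    )


def _em_lcga(Y, resp, tol, max_iter, var_floor):
    n, _, _ = Y.shape
    K = resp.shape[1]
    weights = resp.mean(axis=0)
    trace = []
    prev = -np.inf
    coef, resid = _m_step(Y, resp, var_floor)
    for _ in range(max_iter):
        logp = _class_loglik(Y, coef, resid) + np.log(np.maximum(weights, 1e-300))[None]
        norm = logsumexp(logp, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(logp - norm[:, None])
        weights = resp.mean(axis=0)
        if K > 1 and (weights < 1.0 / n).any():
            raise LcgaError("degenerate class weight")
        if np.isfinite(prev) and (loglik - prev) <= tol * (abs(prev) + 1.0):
            break
        prev = loglik
        coef, resid = _m_step(Y, resp, var_floor)
    logp = _class_loglik(Y, coef, resid) + np.log(np.maximum(weights, 1e-300))[None]
    norm = logsumexp(logp, axis=1)
    post = np.exp(logp - norm[:, None])
    return weights, coef, resid, post, float(norm.sum()), np.array(trace)


def panel_trajectories(panel) -> np.ndarray:
    """Extract the (n, 5, 3) friendship-dimension array from a panel."""
    wide = panel.wide(DIMS)
    n = len(wide)
    Y = np.empty((n, T_WAVES, len(DIMS)))
    for d, name in enumerate(DIMS):
        Y[:, :, d] = wide[[f"{name}_w{w}" for w in range(1, T_WAVES + 1)]].to_numpy()
    return Y


# ----------------------------------------------------------------------
# parametric bootstrap likelihood-ratio test for K0 vs K0 + 1 classes
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BootstrapLrtResult:
    statistic: float
    boot_statistics: np.ndarray
    p_value: float
    seed: int | None
    n_failed: int

    @property
    def B(self) -> int:
        return len(self.boot_statistics)


def _simulate_from(model: GrowthMixtureModel, obs_mask, rng):
    """Draw a dataset from a fitted LCGA at the observed cells only."""
    n, T, D = obs_mask.shape
    z = rng.choice(model.K, size=n, p=model.weights / model.weights.sum())
    Y = np.full((n, T, D), np.nan)
    for k in range(model.K):
        rows = z == k
        mu = np.stack([_X @ model.coef[k, d] for d in range(D)], axis=1)  # (T, D)
        draws = rng.normal(mu[None], np.sqrt(model.resid_var[k])[None, None], size=(rows.sum(), T, D))
        Y[rows] = draws
    Y[~obs_mask] = np.nan
    return Y


def bootstrap_lrt(
    Y,
    K0: int,
    *,
    B: int = 99,
    n_starts: int = 5,
    seed=None,
    max_failure_rate: float = 0.2,
    **fit_kwargs,
) -> BootstrapLrtResult:
    """Parametric bootstrap LRT of K0 classes against K0 + 1.

    The null model is fit, B bootstrap datasets are simulated from it (with
    the empirical missingness pattern), both models are refit per replicate,
    and p = (1 + #{boot >= observed}) / (B + 1). Replicates whose refits
    degenerate are dropped with a warning; more than ``max_failure_rate``
    failures aborts.
    """
    if B < 19:
        raise ValueError("B must be at least 19")
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    s0, s1 = int(rng.integers(2**31 - 1)), int(rng.integers(2**31 - 1))
    m0 = fit_lcga(Y, K0, n_starts=n_starts, seed=s0, **fit_kwargs)
    m1 = fit_lcga(Y, K0 + 1, n_starts=n_starts, seed=s1, **fit_kwargs)
    observed = 2.0 * (m1.loglik - m0.loglik)

    obs_mask = ~np.isnan(Y)
    stats = []
    failed = 0
    for _ in range(B):
        Yb = _simulate_from(m0, obs_mask, rng)
        try:
            b0 = fit_lcga(Yb, K0, n_starts=n_starts, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
            b1 = fit_lcga(Yb, K0 + 1, n_starts=n_starts, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
        except (LcgaError, ValueError):
            failed += 1
            continue
        stats.append(2.0 * (b1.loglik - b0.loglik))
    if failed > 0:
        warnings.warn(f"{failed} bootstrap refits failed and were dropped")
    if failed > max_failure_rate * B:
        raise LcgaError(f"{failed}/{B} bootstrap refits failed")
    stats = np.array(stats)
    p = (1.0 + (stats >= observed - 1e-12).sum()) / (len(stats) + 1.0)
    return BootstrapLrtResult(
        statistic=float(observed),
        boot_statistics=stats,
        p_value=float(p),
        seed=seed,
        n_failed=failed,
    )
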