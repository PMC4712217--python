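"""Stationary latent transition analysis (hidden-Markov Gaussian mixture).

The model: each subject carries a latent aggression/anxiety class
z_t in {1..K} at each of T = 5 annual waves. Class-conditional measurement
is a diagonal Gaussian over (anx, agg), constrained equal across waves
(measurement invariance, so a class means the same thing at every wave).
Initial class probabilities and the one-year transition matrix are
multinomial-logit functions of binary covariates (main effects; reference
class = the last class, Np in the canonical labelling):

    P(z_1 = k | x)          = softmax_k(a_k + b_k' x)
    P(z_{t+1} = k | z_t = j, x) = softmax_k(beta_{jk} + gamma_{jk}' x)

with one shared transition parameter set for every wave pair
(stationarity). Estimation is EM with an exact forward--backward E-step
(scaled recursions; missing indicators contribute likelihood one) and an
M-step that updates measurement parameters in closed form and the logit
coefficients by weighted multinomial-logistic optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .panel import PanelDataset
from .tables import TYPES

T_WAVES = 5


class LtaError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# model container
# ----------------------------------------------------------------------
def _softmax_rows(logits):
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class TransitionModel:
    K: int
    covariates: tuple[str, ...]
    means: np.ndarray  # (K, V)
    variances: np.ndarray  # (K, V)
    init_coef: np.ndarray  # (K-1, 1+C) logits vs reference class K-1
    trans_coef: np.ndarray  # (K, K-1, 1+C)
    loglik: float = np.nan
    bic: float = np.nan
    entropy: float = np.nan
    n: int = 0
    var_names: tuple[str, ...] = ("anx", "agg")
    loglik_trace: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def _design(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.shape[-1] != len(self.covariates):
            raise ValueError(f"expected covariate vector of length {len(self.covariates)}")
        return np.concatenate([[1.0], x])

    def initial_probs(self, x) -> np.ndarray:
        d = self._design(x)
        logits = np.concatenate([self.init_coef @ d, [0.0]])
        return _softmax_rows(logits)

    def transition_matrix(self, x) -> np.ndarray:
        """One-year K x K transition matrix for covariate pattern ``x``."""
        d = self._design(x)
        logits = np.concatenate([self.trans_coef @ d, np.zeros((self.K, 1))], axis=1)
        return _softmax_rows(logits)

    @property
    def n_params(self) -> int:
        V = self.means.shape[1]
        q = 1 + len(self.covariates)
        return 2 * self.K * V + (self.K - 1) * q + self.K * (self.K - 1) * q

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "covariates": list(self.covariates),
            "var_names": list(self.var_names),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "init_coef": self.init_coef.tolist(),
            "trans_coef": self.trans_coef.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "entropy": self.entropy,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d) -> "TransitionModel":
        return cls(
            K=d["K"],
            covariates=tuple(d["covariates"]),
            var_names=tuple(d["var_names"]),
            means=np.asarray(d["means"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
            init_coef=np.asarray(d["init_coef"], dtype=float),
            trans_coef=np.asarray(d["trans_coef"], dtype=float),
            loglik=d.get("loglik", np.nan),
            bic=d.get("bic", np.nan),
            entropy=d.get("entropy", np.nan),
            n=d.get("n", 0),
        )


# ----------------------------------------------------------------------
# forward-backward (vectorized over subjects)
# ----------------------------------------------------------------------
def _obs_logdensity(Y, means, variances):
    """(n, T, K) log-likelihood of the observed indicator subsets.

    Missing cells contribute zero (likelihood one); a fully missing wave
    therefore has log-density 0 for every class.
    """
    n, T, V = Y.shape
    L = np.zeros((n, T, means.shape[0]))
    for v in range(V):
        y = Y[:, :, v]
        obs = ~np.isnan(y)
        yv = np.where(obs, y, 0.0)
        contrib = -0.5 * (
            np.log(2 * np.pi * variances[:, v])[None, None]
            + (yv[:, :, None] - means[None, None, :, v]) ** 2 / variances[:, v][None, None]
        )
        L += np.where(obs[:, :, None], contrib, 0.0)
    return L


def _forward_backward_batch(L, pi, A):
    """Scaled forward--backward for a batch of sequences.

    Parameters: L (n,T,K) observation log-densities, pi (n,K) initial
    probabilities, A (n,K,K) transition matrices. Returns per-wave marginal
    posteriors gamma (n,T,K), summed-over-time pairwise posteriors xi
    (n,K,K) and the per-subject log-likelihood (n,).
    """
    n, T, K = L.shape
    Lmax = L.max(axis=2)
    B = np.exp(L - Lmax[:, :, None])  # scaled emission likelihoods

    alpha = np.empty((n, T, K))
    c = np.empty((n, T))
    a = pi * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0][:, None]
    for t in range(1, T):
        a = np.einsum("ij,ijk->ik", alpha[:, t - 1], A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t][:, None]

    beta = np.empty((n, T, K))
    beta[:, T - 1] = 1.0
    xi = np.zeros((n, K, K))
    for t in range(T - 2, -1, -1):
        w = B[:, t + 1] * beta[:, t + 1] / c[:, t + 1][:, None]
        xi += alpha[:, t][:, :, None] * A * w[:, None, :]
        beta[:, t] = np.einsum("ijk,ik->ij", A, w)

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = np.log(c).sum(axis=1) + Lmax.sum(axis=1)
    return gamma, xi, loglik


def forward_backward(obs, model: TransitionModel, x):
    """Exact marginal posteriors and log-likelihood for one subject.

    ``obs`` is a (T, V) array of indicator values with NaN for missing
    cells (T <= 5); ``x`` is the subject's covariate vector. Returns
    ``(posteriors, loglik)`` with posteriors of shape (T, K).
    """
    Y = np.asarray(obs, dtype=float)[None]
    if Y.shape[1] > T_WAVES:
        raise ValueError(f"sequence longer than {T_WAVES} waves")
    pi = model.initial_probs(x)[None]
    A = model.transition_matrix(x)[None]
    gamma, _, ll = _forward_backward_batch(
        _obs_logdensity(Y, model.means, model.variances), pi, A
    )
    return gamma[0], float(ll[0])


# ----------------------------------------------------------------------
# weighted multinomial logit (M-step helper)
# ----------------------------------------------------------------------
def _fit_multinomial_logit(X, N, theta0=None, ridge=1e-8):
    """Minimize -sum_p sum_k N[p,k] log softmax_k(theta X_p) + ridge penalty.

    X: (P, q) design rows (one per covariate pattern); N: (P, K) nonnegative
    expected counts. theta has shape (K-1, q), reference = last class.
    Falls back to a stronger ridge if the optimizer reports non-finite
    values (separation).
    """
    P, q = X.shape
    K = N.shape[1]
    size = (K - 1) * q

    def negll(flat, lam):
        theta = flat.reshape(K - 1, q)
        logits = np.concatenate([X @ theta.T, np.zeros((P, 1))], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        logZ = np.log(np.exp(logits).sum(axis=1))
        f = -(N * (logits - logZ[:, None])).sum() + 0.5 * lam * (flat**2).sum()
        prob = np.exp(logits - logZ[:, None])
        resid = prob * N.sum(axis=1, keepdims=True) - N  # (P, K)
        grad = (resid[:, : K - 1].T @ X).ravel() + lam * flat
        return f, grad

    x0 = np.zeros(size) if theta0 is None else np.asarray(theta0, dtype=float).ravel()
    res = optimize.minimize(negll, x0, args=(ridge,), jac=True, method="L-BFGS-B")
    if not np.all(np.isfinite(res.x)) or np.abs(res.x).max() > 30.0:
        warnings.warn("separation detected in logit update; refitting with ridge 1e-3")
        res = optimize.minimize(negll, x0, args=(1e-3,), jac=True, method="L-BFGS-B")
    return res.x.reshape(K - 1, q)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
def _prepare(panel: PanelDataset, covariates, var_names):
    subj = panel.subjects()
    for c in covariates:
        if c not in subj.columns:
            raise LtaError(f"covariate {c!r} not present on the panel")
        if subj[c].isna().any():
            raise LtaError(f"covariate {c!r} must be complete for every subject")
    wide = panel.wide(var_names)
    n = len(wide)
    V = len(var_names)
    Y = np.empty((n, T_WAVES, V))
    for v, name in enumerate(var_names):
        Y[:, :, v] = wide[[f"{name}_w{w}" for w in range(1, T_WAVES + 1)]].to_numpy()
    Xc = subj.loc[wide.index, list(covariates)].to_numpy(dtype=float) if covariates else np.zeros((n, 0))
    return Y, Xc, wide.index


def fit_lta(
    panel: PanelDataset,
    covariates=(),
    *,
    n_starts: int = 30,
    tol: float = 1e-6,
    max_iter: int = 1000,
    variance_floor: float = 1e-4,
    K: int = 4,
    seed=None,
    var_names=("anx", "agg"),
) -> TransitionModel:
    """Fit the stationary covariate-moderated latent transition model.

    ``covariates`` is a subset of {"cohort", "sex", "friendship_class"}
    (the friendship class must have been attached to the panel first).
    Returns the best-of-multistart model with log-likelihood, BIC and
    relative entropy filled in.
    """
    covariates = tuple(covariates)
    Y, Xc, _ = _prepare(panel, covariates, var_names)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)

    design = np.concatenate([np.ones((n, 1)), Xc], axis=1)  # (n, q)
    patterns, pat_idx = np.unique(design, axis=0, return_inverse=True)

    best = None
    for _ in range(max(1, n_starts)):
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            fit = _fit_once(
                Y, design, patterns, pat_idx, K, tol, max_iter, variance_floor, sub_seed
            )
        except (LtaError, np.linalg.LinAlgError):
            continue
        if best is None or fit["loglik"] > best["loglik"]:
            best = fit
    if best is None:
        raise LtaError("every EM start failed; try a higher variance floor")

    q = design.shape[1]
    p = 2 * K * Y.shape[2] + (K - 1) * q + K * (K - 1) * q
    gamma = best["gamma"]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(gamma > 0, -gamma * np.log(gamma), 0.0).sum()
    entropy = float(1.0 - h / (gamma.shape[0] * gamma.shape[1] * np.log(K)))
    return TransitionModel(
        K=K,
        covariates=covariates,
        var_names=tuple(var_names),
        means=best["means"],
        variances=best["variances"],
        init_coef=best["init_coef"],
        trans_coef=best["trans_coef"],
        loglik=best["loglik"],
        bic=-2.0 * best["loglik"] + p * np.log(n),
        entropy=entropy,
        n=n,
        loglik_trace=best["trace"],
    )


def _start_values(Y, K, variance_floor, seed):
    """Measurement starts from a quick pooled cross-sectional mixture."""
    from .lca import fit_lca

    pooled = Y.reshape(-1, Y.shape[2])
    pooled = pooled[~np.isnan(pooled).any(axis=1)]
    model, _ = fit_lca(
        pooled, K, n_starts=3, tol=1e-5, max_iter=100, variance_floor=variance_floor, seed=seed
    )
    order = np.argsort(-model.weights)  # reference class = largest (Np-like)
    order = np.concatenate([np.sort(order[:-1]), order[[-1]]])
    return model.means[order], np.maximum(model.variances[order], variance_floor)


def _fit_once(Y, design, patterns, pat_idx, K, tol, max_iter, variance_floor, seed):
    rng = np.random.default_rng(seed)
    n, T, V = Y.shape
    q = design.shape[1]
    means, variances = _start_values(Y, K, variance_floor, seed)
    init_coef = rng.normal(scale=0.1, size=(K - 1, q))
    trans_coef = rng.normal(scale=0.1, size=(K, K - 1, q))
    trans_coef[:, :, 0] += -1.0  # favour self-persistence at the start
    for j in range(min(K - 1, trans_coef.shape[0])):
        trans_coef[j, j, 0] += 2.0

    obs = ~np.isnan(Y)
    Y0 = np.where(obs, Y, 0.0)

    trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        # E-step
        pi_pat = _softmax_rows(
            np.concatenate([patterns @ init_coef.T, np.zeros((len(patterns), 1))], axis=1)
        )
        A_pat = _softmax_rows(
            np.concatenate(
                [np.einsum("pq,jkq->pjk", patterns, trans_coef), np.zeros((len(patterns), K, 1))],
                axis=2,
            )
        )
        pi = pi_pat[pat_idx]
        A = A_pat[pat_idx]
        L = _obs_logdensity(Y, means, variances)
        gamma, xi, ll = _forward_backward_batch(L, pi, A)
        loglik = float(ll.sum())
        trace.append(loglik)
        if np.isfinite(prev) and (loglik - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = loglik

        # M-step: measurement (shared across waves)
        for v in range(V):
            w = gamma * obs[:, :, [v]]  # zero weight where unobserved
            denom = w.sum(axis=(0, 1))
            if (denom < 1e-8).any():
                raise LtaError("a class received no weight on an indicator")
            mu = (w * Y0[:, :, [v]]).sum(axis=(0, 1)) / denom
            var = (w * (Y0[:, :, [v]] - mu[None, None, :]) ** 2).sum(axis=(0, 1)) / denom
            means[:, v] = mu
            variances[:, v] = np.maximum(var, variance_floor)

        # M-step: initial-probability logits from wave-1 marginals
        N0 = np.zeros((len(patterns), K))
        np.add.at(N0, pat_idx, gamma[:, 0])
        init_coef = _fit_multinomial_logit(patterns, N0, theta0=init_coef)

        # M-step: transition logits, one weighted logit per origin class
        for j in range(K):
            Nj = np.zeros((len(patterns), K))
            np.add.at(Nj, pat_idx, xi[:, j])
            trans_coef[j] = _fit_multinomial_logit(patterns, Nj, theta0=trans_coef[j])
    if not converged:
        last = trace[-1] - trace[-2] if len(trace) > 1 else np.nan
        raise LtaError(
            f"EM did not converge within {max_iter} iterations (last change {last:.3g})"
        )
    return {
        "means": means,
        "variances": variances,
        "init_coef": init_coef,
        "trans_coef": trans_coef,
        "loglik": trace[-1],
        "gamma": gamma,
        "trace": np.array(trace),
    }


# ----------------------------------------------------------------------
# derived quantities
# ----------------------------------------------------------------------
def power_transition(model: TransitionModel, x, years: int) -> np.ndarray:
    """The ``years``-year transition matrix: one-year matrix to that power."""
    if years < 1:
        raise ValueError("years must be a positive integer")
    return np.linalg.matrix_power(model.transition_matrix(x), int(years))


def posterior_marginals(model: TransitionModel, panel: PanelDataset):
    """Per-subject per-wave posterior class probabilities under the model."""
    Y, Xc, index = _prepare(panel, model.covariates, model.var_names)
    n = Y.shape[0]
    design = np.concatenate([np.ones((n, 1)), Xc], axis=1)
    pi = np.stack([model.initial_probs(x) for x in Xc]) if n else np.zeros((0, model.K))
    A = np.stack([model.transition_matrix(x) for x in Xc])
    gamma, xi, ll = _forward_backward_batch(
        _obs_logdensity(Y, model.means, model.variances), pi, A
    )
    _ = design
    return gamma, xi, ll, index, Xc


def class_size_table(
    model: TransitionModel,
    panel: PanelDataset,
    subgroups: dict[str, np.ndarray] | None = None,
    modal: bool = False,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Expected class sizes per subgroup and wave.

    Cells are sums of posterior class probabilities (model-based expected
    counts, generally fractional) or, with ``modal=True``, counts of modal
    assignments. ``subgroups`` maps labels to boolean masks over subjects
    (aligned with ``panel.subjects()``); default is the whole sample.
    ``labels`` maps fitted class indices to type names (e.g. the output of
    :func:`panelmix.lca.label_classes`); without it classes are labelled
    positionally.
    """
    gamma, _, _, index, _ = posterior_marginals(model, panel)
    subj = panel.subjects().loc[index]
    if subgroups is None:
        subgroups = {"all": np.ones(len(subj), dtype=bool)}
    rows = []
    for label, mask in subgroups.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise LtaError(f"subgroup {label!r} is empty")
        g = gamma[mask]
        if modal:
            hard = np.zeros_like(g)
            idx = g.argmax(axis=2)
            n_, T_ = idx.shape
            hard[np.arange(n_)[:, None], np.arange(T_)[None, :], idx] = 1.0
            g = hard
        counts = g.sum(axis=0)  # (T, K)
        for t in range(counts.shape[0]):
            for k in range(model.K):
                if labels is not None:
                    type_name = labels[k]
                elif model.K == 4:
                    type_name = TYPES[k]
                else:
                    type_name = f"class{k}"
                rows.append(
                    {
                        "subgroup": label,
                        "wave": t + 1,
                        "type": type_name,
                        "count": counts[t, k],
                        "percent": 100.0 * counts[t, k] / mask.sum(),
                    }
                )
    return pd.DataFrame(rows)


def four_year_table(model: TransitionModel, panel: PanelDataset, mask=None):
    """Model-implied wave-1 x wave-5 contingency table for a subgroup.

    For each subject the joint P(z1 = j, z5 = k | x) = pi_j(x) (A(x)^4)_{jk};
    summing over the subgroup gives expected counts. Returns
    ``(counts, row_normalized)``.
    """
    _, Xc, index = _prepare(panel, model.covariates, model.var_names)
    if mask is None:
        mask = np.ones(len(index), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    joint = np.zeros((model.K, model.K))
    for x in Xc[mask]:
        pi = model.initial_probs(x)
        A4 = np.linalg.matrix_power(model.transition_matrix(x), 4)
        joint += pi[:, None] * A4
    rows = joint / joint.sum(axis=1, keepdims=True)
    return joint, rows


def reconstruct_contingency(wave1_counts, four_year_rows, row_sum_tol: float = 0.02):
    """Expected wave-1 x wave-5 counts from wave-1 type counts and 4-year rows.

    Entry (j, k) = count_j * prob_{j->k} after exact renormalization of each
    row (printed rows may sum to 1 only within rounding). Fractional entries
    are retained.
    """
    c = np.asarray(wave1_counts, dtype=float)
    P = np.asarray(four_year_rows, dtype=float)
    if (c < 0).any() or (P < 0).any():
        raise ValueError("counts and probabilities must be nonnegative")
    sums = P.sum(axis=1)
    if (np.abs(sums - 1.0) > row_sum_tol + 1e-12).any():
        raise ValueError(f"a transition row sums to {sums}, beyond +-{row_sum_tol}")
    P = P / sums[:, None]
    return c[:, None] * P
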