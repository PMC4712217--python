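"""Cross-sectional latent class analysis with continuous indicators.

A finite mixture of diagonal-covariance Gaussians fit by EM, with
best-of-multistart initialization (perturbed k-means++ centers), a variance
floor against degenerate components, BIC-based class enumeration, the
relative-entropy classification diagnostic, and the deterministic profile
labelling rule that maps a 4-class solution onto the aggression/anxiety
types GAD (anxious), DA (aggressive), C-DA (comorbid aggressive) and Np
(no problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .tables import TYPES


class DegenerateFitError(RuntimeError):
    """All EM starts collapsed; advise raising the variance floor."""


@dataclass
class LatentClassModel:
    K: int
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, V)
    variances: np.ndarray  # (K, V)
    loglik: float
    bic: float
    n: int
    var_names: tuple[str, ...] = ("anx", "agg")
    loglik_trace: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_params(self) -> int:
        V = self.means.shape[1]
        return (self.K - 1) + 2 * self.K * V

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n": self.n,
            "var_names": list(self.var_names),
        }


def _log_gauss(X, means, variances):
    """(n, K) log density under diagonal Gaussians."""
    diff = X[:, None, :] - means[None, :, :]
    return -0.5 * (np.log(2 * np.pi * variances)[None] + diff**2 / variances[None]).sum(axis=2)


def _em(X, K, weights, means, variances, tol, max_iter, variance_floor):
    n = X.shape[0]
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logp = _log_gauss(X, means, variances) + np.log(weights)[None]
        norm = logsumexp(logp, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(logp - norm[:, None])
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise DegenerateFitError("a class emptied during EM")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        variances = (resp.T @ X**2) / nk[:, None] - means**2
        variances = np.maximum(variances, variance_floor)
        if np.isfinite(prev) and (loglik - prev) <= tol * (abs(prev) + 1.0):
            break
        prev = loglik
    logp = _log_gauss(X, means, variances) + np.log(weights)[None]
    norm = logsumexp(logp, axis=1)
    post = np.exp(logp - norm[:, None])
    return weights, means, variances, float(norm.sum()), post, np.array(trace)


def fit_lca(
    X,
    K: int,
    *,
    n_starts: int = 50,
    tol: float = 1e-8,
    max_iter: int = 500,
    variance_floor: float = 1e-4,
    seed=None,
):
    """Fit a K-class diagonal-Gaussian mixture; returns (model, posteriors).

    ``X`` is an (n, V) array of complete observations (rows with NaN are
    dropped). The best of ``n_starts`` seeded EM runs (perturbed k-means++
    centers) is kept; the log-likelihood is non-decreasing within each run.
    """
    X = np.asarray(X, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, V = X.shape
    if n < 2 * K:
        raise ValueError(f"need at least {2 * K} complete observations for K={K}")
    rng = np.random.default_rng(seed)
    scale = X.std(axis=0) + 1e-12

    best = None
    failures = 0
    for s in range(max(1, n_starts)):
        try:
            if K == 1:
                means0 = X.mean(axis=0, keepdims=True).copy()
            else:
                centers, _ = kmeans_plusplus(
                    X, n_clusters=K, random_state=int(rng.integers(2**31 - 1))
                )
                means0 = centers + rng.normal(scale=0.1 * scale, size=(K, V)) * (s > 0)
            var0 = np.tile(np.maximum(X.var(axis=0), variance_floor), (K, 1))
            w0 = np.full(K, 1.0 / K)
            out = _em(X, K, w0, means0, var0, tol, max_iter, variance_floor)
        except DegenerateFitError:
            failures += 1
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:
        raise DegenerateFitError(
            f"all {n_starts} starts degenerated; consider a higher variance_floor"
        )
    weights, means, variances, loglik, post, trace = best
    p = (K - 1) + 2 * K * V
    model = LatentClassModel(
        K=K,
        weights=weights,
        means=means,
        variances=variances,
        loglik=loglik,
        bic=-2.0 * loglik + p * np.log(n),
        n=n,
        loglik_trace=trace,
    )
    return model, post


def select_k(X, K_max: int, *, n_starts: int = 20, seed=None, **settings) -> pd.DataFrame:
    """Fit K = 1..K_max and tabulate (K, loglik, n_params, bic).

    The recommended number of classes is the BIC minimizer; per-K failures
    are recorded as NaN rows and do not abort the sweep. The result carries
    the recommendation in ``df.attrs["selected"]``.
    """
    if K_max < 2:
        raise ValueError("K_max must be at least 2")
    rng = np.random.default_rng(seed)
    rows = []
    for K in range(1, K_max + 1):
        sub = int(rng.integers(2**31 - 1))
        try:
            model, _ = fit_lca(X, K, n_starts=n_starts, seed=sub, **settings)
            rows.append((K, model.loglik, model.n_params, model.bic))
        except (DegenerateFitError, ValueError):
            rows.append((K, np.nan, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["K", "loglik", "n_params", "bic"])
    df.attrs["selected"] = int(df.loc[df["bic"].idxmin(), "K"])
    return df


def relative_entropy(posteriors: np.ndarray, K: int) -> float:
    """Classification certainty: E = 1 - sum_i H(p_i) / (n ln K), in [0, 1].

    1 means perfectly separated classes (one-hot posteriors), 0 means
    uniform posteriors. Undefined for K < 2.
    """
    if K < 2:
        raise ValueError("relative entropy undefined for K < 2")
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2 or P.shape[1] != K:
        raise ValueError("posterior matrix must be (n, K)")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(P > 0, -P * np.log(P), 0.0).sum()
    return float(1.0 - h / (P.shape[0] * np.log(K)))


def label_classes(model: LatentClassModel, anx_idx: int = 0, agg_idx: int = 1, tie_tol: float = 1e-9):
    """Deterministic mapping of a 4-class solution onto the four types.

    Rule: C-DA is the highest-aggression class among classes with
    above-median anxiety; DA is the highest-aggression class among the
    remainder; GAD is the highest-anxiety class among the two left; Np is
    the last. The mapping is invariant under permutation of class indices.
    """
    if model.K != 4:
        raise ValueError("profile labelling requires exactly 4 classes")
    anx = model.means[:, anx_idx]
    agg = model.means[:, agg_idx]

    def argmax_strict(values, candidates):
        vals = [(values[c], c) for c in candidates]
        vals.sort(reverse=True)
        if len(vals) > 1 and abs(vals[0][0] - vals[1][0]) < tie_tol:
            raise ValueError(
                "tie between class profiles beyond tolerance; map classes manually"
            )
        return vals[0][1]

    med = np.median(anx)
    high_anx = [k for k in range(4) if anx[k] > med]
    cda = argmax_strict(agg, high_anx)
    rest = [k for k in range(4) if k != cda]
    da = argmax_strict(agg, rest)
    rest = [k for k in rest if k != da]
    gad = argmax_strict(anx, rest)
    np_ = next(k for k in rest if k != gad)
    mapping = {gad: TYPES[0], da: TYPES[1], cda: TYPES[2], np_: TYPES[3]}
    return mapping
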