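"""Missing-data diagnostics and single imputation.

Implements maximum-likelihood EM estimation of a multivariate-normal mean
and covariance under arbitrary missingness, Little's MCAR chi-square test
built on those estimates, and conditional-mean (EM) imputation of missing
scale scores.

Little's statistic compares, per missingness pattern j, the observed-variable
subvector mean against the EM grand-mean estimate using the EM covariance:

    d2 = sum_j  n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j)

with df = (total count of observed variables over patterns) - (number of
variables). Under MCAR, d2 is asymptotically chi-square(df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MEASURE_COLS, RANGES, PanelDataset


class MissingDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# EM for the multivariate normal with missing values
# ----------------------------------------------------------------------
def em_mvnorm(X: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
    """ML estimates (mu, Sigma) of a multivariate normal from data with NaNs.

    Classic EM: the E-step fills in conditional means and adds conditional
    covariances to the expected sufficient statistics; the M-step recomputes
    moments (denominator n). Convergence is declared when the relative change
    in log-likelihood falls below ``tol``.

    Returns ``(mu, Sigma, loglik_trace)``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        raise MissingDataError("at least one variable has no observed values")

    mu = np.nanmean(X, axis=0)
    # start from diagonal covariance of observed values
    var = np.nanvar(X, axis=0)
    var[var <= 0] = 1e-6
    sigma = np.diag(var)

    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        loglik = 0.0
        for j, pat in enumerate(patterns):
            rows = np.where(inverse == j)[0]
            o = np.where(pat)[0]
            m = np.where(~pat)[0]
            Xo = X[np.ix_(rows, o)]
            nj = len(rows)
            if len(o) == 0:
                filled = np.tile(mu, (nj, 1))
                cond_cov = sigma.copy()
            else:
                Soo = sigma[np.ix_(o, o)]
                try:
                    Soo_inv = np.linalg.inv(Soo)
                except np.linalg.LinAlgError as exc:
                    raise MissingDataError(
                        f"singular covariance for pattern with observed variables {o.tolist()}"
                    ) from exc
                resid = Xo - mu[o]
                sign, logdet = np.linalg.slogdet(Soo)
                if sign <= 0:
                    raise MissingDataError("covariance estimate lost positive definiteness")
                mahal = np.einsum("ij,jk,ik->i", resid, Soo_inv, resid)
                loglik += -0.5 * nj * (len(o) * np.log(2 * np.pi) + logdet) - 0.5 * mahal.sum()
                filled = np.tile(mu, (nj, 1))
                filled[:, o] = Xo
                cond_cov = np.zeros((p, p))
                if len(m) > 0:
                    Smo = sigma[np.ix_(m, o)]
                    B = Smo @ Soo_inv
                    filled[:, m] = mu[m] + resid @ B.T
                    cond_cov[np.ix_(m, m)] = sigma[np.ix_(m, m)] - B @ Smo.T
            sum_x += filled.sum(axis=0)
            sum_xx += filled.T @ filled + nj * cond_cov
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        trace.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= tol * (abs(prev) + 1.0):
            break
        prev = loglik
    else:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last relative change {abs(trace[-1] - prev):.3g})"
        )
    return mu, sigma, np.array(trace)


def _conditional_means(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Fill NaNs in ``X`` with conditional means under N(mu, sigma)."""
    X = np.array(X, dtype=float)
    obs = ~np.isnan(X)
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    for j, pat in enumerate(patterns):
        rows = np.where(inverse == j)[0]
        o = np.where(pat)[0]
        m = np.where(~pat)[0]
        if len(m) == 0:
            continue
        if len(o) == 0:
            X[np.ix_(rows, m)] = mu[m]
            continue
        Soo_inv = np.linalg.inv(sigma[np.ix_(o, o)])
        B = sigma[np.ix_(m, o)] @ Soo_inv
        X[np.ix_(rows, m)] = mu[m] + (X[np.ix_(rows, o)] - mu[o]) @ B.T
    return X


# ----------------------------------------------------------------------
# Little's MCAR test
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class McarResult:
    chi_square: float
    df: int
    p_value: float

    @property
    def normed(self) -> float:
        """chi-square divided by degrees of freedom."""
        return self.chi_square / self.df


def _pool_small_patterns(obs: np.ndarray, min_size: int):
    """Assign each row a pattern id; patterns with < min_size cases are pooled.

    The pooled residual pattern uses the intersection of its members'
    observed-variable sets (so pattern-homogeneous means remain defined);
    rows whose intersection is empty are dropped.
    """
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    counts = np.bincount(inverse)
    small = np.where(counts < min_size)[0]
    keep_rows = np.ones(len(obs), dtype=bool)
    groups = []
    for j in np.where(counts >= min_size)[0]:
        groups.append((np.where(inverse == j)[0], patterns[j]))
    if len(small) > 0:
        rows = np.where(np.isin(inverse, small))[0]
        pooled = patterns[small].all(axis=0)
        if pooled.any():
            groups.append((rows, pooled))
        else:
            keep_rows[rows] = False
    return groups, keep_rows


def mcar_test(
    panel: PanelDataset,
    variables=("anx", "agg"),
    waves=(1, 2, 3, 4, 5),
    min_pattern_size: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> McarResult:
    """Little's MCAR test on wave-stacked scale scores.

    Each subject contributes one row of ``len(variables) * len(waves)``
    values. Fully missing rows are excluded. Raises if the data are complete
    (the test is undefined) or a pattern covariance is singular.
    """
    wide = panel.wide(variables, waves)
    X = wide.to_numpy(dtype=float)
    X = X[~np.isnan(X).all(axis=1)]
    obs = ~np.isnan(X)
    if obs.all():
        raise MissingDataError("MCAR test undefined on complete data")
    # variables never observed cannot enter the statistic
    seen = obs.any(axis=0)
    X, obs = X[:, seen], obs[:, seen]
    p = X.shape[1]

    mu, sigma, _ = em_mvnorm(X, tol=tol, max_iter=max_iter)

    groups, keep = _pool_small_patterns(obs, min_pattern_size)
    d2 = 0.0
    total_obs_vars = 0
    n_patterns = 0
    for rows, pat in groups:
        rows = rows[keep[rows]]
        o = np.where(pat)[0]
        if len(rows) == 0 or len(o) == 0:
            continue
        ybar = np.nanmean(X[np.ix_(rows, o)], axis=0)
        if np.isnan(ybar).any():  # pooled pattern guard
            continue
        diff = ybar - mu[o]
        Soo = sigma[np.ix_(o, o)]
        try:
            sol = np.linalg.solve(Soo, diff)
        except np.linalg.LinAlgError as exc:
            raise MissingDataError(
                f"singular covariance for pattern with observed variables {o.tolist()}"
            ) from exc
        d2 += len(rows) * float(diff @ sol)
        total_obs_vars += len(o)
        n_patterns += 1
    if n_patterns < 2:
        raise MissingDataError("need at least two distinct missingness patterns")
    df = total_obs_vars - p
    if df <= 0:
        raise MissingDataError("nonpositive degrees of freedom; too few patterns")
    return McarResult(chi_square=float(d2), df=int(df), p_value=float(stats.chi2.sf(d2, df)))


# ----------------------------------------------------------------------
# EM imputation
# ----------------------------------------------------------------------
def em_impute(
    panel: PanelDataset,
    groups=("cohort",),
    variables=tuple(MEASURE_COLS),
    waves=(1, 2, 3, 4, 5),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PanelDataset:
    """Replace missing scale scores by EM conditional means.

    A multivariate-normal working model over the wave-stacked indicators is
    fit separately per covariate group (default: per cohort). Observed cells
    are never altered; imputed values are clipped to the variable's
    admissible range; the observed mask of the returned panel still flags
    imputed cells as unobserved.

    Variables with no observed value inside a group are left missing.
    """
    data = panel.data.copy()
    subj = panel.subjects()

    for _, sids in _group_subjects(subj, groups):
        wide = panel.wide(variables, waves).loc[sids]
        X = wide.to_numpy(dtype=float)
        if not np.isnan(X).any():
            continue
        seen = ~np.isnan(X).all(axis=0)
        mu, sigma, _ = em_mvnorm(X[:, seen], tol=tol, max_iter=max_iter)
        filled = X.copy()
        filled[:, seen] = _conditional_means(X[:, seen], mu, sigma)
        fdf = pd.DataFrame(filled, index=wide.index, columns=wide.columns)
        for col in wide.columns:
            var, wave = col.rsplit("_w", 1)
            lo, hi = RANGES[var]
            wave = int(wave)
            sel = (data["wave"] == wave) & data["subject_id"].isin(sids)
            vals = data.loc[sel, "subject_id"].map(fdf[col]).clip(lo, hi)
            missing_here = data.loc[sel, var].isna()
            data.loc[sel[sel].index[missing_here], var] = vals[missing_here.to_numpy()]
    return PanelDataset(data, panel.observed.copy())


def _group_subjects(subj: pd.DataFrame, groups):
    if not groups:
        yield (), subj.index.to_numpy()
        return
    for key, grp in subj.groupby(list(groups)):
        yield key, grp.index.to_numpy()
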