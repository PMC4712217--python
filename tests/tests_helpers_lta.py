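"""Shared independent oracles for latent-chain likelihoods (test-only)."""

from itertools import product

import numpy as np

from panelmix.lta import TransitionModel


def random_transition_model(rng, K=4, V=2):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), K)
    return TransitionModel(
        K=K,
        covariates=(),
        means=rng.normal(1.5, 0.8, (K, V)),
        variances=rng.uniform(0.05, 0.4, (K, V)),
        init_coef=np.log(pi[: K - 1] / pi[-1])[:, None],
        trans_coef=np.log(A[:, : K - 1] / A[:, [-1]])[:, :, None],
    )


def brute_force_loglik(Y, pi, A, means, variances):
    """Total likelihood by exhaustive summation over all latent paths."""
    K, T = len(pi), Y.shape[0]

    def dens(t, k):
        p = 1.0
        for v in range(Y.shape[1]):
            if not np.isnan(Y[t, v]):
                p *= np.exp(
                    -0.5 * np.log(2 * np.pi * variances[k, v])
                    - 0.5 * (Y[t, v] - means[k, v]) ** 2 / variances[k, v]
                )
        return p

    total = 0.0
    for path in product(range(K), repeat=T):
        p = pi[path[0]] * dens(0, path[0])
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * dens(t, path[t])
        total += p
    return np.log(total)
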