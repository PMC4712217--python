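"""Latent transition model: exact inference, fitting, derived tables."""

from itertools import product

import numpy as np
import pytest

import panelmix as pm
from panelmix import cohort, lca, lta
from panelmix.lta import (
    TransitionModel,
    fit_lta,
    forward_backward,
    four_year_table,
    class_size_table,
    power_transition,
    reconstruct_contingency,
)


def _random_model(rng, K=4, V=2, covariates=()):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), K)
    C = len(covariates)
    init_coef = np.log(pi[: K - 1] / pi[-1])[:, None]
    trans_coef = np.log(A[:, : K - 1] / A[:, [-1]])[:, :, None]
    if C:
        init_coef = np.concatenate([init_coef, rng.normal(0, 0.5, (K - 1, C))], axis=1)
        trans_coef = np.concatenate([trans_coef, rng.normal(0, 0.5, (K, K - 1, C))], axis=2)
    return TransitionModel(
        K=K,
        covariates=tuple(covariates),
        means=rng.normal(1.5, 0.8, (K, V)),
        variances=rng.uniform(0.05, 0.4, (K, V)),
        init_coef=init_coef,
        trans_coef=trans_coef,
    )


def _brute_force_loglik(Y, pi, A, means, variances):
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


@pytest.mark.parametrize("K,T", [(2, 2), (3, 3), (4, 3), (4, 4)])
def test_forward_backward_equals_path_enumeration(K, T):
    """Scaled recursions agree with exhaustive summation over latent paths."""
    rng = np.random.default_rng(10 * K + T)
    for rep in range(4):
        model = _random_model(rng, K=K)
        Y = rng.normal(1.5, 1.0, size=(T, 2))
        if rep % 2:  # sprinkle missingness, including a fully missing wave
            Y[rng.integers(T), rng.integers(2)] = np.nan
            Y[rng.integers(T)] = np.nan
        x = []
        post, ll = forward_backward(Y, model, x)
        expected = _brute_force_loglik(
            Y, model.initial_probs(x), model.transition_matrix(x), model.means, model.variances
        )
        assert ll == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


def test_degenerate_single_class_chain(rng):
    model = _random_model(rng, K=1)
    Y = rng.normal(1.5, 0.5, size=(5, 2))
    post, ll = forward_backward(Y, model, [])
    np.testing.assert_allclose(post, 1.0)
    direct = sum(
        -0.5 * np.log(2 * np.pi * model.variances[0, v])
        - 0.5 * (Y[t, v] - model.means[0, v]) ** 2 / model.variances[0, v]
        for t in range(5)
        for v in range(2)
    )
    assert ll == pytest.approx(direct, abs=1e-10)


def test_all_missing_wave_posterior_is_propagated_prior(rng):
    """With no data at all, posteriors equal the chain's marginal prior."""
    model = _random_model(rng, K=3)
    Y = np.full((3, 2), np.nan)
    post, ll = forward_backward(Y, model, [])
    pi = model.initial_probs([])
    A = model.transition_matrix([])
    np.testing.assert_allclose(post[0], pi, atol=1e-12)
    np.testing.assert_allclose(post[1], pi @ A, atol=1e-12)
    np.testing.assert_allclose(post[2], pi @ A @ A, atol=1e-12)
    assert ll == pytest.approx(0.0, abs=1e-12)


def test_power_transition_identity_and_stationary_rows(rng):
    model = _random_model(rng, K=4)
    eye_model = TransitionModel(
        K=4,
        covariates=(),
        means=model.means,
        variances=model.variances,
        init_coef=model.init_coef,
        trans_coef=np.concatenate(
            [np.full((4, 3, 1), -40.0) + 80.0 * np.eye(4)[:, :3, None], ], axis=2
        ),
    )
    np.testing.assert_allclose(power_transition(eye_model, [], 4), np.eye(4), atol=1e-10)
    # rank-one matrix with identical rows is idempotent under powers
    st = rng.dirichlet(np.ones(4))
    rank1 = TransitionModel(
        K=4, covariates=(), means=model.means, variances=model.variances,
        init_coef=model.init_coef,
        trans_coef=np.tile(np.log(st[:3] / st[3])[None, :, None], (4, 1, 1)),
    )
    P4 = power_transition(rank1, [], 4)
    np.testing.assert_allclose(P4, np.tile(st, (4, 1)), atol=1e-12)
    np.testing.assert_allclose(P4.sum(axis=1), 1.0, atol=1e-12)


def test_four_year_power_matches_chained_one_year_steps(rng):
    model = _random_model(rng, K=4)
    A = model.transition_matrix([])
    np.testing.assert_allclose(power_transition(model, [], 4), A @ A @ A @ A, atol=1e-12)


@pytest.fixture(scope="module")
def fitted_study():
    """One LTA fit on a study-sized simulated panel, reused across tests."""
    cfg = cohort.default_study_config()
    sim = cohort.simulate_panel(cfg, seed=77)
    model = fit_lta(sim.panel, covariates=("cohort",), n_starts=4, seed=1, tol=1e-6)
    return cfg, sim, model


def test_lta_em_loglik_monotone(fitted_study):
    _, _, model = fitted_study
    assert np.all(np.diff(model.loglik_trace) >= -1e-6)


def test_lta_recovers_transition_probabilities(study_config):
    """Mean absolute error of 1-year transition probabilities < .03 at n~5000."""
    cfg = cohort.default_study_config()
    cfg.n_per_cohort = (3500, 1500)
    sim = cohort.simulate_panel(cfg, seed=3)
    model = fit_lta(sim.panel, covariates=("cohort",), n_starts=3, seed=0)
    mapping = lca.label_classes(
        lca.LatentClassModel(
            K=4, weights=np.full(4, 0.25), means=model.means,
            variances=model.variances, loglik=0, bic=0, n=1,
        )
    )
    inv = {v: k for k, v in mapping.items()}
    perm = np.array([inv[t] for t in pm.TYPES])
    errs = []
    for c in (0, 1):
        est = model.transition_matrix([c])[np.ix_(perm, perm)]
        errs.append(np.abs(est - cfg.transitions[(c, 0, 0)]))
    assert np.mean(errs) < 0.03


def test_covariate_model_beats_null_when_effects_exist():
    """BIC prefers the cohort-moderated model when cohorts truly differ."""
    cfg = cohort.default_study_config()
    cfg.n_per_cohort = (900, 700)
    sim = cohort.simulate_panel(cfg, seed=21)
    with_cov = fit_lta(sim.panel, covariates=("cohort",), n_starts=3, seed=2)
    without = fit_lta(sim.panel, covariates=(), n_starts=3, seed=2)
    assert with_cov.bic < without.bic


def test_null_covariate_effects_estimated_near_zero():
    """Sex has no true effect in the generator; the fitted sex contrast is small.

    Checked on the probability scale (the logit coefficients of rare
    transition cells have standard errors of ~0.5 at this sample size, so
    the implied probabilities are the meaningful quantity).
    """
    cfg = cohort.default_study_config()
    cfg.n_per_cohort = (3500, 1500)
    sim = cohort.simulate_panel(cfg, seed=31)
    model = fit_lta(sim.panel, covariates=("sex",), n_starts=3, seed=3)
    A_m, A_f = model.transition_matrix([0]), model.transition_matrix([1])
    assert np.abs(A_m - A_f).mean() < 0.02
    assert np.abs(A_m - A_f).max() < 0.08
    assert np.abs(model.initial_probs([0]) - model.initial_probs([1])).max() < 0.04


def test_class_size_table_additive_over_partition(fitted_study):
    _, sim, model = fitted_study
    subj = sim.panel.subjects()
    groups = {
        "males": (subj["sex"] == 0).to_numpy(),
        "females": (subj["sex"] == 1).to_numpy(),
        "all": np.ones(len(subj), dtype=bool),
    }
    df = class_size_table(model, sim.panel, subgroups=groups)
    for w in range(1, 6):
        m = df[(df.subgroup == "males") & (df.wave == w)]["count"].to_numpy()
        f = df[(df.subgroup == "females") & (df.wave == w)]["count"].to_numpy()
        a = df[(df.subgroup == "all") & (df.wave == w)]["count"].to_numpy()
        np.testing.assert_allclose(m + f, a, atol=1e-6)


def test_class_size_table_wave1_matches_generator_shares():
    cfg = cohort.default_study_config()
    cfg.n_per_cohort = (14000, 0)
    sim = cohort.simulate_panel(cfg, seed=41)
    model = fit_lta(sim.panel, covariates=(), n_starts=3, seed=4)
    mapping = lca.label_classes(
        lca.LatentClassModel(
            K=4, weights=np.full(4, 0.25), means=model.means,
            variances=model.variances, loglik=0, bic=0, n=1,
        )
    )
    df = class_size_table(model, sim.panel, labels=mapping)
    w1 = df[(df.wave == 1)].set_index("type")["count"]
    n = sim.panel.n_subjects
    for label in pm.TYPES:
        conf = cfg.initial_probs[(0, 0, 0)][pm.TYPES.index(label)]
        assert abs(w1[label] / n - conf) < 0.01


def test_reconstruct_contingency_printed_example():
    """107 anxious wave-1 subjects spread over the printed 4-year row."""
    row = np.array([0.58, 0.20, 0.03, 0.19])
    out = reconstruct_contingency(
        np.array([107.0, 0, 0, 0]), np.vstack([row, np.tile([0.25] * 4, (3, 1))])
    )
    np.testing.assert_allclose(out[0], [62.06, 21.40, 3.21, 20.33], atol=1e-10)


def test_reconstruct_contingency_conserves_and_validates(rng):
    counts = rng.uniform(0, 100, 4)
    rows = rng.dirichlet(np.ones(4), 4)
    out = reconstruct_contingency(counts, rows)
    np.testing.assert_allclose(out.sum(axis=1), counts, atol=1e-9)
    uniform = reconstruct_contingency([4, 4, 4, 4], np.full((4, 4), 0.25))
    np.testing.assert_allclose(uniform, 1.0)
    with pytest.raises(ValueError):
        reconstruct_contingency([-1, 0, 0, 0], np.full((4, 4), 0.25))
    with pytest.raises(ValueError, match="sums"):
        reconstruct_contingency([1, 1, 1, 1], np.full((4, 4), 0.3))


def test_four_year_table_consistent_with_matrix_power(fitted_study):
    _, sim, model = fitted_study
    subj = sim.panel.subjects()
    mask = (subj["cohort"] == 0).to_numpy()
    counts, rows = four_year_table(model, sim.panel, mask)
    np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-10)
    # single-pattern subgroup: rows equal the 4-year matrix of that pattern
    cfg_rows = power_transition(model, [0], 4)
    # cohort-only covariate: every subject in the mask shares the pattern
    np.testing.assert_allclose(rows, cfg_rows, atol=1e-8)
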