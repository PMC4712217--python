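"""Encompassing-prior Bayes factors: symmetry, oracles, bounds, PMPs."""

import numpy as np
import pytest
from scipy import integrate, stats

from panelmix.bayes import (
    BayesError,
    Constraint,
    ConstrainedHypothesis,
    ParameterSpace,
    encompassing_bf,
    posterior_model_probs,
    run_model_set,
)

DRAWS = 200_000


def _two_group_space(counts_a, counts_b):
    return (
        ParameterSpace()
        .add_group("a", ["x", "y"], counts=np.asarray(counts_a, dtype=float))
        .add_group("b", ["x", "y"], counts=np.asarray(counts_b, dtype=float))
    )


def _gt(lhs, rhs):
    return ConstrainedHypothesis("H", (Constraint(lhs=(lhs,), op=">", rhs=(rhs,)),))


def test_symmetric_counts_give_bf_one():
    space = _two_group_space([50, 50], [50, 50])
    res = encompassing_bf(space, _gt((1, "a", "x"), (1, "b", "x")), draws=DRAWS, seed=1)
    assert abs(res.bf - 1.0) <= 3 * res.mcse_bf


def test_prior_only_space_gives_bf_one():
    space = _two_group_space([0, 0], [0, 0])
    res = encompassing_bf(space, _gt((1, "a", "x"), (1, "b", "x")), draws=DRAWS, seed=2)
    assert abs(res.bf - 1.0) <= 3 * res.mcse_bf


def test_single_inequality_bf_approaches_two_with_strong_data():
    """One inequality has complexity 1/2, so BF is capped near 2."""
    space = ParameterSpace().add_group("g", ["x", "y"], counts=[900.0, 100.0])
    hyp = _gt((1, "g", "x"), (1, "g", "y"))
    res = encompassing_bf(space, hyp, draws=DRAWS, seed=3)
    assert res.bf == pytest.approx(2.0, abs=0.02)
    assert res.bf <= 1.0 / res.complexity + 3 * res.mcse_bf


@pytest.mark.parametrize("counts", [(3.0, 7.0), (25.5, 14.5), (0.0, 9.0)])
def test_two_cell_bf_matches_beta_quadrature_oracle(counts):
    """MC fit/complexity match deterministic integration of the Beta posterior."""
    a, b = counts
    space = ParameterSpace().add_group("g", ["x", "y"], counts=[a, b])
    hyp = ConstrainedHypothesis(
        "H", (Constraint(lhs=((1, "g", "x"),), op=">", rhs=(), rhs_const=0.55),)
    )
    res = encompassing_bf(space, hyp, draws=400_000, seed=4)
    f_exact = 1.0 - stats.beta.cdf(0.55, 1 + a, 1 + b)
    c_exact = 1.0 - stats.beta.cdf(0.55, 1, 1)
    assert abs(res.fit - f_exact) <= 3 * max(res.mcse_fit, 1e-4)
    assert abs(res.complexity - c_exact) <= 3 * max(res.mcse_complexity, 1e-4)


def test_about_equality_band_matches_quadrature_oracle():
    """P(|p_a - p_b| <= tol) against 2-D quadrature over Beta densities."""
    ca, cb = (12.0, 20.0), (30.0, 18.0)
    tol = 0.1
    space = _two_group_space(ca, cb)
    hyp = ConstrainedHypothesis(
        "H", (Constraint(lhs=((1, "a", "x"),), op="~", rhs=((1, "b", "x"),), tol=tol),)
    )
    res = encompassing_bf(space, hyp, draws=400_000, seed=5)
    da = stats.beta(1 + ca[0], 1 + ca[1])
    db = stats.beta(1 + cb[0], 1 + cb[1])
    f_exact, _ = integrate.quad(
        lambda p: da.pdf(p) * (db.cdf(min(p + tol, 1)) - db.cdf(max(p - tol, 0))), 0, 1
    )
    assert abs(res.fit - f_exact) <= 3 * res.mcse_fit + 1e-4


@pytest.mark.parametrize("q", [1, 2, 3])
def test_complexity_of_q_inequalities_is_two_to_minus_q(q):
    """Independent orderings of exchangeable cells have complexity 2^-q."""
    space = ParameterSpace()
    cons = []
    for i in range(q):
        space.add_group(f"g{i}", ["x", "y"])
        cons.append(Constraint(lhs=((1, f"g{i}", "x"),), op=">", rhs=((1, f"g{i}", "y"),)))
    res = encompassing_bf(space, ConstrainedHypothesis("H", tuple(cons)), draws=DRAWS, seed=q)
    assert abs(res.complexity - 2.0**-q) <= 3 * res.mcse_complexity


def test_mcse_halves_when_draws_quadruple():
    space = _two_group_space([10, 5], [5, 10])
    hyp = _gt((1, "a", "x"), (1, "b", "x"))
    r1 = encompassing_bf(space, hyp, draws=50_000, seed=6)
    r2 = encompassing_bf(space, hyp, draws=200_000, seed=6)
    assert r2.mcse_fit == pytest.approx(r1.mcse_fit / 2, rel=0.2)


def test_unconstrained_hypothesis_is_reference():
    space = _two_group_space([10, 5], [5, 10])
    res = encompassing_bf(space, ConstrainedHypothesis("M3"), draws=DRAWS, seed=7)
    assert (res.fit, res.complexity, res.bf) == (1.0, 1.0, 1.0)


def test_zero_complexity_raises_rather_than_divides():
    space = ParameterSpace().add_group("g", ["x", "y"], counts=[5.0, 5.0])
    hyp = ConstrainedHypothesis(
        "H", (Constraint(lhs=((1, "g", "x"),), op=">", rhs=(), rhs_const=1.5),)
    )
    with pytest.raises(BayesError, match="complexity"):
        encompassing_bf(space, hyp, draws=10_000, seed=8)


def test_pmp_printed_example_and_invariants():
    pmps = posterior_model_probs([0.001, 1156.44, 1.0])
    assert pmps[1] >= 0.99
    assert pmps[0] < 0.001 and pmps[2] < 0.001
    np.testing.assert_allclose(posterior_model_probs([2.0, 2.0, 2.0]), 1 / 3)
    rng = np.random.default_rng(0)
    for _ in range(5):
        assert posterior_model_probs(rng.uniform(0.001, 10, 4)).sum() == pytest.approx(1.0)
    with pytest.raises(BayesError):
        posterior_model_probs([])


def test_equal_counts_give_no_support_to_inequality_models():
    """Symmetric tables: no pure-inequality model exceeds BF 1 within MC error.

    (About-equality models are excluded: symmetric data genuinely support
    "no difference" bands, so their BF legitimately exceeds 1.)
    """

    class FlatSizes:
        def counts_vector(self, subgroup, wave):
            return np.array([100.0, 100.0, 100.0, 100.0])

    class FlatTrans:
        def matrix(self, subgroup):
            return np.full((4, 4), 0.25)

    for set_id in (
        "gender_prevalence",
        "age_transition_strength",
        "gender_transition_strength",
        "friendship_transition_strength",
    ):
        rep = run_model_set(
            set_id, draws=DRAWS, seed=9, class_sizes=FlatSizes(), transitions=FlatTrans()
        )
        m2 = next(m for m in rep["models"] if m["name"] == "M2")
        mcse = m2["mcse_bf"] if np.isfinite(m2["mcse_bf"]) else 0.1
        assert m2["bf"] <= 1.0 + 3 * mcse + 0.05


def test_run_model_set_unknown_id():
    with pytest.raises(BayesError):
        run_model_set("nonexistent_set")


def test_run_model_set_deterministic_given_seed():
    a = run_model_set("age_transition_strength", draws=50_000, seed=10)
    b = run_model_set("age_transition_strength", draws=50_000, seed=10)
    assert a["models"] == b["models"]
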