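"""Encompassing-prior Bayesian evaluation of constrained hypotheses.

Multinomial parameter groups (class shares at a wave; a row of a transition
table) receive independent Dirichlet priors (default Dirichlet(1,...,1), the
neutral encompassing prior) and conjugate Dirichlet posteriors from
(possibly fractional) counts. An inequality/about-equality constrained
hypothesis H is scored against the unconstrained encompassing model via

    BF_H = f / c,

where f (the *fit*) is the posterior probability and c (the *complexity*)
the prior probability that every constraint holds; both are estimated by
independent Monte Carlo sampling. About-equality constraints |lhs - rhs| <=
tol operationalize "no difference" hypotheses. Bayes factors may be floored
(at .001 in the packaged model sets) before posterior model probabilities
PMP_m = BF_m / sum(BF) are formed; the unconstrained model has BF = 1 by
definition.
"""

from __future__ import annotations

import json
import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .lta import reconstruct_contingency
from .tables import TYPES, load_class_sizes, load_transitions

DEFAULT_DRAWS = 1_000_000
DEFAULT_FLOOR = 0.001
DEFAULT_TOL = 0.02


class BayesError(ValueError):
    pass


# ----------------------------------------------------------------------
# parameter space
# ----------------------------------------------------------------------
@dataclass
class ParameterSpace:
    """Named multinomial groups with independent Dirichlet posteriors.

    ``groups`` maps a group name to ``(cells, prior, counts)`` where
    ``cells`` are cell labels, ``prior`` the prior concentration (all ones
    by default) and ``counts`` nonnegative (possibly fractional) data
    counts; the posterior concentration is ``prior + counts``.
    """

    groups: dict[str, tuple[list[str], np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_group(self, name: str, cells, counts=None, prior=None):
        cells = list(cells)
        m = len(cells)
        prior = np.ones(m) if prior is None else np.asarray(prior, dtype=float)
        counts = np.zeros(m) if counts is None else np.asarray(counts, dtype=float)
        if name in self.groups:
            raise BayesError(f"duplicate group name {name!r}")
        if (prior <= 0).any():
            raise BayesError("prior concentrations must be positive")
        if (counts < 0).any():
            raise BayesError("counts must be nonnegative")
        self.groups[name] = (cells, prior, counts)
        return self

    def sample(self, rng, draws: int, posterior: bool) -> dict[str, np.ndarray]:
        out = {}
        for name, (cells, prior, counts) in self.groups.items():
            alpha = prior + counts if posterior else prior
            out[name] = rng.dirichlet(alpha, size=draws)
        return out


@dataclass(frozen=True)
class Constraint:
    """lhs (op) rhs, with lhs/rhs linear combinations of parameters.

    Each side is a list of ``(coef, group, cell)`` terms plus an optional
    constant. ``op`` is ``">"``, ``"<"`` or ``"~"`` (about equality within
    ``tol``).
    """

    lhs: tuple
    op: str
    rhs: tuple
    tol: float | None = None
    lhs_const: float = 0.0
    rhs_const: float = 0.0

    def evaluate(self, samples, space: ParameterSpace, default_tol: float):
        def side(terms, const):
            total = np.full(next(iter(samples.values())).shape[0], const, dtype=float)
            for coef, group, cell in terms:
                cells, _, _ = space.groups[group]
                total += coef * samples[group][:, cells.index(cell)]
            return total

        l = side(self.lhs, self.lhs_const)
        r = side(self.rhs, self.rhs_const)
        if self.op == ">":
            return l > r
        if self.op == "<":
            return l < r
        if self.op == "~":
            tol = self.tol if self.tol is not None else default_tol
            if tol is None or tol <= 0:
                raise BayesError("about-equality constraints need a positive tol")
            return np.abs(l - r) <= tol
        raise BayesError(f"unknown constraint operator {self.op!r}")


@dataclass(frozen=True)
class ConstrainedHypothesis:
    name: str
    constraints: tuple[Constraint, ...] = ()
    label: str = ""

    @property
    def unconstrained(self) -> bool:
        return len(self.constraints) == 0


@dataclass(frozen=True)
class BayesFactorResult:
    hypothesis: str
    fit: float
    complexity: float
    bf: float
    mcse_fit: float
    mcse_complexity: float
    draws: int
    seed: int | None
    floor: float | None = None

    @property
    def floored(self) -> bool:
        return self.floor is not None and self.bf < self.floor

    @property
    def bf_floored(self) -> float:
        return max(self.bf, self.floor) if self.floor is not None else self.bf

    @property
    def mcse_bf(self) -> float:
        """Delta-method standard error of the BF ratio estimate."""
        if self.fit == 0 or self.complexity == 0:
            return np.nan
        rel = (self.mcse_fit / self.fit) ** 2 + (self.mcse_complexity / self.complexity) ** 2
        return self.bf * np.sqrt(rel)


def encompassing_bf(
    space: ParameterSpace,
    hypothesis: ConstrainedHypothesis,
    draws: int = DEFAULT_DRAWS,
    seed=None,
    tol: float = DEFAULT_TOL,
    floor: float | None = None,
) -> BayesFactorResult:
    """Estimate fit, complexity and BF = fit/complexity by Monte Carlo.

    The unconstrained hypothesis returns BF = 1 exactly. A complexity
    estimate of zero raises (increase draws or widen tol) rather than
    silently dividing by zero.
    """
    if draws < 10_000:
        raise BayesError("use at least 10,000 draws")
    if hypothesis.unconstrained:
        return BayesFactorResult(hypothesis.name, 1.0, 1.0, 1.0, 0.0, 0.0, draws, seed, floor)
    rng = np.random.default_rng(seed)

    def proportion(posterior: bool) -> float:
        samples = space.sample(rng, draws, posterior)
        ok = np.ones(draws, dtype=bool)
        for con in hypothesis.constraints:
            ok &= con.evaluate(samples, space, tol)
        return float(ok.mean())

    f = proportion(True)
    c = proportion(False)
    if c == 0.0:
        raise BayesError(
            f"complexity of {hypothesis.name!r} estimated as 0 from {draws} draws; "
            "increase draws or widen the about-equality tolerance"
        )
    mcse = lambda p: float(np.sqrt(p * (1.0 - p) / draws))
    return BayesFactorResult(
        hypothesis.name, f, c, f / c, mcse(f), mcse(c), draws, seed, floor
    )


def posterior_model_probs(bfs, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """PMPs from a list of Bayes factors (floored, then normalized)."""
    if len(bfs) == 0:
        raise BayesError("need at least one Bayes factor")
    b = np.maximum(np.asarray(bfs, dtype=float), floor)
    if (b <= 0).any():
        raise BayesError("Bayes factors must exceed a positive floor")
    return b / b.sum()


# ----------------------------------------------------------------------
# packaged model sets
# ----------------------------------------------------------------------
MODEL_SETS = (
    "age_prevalence",
    "gender_prevalence",
    "age_transition",
    "age_transition_strength",
    "gender_transition",
    "gender_transition_strength",
    "friendship_transition",
    "friendship_transition_strength",
)


def _load_set_spec(set_id: str) -> dict:
    if set_id not in MODEL_SETS:
        raise BayesError(f"unknown model set {set_id!r}; choose from {MODEL_SETS}")
    ref = importlib.resources.files("panelmix.fixtures").joinpath(
        f"constraints/{set_id}.json"
    )
    with importlib.resources.as_file(ref) as path:
        return json.loads(path.read_text())


def _parse_terms(raw):
    return tuple((float(c), g, cell) for c, g, cell in raw)


def _parse_hypothesis(raw) -> ConstrainedHypothesis:
    cons = tuple(
        Constraint(
            lhs=_parse_terms(c["lhs"]),
            op=c["op"],
            rhs=_parse_terms(c["rhs"]),
            tol=c.get("tol"),
            lhs_const=float(c.get("lhs_const", 0.0)),
            rhs_const=float(c.get("rhs_const", 0.0)),
        )
        for c in raw.get("constraints", [])
    )
    return ConstrainedHypothesis(name=raw["name"], constraints=cons, label=raw.get("label", ""))


def build_space(spec: dict, class_sizes=None, transitions=None) -> ParameterSpace:
    """Build the Dirichlet parameter space a packaged model set refers to.

    Prevalence sets use the wave-1 and wave-5 class-count vectors of two
    subgroups; transition sets use the GAD and DA origin rows of the
    reconstructed wave-1 x wave-5 contingency tables (wave-1 counts times
    renormalized 4-year rows; fractional counts enter the Dirichlet update
    unrounded).
    """
    t1 = class_sizes if class_sizes is not None else load_class_sizes()
    space = ParameterSpace()
    if spec["kind"] == "prevalence":
        for sub in spec["subgroups"]:
            for wave in spec["waves"]:
                space.add_group(
                    f"{sub}.w{wave}", TYPES, counts=t1.counts_vector(sub, wave)
                )
    elif spec["kind"] == "transition":
        t4 = transitions if transitions is not None else load_transitions()
        for sub in spec["subgroups"]:
            counts1 = t1.counts_vector(sub, 1)
            table = reconstruct_contingency(counts1, t4.matrix(sub))
            for frm in spec["rows"]:
                j = TYPES.index(frm)
                space.add_group(f"{sub}.{frm}", TYPES, counts=table[j])
    else:
        raise BayesError(f"unknown space kind {spec['kind']!r}")
    return space


def run_model_set(
    set_id: str,
    draws: int = DEFAULT_DRAWS,
    seed=None,
    tol: float = DEFAULT_TOL,
    floor: float = DEFAULT_FLOOR,
    class_sizes=None,
    transitions=None,
) -> dict:
    """Evaluate one packaged model set (M1, M2, unconstrained M3).

    Returns a report dict with, per model: fit, complexity, BF, floored BF,
    BF ratio versus M1, PMP, and Monte-Carlo standard errors.
    """
    spec = _load_set_spec(set_id)
    space = build_space(spec["space"], class_sizes=class_sizes, transitions=transitions)
    rng = np.random.default_rng(seed)
    results = []
    for raw in spec["models"]:
        hyp = _parse_hypothesis(raw)
        sub_seed = int(rng.integers(2**31 - 1))
        results.append(
            encompassing_bf(space, hyp, draws=draws, seed=sub_seed, tol=tol, floor=floor)
        )
    floored = [r.bf_floored for r in results]
    pmps = posterior_model_probs(floored, floor=floor)
    bf_m1 = floored[0]
    report = {
        "set_id": set_id,
        "draws": draws,
        "tol": tol,
        "floor": floor,
        "seed": seed,
        "models": [],
    }
    for r, pmp in zip(results, pmps):
        report["models"].append(
            {
                "name": r.hypothesis,
                "fit": r.fit,
                "complexity": r.complexity,
                "bf": r.bf,
                "bf_floored": r.bf_floored,
                "bf_vs_m1": r.bf_floored / bf_m1,
                "pmp": float(pmp),
                "mcse_fit": r.mcse_fit,
                "mcse_complexity": r.mcse_complexity,
                "mcse_bf": r.mcse_bf,
            }
        )
    report["ranking"] = [
        report["models"][i]["name"]
        for i in np.argsort([-m["pmp"] for m in report["models"]])
    ]
    return report
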