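"""Synthetic inputs: random valid model specs, analytic toy models, and
parametric life tables.

Everything the pipeline consumes can be generated here, so every stage is
testable without external data.  The toy models carry closed-form expected
outcomes that serve as independent oracles for the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .model import (
    ALL_PARAMS,
    AnalysisSettings,
    Calibration,
    CalibrationError,
    ConfigError,
    CostSet,
    LifeTable,
    ModelSpec,
    ParameterDistribution,
    StrategyTransitions,
    TransitionParameters,
    UtilitySet,
    parameter_value,
)

__all__ = [
    "ScenarioRecipe",
    "generate_random_model",
    "ToyModel",
    "toy_geometric_model",
    "toy_catalog",
    "synthetic_life_table",
]


# ---------------------------------------------------------------------------
# Parametric life tables

_MAKEHAM = 2.0e-4    # age-independent background hazard (accidents etc.)
_GOMPERTZ_B = 0.09   # log-slope of the senescent hazard, per year of age


def _life_table_from_level(a: float, max_age: int) -> LifeTable:
    ages = np.arange(max_age + 1)
    # integrated hazard over [x, x+1) for mu(x) = lambda + a*exp(b*x)
    cumhaz = _MAKEHAM + a / _GOMPERTZ_B * np.exp(_GOMPERTZ_B * ages) \
        * (np.exp(_GOMPERTZ_B) - 1.0)
    q = 1.0 - np.exp(-cumhaz)
    q[-1] = 1.0  # close the table: no survival past max_age
    return LifeTable(ages=ages, q=q)


def _life_expectancy(table: LifeTable) -> float:
    surv = np.cumprod(1.0 - table.q)
    # trapezoid on the survival curve: deaths assumed mid-year
    return 0.5 + float(surv[:-1].sum())


def life_expectancy(table: LifeTable) -> float:
    """Period life expectancy at birth implied by a life table."""
    return _life_expectancy(table)


def synthetic_life_table(target_life_expectancy: float, max_age: int = 110) -> LifeTable:
    """Gompertz-Makeham life table calibrated to a target life expectancy.

    The hazard is mu(x) = lambda + a * exp(b*x) with fixed lambda and b; the
    level ``a`` is solved so that period life expectancy at birth matches the
    target (well within the 0.5-year guarantee).
    """
    if not 40.0 < target_life_expectancy < max_age:
        raise CalibrationError(
            f"target life expectancy {target_life_expectancy} not in (40, {max_age})")

    def gap(log_a: float) -> float:
        return _life_expectancy(_life_table_from_level(np.exp(log_a), max_age)) \
            - target_life_expectancy

    lo, hi = np.log(1e-9), np.log(5e-2)
    if gap(lo) < 0 or gap(hi) > 0:
        raise CalibrationError(
            f"life expectancy {target_life_expectancy} unattainable with the "
            f"fixed Gompertz slope")
    log_a = brentq(gap, lo, hi, xtol=1e-12)
    table = _life_table_from_level(np.exp(log_a), max_age)
    if abs(_life_expectancy(table) - target_life_expectancy) > 0.5:
        raise CalibrationError("life-table calibration did not converge")
    return table


def constant_mortality_table(q: float, max_age: int = 200) -> LifeTable:
    """Life table with the same annual death probability at every age."""
    ages = np.arange(max_age + 1)
    return LifeTable(ages=ages, q=np.full(ages.shape, float(q)))


# ---------------------------------------------------------------------------
# Random valid model specifications


@dataclass(frozen=True)
class ScenarioRecipe:
    """Bounds from which a random but always-valid model spec is drawn."""

    seed: int
    horizon_range: tuple[int, int] = (5, 60)
    discount_range: tuple[float, float] = (0.0, 0.10)
    start_age: int = 20
    life_expectancy_range: tuple[float, float] = (70.0, 90.0)
    utility_range: tuple[float, float] = (0.3, 1.0)     # for disease states
    incidence_range: tuple[float, float] = (0.0, 0.3)   # health -> benign
    progression_range: tuple[float, float] = (0.0, 0.05)
    cost_range: tuple[float, float] = (10.0, 30_000.0)

    def __post_init__(self):
        for name in ("horizon_range", "discount_range", "utility_range",
                     "incidence_range", "progression_range", "cost_range",
                     "life_expectancy_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} bounds reversed: {lo} > {hi}")
        if self.horizon_range[0] < 1:
            raise ConfigError("horizon must be at least 1 cycle")


def _relative_range(base: float, cap: float | None = None) -> tuple[float, float]:
    lo, hi = 0.9 * base, 1.1 * base
    if cap is not None:
        hi = min(hi, cap)
    return lo, hi


def generate_random_model(recipe: ScenarioRecipe) -> ModelSpec:
    """Draw a random model spec that passes validation by construction."""
    rng = np.random.default_rng(recipe.seed)
    u = lambda lo, hi: float(rng.uniform(lo, hi))

    ur = recipe.utility_range
    utilities = UtilitySet(
        health=1.0,
        benign=u(*ur),
        malignant=u(*ur),
        postop=u(*ur),
        recurrence=u(*ur),
        death=0.0,
    )

    cr = recipe.cost_range
    physical = u(cr[0], cr[0] + 0.2 * (cr[1] - cr[0]))
    costs = CostSet(
        treatment=u(*cr),
        screening_exam=physical * u(1.5, 5.0),
        cancer_followup=u(*cr),
        nodule_followup=u(*cr),
        recurrence=u(*cr),
        physical_exam=physical,
    )

    ir, pr = recipe.incidence_range, recipe.progression_range
    shared_prog = u(*pr)
    shared_rec = u(*pr)

    def arm() -> StrategyTransitions:
        return StrategyTransitions(
            health_to_benign=u(*ir),
            health_to_malignant=u(pr[0], pr[1] / 2),
            benign_to_malignant=shared_prog,
            malignant_to_death=u(pr[0], pr[1] / 2),
            postop_to_recurrence=shared_rec,
        )

    transitions = TransitionParameters(sg=arm(), nsg=arm())

    settings = AnalysisSettings(
        horizon_cycles=int(rng.integers(recipe.horizon_range[0],
                                        recipe.horizon_range[1] + 1)),
        cycle_length=1.0,
        start_age=recipe.start_age,
        discount_rate=u(*recipe.discount_range),
        wtp_threshold=50_000.0,
        rng_seed=int(recipe.seed),
    )
    life_table = synthetic_life_table(u(*recipe.life_expectancy_range))

    distributions: dict[str, ParameterDistribution] = {}
    spec = ModelSpec(
        utilities=utilities,
        costs=costs,
        transitions=transitions,
        distributions=distributions,
        settings=settings,
        calibration=Calibration(
            discount_timing=str(rng.choice(["start", "end"])),
            half_cycle_correction=bool(rng.integers(0, 2)),
            screening_per_cycle=True,
            exam_states_sg=("health", "benign", "malignant", "postop", "recurrence"),
            exam_states_nsg=("health", "benign", "malignant", "postop", "recurrence"),
        ),
        life_table=life_table,
    )
    for name in ALL_PARAMS:
        base = parameter_value(spec, name)
        if name.startswith("utility."):
            if name in ("utility.health", "utility.death"):
                distributions[name] = ParameterDistribution("fixed", base)
                continue
            lo, hi = _relative_range(base, cap=1.0)
        elif name.startswith("prob."):
            lo, hi = _relative_range(base, cap=1.0)
        else:
            lo, hi = _relative_range(base)
        distributions[name] = ParameterDistribution(
            family="fixed", base_value=base, range_low=lo, range_high=hi)
    return spec


# ---------------------------------------------------------------------------
# Analytic toy models


@dataclass(frozen=True)
class ToyModel:
    """A model spec bundled with closed-form expected discounted outcomes."""

    name: str
    spec: ModelSpec
    expected_qaly: float
    expected_cost: float
    description: str


def _toy_spec(p_death: float, r: float, horizon: int,
              exam_cost: float = 0.0) -> ModelSpec:
    """Two-state (alive/dead) model embedded in the six-state frame."""
    transitions = TransitionParameters(
        sg=StrategyTransitions(0.0, 0.0, 0.0, 0.0, 0.0),
        nsg=StrategyTransitions(0.0, 0.0, 0.0, 0.0, 0.0),
    )
    return ModelSpec(
        utilities=UtilitySet(health=1.0, benign=1.0, malignant=1.0,
                             postop=1.0, recurrence=1.0, death=0.0),
        costs=CostSet(treatment=0.0, screening_exam=max(exam_cost, 1e-9),
                      cancer_followup=0.0, nodule_followup=0.0,
                      recurrence=0.0, physical_exam=0.0),
        transitions=transitions,
        distributions={},
        settings=AnalysisSettings(horizon_cycles=horizon, start_age=20,
                                  discount_rate=r),
        calibration=Calibration(
            discount_timing="start",
            half_cycle_correction=False,
            screening_per_cycle=True,
            exam_states_sg=("health", "benign", "malignant", "postop", "recurrence"),
            exam_states_nsg=("health", "benign", "malignant", "postop", "recurrence"),
        ),
        life_table=constant_mortality_table(p_death),
    )


def toy_geometric_model(p_death: float, r: float, horizon: int = 55
                        ) -> tuple[ModelSpec, float]:
    """Alive/dead toy model and its exact discounted QALY total.

    Survival to the start of cycle k is (1 - p_death)**k, so the discounted
    QALY total is the geometric sum over ((1 - p_death)/(1 + r))**k for
    k = 0..horizon-1.
    """
    if not 0.0 <= p_death <= 1.0:
        raise ConfigError(f"p_death {p_death} outside [0, 1]")
    spec = _toy_spec(p_death, r, horizon)
    ratio = (1.0 - p_death) / (1.0 + r)
    expected = float(sum(ratio ** k for k in range(horizon)))
    return spec, expected


def toy_catalog() -> list[ToyModel]:
    """Named toy models with closed-form discounted QALY and cost totals.

    The cost closed form uses a unit per-cycle exam cost on the screening
    arm, so expected cost equals the same geometric sum as the QALYs.
    """
    entries = []
    cases = [
        ("immortal_discounted", 0.0, 0.05, 3,
         "no mortality, 5% discount over 3 cycles"),
        ("mortal_undiscounted", 0.1, 0.0, 3,
         "10%/yr mortality, no discounting, 3 cycles"),
        ("mortal_discounted_long", 0.1, 0.05, 55,
         "10%/yr mortality with 5% discount over the full horizon"),
        ("certain_death", 1.0, 0.05, 10,
         "everyone dies in the first cycle; only cycle 0 accrues"),
    ]
    for name, p, r, horizon, desc in cases:
        spec = _toy_spec(p, r, horizon, exam_cost=1.0)
        ratio = (1.0 - p) / (1.0 + r)
        total = float(sum(ratio ** k for k in range(horizon)))
        entries.append(ToyModel(name=name, spec=spec,
                                expected_qaly=total, expected_cost=total,
                                description=desc))
    return entries
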