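"""Domain types and core formulas for the thyroid-screening decision model.

The decision problem compares two strategies for asymptomatic adults:
annual neck-ultrasound screening (SG) versus routine physical examination
without ultrasound (NSG).  Disease natural history is a six-state Markov
chain (health, benign nodules, malignant nodules, post-operative stability,
recurrence, death) advanced in annual cycles, with age-specific background
mortality layered on top of the disease transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Mapping

import numpy as np

__all__ = [
    "HealthState",
    "SCREENING",
    "NON_SCREENING",
    "STRATEGIES",
    "InvalidParameterError",
    "ConfigError",
    "CalibrationError",
    "UtilitySet",
    "CostSet",
    "StrategyTransitions",
    "TransitionParameters",
    "ParameterDistribution",
    "ResolvedDistribution",
    "AnalysisSettings",
    "Calibration",
    "LifeTable",
    "ModelSpec",
    "annualize_probability",
    "validate_model",
    "build_transition_matrix",
    "build_transition_stack",
    "resolve_distribution",
    "parameter_value",
    "with_parameter_values",
    "UTILITY_PARAMS",
    "COST_PARAMS",
    "TRANSITION_PARAMS",
]


class HealthState(IntEnum):
    """The six health states, in the fixed column order used everywhere."""

    HEALTH = 0
    BENIGN = 1      # benign thyroid nodules (BTNs), follow-up without treatment
    MALIGNANT = 2   # malignant thyroid nodules (MTNs), treated within the cycle
    POSTOP = 3      # stable after thyroid-cancer surgery
    RECURRENCE = 4  # recurrent thyroid cancer (absorbing for disease moves)
    DEATH = 5


N_STATES = len(HealthState)

SCREENING = "SG"
NON_SCREENING = "NSG"
STRATEGIES = (SCREENING, NON_SCREENING)

ALIVE_STATES = (
    HealthState.HEALTH,
    HealthState.BENIGN,
    HealthState.MALIGNANT,
    HealthState.POSTOP,
    HealthState.RECURRENCE,
)


class InvalidParameterError(ValueError):
    """A numeric input is outside its validity domain."""


class ConfigError(ValueError):
    """A model configuration is structurally malformed."""


class CalibrationError(RuntimeError):
    """A numerical calibration (e.g. life-table fitting) failed to converge."""


def annualize_probability(p_cum: float, t: float) -> float:
    """Convert a cumulative probability over ``t`` years to an annual one.

    Uses the constant-rate identity ``p_annual = 1 - (1 - p_cum)**(1/t)``,
    the standard conversion between an observation window of ``t`` years and
    the 1-year model cycle.

    Parameters
    ----------
    p_cum
        Probability of the event occurring at least once within ``t`` years.
    t
        Length of the observation window in years, > 0.
    """
    if not 0.0 <= p_cum <= 1.0:
        raise InvalidParameterError(f"cumulative probability {p_cum!r} outside [0, 1]")
    if t <= 0:
        raise InvalidParameterError(f"duration t={t!r} must be positive")
    return 1.0 - (1.0 - p_cum) ** (1.0 / t)


@dataclass(frozen=True)
class UtilitySet:
    """Per-state utility weights on the 0 (dead) to 1 (perfect health) scale."""

    health: float = 1.0
    benign: float = 0.99
    malignant: float = 0.60
    postop: float = 0.99
    recurrence: float = 0.54
    death: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.health, self.benign, self.malignant,
             self.postop, self.recurrence, self.death]
        )


@dataclass(frozen=True)
class CostSet:
    """Cost components in USD.

    ``treatment`` is a one-time cost charged on entry into the malignant
    state; all other components accrue per annual cycle while the member
    occupies the relevant state (which states incur the arm's exam cost is
    a :class:`Calibration` switch).
    """

    treatment: float = 20174.5786        # c_t, cancer surgery + hospitalization
    screening_exam: float = 251.46       # c_n, annual ultrasound (screening arm)
    cancer_followup: float = 1264.9032   # c_tf, post-cancer follow-up per year
    nodule_followup: float = 798.6       # c_nf, benign-nodule follow-up per year
    recurrence: float = 6050.22          # per year in the recurrence state
    physical_exam: float = 50.16         # c_o, annual palpation (non-screening arm)


@dataclass(frozen=True)
class StrategyTransitions:
    """Annual disease-transition probabilities for one strategy arm."""

    health_to_benign: float
    health_to_malignant: float
    benign_to_malignant: float
    malignant_to_death: float   # excess (disease-specific) mortality
    postop_to_recurrence: float


@dataclass(frozen=True)
class TransitionParameters:
    sg: StrategyTransitions
    nsg: StrategyTransitions

    def for_strategy(self, strategy: str) -> StrategyTransitions:
        if strategy == SCREENING:
            return self.sg
        if strategy == NON_SCREENING:
            return self.nsg
        raise InvalidParameterError(f"unknown strategy {strategy!r}")


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty description for a single model parameter.

    ``shape_b`` is the Beta second shape for ``family='beta'`` and the Gamma
    *scale* for ``family='gamma'`` (so the Gamma mean is ``shape_a * shape_b``).
    ``range_low``/``range_high`` are the bounds used in one-way sensitivity
    analysis; ``None`` means no published range (a relative default applies).
    """

    family: str
    base_value: float
    shape_a: float | None = None
    shape_b: float | None = None
    range_low: float | None = None
    range_high: float | None = None


@dataclass(frozen=True)
class ResolvedDistribution:
    """Sampling-ready form of a :class:`ParameterDistribution`."""

    family: str          # "beta", "gamma" or "fixed"
    a: float
    b: float
    base_value: float
    moment_matched: bool = False

    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        return self.base_value

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        if size is None:
            return self.base_value
        return np.full(size, self.base_value)


def resolve_distribution(dist: ParameterDistribution) -> ResolvedDistribution:
    """Turn a declared distribution into a sampling-ready one.

    Gamma shapes are read as (shape, scale).  A Beta whose printed shapes are
    degenerate (either shape <= 0) is replaced by a moment-matched Beta with
    mean equal to the base value and standard deviation one quarter of the
    published range, so that roughly 95% of draws fall inside that range.
    """
    fam = dist.family.lower()
    if fam == "fixed":
        return ResolvedDistribution("fixed", 0.0, 0.0, dist.base_value)
    if fam == "gamma":
        if dist.shape_a is None or dist.shape_b is None or dist.shape_a <= 0 or dist.shape_b <= 0:
            raise ConfigError(f"gamma distribution requires positive shapes, got {dist}")
        return ResolvedDistribution("gamma", float(dist.shape_a), float(dist.shape_b),
                                    dist.base_value)
    if fam == "beta":
        a, b = dist.shape_a, dist.shape_b
        if a is not None and b is not None and a > 0 and b > 0:
            return ResolvedDistribution("beta", float(a), float(b), dist.base_value)
        # degenerate printed shapes -> method-of-moments repair
        mu = dist.base_value
        if dist.range_low is None or dist.range_high is None:
            raise ConfigError(
                f"cannot moment-match beta without a range: {dist}")
        sd = (dist.range_high - dist.range_low) / 4.0
        if not 0.0 < mu < 1.0 or sd <= 0 or sd * sd >= mu * (1.0 - mu):
            raise ConfigError(
                f"moment matching infeasible for mean {mu}, sd {sd}")
        nu = mu * (1.0 - mu) / (sd * sd) - 1.0
        return ResolvedDistribution("beta", mu * nu, (1.0 - mu) * nu,
                                    dist.base_value, moment_matched=True)
    raise ConfigError(f"unknown distribution family {dist.family!r}")


@dataclass(frozen=True)
class AnalysisSettings:
    horizon_cycles: int = 55
    cycle_length: float = 1.0      # years per cycle
    start_age: int = 20
    discount_rate: float = 0.05    # per year, applied to both costs and QALYs
    wtp_threshold: float = 50_000.0
    psa_draws: int = 1000
    rng_seed: int = 0


_ALL_ALIVE_NAMES = ("health", "benign", "malignant", "postop", "recurrence")


@dataclass(frozen=True)
class Calibration:
    """Structural switches that the published model description leaves open.

    discount_timing
        "start": rewards of cycle k are discounted by (1+r)**-k (cycle 0
        undiscounted); "end": by (1+r)**-(k+1), i.e. rewards credited at
        cycle end, the default of common decision-tree software.
    half_cycle_correction
        Average the occupancy at the start and end of each cycle before
        accruing rewards (membership assumed to change mid-cycle).
    screening_per_cycle
        Charge the arm's examination cost every cycle (lifelong annual
        follow-up) rather than once at model start.
    exam_states_sg / exam_states_nsg
        The states whose members incur the arm's examination cost each
        cycle.  Default: the screening program's annual ultrasound reaches
        every living member of the screening arm, whereas the comparator's
        routine physical is subsumed by disease-specific follow-up once a
        nodule or cancer is under management, so it is charged in the
        health state only.
    """

    discount_timing: str = "end"
    half_cycle_correction: bool = False
    screening_per_cycle: bool = True
    exam_states_sg: tuple[str, ...] = _ALL_ALIVE_NAMES
    exam_states_nsg: tuple[str, ...] = ("health",)

    def __post_init__(self):
        if self.discount_timing not in ("start", "end"):
            raise ConfigError(
                f"discount_timing must be 'start' or 'end', got {self.discount_timing!r}")
        for attr in ("exam_states_sg", "exam_states_nsg"):
            names = tuple(getattr(self, attr))
            object.__setattr__(self, attr, names)
            bad = set(names) - set(_ALL_ALIVE_NAMES)
            if bad:
                raise ConfigError(f"{attr}: unknown state(s) {sorted(bad)}")

    def exam_states(self, strategy: str) -> tuple["HealthState", ...]:
        names = self.exam_states_sg if strategy == SCREENING else self.exam_states_nsg
        return tuple(HealthState[n.upper()] for n in names)


@dataclass(frozen=True)
class LifeTable:
    """Annual background mortality q(age), clamped outside the tabulated ages."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.shape != q.shape or ages.ndim != 1 or ages.size == 0:
            raise ConfigError("life table needs matching 1-d age and q columns")
        if np.any(np.diff(ages) != 1):
            raise ConfigError("life-table ages must be consecutive integers")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)

    def annual_mortality(self, age) -> np.ndarray:
        """q at integer age(s); ages beyond the table reuse the boundary rows."""
        idx = np.clip(np.asarray(age) - self.ages[0], 0, self.ages.size - 1)
        return self.q[idx]


@dataclass(frozen=True)
class ModelSpec:
    """The complete parameterized decision problem."""

    utilities: UtilitySet
    costs: CostSet
    transitions: TransitionParameters
    distributions: Mapping[str, ParameterDistribution]
    settings: AnalysisSettings
    calibration: Calibration
    life_table: LifeTable


# ---------------------------------------------------------------------------
# Parameter registry: canonical names used by OWSA/PSA and the config format.
# Order here fixes the PSA draw order.

UTILITY_PARAMS: dict[str, str] = {
    "utility.recurrence": "recurrence",
    "utility.postop": "postop",
    "utility.malignant": "malignant",
    "utility.benign": "benign",
    "utility.health": "health",
    "utility.death": "death",
}

COST_PARAMS: dict[str, str] = {
    "cost.treatment": "treatment",
    "cost.screening_exam": "screening_exam",
    "cost.cancer_followup": "cancer_followup",
    "cost.nodule_followup": "nodule_followup",
    "cost.recurrence": "recurrence",
    "cost.physical_exam": "physical_exam",
}

# name -> (arms it applies to, StrategyTransitions attribute)
TRANSITION_PARAMS: dict[str, tuple[tuple[str, ...], str]] = {
    "prob.health_to_benign.sg": (("sg",), "health_to_benign"),
    "prob.health_to_benign.nsg": (("nsg",), "health_to_benign"),
    "prob.health_to_malignant.sg": (("sg",), "health_to_malignant"),
    "prob.health_to_malignant.nsg": (("nsg",), "health_to_malignant"),
    "prob.benign_to_malignant": (("sg", "nsg"), "benign_to_malignant"),
    "prob.malignant_to_death.sg": (("sg",), "malignant_to_death"),
    "prob.malignant_to_death.nsg": (("nsg",), "malignant_to_death"),
    "prob.postop_to_recurrence": (("sg", "nsg"), "postop_to_recurrence"),
}

ALL_PARAMS: tuple[str, ...] = (
    tuple(UTILITY_PARAMS) + tuple(COST_PARAMS) + tuple(TRANSITION_PARAMS)
)


def parameter_value(spec: ModelSpec, name: str) -> float:
    """Current value of a named parameter in the structured spec."""
    if name in UTILITY_PARAMS:
        return getattr(spec.utilities, UTILITY_PARAMS[name])
    if name in COST_PARAMS:
        return getattr(spec.costs, COST_PARAMS[name])
    if name in TRANSITION_PARAMS:
        arms, attr = TRANSITION_PARAMS[name]
        return getattr(getattr(spec.transitions, arms[0]), attr)
    raise InvalidParameterError(f"unknown parameter {name!r}")


def with_parameter_values(spec: ModelSpec, values: Mapping[str, float]) -> ModelSpec:
    """Return a copy of ``spec`` with the named parameters set to new values.

    Parameters shared between arms (benign->malignant progression and the
    post-operative recurrence rate) are written to both arms at once.
    """
    util = {f: getattr(spec.utilities, f) for f in UTILITY_PARAMS.values()}
    cost = {f: getattr(spec.costs, f) for f in COST_PARAMS.values()}
    trans = {
        arm: {
            f: getattr(getattr(spec.transitions, arm), f)
            for f in StrategyTransitions.__dataclass_fields__
        }
        for arm in ("sg", "nsg")
    }
    for name, value in values.items():
        value = float(value)
        if name in UTILITY_PARAMS:
            util[UTILITY_PARAMS[name]] = value
        elif name in COST_PARAMS:
            cost[COST_PARAMS[name]] = value
        elif name in TRANSITION_PARAMS:
            arms, attr = TRANSITION_PARAMS[name]
            for arm in arms:
                trans[arm][attr] = value
        else:
            raise InvalidParameterError(f"unknown parameter {name!r}")
    dists = dict(spec.distributions)
    for name, value in values.items():
        if name in dists:
            dists[name] = replace(dists[name], base_value=float(value))
    return replace(
        spec,
        utilities=UtilitySet(**util),
        costs=CostSet(**cost),
        transitions=TransitionParameters(
            sg=StrategyTransitions(**trans["sg"]),
            nsg=StrategyTransitions(**trans["nsg"]),
        ),
        distributions=dists,
    )


# ---------------------------------------------------------------------------
# Transition matrices


def build_transition_stack(spec: ModelSpec, strategy: str) -> np.ndarray:
    """All per-cycle transition matrices for one strategy.

    Returns an array of shape (horizon_cycles, 6, 6); entry ``[k]`` governs
    the transition from cycle k to cycle k+1 at age ``start_age + k``.

    Row composition: disease transitions compete with background mortality
    q(age) within each row and the remainder stays put, except the malignant
    row, whose survivors all move to post-operative stability (treatment is
    completed within the one-year cycle).  Death is absorbing; recurrence is
    absorbing for disease moves but still exposed to background mortality.
    """
    s = spec.settings
    tr = spec.transitions.for_strategy(strategy)
    ages = s.start_age + np.arange(s.horizon_cycles)
    q = spec.life_table.annual_mortality(ages)

    H = s.horizon_cycles
    P = np.zeros((H, N_STATES, N_STATES))
    HEALTH, BENIGN, MALIGNANT = HealthState.HEALTH, HealthState.BENIGN, HealthState.MALIGNANT
    POSTOP, RECURRENCE, DEATH = HealthState.POSTOP, HealthState.RECURRENCE, HealthState.DEATH

    P[:, HEALTH, BENIGN] = tr.health_to_benign
    P[:, HEALTH, MALIGNANT] = tr.health_to_malignant
    P[:, HEALTH, DEATH] = q
    P[:, HEALTH, HEALTH] = 1.0 - tr.health_to_benign - tr.health_to_malignant - q

    P[:, BENIGN, MALIGNANT] = tr.benign_to_malignant
    P[:, BENIGN, DEATH] = q
    P[:, BENIGN, BENIGN] = 1.0 - tr.benign_to_malignant - q

    P[:, MALIGNANT, DEATH] = tr.malignant_to_death + q
    P[:, MALIGNANT, POSTOP] = 1.0 - tr.malignant_to_death - q

    P[:, POSTOP, RECURRENCE] = tr.postop_to_recurrence
    P[:, POSTOP, DEATH] = q
    P[:, POSTOP, POSTOP] = 1.0 - tr.postop_to_recurrence - q

    P[:, RECURRENCE, DEATH] = q
    P[:, RECURRENCE, RECURRENCE] = 1.0 - q

    P[:, DEATH, DEATH] = 1.0

    if np.min(P) < -1e-12:
        k, i, j = np.unravel_index(np.argmin(P), P.shape)
        raise InvalidParameterError(
            f"competing probabilities exceed 1 in row {HealthState(i).name} "
            f"at age {s.start_age + k} (entry {P[k, i, j]:.3g})")
    np.clip(P, 0.0, None, out=P)
    return P


def build_transition_matrix(spec: ModelSpec, strategy: str, age: int) -> np.ndarray:
    """Single 6x6 row-stochastic transition matrix at one age."""
    s = spec.settings
    k = int(age) - s.start_age
    if not 0 <= k < s.horizon_cycles:
        # build a one-off stack around the requested age
        shifted = replace(spec, settings=replace(s, start_age=int(age), horizon_cycles=1))
        return build_transition_stack(shifted, strategy)[0]
    return build_transition_stack(spec, strategy)[k]


# ---------------------------------------------------------------------------
# Validation


def validate_model(spec: ModelSpec) -> list[str]:
    """Check a spec against the model's structural invariants.

    Returns a list of human-readable violations; an empty list means valid.
    """
    problems: list[str] = []
    u = spec.utilities
    for name, attr in UTILITY_PARAMS.items():
        v = getattr(u, attr)
        if not 0.0 <= v <= 1.0:
            problems.append(f"{name} = {v} outside [0, 1]")
    if u.death != 0.0:
        problems.append(f"utility.death must be 0, got {u.death}")
    if u.health != 1.0:
        problems.append(f"utility.health must be 1, got {u.health}")

    c = spec.costs
    for name, attr in COST_PARAMS.items():
        v = getattr(c, attr)
        if v < 0:
            problems.append(f"{name} = {v} is negative")
    if c.screening_exam <= c.physical_exam:
        problems.append(
            f"screening exam cost {c.screening_exam} must exceed "
            f"routine physical exam cost {c.physical_exam}")

    for name, (arms, attr) in TRANSITION_PARAMS.items():
        v = getattr(getattr(spec.transitions, arms[0]), attr)
        if not 0.0 <= v <= 1.0:
            problems.append(f"{name} = {v} outside [0, 1]")
    for attr in ("benign_to_malignant", "postop_to_recurrence"):
        if getattr(spec.transitions.sg, attr) != getattr(spec.transitions.nsg, attr):
            problems.append(f"{attr} must be identical in both arms")

    for name in ALL_PARAMS:
        dist = spec.distributions.get(name)
        if dist is None:
            continue
        v = parameter_value(spec, name)
        if dist.base_value != v:
            problems.append(
                f"{name}: declared base {dist.base_value} != structured value {v}")
        # probabilities must stay inside their published ranges
        if (name.startswith("prob.") and dist.range_low is not None
                and dist.range_high is not None):
            if not dist.range_low <= dist.base_value <= dist.range_high:
                problems.append(
                    f"{name}: base {dist.base_value} outside published range "
                    f"[{dist.range_low}, {dist.range_high}]")

    s = spec.settings
    if s.horizon_cycles < 1:
        problems.append(f"horizon_cycles must be >= 1, got {s.horizon_cycles}")
    if not 0.0 <= s.discount_rate < 1.0:
        problems.append(f"discount_rate {s.discount_rate} outside [0, 1)")
    if s.cycle_length <= 0:
        problems.append(f"cycle_length must be positive, got {s.cycle_length}")

    lt = spec.life_table
    if np.any((lt.q < 0) | (lt.q > 1)):
        problems.append("life-table q values outside [0, 1]")

    if not problems:
        for strategy in STRATEGIES:
            try:
                build_transition_stack(spec, strategy)
            except InvalidParameterError as exc:
                problems.append(f"{strategy}: {exc}")
    return problems
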