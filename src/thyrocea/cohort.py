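"""Annual-cycle Markov cohort simulation and its microsimulation oracle.

``run_cohort`` advances the full cohort occupancy vector through the
age-dependent transition matrices and accrues discounted costs and QALYs.
``microsim_oracle`` replays the same model as individual random walks; it is
deliberately an independent code path so the two can cross-validate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    N_STATES,
    SCREENING,
    HealthState,
    InvalidParameterError,
    ModelSpec,
    build_transition_stack,
    validate_model,
)

__all__ = [
    "CohortTrace",
    "StrategyOutcome",
    "MicrosimOutcome",
    "discount_weights",
    "state_cost_vector",
    "run_cohort",
    "microsim_oracle",
]


@dataclass(frozen=True)
class CohortTrace:
    """Fraction of the cohort in each state at the start of every cycle.

    ``occupancy`` has shape (horizon_cycles + 1, 6); row 0 is the initial
    distribution (everyone in health), row k the distribution after k cycles.
    """

    occupancy: np.ndarray
    start_age: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy,
                          columns=[s.name.lower() for s in HealthState])
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "age", self.start_age + df["cycle"])
        return df


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals and per-cycle reward streams for one strategy arm."""

    strategy: str
    total_cost: float
    total_qaly: float
    trace: CohortTrace
    per_cycle_cost: np.ndarray          # discounted, sums to total_cost
    per_cycle_qaly: np.ndarray          # discounted, sums to total_qaly
    per_cycle_cost_undiscounted: np.ndarray
    per_cycle_qaly_undiscounted: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = self.trace.to_dataframe().iloc[:-1].copy()
        df["cost"] = self.per_cycle_cost_undiscounted
        df["qaly"] = self.per_cycle_qaly_undiscounted
        df["discounted_cost"] = self.per_cycle_cost
        df["discounted_qaly"] = self.per_cycle_qaly
        return df


def discount_weights(spec: ModelSpec) -> np.ndarray:
    """Per-cycle discount factors under the spec's timing convention."""
    s = spec.settings
    k = np.arange(s.horizon_cycles, dtype=float)
    if spec.calibration.discount_timing == "end":
        k = k + 1.0
    return (1.0 + s.discount_rate) ** (-k)


def state_cost_vector(spec: ModelSpec, strategy: str) -> np.ndarray:
    """Per-cycle cost attached to occupying each state, excluding exam costs.

    The one-time cancer-treatment cost appears here as the malignant state's
    per-cycle cost: residence in that state lasts exactly one cycle, so a
    per-cycle charge on its occupancy is a once-per-case charge on the mass
    entering it.
    """
    c = spec.costs
    v = np.zeros(N_STATES)
    v[HealthState.BENIGN] = c.nodule_followup
    v[HealthState.MALIGNANT] = c.treatment
    v[HealthState.POSTOP] = c.cancer_followup
    v[HealthState.RECURRENCE] = c.recurrence
    return v


def _exam_cost(spec: ModelSpec, strategy: str) -> float:
    c = spec.costs
    return c.screening_exam if strategy == SCREENING else c.physical_exam


def run_cohort(spec: ModelSpec, strategy: str, *, check: bool = True) -> StrategyOutcome:
    """Run the cohort model for one strategy and accumulate discounted rewards.

    Rewards of cycle k are based on the cycle-k occupancy (or the mid-cycle
    average when half-cycle correction is on) and discounted according to the
    spec's timing switch.  The one-time treatment cost rides on the malignant
    state's occupancy (one-cycle dwell, so one charge per treated case).
    """
    if check:
        problems = validate_model(spec)
        if problems:
            raise InvalidParameterError(
                "invalid model spec: " + "; ".join(problems))
    s = spec.settings
    H = s.horizon_cycles
    P = build_transition_stack(spec, strategy)

    occ = np.empty((H + 1, N_STATES))
    occ[0] = 0.0
    occ[0, HealthState.HEALTH] = 1.0
    for k in range(H):
        occ[k + 1] = occ[k] @ P[k]

    if spec.calibration.half_cycle_correction:
        occ_eff = 0.5 * (occ[:H] + occ[1:])
    else:
        occ_eff = occ[:H]

    u = spec.utilities.as_array()
    qaly = occ_eff @ u * s.cycle_length

    state_costs = occ_eff @ state_cost_vector(spec, strategy)
    examined = occ_eff[:, list(spec.calibration.exam_states(strategy))].sum(axis=1)
    exam = _exam_cost(spec, strategy)
    if spec.calibration.screening_per_cycle:
        exam_costs = exam * examined
    else:
        exam_costs = np.zeros(H)
        exam_costs[0] = exam * examined[0]
    cost = state_costs + exam_costs

    w = discount_weights(spec)
    trace = CohortTrace(occupancy=occ, start_age=s.start_age)
    return StrategyOutcome(
        strategy=strategy,
        total_cost=float(cost @ w),
        total_qaly=float(qaly @ w),
        trace=trace,
        per_cycle_cost=cost * w,
        per_cycle_qaly=qaly * w,
        per_cycle_cost_undiscounted=cost,
        per_cycle_qaly_undiscounted=qaly,
    )


@dataclass(frozen=True)
class MicrosimOutcome:
    """Monte Carlo estimate of a strategy outcome with standard errors."""

    strategy: str
    n_individuals: int
    total_cost: float
    total_qaly: float
    se_cost: float
    se_qaly: float


def microsim_oracle(spec: ModelSpec, strategy: str, n_individuals: int,
                    seed: int) -> MicrosimOutcome:
    """Estimate the cohort outcome by simulating individual random walks.

    Each individual starts in health and moves through the same age-dependent
    transition matrices; per-individual discounted rewards follow exactly the
    reward rules of :func:`run_cohort`, so the sample means are unbiased for
    the cohort values.  Standard errors are the sample-mean standard errors.
    """
    if n_individuals < 1:
        raise InvalidParameterError("n_individuals must be >= 1")
    s = spec.settings
    H = s.horizon_cycles
    P = build_transition_stack(spec, strategy)
    cum = P.cumsum(axis=2)
    rng = np.random.default_rng(seed)

    u = spec.utilities.as_array()
    base_cost = state_cost_vector(spec, strategy)
    exam = _exam_cost(spec, strategy)
    exam_mask = np.zeros(N_STATES, dtype=bool)
    exam_mask[list(spec.calibration.exam_states(strategy))] = True
    w = discount_weights(spec)
    hcc = spec.calibration.half_cycle_correction

    states = np.zeros(n_individuals, dtype=np.int64)
    qaly = np.zeros(n_individuals)
    cost = np.zeros(n_individuals)
    for k in range(H):
        r = rng.random(n_individuals)
        nxt = (r[:, None] > cum[k][states]).sum(axis=1)
        if hcc:
            q_k = 0.5 * (u[states] + u[nxt])
            c_k = 0.5 * (base_cost[states] + base_cost[nxt])
            e_k = 0.5 * (exam_mask[states].astype(float)
                         + exam_mask[nxt].astype(float))
        else:
            q_k = u[states]
            c_k = base_cost[states].copy()
            e_k = exam_mask[states].astype(float)
        if spec.calibration.screening_per_cycle or k == 0:
            c_k = c_k + exam * e_k
        qaly += w[k] * q_k * s.cycle_length
        cost += w[k] * c_k
        states = nxt

    n = n_individuals
    return MicrosimOutcome(
        strategy=strategy,
        n_individuals=n,
        total_cost=float(cost.mean()),
        total_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )
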