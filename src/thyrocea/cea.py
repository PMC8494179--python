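"""Cost-effectiveness statistics and decision rules for two strategies.

Conventions: "strategy 1" is the intervention under evaluation (screening)
and "strategy 0" the comparator (non-screening); increments are 1 minus 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import NON_SCREENING, SCREENING, InvalidParameterError, ModelSpec
from .cohort import StrategyOutcome, run_cohort

__all__ = [
    "ICER",
    "CEAResult",
    "icer",
    "net_monetary_benefit",
    "threshold_decision",
    "cea_result",
    "compare_strategies",
    "DOMINANT",
    "DOMINATED",
    "EQUIVALENT",
    "EQUAL_EFFECT",
]

DOMINANT = "strategy1_dominant"      # cheaper and more effective
DOMINATED = "strategy1_dominated"    # costlier and less effective
EQUIVALENT = "equivalent"            # identical cost and effect
EQUAL_EFFECT = "equal_effect"        # same effect; compare costs only


@dataclass(frozen=True)
class ICER:
    """An incremental cost-effectiveness ratio or a dominance classification.

    ``value`` is in USD per QALY and is ``None`` exactly when the increments
    make the ratio meaningless (dominance or an equal-effect tie).
    """

    value: float | None
    classification: str | None


def icer(cost1: float, qaly1: float, cost0: float, qaly0: float) -> ICER:
    """Classify the strategy-1 vs strategy-0 comparison.

    Returns a ratio when both strategies trade off cost against effect, and a
    dominance/tie classification otherwise.
    """
    d_cost = cost1 - cost0
    d_qaly = qaly1 - qaly0
    if d_qaly == 0.0:
        if d_cost == 0.0:
            return ICER(None, EQUIVALENT)
        return ICER(None, EQUAL_EFFECT)
    if d_cost < 0.0 and d_qaly > 0.0:
        return ICER(None, DOMINANT)
    if d_cost > 0.0 and d_qaly < 0.0:
        return ICER(None, DOMINATED)
    return ICER(d_cost / d_qaly, None)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = wtp * qaly - cost, in USD."""
    if wtp < 0:
        raise InvalidParameterError(f"willingness-to-pay {wtp} must be >= 0")
    return wtp * qaly - cost


@dataclass(frozen=True)
class CEAResult:
    """Full two-strategy comparison at a willingness-to-pay threshold."""

    strategy1: str
    strategy0: str
    cost1: float
    qaly1: float
    cost0: float
    qaly0: float
    incremental_cost: float
    incremental_qaly: float
    icer: ICER
    cer1: float
    cer0: float
    wtp_threshold: float
    decision: str

    def to_dataframe(self) -> pd.DataFrame:
        """Summary table with one row per strategy."""
        v = self.icer.value
        return pd.DataFrame(
            {
                "strategy": [self.strategy1, self.strategy0],
                "total_cost": [self.cost1, self.cost0],
                "total_qaly": [self.qaly1, self.qaly0],
                "cer": [self.cer1, self.cer0],
                "incremental_cost": [self.incremental_cost, None],
                "incremental_qaly": [self.incremental_qaly, None],
                "icer": [v if v is not None else self.icer.classification, None],
                "recommended": [self.decision == self.strategy1,
                                self.decision == self.strategy0],
            }
        )


def _decide(cost1, qaly1, cost0, qaly0, wtp) -> str:
    """Pick the strategy with the higher net monetary benefit at ``wtp``.

    Exact NMB ties go to the cheaper strategy (cost minimization); a full
    tie keeps the comparator.  For a positive QALY increment this reduces to
    the textbook rule "adopt the costlier strategy iff its ICER is below the
    threshold".
    """
    d_nmb = net_monetary_benefit(cost1, qaly1, wtp) - net_monetary_benefit(cost0, qaly0, wtp)
    if d_nmb > 0:
        return "strategy1"
    if d_nmb < 0:
        return "strategy0"
    if cost1 < cost0:
        return "strategy1"
    if cost0 < cost1:
        return "strategy0"
    return "strategy0"


def threshold_decision(cea: "CEAResult", wtp_threshold: float) -> str:
    """Recommended strategy name at the given willingness-to-pay threshold."""
    side = _decide(cea.cost1, cea.qaly1, cea.cost0, cea.qaly0, wtp_threshold)
    return cea.strategy1 if side == "strategy1" else cea.strategy0


def cea_result(cost1, qaly1, cost0, qaly0, wtp_threshold,
               strategy1: str = SCREENING, strategy0: str = NON_SCREENING) -> CEAResult:
    """Assemble a :class:`CEAResult` from raw per-strategy totals."""
    side = _decide(cost1, qaly1, cost0, qaly0, wtp_threshold)
    return CEAResult(
        strategy1=strategy1,
        strategy0=strategy0,
        cost1=cost1,
        qaly1=qaly1,
        cost0=cost0,
        qaly0=qaly0,
        incremental_cost=cost1 - cost0,
        incremental_qaly=qaly1 - qaly0,
        icer=icer(cost1, qaly1, cost0, qaly0),
        cer1=cost1 / qaly1 if qaly1 != 0 else float("inf"),
        cer0=cost0 / qaly0 if qaly0 != 0 else float("inf"),
        wtp_threshold=wtp_threshold,
        decision=strategy1 if side == "strategy1" else strategy0,
    )


def compare_strategies(spec: ModelSpec, *, check: bool = True
                       ) -> tuple[CEAResult, StrategyOutcome, StrategyOutcome]:
    """Run both arms of the model and compare them at the spec's threshold."""
    sg = run_cohort(spec, SCREENING, check=check)
    nsg = run_cohort(spec, NON_SCREENING, check=False)
    result = cea_result(sg.total_cost, sg.total_qaly,
                        nsg.total_cost, nsg.total_qaly,
                        spec.settings.wtp_threshold)
    return result, sg, nsg
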