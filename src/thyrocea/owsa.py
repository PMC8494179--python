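"""One-way deterministic sensitivity analysis and tornado-diagram data.

Each parameter is pushed to the bounds of its published range (or base
+/-10% when no range is published) while everything else stays at base; the
model is re-run for both strategies at each bound.  The headline metric is
the incremental net monetary benefit of screening at the willingness-to-pay
threshold, which stays well-defined even where the ICER does not (dominance
regions); the ICER at each bound is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import cea_result, net_monetary_benefit
from .cohort import run_cohort
from .model import (
    ALL_PARAMS,
    SCREENING,
    NON_SCREENING,
    InvalidParameterError,
    ModelSpec,
    parameter_value,
    with_parameter_values,
)

__all__ = ["OWSAEntry", "one_way_sensitivity", "tornado", "tornado_to_dataframe"]

DEFAULT_RELATIVE_RANGE = 0.10


@dataclass(frozen=True)
class OWSAEntry:
    parameter: str
    low_value: float
    high_value: float
    metric_low: float          # incremental NMB of screening at the threshold
    metric_high: float
    icer_low: float | str
    icer_high: float | str
    bar_width: float
    decision_low: str
    decision_high: str
    decision_flip: bool


def _evaluate(spec: ModelSpec, wtp: float):
    sg = run_cohort(spec, SCREENING, check=False)
    nsg = run_cohort(spec, NON_SCREENING, check=False)
    res = cea_result(sg.total_cost, sg.total_qaly, nsg.total_cost,
                     nsg.total_qaly, wtp)
    inmb = net_monetary_benefit(sg.total_cost, sg.total_qaly, wtp) \
        - net_monetary_benefit(nsg.total_cost, nsg.total_qaly, wtp)
    icer_repr = res.icer.value if res.icer.value is not None else res.icer.classification
    return inmb, icer_repr, res.decision


def parameter_bounds(spec: ModelSpec, name: str) -> tuple[float, float]:
    """Published OWSA range for a parameter, or base +/-10% when absent."""
    dist = spec.distributions.get(name)
    base = parameter_value(spec, name)
    if dist is not None and dist.range_low is not None and dist.range_high is not None:
        return dist.range_low, dist.range_high
    return base * (1 - DEFAULT_RELATIVE_RANGE), base * (1 + DEFAULT_RELATIVE_RANGE)


def one_way_sensitivity(spec: ModelSpec, parameter: str,
                        low: float | None = None,
                        high: float | None = None) -> OWSAEntry:
    """Re-run both arms with one parameter at each bound of its range."""
    base = parameter_value(spec, parameter)  # raises on unknown parameter
    d_low, d_high = parameter_bounds(spec, parameter)
    low = d_low if low is None else float(low)
    high = d_high if high is None else float(high)
    if low > high:
        raise InvalidParameterError(
            f"{parameter}: low bound {low} exceeds high bound {high}")
    if (parameter.startswith(("utility.", "prob."))
            and not (0.0 <= low and high <= 1.0)) or low < 0:
        raise InvalidParameterError(
            f"{parameter}: bounds [{low}, {high}] outside validity domain")

    wtp = spec.settings.wtp_threshold
    _, _, base_decision = _evaluate(spec, wtp)
    m_low, icer_low, dec_low = _evaluate(
        with_parameter_values(spec, {parameter: low}), wtp)
    m_high, icer_high, dec_high = _evaluate(
        with_parameter_values(spec, {parameter: high}), wtp)
    return OWSAEntry(
        parameter=parameter,
        low_value=low,
        high_value=high,
        metric_low=m_low,
        metric_high=m_high,
        icer_low=icer_low,
        icer_high=icer_high,
        bar_width=abs(m_high - m_low),
        decision_low=dec_low,
        decision_high=dec_high,
        decision_flip=(dec_low != base_decision) or (dec_high != base_decision),
    )


def varied_parameters(spec: ModelSpec) -> list[str]:
    """Parameters included in the tornado: everything not declared fixed."""
    return [name for name in ALL_PARAMS
            if spec.distributions.get(name) is None
            or spec.distributions[name].family != "fixed"]


def tornado(spec: ModelSpec, parameters: list[str] | None = None) -> list[OWSAEntry]:
    """One-way analysis of every varied parameter, widest bar first.

    Ties in bar width break alphabetically so the ordering is deterministic.
    """
    names = varied_parameters(spec) if parameters is None else list(parameters)
    entries = [one_way_sensitivity(spec, name) for name in names]
    return sorted(entries, key=lambda e: (-e.bar_width, e.parameter))


def tornado_to_dataframe(entries: list[OWSAEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low_value for e in entries],
            "high": [e.high_value for e in entries],
            "metric_low": [e.metric_low for e in entries],
            "metric_high": [e.metric_high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "width": [e.bar_width for e in entries],
            "flip": [e.decision_flip for e in entries],
        }
    )
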