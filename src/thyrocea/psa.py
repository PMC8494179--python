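"""Probabilistic sensitivity analysis.

Every uncertain parameter is drawn from its declared distribution (Beta for
probabilities and utilities, Gamma for costs), both strategy arms are re-run
with the same draw, and the cloud of (incremental QALY, incremental cost)
points summarizes the joint decision uncertainty.  Parameters shared between
arms are drawn once per iteration; all draws are independent.  A single
seeded generator drives the whole run, with the draw order fixed by the
parameter declaration order, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import run_cohort
from .model import (
    NON_SCREENING,
    SCREENING,
    InvalidParameterError,
    ModelSpec,
    ResolvedDistribution,
    resolve_distribution,
    with_parameter_values,
)
from .owsa import varied_parameters

__all__ = [
    "PSASample",
    "PSAScatter",
    "CEACCurve",
    "sample_parameters",
    "run_psa",
    "prob_cost_effective",
    "ceac",
    "default_wtp_grid",
]

logger = logging.getLogger(__name__)

MAX_REDRAWS = 100


@dataclass(frozen=True)
class PSASample:
    """One joint draw of all distributed parameters."""

    values: dict[str, float]
    index: int = 0


@dataclass(frozen=True)
class PSAScatter:
    """Monte Carlo cloud of incremental outcomes (screening minus non-screening)."""

    inc_qaly: np.ndarray
    inc_cost: np.ndarray
    seed: int
    n_draws: int
    redraws: int = 0
    samples: pd.DataFrame | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"draw": np.arange(self.n_draws),
             "inc_qaly": self.inc_qaly,
             "inc_cost": self.inc_cost}
        )


def _resolved(spec: ModelSpec) -> dict[str, ResolvedDistribution]:
    return {name: resolve_distribution(spec.distributions[name])
            for name in varied_parameters(spec)
            if name in spec.distributions}


def sample_parameters(spec: ModelSpec, rng: np.random.Generator,
                      index: int = 0) -> PSASample:
    """Draw one value per distributed parameter (shared ones drawn once).

    Beta draws land in [0, 1] by construction, so utilities and probabilities
    need no clamping; fixed parameters return their base value.
    """
    resolved = _resolved(spec)
    return PSASample(
        values={name: float(dist.sample(rng)) for name, dist in resolved.items()},
        index=index,
    )


def run_psa(spec: ModelSpec, n_draws: int | None = None,
            seed: int | None = None, keep_samples: bool = False) -> PSAScatter:
    """Monte Carlo PSA: re-run both arms per draw, collect increments.

    A draw that yields a structurally invalid model (competing probabilities
    exceeding 1 in some row) is discarded and redrawn; the redraw count is
    logged and recorded on the scatter.
    """
    n_draws = spec.settings.psa_draws if n_draws is None else int(n_draws)
    seed = spec.settings.rng_seed if seed is None else int(seed)
    if n_draws < 1:
        raise InvalidParameterError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)

    inc_qaly = np.empty(n_draws)
    inc_cost = np.empty(n_draws)
    redraws = 0
    rows = [] if keep_samples else None
    for i in range(n_draws):
        for attempt in range(MAX_REDRAWS):
            sample = sample_parameters(spec, rng, index=i)
            try:
                drawn = with_parameter_values(spec, sample.values)
                sg = run_cohort(drawn, SCREENING, check=False)
                nsg = run_cohort(drawn, NON_SCREENING, check=False)
            except InvalidParameterError:
                redraws += 1
                continue
            break
        else:
            raise InvalidParameterError(
                f"draw {i}: no valid parameter set in {MAX_REDRAWS} attempts")
        inc_qaly[i] = sg.total_qaly - nsg.total_qaly
        inc_cost[i] = sg.total_cost - nsg.total_cost
        if rows is not None:
            rows.append(sample.values)
    if redraws:
        logger.info("PSA discarded and redrew %d invalid draw(s)", redraws)
    return PSAScatter(
        inc_qaly=inc_qaly,
        inc_cost=inc_cost,
        seed=seed,
        n_draws=n_draws,
        redraws=redraws,
        samples=pd.DataFrame(rows) if rows is not None else None,
    )


def _screening_wins(inc_qaly, inc_cost, wtp) -> np.ndarray:
    """Per-point indicator that screening is the cost-effective choice.

    Decided by the sign of the incremental NMB; exact ties go to the cheaper
    strategy, and a cost tie to the more effective one, so the two
    strategies' probabilities always sum to one.
    """
    inmb = wtp * inc_qaly - inc_cost
    tie = inmb == 0.0
    return (inmb > 0.0) | (tie & ((inc_cost < 0.0)
                                  | ((inc_cost == 0.0) & (inc_qaly >= 0.0))))


def prob_cost_effective(scatter: PSAScatter, wtp: float,
                        strategy: str = SCREENING) -> float:
    """Fraction of PSA draws in which the strategy has the higher NMB."""
    if scatter.n_draws < 1:
        raise InvalidParameterError("empty scatter")
    wins = _screening_wins(scatter.inc_qaly, scatter.inc_cost, wtp)
    p = float(wins.mean())
    if strategy == SCREENING:
        return p
    if strategy == NON_SCREENING:
        return 1.0 - p
    raise InvalidParameterError(f"unknown strategy {strategy!r}")


def default_wtp_grid() -> np.ndarray:
    """0 to 200,000 USD/QALY in steps of 5,000."""
    return np.arange(0.0, 200_000.0 + 1, 5_000.0)


@dataclass(frozen=True)
class CEACCurve:
    """Cost-effectiveness acceptability as a function of willingness to pay."""

    wtp: np.ndarray
    p_screening: np.ndarray
    p_non_screening: np.ndarray
    crossover_wtp: float | None   # smallest grid wtp with p_screening > 0.5

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp,
             "p_screening": self.p_screening,
             "p_non_screening": self.p_non_screening}
        )


def ceac(scatter: PSAScatter, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Acceptability curve over a willingness-to-pay grid."""
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("wtp grid must be strictly increasing")
    p_sg = np.array([prob_cost_effective(scatter, w) for w in grid])
    above = np.nonzero(p_sg > 0.5)[0]
    crossover = float(grid[above[0]]) if above.size else None
    return CEACCurve(
        wtp=grid,
        p_screening=p_sg,
        p_non_screening=1.0 - p_sg,
        crossover_wtp=crossover,
    )
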