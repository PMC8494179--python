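#!/usr/bin/env python
"""Probabilistic sensitivity analysis: 1,000 Monte Carlo draws.

Every uncertain parameter is drawn from its Beta (probabilities, utilities)
or Gamma (costs) distribution; both arms are re-run per draw and the cloud
of incremental (QALY, cost) points is summarized at the $50,000/QALY
threshold.
"""

from pathlib import Path

import numpy as np

import thyrocea as t
from thyrocea.plots import scatter_plot

OUT = Path(__file__).resolve().parent.parent / "results" / "psa"
SEED = 2021


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = t.default_model()
    scatter = t.run_psa(spec, n_draws=1000, seed=SEED)
    df = scatter.to_dataframe()
    df.to_csv(OUT / "scatter.csv", index=False)
    scatter_plot(df, OUT / "scatter.png", wtp=spec.settings.wtp_threshold)

    wtp = spec.settings.wtp_threshold
    q1 = float(np.mean((scatter.inc_cost > 0) & (scatter.inc_qaly > 0)))
    p_nsg = t.prob_cost_effective(scatter, wtp, t.NON_SCREENING)
    print(f"PSA: {scatter.n_draws} draws, seed {scatter.seed}, "
          f"{scatter.redraws} redraws")
    print(f"  first-quadrant share (costlier and more effective): {q1:.1%}")
    print(f"  P(non-screening cost-effective at ${wtp:,.0f}/QALY): {p_nsg:.1%}")
    print(f"  P(screening cost-effective):                        {1-p_nsg:.1%}")
    print(f"  outputs in {OUT}")


if __name__ == "__main__":
    main()
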