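#!/usr/bin/env python
"""Cost-effectiveness acceptability curves from the PSA scatter.

Sweeps the willingness-to-pay threshold from $0 to $200,000/QALY in $5,000
steps and reports, at each threshold, the probability that each strategy has
the higher net monetary benefit, plus the crossover threshold above which
screening becomes the more acceptable strategy.
"""

from pathlib import Path

import thyrocea as t
from thyrocea.plots import ceac_plot

OUT = Path(__file__).resolve().parent.parent / "results" / "ceac"
SEED = 2021


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = t.default_model()
    scatter = t.run_psa(spec, n_draws=1000, seed=SEED)
    curve = t.ceac(scatter)
    df = curve.to_dataframe()
    df.to_csv(OUT / "ceac.csv", index=False)
    ceac_plot(df, OUT / "ceac.png")

    p50 = curve.p_screening[curve.wtp == 50_000][0]
    print(f"CEAC over {len(curve.wtp)} thresholds (0 to 200k step 5k)")
    print(f"  acceptability of screening at $50,000/QALY: {p50:.1%}")
    if curve.crossover_wtp is not None:
        print(f"  screening overtakes non-screening above "
              f"${curve.crossover_wtp:,.0f}/QALY")
    else:
        print("  screening never overtakes non-screening on the grid")
    print(f"  outputs in {OUT}")


if __name__ == "__main__":
    main()
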