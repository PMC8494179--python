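# Methods

## Model structure

The decision problem compares two lifetime strategies for an asymptomatic
cohort entering at age 20: annual neck-ultrasound screening (SG) versus
routine physical examination without ultrasound (NSG). Disease natural
history is a discrete-time Markov chain over six states — health, benign
thyroid nodules (BTN), malignant thyroid nodules (MTN), post-operative
stability, recurrence, death — advanced in 1-year cycles over a 55-year
horizon.

Row composition of the transition matrix at each age:

- **health** → BTN (arm-specific incidence), → MTN (arm-specific
  incidence), → death (background mortality `q(age)`), remainder stays;
- **BTN** → MTN (progression, shared across arms), → death (`q`),
  remainder stays; no regression to health;
- **MTN** → death (`q` plus the arm's excess cancer mortality); all other
  residents move to post-operative stability — surgery is assumed completed
  within the one-year cycle, so MTN is a one-cycle tunnel;
- **post-op** → recurrence (shared rate), → death (`q`), remainder stays;
- **recurrence** is absorbing for disease moves but remains exposed to
  `q`; **death** is absorbing outright.

Rates observed over multi-year windows are converted to annual
probabilities with `p = 1 − (1 − p_t)^(1/t)`; the bundled transition values
are already annual. Ages past the life table's last row reuse its final
entry.

## Rewards and discounting

Cycle `k` accrues `occupancy(k) · u` QALYs and `occupancy(k) · c` dollars,
both discounted at 5%/year for the default horizon. Per-state annual costs:
benign-nodule follow-up in BTN, post-cancer follow-up in post-op,
recurrence care in recurrence, and the arm's examination cost (ultrasound
vs. physical exam). The one-off cancer treatment cost is implemented as the
MTN state's per-cycle cost: residence there lasts exactly one cycle, so a
per-cycle charge is a once-per-case charge on entrants.

Three reward conventions are deliberately configurable, because published
cohort models vary on them and printed summary tables rarely say which was
used:

- `discount_timing` — `"start"` (cycle 0 undiscounted, weight `(1+r)^-k`)
  or `"end"` (rewards credited at cycle end, weight `(1+r)^-(k+1)`, the
  default of common decision-tree software);
- `half_cycle_correction` — accrue on the mean of start- and end-of-cycle
  occupancy instead of the start-of-cycle vector;
- `screening_per_cycle` — charge the exam every cycle (lifelong annual
  programme) or once at entry;
- `exam_states_sg` / `exam_states_nsg` — which states incur the arm's exam
  cost each cycle.

## Bundled calibration

The bundled configuration reproduces the published base-case totals of the
analysis this package re-implements with: end-of-cycle discounting, no
half-cycle correction, annual screening charged to **every living member**
of the screening arm, the comparator's routine physical charged **only in
the health state** (once a nodule or cancer is under dedicated follow-up,
that follow-up subsumes the routine exam), and **no background mortality
within the horizon**. The last choice follows from two observations: the
55-year horizon itself encodes the cohort's remaining life expectancy
(healthy members are assumed to reach it), and the published QALY totals
(~18.7) equal the full 55-term discount sum (18.93) minus disease
disutility alone — a cohort thinned by ordinary mortality could not reach
them under end-timing, and start-timing pushes the comparator's cost total
out of range. A Gompertz–Makeham life table remains available
(`life_table: {kind: synthetic, life_expectancy: 80}`) and any real table
can be supplied as CSV.

Under this calibration the model yields SG $19,093.49 / 18.44 QALYs and
NSG $17,303.27 / 18.40 QALYs — within 2% and 10% respectively of the
published totals — but an ICER of ≈$46.6k/QALY against the published
≈$107k/QALY. This gap is structural, not a tuning failure: enumerating
every assignment of the six cost components to states and arms shows that
any mapping keeping the comparator's total near its published value must
charge nodule follow-up on the comparator's (larger) BTN occupancy, which
caps the incremental cost near $2,000, while the published ICER needs
roughly twice that at the QALY increment the published utility table
implies. Equivalently, the published increments require the comparator's
extra nodule-years to carry disutility but no follow-up cost — inconsistent
with its own cost table under any six-state structure of this shape. The
base-case totals are therefore reproduced; the published ICER, the derived
decision at $50,000/QALY, the ~70% PSA probability for non-screening and
the ~$115k CEAC crossover are not, and the corresponding acceptance tests
are left failing by design rather than loosened.

## Parameters

All parameters carry a base value, a one-way range, and a sampling
distribution in the bundled YAML config (schema-versioned; unknown keys are
rejected). Utilities are dimensionless in [0, 1] with health pinned at 1
and death at 0; costs are 2017 USD; probabilities are annual. Gamma shapes
are read as (shape, scale), so the treatment-cost Gamma(29, 706) has mean
20,474 ≈ its base 20,174.58. A Beta whose printed shapes are degenerate
(the post-operative utility's Beta(1, 0)) is repaired by moment matching:
mean = base value, SD = range/4, putting ~95% of draws inside the published
range. Known discrepancies retained as printed: the exam and follow-up
cost Gammas imply means 4–17% off their base values, the two
cancer-mortality Betas ~11–13% off, and the recurrence-cost range's upper
bound is garbled in the source (repaired to 1.5× base; the printed lower
bound equals base/2).

## Sensitivity analyses

**One-way:** each parameter (18 varied; the pinned utilities of health and
death are not uncertain quantities) is set to each bound of its range, both
arms re-run, and the swing recorded. The headline metric is the
incremental net monetary benefit of screening at $50,000/QALY — continuous
through dominance regions where the ICER is undefined — with the ICER
reported alongside. Parameters shared between arms (BTN→MTN progression,
post-operative recurrence) move in both arms at once. Ties in bar width
break alphabetically so the tornado is deterministic.

**Probabilistic:** one seeded generator drives the whole run; each of the
1,000 iterations draws every distributed parameter independently (shared
parameters once, applied to both arms), re-runs both arms, and records the
incremental pair. Draw order follows parameter declaration order, so runs
are bit-for-bit reproducible by (config, n_draws, seed). A draw producing
an infeasible row (competing probabilities > 1) is rejected and redrawn
with the count logged; under the bundled distributions this is never
triggered in practice. Acceptability at a threshold is the fraction of
draws with the higher net monetary benefit; exact ties (measure-zero) go to
the cheaper strategy, cost ties to the more effective one, so the two
curves always sum to 1. The CEAC grid spans $0–200,000 in $5,000 steps.

## Synthetic scenarios and oracles

`scenarios` generates three kinds of input so every stage is testable
without external data. Random model specifications draw utilities, costs
(exam ordering enforced), probabilities and settings from configurable
ranges chosen to be valid by construction at every age in the horizon.
Toy models embed an alive/dead chain in the six-state frame with
closed-form discounted totals (geometric sums), matched by the cohort
engine to 1e−9. Synthetic life tables use a Gompertz–Makeham hazard
`μ(x) = λ + a·e^{bx}` with λ = 2×10⁻⁴ and b = 0.09 fixed and the level `a`
solved by root-finding so that period life expectancy at birth hits a
target (default 80 years, a round value typical of high-income populations
in the study period); the last row is closed at q = 1.

A vectorized microsimulation replays the identical transition matrices and
reward rules as individual random walks. It shares no accumulation code
with the cohort recursion and serves as the Monte Carlo oracle: sample
means are unbiased for the cohort totals and the suite checks agreement
within three standard errors on toy, random and bundled models.

What the synthetic inputs do not emulate: real age-specific disease
incidence (transition probabilities are age-constant; only background
mortality is age-dependent), correlation between parameters (PSA draws are
independent), nodule size/stage structure, and treatment complications.
Passing tests therefore certify the machinery — conservation, discounting,
decision rules, reproducibility — not the epidemiological fidelity of any
particular parameterization.

## Numerical choices and limitations

Transition rows are validated to sum to 1 within 1e−12 and the engine
raises rather than renormalizes when competing probabilities exceed 1.
Cohort conservation holds to 1e−10 per cycle. Currency is carried at full
precision and rounded only for display. Problem sizes throughout (55×6×6
recursions, 10⁳-draw PSA, ~10⁵-walker microsimulations) run in seconds on
one core. The model inherits the published framework's simplifications: two
nodule classes only, immediate surgery for every detected cancer, no
active-surveillance arm, no post-operative complication costs, and a single
cohort without age/sex stratification.
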