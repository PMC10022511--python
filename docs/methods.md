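# Methods

## The model

`centolla` couples two dynamical layers of an artisanal king-crab
(*Lithodes santolla*) fishery in which part of the registered fleet
launders — "whitewashes" — the catch of unregistered, illegal vessels.

**Slow layer (the stock).** The crab population is a single dimensionless
state `x` (fraction of the carrying capacity `x0 = 1`) with an Allee
effect and a seasonal harvest term:

    dx/dt = x (1 - x)(x - λ) - e · (x / x0) · I(t, σ)

`λ` is the Allee threshold (default 0.1): an unfished stock below `λ`
declines to extinction, above it recovers to `x0`. `e` is the extraction
rate *relative to the crab's reproduction rate*, and `I(t, σ)` is 1 during
the open fraction `σ` of each year (window `[k, k + σ)` of year `k`) and 0
during the closure. The default `σ = 0.5` idealises the roughly
seven-month real season as half a year.

For constant `e` the in-season system has the two non-trivial equilibria

    x± = (1 + λ)/2 ± ½ √((1 + λ)² − 4(λ + e)),

which satisfy `x− + x+ = 1 + λ` and `x− · x+ = λ + e` and merge in a
saddle-node at the critical extraction rate `e* = (1 + λ)²/4 − λ`
(`e*(0.1) = 0.2025`). The `(e, x)` plane splits into regions I/II
(sustainable: the stock relaxes to `x+`), III (decays to extinction) and
IV (`e > e*`: no equilibria, unconditional collapse under year-round
harvest). Boundary ties are resolved by strict inequalities (`x = x+` → II,
`x = x−` → III) so the classification is deterministic.

**Fast layer (the fleet).** The `n = 1000` registered vessels are nodes of
an Erdős–Rényi `G(n, M)` graph with exactly `M = 1000` edges (mean degree
2 — vessels are sparsely spread over the grounds). Each vessel plays
*standard* (ignores the illegal fleet) or *super* (whitewashes for a
premium). Per-season payoffs are

    c(k_c, k_d) = (a/n) · x / (1 + [k_c + (1 + ψ k_d)]^γ)      (standard)
    d(k_c, k_d) = (1 + ψ) · c(k_c, k_d)                         (super)

with `k_c`/`k_d` the standard/super neighbours, `a` the share parameter
(what an interference-free all-standard fleet would extract in total), `ψ`
the mean-field intensity of unregistered vessels (default 0.3 — roughly
300 illegal vessels per 1000 registered) and `γ ∈ [0, 1]` the interference
exponent (default 0.25). The fleet's net extraction `e` is the sum of the
`n` payoffs. Note an asymmetry inherited from the bracket
`k_c + (1 + ψ k_d)`: super neighbours interfere only in proportion to the
illegal field, so at `ψ = 0` an all-super fleet feels no interference at
all while an all-standard fleet still does.

**Decisions.** Once per season every skipper evaluates the relative gain
`ΔS/S` of the opposite strategy. Because `d = (1 + ψ) c` identically, the
gain is a constant of the game: `+ψ` for standard → super and
`−ψ/(1 + ψ)` for super → standard, independent of neighbourhood and stock.
A standard fisher defects iff the gain strictly exceeds their aversion to
super fishing (`atsf`); a super fisher reverts iff the loss is strictly
smaller in magnitude than the social pressure they feel. Thresholds are
identical for all skippers and fixed for a run. From an all-super start
the stationary composition therefore falls into exactly three regimes —
ALL_SUPER (`|social pressure| < ψ/(1+ψ)`), ALL_STANDARD (pressure above
that line and `atsf > ψ`), and MIXED_HALF (both switches keep firing; the
fleet alternates all-super/all-standard seasons and averages one half) —
and the simulation must reproduce this map exactly, which the acceptance
suite checks against 100 random threshold draws.

## The coupling, and where the stock enters the payoff

A simulated year runs: decision phase → extraction `e_k` → integrate the
stock over `[k, k+σ)` with `e_k` and over `[k+σ, k+1)` unfished. `e_k` is
fixed at the season's start; there is no within-season feedback.

The stock dependence of harvesting is applied **once**, continuously,
through the `e · x / x0` term of the ODE, with seasonal payoffs evaluated
at full stock (`payoff_stock_coupling=False`, the default). Multiplying
the payoffs *additionally* by the previous-closure population double-counts
the dependence: in the reference half-year scenario (`a = 0.64`) it drives
the year-50 extraction down to ≈ 0.31 and the stock up to ≈ 0.79·x0,
whereas single coupling yields `e ≈ 0.393` and `x ≈ 0.66·x0` — the
sustainable-scenario values the model is built to produce (≈ 0.38 and
≈ 68 %). The double-counted variant is retained behind
`payoff_stock_coupling=True` for sensitivity analysis.

Decision scheduling is asynchronous: skippers are visited once per season
in a fresh uniformly random order and see earlier switches immediately,
with at most one switch each. Because the relative gain is
state-independent, this is outcome-equivalent to a synchronous pass; both
schemes are implemented (`update_scheme`) and their equivalence is tested
rather than assumed.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `n` | registered vessels | 1000 | count |
| `m_links` | competition edges | 1000 | count |
| `a` | share parameter | 0.64 | extraction / reproduction rate |
| `ψ` (`psi`) | illegal mean-field intensity; also the exact temptation | 0.3 | dimensionless |
| `γ` (`gamma`) | interference exponent | 0.25 | dimensionless |
| `λ` (`lambda_allee`) | Allee threshold | 0.1 | fraction of `x0` |
| `σ` (`sigma`) | open fraction of the year | 0.5 | years/year |
| `x0` | carrying capacity | 1.0 | normalised |
| `x_init` | initial stock | 1.0 | fraction of `x0` |
| `atsf` | aversion-to-super-fishing threshold | 0.5 | relative-gain units |
| `social_pressure` | tolerable relative loss (signed ≤ 0) | −0.1 | relative-gain units |
| `years` | horizon | 50 | years |

The default social pair (0.5, −0.1) lies in the no-switching ALL_SUPER
regime — the worst case an all-super fleet never leaves. Monte-Carlo
sweeps resample `atsf ~ U(0, 1)` and `social_pressure ~ U(−1, 0)`; these
ranges span all three regimes at `ψ = 0.3` and are this package's
convention (no field estimates exist), configurable per sweep.

## Numerical choices

* **Integration.** Adaptive RK45 (`scipy.integrate.solve_ivp`,
  `rtol 1e-9`, `atol 1e-12`) restarted at every season boundary; the
  forcing is discontinuous there and stepping across a switch biases
  collapse times. Output grid: 50 points per year, linear interpolation
  for threshold crossings.
* **Extinction.** Once `x < 1e-9` it is pinned to exactly 0 for the rest
  of the run; 0 is absorbing and floating-point undershoot must not go
  negative.
* **Collapse flag.** A run is "collapsed" when `x` first falls below
  `0.02·x0` — effectively extinct, well under the `λ = 0.1` threshold from
  which recovery is impossible anyway. This convention is used for
  reporting only; the dynamics never read it.
* **Reporting phase.** All "final" values are taken at the end of the last
  year's closure; the season records also carry the within-year minimum
  phase (`x_end_season`).
* **Ties.** Exact threshold equalities (relative gain = `atsf`, loss
  magnitude = pressure magnitude; `x` exactly on `x±`) never switch /
  classify to the region given by the strict inequality. Measure zero, but
  deterministic.
* **Seeding.** A single master seed feeds `numpy.random.SeedSequence`;
  each run spawns independent child streams for the graph draw and the
  per-season visiting orders, and sweeps spawn per-run seeds from the
  master stream, so every table is bit-reproducible.

## What the simulator does and does not emulate

The generator *is* the study system: there is no external data. Runs under
the default conditions reproduce the model's qualitative phenomenology —
bistability and harvest-induced saddle-node collapse, the three social
regimes, and the seasonal-closure rescue, where fleets extracting at
nominally unsustainable rates (`e > e*`, region IV) persist because the
stock recovers during closures. Passing tests therefore validate the
model's internal logic and its closed-form analysis, not the real fishery:
the model has no age/sex structure, no spatial heterogeneity or
demographic noise, a constant illegal field uncoupled from abundance or
enforcement, no price dynamics, and utilities are extraction rates, not
money. `λ` and the crab's reproduction rate are unknown for the real
species; all rates are relative.

## Problem sizes

The acceptance suite uses 30 graph realisations for the half-year-season
ensemble, 100 social-parameter draws for the regime map, and a 20 × 20
`(a, σ)` grid with one run per cell; ensemble standard errors at these
sizes are an order of magnitude below the tolerances checked.

## Known limitations

* `G(n, M)` degree fluctuations make fleet-level extraction vary by well
  under 1 % across realisations at `n = 1000`; single-run results are
  nearly deterministic, so ensembles are about degree mixing, not noise.
* The mixed regime is an alternating state; its "half standard"
  composition is a time average (last 20 seasons), not a frozen mixture.
* With `σ = 1` there is no closure; "population at the end of the previous
  closure" then means the end-of-year value.
* The closed-form region classification applies to the constant-harvest
  system; projecting seasonal runs onto it (the bifurcation projection) is
  diagnostic, not dynamical.
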