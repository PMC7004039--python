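# Methods

## Model

Six plant types share a homogeneous plot (order 10^4 m², within which all
seed dispersal is assumed homogeneous). The state is the vector of cover
fractions `b_1..b_6` (indices in competitive order: oak > pine >
rosemary > gorse > rock-rose > grass), four seed-bank levels for the
seeder types, and the time since the last fire. Competition follows the
hierarchical colonization model: type *i* colonizes any space not held by
itself or its superiors at rate `c_i`, dies at rate `m_i`, and is overgrown
in place by superior colonizers. Coexistence is possible only through a
competition–colonization trade-off; under the standard parameter set the
fire-free dynamics converge to an oak monoculture.

**Closed-form equilibrium.** The fire-free equilibrium is solved
sequentially down the hierarchy:
`b_i* = max(0, 1 − m_i/c_i − Σ_{j<i, b_j*>0} b_j*(1 + c_j/c_i))`, with
extinct types dropped from subsequent sums. The top competitor's
equilibrium `1 − m_1/c_1` never depends on lower types. This closed form
is used as an independent oracle for long integrations, including across
random parameter draws in the property tests.

**Fires.** The hazard is `λ(t) = F · Σ l_i b_i(t) + ε` with per-type
flammabilities `l_i`, a scenario multiplier `F`, and a bare-ground floor
`ε = 1e-4`/yr (mean return 10⁴ yr on empty ground). Waiting times are
exponential on this time-varying hazard, realized by time rescaling: an
Exp(1) variate is drawn after each fire and the next fire occurs when the
hazard integral along the running solution reaches it. A 2-yr minimum
return interval is enforced by deferring (not redrawing) the event. We
verified the alternative reading — freezing `T_f` at the composition of
the previous event — and rejected it: it abolishes the shrubland
attractor entirely (post-fire covers are low, so frozen hazards are always
small), which contradicts the bistability the model is built to study.

**Post-fire responses.** At a fire, seeders lose all cover (severe
crown-fire assumption) and resprouters retain `r_i` (oak 0.9, grass 0.4).
Seeders re-establish through `α_i = C γ_i S_i / Σ γ_k S_k`, which
partitions the fixed capacity `C = 0.014`/yr across seeders by germinable
seed mass; `Σα` is exactly `C` whenever any bank is positive. The term
represents post-fire establishment, so it is inactive in stands that have
never burned (it switches on at the first fire, or immediately when a run
is started from a recently burned stand via a finite `tau0`); once active
it stays on, its magnitude governed entirely by the banks. The pine
aerial bank is released by fire — set to the pre-fire pine cover,
provided the stand age reached pine maturity — and expires 2 yr later;
this reproduces the loss of pines whenever two fires fall within the
maturity age. Shrub soil banks follow `dS/dt = p·b − d·S` (defaults
`p = 1`, `d = 0.2`/yr); only bank *ratios* enter `α`, so these constants
mainly set how fast the seeder mix re-equilibrates.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `c_i` | colonization rates | 0.047, 0.053, 0.045, 0.067, 0.11, 0.22 | 1/yr |
| `m_i` | mortality (1/lifespan) | 1/400, 1/125, 1/50, 1/25, 1/15, 1/40 | 1/yr |
| `r_i` | cover kept at fire | 0.9, 0, 0, 0, 0, 0.4 | – |
| `l_i` | flammability | 1/400, 1/20, 1/15, 1/10, 1/10, 1/10 | 1/yr |
| `γ_i` | post-fire establishment fraction | –, 0.040, 0.0016, 0.0029, 0.00078, – | – |
| `C` | seeder recruitment capacity | 0.014 | 1/yr |
| `ε` | bare-ground hazard | 1e-4 | 1/yr |

Aridity scenarios vary `r1 ∈ {0.9, 0.75, 0.6}`,
`c1 ∈ {0.047, 0.035, 0.023, 0.011}` and `F ∈ {1, 1.2, 1.5, 3}` (48 cells;
only the endpoints of the latter two grids are published, the interior
values being the ones used in the published example scenarios). The
bistable example cell is `(r1=0.6, c1=0.023, F=1.2)`; a published caption
prints `c1 = 0.0023`/yr for it, but that value is below oak mortality
(1/400/yr), under which no forest state can exist at all, and the same
caption cross-references the grid column whose value is 0.023 — we treat
the printed 0.0023 as a typo and use 0.023 (both reachable via config).

## Numerics

Fixed-step classical RK4 at `dt = 1/365` yr, with the establishment rates
held over each step, the seed-bank linear ODE advanced exactly per step,
and fires applied as instantaneous resets at step boundaries (event
timing is therefore resolved to one day). Covers below 1e-12 are clipped
to zero (RK overshoot near extinction); a run aborts if total cover
exceeds `1 + 1e-6`, and the suite verifies the simplex is respected on
all 48 scenario cells. Halving `dt` changes 1000-yr fire-free endpoints
by < 1e-6, and the kernel endpoint agrees with an adaptive
reference integration (scipy `solve_ivp` at rtol 1e-10) to < 1e-6. The
inner loop is numba-compiled; every run is bit-reproducible given its
seed, and ensembles spawn per-replicate streams from one master seed.

## Calibration

Old-field chronosequence records (site, years since abandonment, cover
per type) are treated as one successional time series (space-for-time
substitution) and compared with the fire-free model started from small
abandonment covers `(0.01, 0.01, 0.01, 0.01, 0.01, 0.02)`. The objective
is the squared deviation summed over records, normalized per type by the
data variance; goodness of fit is reported as the pooled efficiency
`H² = 1 − SSE_norm/N_norm` (1 = perfect, 0 = per-type-mean predictor).
The minimizer is simulated annealing: single-coordinate Gaussian
proposals of s.d. 5% of the box width, scaled with √(T/T₀) (floored at
2%) as the geometric schedule (T₀ = 1, ratio 0.995/step, 2·10⁴ steps)
cools — fixed-width proposals stall in ≥5 dimensions. Best-ever point is
returned; runs are seed-reproducible. Fire-plot series are fitted the
same way with `(C, r6, c6)` free, simulating each plot's imposed burn
times instead of stochastic fires. Data uncertainty is propagated by
re-calibrating on site-level bootstrap resamples with additive truncated
Gaussian cover noise (default s.d. 0.05) and reporting the pointwise
min/max trajectory envelope.

## Synthetic data

The generator emulates the two calibration datasets: 73 old-field sites
with ages uniform on [1, 100] yr sampled from the fire-free trajectory,
and 4 fire-plot series with one or two experimental burns in the first
15 yr, sampled annually for 20 yr. Noise is independent truncated
Gaussian per record and type (clip to [0, 1], renormalize totals above 1),
and generating truth is stored for recovery tests. The generator does not
emulate between-site environmental heterogeneity, spatial autocorrelation
or observer bias, so passing recovery tests demonstrate correctness of
the pipeline under the assumed error model, not robustness to structured
field error.

## Experiment conventions

Long-term runs last 10,000 yr; "final" covers are means over the last
20% of a run. States are classified as forest (oak > 0.5), open
shrubland (oak < 0.05 and shrubs+grass > 0.05) or mixed; bistability is
detected as replicate-level divergence of classified states within one
scenario cell. Fire-free runs last 1000 yr. Short-term experiments run
100 replicates of 100 yr and evaluate covers as means over years 80–100,
with threshold probabilities P(oak < 0.5), P(oak < 0.65), P(oak > 0.3).
Named starting communities: forest `(0.9, 0, 0, 0, 0, 0.05)`, shrubland
with grasses `(0.01, 0, 0.1, 0.1, 0.2, 0.2)`, mixed `0.15` per type (the
published community); the first two are stand-ins for supplementary-only
tables. Ensemble sizes in the shipped analyses (e.g. 40 replicates for
the baseline fire regime, 10 shrubland-start plus 30 forest-start for the
bistable cell — forest-phase fires are rare, so that side needs the
larger ensemble — and 100 for
short-term runs) were chosen so that ensemble means are stable to a few
percent across master seeds; the factorial Monte-Carlo over initial
conditions is provided as a scaled-down routine (default 100 random
draws per cell rather than thousands).

A gradually-harshening-aridity variant interpolates `(r1, c1, F)`
linearly in time, implemented piecewise-constant over 1-yr slices with
state carried across slices; restarting the exponential fire clock at
slice boundaries is statistically neutral by memorylessness.

## Known limitations

- **Shrubland fire frequency.** Our open-shrubland attractor burns every
  ~15 yr (bistable cell, F = 1.2) with grass rebounding to ~0.7 cover
  between fires, where published estimates for the same cell are ~27 yr,
  implying ~0.3 mean flammable cover. Every parameter controlling this
  recovery (grass colonization 0.22/yr, retention 0.4, flammabilities) is
  from the published standard set, so the gap must trace to unpublished
  seed-bank/recolonization detail not recoverable from the main text.
  Consequences: shrubland return intervals sit at the fast end of the
  published 13–33 yr cross-scenario band, and the probability that a
  shrubland gains oak within a century is correspondingly low (~0.1–0.15
  rather than ~0.46), because twice-as-frequent fires suppress oak
  recovery. The forest-side regimes (~275 yr baseline, ~500 yr bistable
  forest) and all deterministic results are unaffected. Two acceptance
  checks encode the published shrubland numbers and are expected to fail
  against this implementation; they are kept failing rather than
  recalibrated.
- Fires are total-plot, severity-uniform crown fires; no partial burns,
  fuel-moisture dynamics or spatial spread.
- Aridity enters only through constant (or linearly ramped) parameter
  shifts; rainfall variability and CO₂ effects are out of scope.
- Competition is implicit (space proxy); no age/size structure within a
  type, so e.g. pine maturity is tracked by stand age, not cohorts.
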