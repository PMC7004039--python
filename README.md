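# firesucc

A stochastic vegetation–fire succession model for Western Mediterranean
plant communities, with parameter calibration and aridity-scenario
experiment runners.

Mediterranean old fields recover toward *Quercus*-dominated forest, but
recurrent wildfire and increasing aridity can instead stall them in a
flammable open shrubland. `firesucc` implements a six-type
competition–colonization model with differential post-fire plant responses
and cover-dependent stochastic fires, and the analyses that ask whether
forest and shrubland are alternative (stochastically) stable states. It is
aimed at fire ecologists and modellers who want a small, fully tested,
reproducible simulator of this feedback.

## The model

Six plant types in competitive (inverse-successional) order — *Quercus*
spp. (Q, resprouter), *Pinus halepensis* (P, seeder), *Rosmarinus
officinalis* (R), *Ulex parviflorus* (U), *Cistus* spp. (C, all seeders)
and *Brachypodium retusum* (B, resprouter) — occupy cover fractions
`b_1..b_6` of a homogeneous plot. Cover obeys a hierarchical
competition–colonization system (Tilman-style):

    db_i/dt = c_i b_i (1 − Σ_{j≤i} b_j) − m_i b_i − Σ_{j<i} c_j b_j b_i
              + α_i(t) (1 − Σ_j b_j)

with colonization rates `c_i` (1/yr), mortalities `m_i = 1/lifespan`, and a
post-fire establishment term `α_i` for the four seeders,

    α_i = C γ_i S_i / Σ_k γ_k S_k ,

which splits a fixed recruitment capacity `C` across seeders in proportion
to germinable seed mass `γ_i S_i`. Pine carries an aerial seed bank
released by fire (only if the stand reached maturity, ~10 yr) and viable
~2 yr; shrub soil banks are fed by standing cover and decay between fires.

Fires are instantaneous random events with exponential waiting times on
the cover-dependent hazard

    1/T_f = Σ_i l_i b_i + ε ,

(`l_i` = flammability, `ε = 1e-4`/yr a bare-ground floor; minimum 2 yr
between fires). At a fire, seeders lose all cover; resprouters keep a
fraction `r_i` (oak 0.9, grass 0.4). Aridity scenarios lower oak
resprouting `r1` and colonization `c1` and scale all flammabilities,
combined in a 3 × 4 × 4 factorial of 48 cells.

Calibration fits `c1..c5` to old-field chronosequence cover data (and
`C, r6, c6` to experimental fire-plot series) by simulated annealing on a
variance-normalized squared deviation; a bundled synthetic-data generator
emulates both datasets so the whole pipeline is testable offline.

## Worked example

```python
from firesucc import FireVegetationModel

model = FireVegetationModel()          # standard calibrated parameters
res = model.simulate(duration=10_000, seed=42)
print(res.summary())
```

```
Fire-vegetation simulation
==========================
duration: 10000 yr   dt: 0.00273973 yr   seed: 42
fires realized: 45
state (mean cover, last 20%): forest

type   final cover
  Q    0.9356
  P    0.0000
  R    0.0000
  U    0.0091
  C    0.0000
  B    0.0000
  free space 0.0553
mean fire return interval (last 20%): 221.7 yr
time to oak dominance (cover > 0.5): 148 yr
```

Under the historical-climate parameter set the system converges to oak
forest (`b_Q ≈ 0.94`, near the closed-form fire-free equilibrium
`1 − m_1/c_1 ≈ 0.95`) with rare fires, despite starting from a recently
abandoned field. Oak crosses dominance (cover 0.5) around 150 yr here;
the realized fire regime emerges from the community composition rather
than being imposed. Under harsher aridity cells — try
`model.with_scenario(ScenarioSpec(r1=0.6, c1=0.023, flam_mult=1.2))` —
the same code produces either oak forest with centennial fires or an open
shrubland burning every ~15 yr, depending on the starting community and
the realized fire sequence (stochastic bistability).

The same machinery is scriptable from the shell:

```bash
firesucc simulate --seed 1 --outdir out/          # one run + fire log
firesucc grid --seed 1 --replicates 2             # 48-cell aridity factorial
firesucc synthesize --seed 1 --outdir syn/        # synthetic old-field data
firesucc calibrate --observations syn/observations.tsv --seed 1
```

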