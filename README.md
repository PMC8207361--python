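# fishscape

An individual-based model of an age-structured fish population on a
two-dimensional habitat landscape, built to study how **size-selective
fishing** changes the **spatial variability** of a population through
**age truncation**.

Exploited fish stocks lose their older age classes. If different ages
prefer different habitats (ontogenetic niche shift), removing the old
fish empties the habitats they occupied while the juveniles' habitats
stay crowded — the population becomes spatially more aggregated and,
plausibly, less resilient. Whether that happens, and how strongly,
should depend on how sharp the age-specific habitat preference is, on
the environment's carrying capacity, and on whether the landscape is
spatially smooth or fragmented. `fishscape` makes those ingredients
explicit and simulates them factorially. It is aimed at quantitative
ecologists and fisheries scientists who want a transparent, fast,
fully reproducible re-implementation of this class of model.

## The model in brief

* 11 × 11 closed-boundary lattice; cell `c` has fixed habitat index
  `H_c ∈ {0, 0.1, …, 1}` arranged as a smooth **gradient** or a random
  **fragmented** layout; all cells share carrying capacity `K`.
* Nine age classes; age `i` draws its habitat preference `Z_i` from a
  scaled Beta(1.2, 1.2) niche — **strong** preference (centers 0.2–0.8,
  width 0.4) or **weak** (centers 0.4–0.6, width 0.8).
* Movement (40 steps/year): each fish compares its cell with one random
  Moore neighbor and moves on a strict improvement of the basin-model
  suitability

      R(c, i) = 1 − |H_c − Z_i| − N_c / K.

* Yearly demography via Bernoulli draws from a Leslie design:
  reproduction (R₁=0.53, R₂=0.50, rest 0.01), survival
  (M₁,₂=0.10, M₃₋₈=0.40, M₉=1), fishing mortality `F ∈ {0,…,0.5}` added
  to ages 4–8; λ ≈ 0.9998 unfished, ≈ 0.9956 at F=0.5.
* Per year we record abundance by (cell, age class); per replicate we
  average **Shannon age diversity** `H' = −Σ p_i ln p_i` and **spatial
  CV** (sd/mean of per-cell totals) over years 5–15, then regress CV on
  diversity. A negative slope means age truncation raises spatial
  variability.

See `docs/methods.md` for the full model description and the reasoning
behind every numerical choice.

## Worked example

One replicate per fishing extreme, default scenario (strong preference,
gradient landscape, K = 40):

```python
from fishscape import SimConfig, run_simulation, summarize_replicate

for f in (0.0, 0.5):
    out = run_simulation(SimConfig(fishing_mortality=f, seed=42))
    s = summarize_replicate(out)
    print(f"F={f:.1f}  mean_shannon={s.mean_shannon:.4f}  "
          f"mean_cv={s.mean_cv:.4f}  mean_popsize={s.mean_popsize:.1f}")
```

prints

```
F=0.0  mean_shannon=1.8278  mean_cv=0.9252  mean_popsize=444.6
F=0.5  mean_shannon=1.4040  mean_cv=1.1025  mean_popsize=317.3
```

Maximal fishing truncates the age structure (Shannon diversity falls
from 1.83 to 1.40) and the population becomes more aggregated in space
(CV rises from 0.93 to 1.10), while total abundance changes relatively
less — the vital rates are designed so that age structure, not
population size, drives the spatial signal.

The same workflow from the shell:

```bash
fishscape grid --replicates 10 --seed 0 --out results/   # factorial experiment
fishscape analyze --summaries results/summaries.parquet --out results/ --plots
```

`analyze` writes `slopes.csv` (one CV~diversity slope ± SE per
preference × landscape × K combination), `factorial_model.txt` (the
per-landscape OLS fits with the diversity × preference × K interaction)
and optional figures. Single scenarios run with `fishscape run
--config cfg.yaml --seed 1 --out dir/`; every command writes a JSON
manifest from which the run can be reproduced bit for bit.

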