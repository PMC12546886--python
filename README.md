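# emseed

Toolkit for closed-loop electromagnetic-vibration seed treatment:

* **physics** — closed-form treatment physics: oscillating attenuated field,
  resonance-driven seed vibration amplitude, deposited energy (Simpson
  quadrature with an alias-free handling of the field oscillation),
  Helmholtz-coil center field, and the electrical power/energy budget.
* **phenotype** — a calibrated "virtual seed lab": logistic germination
  kinetics, vigor indices, composite seed-vigor score, a hormetic
  dose–response linking delivered electromagnetic dose to germination and
  vigor gains for three corn variety profiles, and stochastic batch
  simulation with beta-overdispersed replicates.  Includes the
  benefit–cost-ratio helper.
* **moo** — a hybrid GA–PSO cooperative-coevolution multi-objective
  optimizer over the six treatment variables (NSGA-II machinery, shared
  nondominated archive, crowding-guided swarm, periodic elite migration,
  on-line rate adaptation), plus plain NSGA-II and a Tchebycheff
  decomposition baseline, and exact 2-D/3-D hypervolume.
* **surrogate** — a pure-NumPy CNN-LSTM multi-task network (64×64×3 image
  branch, 50×128 sensor-sequence branch, attention pooling, 2176-dim
  fusion, 8 regression heads) with hand-written backpropagation, Adam,
  triangular cyclical learning rate, gradient clipping, leakage-safe
  batch-level 70/15/15 splitting and permutation attribution.
* **fixtures** — deterministic generators for all test inputs: the
  5×6×4 factorial treatment design (120 cells), per-variety dataset
  skeletons, synthetic seed images (rotated-ellipse morphology with a
  recoverable latent) and treatment sensor sequences with a documented
  channel map and known ground truth.
* **cli** — `emseed` command-line entry point tying everything together.

No deep-learning framework is required: the network runs on NumPy alone.

## CLI

All commands accept `--config FILE` (YAML, deep-merged over the shipped
`src/emseed/defaults.yaml`).

```bash
# generate fixtures (dataset skeleton: records.csv + arrays.npz + manifest.json)
emseed fixtures --mode dataset --out runs/fx --seed 1 --n-per-variety 200

# factorial experiment (phenotype records for every treatment cell)
emseed fixtures --mode factorial --out runs/fa --seed 1 --seeds-per-cell 10

# simulate a control or treated batch
emseed simulate --variety zhengdan958 --protocol control -n 2000 --seed 42 --out runs/sim
emseed simulate --variety zhengdan958 --protocol reference -n 2000 --seed 42 --out runs/sim2

# multi-objective optimization (hybrid | nsga2 | moead-tcheby)
emseed optimize --variety zhengdan958 --algorithm hybrid --iters 100 --seed 0 --out runs/opt

# validate a front against control batches
emseed evaluate --front runs/opt/front.tsv --variety zhengdan958 -n 500 --seed 3 --out runs/eval

# train the surrogate on generated fixtures
emseed train --fixtures runs/fx --seed 0 --out runs/train

# hypervolume of a front TSV
emseed hv --front runs/opt/front.tsv --ref "0,25000,330"
```

A custom protocol is six comma-separated values in the order
field_strength_mT, frequency_Hz, duration_s, voltage_amplitude_V,
pulse_width_ms, duty_cycle_pct.

## File formats

* `records.csv` — one row per seed (variety, batch id, treatment cell
  parameters, germination outcome and day, seedling/root lengths, latent
  and target columns).
* `arrays.npz` — named arrays `images` (N×64×64×3 uint8), `sequences`
  (N×50×128 float32), `targets` (N×8 float64), `batch_ids`; written by
  the dataset fixture mode next to a `manifest.json` carrying counts,
  the generator seed and a SHA-256 of the records file.
* `front.tsv` — decision variables + objective columns (`obj_neg_gain`,
  `obj_energy_J`, `obj_time_s`).
* `history.csv` — per-iteration hypervolume, diversity and operator rates.
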