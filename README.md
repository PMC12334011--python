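# crimedyn

A dynamical-systems toolkit for analyzing criminal involvement over the
life course.  The model is a discrete-time (annual) linear compartmental
system on five behavioral states:

| State | Meaning |
|-------|---------|
| `X`   | criminally inactive, no recent arrest history (never involved, or rehabilitated after three inactive years) |
| `C1`  | criminally active, never arrested |
| `A`   | arrested within the last year |
| `R`   | inactive within the last year but active within the last three, with an arrest history |
| `C2`  | criminally active with a past (not current) arrest |

Eleven flow rates between these states are free parameters; the five
stay probabilities are complements.  The package provides:

- **`crimedyn.model`** — the 5×5 row-stochastic transition structure,
  single-step updates, trajectory simulation, and the long-run
  equilibrium by closed form, stationary-distribution solve, and
  fixed-point iteration.
- **`crimedyn.sensitivity`** — partial derivatives, 1%-change
  elasticities, percentage-point changes, full-range one-parameter
  sweeps, and curvature (diminishing-returns) checks of the equilibrium
  law-abiding fraction X*.
- **`crimedyn.disparity`** — between-group gap tables, single-parameter
  equalization experiments, and gap-reduction elasticities for the
  equilibrium gap between two groups.
- **`crimedyn.states`** — assignment of person-wave panel records
  (offense/arrest flags) to the five states, wave-to-wave transition
  construction, and count-based empirical transition matrices by
  subgroup.
- **`crimedyn.estimation`** — per-arrow random-intercept logistic
  regression (adaptive Gauss–Hermite quadrature, 21 nodes) with
  quadratic age and sex×race interactions, population-averaged
  predictions, and subgroup probability tables with bootstrap or
  delta-method intervals.
- **`crimedyn.synth`** — a seeded synthetic panel generator with a
  `markov` mode (latent chain follows the configured rates exactly) and
  a `history` mode (the 3-year rehabilitation window is enforced so
  state assignment round-trips exactly).
- **`crimedyn.io` / `crimedyn.pipeline` / `crimedyn.cli`** — JSON/CSV
  formats, packaged parameter fixtures, an end-to-end pipeline with a
  run manifest, and a `crimedyn` command-line tool.

## Command line

```bash
# equilibrium of a packaged or user parameter file
crimedyn equilibrium --params params.json --out eq.json

# trajectory, sensitivity, sweep, disparity
crimedyn simulate --params params.json --steps 300 --out traj.csv
crimedyn sensitivity --params params.json --mode elasticity --out elast.csv
crimedyn sensitivity --params params.json --mode sweep --param "R->X" --out sweep.csv
crimedyn disparity --params-a black_men.json --params-b white_men.json --out gaps.csv

# synthetic panel -> state assignment -> estimation
crimedyn synth --config synth.yaml --seed 1 --out panel.csv --truth truth.csv
crimedyn assign --panel panel.csv --out states.csv --transitions trans.csv
crimedyn estimate --panel panel.csv --method empirical --out params.json

# full pipeline from a YAML config
crimedyn run --config run.yaml
```

Parameter JSON uses the eleven arrow keys (`"X->C1"`, `"X->A"`,
`"C1->X"`, `"C1->A"`, `"A->C2"`, `"A->R"`, `"C2->A"`, `"C2->R"`,
`"R->C2"`, `"R->A"`, `"R->X"`); stays are always derived.  Packaged
fixtures (accessible via `crimedyn.io.load_fixture_params` /
`load_fixture_state`) include the published men's parameter sets, the
full-sample average transition rows, and the printed initial state
distributions.

Exit codes: 0 success, 2 validation error, 3 numerical failure.

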