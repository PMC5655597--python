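# mcatsim

Simulation toolkit for **multidimensional computerized adaptive testing
(MCAT)** over a between-item multidimensional graded response model,
built around a 4-domain health-related-quality-of-life item bank design:

- **`mcatsim.mgrm`** — graded-response category probabilities, response
  simulation, log-likelihood, and per-item Fisher information (rank-1,
  one loading per item).
- **`mcatsim.estimation`** — MAP trait estimation with a correlated
  multivariate-normal prior (Newton–Raphson with expected-information
  Hessian), posterior information matrix, per-dimension standard errors.
- **`mcatsim.engine`** — the adaptive loop: one random starting item per
  domain, item selection maximising the determinant of the posterior
  information matrix (via the rank-1 determinant identity), per-dimension
  SE(θ) < 0.316 termination.
- **`mcatsim.study`** — the simulee grid (θ from −2 to +2 in steps of
  0.2, equal coordinates, 1000 replicates per point) with per-respondent
  seeded substreams; serial/parallel equivalence.
- **`mcatsim.usage`** — usage rates conditional on θ, overuse
  classification (rate > mean test length / bank size), active
  domain/bank size, overused-to-active overlap, RMSE/bias.
- **`mcatsim.synthetic`** — synthetic 194-item bank generator
  (domain sizes 50/63/35/46, discriminations 0.82–5.40, thresholds
  −7.57..7.67, 3–5 ordered categories, fixed 4×4 trait correlation
  matrix), MVN respondent populations, and the sparse-category
  collapsing rule (< 10 responses merged with adjacent categories).
- **`mcatsim.bankio` / `mcatsim.cli`** — bank CSV + YAML-sidecar format
  (with easiness→difficulty sign conversion), study output bundle,
  run manifests, and the `mcatsim` command line.

## CLI

```sh
mcatsim generate-bank --seed 1 --out bank.csv          # synthetic bank + sidecar
mcatsim run-cat --bank bank.csv --theta 0,0,0,0 --seed 1
mcatsim run-study --bank bank.csv --replicates 1000 --seed 1 --out run/
mcatsim summarize --bank bank.csv --results run/respondents.csv --out tables/
mcatsim accuracy  --bank bank.csv --results run/respondents.csv --out acc.csv
```

`run-study` writes `respondents.csv` (one row per simulated test),
`item_usage.csv`, `summary_{active_size,overused,overlap}.csv`
(rows = grid values, columns = Total + the four domains, integer
percents), `accuracy.csv`, and `manifest.json`. A flat YAML config can
replace the options (`--config run.yaml`).

## Notes

- Test length includes the random starting items; item-usage statistics
  count only adaptively selected items (see the `mcatsim.usage`
  docstring for why).
- All randomness flows through `numpy.random.Generator`; every simulee
  gets an independent substream derived from the master seed, so any
  single test is reproducible in isolation.
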