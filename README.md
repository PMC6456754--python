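# methyloflux

Constraint-based flux analysis and ¹³C mass-isotopomer algebra for
methylotroph central carbon metabolism. The package covers:

- **`model_io`** — metabolic-model data structures, a native JSON schema and
  a delimited reaction-table dialect (`id, name, equation, lb, ub,
  objective`), validation, and a desk-scale core-network fixture
  (methanol oxidation, RuMP, EMP/ED split, C3–C4 carboxylation, the
  PDH/MCL acetyl-CoA node, TCA, maintenance, glycogen/EPS sinks). The
  fixture uses lumped cofactors and an illustrative biomass equation: it
  exercises the engine and is **not** a substitute for a genome-scale model.
- **`fba`** — linear-programming flux balance analysis (scipy/HiGHS)
  maximizing biomass, with isotope-derived side constraints: flux-ratio
  equalities, flux-order inequalities, fixed fluxes/knockouts, an
  O₂/substrate consumption-ratio floor, growth-coupled biomass-composition
  sinks, and growth-/non-growth-associated ATP maintenance. Analyses:
  nested scenario ladders, robustness scans (fix one flux, re-optimize, map
  the feasibility limit), ratio-sensitivity scans, and maintenance grids.
- **`mid`** — mass-isotopomer distribution algebra: condensation
  convolution, a two-parameter forward labeling model of the acetyl-CoA
  node (PDH fraction `p`, CO₂ labeled fraction `f`), and inverse estimators
  for the acetyl-CoA MID, the PDH/MCL flux split, and the CO₂ pool.
- **`metabolomics`** — internal-standard + biomass normalization of pool
  measurements and volcano analysis (log2 fold change, Welch's t-test on
  log abundances, optional Benjamini–Hochberg).
- **`yields`** — exponential growth-rate fitting and specific-rate/yield
  arithmetic (product yields per substrate, biomass yield in g/g).
- **`synth`** — seeded, byte-reproducible generators for every input:
  labeling datasets, pool tables, growth curves.
- **`pipeline` / `cli`** — end-to-end orchestration with stage isolation.

## CLI

One executable, `methyloflux` (or `python -m methyloflux.cli`):

```sh
# write + validate the packaged core model
methyloflux model fixture core.json
methyloflux model validate core.json

# FBA
methyloflux fba run --model core.json --scenario scenario.yaml
methyloflux fba ladder --model core.json
methyloflux fba robustness --model core.json --reaction PDH --step 0.1
methyloflux fba ratio-scan --model core.json --num EDD --den EMP --values 0.1,1,10
methyloflux fba atpm-grid --model core.json --gam 0,30,60 --ngam 0,5,10

# 13C labeling
methyloflux mid simulate --p 0.33 --f 0.24 --out mids.tsv
methyloflux mid estimate --input mids.tsv

# pools, yields, synthetic data
methyloflux volcano --input pools.tsv
methyloflux yields --rates rates.yaml
methyloflux synth label --seed 0 --out mids.tsv

# everything at once (falls back to packaged synthetic data + core fixture)
methyloflux run-all --out out/ --seed 1
```

Scenario files are YAML mirroring `ScenarioConfig`:

```yaml
name: control
methanol_uptake: 19.3          # mmol/(gcdw.h), fixed
formate_production: 1.82
glycogen_fraction: 0.42        # share of dry weight, growth-coupled sink
eps_fraction: 0.10
o2_per_methanol_min: 0.5
maintenance: {gam: 54.35, ngam: 8.39}
ratio_constraints: [{numerator: MCL, denominator: PDH, ratio: 3.0}]
order_constraints: [{greater: AKGDH, lesser: SCS}]
fixed_fluxes: {FUM: 0.0}       # knockout (both bounds pinned)
```

Ladder files hold `scenarios:` lists with nested semantics (each entry
inherits and extends the previous one).

## Genome-scale models

A published genome-scale reaction table exported to the delimited dialect
loads via `methyloflux.model_io.read_model(path, format="reaction-table")`;
role annotations (`annotations["roles"]`: `methanol_uptake`,
`formate_excretion`, `o2_uptake`, `maintenance`, `biomass`, `emp`, `ed`,
`pdh`, `mcl`, `fumarase`, `akgdh`, `scs`, `gam_atp`, `gam_adp`) tell the
scenario machinery which reactions to constrain.

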