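# allopred

Single-species allometric projection of human pharmacokinetics from rat or
monkey data, aimed at antibody–drug conjugates and other IV biologics.

The package provides:

- **Concentration–time projection** (`allopred.scaling_methods`): eight preset
  methods that map an animal profile to a predicted human profile via
  `(D_h/D_a)^dose_exp × (W_a/W_h)^b(t)`, with volume exponents b ∈
  {1.0, 0.9, 0.8}, an optional 0.85 dose (clearance) exponent, and two
  piecewise methods that switch to b = 0.8 from day 14 onwards. Time points
  are never rescaled.
- **Fixed-exponent PK scaling** (`allopred.pk_scaling`): human clearance as
  `CL_a × (W_h/W_a)^0.85` and half-life as `t½_a × (W_h/W_a)^0.15`, plus the
  equivalent-time diagnostic `(W_h/W_a)^(e_V − e_CL)`.
- **Noncompartmental analysis** (`allopred.nca`): AUC (linear or
  linear-up/log-down trapezoid), terminal λz by best-adjusted-R² log-linear
  regression, half-life, clearance.
- **Prediction-error evaluation** (`allopred.evaluation`): predicted/observed
  fold ratios, counts inside the [0.5, 2], [0.5, 1.5] and [0.7, 1.3] ranges
  (plus the < 0.5 and > 2 tails), and the average fold error (geometric mean).
- **Synthetic ground truth** (`allopred.synthetic_pk`): paired animal/human
  two-compartment IV-bolus profiles whose CL/Q and V1/V2 obey configurable
  allometric exponents, with optional lognormal noise and LLOQ censoring.

Units throughout: time in days, concentration in µg/mL (≡ mg/L), body weight
in kg, dose in mg (per-kg doses in mg/kg), clearance in L/day. Dose ratios in
the projection always use total amounts; per-kg inputs are converted via body
weight at ingestion.

## Profile CSV format

UTF-8 CSV with a leading `#key=value` metadata block:

```
#species=monkey
#dose=1 mg/kg
#analyte=total
time_days,conc_ug_ml
1,100
7,50
```

`species` presets rat/monkey/human carry fixed weights 0.25/3.5/70 kg;
other labels need an explicit `body_weight_kg`. `dose` takes an `mg/kg` or
`mg` suffix. Optional keys: `lloq_ug_ml` (rows below it are dropped on read),
`matrix`. Concentrations of zero are invalid — censored values are excluded,
never stored as 0.

## CLI

```sh
allopred simulate scenario.yaml -o animal.csv human.csv --truth truth.json
allopred predict --method VIII --animal animal.csv --human-dose 5 --human-weight 70 -o pred.csv
allopred nca pred.csv --rule linlog --lambda-z auto --csv nca.csv
allopred evaluate --pred pred.csv --obs human.csv --policy exact --tol 0.05 --json eval.json
allopred compare-methods --animal animal.csv --obs human.csv --human-dose 5 -o table.csv
allopred scale-pk --cl 0.01 --thalf 5 --species monkey
```

Methods can be named by roman numeral (`I`–`VIII`) or mnemonic (`v1.0`,
`v0.9`, `v0.8`, `cl0.85-v1.0`, `cl0.85-v0.9`, `cl0.85-v0.8`, `v1.0+0.8`,
`v0.9+0.8`). Every subcommand also accepts `--config file.yaml` with flat
key-value defaults (explicit flags win). Logs go to stderr, data to
stdout/files; CSVs use 6 significant digits; runs are deterministic for a
fixed seed.

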