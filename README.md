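# respirox

Analysis pipeline for intermittent-flow aquatic respirometry. Converts
chamber oxygen traces into three per-animal endpoints —

* **MMR** — maximum metabolic rate (μmol O₂ g⁻¹ h⁻¹), from the
  measurement period in which PO₂ declined most rapidly, mass-corrected
  via a fitted power law `mo2 = c·W^b`;
* **α** — oxygen supply capacity (μmol O₂ g⁻¹ h⁻¹ kPa⁻¹), the mean of
  the three largest per-bin supply ratios α₀ = ṀO₂/PO₂ from a closed
  hypoxia trial, with the regression bin width chosen automatically from
  a stability scan;
* **P_cMax** — the critical oxygen pressure for maximum metabolism,
  `MMR / α` (kPa);

and compares them across salinity treatment groups with a permutation
statistics layer (one-way ANOVA + Tukey post hoc, linear regression,
Lilliefors normality, Levene/Brown–Forsythe homogeneity), reporting
permutation and classical p-values side by side.

Because raw field traces are rarely deposited, the package ships a
first-class synthetic-data generator: a closed-chamber ODE model with
demand-limited/supply-limited uptake (`uptake = min(demand(t), α·PO₂)`),
exercise-recovery decay of demand, flush periods, microbial background
uptake and Gaussian sensor noise in % air-saturation space. Every
downstream stage is validated against this generator's ground truth.

Unit conversions use standard published fits: Green & Carritt (1967) for
seawater vapour pressure and the García & Gordon (1992) refit of
Benson & Krause (1984) for O₂ solubility (per-litre basis).

## CLI

```sh
respirox all --seed 1 --outdir run/             # simulate -> process -> metrics -> stats
respirox simulate --seed 1 --outdir run/        # stages are also available individually
respirox process  --seed 1 --outdir run/
respirox metrics  --seed 1 --outdir run/
respirox stats    --seed 1 --outdir run/ --n-perm 10000
```

Options: `--config cfg.yaml` (run configuration, YAML),
`--mmr-mode {period_regression,max_bin}`, `--n-perm N`. A master
`--seed` is mandatory and deterministically spawns per-stage seeds;
re-runs are byte-identical (see `files.json` checksums).

Run-directory outputs: `manifest.csv`, `traces/*.csv`,
`ground_truth.csv`, `bins_<trial>.csv`, `scan_<trial>.csv`,
`microbial_shares.csv`, `metrics.csv`, `group_stats.csv`,
`stats_report.json`, `files.json`, `run.log`.

### File formats

Trace CSV: `time_s, o2_value, o2_unit (percent_sat|kpa), phase`.
Manifest CSV: `trial_id, animal_id, group_psu, salinity_psu, temp_C,
chamber_volume_L, animal_mass_g, trial_type (mmr|hypoxia|blank),
start_po2_kpa, trace_file`.

## Notes and caveats

* The resting-rate floor used by the generator (`smr = mmr0/3`) is a
  placeholder; no measured resting rate exists for the modelled species.
* Mass correction uses the mass-specific exponent convention
  `mo2 × (common_mass/W)^b`; the whole-animal convention (exponent
  `b − 1`) is not applied.
* Both MMR and the hypoxia-trial rates entering α₀ are mass-corrected
  with the same scaling fit, so `P_cMax = MMR/α` compares like with like.
* Background subtraction removes the blank's whole-chamber rate
  (μmol h⁻¹) divided by animal mass; the blank is additionally reported
  in the nominal-mass convention (W = 0.0001 g).
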