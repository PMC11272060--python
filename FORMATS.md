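# File formats

All pipeline inputs and outputs are plain text.  The synthetic generator
(`denitflux simulate` / `denitflux.synthetic_data.write_fixture`) emits a
fixture directory containing exactly these files.

## Sample table — `samples.csv`

Effluent concentrations at labelled positions within an oxic/anoxic cycle,
with replicates.

| column | type | meaning |
|---|---|---|
| `time_h` | float | sampling time since start of the record (h) |
| `phase_label` | str | `start_oxic`, `end_oxic` or `end_anoxic` |
| `compound` | str | `no3`, `no2`, `nh4`, `acetate`, `propionate`, `butyrate` |
| `replicate` | int | replicate index (1-based) |
| `conc_mM` | float | concentration, mmol/L (N-mmol/L for N species, C-mmol/L for VFAs) |

When the three canonical labels are present and a schedule is known, the
pipeline forms the trapezoidal time-weighted cycle mean; otherwise all rows
are averaged equally.

## Gas trace — `gas_trace.csv`

Minute-resolution dried off-gas fractions and dissolved oxygen.

| column | type | meaning |
|---|---|---|
| `time_min` | float | uniform 1-min grid |
| `y_o2`, `y_n2o`, `y_co2` | float | outlet dry-gas mole fractions |
| `do_percent_airsat` | float | dissolved O2, % of air saturation |
| `y_o2_in`, `y_n2o_in`, `y_co2_in` | float | inlet mole fractions (set by the sparge gas; optional, default 0) |

## Configuration — `config.yaml`

```yaml
reactor:
  volume_L: 0.75          # working volume V
  hrt_h: 48.0             # hydraulic retention time (= SRT here)
  srt_h: 48.0
  temperature_K: 293.15
  pressure_atm: 1.0
  gas_flow_L_h: 24.0      # F_V,gas
  kla_per_h: 50.0         # volumetric O2 transfer coefficient
  henry_o2_mol_L_atm: 1.356e-3
  gas_constant_L_atm_mol_K: 0.08206
  y_in: {o2_air: 0.2095, co2_air: 4.0e-4, n2o_air: 0.0,
         o2_n2: 0.0, co2_n2: 0.0, n2o_n2: 0.0}
schedule:
  cycles_per_day: 4
  t_oxic_h: 4.0
  t_anoxic_h: 2.0
  net_oxic_h: 16.0        # measured by the 1 % DO threshold rule
  net_anoxic_h: 8.0
feed:
  flow_L_h: 0.015625
  concentrations_mM: {no3: ..., nh4: ..., acetate: ..., propionate: ..., butyrate: ...}
days: 4.0
```

## Ground truth — `truth.json`

Simulator echo: the `TruthParams` fields, the noise model, the exact
overall rates over the analysis window (`true_rates_mmol_h`) and the
per-phase truth (`true_phase`).

## Reports

JSON reports embed units in every key (`value_N_mmol_h`, `value_C_mmol_h`,
`value_mmol_h`, `*_percent`); uncertain quantities serialise as
`[value, sd]` pairs or `{"value": ..., "sd": ...}` objects.  `denitflux
report` additionally writes a Markdown twin with the yield table in the
conventional column order.
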