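# Methods

## Scope and sign conventions

`denitflux` converts chemostat observables into steady-state conversion
rates and stoichiometric balances for cultures respiring O2 and nitrogen
oxides under alternating aeration.  Rates are signed (consumption < 0,
production > 0) and carried on the basis natural to each compound: C-mmol/h
for organics, biomass and CO2; N-mmol/h for NO3-, NO2-, N2O (2 N per
molecule), N2 and NH4+; mmol/h for O2.  Degree-of-reduction coefficients
count electron equivalents against the fully oxidised reference state with
nitrogen at the ammonia level, which gives the acceptor coefficients
8 (NO3-), 6 (NO2-), 4 (N2O) and 3 (N2) e-/N, 4 e-/mol for O2, and the
donor coefficients 4 (acetate), 4.7 (propionate), 5 (butyrate) and 4.2
(biomass) e-/C-mol.  Propionate is stored as the rounded 4.7 rather than
14/3 so balances computed from printed rate tables reproduce published
figures digit for digit; the biomass composition CH1.8O0.5N0.2
(24.63 g/C-mol) is the unique single-carbon formula satisfying both
N/C = 0.2 and a degree of reduction of 4.2, and is configurable.

## Rate reconstruction

Dissolved rates use the influent/effluent balance
`R_i = F_out·C_out − F_in·C_in`.  Replicates are averaged; when samples
come from the three canonical cycle positions (start oxic, end oxic, end
anoxic) and the schedule is known, the effluent mean is the trapezoidal
time-weighted cycle average — concentrations of compounds consumed at
phase-dependent rates (NO3-) vary piecewise-linearly over a cycle, and an
unweighted three-point mean would bias the rate by a few tenths of a
percent.  Gas rates use the inlet/outlet mole-fraction difference times
the ideal-gas molar flow `P·F/(R·T)`.  O2 uptake uses the transfer balance
`kLa·(H·P·y_O2 − C_O2)·V`, re-expressing the probe signal (% of *air*
saturation) on the saturation set by the prevailing off-gas `y_O2`.
Biomass production is derived from NH4+ uptake assuming full assimilation
at the registry N/C ratio (valid when nitrification is chemically
suppressed), and N2 closes the nitrogen balance (valid when NO does not
accumulate and NO2- accumulation is negligible).

Two estimator details matter in practice.  First, the transfer balances
equal the biological rates only at quasi-steady dissolved pools, so
phase-resolved averages exclude a configurable window (default 15 min,
capped at a quarter of the interval length for short cycles) at *both*
ends of every DO-labelled interval: the labelled phase lags the gas switch,
so an interval's head and tail both sit inside transition windows.
Second, phase labelling (oxic: DO ≥ 1 % of air saturation) absorbs runs
shorter than 5 min into their neighbours; DO sensor noise straddling the
threshold otherwise shatters the segmentation into spurious one-minute
phases.  Setting `min_interval_min=0` recovers the raw threshold rule.

## Phase deconvolution

The overall rate of any compound is the time-weighted phase combination
`R_overall = (t_aer/24)·R_aer + (t_ana/24)·R_ana` with the *measured* net
oxic/anoxic hours per day.  The inverse estimate of aerobic vs anaerobic
NO3- reduction closes the electron balance per phase: with substrate
supplied continuously and fully consumed, the per-hour catabolic electron
supply `e_cat = |Σγ_S·R_S| − γ_X·R_X` is phase-uniform (biomass synthesis
is likewise assumed phase-uniform); aerobically `e_NOx = e_cat −
4·|R_O2,aer|` (clipped at zero with a warning if measured O2 respiration
exceeds the supply), anaerobically `e_NOx = e_cat`.  The phase N2O rate
then fixes the N2O/N2 split through `5·|R_NO3| − R_N2O = e_NOx`.  The
recombined overall NO3- rate is always compared against the independently
measured one; the relative residual is reported with a default 10 %
acceptance (rounding of printed yields alone produces ~3 %).  Derived
summaries are the aerobic electron share `e_NOx,aer/e_cat`, the aerobic
N2O fraction `R_N2O,aer/|R_NO3,aer|`, and the anaerobic:aerobic
fold-difference.

## Uncertainty

Every derived quantity uses first-order propagation,
`sd² = Σ (∂f/∂x_i)²·sd_i²`, with central finite-difference partials
(relative step 1e-6) so any pipeline expression is propagatable without a
hand-derived Jacobian.  Inputs are treated as independent; a covariance
hook exists but defaults to diagonal.  A seeded Monte-Carlo resampler
provides the validation oracle; the test suite requires linear and
resampled sds to agree within 10 % relative for the balance expressions at
input CVs up to 10 %.

## Synthetic data generator

The simulator integrates liquid-phase balances for three VFAs, NO3-, NH4+,
biomass, dissolved O2 and dissolved N2O,
`dC/dt = D·(C_in − C) + r(C) + kLa·(C_sat(sparge) − C)`, with LSODA at
rtol 1e-8/atol 1e-10, one integration segment per sparge phase.  Kinetics:
Monod uptake per VFA (q_max 0.3 C-mmol/(C-mmol X·h), Ks 0.1 mmol/L — fast
enough that residual VFAs stay far below detection, as in carbon-limited
operation); a fixed biomass yield; catabolic electrons routed aerobically
as a fraction `phi_aer` to nitrogen oxides with the rest to O2 (O2 use
saturates with a 0.002 mmol/L half-saturation so anoxic transitions emerge
from the kLa dynamics rather than being imposed); anaerobically everything
goes to NOx.  A phase-specific fraction of reduced NO3- leaves as N2O
(blended smoothly between the phase values by the same O2 saturation
function), the remainder as N2.  The O2 saturation concentration follows
the *outlet* mole fraction by solving the linear liquid/headspace coupling,
so the kLa-based estimator applied to the simulated observables is exactly
self-consistent.  CO2 is treated as instantly stripped (no carbonate
chemistry); N2O strips against a zero-N2O sparge gas with
`kLa_N2O = kla_n2o_scale·kLa` (default scale 1.0, since no transfer data
distinguish the two gases).

Defaults are the study conditions of the low-frequency reactor: 0.75 L,
HRT = SRT = 48 h, 20 °C, 24 L/h sparging, kLa 50 1/h (giving a ~5-min DO
transition and DO ≈ 80–90 % of air saturation under load), 4 cycles/day of
4 h air + 2 h N2, feeds 0.94/1.00/0.75 C-mmol/h VFAs + 0.93 N-mmol/h NO3-,
biomass yield 0.44 C-mol/C-mol, `phi_aer` 0.36, and phase N2O emission
fractions 0.107/0.0254 chosen so the emitted N2O matches the observed
oxic/anoxic means (0.057/0.037 N-mmol/h).  NH4+ is supplied in excess
(0.47 mmol/h) and consumed only assimilatorily — nitrification is not
modelled, mirroring chemically inhibited operation.  Effluent withdrawal
is continuous (D = 1/HRT) by default; a discrete 6-h bolus mode (volume
ramping between withdrawals aligned with anoxic-phase ends) exists for
robustness checks and agrees with the continuous mode within a few
percent.

Runs start from the analytic chemostat steady state and discard a 2-day
burn-in (unrecorded) plus the first recorded day for the trajectory-derived
truth, because the slow dissolved pools relax on the HRT scale.
Cumulative conversions are integrated alongside the states, attributed to
phases by the same 1 % DO threshold the pipeline uses, so carbon/nitrogen
conservation and parameter recovery can be asserted exactly.  Measurement
noise (multiplicative 3 % CV on concentration replicates, quadruplicate by
default; 1e-6 absolute on mole fractions; 0.005 absolute on the DO
fraction) affects only the observables, never the truth, and is fully
seeded.

What the generator does **not** emulate: within-cycle N2O dynamics
(anoxia-onset peaks, gradual aerobic accumulation) — emission fractions
are phase-constant; NO2-/NO intermediate pools; community or enzyme-level
dynamics; analyser drift; carbonate buffering of CO2.  Passing the
recovery tests therefore demonstrates that the estimators are unbiased
under the model's statistical structure (phase-switching, gas-transfer
lags, replicate and sensor noise), not that they are robust to chemistry
or biology the model omits.

## Numerical and design choices

- Problem sizes: the shared noise-free check runs 4 recorded days after a
  4-day burn-in; the seeded noisy recovery uses 20 seeds of 30 recorded
  days, which bounds the recovered aerobic electron-routing fraction
  within 10 points of truth per seed (2 points noise-free).
- Degenerate inputs raise typed errors (`DataError`, `ConfigError`,
  `BalanceError`, `RegistryError`) rather than returning NaNs: empty
  windows, missing compounds, zero denominators, unset kLa/Henry
  coefficients.
- Ties at the DO threshold go to "oxic" (`>=`), matching the inclusive
  1 %-air-saturation convention.
- The aeration-overcapacity diagnostic (max transfer `kLa·C_sat,air·V`
  over measured aerobic uptake) is reported but not asserted; it depends
  only on config values.
- Reports embed units in keys to keep per-mol and per-N bases apart, and
  JSON serialisation is sorted so identical inputs and seed give
  byte-identical reports.

## Known limitations

The deconvolution inherits its assumptions: phase-uniform substrate uptake
and biomass synthesis, negligible NO2-/NO accumulation, and a correct kLa.
Errors in kLa propagate one-to-one into the aerobic O2 rate and hence into
the aerobic NO3- estimate.  Dissolved N2O leaving with the effluent is
neglected in the emission accounting (it is O(1e-4) of the stripped flux
at the default transfer coefficients).  For high-frequency schedules the
transition trimming can retain up to a quarter of each short interval
inside transition windows, biasing per-phase gas rates by a few percent;
the Eq-2 closure residual makes such bias visible.
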