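"""Mechanistic dual-phase CSTR simulator with ground truth.

Emulates a carbon-limited chemostat continuously fed a VFA mixture and
nitrate, sparged alternately with air and N2 (2:1 oxic:anoxic), with
Monod uptake kinetics, electron-partitioned respiration, kLa-controlled
gas-liquid exchange and configurable measurement noise.  The simulator
integrates the liquid-phase mass balances

    dC/dt = D*(C_in - C) + r(C) + kLa*(C_sat(sparge) - C)

and books cumulative conversions per phase, so every pipeline stage can
be checked against an exact ground truth.  Aerobically a fraction
``phi_aer`` of the catabolic electron flow is routed to nitrogen oxides
(the rest to O2); anaerobically all of it is.  A phase-specific fraction
of the reduced NO3- is emitted as N2O, the remainder as N2.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .rate_estimation import GasTrace, Rate, RateSet, ReactorConfig
from .phase_resolution import PhaseSchedule, low_frequency_schedule
from .stoichiometry import StoichRegistry, default_registry

__all__ = [
    "TruthParams",
    "NoiseModel",
    "SimOutput",
    "simulate",
    "write_fixture",
    "read_fixture",
    "analytic_true_rates",
]

#: pipeline-facing DO threshold used for the simulator's phase bookkeeping
DO_THRESHOLD = 0.01

_SAMPLED_COMPOUNDS = ("no3", "no2", "nh4", "acetate", "propionate", "butyrate")


@dataclass
class TruthParams:
    """Ground-truth kinetic and partition parameters.

    Feed defaults are the study conditions of the low-frequency reactor:
    0.93 N-mmol/h NO3- and acetate/propionate/butyrate at 0.94/1.00/0.75
    C-mmol/h, a biomass yield of 0.44 C-mol/C-mol, 36 % of the aerobic
    catabolic electrons routed to nitrogen oxides, and phase N2O emission
    fractions chosen so the emitted N2O matches the observed oxic/anoxic
    means (0.057 / 0.037 N-mmol/h).
    """

    feed_no3: float = 0.93        # N-mmol/h
    feed_vfa: Mapping[str, float] = field(
        default_factory=lambda: {"acetate": 0.94, "propionate": 1.00, "butyrate": 0.75}
    )
    feed_nh4: float = 0.47        # mmol/h (ample nitrogen source)
    y_x_s_true: float = 0.44      # C-mol/C-mol
    phi_aer: float = 0.36         # aerobic catabolic electron fraction to NOx
    y_n2o_aer: float = 0.107      # N-mol N2O per N-mol NO3- reduced, oxic phase
    y_n2o_ana: float = 0.0254     # idem, anoxic phase
    monod_ks: float = 0.1         # mmol/L, VFA half-saturation
    q_s_max: float = 0.3          # C-mmol/(C-mmol X * h)
    ks_o2: float = 0.002          # mmol/L, O2 half-saturation of respiration
    ks_no3: float = 0.05          # N-mmol/L
    kla_n2o_scale: float = 1.0    # kLa(N2O)/kLa(O2)

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_aer <= 1.0):
            raise ValueError("phi_aer must lie in [0, 1]")
        for y in (self.y_n2o_aer, self.y_n2o_ana):
            if not (0.0 <= y <= 1.0):
                raise ValueError("N2O emission fractions must lie in [0, 1]")
        if self.feed_no3 <= 0 or any(v <= 0 for v in self.feed_vfa.values()):
            raise ValueError("feed rates must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feed_vfa"] = dict(self.feed_vfa)
        return d


@dataclass
class NoiseModel:
    """Measurement-noise configuration for the synthetic observables."""

    conc_cv: float = 0.03       # relative sd on concentration replicates
    gas_abs_sd: float = 1e-6    # absolute sd on off-gas mole fractions
    do_abs_sd: float = 0.005    # absolute sd on DO (fraction of air sat)
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.conc_cv, self.gas_abs_sd, self.do_abs_sd) < 0:
            raise ValueError("noise sds must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @classmethod
    def none(cls, n_replicates: int = 1) -> "NoiseModel":
        return cls(conc_cv=0.0, gas_abs_sd=0.0, do_abs_sd=0.0, n_replicates=n_replicates)


@dataclass
class SimOutput:
    """Everything one simulation produces."""

    config: ReactorConfig
    truth: TruthParams
    noise: NoiseModel
    days: float
    trace: GasTrace                 # noisy observables
    clean_trace: GasTrace           # noise-free observables
    samples: pd.DataFrame           # noisy effluent sample table
    clean_samples: pd.DataFrame
    states: pd.DataFrame            # minute-resolution noise-free state
    true_rates: RateSet             # overall rates over the analysis window
    true_phase: dict                # per-phase ground truth
    feed_concentrations: dict[str, float]  # mmol/L in the combined feed

    @property
    def schedule(self) -> PhaseSchedule:
        assert self.config.schedule is not None
        return self.config.schedule


# ---------------------------------------------------------------------------
# model right-hand side
# ---------------------------------------------------------------------------

_IDX = {
    "ace": 0, "pro": 1, "but": 2, "no3": 3, "nh4": 4, "x": 5, "o2": 6, "n2o": 7,
    "cum_co2": 8, "cum_o2": 9, "cum_n2": 10,
    "cum_no3_aer": 11, "cum_no3_ana": 12,
    "cum_n2o_aer": 13, "cum_n2o_ana": 14,
    "cum_n2o_gas": 15, "cum_t_aer": 16,
}
_NSTATE = 17


class _Model:
    def __init__(
        self,
        config: ReactorConfig,
        truth: TruthParams,
        registry: StoichRegistry,
        effluent_mode: str,
    ) -> None:
        self.cfg = config
        self.truth = truth
        self.reg = registry
        self.effluent_mode = effluent_mode
        self.gammas = np.array(
            [registry.get(n).gamma for n in ("acetate", "propionate", "butyrate")]
        )
        self.g_x = registry.get("biomass").gamma
        self.e_n2o = registry.get("no3").gamma - registry.get("n2o").gamma  # 4 e/N
        self.e_n2 = registry.get("no3").gamma - registry.get("n2").gamma    # 5 e/N
        self.sat_air = config.o2_air_saturation()
        self.kla = float(config.kla)
        self.kla_n2o = self.kla * truth.kla_n2o_scale
        self.flow = config.flow
        # well-mixed headspace: O2 saturation follows the *outlet* fraction,
        # which itself depends on the transfer rate; solving the linear
        # coupling gives kLa*(C_sat,in - C) damped by this factor
        self.o2_headspace_factor = 1.0 + (
            self.kla * 1e3 * config.henry_o2 * config.pressure
            * config.volume / config.molar_gas_flow
        )
        self.feed_conc = {
            "acetate": truth.feed_vfa["acetate"] / self.flow,
            "propionate": truth.feed_vfa["propionate"] / self.flow,
            "butyrate": truth.feed_vfa["butyrate"] / self.flow,
            "no3": truth.feed_no3 / self.flow,
            "nh4": truth.feed_nh4 / self.flow,
        }

    def volume(self, t_h: float) -> float:
        if self.effluent_mode == "continuous":
            return self.cfg.volume
        # discrete 6-h bolus withdrawal: volume ramps up between boluses
        dt = t_h % 6.0
        return self.cfg.volume + self.flow * (dt - 3.0)

    def kinetics(self, s: np.ndarray, air: bool) -> dict:
        tr = self.truth
        vfas = np.maximum(s[0:3], 0.0)
        x = max(s[_IDX["x"]], 0.0)
        o2 = max(s[_IDX["o2"]], 0.0)
        no3 = max(s[_IDX["no3"]], 0.0)
        q = tr.q_s_max * x * vfas / (tr.monod_ks + vfas)       # C-mmol/L/h
        uptake = float(q.sum())
        r_x = tr.y_x_s_true * uptake
        r_co2 = uptake - r_x
        e_cat = float(self.gammas @ q) - self.g_x * r_x        # e-mmol/L/h
        f_o2 = o2 / (tr.ks_o2 + o2)
        f_no3 = no3 / (tr.ks_no3 + no3)
        e_o2 = (1.0 - tr.phi_aer) * f_o2 * e_cat
        e_nox = (e_cat - e_o2) * f_no3
        # phase-specific N2O emission fraction, blended smoothly with O2
        y = tr.y_n2o_ana + (tr.y_n2o_aer - tr.y_n2o_ana) * f_o2
        r_no3 = e_nox / (self.e_n2 - (self.e_n2 - self.e_n2o) * y)  # N-mmol/L/h reduced
        r_n2o = y * r_no3
        r_n2 = (1.0 - y) * r_no3
        r_o2bio = e_o2 / 4.0
        sat = self.sat_air if air else 0.0
        t_o2 = self.kla * (sat - s[_IDX["o2"]]) / self.o2_headspace_factor
        t_n2o = -self.kla_n2o * s[_IDX["n2o"]]
        return dict(
            q=q, r_x=r_x, r_co2=r_co2, r_no3=r_no3, r_n2o=r_n2o, r_n2=r_n2,
            r_o2bio=r_o2bio, t_o2=t_o2, t_n2o=t_n2o,
        )

    def rhs(self, t_h: float, s: np.ndarray, air: bool) -> np.ndarray:
        k = self.kinetics(s, air)
        v = self.volume(t_h)
        d = self.flow / v
        fc = self.feed_conc
        ds = np.zeros(_NSTATE)
        ds[0] = d * (fc["acetate"] - s[0]) - k["q"][0]
        ds[1] = d * (fc["propionate"] - s[1]) - k["q"][1]
        ds[2] = d * (fc["butyrate"] - s[2]) - k["q"][2]
        ds[_IDX["no3"]] = d * (fc["no3"] - s[_IDX["no3"]]) - k["r_no3"]
        ds[_IDX["nh4"]] = d * (fc["nh4"] - s[_IDX["nh4"]]) - self.reg.biomass_nc_ratio * k["r_x"]
        # in discrete mode the bolus removes volume, not concentration, so
        # the same feed-dilution term applies between boluses
        ds[_IDX["x"]] = k["r_x"] - d * s[_IDX["x"]]
        ds[_IDX["o2"]] = k["t_o2"] - k["r_o2bio"] - d * s[_IDX["o2"]]
        ds[_IDX["n2o"]] = k["t_n2o"] + k["r_n2o"] - d * s[_IDX["n2o"]]
        aer = 1.0 if s[_IDX["o2"]] >= DO_THRESHOLD * self.sat_air else 0.0
        ds[_IDX["cum_co2"]] = k["r_co2"] * v
        ds[_IDX["cum_o2"]] = k["r_o2bio"] * v
        ds[_IDX["cum_n2"]] = k["r_n2"] * v
        ds[_IDX["cum_no3_aer"]] = k["r_no3"] * v * aer
        ds[_IDX["cum_no3_ana"]] = k["r_no3"] * v * (1.0 - aer)
        ds[_IDX["cum_n2o_aer"]] = k["r_n2o"] * v * aer
        ds[_IDX["cum_n2o_ana"]] = k["r_n2o"] * v * (1.0 - aer)
        ds[_IDX["cum_n2o_gas"]] = -k["t_n2o"] * v
        ds[_IDX["cum_t_aer"]] = aer
        return ds

    def observables(self, t_h: np.ndarray, states: np.ndarray, air: np.ndarray) -> pd.DataFrame:
        """Noise-free off-gas fractions and DO from the state trajectory."""
        cfg = self.cfg
        n_gas = cfg.molar_gas_flow  # mmol/h
        rows = np.zeros((len(t_h), 7))
        for i, (t, s, a) in enumerate(zip(t_h, states, air)):
            k = self.kinetics(s, bool(a))
            v = self.volume(t)
            y_o2_in = cfg.y_in["o2_air"] if a else cfg.y_in["o2_n2"]
            y_co2_in = cfg.y_in["co2_air"] if a else cfg.y_in["co2_n2"]
            y_n2o_in = cfg.y_in["n2o_air"] if a else cfg.y_in["n2o_n2"]
            y_o2 = max(y_o2_in - k["t_o2"] * v / n_gas, 0.0)
            y_co2 = max(y_co2_in + k["r_co2"] * v / n_gas, 0.0)
            y_n2o = max(y_n2o_in + max(-k["t_n2o"], 0.0) * v / 2.0 / n_gas, 0.0)
            do = max(s[_IDX["o2"]], 0.0) / self.sat_air
            rows[i] = (y_o2, y_n2o, y_co2, do, y_o2_in, y_n2o_in, y_co2_in)
        return pd.DataFrame(
            rows,
            columns=["y_o2", "y_n2o", "y_co2", "do_frac", "y_o2_in", "y_n2o_in", "y_co2_in"],
        )


def _steady_state_guess(model: _Model, schedule: PhaseSchedule) -> np.ndarray:
    """Analytic chemostat steady state (oxic-phase values) as initial state."""
    tr = model.truth
    fc = model.feed_conc
    d = model.flow / model.cfg.volume
    s0 = np.zeros(_NSTATE)
    x = tr.y_x_s_true * (fc["acetate"] + fc["propionate"] + fc["butyrate"])
    for i, name in enumerate(("acetate", "propionate", "butyrate")):
        load = d * fc[name]
        cap = tr.q_s_max * x
        s0[i] = tr.monod_ks * load / max(cap - load, 1e-9)
    s0[_IDX["x"]] = x
    s0[_IDX["nh4"]] = max(fc["nh4"] - model.reg.biomass_nc_ratio * x, 0.0)
    # per-litre catabolic electron supply at full consumption
    load = np.array([d * fc[n] for n in ("acetate", "propionate", "butyrate")])
    r_x = tr.y_x_s_true * load.sum()
    e_cat = float(model.gammas @ load) - model.g_x * r_x
    w = schedule.net_oxic_h / 24.0
    r_red = (
        w * tr.phi_aer * e_cat / (5.0 - tr.y_n2o_aer)
        + (1.0 - w) * e_cat / (5.0 - tr.y_n2o_ana)
    )
    s0[_IDX["no3"]] = max(fc["no3"] - r_red / d, 0.0)
    r_o2_aer = (1.0 - tr.phi_aer) * e_cat / 4.0
    s0[_IDX["o2"]] = max(
        model.sat_air - r_o2_aer * model.o2_headspace_factor / model.kla, 0.0
    )
    r_n2o_aer = tr.y_n2o_aer * tr.phi_aer * e_cat / (5.0 - tr.y_n2o_aer)
    s0[_IDX["n2o"]] = r_n2o_aer / model.kla_n2o
    return s0


def analytic_true_rates(
    truth: TruthParams,
    config: ReactorConfig,
    registry: StoichRegistry | None = None,
) -> RateSet:
    """Idealised steady-state overall rates implied by the truth parameters.

    Assumes complete VFA consumption and no dissolved-pool storage; useful
    as a closed-form check against the trajectory-derived true rates.
    """
    reg = registry or default_registry()
    schedule = config.schedule or low_frequency_schedule()
    feeds = truth.feed_vfa
    s_tot = sum(feeds.values())
    r_x = truth.y_x_s_true * s_tot
    gam = {n: reg.get(n).gamma for n in ("acetate", "propionate", "butyrate")}
    e_cat = sum(gam[n] * feeds[n] for n in feeds) - reg.get("biomass").gamma * r_x
    w = schedule.net_oxic_h / 24.0
    r_red_aer = truth.phi_aer * e_cat / (5.0 - truth.y_n2o_aer)  # per oxic hour
    r_red_ana = e_cat / (5.0 - truth.y_n2o_ana)
    r_no3 = w * r_red_aer + (1 - w) * r_red_ana
    r_n2o = w * truth.y_n2o_aer * r_red_aer + (1 - w) * truth.y_n2o_ana * r_red_ana
    r_o2_aer = (1.0 - truth.phi_aer) * e_cat / 4.0
    rates: RateSet = {
        "acetate": Rate("acetate", -feeds["acetate"]),
        "propionate": Rate("propionate", -feeds["propionate"]),
        "butyrate": Rate("butyrate", -feeds["butyrate"]),
        "biomass": Rate("biomass", r_x),
        "co2": Rate("co2", s_tot - r_x),
        "nh4": Rate("nh4", -reg.biomass_nc_ratio * r_x),
        "no3": Rate("no3", -r_no3),
        "n2o": Rate("n2o", r_n2o),
        "n2": Rate("n2", r_no3 - r_n2o),
        "o2": Rate("o2", -w * r_o2_aer),
        "no2": Rate("no2", 0.0),
    }
    return rates


def simulate(
    config: ReactorConfig | None = None,
    truth: TruthParams | None = None,
    days: float = 6.0,
    seed: int = 0,
    noise: NoiseModel | None = None,
    registry: StoichRegistry | None = None,
    effluent_mode: str = "continuous",
    analysis_skip_days: float = 1.0,
    burn_in_days: float = 2.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimOutput:
    """Run the dual-phase CSTR model and assemble observables + truth.

    The simulation starts from the analytic steady state, integrates
    *burn_in_days* of unrecorded cycles (the slow dissolved pools relax on
    the HRT scale), then records *days* of minute-resolution output and
    discards the first *analysis_skip_days* of it when computing the
    trajectory-derived true rates.  Noise (seeded by *seed*, overriding
    ``noise.seed``) affects only the observables; the state trajectory and
    true rates are exact.
    """
    if days < 1:
        raise ValueError("simulate at least one day")
    if effluent_mode not in ("continuous", "discrete"):
        raise ValueError(f"unknown effluent mode {effluent_mode!r}")
    config = config or ReactorConfig()
    if config.schedule is None:
        config.schedule = low_frequency_schedule()
    truth = truth or TruthParams()
    noise = noise or NoiseModel()
    reg = registry or default_registry()
    schedule = config.schedule
    model = _Model(config, truth, reg, effluent_mode)

    # --- integrate segment by segment (sparge gas constant per segment)
    s = _steady_state_guess(model, schedule)
    n_burn_cycles = int(round(burn_in_days * schedule.cycles_per_day))
    t_burn = 0.0
    for cycle in range(n_burn_cycles):
        for air, dur in ((True, schedule.t_oxic), (False, schedule.t_anoxic)):
            sol = solve_ivp(
                model.rhs, (t_burn, t_burn + dur), s, args=(air,),
                method="LSODA", rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"stiff-solver failure in burn-in: {sol.message}")
            s = sol.y[:, -1].copy()
            t_burn += dur
    s[8:] = 0.0  # reset the cumulative bookkeeping after burn-in

    minutes_all: list[np.ndarray] = []
    states_all: list[np.ndarray] = []
    air_all: list[np.ndarray] = []
    t0 = 0.0
    n_cycles = int(round(days * schedule.cycles_per_day))
    for cycle in range(n_cycles):
        for air, dur in ((True, schedule.t_oxic), (False, schedule.t_anoxic)):
            t1 = t0 + dur
            t_eval = t0 + np.arange(0.0, dur * 60.0) / 60.0
            sol = solve_ivp(
                model.rhs, (t0, t1), s, t_eval=t_eval, args=(air,),
                method="LSODA", rtol=rtol, atol=atol, max_step=dur,
            )
            if not sol.success:
                raise RuntimeError(f"stiff-solver failure at t={t0:.2f} h: {sol.message}")
            if np.any(sol.y[:8, :] < -1e-6):
                raise RuntimeError("negative state: tighten solver tolerances")
            minutes_all.append(sol.t * 60.0)
            states_all.append(sol.y.T)
            air_all.append(np.full(sol.t.size, air))
            s = sol.y[:, -1].copy()
            # advance to the exact segment end
            sol_end = solve_ivp(
                model.rhs, (sol.t[-1], t1), s, args=(air,),
                method="LSODA", rtol=rtol, atol=atol,
            )
            s = sol_end.y[:, -1].copy()
            t0 = t1

    time_min = np.concatenate(minutes_all)
    states = np.vstack(states_all)
    air_flags = np.concatenate(air_all)

    obs = model.observables(time_min / 60.0, states, air_flags)
    clean_trace = GasTrace(
        time_min=np.round(time_min).astype(float),
        y_o2=obs["y_o2"].to_numpy(),
        y_n2o=obs["y_n2o"].to_numpy(),
        y_co2=obs["y_co2"].to_numpy(),
        do_frac=obs["do_frac"].to_numpy(),
        y_o2_in=obs["y_o2_in"].to_numpy(),
        y_n2o_in=obs["y_n2o_in"].to_numpy(),
        y_co2_in=obs["y_co2_in"].to_numpy(),
    )

    rng = np.random.default_rng(seed)
    trace = GasTrace(
        time_min=clean_trace.time_min.copy(),
        y_o2=np.clip(clean_trace.y_o2 + rng.normal(0, noise.gas_abs_sd, len(time_min)), 0, 1),
        y_n2o=np.clip(clean_trace.y_n2o + rng.normal(0, noise.gas_abs_sd, len(time_min)), 0, 1),
        y_co2=np.clip(clean_trace.y_co2 + rng.normal(0, noise.gas_abs_sd, len(time_min)), 0, 1),
        do_frac=np.clip(
            clean_trace.do_frac + rng.normal(0, noise.do_abs_sd, len(time_min)), 0, None
        ),
        y_o2_in=clean_trace.y_o2_in.copy(),
        y_n2o_in=clean_trace.y_n2o_in.copy(),
        y_co2_in=clean_trace.y_co2_in.copy(),
    )

    clean_samples, samples = _sample_tables(model, schedule, time_min, states, noise, rng, days)

    state_cols = [
        "acetate_mM", "propionate_mM", "butyrate_mM", "no3_mM", "nh4_mM",
        "biomass_mM", "o2_mM", "n2o_mM",
        "cum_co2", "cum_o2", "cum_n2", "cum_no3_aer", "cum_no3_ana",
        "cum_n2o_aer", "cum_n2o_ana", "cum_n2o_gas", "cum_t_aer",
    ]
    states_df = pd.DataFrame(states, columns=state_cols)
    states_df.insert(0, "time_min", time_min)

    true_rates, true_phase = _trajectory_truth(
        model, schedule, time_min, states, analysis_skip_days
    )

    return SimOutput(
        config=config,
        truth=truth,
        noise=noise,
        days=days,
        trace=trace,
        clean_trace=clean_trace,
        samples=samples,
        clean_samples=clean_samples,
        states=states_df,
        true_rates=true_rates,
        true_phase=true_phase,
        feed_concentrations=dict(model.feed_conc),
    )


def _sample_tables(model, schedule, time_min, states, noise, rng, days):
    """Effluent sample tables at the three canonical cycle positions."""
    cycle_min = schedule.cycle_h * 60.0
    oxic_min = schedule.t_oxic * 60.0
    rows_clean, rows_noisy = [], []
    for day in range(int(days)):
        base = day * 1440.0
        # boundary instants: concentrations are continuous across the gas
        # switch, so the first minute of the following segment is the exact
        # end-of-phase state
        positions = (
            ("start_oxic", base),
            ("end_oxic", base + oxic_min),
            ("end_anoxic", base + cycle_min),
        )
        for label, t in positions:
            i = int(np.argmin(np.abs(time_min - t)))
            conc = {
                "no3": states[i, _IDX["no3"]],
                "no2": 0.0,
                "nh4": states[i, _IDX["nh4"]],
                "acetate": states[i, _IDX["ace"]],
                "propionate": states[i, _IDX["pro"]],
                "butyrate": states[i, _IDX["but"]],
            }
            for compound in _SAMPLED_COMPOUNDS:
                c = conc[compound]
                for rep in range(noise.n_replicates):
                    noisy = max(c * (1.0 + rng.normal(0.0, noise.conc_cv)), 0.0)
                    common = {
                        "time_h": time_min[i] / 60.0,
                        "phase_label": label,
                        "compound": compound,
                        "replicate": rep + 1,
                    }
                    rows_clean.append({**common, "conc_mM": c})
                    rows_noisy.append({**common, "conc_mM": noisy})
    return pd.DataFrame(rows_clean), pd.DataFrame(rows_noisy)


def _trajectory_truth(model, schedule, time_min, states, skip_days):
    """Exact overall and per-phase rates from the integrated trajectory."""
    total_days = (time_min[-1] + 1 - time_min[0]) / 1440.0
    skip_days = min(skip_days, 0.5 * total_days)  # keep at least half the run
    lo = int(skip_days * 1440)
    if lo >= len(time_min) - 1:
        raise ValueError("analysis window empty: simulate longer or skip less")
    t_h = (time_min[-1] - time_min[lo]) / 60.0
    window = slice(lo, len(time_min))
    f = model.flow
    v = model.cfg.volume
    fc = model.feed_conc

    def dissolved(name, idx, feed_conc):
        c = states[window, idx]
        dstore = v * (c[-1] - c[0]) / t_h
        value = f * float(np.mean(c)) - f * feed_conc + dstore
        return Rate(name, value, 0.0, "overall")

    def dcum(idx):
        return (states[-1, idx] - states[lo, idx]) / t_h

    x = states[window, _IDX["x"]]
    r_x = f * float(np.mean(x)) + v * (x[-1] - x[0]) / t_h
    aer_h = states[-1, _IDX["cum_t_aer"]] - states[lo, _IDX["cum_t_aer"]]
    ana_h = t_h - aer_h

    r_no3_red = dcum(_IDX["cum_no3_aer"]) + dcum(_IDX["cum_no3_ana"])
    r_n2o_prod = dcum(_IDX["cum_n2o_aer"]) + dcum(_IDX["cum_n2o_ana"])
    rates: RateSet = {
        "acetate": dissolved("acetate", 0, fc["acetate"]),
        "propionate": dissolved("propionate", 1, fc["propionate"]),
        "butyrate": dissolved("butyrate", 2, fc["butyrate"]),
        "no3": dissolved("no3", _IDX["no3"], fc["no3"]),
        "nh4": dissolved("nh4", _IDX["nh4"], fc["nh4"]),
        "no2": Rate("no2", 0.0),
        "biomass": Rate("biomass", r_x),
        "co2": Rate("co2", dcum(_IDX["cum_co2"])),
        "o2": Rate("o2", -dcum(_IDX["cum_o2"])),
        "n2": Rate("n2", dcum(_IDX["cum_n2"])),
        "n2o": Rate("n2o", r_n2o_prod),
    }

    true_phase = {
        "aerobic_h": float(aer_h),
        "anaerobic_h": float(ana_h),
        "no3_aerobic": -(states[-1, _IDX["cum_no3_aer"]] - states[lo, _IDX["cum_no3_aer"]])
        / max(aer_h, 1e-9),
        "no3_anaerobic": -(states[-1, _IDX["cum_no3_ana"]] - states[lo, _IDX["cum_no3_ana"]])
        / max(ana_h, 1e-9),
        "n2o_aerobic": (states[-1, _IDX["cum_n2o_aer"]] - states[lo, _IDX["cum_n2o_aer"]])
        / max(aer_h, 1e-9),
        "n2o_anaerobic": (states[-1, _IDX["cum_n2o_ana"]] - states[lo, _IDX["cum_n2o_ana"]])
        / max(ana_h, 1e-9),
        "o2_aerobic": -dcum(_IDX["cum_o2"]) * t_h / max(aer_h, 1e-9),
        "n2o_emitted": dcum(_IDX["cum_n2o_gas"]),
        "no3_reduced_overall": r_no3_red,
    }
    return rates, true_phase


# ---------------------------------------------------------------------------
# fixture IO
# ---------------------------------------------------------------------------

def write_fixture(sim: SimOutput, directory: str | Path) -> dict[str, Path]:
    """Write the sample-table CSV, gas-trace CSV, config YAML and truth JSON.

    Byte-stable for a given seed: floats are serialised with a fixed
    general format.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": directory / "samples.csv",
        "gas_trace": directory / "gas_trace.csv",
        "config": directory / "config.yaml",
        "truth": directory / "truth.json",
    }
    sim.samples.to_csv(paths["samples"], index=False, float_format="%.10g")
    sim.trace.to_frame().to_csv(paths["gas_trace"], index=False, float_format="%.10g")

    sched = sim.schedule
    cfg = sim.config
    config_doc = {
        "reactor": {
            "volume_L": cfg.volume,
            "hrt_h": cfg.hrt,
            "srt_h": cfg.srt,
            "temperature_K": cfg.temperature,
            "pressure_atm": cfg.pressure,
            "gas_flow_L_h": cfg.gas_flow,
            "kla_per_h": cfg.kla,
            "henry_o2_mol_L_atm": cfg.henry_o2,
            "gas_constant_L_atm_mol_K": cfg.gas_constant,
            "y_in": dict(cfg.y_in),
        },
        "schedule": {
            "cycles_per_day": sched.cycles_per_day,
            "t_oxic_h": sched.t_oxic,
            "t_anoxic_h": sched.t_anoxic,
            "net_oxic_h": sched.net_oxic_h,
            "net_anoxic_h": sched.net_anoxic_h,
        },
        "feed": {
            "flow_L_h": cfg.flow,
            "concentrations_mM": {k: float(v) for k, v in sim.feed_concentrations.items()},
        },
        "days": sim.days,
    }
    paths["config"].write_text(yaml.safe_dump(config_doc, sort_keys=True))

    truth_doc = {
        "params": sim.truth.to_dict(),
        "noise": asdict(sim.noise),
        "true_rates_mmol_h": {
            name: {"value": r.value, "sd": r.sd} for name, r in sim.true_rates.items()
        },
        "true_phase": sim.true_phase,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")
    return paths


def read_fixture(directory: str | Path) -> tuple[pd.DataFrame, GasTrace, dict, dict]:
    """Read back a fixture directory: (samples, trace, config doc, truth doc)."""
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.csv")
    trace = GasTrace.from_frame(pd.read_csv(directory / "gas_trace.csv"))
    config_doc = yaml.safe_load((directory / "config.yaml").read_text())
    truth_path = directory / "truth.json"
    truth_doc = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return samples, trace, config_doc, truth_doc
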