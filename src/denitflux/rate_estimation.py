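"""Signed molar conversion rates from chemostat measurements.

Dissolved-compound rates come from the influent/effluent mass balance
``R_i = F_out*C_out - F_in*C_in``; gaseous rates (N2O, CO2) from the
inlet/outlet off-gas mole-fraction difference and the ideal-gas molar gas
flow; the O2 uptake rate from the volumetric mass-transfer coefficient and
the dissolved-oxygen driving force.  Consumption is negative, production
positive, throughout the package.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .uncertainty import UncertainValue
from .stoichiometry import StoichRegistry

if TYPE_CHECKING:  # pragma: no cover
    from .phase_resolution import PhaseSchedule

__all__ = [
    "AIR_O2_FRACTION",
    "DataError",
    "ConfigError",
    "Rate",
    "RateSet",
    "StreamSpec",
    "ReactorConfig",
    "GasTrace",
    "overall_dissolved_rate",
    "dissolved_rates_from_table",
    "gas_accumulation_rate",
    "o2_consumption_rate",
    "biomass_production_rate",
    "n2_rate_by_difference",
    "overall_from_aerobic_o2",
]

#: O2 mole fraction of dry air; the DO probe's 100 % air-saturation point.
AIR_O2_FRACTION = 0.2095


class DataError(ValueError):
    """Measurement table is missing or inconsistent."""


class ConfigError(ValueError):
    """Reactor configuration is missing or inconsistent."""


@dataclass(frozen=True)
class Rate:
    """A signed molar conversion rate with uncertainty.

    ``value`` is in mmol/h on the compound's basis (C-mmol/h for carbon
    compounds, N-mmol/h for nitrogen compounds).  Negative = consumption,
    positive = production.  ``phase_scope`` records whether the rate is an
    overall (cycle-averaged), aerobic-phase or anaerobic-phase quantity.
    """

    compound: str
    value: float
    sd: float = 0.0
    phase_scope: str = "overall"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.phase_scope not in ("overall", "aerobic", "anaerobic"):
            raise ValueError(f"unknown phase_scope {self.phase_scope!r}")

    def as_uncertain(self) -> UncertainValue:
        return UncertainValue(self.value, self.sd)


#: a rate set maps compound name -> Rate (one phase scope per set)
RateSet = dict[str, Rate]


@dataclass
class StreamSpec:
    """A liquid stream: flow (L/h) and per-compound replicate concentrations (mmol/L)."""

    flow: float
    concentrations: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        if self.flow < 0:
            raise ConfigError("stream flow must be non-negative")

    def mean_sd(self, compound: str) -> UncertainValue:
        if compound not in self.concentrations:
            raise DataError(f"compound {compound!r} absent from stream")
        reps = np.asarray(self.concentrations[compound], dtype=float)
        if reps.size == 0:
            raise DataError(f"no replicates for {compound!r}")
        sd = float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0
        return UncertainValue(float(np.mean(reps)), sd)


@dataclass
class ReactorConfig:
    """Physical configuration of the chemostat.

    Defaults describe a 0.75-L vessel at 20 degC on a 2-day HRT = SRT,
    sparged at 24 L/h, with kLa = 50 1/h and an O2 Henry coefficient of
    1.356e-3 mol/(L*atm) (air saturation 0.284 mmol/L ~ 9.1 mg/L).
    """

    volume: float = 0.75            # L
    hrt: float = 48.0               # h
    srt: float = 48.0               # h
    temperature: float = 293.15     # K
    pressure: float = 1.0           # atm
    gas_flow: float = 24.0          # L/h
    kla: float | None = 50.0        # 1/h
    henry_o2: float | None = 1.356e-3  # mol/(L*atm)
    gas_constant: float = 0.08206   # L*atm/(mol*K)
    schedule: "PhaseSchedule | None" = None
    # inlet off-gas mole fractions per sparge gas
    y_in: dict[str, float] = field(
        default_factory=lambda: {
            "o2_air": AIR_O2_FRACTION,
            "co2_air": 4.0e-4,
            "n2o_air": 0.0,
            "o2_n2": 0.0,
            "co2_n2": 0.0,
            "n2o_n2": 0.0,
        }
    )

    def __post_init__(self) -> None:
        for name in ("volume", "hrt", "srt", "temperature", "pressure", "gas_flow"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if abs(self.hrt - self.srt) > 1e-9:
            warnings.warn(
                "HRT != SRT: chemostat identities (D = 1/HRT = growth rate) no longer hold",
                stacklevel=2,
            )

    @property
    def dilution_rate(self) -> float:
        """D = 1/HRT (1/h)."""
        return 1.0 / self.hrt

    @property
    def flow(self) -> float:
        """Liquid throughput V/HRT (L/h)."""
        return self.volume / self.hrt

    @property
    def molar_gas_flow(self) -> float:
        """Total molar gas flow P*F/(R*T) in mmol/h."""
        return 1e3 * self.pressure * self.gas_flow / (self.gas_constant * self.temperature)

    def o2_air_saturation(self) -> float:
        """Dissolved O2 at equilibrium with air (mmol/L)."""
        if self.henry_o2 is None:
            raise ConfigError("henry_o2 is unset")
        return 1e3 * self.henry_o2 * self.pressure * AIR_O2_FRACTION


@dataclass
class GasTrace:
    """Minute-resolution off-gas and DO trace.

    ``y_*`` are dry-gas mole fractions at the outlet, ``y_*_in`` at the
    inlet (set by the sparge gas), ``do_frac`` the dissolved O2 as a
    fraction of air saturation.  Sampling must be uniform at 1 min.
    """

    time_min: np.ndarray
    y_o2: np.ndarray
    y_n2o: np.ndarray
    y_co2: np.ndarray
    do_frac: np.ndarray
    y_o2_in: np.ndarray | None = None
    y_n2o_in: np.ndarray | None = None
    y_co2_in: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time_min)
        for name in ("y_o2", "y_n2o", "y_co2", "do_frac"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise DataError(f"{name} length mismatch")
            setattr(self, name, arr)
        self.time_min = np.asarray(self.time_min, dtype=float)
        for name in ("y_o2_in", "y_n2o_in", "y_co2_in"):
            arr = getattr(self, name)
            if arr is None:
                arr = np.zeros(n)
            setattr(self, name, np.asarray(arr, dtype=float))
        if n > 1:
            steps = np.diff(self.time_min)
            if not np.allclose(steps, 1.0, atol=1e-6):
                raise DataError("gas trace must be uniformly sampled at 1 min")
        for name in ("y_o2", "y_n2o", "y_co2"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise DataError(f"{name} outside [0, 1]")
        if np.any(self.do_frac < 0):
            raise DataError("do_frac must be non-negative")

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        if window is None:
            return np.ones(len(self.time_min), dtype=bool)
        lo, hi = window
        mask = (self.time_min >= lo) & (self.time_min < hi)
        if not mask.any():
            raise DataError(f"window {window} contains no trace samples")
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "y_o2": self.y_o2,
                "y_n2o": self.y_n2o,
                "y_co2": self.y_co2,
                "do_percent_airsat": 100.0 * self.do_frac,
                "y_o2_in": self.y_o2_in,
                "y_n2o_in": self.y_n2o_in,
                "y_co2_in": self.y_co2_in,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GasTrace":
        required = {"time_min", "y_o2", "y_n2o", "y_co2", "do_percent_airsat"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"gas trace missing columns: {sorted(missing)}")
        kwargs = {}
        for name in ("y_o2_in", "y_n2o_in", "y_co2_in"):
            if name in df.columns:
                kwargs[name] = df[name].to_numpy(dtype=float)
        return cls(
            time_min=df["time_min"].to_numpy(dtype=float),
            y_o2=df["y_o2"].to_numpy(dtype=float),
            y_n2o=df["y_n2o"].to_numpy(dtype=float),
            y_co2=df["y_co2"].to_numpy(dtype=float),
            do_frac=df["do_percent_airsat"].to_numpy(dtype=float) / 100.0,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

#: number of the compound's basis units per molecule in the gas phase
_GAS_BASIS_PER_MOLECULE = {"n2o": 2.0, "co2": 1.0, "n2": 2.0, "o2": 1.0}


def overall_dissolved_rate(feed: StreamSpec, effluent: StreamSpec, compound: str) -> Rate:
    """Influent/effluent mass balance: R = F_out*C_out - F_in*C_in (mmol/h).

    Replicate concentrations are averaged; their spread propagates to the
    rate sd in quadrature (flows are treated as exact here).
    """
    cin = feed.mean_sd(compound)
    cout = effluent.mean_sd(compound)
    value = effluent.flow * cout.value - feed.flow * cin.value
    sd = float(np.hypot(effluent.flow * cout.sd, feed.flow * cin.sd))
    return Rate(compound, value, sd, "overall")


def dissolved_rates_from_table(
    samples: pd.DataFrame,
    feed_concentrations: Mapping[str, float],
    config: ReactorConfig,
    schedule: "PhaseSchedule | None" = None,
) -> RateSet:
    """Overall dissolved rates from a cycle-position sample table.

    The table has columns ``time_h, phase_label, compound, replicate,
    conc_mM``.  When a schedule is given and the canonical cycle positions
    (start_oxic, end_oxic, end_anoxic) are present, the effluent mean is
    the trapezoidal time-weighted average over the cycle (concentrations
    vary piecewise-linearly between positions in a periodic cycle);
    otherwise all samples are weighted equally.  Feed concentrations are
    taken as exact; the influent and effluent flows both equal V/HRT.
    """
    required = {"time_h", "phase_label", "compound", "replicate", "conc_mM"}
    missing = required - set(samples.columns)
    if missing:
        raise DataError(f"sample table missing columns: {sorted(missing)}")
    if len(samples) == 0:
        raise DataError("sample table is empty")

    canonical = ("start_oxic", "end_oxic", "end_anoxic")
    weights: dict[str, float] | None = None
    if schedule is not None and set(samples["phase_label"]) == set(canonical):
        t_ox, t_an = schedule.t_oxic, schedule.t_anoxic
        cycle = t_ox + t_an
        weights = {
            "start_oxic": 0.5 * t_ox / cycle,
            "end_oxic": 0.5 * (t_ox + t_an) / cycle,
            "end_anoxic": 0.5 * t_an / cycle,
        }

    flow = config.flow
    rates: RateSet = {}
    for compound, group in samples.groupby("compound"):
        if weights is None:
            reps = group["conc_mM"].to_numpy(dtype=float)
            mean = float(np.mean(reps))
            sd = float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0
        else:
            mean = 0.0
            var = 0.0
            for label, w in weights.items():
                reps = group.loc[group.phase_label == label, "conc_mM"].to_numpy(dtype=float)
                mean += w * float(np.mean(reps))
                var += (w * (float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0)) ** 2
            sd = float(np.sqrt(var))
        c_in = float(feed_concentrations.get(compound, 0.0))
        rates[compound] = Rate(compound, flow * mean - flow * c_in, flow * sd, "overall")
    return rates


def gas_accumulation_rate(
    trace: GasTrace,
    window: tuple[float, float] | None,
    gas: str,
    config: ReactorConfig,
    phase_scope: str = "overall",
) -> Rate:
    """Off-gas accumulation rate of N2O or CO2 over a time window.

    Per-minute rate = (y_out - y_in) * P*F_gas/(R*T), averaged over the
    window and converted to the compound basis (N-mmol/h for N2O,
    C-mmol/h for CO2).  The sd is the standard deviation of the
    minute-resolution rates within the window.
    """
    gas = gas.lower()
    if gas not in ("n2o", "co2"):
        raise DataError(f"gas must be 'n2o' or 'co2', got {gas!r}")
    mask = trace.window_mask(window)
    y_out = getattr(trace, f"y_{gas}")[mask]
    y_in = getattr(trace, f"y_{gas}_in")[mask]
    per_min = (y_out - y_in) * config.molar_gas_flow * _GAS_BASIS_PER_MOLECULE[gas]
    sd = float(np.std(per_min, ddof=1)) if per_min.size > 1 else 0.0
    return Rate(gas, float(np.mean(per_min)), sd, phase_scope)


def o2_consumption_rate(
    trace: GasTrace,
    oxic_window: tuple[float, float] | None,
    config: ReactorConfig,
) -> Rate:
    """O2 uptake from the kLa-based transfer balance over an oxic window.

    Magnitude = mean of ``kLa * H_O2*P*y_O2 * (1 - DO) * V`` with DO
    re-expressed as a fraction of the saturation concentration set by the
    prevailing off-gas y_O2 (the probe reports % of *air* saturation).
    Reported as consumption (negative), in mmol O2/h, aerobic scope.
    """
    if config.kla is None or config.henry_o2 is None:
        raise ConfigError("kla and henry_o2 must be set for the O2 rate")
    mask = trace.window_mask(oxic_window)
    y_o2 = trace.y_o2[mask]
    sat = 1e3 * config.henry_o2 * config.pressure * y_o2  # mmol/L at prevailing y_O2
    c_liquid = trace.do_frac[mask] * config.o2_air_saturation()
    per_min = config.kla * (sat - c_liquid) * config.volume  # mmol O2/h
    sd = float(np.std(per_min, ddof=1)) if per_min.size > 1 else 0.0
    return Rate("o2", -float(np.mean(per_min)), sd, "aerobic")


def biomass_production_rate(r_nh4: Rate, registry: StoichRegistry) -> Rate:
    """Biomass rate from NH4+ uptake, assuming full assimilation.

    ``R_X = -R_NH4 / (N/C)`` in C-mmol/h; holds when nitrification is
    suppressed and ammonium serves only as nitrogen source.
    """
    if r_nh4.value > 0:
        warnings.warn(
            "positive NH4+ rate (net ammonification?) - biomass rate will be negative",
            stacklevel=2,
        )
    ratio = registry.biomass_nc_ratio
    return Rate(
        "biomass",
        -r_nh4.value / ratio,
        r_nh4.sd / ratio,
        r_nh4.phase_scope,
    )


def n2_rate_by_difference(r_no3: Rate, r_n2o: Rate, r_no2: Rate | None = None) -> Rate:
    """N2 production closing the nitrogen balance (N-mmol/h).

    ``R_N2 = -R_NO3 - R_N2O - R_NO2``; valid when NO accumulation is
    absent, as in the steady-state cultures modelled here.
    """
    if r_no2 is None:
        r_no2 = Rate("no2", 0.0, 0.0, r_no3.phase_scope)
    scopes = {r_no3.phase_scope, r_n2o.phase_scope, r_no2.phase_scope}
    if len(scopes) != 1:
        raise ValueError(f"mixed phase scopes {scopes} in nitrogen balance")
    value = -r_no3.value - r_n2o.value - r_no2.value
    sd = float(np.sqrt(r_no3.sd**2 + r_n2o.sd**2 + r_no2.sd**2))
    return Rate("n2", value, sd, r_no3.phase_scope)


def overall_from_aerobic_o2(r_o2_aerobic: Rate, schedule: "PhaseSchedule") -> Rate:
    """Cycle-averaged 'overall' O2 rate from the aerobic-phase rate.

    The anaerobic O2 term is zero, so the time-weighted combination
    reduces to ``R_overall = R_aerobic * t_aerobic/24``.
    """
    if r_o2_aerobic.phase_scope != "aerobic":
        raise ValueError("input O2 rate must have aerobic scope")
    w = schedule.net_oxic_h / 24.0
    return Rate("o2", r_o2_aerobic.value * w, r_o2_aerobic.sd * w, "overall")
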