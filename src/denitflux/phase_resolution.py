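"""Oxic/anoxic phase segmentation and phase-resolved rate deconvolution.

Minutes are labelled oxic when DO >= 1 % of air saturation, anoxic
otherwise.  Overall rates are the time-weighted combination of the phase
rates, ``R_overall = (t_aer/24)*R_aer + (t_ana/24)*R_ana``.  The inverse
problem — splitting the NO3- uptake into its aerobic and anaerobic parts —
is solved by closing the electron balance in each phase: the organic
substrate is supplied continuously and fully consumed, so the per-hour
catabolic electron supply is phase-uniform; subtracting the aerobic O2
respiration leaves the electrons that must have ended on nitrogen oxides,
which the per-phase N2O rate then splits between N2O (4 e/N) and N2
(5 e/N).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rate_estimation import (
    DataError,
    GasTrace,
    Rate,
    RateSet,
    ReactorConfig,
    gas_accumulation_rate,
)
from .stoichiometry import StoichRegistry, default_registry
from .uncertainty import UncertainValue, propagate_linear
from .balances import VFA_NAMES, BalanceError

__all__ = [
    "PhaseSchedule",
    "PhaseSegmentation",
    "PhaseRates",
    "PhaseGasRates",
    "DeconvolutionReport",
    "segment_phases",
    "trimmed_mask",
    "phase_gas_rates",
    "combine_phase_rates",
    "deconvolve_no3_rates",
    "phase_n2o_statistics",
    "aerobic_n2o_fraction",
]


@dataclass(frozen=True)
class PhaseSchedule:
    """Oxic/anoxic cycling schedule.

    ``t_oxic``/``t_anoxic`` are the nominal sparge durations per cycle
    (h); ``net_oxic_h``/``net_anoxic_h`` the measured net hours per day by
    the DO-threshold rule, defaulting to the nominal values.
    """

    cycles_per_day: int
    t_oxic: float
    t_anoxic: float
    net_oxic_h: float | None = None
    net_anoxic_h: float | None = None

    def __post_init__(self) -> None:
        total = self.cycles_per_day * (self.t_oxic + self.t_anoxic)
        if abs(total - 24.0) > 1e-6:
            raise ValueError(f"schedule covers {total} h/day, expected 24")
        if self.net_oxic_h is None:
            object.__setattr__(self, "net_oxic_h", self.cycles_per_day * self.t_oxic)
        if self.net_anoxic_h is None:
            object.__setattr__(self, "net_anoxic_h", 24.0 - self.net_oxic_h)
        if abs(self.net_oxic_h + self.net_anoxic_h - 24.0) > 1e-6:
            raise ValueError("net oxic + anoxic hours must total 24 per day")

    @property
    def cycle_h(self) -> float:
        return self.t_oxic + self.t_anoxic


#: R4-like low-frequency schedule: 4 cycles/day of 4 h oxic + 2 h anoxic.
def low_frequency_schedule() -> PhaseSchedule:
    return PhaseSchedule(cycles_per_day=4, t_oxic=4.0, t_anoxic=2.0)


#: R32-like high-frequency schedule: 32 cycles/day of 30 min + 15 min.
def high_frequency_schedule(net_oxic_h: float = 17.0) -> PhaseSchedule:
    return PhaseSchedule(
        cycles_per_day=32, t_oxic=0.5, t_anoxic=0.25, net_oxic_h=net_oxic_h
    )


@dataclass
class PhaseSegmentation:
    """Ordered, non-overlapping intervals labelling a trace by phase."""

    intervals: list[tuple[float, float, str]]
    threshold: float
    oxic_h_per_day: float
    anoxic_h_per_day: float

    def mask(self, time_min: np.ndarray, label: str) -> np.ndarray:
        out = np.zeros(time_min.shape, dtype=bool)
        for start, end, lab in self.intervals:
            if lab == label:
                out |= (time_min >= start) & (time_min < end)
        return out

    def switches(self, label: str) -> list[float]:
        """Start times (min) of the intervals with the given label."""
        return [start for start, _, lab in self.intervals if lab == label]


def segment_phases(
    trace: GasTrace, threshold: float = 0.01, min_interval_min: float = 5.0
) -> PhaseSegmentation:
    """Label each minute oxic (DO >= threshold of air saturation) or anoxic.

    Transition minutes are assigned by the threshold rule alone.  Runs
    shorter than *min_interval_min* are absorbed into their neighbours:
    sensor noise near the threshold otherwise shatters the segmentation
    into spurious one-minute phases (set it to 0 for the raw rule).  The
    net oxic/anoxic hours per day follow from the final labelling.
    """
    labels = (trace.do_frac >= threshold).astype(int)  # 1 = oxic
    if labels.min() == labels.max():
        warnings.warn("DO never crosses the threshold: single-phase trace", stacklevel=2)
    if min_interval_min > 0:
        labels = _absorb_short_runs(labels, int(min_interval_min))
    t = trace.time_min
    step = 1.0
    names = {1: "oxic", 0: "anoxic"}
    intervals: list[tuple[float, float, str]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            intervals.append((float(t[start]), float(t[i - 1] + step), names[int(labels[start])]))
            start = i
    total_min = float(t[-1] + step - t[0])
    oxic_min = sum(e - s for s, e, lab in intervals if lab == "oxic")
    days = total_min / 1440.0
    return PhaseSegmentation(
        intervals=intervals,
        threshold=threshold,
        oxic_h_per_day=oxic_min / 60.0 / days,
        anoxic_h_per_day=(total_min - oxic_min) / 60.0 / days,
    )


def _absorb_short_runs(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Flip runs shorter than *min_len* samples, shortest first, until stable."""
    labels = labels.copy()
    for _ in range(len(labels)):
        # run-length encode
        edges = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [len(labels)]))
        lengths = ends - starts
        if len(starts) <= 1:
            break
        short = np.flatnonzero(lengths < min_len)
        if short.size == 0:
            break
        k = short[np.argmin(lengths[short])]
        labels[starts[k]:ends[k]] = 1 - labels[starts[k]]
    return labels


def combine_phase_rates(aerobic: Rate, anaerobic: Rate, schedule: PhaseSchedule) -> Rate:
    """Time-weighted overall rate from the aerobic and anaerobic rates."""
    if aerobic.compound != anaerobic.compound:
        raise ValueError("phase rates refer to different compounds")
    w_aer = schedule.net_oxic_h / 24.0
    w_ana = schedule.net_anoxic_h / 24.0
    value = w_aer * aerobic.value + w_ana * anaerobic.value
    sd = float(np.hypot(w_aer * aerobic.sd, w_ana * anaerobic.sd))
    return Rate(aerobic.compound, value, sd, "overall")


@dataclass(frozen=True)
class PhaseRates:
    """Aerobic/anaerobic/overall rate triple for one compound."""

    aerobic: Rate
    anaerobic: Rate
    overall: Rate


@dataclass
class PhaseGasRates:
    """Per-phase gas-derived rates feeding the deconvolution."""

    n2o_aerobic: Rate
    n2o_anaerobic: Rate
    o2_aerobic: Rate | None = None   # aerobic-scope O2 rate (negative)
    co2_aerobic: Rate | None = None
    co2_anaerobic: Rate | None = None


@dataclass
class DeconvolutionReport:
    """Phase-resolved NO3- reduction estimate and its diagnostics."""

    no3: PhaseRates
    n2: PhaseRates
    aerobic_e_share: UncertainValue         # % of aerobic catabolic electrons to NOx
    anaerobic_e_share: UncertainValue       # % (100 unless O2 intrudes anaerobically)
    aerobic_n2o_fraction: UncertainValue    # % of aerobic NO3- emitted as N2O
    fold_difference: UncertainValue         # anaerobic/aerobic NO3- rate ratio
    eq2_residual_percent: float             # recombined vs measured overall NO3-
    eq2_tolerance_percent: float
    clipped_phases: list[str] = field(default_factory=list)

    @property
    def eq2_consistent(self) -> bool:
        return abs(self.eq2_residual_percent) <= self.eq2_tolerance_percent

    def to_dict(self) -> dict:
        def rate(r: Rate) -> dict:
            return {"value_N_mmol_h": r.value, "sd_N_mmol_h": r.sd}

        return {
            "no3": {
                "aerobic": rate(self.no3.aerobic),
                "anaerobic": rate(self.no3.anaerobic),
                "overall_recombined": rate(self.no3.overall),
            },
            "n2": {
                "aerobic": rate(self.n2.aerobic),
                "anaerobic": rate(self.n2.anaerobic),
                "overall_recombined": rate(self.n2.overall),
            },
            "aerobic_e_share_percent": self.aerobic_e_share.as_tuple(),
            "anaerobic_e_share_percent": self.anaerobic_e_share.as_tuple(),
            "aerobic_n2o_fraction_percent": self.aerobic_n2o_fraction.as_tuple(),
            "fold_difference_anaerobic_over_aerobic": self.fold_difference.as_tuple(),
            "eq2_residual_percent": self.eq2_residual_percent,
            "eq2_consistent": self.eq2_consistent,
            "clipped_phases": self.clipped_phases,
        }


def deconvolve_no3_rates(
    overall_rates: RateSet,
    phase_gas: PhaseGasRates,
    schedule: PhaseSchedule,
    registry: StoichRegistry | None = None,
    eq2_tolerance_percent: float = 10.0,
) -> DeconvolutionReport:
    """Aerobic vs anaerobic NO3- reduction by per-phase electron balances.

    Per phase p, the catabolic electron supply (donor electrons minus the
    anabolic share, both phase-uniform per hour) minus the O2 respiration
    leaves ``e_NOx(p)``; with the phase N2O rate, ``5*|R_NO3(p)| -
    R_N2O(p) = e_NOx(p)`` yields the phase NO3- uptake.  The recombined
    overall rate is compared with the measured one and reported as a
    relative residual.
    """
    reg = registry or default_registry()
    for name in (*VFA_NAMES, "biomass", "no3"):
        if name not in overall_rates:
            raise BalanceError(f"overall rate set missing {name!r}")

    o2_aer = phase_gas.o2_aerobic
    if o2_aer is None:
        if "o2" not in overall_rates:
            raise BalanceError("need an aerobic or overall O2 rate")
        w = schedule.net_oxic_h / 24.0
        r = overall_rates["o2"]
        o2_aer = Rate("o2", r.value / w, r.sd / w, "aerobic")

    e_n2o = reg.get("no3").gamma - reg.get("n2o").gamma   # 4 e/N
    e_n2 = reg.get("no3").gamma - reg.get("n2").gamma     # 5 e/N
    g = [reg.get(n).gamma for n in VFA_NAMES]
    g_x = reg.get("biomass").gamma
    g_o2 = reg.get("o2").gamma

    clipped: list[str] = []

    def e_cat(x) -> float:
        # x: [ace, pro, but, biomass, ...]
        donor = abs(g[0] * x[0] + g[1] * x[1] + g[2] * x[2])
        return donor - g_x * x[3]

    # -- point estimates, with clipping bookkeeping --------------------
    base_vals = [overall_rates[n].value for n in (*VFA_NAMES, "biomass")]
    ecat0 = e_cat(base_vals)

    e_nox_aer0 = ecat0 - g_o2 * abs(o2_aer.value)
    if e_nox_aer0 < 0:
        warnings.warn(
            "aerobic O2 respiration exceeds the catabolic electron supply; "
            "clipping the aerobic NOx electron flow to zero",
            stacklevel=2,
        )
        clipped.append("aerobic")

    inputs = [overall_rates[n].as_uncertain() for n in (*VFA_NAMES, "biomass")]
    uv_o2 = o2_aer.as_uncertain()
    uv_n2o_aer = phase_gas.n2o_aerobic.as_uncertain()
    uv_n2o_ana = phase_gas.n2o_anaerobic.as_uncertain()

    def phase_exprs(aerobic: bool):
        """Build closures over [ace, pro, but, X, o2_aer, n2o_p]."""

        def nox_e(x):
            supply = e_cat(x)
            if aerobic:
                supply -= g_o2 * abs(x[4])
            return max(supply, 0.0)

        def no3(x):
            return -(nox_e(x) + x[5]) / e_n2

        def n2(x):
            return abs(no3(x)) - x[5]

        def share(x):
            return 100.0 * nox_e(x) / e_cat(x)

        return no3, n2, share

    def run_phase(aerobic: bool, uv_n2o):
        no3_f, n2_f, share_f = phase_exprs(aerobic)
        ins = inputs + [uv_o2, uv_n2o]
        scope = "aerobic" if aerobic else "anaerobic"
        uv_no3 = propagate_linear(no3_f, ins)
        uv_n2 = propagate_linear(n2_f, ins)
        uv_share = propagate_linear(share_f, ins)
        return (
            Rate("no3", uv_no3.value, uv_no3.sd, scope),
            Rate("n2", uv_n2.value, uv_n2.sd, scope),
            uv_share,
        )

    no3_aer, n2_aer, share_aer = run_phase(True, uv_n2o_aer)
    no3_ana, n2_ana, share_ana = run_phase(False, uv_n2o_ana)

    no3_overall = combine_phase_rates(no3_aer, no3_ana, schedule)
    n2_overall = combine_phase_rates(n2_aer, n2_ana, schedule)

    measured = overall_rates["no3"].value
    residual = (
        100.0 * (no3_overall.value - measured) / measured if measured != 0 else float("inf")
    )

    if no3_aer.value == 0:
        raise BalanceError("aerobic NO3- rate is zero: N2O fraction undefined")
    frac = propagate_linear(
        lambda x: 100.0 * x[0] / abs(x[1]),
        [uv_n2o_aer, no3_aer.as_uncertain()],
    )
    fold = propagate_linear(
        lambda x: abs(x[0]) / abs(x[1]),
        [no3_ana.as_uncertain(), no3_aer.as_uncertain()],
    )

    return DeconvolutionReport(
        no3=PhaseRates(no3_aer, no3_ana, no3_overall),
        n2=PhaseRates(n2_aer, n2_ana, n2_overall),
        aerobic_e_share=share_aer,
        anaerobic_e_share=share_ana,
        aerobic_n2o_fraction=frac,
        fold_difference=fold,
        eq2_residual_percent=residual,
        eq2_tolerance_percent=eq2_tolerance_percent,
        clipped_phases=clipped,
    )


def aerobic_n2o_fraction(no3_aerobic: Rate, r_n2o_aer: Rate) -> UncertainValue:
    """% of the aerobic NO3- uptake emitted as N2O (N basis)."""
    if no3_aerobic.value == 0:
        raise BalanceError("zero aerobic NO3- rate")
    return propagate_linear(
        lambda x: 100.0 * x[0] / abs(x[1]),
        [r_n2o_aer.as_uncertain(), no3_aerobic.as_uncertain()],
    )


def trimmed_mask(seg: PhaseSegmentation, time_min: np.ndarray, label: str, trim_min: float) -> np.ndarray:
    """Minutes belonging to *label* intervals, excluding *trim_min* minutes
    at both interval ends (the DO-labelled phase lags the gas switch, so an
    interval's head and tail both sit inside gas-transition windows)."""
    out = np.zeros(time_min.shape, dtype=bool)
    for start, end, lab in seg.intervals:
        if lab == label and end - start > 2 * trim_min:
            out |= (time_min >= start + trim_min) & (time_min < end - trim_min)
    return out


def phase_gas_rates(
    trace: GasTrace,
    seg: PhaseSegmentation,
    config: ReactorConfig,
    trim_min: float = 15.0,
) -> PhaseGasRates:
    """Per-phase N2O rates and the aerobic O2 rate from a labelled trace.

    The Eq-3/Eq-4 balances equal the biological rates only at quasi-steady
    dissolved pools, so the first *trim_min* minutes after each gas switch
    are excluded from the phase averages.  The N2O sd is the spread of the
    minute-resolution rates; the O2 rate is returned as consumption
    (negative, aerobic scope).
    """
    if config.kla is None or config.henry_o2 is None:
        raise DataError("kla and henry_o2 must be set for the aerobic O2 rate")
    t = trace.time_min

    def effective_trim(label: str) -> float:
        # keep at least half of each interval: cap the trim at a quarter of
        # the median interval length (short high-frequency cycles)
        durations = [e - s for s, e, lab in seg.intervals if lab == label]
        if not durations:
            raise DataError(f"no {label} intervals in the segmentation")
        return min(trim_min, 0.25 * float(np.median(durations)))

    trims = {label: effective_trim(label) for label in ("oxic", "anoxic")}
    rates: dict[str, Rate] = {}
    for label, scope in (("oxic", "aerobic"), ("anoxic", "anaerobic")):
        mask = trimmed_mask(seg, t, label, trims[label])
        if not mask.any():
            raise DataError(f"no {label} minutes left after trimming {trims[label]} min")
        per_min = (trace.y_n2o[mask] - trace.y_n2o_in[mask]) * config.molar_gas_flow * 2.0
        sd = float(np.std(per_min, ddof=1)) if per_min.size > 1 else 0.0
        rates[label] = Rate("n2o", float(np.mean(per_min)), sd, scope)

    oxic = trimmed_mask(seg, t, "oxic", trims["oxic"])
    sat = 1e3 * config.henry_o2 * config.pressure * trace.y_o2[oxic]
    c = trace.do_frac[oxic] * config.o2_air_saturation()
    per_min = config.kla * (sat - c) * config.volume
    o2 = Rate(
        "o2",
        -float(np.mean(per_min)),
        float(np.std(per_min, ddof=1)) if per_min.size > 1 else 0.0,
        "aerobic",
    )
    return PhaseGasRates(
        n2o_aerobic=rates["oxic"], n2o_anaerobic=rates["anoxic"], o2_aerobic=o2
    )


def phase_n2o_statistics(
    trace: GasTrace,
    seg: PhaseSegmentation,
    config: ReactorConfig,
) -> tuple[pd.DataFrame, dict]:
    """Daily mean N2O rate per phase plus boxplot summary statistics.

    Applies the off-gas accumulation balance within labelled intervals,
    groups by calendar day, and summarises each phase's daily means with
    median, quartiles and 1.5-IQR whiskers.
    """
    t = trace.time_min
    total_days = int(np.ceil((t[-1] + 1 - t[0]) / 1440.0))
    if total_days < 1:
        raise DataError("segmentation must cover at least one day")
    rows = []
    for day in range(total_days):
        lo = t[0] + 1440.0 * day
        hi = lo + 1440.0
        day_mask = (t >= lo) & (t < hi)
        for label in ("oxic", "anoxic"):
            mask = day_mask & seg.mask(t, label)
            if not mask.any():
                rows.append({"day": day, "phase": label, "rate_N_mmol_h": np.nan, "n_min": 0})
                continue
            per_min = (
                (trace.y_n2o[mask] - trace.y_n2o_in[mask]) * config.molar_gas_flow * 2.0
            )
            rows.append(
                {
                    "day": day,
                    "phase": label,
                    "rate_N_mmol_h": float(np.mean(per_min)),
                    "n_min": int(mask.sum()),
                }
            )
    daily = pd.DataFrame(rows)

    summary: dict[str, dict[str, float]] = {}
    for label in ("oxic", "anoxic"):
        vals = daily.loc[daily.phase == label, "rate_N_mmol_h"].dropna().to_numpy()
        if vals.size == 0:
            summary[label] = {"n_days": 0}
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_whisker = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        summary[label] = {
            "n_days": int(vals.size),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(in_whisker.min()),
            "whisker_high": float(in_whisker.max()),
        }
    return daily, summary
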