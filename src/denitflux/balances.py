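"""Steady-state yields, carbon and electron balances.

Yields are referenced to the total organic-substrate (VFA) uptake; the
carbon balance compares substrate carbon to biomass + CO2 carbon; the
electron balance compares donor electrons (VFAs, per degree of reduction)
to acceptor plus anabolic electrons (nitrogen oxides down to the ammonia
reference level, O2, biomass).  All outputs carry first-order-propagated
standard deviations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .rate_estimation import Rate, RateSet
from .stoichiometry import StoichRegistry, default_registry
from .uncertainty import UncertainValue, propagate_linear

__all__ = [
    "VFA_NAMES",
    "BalanceError",
    "YieldTable",
    "BalanceReport",
    "yields_from_rates",
    "carbon_balance",
    "electron_balance",
    "catabolic_electron_partition",
    "rates_from_yields",
]

#: the organic substrates of the enrichment medium, on a C-mol basis
VFA_NAMES = ("acetate", "propionate", "butyrate")


class BalanceError(ValueError):
    """A balance cannot be evaluated (missing rate or zero denominator)."""


def _require(rates: RateSet, names) -> None:
    missing = [n for n in names if n not in rates]
    if missing:
        raise BalanceError(f"rate set missing compounds: {missing}")


def _uv(rates: RateSet, *names: str) -> list[UncertainValue]:
    return [rates[n].as_uncertain() for n in names]


@dataclass(frozen=True)
class YieldTable:
    """Overall steady-state stoichiometric yields (substrate basis C-mol)."""

    y_n2o_no3: UncertainValue   # N-mol N2O per N-mol NO3- reduced
    y_x_s: UncertainValue       # C-mol biomass per C-mol substrate
    y_no3_s: UncertainValue     # N-mol NO3- per C-mol substrate
    y_o2_s: UncertainValue      # mol O2 per C-mol substrate
    y_co2_s: UncertainValue     # C-mol CO2 per C-mol substrate

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            name: {"value": uv.value, "sd": uv.sd}
            for name, uv in self.__dict__.items()
        }

    def to_markdown(self) -> str:
        cols = [
            ("Y_N2O/NO3- (Nmol/Nmol)", self.y_n2o_no3),
            ("Y_X/S (Cmol/Cmol)", self.y_x_s),
            ("Y_NO3-/S (Nmol/Cmol)", self.y_no3_s),
            ("Y_O2/S (mol/Cmol)", self.y_o2_s),
            ("Y_CO2/S (Cmol/Cmol)", self.y_co2_s),
        ]
        head = "| " + " | ".join(name for name, _ in cols) + " |"
        sep = "|" + "---|" * len(cols)
        row = "| " + " | ".join(f"{uv.value:.2f} ± {uv.sd:.2f}" for _, uv in cols) + " |"
        return "\n".join([head, sep, row])


@dataclass(frozen=True)
class BalanceReport:
    """Closure percentages plus the catabolic electron partition."""

    c_balance: UncertainValue         # %
    e_balance: UncertainValue         # %
    e_fraction_no3: UncertainValue    # % of catabolic electrons to NO3- reduction

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            "c_balance_percent": {"value": self.c_balance.value, "sd": self.c_balance.sd},
            "e_balance_percent": {"value": self.e_balance.value, "sd": self.e_balance.sd},
            "e_fraction_no3_percent": {
                "value": self.e_fraction_no3.value,
                "sd": self.e_fraction_no3.sd,
            },
        }


def yields_from_rates(rates: RateSet) -> YieldTable:
    """Stoichiometric yields from an overall rate set.

    Each yield is |product or acceptor rate| / |total VFA uptake|, except
    the N2O yield which is referenced to the NO3- uptake.
    """
    _require(rates, VFA_NAMES + ("no3", "n2o", "o2", "co2", "biomass"))
    vfas = _uv(rates, *VFA_NAMES)

    def ratio(num_idx: int):
        # inputs: [num, ace, pro, but]
        return lambda x: abs(x[0]) / abs(x[1] + x[2] + x[3])

    def over_substrate(name: str) -> UncertainValue:
        s = abs(sum(r.value for r in vfas))
        if s == 0:
            raise BalanceError("zero substrate rate")
        return propagate_linear(ratio(0), [rates[name].as_uncertain(), *vfas])

    if rates["no3"].value == 0:
        raise BalanceError("zero NO3- rate in Y_N2O/NO3")
    y_n2o_no3 = propagate_linear(
        lambda x: abs(x[0]) / abs(x[1]),
        _uv(rates, "n2o", "no3"),
    )
    return YieldTable(
        y_n2o_no3=y_n2o_no3,
        y_x_s=over_substrate("biomass"),
        y_no3_s=over_substrate("no3"),
        y_o2_s=over_substrate("o2"),
        y_co2_s=over_substrate("co2"),
    )


def carbon_balance(rates: RateSet) -> UncertainValue:
    """C balance (%) = 100 * |R_Ace + R_Pro + R_But| / (R_X + R_CO2)."""
    _require(rates, VFA_NAMES + ("biomass", "co2"))
    denom = rates["biomass"].value + rates["co2"].value
    if denom == 0:
        raise BalanceError("zero carbon-product rate")
    return propagate_linear(
        lambda x: 100.0 * abs(x[0] + x[1] + x[2]) / (x[3] + x[4]),
        _uv(rates, *VFA_NAMES, "biomass", "co2"),
    )


def electron_balance(rates: RateSet, registry: StoichRegistry | None = None) -> UncertainValue:
    """e- balance (%) = 100 * donor electrons / acceptor + anabolic electrons.

    Donor side: degree-of-reduction-weighted VFA uptake.  Acceptor side:
    ``-8*R_NO3 - 4*R_N2O - 3*R_N2 - 4*R_O2 + gamma_X*R_X`` with the
    signed-rate convention (uptakes negative), so every term is positive
    for a closing balance.
    """
    reg = registry or default_registry()
    _require(rates, VFA_NAMES + ("no3", "n2o", "n2", "o2", "biomass"))
    g = {name: reg.get(name).gamma for name in (*VFA_NAMES, "no3", "n2o", "n2", "o2", "biomass")}

    def f(x):
        ace, pro, but, no3, n2o, n2, o2, bio = x
        donor = abs(g["acetate"] * ace + g["propionate"] * pro + g["butyrate"] * but)
        acceptor = (
            -g["no3"] * no3 - g["n2o"] * n2o - g["n2"] * n2 - g["o2"] * o2 + g["biomass"] * bio
        )
        return 100.0 * donor / acceptor

    inputs = _uv(rates, *VFA_NAMES, "no3", "n2o", "n2", "o2", "biomass")
    if not np.isfinite(f([u.value for u in inputs])):
        raise BalanceError("zero acceptor electron rate")
    return propagate_linear(f, inputs)


def catabolic_electron_partition(
    rates: RateSet, registry: StoichRegistry | None = None
) -> UncertainValue:
    """% of catabolic electrons routed to NO3- reduction.

    Electrons ending in reduced nitrogen products over all catabolic
    electrons: ``100 * (4*R_N2O + 5*R_N2) / (4*R_N2O + 5*R_N2 + 4*|R_O2|)``.
    The per-product counts (4 e/N to N2O, 5 e/N to N2) are the NO3- -> N2O
    and NO3- -> N2 reduction steps encoded by the acceptor coefficients
    (8 - 4 and 8 - 3 e/N).
    """
    reg = registry or default_registry()
    _require(rates, ("n2o", "n2", "o2"))
    e_n2o = reg.get("no3").gamma - reg.get("n2o").gamma   # 4 e/N
    e_n2 = reg.get("no3").gamma - reg.get("n2").gamma     # 5 e/N
    e_o2 = reg.get("o2").gamma                            # 4 e/mol

    def f(x):
        n2o, n2, o2 = x
        nox = e_n2o * n2o + e_n2 * n2
        return 100.0 * nox / (nox + e_o2 * abs(o2))

    vals = [rates[n].value for n in ("n2o", "n2", "o2")]
    if e_n2o * vals[0] + e_n2 * vals[1] + e_o2 * abs(vals[2]) == 0:
        raise BalanceError("zero catabolic electron flow")
    return propagate_linear(f, _uv(rates, "n2o", "n2", "o2"))


def rates_from_yields(
    feeds: Mapping[str, UncertainValue | float],
    yields: Mapping[str, UncertainValue | float],
    registry: StoichRegistry | None = None,
) -> RateSet:
    """Overall rate set from printed feed rates and stoichiometric yields.

    *feeds* gives the VFA supply in C-mmol/h (fully consumed, so uptakes
    equal the negated feeds); *yields* holds ``y_x_s``, ``y_no3_s``,
    ``y_o2_s``, ``y_co2_s`` (per C-mol substrate) and ``y_n2o_no3`` (per
    N-mol NO3-).  N2 closes the nitrogen balance; NH4+ uptake follows from
    the biomass N content.  Uncertainties propagate linearly from the
    feed and yield sds.
    """
    reg = registry or default_registry()

    def uv(x) -> UncertainValue:
        return x if isinstance(x, UncertainValue) else UncertainValue(float(x), 0.0)

    f = {name: uv(feeds[name]) for name in VFA_NAMES}
    y = {name: uv(yields[name]) for name in ("y_n2o_no3", "y_x_s", "y_no3_s", "y_o2_s", "y_co2_s")}
    base = [f["acetate"], f["propionate"], f["butyrate"]]

    rates: RateSet = {}
    for i, name in enumerate(VFA_NAMES):
        rates[name] = Rate(name, -f[name].value, f[name].sd, "overall")

    def derived(name: str, fn) -> None:
        uvv = propagate_linear(fn, base + list(y.values()))
        rates[name] = Rate(name, uvv.value, uvv.sd, "overall")

    # x = [ace, pro, but, y_n2o_no3, y_x_s, y_no3_s, y_o2_s, y_co2_s]
    derived("biomass", lambda x: x[4] * (x[0] + x[1] + x[2]))
    derived("no3", lambda x: -x[5] * (x[0] + x[1] + x[2]))
    derived("o2", lambda x: -x[6] * (x[0] + x[1] + x[2]))
    derived("co2", lambda x: x[7] * (x[0] + x[1] + x[2]))
    derived("n2o", lambda x: x[3] * x[5] * (x[0] + x[1] + x[2]))
    derived("n2", lambda x: (1.0 - x[3]) * x[5] * (x[0] + x[1] + x[2]))
    derived("nh4", lambda x: -reg.biomass_nc_ratio * x[4] * (x[0] + x[1] + x[2]))
    rates["no2"] = Rate("no2", 0.0, 0.0, "overall")
    return rates
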