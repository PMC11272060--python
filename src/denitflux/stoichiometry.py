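"""Compound registry, element counts and degree-of-reduction coefficients.

Every balance computation in the package draws its electron coefficients
from a :class:`StoichRegistry`.  The degree of reduction (gamma) of a
compound is the number of electron equivalents it carries per C-mol
(organics, biomass), per N-mol (nitrogen oxides, counted as electrons
required to reduce the compound to the ammonia reference level) or per mol
(O2).  Acceptor coefficients are stored unsigned; the operation applying
them owns the sign convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = [
    "ATOMIC_MASS",
    "CompoundSpec",
    "StoichRegistry",
    "RegistryError",
    "gamma_from_formula",
    "formula_mass",
    "default_registry",
]

#: atomic masses (g/mol) of the elements appearing in broth compounds
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "S": 32.06,
    "P": 30.974,
}

#: default elemental biomass composition, per C-mol (CH1.8O0.5N0.2).
#: Satisfies both N/C = 0.2 and a degree of reduction of 4.2 with nitrogen
#: taken up at the ammonia reference level.
DEFAULT_BIOMASS_COMPOSITION: Mapping[str, float] = {
    "C": 1.0,
    "H": 1.8,
    "O": 0.5,
    "N": 0.2,
}


class RegistryError(KeyError):
    """Raised when a compound is missing from a registry."""


def gamma_from_formula(formula: Mapping[str, float], per_carbon: bool = True) -> float:
    """Degree of reduction of a molecular formula.

    Electrons are counted relative to the fully oxidised reference state
    (CO2, H2O) with nitrogen at the ammonia level:
    ``4*C + 1*H - 2*O - 3*N``, divided by the carbon count when
    *per_carbon* is true.
    """
    c = formula.get("C", 0.0)
    e = 4.0 * c + formula.get("H", 0.0) - 2.0 * formula.get("O", 0.0) - 3.0 * formula.get("N", 0.0)
    if per_carbon:
        if c == 0:
            raise ValueError("per-carbon gamma undefined for carbon-free formula")
        return e / c
    return e


def formula_mass(formula: Mapping[str, float]) -> float:
    """Molar mass (g/mol) of a formula from atomic masses."""
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class CompoundSpec:
    """One compound as seen by the balance machinery.

    Parameters
    ----------
    name:
        Registry key.
    carbon, nitrogen:
        Atoms per basis unit (so 1 for any organic on a C-mol basis,
        1 for nitrogen oxides on an N-mol basis).
    gamma:
        Electron equivalents per basis unit, stored unsigned.
    molar_mass:
        g per basis unit (g/C-mol for organics and biomass).
    basis:
        One of ``{"C-mol", "N-mol", "mol"}``.
    """

    name: str
    carbon: float
    nitrogen: float
    gamma: float
    molar_mass: float
    basis: str

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"{self.name}: gamma must be stored unsigned")
        if self.basis not in ("C-mol", "N-mol", "mol"):
            raise ValueError(f"{self.name}: unknown basis {self.basis!r}")


@dataclass
class StoichRegistry:
    """Keyed collection of :class:`CompoundSpec` plus the biomass N/C ratio."""

    compounds: dict[str, CompoundSpec] = field(default_factory=dict)
    biomass_nc_ratio: float = 0.2
    biomass_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMASS_COMPOSITION)
    )

    def get(self, name: str) -> CompoundSpec:
        try:
            return self.compounds[name]
        except KeyError:
            raise RegistryError(f"compound {name!r} not registered") from None

    def add(self, spec: CompoundSpec) -> None:
        self.compounds[spec.name] = spec

    def electron_equivalents(self, compound: str, amount: float) -> float:
        """Signed electron equivalents carried by *amount* of *compound*.

        *amount* is in mmol on the compound's own basis (C-mmol for
        organics, N-mmol for nitrogen oxides); the sign is preserved.
        """
        return self.get(compound).gamma * amount

    def biomass_formula_mass(self) -> float:
        """g per C-mol of the configured biomass elemental composition."""
        return formula_mass(self.biomass_composition)

    def biomass_gamma(self) -> float:
        return gamma_from_formula(self.biomass_composition)

    # -- serialisation -------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "biomass_nc_ratio": self.biomass_nc_ratio,
            "biomass_composition": dict(self.biomass_composition),
            "compounds": {
                name: {
                    "carbon": s.carbon,
                    "nitrogen": s.nitrogen,
                    "gamma": s.gamma,
                    "molar_mass": s.molar_mass,
                    "basis": s.basis,
                }
                for name, s in self.compounds.items()
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StoichRegistry":
        doc = yaml.safe_load(text)
        reg = cls(
            biomass_nc_ratio=float(doc.get("biomass_nc_ratio", 0.2)),
            biomass_composition=doc.get(
                "biomass_composition", dict(DEFAULT_BIOMASS_COMPOSITION)
            ),
        )
        for name, f in doc.get("compounds", {}).items():
            reg.add(
                CompoundSpec(
                    name=name,
                    carbon=float(f["carbon"]),
                    nitrogen=float(f["nitrogen"]),
                    gamma=float(f["gamma"]),
                    molar_mass=float(f["molar_mass"]),
                    basis=str(f["basis"]),
                )
            )
        return reg

    def with_biomass_composition(self, composition: Mapping[str, float]) -> "StoichRegistry":
        """Copy of the registry with a different biomass formula."""
        reg = StoichRegistry(
            compounds=dict(self.compounds),
            biomass_nc_ratio=composition.get("N", 0.0) / composition.get("C", 1.0),
            biomass_composition=dict(composition),
        )
        old = reg.compounds["biomass"]
        reg.compounds["biomass"] = replace(
            old,
            nitrogen=reg.biomass_nc_ratio,
            gamma=gamma_from_formula(composition),
            molar_mass=formula_mass(composition),
        )
        return reg


def default_registry() -> StoichRegistry:
    """Registry with the compounds of a VFA-fed denitrifying chemostat.

    Propionate's gamma is the conventional rounded 4.7 (exact 14/3) so
    that balances computed from printed rate tables reproduce published
    figures digit for digit; nitrogen-oxide coefficients (8, 4, 3, 6 e/N)
    count electrons down to the ammonia reference level.
    """
    reg = StoichRegistry()
    # organics on a C-mol basis
    reg.add(CompoundSpec("acetate", 1, 0, 4.0, formula_mass({"C": 2, "H": 4, "O": 2}) / 2, "C-mol"))
    reg.add(CompoundSpec("propionate", 1, 0, 4.7, formula_mass({"C": 3, "H": 6, "O": 2}) / 3, "C-mol"))
    reg.add(CompoundSpec("butyrate", 1, 0, 5.0, formula_mass({"C": 4, "H": 8, "O": 2}) / 4, "C-mol"))
    reg.add(
        CompoundSpec(
            "biomass", 1, 0.2,
            gamma_from_formula(DEFAULT_BIOMASS_COMPOSITION),
            formula_mass(DEFAULT_BIOMASS_COMPOSITION),
            "C-mol",
        )
    )
    reg.add(CompoundSpec("co2", 1, 0, 0.0, formula_mass({"C": 1, "O": 2}), "C-mol"))
    # nitrogen species on an N-mol basis
    reg.add(CompoundSpec("no3", 0, 1, 8.0, formula_mass({"N": 1, "O": 3}), "N-mol"))
    reg.add(CompoundSpec("no2", 0, 1, 6.0, formula_mass({"N": 1, "O": 2}), "N-mol"))
    reg.add(CompoundSpec("n2o", 0, 1, 4.0, formula_mass({"N": 2, "O": 1}) / 2, "N-mol"))
    reg.add(CompoundSpec("n2", 0, 1, 3.0, formula_mass({"N": 2}) / 2, "N-mol"))
    reg.add(CompoundSpec("nh4", 0, 1, 0.0, formula_mass({"N": 1, "H": 4}), "N-mol"))
    # dissolved gases on a mol basis
    reg.add(CompoundSpec("o2", 0, 0, 4.0, formula_mass({"O": 2}), "mol"))
    return reg
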