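"""Gibbs energies of fermentation balances and their dependence on H2.

The central quantity is the condition-adjusted reaction energy

    dG = dG'0 + R*T*ln Q

evaluated in the pH-transformed convention: formation energies are standard
*transformed* values at the table's reference pH, protons carry no explicit
term, water activity is 1, aqueous solutes enter Q as molar concentrations
and gases as partial pressures in atm against a 1 atm standard state.

Because the butyrate/acetate balance family produces 4 - 2b mol H2 per mol
glucose, the slope of dG in ln(pH2) is (4 - 2b)*R*T: acetate-rich
fermentations steepen, and the b = 2 balance (no net H2) is flat.  Dotted
ATP-feasibility thresholds at -n * dG_ATP translate the curves into the
largest number of ATP a fermenting cell could conserve at each H2 level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .stoichiometry import FermentationBalance, build_balance_family

R_KJ = 8.314e-3  # kJ / mol / K


class ThermoLookupError(KeyError):
    pass


class UnboundedFavorabilityError(ValueError):
    """A gas at zero partial pressure appears as a product: ln Q diverges."""


@dataclass
class ThermoTable:
    """Standard transformed formation energies (kJ/mol) at a reference T and pH."""

    formation_energies: dict[str, float]
    reference_temperature_K: float = 298.15
    reference_pH: float = 7.0
    source: str = ""

    def __getitem__(self, name: str) -> float:
        try:
            return self.formation_energies[name]
        except KeyError:
            raise ThermoLookupError(
                f"no formation energy for species {name!r} in thermo table"
            ) from None

    @classmethod
    def from_yaml(cls, path) -> "ThermoTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: Mapping) -> "ThermoTable":
        return cls(
            formation_energies={k: float(v) for k, v in doc["species"].items()},
            reference_temperature_K=float(doc.get("reference_temperature_K", 298.15)),
            reference_pH=float(doc.get("reference_pH", 7.0)),
            source=doc.get("source", ""),
        )


def default_thermo_table() -> ThermoTable:
    doc = yaml.safe_load(resources.files("butyrogen.data").joinpath("thermo.yaml").read_text())
    return ThermoTable._from_doc(doc)


@dataclass
class Conditions:
    """Temperature, pH, solute concentrations (M) and gas partial pressures (atm).

    Water activity is fixed at 1; protons are handled by the transformed
    convention and never enter the reaction quotient.
    """

    temperature_K: float = 310.15
    pH: float = 7.0
    concentrations_M: dict[str, float] = field(default_factory=dict)
    p_CO2_atm: float = 0.3
    p_H2_atm: float = 0.15

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.p_H2_atm < 0 or self.p_CO2_atm < 0:
            raise ValueError("partial pressures must be >= 0")

    def activity(self, name: str) -> float:
        if name == "H2":
            return self.p_H2_atm
        if name == "CO2":
            return self.p_CO2_atm
        if name in ("H2O", "H+"):
            return 1.0
        try:
            return self.concentrations_M[name]
        except KeyError:
            raise ThermoLookupError(f"no concentration given for solute {name!r}") from None

    def replace(self, **kw) -> "Conditions":
        data = {
            "temperature_K": self.temperature_K,
            "pH": self.pH,
            "concentrations_M": dict(self.concentrations_M),
            "p_CO2_atm": self.p_CO2_atm,
            "p_H2_atm": self.p_H2_atm,
        }
        data.update(kw)
        return Conditions(**data)

    @classmethod
    def from_yaml(cls, path) -> "Conditions":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: Mapping) -> "Conditions":
        return cls(
            temperature_K=float(doc.get("temperature_K", 310.15)),
            pH=float(doc.get("pH", 7.0)),
            concentrations_M={k: float(v) for k, v in doc.get("concentrations_M", {}).items()},
            p_CO2_atm=float(doc.get("p_CO2_atm", 0.3)),
            p_H2_atm=float(doc.get("p_H2_atm", 0.15)),
        )


def default_conditions() -> Conditions:
    doc = yaml.safe_load(resources.files("butyrogen.data").joinpath("conditions.yaml").read_text())
    return Conditions._from_doc(doc)


@dataclass(frozen=True)
class AtpThreshold:
    """Feasibility thresholds at -n * dG_ATP for ADP phosphorylation.

    The default energy per ATP is +70 kJ/mol.
    """

    dG_ATP: float = 70.0

    def __post_init__(self) -> None:
        if self.dG_ATP <= 0:
            raise ValueError("dG_ATP must be positive")

    def n_feasible(self, delta_g: float) -> int:
        """Largest n >= 0 with delta_g <= -n * dG_ATP."""
        if delta_g > 0:
            return 0
        return int(math.floor(-delta_g / self.dG_ATP + 1e-12))


def delta_g_standard(balance: FermentationBalance, table: ThermoTable | None = None) -> float:
    """Standard transformed reaction energy: sum of coefficient * dfG'0 (kJ/mol)."""
    table = table or default_thermo_table()
    return sum(c * table[name] for name, c in balance.coefficients.items())


def delta_g(balance: FermentationBalance, table: ThermoTable | None = None,
            cond: Conditions | None = None) -> float:
    """Condition-adjusted reaction energy dG = dG'0 + R*T*ln Q (kJ/mol).

    The formation-energy table is used at its own reference temperature
    (no enthalpy correction is applied); only the R*T*ln Q term follows the
    supplied temperature.  A product gas at zero partial pressure raises
    `UnboundedFavorabilityError` instead of returning -inf.
    """
    table = table or default_thermo_table()
    cond = cond or default_conditions()
    dg = delta_g_standard(balance, table)
    rt = R_KJ * cond.temperature_K
    ln_q = 0.0
    for name, c in balance.coefficients.items():
        if name in ("H2O", "H+") or abs(c) < 1e-12:
            continue
        a = cond.activity(name)
        if a <= 0:
            raise UnboundedFavorabilityError(
                f"activity of {name!r} is {a}: ln Q diverges; dG is unbounded "
                "(use a strictly positive concentration or partial pressure)"
            )
        ln_q += c * math.log(a)
    return dg + rt * ln_q


def sweep_h2(b_grid: Sequence[float], ph2_grid: Sequence[float],
             table: ThermoTable | None = None, cond: Conditions | None = None,
             threshold: AtpThreshold | None = None) -> pd.DataFrame:
    """Tabulate dG(b, pH2) for the balance family, with ATP feasibility.

    Returns one row per (b, pH2) pair with columns ``b``, ``pH2_atm``,
    ``deltaG_kJ_per_mol`` and ``n_atp_feasible`` (the largest ATP count whose
    threshold line -n * dG_ATP the curve still clears).
    """
    b_grid = np.asarray(list(b_grid), float)
    ph2_grid = np.asarray(list(ph2_grid), float)
    if b_grid.size == 0 or ph2_grid.size == 0:
        raise ValueError("b_grid and ph2_grid must be non-empty")
    if np.any(ph2_grid <= 0):
        raise ValueError("pH2 grid must be strictly positive")
    table = table or default_thermo_table()
    cond = cond or default_conditions()
    threshold = threshold or AtpThreshold()

    rows = []
    for b in b_grid:
        balance = build_balance_family(float(b))
        for p in ph2_grid:
            dg = delta_g(balance, table, cond.replace(p_H2_atm=float(p)))
            rows.append((float(b), float(p), dg, threshold.n_feasible(dg)))
    return pd.DataFrame(rows, columns=["b", "pH2_atm", "deltaG_kJ_per_mol", "n_atp_feasible"])


def plot_sweep(sweep: pd.DataFrame, threshold: AtpThreshold | None = None, ax=None):
    """Plot dG against pH2 (log axis), one curve per butyrate yield."""
    import matplotlib.pyplot as plt

    threshold = threshold or AtpThreshold()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for b, grp in sweep.groupby("b"):
        ax.plot(grp["pH2_atm"], grp["deltaG_kJ_per_mol"],
                label=f"but {b:g} / ace {2 - 2 * b:g} / H2 {4 - 2 * b:g}")
    n_max = int(sweep["n_atp_feasible"].max()) if len(sweep) else 0
    for n in range(1, n_max + 1):
        ax.axhline(-n * threshold.dG_ATP, ls=":", color="0.5", lw=0.8)
        ax.annotate(f"{n} ATP", (sweep["pH2_atm"].min(), -n * threshold.dG_ATP),
                    fontsize=7, va="bottom")
    ax.set_xscale("log")
    ax.set_xlabel("pH2 (atm)")
    ax.set_ylabel("dG (kJ/mol glucose)")
    ax.legend(fontsize=7, title="per-glucose balance")
    return ax


# Henry's-law solubility of H2 in water: k_H ~ 7.8e-4 mol/L/atm at 298.15 K
# with van 't Hoff temperature dependence d(ln k)/d(1/T) ~ 500 K.
_HENRY_KH_298 = 7.8e-4
_HENRY_VANT_HOFF_K = 500.0


def henry_dissolved_h2(ph2_atm: float, temperature_K: float = 310.15) -> float:
    """Dissolved H2 (mmol/L) in equilibrium with a partial pressure in atm.

    Linear in pH2; about 0.73 mM per atm at 310 K.
    """
    if ph2_atm < 0:
        raise ValueError("pH2 must be >= 0")
    kh = _HENRY_KH_298 * math.exp(_HENRY_VANT_HOFF_K * (1.0 / temperature_K - 1.0 / 298.15))
    return 1000.0 * kh * ph2_atm
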