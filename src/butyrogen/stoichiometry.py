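"""Redox-balanced stoichiometry of the branched butyrogen fermentation network.

Two complementary views of the same chemistry live here:

1. **Overall balances** (`FermentationBalance`, `build_balance_family`,
   `close_balance`): net reactions per mole glucose, with coefficients
   obtained by solving the elemental/charge linear system rather than being
   hard-coded.  The one-parameter butyrate/acetate/H2/CO2 family

       glucose -> b butyrate + (2-2b) acetate + (4-2b) H2 + 2 CO2 + ...

   interpolates between homoacetate (b=0, 4 H2 per glucose) and net acetate
   consumption (b=2, no H2).

2. **Pathway fluxes** (`BranchParams`, `solve_fluxes`): the branched network
   glycolysis -> {LDH | PFOR | PFL} -> {acetate kinase | butyrate branch},
   with NADH and reduced-ferredoxin pools closed by the Rnf complex, the
   ferredoxin hydrogenase, and (optionally) a generic NADH -> H2 disposal
   route.  Infeasible redox balances are reported, never silently patched.

Cofactor bookkeeping uses *difference pseudo-species*: ``NADH`` is the
reducing equivalent carried by the NAD+/NADH couple (one H, charge -1, two
available electrons), ``Fd_red`` a reduced ferredoxin pair (two electrons),
and acyl-CoA species are the acyl group relative to free CoA-SH.  Every
elementary reaction in the table is exactly balanced in C, H, O and charge
under these conventions, so net balances inherit exact balance from the
flux solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .species import Species, SpeciesRegistry, default_registry

#: absolute tolerance below which a residual counts as zero
RESIDUAL_TOL = 1e-9

# ---------------------------------------------------------------------------
# Overall balances
# ---------------------------------------------------------------------------


@dataclass
class FermentationBalance:
    """An overall fermentation reaction normalized to 1 mol glucose consumed.

    Coefficients are negative for consumption, positive for production.
    """

    coefficients: dict[str, float]
    label: str = ""
    registry: SpeciesRegistry = field(default_factory=default_registry, repr=False)

    def coefficient(self, name: str) -> float:
        return self.coefficients.get(name, 0.0)

    def __add__(self, other: "FermentationBalance") -> "FermentationBalance":
        coeffs = dict(self.coefficients)
        for name, c in other.coefficients.items():
            coeffs[name] = coeffs.get(name, 0.0) + c
        return FermentationBalance(coeffs, label=f"{self.label}+{other.label}",
                                   registry=self.registry)

    def reaction_string(self, digits: int = 3) -> str:
        """Human-readable ``A + 2 B -> C`` form (coefficients rounded)."""
        left, right = [], []
        for name, c in self.coefficients.items():
            if abs(c) < RESIDUAL_TOL:
                continue
            mag = abs(c)
            term = name if abs(mag - 1) < RESIDUAL_TOL else f"{round(mag, digits):g} {name}"
            (left if c < 0 else right).append(term)
        return " + ".join(left) + " -> " + " + ".join(right)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"species": list(self.coefficients), "coefficient": list(self.coefficients.values())}
        )

    @classmethod
    def from_frame(cls, frame, label: str = "", registry: SpeciesRegistry | None = None):
        coeffs = dict(zip(frame["species"], frame["coefficient"].astype(float)))
        return cls(coeffs, label=label, registry=registry or default_registry())


@dataclass
class BalanceReport:
    """Per-element, charge and electron residuals of a balance."""

    element_residuals: dict[str, float]
    charge_residual: float
    electron_residual: float

    @property
    def ok(self) -> bool:
        worst = max(
            max(abs(v) for v in self.element_residuals.values()),
            abs(self.charge_residual),
            abs(self.electron_residual),
        )
        return worst < RESIDUAL_TOL


def balance_check(balance: FermentationBalance) -> BalanceReport:
    """Compute conservation residuals of an overall reaction.

    A valid fermentation balance has zero residual in every element, in
    charge, and in degree of reduction (electrons relative to CO2/H2O/H+).
    """
    reg = balance.registry
    elements = {"C": 0.0, "H": 0.0, "O": 0.0}
    charge = 0.0
    electrons = 0.0
    for name, c in balance.coefficients.items():
        sp = reg[name]
        for el in elements:
            elements[el] += c * sp.atoms(el)
        charge += c * sp.charge
        electrons += c * sp.degree_of_reduction
    return BalanceReport(elements, charge, electrons)


def _species_column(sp: Species) -> np.ndarray:
    return np.array([sp.atoms("C"), sp.atoms("H"), sp.atoms("O"), sp.charge], float)


def _solve_closure(fixed: Mapping[str, float], unknowns: list[str],
                   registry: SpeciesRegistry) -> dict[str, float]:
    """Solve C/H/O/charge conservation for the coefficients of `unknowns`."""
    A = np.column_stack([_species_column(registry[name]) for name in unknowns])
    rhs = -sum(c * _species_column(registry[name]) for name, c in fixed.items())
    sol = np.linalg.solve(A, rhs)
    coeffs = dict(fixed)
    coeffs.update(zip(unknowns, sol))
    return coeffs


def build_balance_family(b: float, registry: SpeciesRegistry | None = None) -> FermentationBalance:
    """Balanced glucose fermentation with butyrate yield ``b`` in [0, 2].

    The family fixes glucose at -1, butyrate at ``b`` and CO2 at 2 (both
    pyruvate decarboxylated, no formate or lactate); acetate, H2, H2O and H+
    are then the unique solution of the elemental/charge linear system.
    The solve reproduces acetate = 2 - 2b and H2 = 4 - 2b, so acetate flips
    from net product to net substrate at exactly b = 1, and the reaction is
    H2-free at b = 2.
    """
    if not 0.0 <= b <= 2.0:
        raise ValueError(
            f"butyrate yield b={b} outside [0, 2]: would require negative H2 or CO2"
        )
    reg = registry or default_registry()
    coeffs = _solve_closure({"glucose": -1.0, "butyrate": float(b), "CO2": 2.0},
                            ["acetate", "H2", "H2O", "H+"], reg)
    return FermentationBalance(coeffs, label=f"family(b={b:g})", registry=reg)


def close_balance(product_yields: Mapping[str, float],
                  registry: SpeciesRegistry | None = None) -> FermentationBalance:
    """Close an arbitrary organic-acid yield vector into a full balance.

    Given net yields (mol per mol glucose) for any of butyrate, acetate,
    lactate and formate, solve for the H2, CO2, H2O and H+ coefficients that
    balance C, H, O and charge.  Raises ``ValueError`` if closure would need
    negative H2 or CO2 production (an electron-balance-infeasible yield set).
    """
    reg = registry or default_registry()
    fixed: dict[str, float] = {"glucose": -1.0}
    for name in ("butyrate", "acetate", "lactate", "formate"):
        fixed[name] = float(product_yields.get(name, 0.0))
    coeffs = _solve_closure(fixed, ["H2", "CO2", "H2O", "H+"], reg)
    if coeffs["H2"] < -RESIDUAL_TOL or coeffs["CO2"] < -RESIDUAL_TOL:
        raise ValueError(
            "product yields cannot be closed: closure requires "
            f"H2={coeffs['H2']:.4g}, CO2={coeffs['CO2']:.4g} per glucose"
        )
    return FermentationBalance(coeffs, label="closed", registry=reg)


# ---------------------------------------------------------------------------
# Pathway fluxes
# ---------------------------------------------------------------------------

#: internal (pseudo-)species of the flux network; zero net production required
INTERNAL_SPECIES = {
    "pyruvate": Species("pyruvate", {"C": 3, "H": 3, "O": 3}, charge=-1),
    # acyl groups relative to free CoA-SH (thioester difference species)
    "acetyl_CoA": Species("acetyl_CoA", {"C": 2, "H": 2, "O": 1}, charge=0),
    "acetyl_P": Species("acetyl_P", {"C": 2, "H": 2, "O": 1}, charge=0),
    "butyryl_CoA": Species("butyryl_CoA", {"C": 4, "H": 6, "O": 1}, charge=0),
    # reducing equivalents: NADH carries (H+ + 2e-), Fd_red a 2e- pair
    "NADH": Species("NADH", {"H": 1}, charge=-1),
    "Fd_red": Species("Fd_red", {}, charge=-2),
}

#: elementary reactions of the Fig-style branched network, per unit flux.
#: ATP is tracked separately (energy, not mass).
REACTIONS: dict[str, dict[str, float]] = {
    # glucose + 2 NAD+ -> 2 pyruvate + 2 NADH (+2 ATP by SLP)
    "glycolysis": {"glucose": -1, "pyruvate": 2, "NADH": 2, "H+": 4},
    "ldh": {"pyruvate": -1, "NADH": -1, "H+": -1, "lactate": 1},
    "pfor": {"pyruvate": -1, "acetyl_CoA": 1, "CO2": 1, "Fd_red": 1, "H+": 1},
    "pfl": {"pyruvate": -1, "acetyl_CoA": 1, "formate": 1},
    "pta": {"acetyl_CoA": -1, "acetyl_P": 1},
    "ack": {"acetyl_P": -1, "H2O": -1, "acetate": 1, "H+": 1},  # +1 ATP
    # thiolase + Bhbd + crotonase + Bcd-Etf, lumped per butyryl-CoA:
    # 2 acetyl-CoA + 3 NADH -> butyryl-CoA + Fd_red (electron bifurcation)
    "butyrate_branch": {"acetyl_CoA": -2, "NADH": -3, "H+": -1,
                        "butyryl_CoA": 1, "Fd_red": 1, "H2O": 1},
    "but_transferase": {"butyryl_CoA": -1, "acetate": -1, "butyrate": 1, "acetyl_CoA": 1},
    "hydrogenase": {"Fd_red": -1, "H+": -2, "H2": 1},
    "rnf": {"Fd_red": -1, "H+": -1, "NADH": 1},  # + eta ATP chemiosmotically
    "nadh_h2": {"NADH": -1, "H+": -1, "H2": 1},
}

#: ATP formed per unit flux (Rnf handled via BranchParams.rnf_atp_per_fd)
ATP_PER_FLUX = {"glycolysis": 2.0, "ack": 1.0}


class RedoxInfeasibleError(ValueError):
    """The requested branch fractions cannot close a cofactor balance."""

    def __init__(self, balance: str, message: str):
        super().__init__(message)
        self.balance = balance


@dataclass(frozen=True)
class BranchParams:
    """Branch fractions of the fermentation network.

    Parameters
    ----------
    lactate_fraction : float in [0, 1]
        Fraction of pyruvate reduced to lactate by LDH.
    pfl_fraction : float in [0, 1]
        Of the pyruvate forming acetyl-CoA, the fraction cleaved by PFL
        (formate route); the remainder goes through PFOR (CO2 + reduced Fd).
    butyrate_fraction : float in [0, 1]
        Fraction of acetyl-CoA entering the butyrate branch.
    rnf_atp_per_fd : float >= 0
        ATP conserved per reduced-ferredoxin pair oxidized by Rnf.  Default
        0.5 (two translocated ions per Fd pair, four ions per ATP).
    allow_nadh_to_h2 : bool
        Enable a generic NADH -> H2 disposal route.  Off by default: the
        strict network names only a ferredoxin hydrogenase, and solutions
        needing another NADH sink are reported as infeasible instead.
    """

    lactate_fraction: float = 0.0
    pfl_fraction: float = 0.0
    butyrate_fraction: float = 1.0
    rnf_atp_per_fd: float = 0.5
    allow_nadh_to_h2: bool = False

    def __post_init__(self) -> None:
        for attr in ("lactate_fraction", "pfl_fraction", "butyrate_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr}={v} outside [0, 1]")
        if self.rnf_atp_per_fd < 0:
            raise ValueError("rnf_atp_per_fd must be >= 0")


@dataclass
class FluxSolution:
    """Reaction fluxes per mole glucose, with the induced net balance."""

    fluxes: dict[str, float]
    atp_yield: float
    net_balance: FermentationBalance
    params: BranchParams

    @property
    def butyrate_yield(self) -> float:
        return self.net_balance.coefficient("butyrate")

    def internal_residuals(self) -> dict[str, float]:
        """Net production of each internal metabolite (all should be ~0)."""
        res = {name: 0.0 for name in INTERNAL_SPECIES}
        for rxn, v in self.fluxes.items():
            for sp, c in REACTIONS[rxn].items():
                if sp in res:
                    res[sp] += v * c
        return res


def solve_fluxes(params: BranchParams, registry: SpeciesRegistry | None = None) -> FluxSolution:
    """Solve the branched network for the given branch fractions.

    Per mole glucose: glycolysis yields 2 pyruvate, 2 NADH and 2 ATP.  LDH
    takes ``2*lambda`` pyruvate; the rest forms acetyl-CoA via PFL (fraction
    phi, formate out) or PFOR (CO2 out, ferredoxin reduced).  A fraction
    beta of acetyl-CoA enters the butyrate branch (two acetyl-CoA, three
    NADH in, one reduced-Fd pair out per butyryl-CoA); the CoA transferase
    trades one free acetate per butyrate released, and the recycled
    acetyl-CoA flows back to acetate kinase.  Rnf flux closes the NADH
    balance and hydrogenase flux closes the ferredoxin balance; if either
    would need to run backwards, `RedoxInfeasibleError` names the violated
    balance (unless the NADH -> H2 route is enabled for an NADH excess).
    """
    reg = registry or default_registry()
    lam, phi, beta = params.lactate_fraction, params.pfl_fraction, params.butyrate_fraction

    acoa = 2.0 * (1.0 - lam)          # acetyl-CoA formed from pyruvate
    but = acoa * beta / 2.0           # butyryl-CoA (= butyrate) formed
    fluxes = {
        "glycolysis": 1.0,
        "ldh": 2.0 * lam,
        "pfor": (1.0 - phi) * acoa,
        "pfl": phi * acoa,
        "butyrate_branch": but,
        "but_transferase": but,
        # Ack serves the acetate branch plus the acetyl-CoA recycled by the
        # CoA transferase (the "Ack credit" of butyrate formation)
        "ack": acoa * (1.0 - beta) + but,
    }
    fluxes["pta"] = fluxes["ack"]

    nadh_gap = 2.0 + 0.0 - (2.0 * lam + 3.0 * but)  # production - consumption sans Rnf
    if nadh_gap <= RESIDUAL_TOL:
        rnf = -nadh_gap
        nadh_h2 = 0.0
    elif params.allow_nadh_to_h2:
        rnf = 0.0
        nadh_h2 = nadh_gap
    else:
        raise RedoxInfeasibleError(
            "NADH",
            f"NADH balance infeasible: {nadh_gap:.4g} mol excess NADH per glucose "
            "has no sink (enable allow_nadh_to_h2 or raise lactate/butyrate flux)",
        )
    fd_produced = fluxes["pfor"] + but
    hyd = fd_produced - rnf
    if hyd < -RESIDUAL_TOL:
        raise RedoxInfeasibleError(
            "ferredoxin",
            f"ferredoxin balance infeasible: Rnf demand {rnf:.4g} exceeds "
            f"reduced-Fd supply {fd_produced:.4g} per glucose",
        )
    fluxes["rnf"] = max(rnf, 0.0)
    fluxes["hydrogenase"] = max(hyd, 0.0)
    fluxes["nadh_h2"] = nadh_h2

    atp = sum(ATP_PER_FLUX.get(r, 0.0) * v for r, v in fluxes.items())
    atp += params.rnf_atp_per_fd * rnf

    net: dict[str, float] = {}
    for rxn, v in fluxes.items():
        for sp, c in REACTIONS[rxn].items():
            if sp in INTERNAL_SPECIES:
                continue
            net[sp] = net.get(sp, 0.0) + v * c
    net = {sp: (0.0 if abs(c) < RESIDUAL_TOL else c) for sp, c in net.items()}
    balance = FermentationBalance(net, label="flux-derived", registry=reg)
    return FluxSolution(fluxes=fluxes, atp_yield=atp, net_balance=balance, params=params)


def net_acetate_sign(flux: "FluxSolution | FermentationBalance",
                     tol: float = RESIDUAL_TOL) -> str:
    """Classify acetate as net ``'product'``, ``'zero'`` or ``'substrate'``.

    Accepts a flux solution or a bare overall balance (the flux network can
    recycle but never net-consume free acetate, so butyrate yields above
    1 mol/mol only arise in the balance family).  The crossover sits exactly
    at a butyrate yield of 1 mol per mol glucose.
    """
    balance = flux.net_balance if isinstance(flux, FluxSolution) else flux
    c = balance.coefficient("acetate")
    if c > tol:
        return "product"
    if c < -tol:
        return "substrate"
    return "zero"


def reaction_balance_report(name: str) -> BalanceReport:
    """Conservation residuals of a single elementary reaction (all zero)."""
    reg = default_registry()
    elements = {"C": 0.0, "H": 0.0, "O": 0.0}
    charge = 0.0
    electrons = 0.0
    for sp_name, c in REACTIONS[name].items():
        sp = INTERNAL_SPECIES.get(sp_name) or reg[sp_name]
        for el in elements:
            elements[el] += c * sp.atoms(el)
        charge += c * sp.charge
        electrons += c * sp.degree_of_reduction
    return BalanceReport(elements, charge, electrons)
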