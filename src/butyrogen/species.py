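"""Chemical species and elemental bookkeeping.

Species are the fermentation metabolites of the glucose -> butyrate/acetate/
lactate/formate network, represented in the ionization state predominant at
pH 7 (carboxylic acids as their anions).  Elemental composition tracks C, H
and O only, plus formal charge; that is sufficient for balancing every
reaction in the network.

The *degree of reduction* of a species counts its available electrons
relative to the CO2 / H2O / H+ reference state:

    gamma = 4*C + H - 2*O - charge

so gamma(CO2) = gamma(H2O) = gamma(H+) = 0 and gamma(H2) = 2.  A reaction
that balances C, H, O and charge automatically balances gamma; the redundant
check is still exposed because it localizes errors to electron bookkeeping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

ELEMENTS = ("C", "H", "O")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownSpeciesError(KeyError):
    """Raised when a balance references a species missing from the registry."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an empirical formula string like ``"C4H7O2"`` into atom counts.

    Elements outside C/H/O raise ``ValueError`` (the network does not track
    N, P or S; CoA, NAD and phosphate are handled as difference pseudo-species).
    """
    counts: dict[str, int] = {el: 0 for el in ELEMENTS}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        el, num = match.group(1), match.group(2)
        if el not in ELEMENTS:
            raise ValueError(f"unsupported element {el!r} in formula {formula!r}")
        counts[el] += int(num) if num else 1
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Species:
    """A chemical species with elemental composition and formal charge."""

    name: str
    formula: Mapping[str, int]
    charge: int = 0
    phase: str = "aq"  # aq | g | l

    def __post_init__(self) -> None:
        for el, n in self.formula.items():
            if el not in ELEMENTS:
                raise ValueError(f"{self.name}: unsupported element {el}")
            if not (isinstance(n, int) and n >= 0):
                raise ValueError(f"{self.name}: atom count for {el} must be a non-negative integer")

    @property
    def degree_of_reduction(self) -> int:
        f = self.formula
        return 4 * f.get("C", 0) + f.get("H", 0) - 2 * f.get("O", 0) - self.charge

    def atoms(self, element: str) -> int:
        return self.formula.get(element, 0)


@dataclass
class SpeciesRegistry:
    """Lookup table of species by name."""

    species: dict[str, Species] = field(default_factory=dict)

    def add(self, sp: Species) -> None:
        self.species[sp.name] = sp

    def __getitem__(self, name: str) -> Species:
        try:
            return self.species[name]
        except KeyError:
            raise UnknownSpeciesError(f"unknown species {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def __iter__(self) -> Iterable[str]:
        return iter(self.species)

    @classmethod
    def from_entries(cls, entries: Iterable[Mapping]) -> "SpeciesRegistry":
        reg = cls()
        for e in entries:
            formula = e["formula"]
            if isinstance(formula, str):
                formula = parse_formula(formula)
            reg.add(Species(name=e["name"], formula=formula,
                            charge=int(e.get("charge", 0)), phase=e.get("phase", "aq")))
        return reg

    @classmethod
    def from_yaml(cls, path) -> "SpeciesRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_entries(doc["species"])


def default_registry() -> SpeciesRegistry:
    """Registry of the fermentation species shipped with the package."""
    ref = resources.files("butyrogen.data").joinpath("species.yaml")
    doc = yaml.safe_load(ref.read_text())
    return SpeciesRegistry.from_entries(doc["species"])
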