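"""Chemical species over {C, H, O, N} with charge, and theoretical oxygen demand.

The species set is the small inorganic/organic vocabulary of anammox-based
nitrogen-removal stoichiometry: fixed-nitrogen ions, dinitrogen, oxygen,
water, protons, acetate and inorganic carbon.  Theoretical oxygen demand
(ThOD) converts organic reactants to COD equivalents via electron
bookkeeping: 8 g O2 per electron equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Species",
    "SpeciesRegistry",
    "builtin_species",
    "theoretical_oxygen_demand",
    "MW_N",
    "MW_O2",
]

#: molar mass of nitrogen, g/mol — the "per mg N" basis of all demand figures
MW_N = 14.0
#: molar mass of dioxygen, g/mol
MW_O2 = 32.0

_ELEMENTS = ("C", "H", "O", "N")


@dataclass(frozen=True)
class Species:
    """An ionic or molecular species with elemental composition and charge.

    Parameters
    ----------
    symbol : str
        Short identifier, unique within a registry (e.g. ``"NO2-"``).
    composition : dict
        Element → atom count over C, H, O, N. Counts must be non-negative.
    charge : int
        Signed charge in elementary units.
    """

    symbol: str
    composition: dict = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for el, n in self.composition.items():
            if el not in _ELEMENTS:
                raise ValueError(f"unsupported element {el!r} in {self.symbol}")
            if n < 0:
                raise ValueError(f"negative atom count for {el} in {self.symbol}")

    def atoms(self, element: str) -> float:
        return float(self.composition.get(element, 0))

    @property
    def n_atoms(self) -> float:
        """Nitrogen atoms per formula unit (mol N / mol species)."""
        return self.atoms("N")


class SpeciesRegistry(dict):
    """Mapping symbol → :class:`Species` with uniqueness enforcement."""

    def add(self, species: Species) -> Species:
        if species.symbol in self and self[species.symbol] != species:
            raise ValueError(f"species {species.symbol!r} already registered")
        self[species.symbol] = species
        return species


def builtin_species() -> SpeciesRegistry:
    """Registry of every species appearing in the built-in reactions."""
    reg = SpeciesRegistry()
    for sym, comp, charge in [
        ("NH3", {"N": 1, "H": 3}, 0),
        ("O2", {"O": 2}, 0),
        ("NO2-", {"N": 1, "O": 2}, -1),
        ("NO3-", {"N": 1, "O": 3}, -1),
        ("N2", {"N": 2}, 0),
        ("H2O", {"H": 2, "O": 1}, 0),
        ("H+", {"H": 1}, 1),
        ("CH3COO-", {"C": 2, "H": 3, "O": 2}, -1),
        ("HCO3-", {"C": 1, "H": 1, "O": 3}, -1),
        ("CO2", {"C": 1, "O": 2}, 0),
    ]:
        reg.add(Species(sym, comp, charge))
    return reg


def theoretical_oxygen_demand(species: Species) -> float:
    """ThOD of a carbonaceous species, g O2 per mol.

    Uses the electron-equivalent formula ``8 × (4·C + H − 2·O − charge)``
    (8 g O2 per electron equivalent), floored at zero for fully oxidised
    species. Only C/H/O(/charge) species are accepted: the carbonaceous vs
    nitrogenous oxygen-demand split is not modelled, so nitrogen-containing
    organics are rejected.

    Examples
    --------
    Acetate (C2H3O2−) gives 8×(8+3−4+1) = 64 g O2/mol; glucose 192; CO2 0.
    """
    if species.atoms("N") > 0:
        raise ValueError(
            f"ThOD undefined for nitrogen-containing species {species.symbol!r}: "
            "carbonaceous/nitrogenous demand split is not modelled"
        )
    eeq = 4.0 * species.atoms("C") + species.atoms("H") - 2.0 * species.atoms("O") - species.charge
    return max(0.0, 8.0 * eeq)
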