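"""Reactions of anammox-based nitrogen removal and their closure combinations.

Three routes achieve complete autotrophic-leaning nitrogen removal from an
ammonium stream:

* **Case I — PN/A + denitrification**: partial nitritation converts roughly
  half the ammonium to nitrite, anammox removes the ammonium/nitrite pair,
  and heterotrophic denitrification polishes the nitrate that anammox
  stoichiometrically produces.
* **Case II — complete nitrification + PD/A**: all ammonium is oxidised to
  nitrate, partial denitrification (denitratation) reduces it back to
  nitrite, and anammox removes the nitrite with the remaining ammonium.
* **Case III — PN/A + PD/A**: partial nitritation supplies most of the
  nitrite; partial denitrification recycles only the anammox-produced
  nitrate.

Each case is a non-negative linear combination of half-reactions whose
weights are fixed by *closure*: the combined reaction, normalised to 1 mol
NH3, must leave no net nitrite or nitrate.  From the combined reaction the
theoretical oxygen demand (mg O2 per mg NH3-N) and organic demand
(mg COD per mg NH3-N, acetate as carbon source) follow directly.

The anammox half-reaction (NH3 + 1.32 NO2− + H+ → 1.02 N2 + 0.26 NO3− +
2 H2O) is an empirical biomass-free stoichiometry and does not balance
exactly in N, O or charge; it is flagged ``empirical`` and exempted from the
strict element-balance check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .species import (
    MW_N,
    MW_O2,
    Species,
    SpeciesRegistry,
    builtin_species,
    theoretical_oxygen_demand,
)

__all__ = [
    "Reaction",
    "DemandSummary",
    "ProcessCase",
    "builtin_reactions",
    "auxiliary_reactions",
    "element_balance",
    "combine_reactions",
    "normalize_to_basis",
    "solve_case_weights",
    "demands",
    "build_case",
    "builtin_cases",
    "pna_nitrate_yield",
    "anammox_reaction",
    "BALANCE_TOL",
    "CASE_MEMBERS",
]

#: tolerance below which an element/charge residual counts as balanced
BALANCE_TOL = 1e-9

#: coefficient magnitudes below this are dropped when combining reactions
_DROP_TOL = 1e-9


@dataclass(frozen=True)
class Reaction:
    """A chemical conversion as signed molar coefficients.

    Reactants carry negative coefficients, products positive.  ``empirical``
    marks biomass-free microbial stoichiometries with known element-balance
    residuals (the anammox equation), which are exempt from the strict
    balance invariant.
    """

    name: str
    coeffs: dict = field(default_factory=dict)
    empirical: bool = False

    def __post_init__(self) -> None:
        for sym, c in self.coeffs.items():
            if not math.isfinite(c):
                raise ValueError(f"non-finite coefficient for {sym} in {self.name!r}")
        if self.coeffs:
            has_neg = any(c < 0 for c in self.coeffs.values())
            has_pos = any(c > 0 for c in self.coeffs.values())
            if not (has_neg and has_pos):
                raise ValueError(
                    f"reaction {self.name!r} needs at least one reactant and one product"
                )

    def coeff(self, symbol: str) -> float:
        return self.coeffs.get(symbol, 0.0)

    def scaled(self, factor: float, name: str | None = None) -> "Reaction":
        return Reaction(
            name or self.name,
            {s: c * factor for s, c in self.coeffs.items()},
            empirical=self.empirical,
        )

    def __str__(self) -> str:  # "NH3 + 1.32 NO2- -> 1.02 N2 + ..."
        def side(sign):
            terms = []
            for s, c in self.coeffs.items():
                if sign * c > 0:
                    mag = abs(c)
                    terms.append(s if abs(mag - 1) < 5e-3 else f"{mag:.2f} {s}")
            return " + ".join(terms) or "∅"

        return f"{side(-1)} -> {side(+1)}"


def anammox_reaction(no2_per_nh3: float = 1.32, no3_per_nh3: float = 0.26) -> Reaction:
    """The anammox stoichiometry with configurable NO2 demand and NO3 yield.

    Defaults are the classic biomass-free values (1.32 mol NO2−, 0.26 mol
    NO3− per mol NH3). The N2 coefficient keeps the printed 1.02 ratio scaled
    to the nitrogen actually converted, so the documented small residuals are
    preserved at the default and the equation degrades gracefully when the
    vector is overridden.
    """
    if no2_per_nh3 <= 0 or no3_per_nh3 < 0:
        raise ValueError("anammox stoichiometry requires NO2 > 0 and NO3 >= 0 per NH3")
    # printed equation: N2 = 1.02 when NO2 = 1.32, NO3 = 0.26; keep the same
    # (slightly short of closure) N share for non-default vectors
    n2 = 1.02 / (1 + 1.32 - 0.26) * (1 + no2_per_nh3 - no3_per_nh3)
    coeffs = {
        "NH3": -1.0,
        "NO2-": -no2_per_nh3,
        "H+": -1.0,
        "N2": n2,
        "H2O": 2.0,
    }
    if no3_per_nh3 > 0:
        coeffs["NO3-"] = no3_per_nh3
    return Reaction("anammox", coeffs, empirical=True)


def builtin_reactions(
    anammox_no2: float = 1.32, anammox_no3: float = 0.26
) -> dict[str, Reaction]:
    """The five named half-reactions of the process cases.

    Returns ``partial_nitritation``, ``complete_nitrification``, ``anammox``
    (empirical), ``partial_denitrification`` (denitratation, NO3→NO2 on
    acetate) and ``complete_denitrification`` (NO3→N2 on acetate).
    """
    return {
        "partial_nitritation": Reaction(
            "partial_nitritation",
            {"NH3": -1.0, "O2": -1.5, "NO2-": 1.0, "H2O": 1.0, "H+": 1.0},
        ),
        "complete_nitrification": Reaction(
            "complete_nitrification",
            {"NH3": -1.0, "O2": -2.0, "NO3-": 1.0, "H2O": 1.0, "H+": 1.0},
        ),
        "anammox": anammox_reaction(anammox_no2, anammox_no3),
        "partial_denitrification": Reaction(
            "partial_denitrification",
            {
                "NO3-": -1.0,
                "CH3COO-": -0.25,
                "NO2-": 1.0,
                "HCO3-": 0.25,
                "CO2": 0.25,
                "H2O": 0.25,
            },
        ),
        "complete_denitrification": Reaction(
            "complete_denitrification",
            {
                "NO3-": -1.0,
                "CH3COO-": -0.625,
                "H+": -0.625,
                "N2": 0.5,
                "HCO3-": 1.0,
                "CO2": 0.25,
                "H2O": 0.75,
            },
        ),
    }


def auxiliary_reactions() -> dict[str, Reaction]:
    """Balanced side-processes used by the cycle simulator.

    ``nitratation`` is the NOB step (NO2−→NO3−); ``denitritation`` is the
    second heterotrophic step (NO2−→N2, obtained as complete minus partial
    denitrification); ``aerobic_cod_oxidation`` burns acetate with oxygen.
    """
    return {
        "nitratation": Reaction(
            "nitratation", {"NO2-": -1.0, "O2": -0.5, "NO3-": 1.0}
        ),
        "denitritation": Reaction(
            "denitritation",
            {
                "NO2-": -1.0,
                "CH3COO-": -0.375,
                "H+": -0.625,
                "N2": 0.5,
                "HCO3-": 0.75,
                "H2O": 0.5,
            },
        ),
        "aerobic_cod_oxidation": Reaction(
            "aerobic_cod_oxidation",
            {"CH3COO-": -1.0, "O2": -2.0, "HCO3-": 1.0, "CO2": 1.0, "H2O": 1.0},
        ),
    }


def element_balance(
    reaction: Reaction, registry: SpeciesRegistry | None = None
) -> dict[str, float]:
    """Element and charge residuals of a reaction, mol (products positive).

    Zero residuals mean the reaction is balanced.  Raises ``KeyError`` naming
    any species absent from the registry.
    """
    registry = registry if registry is not None else builtin_species()
    residuals = {el: 0.0 for el in ("C", "H", "O", "N")}
    residuals["charge"] = 0.0
    for sym, c in reaction.coeffs.items():
        if sym not in registry:
            raise KeyError(f"unknown species {sym!r} in reaction {reaction.name!r}")
        sp = registry[sym]
        for el in ("C", "H", "O", "N"):
            residuals[el] += c * sp.atoms(el)
        residuals["charge"] += c * sp.charge
    return residuals


def combine_reactions(
    members: list[tuple[Reaction, float]], name: str = "combined"
) -> Reaction:
    """Coefficient-wise weighted sum of reactions.

    Weights must be finite and non-negative. Species whose summed coefficient
    falls below 1e-9 in magnitude are dropped.
    """
    if not members:
        raise ValueError("cannot combine an empty member list")
    coeffs: dict[str, float] = {}
    empirical = False
    for rxn, w in members:
        if not math.isfinite(w) or w < 0:
            raise ValueError(f"invalid weight {w!r} for {rxn.name!r}")
        if w > 0:
            empirical = empirical or rxn.empirical
        for sym, c in rxn.coeffs.items():
            coeffs[sym] = coeffs.get(sym, 0.0) + w * c
    coeffs = {s: c for s, c in coeffs.items() if abs(c) >= _DROP_TOL}
    return Reaction(name, coeffs, empirical=empirical)


def normalize_to_basis(reaction: Reaction, basis: str = "NH3") -> Reaction:
    """Scale a reaction so the basis species' coefficient becomes ±1.

    All coefficients are divided by the magnitude of the basis coefficient;
    the basis keeps its original sign.
    """
    c = reaction.coeff(basis)
    if c == 0:
        raise ValueError(f"basis species {basis!r} absent from {reaction.name!r}")
    return reaction.scaled(1.0 / abs(c))


def solve_case_weights(
    reactions: tuple[Reaction, Reaction, Reaction],
    nh3_total: float = 1.0,
) -> np.ndarray:
    """Closure weights for a three-reaction nitrogen-removal case.

    Solves the 3×3 linear system { net NO2− = 0, net NO3− = 0, total NH3
    consumed = ``nh3_total`` } in the member weights.  Raises on a singular
    system (reporting the rank) or on a negative solution (infeasible
    combination).
    """
    if len(reactions) != 3:
        raise ValueError("exactly three reactions are required")
    rows = []
    for constraint in ("NO2-", "NO3-"):
        rows.append([r.coeff(constraint) for r in reactions])
    rows.append([-r.coeff("NH3") for r in reactions])  # NH3 consumed (positive)
    A = np.array(rows, dtype=float)
    b = np.array([0.0, 0.0, nh3_total])
    rank = np.linalg.matrix_rank(A)
    if rank < 3:
        raise ValueError(f"closure system is singular (rank {rank} < 3)")
    w = np.linalg.solve(A, b)
    if np.any(w < -BALANCE_TOL):
        raise ValueError(f"infeasible case: negative solved weight {w}")
    return np.clip(w, 0.0, None)


@dataclass(frozen=True)
class DemandSummary:
    """Oxygen and organic (COD) demands of a combined reaction per unit N.

    ``o2_molar``/``cod_molar`` are mol O2 / mol acetate per mol NH3-N at full
    precision; ``o2_demand``/``cod_demand`` the corresponding mg O2 / mg COD
    per mg NH3-N.  ``o2_demand_table``/``cod_demand_table`` recompute the
    demands from the molar coefficients rounded to two decimals, which is the
    convention of printed summary tables whose demand columns derive from the
    rounded total-reaction coefficients.
    """

    o2_molar: float
    o2_demand: float
    cod_molar: float
    cod_demand: float

    @property
    def o2_demand_table(self) -> float:
        return round(round(self.o2_molar, 2) * MW_O2 / MW_N, 2)

    @property
    def cod_demand_table(self) -> float:
        return round(round(self.cod_molar, 2) * 64.0 / MW_N, 2)


def demands(
    combined: Reaction, registry: SpeciesRegistry | None = None
) -> DemandSummary:
    """Oxygen and organic demands of an NH3-normalised combined reaction.

    ``o2_demand = |O2 coeff| × 32/14``; ``cod_demand`` sums ThOD over organic
    (carbon-bearing) reactants per 14 g N. Missing species contribute zero.
    """
    registry = registry if registry is not None else builtin_species()
    o2_molar = abs(min(combined.coeff("O2"), 0.0))
    cod_molar = 0.0
    cod_g_per_molN = 0.0
    for sym, c in combined.coeffs.items():
        if c >= 0:
            continue
        sp = registry.get(sym)
        if sp is None or sp.atoms("C") == 0 or sym == "O2":
            continue
        thod = theoretical_oxygen_demand(sp)
        if thod > 0:
            cod_molar += abs(c)
            cod_g_per_molN += abs(c) * thod
    return DemandSummary(
        o2_molar=o2_molar,
        o2_demand=o2_molar * MW_O2 / MW_N,
        cod_molar=cod_molar,
        cod_demand=cod_g_per_molN / MW_N,
    )


#: member half-reactions of the built-in cases, in solver order
CASE_MEMBERS: dict[str, tuple[str, str, str]] = {
    "I": ("partial_nitritation", "anammox", "complete_denitrification"),
    "II": ("complete_nitrification", "partial_denitrification", "anammox"),
    "III": ("partial_nitritation", "anammox", "partial_denitrification"),
}

_CASE_LABELS = {
    "I": "PN/A + denitrification",
    "II": "complete nitrification + PD/A",
    "III": "PN/A + PD/A",
}


@dataclass(frozen=True)
class ProcessCase:
    """A closed nitrogen-removal route: members, weights, combined reaction.

    ``combined`` is normalised to 1 mol NH3 consumed and satisfies nitrite
    and nitrate closure (net coefficients zero within tolerance).
    """

    case_id: str
    members: tuple[tuple[Reaction, float], ...]
    combined: Reaction
    demands: DemandSummary

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.members])


def build_case(
    case_id: str,
    reactions: tuple[Reaction, Reaction, Reaction] | None = None,
    registry: SpeciesRegistry | None = None,
    anammox_no2: float = 1.32,
    anammox_no3: float = 0.26,
) -> ProcessCase:
    """Build a closed process case by solving its closure weights.

    For the built-in ids ("I", "II", "III") the member half-reactions are
    looked up automatically (optionally with an overridden anammox vector);
    a user-defined case passes its own ordered reaction triple.
    """
    if reactions is None:
        if case_id not in CASE_MEMBERS:
            raise KeyError(f"unknown case {case_id!r}; built-ins are I, II, III")
        reg = builtin_reactions(anammox_no2, anammox_no3)
        reactions = tuple(reg[n] for n in CASE_MEMBERS[case_id])
    w = solve_case_weights(reactions)
    members = tuple(zip(reactions, w))
    combined = combine_reactions(list(members), name=f"case_{case_id}_total")
    combined = normalize_to_basis(combined, "NH3")
    label = _CASE_LABELS.get(case_id, case_id)
    return ProcessCase(
        case_id=label if case_id in _CASE_LABELS else case_id,
        members=members,
        combined=combined,
        demands=demands(combined, registry),
    )


def builtin_cases(
    anammox_no2: float = 1.32, anammox_no3: float = 0.26
) -> dict[str, ProcessCase]:
    """All three built-in process cases, keyed "I"/"II"/"III"."""
    return {
        cid: build_case(cid, anammox_no2=anammox_no2, anammox_no3=anammox_no3)
        for cid in CASE_MEMBERS
    }


def pna_nitrate_yield(anammox_no2: float = 1.32, anammox_no3: float = 0.26) -> float:
    """Fraction of ammonium converted to nitrate by PN/A alone.

    Combines partial nitritation and anammox with nitrite closure only (no
    denitrification member), normalises to 1 mol NH3, and returns the net
    nitrate coefficient — the stoichiometric nitrate leak of the PN/A route
    (0.26/2.32 ≈ 11 % at the default vector).
    """
    reg = builtin_reactions(anammox_no2, anammox_no3)
    pn, amx = reg["partial_nitritation"], reg["anammox"]
    if amx.coeff("NO2-") == 0:
        raise ValueError("anammox reaction consumes no nitrite; closure impossible")
    # PN weight that zeroes net nitrite per unit anammox weight
    w_pn = -amx.coeff("NO2-") / pn.coeff("NO2-")
    combined = combine_reactions([(pn, w_pn), (amx, 1.0)], name="pna")
    combined = normalize_to_basis(combined, "NH3")
    return combined.coeff("NO3-")
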