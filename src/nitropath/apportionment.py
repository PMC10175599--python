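"""Cycle mass-balance apportionment of nitrogen removal pathways.

A sequencing-batch anammox reactor removes nitrogen through several
concurrent microbial pathways.  Given only the bulk NH4-N, NO2-N and NO3-N
concentrations at the start and end of a react phase, a two-point mass
balance apportions the net conversions among the major pathways, under a
phase-specific assumption about which minor pathway is negligible:

* **phase I** (no readily biodegradable COD in the feed): denitrification is
  ignored.  All TN loss is attributed to anammox; ammonium consumed beyond
  the anammox stoichiometry is credited to aerobic ammonium oxidisers (AOB),
  and nitrate produced beyond the anammox yield to nitrite oxidisers (NOB).
* **phase II** (rbCOD present, stricter anoxia): nitrification is ignored.
  Anammox TN removal is inferred from ammonium loss; nitrate disappearance
  beyond the anammox yield is credited to denitratation (NO3→NO2), and the
  remaining TN loss to denitritation (NO2→N2).

The anammox coupling constants default to the conventional literature
values — 2.04 mg TN removed and 0.26/2.04 mg NO3-N produced per mg NH4-N
removed.  The strictly closed reaction vector (1 + 1.32 − 0.26 = 2.06)
is available via ``consistency_mode="closed"`` for use with simulated data
generated from the same stoichiometry.

Negative apportioned components indicate a violated phase assumption; they
are reported as computed with a warning flag (optionally clamped), since
silently truncating them would hide exactly the diagnostic they carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StoichParams",
    "CycleEndpoints",
    "PathwayApportionment",
    "BatchProfile",
    "NTRResult",
    "mix_feed",
    "apportion_phase1",
    "apportion_phase2",
    "pathway_contributions",
    "delta_nitrate_ammonium_ratio",
    "nitrate_to_nitrite_transformation",
    "nitrogen_removal_efficiency",
    "phase_summary",
    "NTR_EPSILON",
]

#: minimum nitrate drawdown (mg N/L) for an NTR ratio to be evaluated
NTR_EPSILON = 0.1

_PAPER_TN_PER_NH4 = 2.04
_ANAMMOX_NO3_YIELD = 0.26  # mol NO3 per mol NH4 via anammox
_CLOSED_TN_PER_NH4 = 1.0 + 1.32 - 0.26  # = 2.06 from the reaction vector


@dataclass(frozen=True)
class StoichParams:
    """Anammox coupling constants used by the apportionment equations.

    ``r_tn_per_nh4`` — TN removed per NH4-N removed by anammox (> 1);
    ``r_no3_per_tn`` — NO3-N produced per TN removed by anammox (in [0, 1)).
    ``consistency_mode="closed"`` recomputes both from the reaction vector
    (TN per NH4 = 1 + NO2 − NO3 = 2.06 at defaults) so that apportionment is
    exactly consistent with simulation using the same stoichiometry.
    """

    r_tn_per_nh4: float = _PAPER_TN_PER_NH4
    r_no3_per_tn: float = _ANAMMOX_NO3_YIELD / _PAPER_TN_PER_NH4
    consistency_mode: str = "paper"

    def __post_init__(self) -> None:
        if self.consistency_mode not in ("paper", "closed"):
            raise ValueError("consistency_mode must be 'paper' or 'closed'")
        if self.consistency_mode == "closed":
            object.__setattr__(self, "r_tn_per_nh4", _CLOSED_TN_PER_NH4)
            object.__setattr__(
                self, "r_no3_per_tn", _ANAMMOX_NO3_YIELD / _CLOSED_TN_PER_NH4
            )
        if not self.r_tn_per_nh4 > 1:
            raise ValueError("r_tn_per_nh4 must exceed 1")
        if not 0 <= self.r_no3_per_tn < 1:
            raise ValueError("r_no3_per_tn must lie in [0, 1)")

    @classmethod
    def closed(cls, no2_per_nh4: float = 1.32, no3_per_nh4: float = 0.26) -> "StoichParams":
        r = 1.0 + no2_per_nh4 - no3_per_nh4
        return cls(r_tn_per_nh4=r, r_no3_per_tn=no3_per_nh4 / r, consistency_mode="closed")


@dataclass(frozen=True)
class CycleEndpoints:
    """Bulk N-species concentrations (mg N/L) at react-phase start and end."""

    nh4_initial: float
    no2_initial: float
    no3_initial: float
    nh4_final: float
    no2_final: float
    no3_final: float

    def __post_init__(self) -> None:
        for name in (
            "nh4_initial", "no2_initial", "no3_initial",
            "nh4_final", "no2_final", "no3_final",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    @property
    def tn_initial(self) -> float:
        return self.nh4_initial + self.no2_initial + self.no3_initial

    @property
    def tn_final(self) -> float:
        return self.nh4_final + self.no2_final + self.no3_final

    @property
    def delta_n(self) -> float:
        """Net total inorganic nitrogen removed over the cycle, mg N/L."""
        return self.tn_initial - self.tn_final


@dataclass(frozen=True)
class PathwayApportionment:
    """Per-pathway nitrogen amounts (mg N/L) resolved from cycle endpoints.

    Phase-I results populate ``nh4_aob``/``no3_nob``; phase-II results
    populate ``no3_denitratation``/``tn_denitritation``.  ``warnings`` lists
    components that came out negative (assumption violations).
    """

    mode: str
    delta_n: float
    tn_anammox: float
    nh4_aob: float | None = None
    no3_nob: float | None = None
    no3_denitratation: float | None = None
    tn_denitritation: float | None = None
    params: StoichParams = field(default_factory=StoichParams)
    warnings: tuple[str, ...] = ()


def _flag_negatives(components: dict[str, float], clamp: bool) -> tuple[dict, tuple]:
    warnings = tuple(
        f"{name} is negative ({value:.4g} mg N/L): phase assumption violated"
        for name, value in components.items()
        if value < -1e-12
    )
    if clamp:
        components = {k: max(v, 0.0) for k, v in components.items()}
    return components, warnings


def mix_feed(residual: dict, influent: dict, exchange_ratio: float) -> dict:
    """Concentrations right after volume exchange at the start of a cycle.

    Each analyte mixes linearly: ``ratio × influent + (1 − ratio) ×
    residual``.  The analyte sets of the two records must match.
    """
    if not 0 < exchange_ratio <= 1:
        raise ValueError(f"exchange_ratio must be in (0, 1], got {exchange_ratio}")
    if set(residual) != set(influent):
        missing = set(residual) ^ set(influent)
        raise ValueError(f"analyte sets differ between residual and influent: {missing}")
    return {
        k: exchange_ratio * influent[k] + (1 - exchange_ratio) * residual[k]
        for k in influent
    }


def apportion_phase1(
    endpoints: CycleEndpoints,
    params: StoichParams | None = None,
    clamp: bool = False,
) -> PathwayApportionment:
    """Apportion a no-rbCOD cycle among anammox, AOB and NOB.

    Denitrification is assumed absent: anammox takes the whole TN loss
    (ΔN); AOB take ammonium consumed beyond anammox's share; NOB take
    nitrate produced beyond anammox's stoichiometric yield.
    """
    p = params or StoichParams()
    dn = endpoints.delta_n
    tn_anammox = dn
    nh4_aob = (endpoints.nh4_initial - endpoints.nh4_final) - tn_anammox / p.r_tn_per_nh4
    no3_nob = (endpoints.no3_final - endpoints.no3_initial) - tn_anammox * p.r_no3_per_tn
    comps, warnings = _flag_negatives(
        {"tn_anammox": tn_anammox, "nh4_aob": nh4_aob, "no3_nob": no3_nob}, clamp
    )
    return PathwayApportionment(
        mode="phaseI",
        delta_n=dn,
        tn_anammox=comps["tn_anammox"],
        nh4_aob=comps["nh4_aob"],
        no3_nob=comps["no3_nob"],
        params=p,
        warnings=warnings,
    )


def apportion_phase2(
    endpoints: CycleEndpoints,
    params: StoichParams | None = None,
    clamp: bool = False,
) -> PathwayApportionment:
    """Apportion an rbCOD-fed cycle among anammox, denitratation, denitritation.

    Nitrification is assumed absent: anammox TN removal follows from
    ammonium loss; nitrate reduction beyond the anammox yield is
    denitratation; the remaining TN loss is denitritation.  The identity
    ``tn_anammox + tn_denitritation == delta_n`` holds by construction.
    """
    p = params or StoichParams()
    dn = endpoints.delta_n
    tn_anammox = (endpoints.nh4_initial - endpoints.nh4_final) * p.r_tn_per_nh4
    no3_denitratation = (
        endpoints.no3_initial + tn_anammox * p.r_no3_per_tn - endpoints.no3_final
    )
    tn_denitritation = dn - tn_anammox
    comps, warnings = _flag_negatives(
        {
            "tn_anammox": tn_anammox,
            "no3_denitratation": no3_denitratation,
            "tn_denitritation": tn_denitritation,
        },
        clamp,
    )
    return PathwayApportionment(
        mode="phaseII",
        delta_n=dn,
        tn_anammox=comps["tn_anammox"],
        no3_denitratation=comps["no3_denitratation"],
        tn_denitritation=comps["tn_denitritation"],
        params=p,
        warnings=warnings,
    )


def pathway_contributions(app: PathwayApportionment) -> dict[str, float]:
    """Percent shares of the apportioned pathways.

    Phase II: anammox vs denitritation shares of net TN removal.  Phase I:
    NOB vs anammox shares of nitrate *production* (nitrate is the phase-I
    symptom; TN removal is all-anammox by assumption).
    """
    if app.delta_n <= 0:
        raise ValueError("no net nitrogen removal; contributions undefined")
    if app.mode == "phaseII":
        anammox = app.tn_anammox / app.delta_n * 100.0
        return {"anammox": anammox, "denitritation": 100.0 - anammox}
    anammox_no3 = app.tn_anammox * app.params.r_no3_per_tn
    total_no3 = anammox_no3 + (app.no3_nob or 0.0)
    if total_no3 <= 0:
        raise ValueError("no nitrate production; shares undefined")
    nob = (app.no3_nob or 0.0) / total_no3 * 100.0
    return {"nob_nitrate": nob, "anammox_nitrate": 100.0 - nob}


def delta_nitrate_ammonium_ratio(endpoints: CycleEndpoints) -> float:
    """ΔNO3-N produced per ΔNH4-N removed over a cycle.

    The anammox reaction alone gives 0.26; substantially higher values
    indicate additional nitrate generation (NOB), negative values net
    nitrate consumption (denitrification).
    """
    removed = endpoints.nh4_initial - endpoints.nh4_final
    if removed <= 0:
        raise ValueError("no ammonium removal; ratio undefined")
    return (endpoints.no3_final - endpoints.no3_initial) / removed


@dataclass(frozen=True)
class BatchProfile:
    """A batch-test concentration time course (minutes, mg N/L)."""

    time: np.ndarray
    nh4: np.ndarray
    no2: np.ndarray
    no3: np.ndarray
    cod: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.size < 2:
            raise ValueError("a profile needs at least two time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        for name in ("nh4", "no2", "no3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} length does not match time")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "time", t)
        if self.cod is not None:
            object.__setattr__(self, "cod", np.asarray(self.cod, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_min": self.time,
            "nh4_mgN_L": self.nh4,
            "no2_mgN_L": self.no2,
            "no3_mgN_L": self.no3,
        }
        if self.cod is not None:
            data["cod_mg_L"] = self.cod
        return pd.DataFrame(data)


@dataclass(frozen=True)
class NTRResult:
    """Nitrate-to-nitrite transformation ratio along a batch trace.

    ``series`` is NTR(t) in percent where defined (NaN where the nitrate
    drawdown is below the ε guard); ``maximum`` is NaN when nitrate is never
    reduced beyond ε (``defined`` False).
    """

    time: np.ndarray
    series: np.ndarray
    maximum: float
    defined: bool


def nitrate_to_nitrite_transformation(
    profile: BatchProfile, epsilon: float = NTR_EPSILON
) -> NTRResult:
    """Per-time NTR series and its maximum for a denitrification batch test.

    NTR(t) = accumulated NO2-N over reduced NO3-N × 100, evaluated only
    where the nitrate drawdown exceeds ``epsilon`` (default 0.1 mg N/L,
    typical analytical precision) to avoid ratio blow-up early in the trace.
    The maximum is taken over the whole series, so transient nitrite peaks
    of a complete-denitrification trace are captured.
    """
    if profile.no3[0] <= 0:
        raise ValueError("initial nitrate must be positive for an NTR test")
    drawdown = profile.no3[0] - profile.no3
    accumulated = profile.no2 - profile.no2[0]
    series = np.full_like(drawdown, np.nan)
    mask = drawdown > epsilon
    series[mask] = accumulated[mask] / drawdown[mask] * 100.0
    defined = bool(mask.any())
    maximum = float(np.nanmax(series)) if defined else float("nan")
    return NTRResult(time=profile.time, series=series, maximum=maximum, defined=defined)


def nitrogen_removal_efficiency(influent_tn: float, effluent_tn: float) -> float:
    """Percent TN removal, (1 − effluent/influent) × 100."""
    if influent_tn <= 0:
        raise ValueError("influent TN must be positive")
    if effluent_tn < 0:
        raise ValueError("effluent TN cannot be negative")
    return (1.0 - effluent_tn / influent_tn) * 100.0


def phase_summary(
    campaign: pd.DataFrame,
    phase_col: str = "phase",
    analytes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-phase mean ± sample standard deviation of campaign analytes.

    Mirrors an influent-characterisation table: one row per phase, one
    (mean, sd, n) triple per analyte; sd uses the n−1 denominator.  Raises
    if any phase holds fewer than two records.
    """
    if analytes is None:
        analytes = [
            c for c in campaign.columns
            if c != phase_col and pd.api.types.is_numeric_dtype(campaign[c])
        ]
    if campaign.empty:
        raise ValueError("empty campaign")
    grouped = campaign.groupby(phase_col)
    counts = grouped.size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"phases with fewer than two records: {bad}")
    out = grouped[analytes].agg(["mean", "std", "count"])
    out.columns = [f"{a}_{stat}" for a, stat in out.columns]
    return out
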