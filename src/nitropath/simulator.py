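"""Kinetic simulation of an anoxic sequencing-batch anammox reactor cycle.

The reactor runs three identical cycles per day: a short feed (50 % volume
exchange), a long anoxic react phase, settling, decant and idle.  During the
react phase five microbial guilds convert the nitrogen and acetate pools:

==================  =====================  ==========================
guild               conversion             electron donor / acceptor
==================  =====================  ==========================
AnAOB (anammox)     NH4 + NO2 → N2 (+NO3)  ammonium / nitrite
AOB                 NH4 → NO2              ammonium / oxygen
NOB                 NO2 → NO3              nitrite / oxygen
OHO denitratation   NO3 → NO2              acetate / nitrate
OHO denitritation   NO2 → N2               acetate / nitrite
OHO aerobic         acetate → CO2          acetate / oxygen
==================  =====================  ==========================

Each guild follows a dual-Monod rate law, ``μmax · X · Π s/(K+s)``, with
anoxic guilds additionally inhibited by dissolved oxygen through a
non-competitive ``K_O2/(K_O2+DO)`` factor.  Species updates follow the same
stoichiometric reaction vectors used by the closure/demand calculations, so
simulated cycles are exactly consistent with the mass-balance apportionment
when the closed anammox vector is selected.

Alongside each concentration profile the simulator integrates the
*ground-truth* nitrogen flux through every process (mg N per litre of
reactor volume per cycle).  These integrals are the oracle against which the
two-point endpoint apportionment can be validated: the apportionment sees
only start/end concentrations, the ground truth knows the actual pathway
fluxes.

No kinetic constants are reported for the emulated reactor; the defaults
here are order-of-magnitude literature-typical values for mainstream
low-strength operation, chosen so that a default phase-I cycle removes most
of its ammonium and nitrite within the 360-min react phase.  They are
illustrative operating points, not fitted parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import truncnorm

from .apportionment import mix_feed
from .species import MW_N, MW_O2
from .stoichiometry import anammox_reaction, auxiliary_reactions, builtin_reactions

__all__ = [
    "CycleSchedule",
    "InfluentSpec",
    "GuildKinetics",
    "KineticParams",
    "DOMode",
    "NoiseSpec",
    "SimConfig",
    "SimGroundTruth",
    "sample_influent",
    "simulate_cycle",
    "simulate_campaign",
    "add_measurement_noise",
    "phase1_config",
    "phase2_config",
    "ANALYTES",
]

#: analyte keys of a reactor state record (mg N/L except cod, mg COD/L)
ANALYTES = ("nh4", "no2", "no3", "cod")

_COD_PER_ACETATE_N = 64.0 / MW_N  # mg COD per mg N at 1 mol acetate per mol N


@dataclass(frozen=True)
class CycleSchedule:
    """SBR cycle timing (minutes) and volume exchange.

    Defaults: 10 min feed at 50 % exchange, 360 min anoxic react, 30 min
    settle, 10 min decant, 70 min idle — an 8-h cycle, three per day.
    """

    feed_min: float = 10.0
    react_min: float = 360.0
    settle_min: float = 30.0
    decant_min: float = 10.0
    idle_min: float = 70.0
    exchange_ratio: float = 0.5
    cycles_per_day: int = 3

    def __post_init__(self) -> None:
        for name in ("feed_min", "react_min", "settle_min", "decant_min", "idle_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.exchange_ratio <= 1:
            raise ValueError("exchange_ratio must be in (0, 1]")
        if self.cycles_per_day < 1:
            raise ValueError("cycles_per_day must be >= 1")

    @property
    def total_min(self) -> float:
        return (
            self.feed_min + self.react_min + self.settle_min
            + self.decant_min + self.idle_min
        )


@dataclass(frozen=True)
class InfluentSpec:
    """Influent composition as truncated-at-zero normal per analyte.

    Means/sds in mg N/L (nh4, no2, no3) and mg COD/L (cod, the readily
    biodegradable acetate fraction).
    """

    phase: str
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in ANALYTES:
            if self.mean.get(k, 0.0) < 0 or self.sd.get(k, 0.0) < 0:
                raise ValueError(f"negative mean/sd for {k}")


#: phase-I influent: low-strength ammonium+nitrite, negligible rbCOD
PHASE1_INFLUENT = InfluentSpec(
    phase="phase1",
    mean={"nh4": 14.3, "no2": 14.1, "no3": 1.2, "cod": 0.0},
    sd={"nh4": 2.5, "no2": 2.4, "no3": 0.8, "cod": 0.0},
)

#: phase-II influent: slightly weaker N load plus 24.2 mg/L acetate COD
PHASE2_INFLUENT = InfluentSpec(
    phase="phase2",
    mean={"nh4": 12.5, "no2": 12.3, "no3": 2.0, "cod": 24.2},
    sd={"nh4": 1.8, "no2": 1.4, "no3": 0.6, "cod": 0.0},
)


def sample_influent(spec: InfluentSpec, rng: np.random.Generator | int) -> dict:
    """Draw one influent record from a spec; deterministic given the seed.

    Each analyte comes from a normal truncated at zero; a zero sd returns
    the mean exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    record = {}
    for k in ANALYTES:
        mu, sd = spec.mean.get(k, 0.0), spec.sd.get(k, 0.0)
        if sd == 0:
            record[k] = mu
        else:
            a = (0.0 - mu) / sd
            record[k] = float(truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))
    return record


@dataclass(frozen=True)
class GuildKinetics:
    """Rate parameters of one guild.

    ``mu_max`` is the maximum specific conversion rate of the guild's key
    substrate (mg N or mg COD per g VSS per h); ``half_sat`` maps each
    limiting substrate to its half-saturation constant (mg/L); ``k_o2`` is
    either the oxygen Monod constant (aerobic guilds) or the oxygen
    inhibition constant (anoxic guilds); ``fraction`` the guild's share of
    total biomass.
    """

    mu_max: float
    half_sat: dict
    k_o2: float
    fraction: float
    aerobic: bool = False

    def __post_init__(self) -> None:
        if self.mu_max < 0 or self.k_o2 < 0 or self.fraction < 0:
            raise ValueError("kinetic parameters must be non-negative")
        for s, k in self.half_sat.items():
            if k < 0:
                raise ValueError(f"negative half-saturation for {s}")


_GUILDS = ("anammox", "aob", "nob", "denitratation", "denitritation", "aerobic")


@dataclass(frozen=True)
class KineticParams:
    """Guild kinetics, biomass inventory and the shared anammox vector.

    ``biomass_total`` is g VSS/L (default 4.9, a freshly inoculated
    mainstream reactor); guild fractions need not sum to one (the remainder
    is inert).  ``closed_stoichiometry`` replaces the empirical anammox N2
    yield with the value that closes the nitrogen balance exactly — use it
    whenever simulated cycles feed the closed-mode apportionment.
    """

    biomass_total: float = 4.9
    anammox_no2: float = 1.32
    anammox_no3: float = 0.26
    closed_stoichiometry: bool = True
    guilds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biomass_total < 0:
            raise ValueError("biomass_total must be non-negative")
        defaults = default_guilds()
        merged = {**defaults, **self.guilds}
        unknown = set(merged) - set(_GUILDS)
        if unknown:
            raise ValueError(f"unknown guilds {sorted(unknown)}")
        object.__setattr__(self, "guilds", merged)

    def biomass(self, guild: str) -> float:
        return self.biomass_total * self.guilds[guild].fraction


def default_guilds() -> dict[str, GuildKinetics]:
    """Literature-order default kinetics for a mainstream anoxic SBR."""
    return {
        "anammox": GuildKinetics(
            mu_max=4.0, half_sat={"nh4": 0.5, "no2": 0.5}, k_o2=0.2, fraction=0.10
        ),
        "aob": GuildKinetics(
            mu_max=20.0, half_sat={"nh4": 0.5}, k_o2=0.3, fraction=0.010,
            aerobic=True,
        ),
        "nob": GuildKinetics(
            mu_max=30.0, half_sat={"no2": 0.3}, k_o2=0.15, fraction=0.010,
            aerobic=True,
        ),
        "denitratation": GuildKinetics(
            mu_max=10.0, half_sat={"no3": 0.5, "cod": 5.0}, k_o2=0.2, fraction=0.15
        ),
        "denitritation": GuildKinetics(
            mu_max=4.0, half_sat={"no2": 0.5, "cod": 5.0}, k_o2=0.2, fraction=0.15
        ),
        "aerobic": GuildKinetics(
            mu_max=30.0, half_sat={"cod": 5.0}, k_o2=0.2, fraction=0.15,
            aerobic=True,
        ),
    }


@dataclass(frozen=True)
class DOMode:
    """Dissolved-oxygen regime of the react phase.

    ``prescribed`` holds DO at a constant measured level (default; the
    emulated reactor reports DO as narrow measured ranges: 0.06–0.08 mg/L
    without rbCOD, 0.02–0.04 mg/L with it).  ``mass_transfer`` integrates
    dDO/dt = kLa·(DO_sat − DO) − consumption instead.
    """

    kind: str = "prescribed"
    level: float = 0.07
    kla_per_h: float = 0.0
    do_sat: float = 8.6
    do_influent: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("prescribed", "mass_transfer"):
            raise ValueError("DO mode must be 'prescribed' or 'mass_transfer'")
        if self.level < 0 or self.kla_per_h < 0 or self.do_sat < 0:
            raise ValueError("DO parameters must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Analytical measurement noise: sd = sigma_abs + sigma_rel × value."""

    sigma_abs: float = 0.0
    sigma_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise ValueError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class SimGroundTruth:
    """Time-integrated conversion through each process over one cycle.

    All entries in mg N per litre of reactor volume (``cod_*`` in mg COD/L).
    ``tn_anammox`` is total inorganic N removed via anammox; ``n2_n`` the
    cumulative dinitrogen-N produced; ``n_incorporated`` the small nitrogen
    residual of an unbalanced empirical anammox vector (zero in closed
    mode).
    """

    tn_anammox: float
    nh4_aob: float
    no3_nob: float
    no3_denitratation: float
    tn_denitritation: float
    n2_n: float
    n_incorporated: float
    cod_denitratation: float
    cod_denitritation: float
    cod_aerobic: float

    def as_dict(self) -> dict:
        return {
            "tn_anammox": self.tn_anammox,
            "nh4_aob": self.nh4_aob,
            "no3_nob": self.no3_nob,
            "no3_denitratation": self.no3_denitratation,
            "tn_denitritation": self.tn_denitritation,
            "n2_n": self.n2_n,
            "n_incorporated": self.n_incorporated,
            "cod_denitratation": self.cod_denitratation,
            "cod_denitritation": self.cod_denitritation,
            "cod_aerobic": self.cod_aerobic,
        }


def _process_vectors(params: KineticParams) -> dict[str, dict]:
    """Per-guild species increments per mg of key substrate converted.

    Derived from the reaction definitions so the simulator shares one
    stoichiometric source of truth with the closure calculations.  Keys of
    each vector: nh4, no2, no3, cod (mg/L), o2 (mg O2/L), n2 (mg N/L),
    n_inc (mg N/L incorporated, i.e. the reaction's N-balance shortfall).
    """
    rxns = builtin_reactions(params.anammox_no2, params.anammox_no3)
    aux = auxiliary_reactions()
    amx = rxns["anammox"]
    no2 = -amx.coeff("NO2-")
    no3 = amx.coeff("NO3-")
    if params.closed_stoichiometry:
        n2_n = 1.0 + no2 - no3  # closes the N balance exactly
    else:
        n2_n = 2.0 * amx.coeff("N2")
    vectors = {
        "anammox": {
            "nh4": -1.0, "no2": -no2, "no3": no3, "cod": 0.0, "o2": 0.0,
            "n2": n2_n, "n_inc": (1.0 + no2 - no3) - n2_n,
        },
        "aob": {
            "nh4": -1.0, "no2": 1.0, "no3": 0.0, "cod": 0.0,
            "o2": -abs(rxns["partial_nitritation"].coeff("O2")) * MW_O2 / MW_N,
            "n2": 0.0, "n_inc": 0.0,
        },
        "nob": {
            "nh4": 0.0, "no2": -1.0, "no3": 1.0, "cod": 0.0,
            "o2": -abs(aux["nitratation"].coeff("O2")) * MW_O2 / MW_N,
            "n2": 0.0, "n_inc": 0.0,
        },
        "denitratation": {
            "nh4": 0.0, "no2": 1.0, "no3": -1.0,
            "cod": -abs(rxns["partial_denitrification"].coeff("CH3COO-")) * _COD_PER_ACETATE_N,
            "o2": 0.0, "n2": 0.0, "n_inc": 0.0,
        },
        "denitritation": {
            "nh4": 0.0, "no2": -1.0, "no3": 0.0,
            "cod": -abs(aux["denitritation"].coeff("CH3COO-")) * _COD_PER_ACETATE_N,
            "o2": 0.0, "n2": 1.0, "n_inc": 0.0,
        },
        "aerobic": {  # key substrate is COD itself; 1 mg O2 per mg COD
            "nh4": 0.0, "no2": 0.0, "no3": 0.0, "cod": -1.0, "o2": -1.0,
            "n2": 0.0, "n_inc": 0.0,
        },
    }
    return vectors


_SUBSTRATE_INDEX = {"nh4": 0, "no2": 1, "no3": 2, "cod": 3}


def simulate_cycle(
    state: dict,
    influent: dict,
    schedule: CycleSchedule | None = None,
    kinetics: KineticParams | None = None,
    do_mode: DOMode | None = None,
    profile_resolution_min: float = 5.0,
) -> tuple[pd.DataFrame, SimGroundTruth, dict]:
    """One SBR cycle: feed mixing, anoxic react ODE, profile and truth.

    ``state`` and ``influent`` are analyte records (nh4/no2/no3/cod).  Feed
    is treated as instantaneous at react start (the 10-min feed is short
    against the 360-min react phase), so cycle endpoints are exactly the
    two-point balance the apportionment expects.  Returns the concentration
    profile (including DO), the ground-truth pathway integrals and the end
    state (= residual entering the next cycle; settling and decant are
    reaction-free).
    """
    schedule = schedule or CycleSchedule()
    kinetics = kinetics or KineticParams()
    do_mode = do_mode or DOMode()
    for rec, label in ((state, "state"), (influent, "influent")):
        for k in ANALYTES:
            if rec.get(k, 0.0) < 0:
                raise ValueError(f"negative {k} in {label}")
    state = {k: state.get(k, 0.0) for k in ANALYTES}
    influent = {k: influent.get(k, 0.0) for k in ANALYTES}
    mixed = mix_feed(state, influent, schedule.exchange_ratio)

    vectors = _process_vectors(kinetics)
    guilds = kinetics.guilds
    biomass = {g: kinetics.biomass(g) for g in guilds}
    dynamic_do = do_mode.kind == "mass_transfer"

    def rates(y: np.ndarray) -> np.ndarray:
        conc = np.clip(y[:4], 0.0, None)
        do = max(y[4], 0.0) if dynamic_do else do_mode.level
        r = np.empty(len(_GUILDS))
        for i, g in enumerate(_GUILDS):
            gk = guilds[g]
            rate = gk.mu_max * biomass[g]
            for sub, k in gk.half_sat.items():
                s = conc[_SUBSTRATE_INDEX[sub]]
                rate *= s / (k + s) if (k + s) > 0 else 0.0
            if gk.aerobic:
                rate *= do / (gk.k_o2 + do) if (gk.k_o2 + do) > 0 else 0.0
            else:
                rate *= gk.k_o2 / (gk.k_o2 + do) if (gk.k_o2 + do) > 0 else 1.0
            r[i] = rate
        return r

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        r = rates(y)
        dy = np.zeros_like(y)
        do_cons = 0.0
        for i, g in enumerate(_GUILDS):
            v = vectors[g]
            dy[0] += r[i] * v["nh4"]
            dy[1] += r[i] * v["no2"]
            dy[2] += r[i] * v["no3"]
            dy[3] += r[i] * v["cod"]
            do_cons += r[i] * (-v["o2"])
            dy[5 + i] = r[i]
        if dynamic_do:
            dy[4] = do_mode.kla_per_h * (do_mode.do_sat - max(y[4], 0.0)) - do_cons
        return dy

    do0 = do_mode.do_influent if dynamic_do else do_mode.level
    y0 = np.array(
        [mixed["nh4"], mixed["no2"], mixed["no3"], mixed["cod"], do0]
        + [0.0] * len(_GUILDS)
    )
    hours = schedule.react_min / 60.0
    n_pts = int(round(schedule.react_min / profile_resolution_min)) + 1
    t_eval = np.linspace(0.0, hours, n_pts)
    sol = solve_ivp(
        rhs, (0.0, hours), y0, method="LSODA", t_eval=t_eval,
        rtol=1e-8, atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"cycle integration failed: {sol.message}")

    conc = np.clip(sol.y[:4], 0.0, None)
    do_series = (
        np.clip(sol.y[4], 0.0, None) if dynamic_do
        else np.full_like(sol.t, do_mode.level)
    )
    profile = pd.DataFrame(
        {
            "time_min": sol.t * 60.0,
            "nh4_mgN_L": conc[0],
            "no2_mgN_L": conc[1],
            "no3_mgN_L": conc[2],
            "cod_mg_L": conc[3],
            "do_mg_L": do_series,
        }
    )
    extents = dict(zip(_GUILDS, sol.y[5:, -1]))
    v_amx = vectors["anammox"]
    tn_per_nh4 = -(v_amx["nh4"] + v_amx["no2"] + v_amx["no3"])
    truth = SimGroundTruth(
        tn_anammox=extents["anammox"] * tn_per_nh4,
        nh4_aob=extents["aob"],
        no3_nob=extents["nob"],
        no3_denitratation=extents["denitratation"],
        tn_denitritation=extents["denitritation"],
        n2_n=extents["anammox"] * v_amx["n2"] + extents["denitritation"],
        n_incorporated=extents["anammox"] * v_amx["n_inc"],
        cod_denitratation=extents["denitratation"] * (-vectors["denitratation"]["cod"]),
        cod_denitritation=extents["denitritation"] * (-vectors["denitritation"]["cod"]),
        cod_aerobic=extents["aerobic"],
    )
    end_state = {
        "nh4": float(conc[0, -1]),
        "no2": float(conc[1, -1]),
        "no3": float(conc[2, -1]),
        "cod": float(conc[3, -1]),
    }
    return profile, truth, end_state


def simulate_batch(
    initial: dict,
    duration_min: float = 360.0,
    kinetics: KineticParams | None = None,
    do_level: float = 0.0,
    profile_resolution_min: float = 5.0,
) -> tuple[pd.DataFrame, SimGroundTruth]:
    """Anoxic batch-flask test: no feed exchange, nitrogen-stripped headspace.

    Runs the react kinetics on the given initial composition (a full volume
    exchange with the initial record, i.e. no residual), by default with
    zero dissolved oxygen as in a continuously N2-sparged flask.
    """
    schedule = CycleSchedule(react_min=duration_min, exchange_ratio=1.0)
    profile, truth, _end = simulate_cycle(
        {k: 0.0 for k in ANALYTES},
        initial,
        schedule,
        kinetics,
        DOMode(level=do_level),
        profile_resolution_min=profile_resolution_min,
    )
    return profile, truth


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to run a multi-day campaign."""

    schedule: CycleSchedule = field(default_factory=CycleSchedule)
    influent: InfluentSpec = PHASE1_INFLUENT
    kinetics: KineticParams = field(default_factory=KineticParams)
    do_mode: DOMode = field(default_factory=DOMode)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    initial_state: dict = field(
        default_factory=lambda: {"nh4": 1.0, "no2": 1.0, "no3": 2.0, "cod": 0.0}
    )
    #: relative biomass change per guild per day (e.g. {"nob": 0.01})
    biomass_drift: dict = field(default_factory=dict)


def phase1_config(**overrides) -> SimConfig:
    """Operating point without rbCOD: DO 0.07 mg/L, nitrifiers active."""
    return SimConfig(
        influent=PHASE1_INFLUENT, do_mode=DOMode(level=0.07), **overrides
    )


def phase2_config(**overrides) -> SimConfig:
    """Operating point with 24.2 mg/L acetate COD and DO 0.03 mg/L."""
    return SimConfig(
        influent=PHASE2_INFLUENT, do_mode=DOMode(level=0.03), **overrides
    )


def _drifted(kinetics: KineticParams, drift: dict, day: int) -> KineticParams:
    if not drift:
        return kinetics
    guilds = dict(kinetics.guilds)
    for g, rate in drift.items():
        gk = guilds[g]
        guilds[g] = replace(gk, fraction=max(0.0, gk.fraction * (1.0 + rate * day)))
    return replace(kinetics, guilds=guilds)


def simulate_campaign(
    config: SimConfig,
    n_days: int,
    seed: int,
    keep_profiles: bool = False,
) -> dict:
    """Multi-day campaign with carry-over residuals and per-cycle truth.

    Returns a dict with ``campaign`` (one effluent record per day — the last
    cycle's react endpoint, a deliberate sampling convention recorded in the
    frame's metadata), ``truth`` (per-cycle ground-truth integrals) and,
    optionally, ``profiles`` (list of per-cycle concentration frames).
    Deterministic given the seed: all randomness flows from one seed
    sequence split into per-cycle streams.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    n_cycles = n_days * config.schedule.cycles_per_day
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_cycles + 1)]
    noise_rng = streams[-1]
    state = dict(config.initial_state)
    rows, truth_rows, profiles = [], [], []
    cycle_idx = 0
    for day in range(1, n_days + 1):
        kin = _drifted(config.kinetics, config.biomass_drift, day - 1)
        day_influents = []
        for _c in range(config.schedule.cycles_per_day):
            influent = sample_influent(config.influent, streams[cycle_idx])
            profile, truth, state = simulate_cycle(
                state, influent, config.schedule, kin, config.do_mode
            )
            day_influents.append(influent)
            truth_rows.append({"day": day, "cycle": cycle_idx + 1, **truth.as_dict()})
            if keep_profiles:
                profiles.append(profile)
            cycle_idx += 1
        inf_mean = {k: float(np.mean([d[k] for d in day_influents])) for k in ANALYTES}
        rows.append(
            {
                "day": day,
                "phase": config.influent.phase,
                "inf_nh4": inf_mean["nh4"],
                "inf_no2": inf_mean["no2"],
                "inf_no3": inf_mean["no3"],
                "inf_cod": inf_mean["cod"],
                "eff_nh4": state["nh4"],
                "eff_no2": state["no2"],
                "eff_no3": state["no3"],
                "eff_cod": state["cod"],
            }
        )
    campaign = pd.DataFrame(rows)
    if config.noise.sigma_abs > 0 or config.noise.sigma_rel > 0:
        for col in ("eff_nh4", "eff_no2", "eff_no3", "eff_cod"):
            sd = config.noise.sigma_abs + config.noise.sigma_rel * campaign[col]
            campaign[col] = np.clip(
                campaign[col] + noise_rng.normal(0.0, 1.0, len(campaign)) * sd, 0.0, None
            )
    campaign.attrs["effluent_sampling"] = "last-cycle react endpoint per day"
    out = {"campaign": campaign, "truth": pd.DataFrame(truth_rows)}
    if keep_profiles:
        out["profiles"] = profiles
    return out


def add_measurement_noise(
    profile: pd.DataFrame,
    sigma_abs: float,
    sigma_rel: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Gaussian analytical noise on every concentration column.

    Each reading gains Normal(0, sigma_abs + sigma_rel × value) and is
    truncated at zero.  The time column is untouched; deterministic given
    the seed.
    """
    if sigma_abs < 0 or sigma_rel < 0:
        raise ValueError("noise sigmas must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = profile.copy()
    for col in noisy.columns:
        if col == "time_min":
            continue
        values = noisy[col].to_numpy(dtype=float)
        sd = sigma_abs + sigma_rel * values
        noisy[col] = np.clip(values + rng.normal(0.0, 1.0, len(values)) * sd, 0.0, None)
    return noisy
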