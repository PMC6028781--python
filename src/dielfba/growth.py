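"""The dynamic layer: day-by-day growth of the diel plant model.

Each simulated day:

1. the maximum whole-plant nitrate uptake is computed from soil nitrate by
   Michaelis-Menten kinetics scaled by root biomass,
2. the projected leaf area (PLA) caps the photon influx,
3. the leaf growth proportion g_r splits whole-plant biomass synthesis
   between leaf and root -- the balanced-growth heuristic

       g_r = ln(PN_r) / [ ln(P_max / S) + L_B / R_B ],
       PN_r = PLA * P_max / sigma_N_max,

   with P_max the areal photon dose per light phase (irradiance times
   photoperiod), S the available soil nitrate (mol) and sigma_N_max the
   Michaelis-Menten uptake cap; g_r is clamped away from exactly 0 and 1,
4. the LP maximizes total biomass synthesis (sum of the four module
   biomass fluxes) under the caps, maintenance equalities and the g_r
   partition row, then re-solves parsimoniously (minimum total flux),
5. soil nitrate is drawn down by the realized uptake (floored at a small
   residual) and the tissue biomasses grow by the realized synthesis.

Perturbation events (herbivory, fertilization, shading) overwrite leaf
biomass, soil nitrate or irradiance at the start of their day.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from optlang.symbolics import Zero

from .builder import (
    DielPlantModel,
    StandingConstraintConfig,
    SUFFIXES,
    apply_standing_constraints,
    maintenance_values,
)
from .network import FluxSolution, pfba_on

__all__ = [
    "GrowthParams",
    "PlantState",
    "DaySolution",
    "DayRecord",
    "PerturbationEvent",
    "Trajectory",
    "GrowthDomainError",
    "DayInfeasibleError",
    "max_nitrate_uptake",
    "projected_leaf_area",
    "leaf_growth_proportion",
    "solve_day",
    "advance_state",
    "run_growth",
    "run_sensitivity_scan",
    "fva_day",
    "day_lp",
]

logger = logging.getLogger(__name__)

#: The compiled LP works in mmol (metabolite fluxes) and mg (biomass
#: fluxes) per phase, a scale on which seedling-sized problems stay
#: well-conditioned; the engine's state and sigma quantities are in mol
#: and g. Biomass composition coefficients are mol/g = mmol/mg, so the
#: stoichiometry is identical on both scales.
MOL_TO_LP = 1000.0


class GrowthDomainError(ValueError):
    """Inputs outside the validity regime of the growth heuristic."""


class DayInfeasibleError(RuntimeError):
    """The daily LP could not be solved; carries the day and diagnostics."""

    def __init__(self, day: int, message: str, trajectory=None):
        super().__init__(f"day {day}: {message}")
        self.day = day
        self.trajectory = trajectory


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic constants, initial state and loop extent.

    Units: v_max in mol nitrate per g root dry weight per day; k_m in mol;
    p_max_irradiance in mol photons m-2 s-1; photoperiod in s; m_slope in
    m2 leaf area per g leaf dry weight; maintenance rates in mmol per g
    dry weight per day (split 50/50 between phases); nitrate amounts in
    mol; biomasses in g dry weight; days in days after sowing.
    """

    v_max: float = 0.00336
    k_m: float = 0.0004
    p_max_irradiance: float = 300e-6
    photoperiod: float = 43200.0
    m_slope: float = 0.03
    atp_maint: float = 7.27
    nadph_maint: float = 2.56
    nitrate_floor: float = 1e-6
    start_day: int = 6
    end_day: int = 36
    initial_lr_ratio: float = 25.8
    initial_total_biomass: float = 5e-5
    initial_nitrate: float = 0.0012
    g_min: float = 1e-3

    def __post_init__(self):
        for name in ("v_max", "k_m", "p_max_irradiance", "photoperiod",
                     "m_slope", "nitrate_floor", "initial_lr_ratio",
                     "initial_total_biomass", "initial_nitrate", "g_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.atp_maint < 0 or self.nadph_maint < 0:
            raise ValueError("maintenance rates must be nonnegative")
        if self.start_day >= self.end_day:
            raise ValueError("start_day must precede end_day")

    @property
    def p_max_daily(self) -> float:
        """Areal photon dose per light phase (mol photons m-2 phase-1)."""
        return self.p_max_irradiance * self.photoperiod

    def daily_dose(self, irradiance: Optional[float] = None) -> float:
        return (self.p_max_irradiance if irradiance is None else irradiance) \
            * self.photoperiod

    def initial_state(self) -> "PlantState":
        ratio = self.initial_lr_ratio
        leaf = self.initial_total_biomass * ratio / (1.0 + ratio)
        root = self.initial_total_biomass / (1.0 + ratio)
        return PlantState(self.start_day, leaf, root, self.initial_nitrate,
                          self.m_slope)

    def hash(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class PlantState:
    """Per-day dynamic state: biomasses, soil nitrate, derived leaf area."""

    day: int
    leaf_biomass: float
    root_biomass: float
    nitrate: float
    m_slope: float

    def __post_init__(self):
        if self.leaf_biomass <= 0 or self.root_biomass <= 0:
            raise ValueError("biomasses must be positive")
        if self.nitrate < 0:
            raise ValueError("nitrate must be nonnegative")

    @property
    def pla(self) -> float:
        return projected_leaf_area(self.leaf_biomass, self.m_slope)

    @property
    def total_biomass(self) -> float:
        return self.leaf_biomass + self.root_biomass

    @property
    def rl_ratio(self) -> float:
        return self.root_biomass / self.leaf_biomass


@dataclass
class DaySolution:
    """One day's LP outcome: partition, uptakes, growth and fluxes.

    The sigma quantities are per phase in mol (nitrate, photons) and g
    (biomass); ``flux_vector`` keeps the raw LP fluxes, which are in mmol
    (metabolites) and mg (biomass reactions) per phase.
    """

    g_r: float
    pn_r: float
    sigma_n_max: float
    sigma_n_day: float
    sigma_n_night: float
    sigma_photon: float
    sigma_leaf_day: float
    sigma_leaf_night: float
    sigma_root_day: float
    sigma_root_night: float
    flux_vector: FluxSolution

    @property
    def leaf_growth(self) -> float:
        return self.sigma_leaf_day + self.sigma_leaf_night

    @property
    def root_growth(self) -> float:
        return self.sigma_root_day + self.sigma_root_night

    @property
    def total_growth(self) -> float:
        return self.leaf_growth + self.root_growth

    @property
    def nitrate_uptake(self) -> float:
        return self.sigma_n_day + self.sigma_n_night


@dataclass(frozen=True)
class PerturbationEvent:
    """State override applied at the start of its day, before solving."""

    day: int
    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("set_leaf_biomass", "set_nitrate", "set_irradiance"):
            raise ValueError(f"unknown perturbation kind {self.kind}")
        if self.value < 0:
            raise ValueError("perturbation value must be nonnegative")


@dataclass
class DayRecord:
    day: int
    state_start: PlantState
    solution: DaySolution
    state_end: PlantState
    nitrate_end_raw: float
    floored: bool
    irradiance: float


@dataclass
class Trajectory:
    """Ordered daily records of a growth run, plus reproducibility metadata."""

    initial_state: PlantState
    records: List[DayRecord]
    params: GrowthParams
    metadata: Dict[str, str] = field(default_factory=dict)

    @property
    def final_state(self) -> PlantState:
        return self.records[-1].state_end if self.records else self.initial_state

    @property
    def days(self) -> List[int]:
        return [r.day for r in self.records]

    def mean_g_r(self) -> float:
        return sum(r.solution.g_r for r in self.records) / len(self.records)

    def total_nitrate_uptake(self) -> float:
        return sum(r.solution.nitrate_uptake for r in self.records)

    def agr_series(self) -> pd.Series:
        return pd.Series({r.day: r.solution.total_growth for r in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "day": self.initial_state.day,
            "L_B": self.initial_state.leaf_biomass,
            "R_B": self.initial_state.root_biomass,
            "S": self.initial_state.nitrate,
            "PLA": self.initial_state.pla,
        }]
        for rec in self.records:
            sol = rec.solution
            rows.append({
                "day": rec.day,
                "L_B": rec.state_start.leaf_biomass,
                "R_B": rec.state_start.root_biomass,
                "S": rec.state_start.nitrate,
                "PLA": rec.state_start.pla,
                "irradiance": rec.irradiance,
                "g_r": sol.g_r,
                "PN_r": sol.pn_r,
                "sigma_N_max": sol.sigma_n_max,
                "sigma_N_D": sol.sigma_n_day,
                "sigma_N_N": sol.sigma_n_night,
                "sigma_P": sol.sigma_photon,
                "sigma_L_D": sol.sigma_leaf_day,
                "sigma_L_N": sol.sigma_leaf_night,
                "sigma_R_D": sol.sigma_root_day,
                "sigma_R_N": sol.sigma_root_night,
                "AGR": sol.total_growth,
                "L_B_end": rec.state_end.leaf_biomass,
                "R_B_end": rec.state_end.root_biomass,
                "S_end": rec.state_end.nitrate,
                "S_end_raw": rec.nitrate_end_raw,
                "floored": rec.floored,
            })
        return pd.DataFrame(rows)


# -- closed-form layers ------------------------------------------------


def max_nitrate_uptake(nitrate: float, root_biomass: float,
                       params: GrowthParams) -> float:
    """Michaelis-Menten daily nitrate uptake cap, mol per day.

    ``v_max * S / (K_M + S)`` per gram of root, scaled by root biomass;
    never negative (no efflux back to the soil).
    """
    if nitrate < 0:
        raise GrowthDomainError("nitrate must be nonnegative")
    if root_biomass <= 0:
        raise GrowthDomainError("root biomass must be positive")
    if nitrate == 0:
        return 0.0
    return params.v_max * nitrate / (params.k_m + nitrate) * root_biomass


def projected_leaf_area(leaf_biomass: float, m_slope: float) -> float:
    """PLA in m2, linear in leaf dry mass with slope ``m_slope``."""
    if leaf_biomass < 0:
        raise GrowthDomainError("leaf biomass must be nonnegative")
    if m_slope <= 0:
        raise GrowthDomainError("PLA slope must be positive")
    return m_slope * leaf_biomass


def leaf_growth_proportion(
    pla: float,
    sigma_n_max: float,
    nitrate: float,
    leaf_biomass: float,
    root_biomass: float,
    params: GrowthParams,
    irradiance: Optional[float] = None,
) -> Tuple[float, float]:
    """Balanced-growth leaf share g_r and the photon:nitrate ratio PN_r.

    Returns ``(g_r, PN_r)`` with g_r clamped to
    ``[g_min, 1 - g_min]``. Raises :class:`GrowthDomainError` when a
    logarithm argument or the denominator is nonpositive, which flags a
    parameter regime outside the heuristic's validity.
    """
    if min(pla, sigma_n_max, nitrate, leaf_biomass, root_biomass) <= 0:
        raise GrowthDomainError(
            "leaf_growth_proportion requires positive PLA, nitrate cap, "
            "soil nitrate and biomasses")
    p_daily = params.daily_dose(irradiance)
    pn_r = pla * p_daily / sigma_n_max
    ratio = p_daily / nitrate
    if ratio <= 0:
        raise GrowthDomainError("photon dose / nitrate ratio is nonpositive")
    denominator = math.log(ratio) + leaf_biomass / root_biomass
    if denominator <= 0:
        raise GrowthDomainError(
            f"g_r denominator {denominator:.3g} <= 0 "
            f"(S={nitrate:.3g} mol vs photon dose {p_daily:.3g}); "
            "outside the heuristic's validity regime")
    g_r = math.log(pn_r) / denominator
    g_r = min(max(g_r, params.g_min), 1.0 - params.g_min)
    return g_r, pn_r


# -- the daily LP ------------------------------------------------------


@contextmanager
def day_lp(model: DielPlantModel, state: PlantState, params: GrowthParams,
           irradiance: Optional[float] = None, g_r: Optional[float] = None):
    """Context with the compiled LP configured for one day.

    Applies the photon cap, the Michaelis-Menten nitrate cap row, the
    maintenance equalities scaled to the current tissue masses and the
    g_r partition row; yields ``(cobra_model, info)`` and reverts all
    changes on exit.
    """
    sigma_n_max = max_nitrate_uptake(state.nitrate, state.root_biomass, params)
    pla = projected_leaf_area(state.leaf_biomass, params.m_slope)
    if g_r is None:
        if sigma_n_max > 0:
            g_r, pn_r = leaf_growth_proportion(
                pla, sigma_n_max, state.nitrate, state.leaf_biomass,
                state.root_biomass, params, irradiance)
        else:  # no nitrate at all: every resource argument says root
            g_r, pn_r = params.g_min, math.inf
    else:
        pn_r = math.nan
    info = {"sigma_n_max": sigma_n_max, "pla": pla, "g_r": g_r, "pn_r": pn_r,
            "photon_cap": params.daily_dose(irradiance) * pla}

    m = model.network.compiled()
    kr = model.key_reactions
    with m:
        photon = m.reactions.get_by_id(kr["photon_uptake"])
        photon.bounds = (0.0, info["photon_cap"] * MOL_TO_LP)
        maint = maintenance_values(params.atp_maint, params.nadph_maint,
                                   state.leaf_biomass, state.root_biomass)
        for sfx in SUFFIXES:
            m.reactions.get_by_id(kr[f"atpase_{sfx.lower()}"]).bounds = \
                (maint[sfx]["atp"], maint[sfx]["atp"])
            m.reactions.get_by_id(kr[f"nadph_oxidase_{sfx.lower()}"]).bounds = \
                (maint[sfx]["nadph"], maint[sfx]["nadph"])
        nd = m.reactions.get_by_id(kr["nitrate_uptake_day"])
        nn = m.reactions.get_by_id(kr["nitrate_uptake_night"])
        # the kinetic cap is additionally limited by the nitrate actually
        # present: the floor applied after the update is bookkeeping, never
        # a nitrate source, so the LP may not overdraw the soil pool
        cap = m.problem.Constraint(
            nd.flux_expression + nn.flux_expression,
            ub=min(sigma_n_max, state.nitrate) * MOL_TO_LP,
            name="_nitrate_day_cap")
        m.add_cons_vars(cap)
        bl = [m.reactions.get_by_id(kr["biomass_leaf_day"]),
              m.reactions.get_by_id(kr["biomass_leaf_night"])]
        br = [m.reactions.get_by_id(kr["biomass_root_day"]),
              m.reactions.get_by_id(kr["biomass_root_night"])]
        partition = m.problem.Constraint(
            (1.0 - g_r) * (bl[0].flux_expression + bl[1].flux_expression)
            - g_r * (br[0].flux_expression + br[1].flux_expression),
            lb=0.0, ub=0.0, name="_partition")
        m.add_cons_vars(partition)
        yield m, info


def solve_day(model: DielPlantModel, state: PlantState, params: GrowthParams,
              irradiance: Optional[float] = None) -> DaySolution:
    """Solve one day: maximize biomass synthesis, then minimize total flux."""
    with day_lp(model, state, params, irradiance) as (m, info):
        z = m.slim_optimize()
        if not math.isfinite(z):
            raise DayInfeasibleError(
                state.day,
                "daily LP infeasible "
                f"(sigma_N_max={info['sigma_n_max']:.3g} mol, "
                f"photon cap={info['photon_cap']:.3g} mol, "
                f"L_B={state.leaf_biomass:.3g} g, "
                f"R_B={state.root_biomass:.3g} g, g_r={info['g_r']:.3g})")
        floor = z - max(1e-12, 1e-9 * abs(z))
        solution = pfba_on(m, floor)
        if solution.status != "optimal":
            raise DayInfeasibleError(
                state.day, "parsimonious re-solve failed "
                f"({solution.status}) at floor {floor:.6g}")
        fluxes = {rid: float(solution.fluxes[rid])
                  for rid in solution.fluxes.index}
    kr = model.key_reactions
    flux = FluxSolution(fluxes, z, "optimal",
                        total_flux=sum(abs(v) for v in fluxes.values()))
    return DaySolution(
        g_r=info["g_r"],
        pn_r=info["pn_r"],
        sigma_n_max=info["sigma_n_max"],
        sigma_n_day=fluxes[kr["nitrate_uptake_day"]] / MOL_TO_LP,
        sigma_n_night=fluxes[kr["nitrate_uptake_night"]] / MOL_TO_LP,
        sigma_photon=fluxes[kr["photon_uptake"]] / MOL_TO_LP,
        sigma_leaf_day=fluxes[kr["biomass_leaf_day"]] / MOL_TO_LP,
        sigma_leaf_night=fluxes[kr["biomass_leaf_night"]] / MOL_TO_LP,
        sigma_root_day=fluxes[kr["biomass_root_day"]] / MOL_TO_LP,
        sigma_root_night=fluxes[kr["biomass_root_night"]] / MOL_TO_LP,
        flux_vector=flux,
    )


def advance_state(state: PlantState, sol: DaySolution,
                  params: GrowthParams) -> Tuple[PlantState, float, bool]:
    """Apply a day's growth and nitrate draw-down to the state.

    Returns ``(new_state, nitrate_raw, floored)`` where ``nitrate_raw``
    is the pre-floor nitrate balance; when uptake numerically overdraws
    the soil pool, the pool is projected back to the configured floor
    with a warning (the floor is bookkeeping, never an LP nitrate
    source).
    """
    raw = state.nitrate - sol.nitrate_uptake
    floored = raw < params.nitrate_floor
    if floored and raw < -1e-12:
        logger.warning(
            "day %d: nitrate uptake %.3g mol exceeds available %.3g mol; "
            "flooring soil nitrate at %.1g mol",
            state.day, sol.nitrate_uptake, state.nitrate, params.nitrate_floor)
    new_state = PlantState(
        state.day + 1,
        state.leaf_biomass + sol.leaf_growth,
        state.root_biomass + sol.root_growth,
        max(raw, params.nitrate_floor),
        state.m_slope,
    )
    return new_state, raw, floored


def run_growth(model: DielPlantModel, params: GrowthParams,
               perturbations: Sequence[PerturbationEvent] = ()) -> Trajectory:
    """Run the full day-by-day growth loop with optional perturbations.

    The initial state holds at ``start_day``; each subsequent day up to
    and including ``end_day`` is solved and applied. Perturbations
    overwrite leaf biomass, soil nitrate or irradiance at the start of
    their day (irradiance changes persist for the rest of the run).
    """
    for ev in perturbations:
        if not (params.start_day <= ev.day <= params.end_day):
            raise ValueError(
                f"perturbation day {ev.day} outside "
                f"[{params.start_day}, {params.end_day}]")
    by_day: Dict[int, List[PerturbationEvent]] = {}
    for ev in perturbations:
        by_day.setdefault(ev.day, []).append(ev)

    state = params.initial_state()
    irradiance = params.p_max_irradiance
    records: List[DayRecord] = []
    trajectory = Trajectory(state, records, params, metadata={
        "params_hash": params.hash(),
        "model_hash": model.model_hash(),
        "perturbations": json.dumps(
            [(e.day, e.kind, e.value) for e in perturbations]),
    })
    for day in range(params.start_day + 1, params.end_day + 1):
        state = replace(state, day=day)
        for ev in by_day.get(day, ()):
            if ev.kind == "set_leaf_biomass":
                state = replace(state, leaf_biomass=ev.value)
            elif ev.kind == "set_nitrate":
                state = replace(state, nitrate=ev.value)
            elif ev.kind == "set_irradiance":
                irradiance = ev.value
        try:
            sol = solve_day(model, state, params, irradiance)
        except DayInfeasibleError as err:
            err.trajectory = trajectory
            raise
        new_state, raw, floored = advance_state(state, sol, params)
        records.append(DayRecord(day, state, sol, new_state, raw, floored,
                                 irradiance))
        logger.info("day %d: AGR=%.4g g, g_r=%.3f, S=%.4g mol%s",
                    day, sol.total_growth, sol.g_r, new_state.nitrate,
                    " (floored)" if floored else "")
        state = new_state
    return trajectory


# -- sensitivity scan and day-level FVA --------------------------------

_SCANNABLE_RATIOS = ("phloem_light_dark", "nitrate_light_dark", "rubisco_c_to_o")


def run_sensitivity_scan(
    model: DielPlantModel,
    params: GrowthParams,
    parameter: str,
    values: Sequence[float],
    perturbations: Sequence[PerturbationEvent] = (),
    sign_reactions: Optional[Sequence[str]] = None,
) -> Tuple[List[Tuple[float, Trajectory]], pd.DataFrame]:
    """Re-run the growth loop varying one constraint parameter.

    ``parameter`` is one of the standing ratio classes
    (``phloem_light_dark``, ``nitrate_light_dark``, ``rubisco_c_to_o``)
    or ``initial_nitrate``. Returns the per-value trajectories and a
    qualitative sign-pattern table (sign of each monitored reaction's
    mean flux across days, one column per scan value). With no values the
    baseline trajectory alone is returned.
    """
    if parameter not in _SCANNABLE_RATIOS + ("initial_nitrate",):
        raise ValueError(f"unknown scan parameter {parameter}")
    if sign_reactions is None:
        sign_reactions = sorted(set(model.key_reactions.values()))
    runs: List[Tuple[float, Trajectory]] = []
    if not values:
        runs.append((math.nan, run_growth(model, params, perturbations)))
    for value in values:
        if parameter == "initial_nitrate":
            runs.append((value, run_growth(
                model, replace(params, initial_nitrate=value), perturbations)))
        else:
            config = model.standing_config or StandingConstraintConfig()
            scanned = apply_standing_constraints(
                model.copy(), replace(config, **{parameter: value}))
            runs.append((value, run_growth(scanned, params, perturbations)))
    table = {}
    for value, traj in runs:
        signs = {}
        for rid in sign_reactions:
            mean = sum(r.solution.flux_vector.fluxes.get(rid, 0.0)
                       for r in traj.records) / max(len(traj.records), 1)
            signs[rid] = "+" if mean > 1e-9 else ("-" if mean < -1e-9 else "0")
        table[value] = signs
    return runs, pd.DataFrame(table)


def fva_day(
    model: DielPlantModel,
    state: PlantState,
    params: GrowthParams,
    reaction_ids: Optional[Sequence[str]] = None,
    irradiance: Optional[float] = None,
    pfba_factor: Optional[float] = None,
    floor_fraction: float = 1.0 - 1e-6,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux variability under one day's constraints.

    The objective floor is ``floor_fraction`` of the day's biomass
    optimum. With ``pfba_factor`` set, the scan is restricted to
    (near-)parsimonious flux vectors; by default the full optimal space
    is scanned, so an interval excluding zero is exactly single-deletion
    essentiality at that floor.
    """
    if reaction_ids is None:
        reaction_ids = [r.id for r in model.network.reactions]
    result: Dict[str, Tuple[float, float]] = {}
    with day_lp(model, state, params, irradiance) as (m, info):
        z = m.slim_optimize()
        if not math.isfinite(z):
            raise DayInfeasibleError(state.day, "daily LP infeasible in FVA")
        floor = m.problem.Constraint(
            m.objective.expression, lb=floor_fraction * z, name="_fva_floor")
        m.add_cons_vars(floor)
        if pfba_factor is not None:
            m.objective = m.problem.Objective(Zero, direction="min", sloppy=True)
            coeffs = {}
            for rxn in m.reactions:
                coeffs[rxn.forward_variable] = 1.0
                coeffs[rxn.reverse_variable] = 1.0
            m.objective.set_linear_coefficients(coeffs)
            min_total = m.slim_optimize()
            cap = m.problem.Constraint(Zero, ub=pfba_factor * min_total,
                                       name="_fva_total_cap", sloppy=True)
            m.add_cons_vars(cap)
            m.solver.update()
            cap.set_linear_coefficients(coeffs)
        for rid in reaction_ids:
            rxn = m.reactions.get_by_id(rid)
            lohi = []
            for direction in ("min", "max"):
                m.objective = m.problem.Objective(
                    rxn.flux_expression, direction=direction, sloppy=True)
                value = m.slim_optimize()
                if not math.isfinite(value):
                    raise DayInfeasibleError(
                        state.day, f"FVA subproblem for {rid} did not solve")
                lohi.append(float(value))
            result[rid] = tuple(lohi)
    return result
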