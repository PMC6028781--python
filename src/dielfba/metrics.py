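"""Derived photosynthesis, partitioning and robustness metrics.

Per-day quantities computed from a solved day's flux vector:

* **quantum demand (QD)** -- photons absorbed per net CO2 fixed during
  the light phase (photon influx / leaf-day CO2 import),
* **assimilation quotient (AQ)** -- net CO2 fixed per net O2 released
  during the light phase; AQ approaches 1 as nitrate assimilation
  approaches zero, because reducing nitrate consumes photosynthetic
  reductant and releases O2 without fixing carbon,
* **C/N fixation and partitioning** -- the ratio of net carbon fixed in
  the light to whole-day nitrate uptake; the fraction of fixed carbon
  (counted as carbon atoms) exported from leaf to root through the
  phloem; the fraction of absorbed nitrate transported to the leaf,
* **storage turnover** -- daily light->dark minus dark->light transfer
  of a stored metabolite per gram of tissue,
* **essentiality** -- per-reaction FVA intervals at the day's biomass
  optimum; an interval excluding zero flags the reaction as essential
  (exactly equivalent to single-deletion lethality at that optimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .builder import DielPlantModel, TISSUES
from .growth import (
    DayRecord,
    DaySolution,
    GrowthParams,
    PlantState,
    Trajectory,
    day_lp,
    fva_day,
)
from .network import NetworkValidationError, is_essential_interval

__all__ = [
    "DayMetrics",
    "quantum_demand",
    "assimilation_quotient",
    "cn_partitioning",
    "day_metrics",
    "trajectory_metrics",
    "trajectory_correlation",
    "storage_turnover",
    "essential_reactions",
    "essentiality_over_days",
]

_FLUX_TOL = 1e-12


@dataclass
class DayMetrics:
    day: int
    qd: float
    aq: float
    c_fix_over_n_fix: float
    c_prop: float
    n_prop: float
    rl_ratio: float


def _flux(sol: DaySolution, rid: Optional[str]) -> float:
    if rid is None:
        return 0.0
    return sol.flux_vector.fluxes.get(rid, 0.0)


def quantum_demand(sol: DaySolution, model: DielPlantModel) -> float:
    """Photons per net CO2 fixed in the leaf during the light phase.

    Both fluxes are read from the same flux vector, so the ratio is
    independent of the flux unit. Returns NaN (missing) when there is no
    net carbon fixation.
    """
    co2 = _flux(sol, model.key_reactions.get("co2_leaf_day"))
    if co2 <= _FLUX_TOL:
        return math.nan
    return _flux(sol, model.key_reactions.get("photon_uptake")) / co2


def assimilation_quotient(sol: DaySolution, model: DielPlantModel) -> float:
    """Net CO2 fixed per net O2 released in the leaf during the light phase.

    O2 exchange is signed as import-positive, so net release is the
    negative of the exchange flux; NaN when no O2 is released.
    """
    co2 = _flux(sol, model.key_reactions.get("co2_leaf_day"))
    o2_release = -_flux(sol, model.key_reactions.get("o2_leaf_day"))
    if o2_release <= _FLUX_TOL:
        return math.nan
    return co2 / o2_release


def cn_partitioning(sol: DaySolution,
                    model: DielPlantModel) -> Tuple[float, float, float]:
    """(C_fix/N_fix, C_prop, N_prop) for one day.

    C_fix/N_fix divides the leaf-day CO2 import by the whole-day nitrate
    uptake. C_prop counts the carbon atoms of every common-pool species
    the leaf exports (both phases) relative to net carbon fixed. N_prop
    is the share of absorbed nitrate delivered to the leaf through the
    common pool (both phases).
    """
    co2 = _flux(sol, model.key_reactions.get("co2_leaf_day"))
    uptake = _flux(sol, model.key_reactions.get("nitrate_uptake_day")) \
        + _flux(sol, model.key_reactions.get("nitrate_uptake_night"))
    cfix_nfix = co2 / uptake if uptake > _FLUX_TOL else math.nan

    carbon_export = 0.0
    for spec in model.transport_specs:
        if spec.mode != "common_pool":
            continue
        atoms = model.carbon_atoms(spec.metabolite)
        if atoms <= 0:
            continue
        for phase in ("Day", "Night"):
            rid = model.cp_reactions.get((spec.metabolite, "Leaf", phase, "load"))
            carbon_export += atoms * _flux(sol, rid)
    c_prop = carbon_export / co2 if co2 > _FLUX_TOL else math.nan

    nitrate_to_leaf = 0.0
    target = model.key_reactions.get("nitrate_cp_to_leaf_day")
    no3 = next((met for (met, _, _, _), rid in model.cp_reactions.items()
                if rid == target), None)
    if no3 is not None:
        for phase in ("Day", "Night"):
            rid = model.cp_reactions.get((no3, "Leaf", phase, "unload"))
            nitrate_to_leaf += _flux(sol, rid)
    n_prop = nitrate_to_leaf / uptake if uptake > _FLUX_TOL else math.nan
    return cfix_nfix, c_prop, n_prop


def day_metrics(rec: DayRecord, model: DielPlantModel) -> DayMetrics:
    cfix_nfix, c_prop, n_prop = cn_partitioning(rec.solution, model)
    return DayMetrics(
        day=rec.day,
        qd=quantum_demand(rec.solution, model),
        aq=assimilation_quotient(rec.solution, model),
        c_fix_over_n_fix=cfix_nfix,
        c_prop=c_prop,
        n_prop=n_prop,
        rl_ratio=rec.state_start.rl_ratio,
    )


def trajectory_metrics(traj: Trajectory, model: DielPlantModel) -> pd.DataFrame:
    """Tidy per-day metric table for a whole run."""
    rows = []
    for rec in traj.records:
        dm = day_metrics(rec, model)
        rows.append({
            "day": dm.day, "QD": dm.qd, "AQ": dm.aq,
            "C_fix_over_N_fix": dm.c_fix_over_n_fix,
            "C_prop": dm.c_prop, "N_prop": dm.n_prop,
            "RL_ratio": dm.rl_ratio, "g_r": rec.solution.g_r,
        })
    return pd.DataFrame(rows)


def trajectory_correlation(metrics_df: pd.DataFrame, x: str,
                           y: str) -> Tuple[float, float]:
    """Pearson r and two-sided t-test p-value between two day-indexed metrics."""
    pairs = metrics_df[[x, y]].dropna()
    if len(pairs) < 3:
        raise ValueError(
            f"correlation of {x} vs {y} needs >= 3 defined days, "
            f"got {len(pairs)}")
    for col in (x, y):
        if pairs[col].nunique() == 1:
            raise ValueError(f"{col} is constant; correlation undefined")
    r, p = stats.pearsonr(pairs[x], pairs[y])
    return float(r), float(p)


def storage_turnover(traj: Trajectory, model: DielPlantModel,
                     metabolite: str, tissue: str) -> pd.Series:
    """Daily net light-phase accumulation of a stored metabolite.

    Light->dark transfer minus dark->light transfer, per gram of the
    tissue's start-of-day biomass. Linker fluxes are on the LP scale
    (mmol per phase), so the series is in mmol per gDW per day.
    """
    key = (metabolite, tissue)
    if key not in model.storage_reactions:
        raise NetworkValidationError(
            f"no storage linker for {metabolite} in {tissue}")
    linker = model.storage_reactions[key]
    deltas = {}
    for rec in traj.records:
        mass = (rec.state_start.leaf_biomass if tissue == "Leaf"
                else rec.state_start.root_biomass)
        d2n = _flux(rec.solution, linker["d2n"])
        n2d = _flux(rec.solution, linker["n2d"])
        deltas[rec.day] = (d2n - n2d) / mass
    return pd.Series(deltas, name=f"{metabolite}_{tissue}_delta")


def essential_reactions(
    model: DielPlantModel,
    state: PlantState,
    params: GrowthParams,
    reaction_ids: Optional[Sequence[str]] = None,
    irradiance: Optional[float] = None,
    parsimonious_factor: Optional[float] = None,
) -> pd.DataFrame:
    """FVA intervals and essentiality flags under one day's constraints.

    ``essential`` is computed on the unrestricted optimal space (interval
    excluding zero, equivalent to single-deletion lethality at the day's
    optimum). Reactions whose own bounds force nonzero flux under the
    day's constraints -- the equality-fixed maintenance sinks -- are
    reported as ``forced`` instead: their pinned interval reflects their
    bounds, not a network requirement, and removing them does not impair
    growth. Passing ``parsimonious_factor`` additionally restricts the
    scan to near-minimum-total-flux vectors, reporting which reactions
    are always active in parsimonious optima.
    """
    intervals = fva_day(model, state, params, reaction_ids, irradiance,
                        pfba_factor=None)
    forced = {}
    with day_lp(model, state, params, irradiance) as (m, _):
        for rid in intervals:
            rxn = m.reactions.get_by_id(rid)
            forced[rid] = rxn.lower_bound > 1e-12 or rxn.upper_bound < -1e-12
    rows = {rid: {"min": lo, "max": hi,
                  "forced": forced[rid],
                  "essential": is_essential_interval((lo, hi))
                  and not forced[rid]}
            for rid, (lo, hi) in intervals.items()}
    if parsimonious_factor is not None:
        pins = fva_day(model, state, params, reaction_ids, irradiance,
                       pfba_factor=parsimonious_factor)
        for rid, (lo, hi) in pins.items():
            rows[rid]["p_min"] = lo
            rows[rid]["p_max"] = hi
            rows[rid]["always_active"] = is_essential_interval((lo, hi))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "reaction"
    return df


def essentiality_over_days(
    model: DielPlantModel,
    traj: Trajectory,
    params: GrowthParams,
    reaction_ids: Sequence[str],
    days: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Fraction of (selected) growth days on which each reaction is essential."""
    chosen = [r for r in traj.records if days is None or r.day in days]
    counts = {rid: 0 for rid in reaction_ids}
    for rec in chosen:
        df = essential_reactions(model, rec.state_start, params, reaction_ids,
                                 irradiance=rec.irradiance)
        for rid in reaction_ids:
            if df.loc[rid, "essential"]:
                counts[rid] += 1
    out = pd.DataFrame({
        "days_essential": pd.Series(counts),
        "days_checked": len(chosen),
    })
    out["fraction_essential"] = out["days_essential"] / max(len(chosen), 1)
    out.index.name = "reaction"
    return out
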