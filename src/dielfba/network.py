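"""Stoichiometric network container and the three LP primitives.

This module holds the in-memory representation of a constraint-based
metabolic network (metabolites, bounded reactions, flux-ratio rows) and the
three solver operations everything else in the package is built on:

* :func:`solve_fba` -- maximize the linear objective at steady state,
* :func:`minimize_total_flux` -- parsimonious selection of a flux vector
  (minimum sum of absolute fluxes) at a given objective floor,
* :func:`run_fva` -- per-reaction flux variability at a given objective
  floor, optionally under a parsimonious total-flux cap.

The LP itself is delegated to cobrapy/optlang (GLPK backend); this module
owns the network semantics: external (boundary) metabolites are exempt from
the steady-state balance, and ratio constraints are equality rows
``v_num - ratio * v_den = 0`` added on top of the stoichiometric rows.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import cobra
from optlang.symbolics import Zero

__all__ = [
    "MetaboliteSpec",
    "ReactionSpec",
    "RatioConstraint",
    "MetabolicNetwork",
    "FluxSolution",
    "NetworkValidationError",
    "SBMLFormatError",
    "read_sbml",
    "write_sbml",
    "solve_fba",
    "minimize_total_flux",
    "run_fva",
    "parse_formula",
]

#: Default bounds used when an SBML file carries no explicit flux bounds.
DEFAULT_BOUND = 1000.0

FEASIBILITY_TOL = 1e-9
#: Relative slack on the parsimonious total-flux cap inside FVA; an exact
#: equality is numerically brittle.
PFBA_RELATIVE_SLACK = 1e-6


class NetworkValidationError(ValueError):
    """A network, reaction or constraint references something that does not exist."""


class SBMLFormatError(ValueError):
    """The SBML input could not be parsed into a usable network."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse a molecular formula string into an element -> count map.

    Empty strings parse to an empty map; this is how massless species
    (photons) and abstract energy tokens (ATP/NADPH treated as carriers)
    participate in elemental audits without contributing atoms.
    """
    counts: Dict[str, float] = {}
    if not formula:
        return counts
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class MetaboliteSpec:
    """A metabolite; external species are unbalanced boundary pools."""

    id: str
    compartment: str = "c"
    is_external: bool = False
    formula: str = ""


@dataclass
class ReactionSpec:
    """A bounded reaction; negative stoichiometric coefficients consume."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id}: empty stoichiometry")


@dataclass
class RatioConstraint:
    """Equality row ``flux(numerator) = ratio * flux(denominator)``."""

    numerator_reaction: str
    denominator_reaction: str
    ratio: float
    tag: str = ""

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise NetworkValidationError(
                f"ratio constraint {self.numerator_reaction}/"
                f"{self.denominator_reaction}: ratio must be positive"
            )


@dataclass
class FluxSolution:
    """An LP outcome: per-reaction fluxes plus the primary objective value."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str
    total_flux: Optional[float] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction\tflux\n")
            for rid in sorted(self.fluxes):
                fh.write(f"{rid}\t{self.fluxes[rid]:.12g}\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "status": self.status,
                    "objective_value": self.objective_value,
                    "total_flux": self.total_flux,
                    "fluxes": self.fluxes,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


class MetabolicNetwork:
    """A stoichiometric network with bounds, objective and ratio rows."""

    def __init__(
        self,
        metabolites: Iterable[MetaboliteSpec] = (),
        reactions: Iterable[ReactionSpec] = (),
        ratio_constraints: Iterable[RatioConstraint] = (),
        id: str = "network",
    ) -> None:
        self.id = id
        self.metabolites: List[MetaboliteSpec] = list(metabolites)
        self.reactions: List[ReactionSpec] = list(reactions)
        self.ratio_constraints: List[RatioConstraint] = list(ratio_constraints)
        self._cobra: Optional[cobra.Model] = None
        self.validate()

    # -- bookkeeping ---------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            raise NetworkValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            raise NetworkValidationError("duplicate reaction ids")
        known = set(met_ids)
        for rxn in self.reactions:
            for mid in rxn.stoichiometry:
                if mid not in known:
                    raise NetworkValidationError(
                        f"reaction {rxn.id} references unknown metabolite {mid}"
                    )
        known_rxn = set(rxn_ids)
        for rc in self.ratio_constraints:
            for rid in (rc.numerator_reaction, rc.denominator_reaction):
                if rid not in known_rxn:
                    raise NetworkValidationError(
                        f"ratio constraint references unknown reaction {rid}"
                    )

    @property
    def metabolite_ids(self) -> set:
        return {m.id for m in self.metabolites}

    @property
    def reaction_ids(self) -> set:
        return {r.id for r in self.reactions}

    def metabolite(self, mid: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def add_metabolite(self, met: MetaboliteSpec) -> None:
        if met.id in self.metabolite_ids:
            raise NetworkValidationError(f"duplicate metabolite {met.id}")
        self.metabolites.append(met)
        self._cobra = None

    def add_reaction(self, rxn: ReactionSpec) -> None:
        if rxn.id in self.reaction_ids:
            raise NetworkValidationError(f"duplicate reaction {rxn.id}")
        missing = set(rxn.stoichiometry) - self.metabolite_ids
        if missing:
            raise NetworkValidationError(
                f"reaction {rxn.id} references unknown metabolites {sorted(missing)}"
            )
        self.reactions.append(rxn)
        self._cobra = None

    def add_ratio_constraint(self, rc: RatioConstraint) -> None:
        for rid in (rc.numerator_reaction, rc.denominator_reaction):
            if rid not in self.reaction_ids:
                raise NetworkValidationError(
                    f"ratio constraint references unknown reaction {rid}"
                )
        self.ratio_constraints.append(rc)
        self._cobra = None

    def set_ratio_constraints(self, rcs: Iterable[RatioConstraint]) -> None:
        self.ratio_constraints = []
        for rc in rcs:
            self.add_ratio_constraint(rc)
        self._cobra = None

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=[MetaboliteSpec(m.id, m.compartment, m.is_external, m.formula)
                         for m in self.metabolites],
            reactions=[ReactionSpec(r.id, dict(r.stoichiometry), r.lower_bound,
                                    r.upper_bound, r.objective_coefficient)
                       for r in self.reactions],
            ratio_constraints=[RatioConstraint(rc.numerator_reaction,
                                               rc.denominator_reaction, rc.ratio, rc.tag)
                               for rc in self.ratio_constraints],
            id=self.id,
        )

    def structural_hash(self) -> str:
        """Deterministic digest of the full network structure."""
        payload = {
            "metabolites": sorted(
                (m.id, m.compartment, m.is_external, m.formula) for m in self.metabolites
            ),
            "reactions": sorted(
                (r.id, sorted(r.stoichiometry.items()), r.lower_bound,
                 r.upper_bound, r.objective_coefficient)
                for r in self.reactions
            ),
            "ratios": sorted(
                (rc.numerator_reaction, rc.denominator_reaction, rc.ratio)
                for rc in self.ratio_constraints
            ),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()

    # -- compilation ---------------------------------------------------

    def compiled(self) -> cobra.Model:
        """Compile (and cache) the network into a cobra/optlang model.

        External metabolites are dropped from the compiled stoichiometry:
        they are boundary pools, so no steady-state row is generated for
        them. Ratio constraints become extra equality rows on the solver.
        """
        if self._cobra is not None:
            return self._cobra
        model = cobra.Model(self.id)
        model.solver = "glpk"
        # the default GLPK feasibility tolerance (1e-7) is too loose for
        # seedling-scale fluxes (down to ~1e-7 mol/phase)
        model.solver.configuration.tolerances.feasibility = FEASIBILITY_TOL
        internal = {
            m.id: cobra.Metabolite(m.id, compartment=m.compartment,
                                   formula=m.formula or None)
            for m in self.metabolites
            if not m.is_external
        }
        rxns = []
        for spec in self.reactions:
            rxn = cobra.Reaction(spec.id,
                                 lower_bound=spec.lower_bound,
                                 upper_bound=spec.upper_bound)
            rxns.append(rxn)
        model.add_reactions(rxns)
        for spec, rxn in zip(self.reactions, rxns):
            coeffs = {internal[mid]: c for mid, c in spec.stoichiometry.items()
                      if mid in internal}
            if coeffs:
                rxn.add_metabolites(coeffs)
        obj_expr = Zero
        for spec in self.reactions:
            if spec.objective_coefficient:
                rxn = model.reactions.get_by_id(spec.id)
                obj_expr = obj_expr + spec.objective_coefficient * rxn.flux_expression
        # non-sloppy on purpose: the objective expression is later reused
        # verbatim as the floor constraint in parsimonious re-solves
        model.objective = model.problem.Objective(obj_expr, direction="max")
        for i, rc in enumerate(self.ratio_constraints):
            num = model.reactions.get_by_id(rc.numerator_reaction)
            den = model.reactions.get_by_id(rc.denominator_reaction)
            cons = model.problem.Constraint(
                num.flux_expression - rc.ratio * den.flux_expression,
                lb=0.0, ub=0.0, name=f"ratio_{i}_{rc.tag or rc.numerator_reaction}",
            )
            model.add_cons_vars(cons)
        model.solver.update()
        self._cobra = model
        return model

    def objective_value_of(self, fluxes: Mapping[str, float]) -> float:
        return sum(r.objective_coefficient * fluxes.get(r.id, 0.0)
                   for r in self.reactions if r.objective_coefficient)


# -- SBML I/O ----------------------------------------------------------


def read_sbml(path) -> MetabolicNetwork:
    """Read an SBML (L2/L3, FBC honored) model into a :class:`MetabolicNetwork`.

    Bounds default to [-1000, 1000] for reversible and [0, 1000] for
    irreversible reactions when the file does not specify them.
    """
    path = Path(path)
    if not path.exists():
        raise SBMLFormatError(f"SBML file not found: {path}")
    if path.stat().st_size == 0:
        raise SBMLFormatError(f"SBML file is empty: {path}")
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml/cobra raise a zoo of types here
        raise SBMLFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    mets = [MetaboliteSpec(m.id, m.compartment or "c", False, m.formula or "")
            for m in model.metabolites]
    rxns = []
    for r in model.reactions:
        lb = r.lower_bound if r.lower_bound is not None else (
            -DEFAULT_BOUND if r.reversibility else 0.0)
        ub = r.upper_bound if r.upper_bound is not None else DEFAULT_BOUND
        if not math.isfinite(lb):
            lb = -DEFAULT_BOUND
        if not math.isfinite(ub):
            ub = DEFAULT_BOUND
        rxns.append(ReactionSpec(
            r.id, {m.id: c for m, c in r.metabolites.items()},
            lb, ub, r.objective_coefficient,
        ))
    return MetabolicNetwork(mets, rxns, id=model.id or path.stem)


def write_sbml(net: MetabolicNetwork, path) -> None:
    """Write the network as SBML L3+FBC (external species are omitted)."""
    cobra.io.write_sbml_model(net.compiled(), str(path))


# -- solver primitives -------------------------------------------------


def _extract(model: cobra.Model, net: MetabolicNetwork,
             solution) -> FluxSolution:
    if solution.status != "optimal":
        return FluxSolution({}, math.nan, solution.status)
    fluxes = {rid: float(solution.fluxes[rid]) for rid in solution.fluxes.index}
    return FluxSolution(
        fluxes,
        net.objective_value_of(fluxes),
        "optimal",
        total_flux=float(sum(abs(v) for v in fluxes.values())),
    )


def solve_fba(net: MetabolicNetwork) -> FluxSolution:
    """Maximize the network objective subject to S v = 0, bounds, ratio rows."""
    if not any(r.objective_coefficient for r in net.reactions):
        raise NetworkValidationError("network has no objective coefficients")
    model = net.compiled()
    solution = model.optimize(raise_error=False)
    return _extract(model, net, solution)


def _total_flux_coefficients(model: cobra.Model) -> Dict:
    coeffs = {}
    for rxn in model.reactions:
        coeffs[rxn.forward_variable] = 1.0
        coeffs[rxn.reverse_variable] = 1.0
    return coeffs


def pfba_on(model: cobra.Model, objective_floor: float):
    """Minimize total |flux| on an already-configured cobra model.

    Must be called inside a ``with model:`` context or on a throwaway
    model: it replaces the objective and adds a floor constraint. The
    original objective expression is constrained to stay at or above
    ``objective_floor`` (the optlang split into forward/reverse variables
    is exactly the nonnegative-part decomposition of each flux).
    """
    floor = model.problem.Constraint(
        model.objective.expression, lb=objective_floor, name="_objective_floor")
    model.add_cons_vars(floor)
    model.objective = model.problem.Objective(Zero, direction="min", sloppy=True)
    model.objective.set_linear_coefficients(_total_flux_coefficients(model))
    return model.optimize(raise_error=False)


def minimize_total_flux(net: MetabolicNetwork,
                        objective_floor: float) -> FluxSolution:
    """Parsimonious flux vector: min sum |v| with objective >= floor."""
    model = net.compiled()
    with model:
        solution = pfba_on(model, objective_floor)
        return _extract(model, net, solution)


def run_fva(
    net: MetabolicNetwork,
    objective_floor: float,
    reaction_ids: Iterable[str],
    pfba_factor: Optional[float] = 1.0 + PFBA_RELATIVE_SLACK,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability under an objective floor.

    With ``pfba_factor`` set (the default), the total absolute flux is
    additionally capped at ``pfba_factor`` times its minimum before the
    per-reaction scan, reproducing variability among (near-)parsimonious
    optima. With ``pfba_factor=None`` the scan explores every flux vector
    attaining the objective floor; an interval excluding zero then marks a
    reaction whose removal makes the floor unattainable (deletion
    essentiality).
    """
    reaction_ids = list(reaction_ids)
    if not reaction_ids:
        return {}
    model = net.compiled()
    unknown = set(reaction_ids) - net.reaction_ids
    if unknown:
        raise NetworkValidationError(f"FVA over unknown reactions {sorted(unknown)}")
    result: Dict[str, Tuple[float, float]] = {}
    with model:
        floor = model.problem.Constraint(
            model.objective.expression, lb=objective_floor, name="_objective_floor")
        model.add_cons_vars(floor)
        if pfba_factor is not None:
            model.objective = model.problem.Objective(
                Zero, direction="min", sloppy=True)
            model.objective.set_linear_coefficients(
                _total_flux_coefficients(model))
            min_total = model.slim_optimize()
            if not math.isfinite(min_total):
                raise NetworkValidationError(
                    "objective floor is not attainable in FVA")
            cap = model.problem.Constraint(Zero, ub=pfba_factor * min_total,
                                           name="_total_flux_cap", sloppy=True)
            model.add_cons_vars(cap)
            model.solver.update()
            cap.set_linear_coefficients(_total_flux_coefficients(model))
        for rid in reaction_ids:
            rxn = model.reactions.get_by_id(rid)
            bounds = []
            for direction in ("min", "max"):
                model.objective = model.problem.Objective(
                    rxn.flux_expression, direction=direction, sloppy=True)
                value = model.slim_optimize()
                if not math.isfinite(value):
                    raise NetworkValidationError(
                        f"FVA subproblem for {rid} ({direction}) did not solve; "
                        "objective floor may be unattainable")
                bounds.append(float(value))
            result[rid] = (bounds[0], bounds[1])
    return result


def is_essential_interval(interval: Tuple[float, float],
                          tol: float = 1e-9) -> bool:
    """An FVA interval marks an essential reaction when it excludes zero."""
    lo, hi = interval
    return (lo > tol and hi > tol) or (lo < -tol and hi < -tol)
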