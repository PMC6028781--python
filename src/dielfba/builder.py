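"""Assembly of the four-module diel leaf/root plant model.

A single-tissue base network is duplicated into four labeled modules
(Leaf_Day, Leaf_Night, Root_Day, Root_Night). The modules are then wired
together:

* a phloem *common pool* (CP), one shared species per transported
  metabolite per phase, through which leaf and root exchange sucrose,
  nitrate, sulfate, phosphate and amino acids; loading into the pool is
  charged an active proton-pump cost (ATP per pumped proton),
* diel *storage* linkers that let carbohydrates, organic acids and nitrate
  accumulate between the light and dark phase of each tissue (amino acids
  may only be stored in the light and used in the dark),
* one biomass drain per module, normalized so unit flux produces one gram
  of tissue dry weight,
* the standing flux-ratio constraints: phloem export 3:1 light:dark,
  nitrate uptake 3:2 light:dark, rubisco carboxylase:oxygenase 3:1.

Exchanges are placed by policy: photon uptake only in Leaf_Day, mineral
(nitrate) uptake only in the root modules, CO2/O2 exchange everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .network import (
    MetabolicNetwork,
    MetaboliteSpec,
    NetworkValidationError,
    RatioConstraint,
    ReactionSpec,
    parse_formula,
)

__all__ = [
    "SUFFIXES",
    "TISSUES",
    "PHASES",
    "ModuleLabel",
    "BiomassComposition",
    "TransportSpec",
    "StandingConstraintConfig",
    "DielPlantModel",
    "expand_to_diel_multitissue",
    "add_storage_linker",
    "apply_standing_constraints",
    "set_maintenance",
    "maintenance_values",
]

TISSUES = ("Leaf", "Root")
PHASES = ("Day", "Night")
SUFFIXES = ("Leaf_Day", "Leaf_Night", "Root_Day", "Root_Night")

#: Default bound for constructed wiring reactions. The compiled LP works in
#: mmol (metabolite fluxes) and mg (biomass fluxes) per phase -- a scale on
#: which seedling-size problems stay well-conditioned for the simplex -- so
#: wiring bounds must accommodate mature-plant fluxes of order 1e3 mmol.
BIG = 1.0e6


@dataclass(frozen=True)
class ModuleLabel:
    tissue: str
    phase: str

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise NetworkValidationError(f"unknown tissue {self.tissue}")
        if self.phase not in PHASES:
            raise NetworkValidationError(f"unknown phase {self.phase}")

    @property
    def suffix(self) -> str:
        return f"{self.tissue}_{self.phase}"


@dataclass
class BiomassComposition:
    """Per-tissue biomass recipe, g-normalized.

    ``components`` maps metabolite id to a positive stoichiometric
    coefficient in mol per gram dry weight, so that unit flux through the
    biomass reaction drains exactly one gram of tissue. ``molar_masses``
    (g/mol) lets :meth:`check_normalization` audit that the coefficients
    indeed sum to one gram.
    """

    tissue: str
    components: Dict[str, float]
    molar_masses: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise NetworkValidationError(f"unknown tissue {self.tissue}")
        for mid, coef in self.components.items():
            if coef <= 0:
                raise NetworkValidationError(
                    f"biomass component {mid}: coefficient must be positive")

    def gram_total(self) -> float:
        return sum(c * self.molar_masses[m] for m, c in self.components.items())

    def check_normalization(self, rel_tol: float = 0.01) -> None:
        if not self.molar_masses:
            return
        total = self.gram_total()
        if abs(total - 1.0) > rel_tol:
            raise NetworkValidationError(
                f"{self.tissue} biomass composition sums to {total:.4f} g "
                "per unit flux, expected 1 g")


@dataclass
class TransportSpec:
    """Inter-module wiring declaration.

    ``mode='common_pool'`` declares a phloem-transportable metabolite;
    ``mode='storage'`` declares a diel storage metabolite. Storage
    direction ``light_to_dark_only`` is the amino-acid rule (stored in the
    light, used in the dark); everything else is ``bidirectional``.
    ``proton_cost`` is the number of protons actively pumped per molecule
    loaded into the common pool (charged as ATP, see module docstring).
    ``day_night_ratio_constrained`` marks common-pool species whose export
    is subject to the 3:1 light:dark phloem ratio (sucrose and amino
    acids, but not nitrate).
    """

    metabolite: str
    mode: str
    direction: str = "bidirectional"
    proton_cost: int = 1
    day_night_ratio_constrained: bool = True

    def __post_init__(self):
        if self.mode not in ("common_pool", "storage"):
            raise NetworkValidationError(f"unknown transport mode {self.mode}")
        if self.direction not in ("bidirectional", "light_to_dark_only"):
            raise NetworkValidationError(f"unknown direction {self.direction}")
        if self.proton_cost < 0:
            raise NetworkValidationError("proton cost must be nonnegative")


@dataclass
class StandingConstraintConfig:
    """The standing flux-ratio constraint set.

    Defaults follow the reference constraint scheme: phloem export
    3:1 light:dark, nitrate uptake 3:2 light:dark, rubisco
    carboxylase:oxygenase 3:1. ``aa_composition`` optionally pins each
    amino acid's phloem export to a fixed ratio against sucrose export.
    """

    phloem_light_dark: float = 3.0
    nitrate_light_dark: float = 1.5
    rubisco_c_to_o: float = 3.0
    aa_composition: Optional[Dict[str, float]] = None


class DielPlantModel:
    """The assembled four-module network plus wiring bookkeeping."""

    def __init__(
        self,
        network: MetabolicNetwork,
        key_reactions: Dict[str, str],
        transport_specs: List[TransportSpec],
        cp_reactions: Dict[Tuple[str, str, str, str], str],
        storage_reactions: Dict[Tuple[str, str], Dict[str, Optional[str]]],
        formulas: Dict[str, str],
        compositions: Dict[str, BiomassComposition],
        build_report: Dict,
        standing_config: Optional[StandingConstraintConfig] = None,
    ) -> None:
        self.network = network
        self.key_reactions = key_reactions
        self.transport_specs = transport_specs
        #: (metabolite, tissue, phase, 'load'|'unload') -> reaction id
        self.cp_reactions = cp_reactions
        #: (metabolite, tissue) -> {'d2n': id, 'n2d': id or None}
        self.storage_reactions = storage_reactions
        self.formulas = formulas
        self.compositions = compositions
        self.build_report = build_report
        self.standing_config = standing_config

    def copy(self) -> "DielPlantModel":
        return DielPlantModel(
            self.network.copy(),
            dict(self.key_reactions),
            list(self.transport_specs),
            dict(self.cp_reactions),
            {k: dict(v) for k, v in self.storage_reactions.items()},
            dict(self.formulas),
            dict(self.compositions),
            json.loads(json.dumps(self.build_report)),
            self.standing_config,
        )

    def model_hash(self) -> str:
        return self.network.structural_hash()

    def carbon_atoms(self, metabolite: str) -> float:
        return parse_formula(self.formulas.get(metabolite, "")).get("C", 0.0)

    def write_build_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.build_report, fh, indent=1, sort_keys=True)

    def module_metabolite_sets(self) -> Dict[str, set]:
        """Base-metabolite copies present per module (for isolation checks)."""
        out = {sfx: set() for sfx in SUFFIXES}
        for met in self.network.metabolites:
            for sfx in SUFFIXES:
                if met.id.endswith("_" + sfx):
                    out[sfx].add(met.id)
        return out

    def reaction_modules(self) -> Dict[str, set]:
        """Map module suffix -> reaction ids whose metabolites touch it."""
        met_mod = {}
        for sfx, mets in self.module_metabolite_sets().items():
            for mid in mets:
                met_mod[mid] = sfx
        out = {sfx: set() for sfx in SUFFIXES}
        for rxn in self.network.reactions:
            for mid in rxn.stoichiometry:
                if mid in met_mod:
                    out[met_mod[mid]].add(rxn.id)
        return out


def _suffixed(base_id: str, suffix: str) -> str:
    return f"{base_id}_{suffix}"


def expand_to_diel_multitissue(
    base: MetabolicNetwork,
    leaf_bm: BiomassComposition,
    root_bm: BiomassComposition,
    transports: Sequence[TransportSpec],
    *,
    exchange_policy: Optional[Mapping[str, Sequence[str]]] = None,
    key_roles: Optional[Mapping[str, str]] = None,
    atp_id: str = "ATP",
    adp_id: str = "ADP",
    allowed_cp: Optional[Iterable[str]] = None,
) -> DielPlantModel:
    """Duplicate, label and wire a base network into a diel plant model.

    ``exchange_policy`` maps a base reaction id to the module suffixes in
    which its copy is kept (e.g. photon uptake only in ``Leaf_Day``);
    unlisted reactions appear in all four modules. ``key_roles`` names the
    base reactions/metabolites playing the framework roles (photon, co2,
    o2, nitrate exchange; rbc, rbo, atpase, nadph_oxidase reactions;
    sucrose and nitrate metabolites) so key reactions can be resolved
    after suffixing.
    """
    exchange_policy = dict(exchange_policy or {})
    key_roles = dict(key_roles or {})
    formulas = {m.id: m.formula for m in base.metabolites}

    for spec in transports:
        if spec.metabolite not in base.metabolite_ids:
            raise NetworkValidationError(
                f"transport spec names unknown metabolite {spec.metabolite}")
    if allowed_cp is not None:
        allowed = set(allowed_cp)
        for spec in transports:
            if spec.mode == "common_pool" and spec.metabolite not in allowed:
                raise NetworkValidationError(
                    f"{spec.metabolite} is not an allowed common-pool metabolite")
    for bm in (leaf_bm, root_bm):
        missing = set(bm.components) - base.metabolite_ids
        if missing:
            raise NetworkValidationError(
                f"{bm.tissue} biomass components missing from base: {sorted(missing)}")
        bm.check_normalization()
    for rid in exchange_policy:
        if rid not in base.reaction_ids:
            raise NetworkValidationError(
                f"exchange policy names unknown reaction {rid}")

    net = MetabolicNetwork(id=f"{base.id}_diel")
    # 1. duplicate metabolites and reactions into the four modules
    for sfx in SUFFIXES:
        for met in base.metabolites:
            net.add_metabolite(MetaboliteSpec(
                _suffixed(met.id, sfx), met.compartment, met.is_external,
                met.formula))
    n_core = 0
    n_removed = 0
    for sfx in SUFFIXES:
        for rxn in base.reactions:
            allowed_sfx = exchange_policy.get(rxn.id)
            if allowed_sfx is not None and sfx not in allowed_sfx:
                n_removed += 1
                continue
            net.add_reaction(ReactionSpec(
                _suffixed(rxn.id, sfx),
                {_suffixed(m, sfx): c for m, c in rxn.stoichiometry.items()},
                rxn.lower_bound, rxn.upper_bound, 0.0))
            n_core += 1

    # 2. common pool
    cp_reactions: Dict[Tuple[str, str, str, str], str] = {}
    n_cp_species = 0
    n_cp_reactions = 0
    for spec in transports:
        if spec.mode != "common_pool":
            continue
        met = spec.metabolite
        if spec.proton_cost > 0 and (atp_id not in base.metabolite_ids
                                     or adp_id not in base.metabolite_ids):
            raise NetworkValidationError(
                "common-pool proton-pump cost requires ATP/ADP species in the base")
        for phase in PHASES:
            cp_id = f"{met}_CP_{phase}"
            net.add_metabolite(MetaboliteSpec(cp_id, "phloem", False,
                                              formulas.get(met, "")))
            formulas[cp_id] = formulas.get(met, "")
            n_cp_species += 1
            for tissue in TISSUES:
                sfx = f"{tissue}_{phase}"
                stoich = {_suffixed(met, sfx): -1.0, cp_id: 1.0}
                if spec.proton_cost > 0:
                    stoich[_suffixed(atp_id, sfx)] = -float(spec.proton_cost)
                    stoich[_suffixed(adp_id, sfx)] = float(spec.proton_cost)
                load = f"{met}_{tissue}_to_CP_{phase}"
                net.add_reaction(ReactionSpec(load, stoich, 0.0, BIG))
                cp_reactions[(met, tissue, phase, "load")] = load
                unload = f"{met}_CP_to_{tissue}_{phase}"
                net.add_reaction(ReactionSpec(
                    unload, {cp_id: -1.0, _suffixed(met, sfx): 1.0}, 0.0, BIG))
                cp_reactions[(met, tissue, phase, "unload")] = unload
                n_cp_reactions += 2

    # 3. diel storage linkers
    model = DielPlantModel(
        net, {}, list(transports), cp_reactions, {}, formulas,
        {"Leaf": leaf_bm, "Root": root_bm}, {},
    )
    n_storage = 0
    for spec in transports:
        if spec.mode != "storage":
            continue
        for tissue in TISSUES:
            add_storage_linker(model, spec.metabolite, tissue, spec.direction)
            n_storage += 1 if spec.direction == "light_to_dark_only" else 2

    # 4. biomass reactions
    n_biomass = 0
    for tissue, bm in (("Leaf", leaf_bm), ("Root", root_bm)):
        for phase in PHASES:
            sfx = f"{tissue}_{phase}"
            rid = f"Biomass_{tissue}_{phase}_tx"
            net.add_reaction(ReactionSpec(
                rid,
                {_suffixed(m, sfx): -c for m, c in bm.components.items()},
                0.0, BIG, objective_coefficient=1.0))
            n_biomass += 1

    # 5. key reaction resolution
    key_reactions: Dict[str, str] = {
        "biomass_leaf_day": "Biomass_Leaf_Day_tx",
        "biomass_leaf_night": "Biomass_Leaf_Night_tx",
        "biomass_root_day": "Biomass_Root_Day_tx",
        "biomass_root_night": "Biomass_Root_Night_tx",
    }

    def _role(role: str, rid: str) -> None:
        if rid not in net.reaction_ids:
            raise NetworkValidationError(
                f"key reaction for role {role} not found: {rid}")
        key_reactions[role] = rid

    if "photon" in key_roles:
        _role("photon_uptake", _suffixed(key_roles["photon"], "Leaf_Day"))
    if "co2" in key_roles:
        _role("co2_leaf_day", _suffixed(key_roles["co2"], "Leaf_Day"))
    if "o2" in key_roles:
        _role("o2_leaf_day", _suffixed(key_roles["o2"], "Leaf_Day"))
    if "nitrate" in key_roles:
        _role("nitrate_uptake_day", _suffixed(key_roles["nitrate"], "Root_Day"))
        _role("nitrate_uptake_night", _suffixed(key_roles["nitrate"], "Root_Night"))
    if "rbc" in key_roles:
        _role("rbc_leaf_day", _suffixed(key_roles["rbc"], "Leaf_Day"))
    if "rbo" in key_roles:
        _role("rbo_leaf_day", _suffixed(key_roles["rbo"], "Leaf_Day"))
    for sfx in SUFFIXES:
        if "atpase" in key_roles:
            _role(f"atpase_{sfx.lower()}", _suffixed(key_roles["atpase"], sfx))
        if "nadph_oxidase" in key_roles:
            _role(f"nadph_oxidase_{sfx.lower()}",
                  _suffixed(key_roles["nadph_oxidase"], sfx))
    if "sucrose_met" in key_roles:
        suc = key_roles["sucrose_met"]
        if (suc, "Leaf", "Day", "load") in cp_reactions:
            key_reactions["sucrose_phloem_day"] = cp_reactions[(suc, "Leaf", "Day", "load")]
            key_reactions["sucrose_phloem_night"] = cp_reactions[(suc, "Leaf", "Night", "load")]
    if "nitrate_met" in key_roles:
        no3 = key_roles["nitrate_met"]
        if (no3, "Leaf", "Day", "unload") in cp_reactions:
            key_reactions["nitrate_cp_to_leaf_day"] = cp_reactions[(no3, "Leaf", "Day", "unload")]

    report = {
        "base_reactions": len(base.reactions),
        "base_metabolites": len(base.metabolites),
        "core_reactions": n_core,
        "exchange_copies_removed": n_removed,
        "common_pool_species": n_cp_species,
        "common_pool_reactions": n_cp_reactions,
        "storage_reactions": n_storage,
        "biomass_reactions": n_biomass,
        "total_reactions": len(net.reactions),
        "total_metabolites": len(net.metabolites),
        "count_formula": (
            "total_reactions = 4*base - removed_exchange_copies "
            "+ common_pool + storage + biomass"),
        "count_check": (
            4 * len(base.reactions) - n_removed + n_cp_reactions
            + n_storage + n_biomass),
    }
    assert report["count_check"] == report["total_reactions"]

    model.key_reactions = key_reactions
    model.build_report = report
    net.validate()
    return model


def add_storage_linker(model: DielPlantModel, metabolite: str, tissue: str,
                       direction: str = "bidirectional") -> DielPlantModel:
    """Add diel accumulation reactions for a metabolite in one tissue.

    The Day and Night copies are linked by irreversible transfer
    reactions: Day->Night always, Night->Day only when bidirectional.
    A transfer flux is the amount of the metabolite carried over the
    phase boundary, i.e. the store drawn down entirely in the opposite
    phase (steady state of the represented diel cycle).
    """
    if tissue not in TISSUES:
        raise NetworkValidationError(f"unknown tissue {tissue}")
    if direction not in ("bidirectional", "light_to_dark_only"):
        raise NetworkValidationError(f"unknown direction {direction}")
    if (metabolite, tissue) in model.storage_reactions:
        raise NetworkValidationError(
            f"duplicate storage linker for {metabolite} in {tissue}")
    day_id = _suffixed(metabolite, f"{tissue}_Day")
    night_id = _suffixed(metabolite, f"{tissue}_Night")
    for mid in (day_id, night_id):
        if mid not in model.network.metabolite_ids:
            raise NetworkValidationError(
                f"storage linker: metabolite {mid} not present")
    d2n = f"{metabolite}_{tissue}_store_light"
    model.network.add_reaction(ReactionSpec(
        d2n, {day_id: -1.0, night_id: 1.0}, 0.0, BIG))
    entry: Dict[str, Optional[str]] = {"d2n": d2n, "n2d": None}
    if direction == "bidirectional":
        n2d = f"{metabolite}_{tissue}_store_dark"
        model.network.add_reaction(ReactionSpec(
            n2d, {night_id: -1.0, day_id: 1.0}, 0.0, BIG))
        entry["n2d"] = n2d
    model.storage_reactions[(metabolite, tissue)] = entry
    return model


def apply_standing_constraints(
    model: DielPlantModel,
    config: Optional[StandingConstraintConfig] = None,
    *,
    rbc_base: Optional[str] = None,
    rbo_base: Optional[str] = None,
) -> DielPlantModel:
    """Install (or re-install) the standing ratio-constraint rows.

    Previously applied standing rows (tagged ``standing``) are replaced,
    so the same model can be re-constrained for sensitivity scans.
    """
    config = config or StandingConstraintConfig()
    net = model.network
    kept = [rc for rc in net.ratio_constraints if rc.tag != "standing"]
    rows: List[RatioConstraint] = []

    # phloem export light:dark per ratio-constrained CP metabolite/tissue
    for spec in model.transport_specs:
        if spec.mode != "common_pool" or not spec.day_night_ratio_constrained:
            continue
        for tissue in TISSUES:
            day = model.cp_reactions.get((spec.metabolite, tissue, "Day", "load"))
            night = model.cp_reactions.get((spec.metabolite, tissue, "Night", "load"))
            if day and night:
                rows.append(RatioConstraint(day, night, config.phloem_light_dark,
                                            tag="standing"))

    # nitrate uptake light:dark
    nd = model.key_reactions.get("nitrate_uptake_day")
    nn = model.key_reactions.get("nitrate_uptake_night")
    if nd and nn:
        rows.append(RatioConstraint(nd, nn, config.nitrate_light_dark,
                                    tag="standing"))
    else:
        raise NetworkValidationError(
            "standing constraints require resolved nitrate uptake reactions")

    # rubisco carboxylase:oxygenase in every module carrying both copies
    rbc = rbc_base or _strip_suffix(model.key_reactions.get("rbc_leaf_day"))
    rbo = rbo_base or _strip_suffix(model.key_reactions.get("rbo_leaf_day"))
    if rbc and rbo:
        for sfx in SUFFIXES:
            rbc_id, rbo_id = _suffixed(rbc, sfx), _suffixed(rbo, sfx)
            if {rbc_id, rbo_id} <= net.reaction_ids:
                rows.append(RatioConstraint(rbc_id, rbo_id, config.rubisco_c_to_o,
                                            tag="standing"))
    else:
        raise NetworkValidationError(
            "standing constraints require resolved rubisco reactions")

    # fixed phloem amino-acid composition against sucrose export
    if config.aa_composition:
        for aa, ratio in config.aa_composition.items():
            for phase in PHASES:
                aa_load = model.cp_reactions.get((aa, "Leaf", phase, "load"))
                suc_load = model.key_reactions.get(
                    "sucrose_phloem_day" if phase == "Day" else "sucrose_phloem_night")
                if aa_load is None or suc_load is None:
                    raise NetworkValidationError(
                        f"amino-acid composition: no phloem loading for {aa}")
                rows.append(RatioConstraint(aa_load, suc_load, ratio,
                                            tag="standing"))

    net.set_ratio_constraints(kept + rows)
    model.standing_config = config
    return model


def _strip_suffix(rid: Optional[str]) -> Optional[str]:
    if rid is None:
        return None
    for sfx in SUFFIXES:
        if rid.endswith("_" + sfx):
            return rid[: -len(sfx) - 1]
    return rid


def maintenance_values(atp_rate: float, nadph_rate: float,
                       leaf_mass: float, root_mass: float) -> Dict[str, Dict[str, float]]:
    """Per-module maintenance fluxes in mmol per phase.

    Rates are given in mmol per gram dry weight per day; half the daily
    requirement falls in each 12-h phase, scaled by the tissue mass (g).
    With the printed 7.27 mmol gDW-1 day-1 ATP requirement and a 1 g
    leaf, the leaf-day ATPase is fixed at 3.635 mmol per phase.
    """
    if atp_rate < 0 or nadph_rate < 0:
        raise NetworkValidationError("maintenance rates must be nonnegative")
    if leaf_mass < 0 or root_mass < 0:
        raise NetworkValidationError("tissue masses must be nonnegative")
    out = {}
    for sfx in SUFFIXES:
        mass = leaf_mass if sfx.startswith("Leaf") else root_mass
        out[sfx] = {
            "atp": 0.5 * atp_rate * mass,
            "nadph": 0.5 * nadph_rate * mass,
        }
    return out


def set_maintenance(model: DielPlantModel, atp_rate: float, nadph_rate: float,
                    leaf_mass: float, root_mass: float) -> DielPlantModel:
    """Equality-fix the generic ATPase and NADPH-oxidase maintenance fluxes."""
    values = maintenance_values(atp_rate, nadph_rate, leaf_mass, root_mass)
    net = model.network
    for sfx in SUFFIXES:
        for role, kind in (("atpase", "atp"), ("nadph_oxidase", "nadph")):
            rid = model.key_reactions.get(f"{role}_{sfx.lower()}")
            if rid is None:
                raise NetworkValidationError(
                    f"maintenance requires resolved {role} reaction in {sfx}")
            rxn = net.reaction(rid)
            value = values[sfx][kind]
            rxn.lower_bound = value
            rxn.upper_bound = value
    net._cobra = None
    return model
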