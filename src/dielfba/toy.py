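"""Synthetic toy plant network: the built-in test instance of the framework.

The generator emits a small single-tissue base network carrying the
minimal biology the framework exercises -- photon capture, rubisco
carboxylation/oxygenation, carbohydrate and organic-acid interconversion
and storage, nitrate reduction and GS/GOGAT-style ammonia assimilation,
generic ATPase / NADPH-oxidase maintenance sinks, and a three-component
biomass (carbohydrate, amino acid, organic acid) -- together with the
biomass compositions, phloem/storage transport declarations, exchange
placement policy and key-role map needed to expand it into the
four-module diel plant model.

Chemistry is simplified but strictly element-balanced (C, N, O, H audit
per reaction): energy carriers (ATP/ADP, NADPH/NADP) are atom-free
tokens, water and protons are external boundary species, and the
redox/energy stoichiometry (photons per ATP and NADPH, ATP and NADPH per
CO2 fixed, NADPH per nitrate reduced) is configurable, which gives the
theoretical minimum quantum demand a closed form
(:func:`min_quantum_demand`).

The toy model validates mechanics, invariants and oracles; it does not
reproduce genome-scale quantitative results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .builder import (
    BiomassComposition,
    DielPlantModel,
    StandingConstraintConfig,
    TransportSpec,
    apply_standing_constraints,
    expand_to_diel_multitissue,
)
from .growth import GrowthParams, PerturbationEvent
from .network import (
    MetabolicNetwork,
    MetaboliteSpec,
    NetworkValidationError,
    ReactionSpec,
    parse_formula,
)

__all__ = [
    "ToyModelSpec",
    "ToyBase",
    "Scenario",
    "make_toy_base",
    "build_toy_model",
    "make_reference_scenarios",
    "min_quantum_demand",
    "element_imbalances",
]

MOLAR_MASS = {"Glc": 180.156, "Glu": 147.129, "Mal": 134.087}

FORMULAS = {
    "Photon": "",
    "CO2": "CO2", "O2": "O2", "NO3": "NO3", "NH3": "NH3",
    "H2O": "H2O", "H": "H",
    "TP": "CH2O", "Glc": "C6H12O6", "Suc": "C12H22O11", "Starch": "C6H10O5",
    "Mal": "C4H6O5", "Cit": "C6H8O7", "OX2": "C5H6O5",
    "Glu": "C5H9NO4", "Gln": "C5H10N2O3",
    "ATP": "", "ADP": "", "NADPH": "", "NADP": "",
}

EXCHANGES = ("Photon_tx", "CO2_tx", "O2_tx", "NO3_tx")


@dataclass(frozen=True)
class ToyModelSpec:
    """Tunable structure of the synthetic base network.

    ``photons_per_atp`` / ``photons_per_nadph`` set the light-reaction
    stoichiometry; ``atp_per_co2`` / ``nadph_per_co2`` the carboxylation
    cost; ``nadph_per_no3`` the nitrate-to-ammonia reduction cost;
    ``resp_atp_per_glc`` the respiratory ATP yield. ``n_filler_reactions``
    pads the network with balanced two-species conversions that cannot
    carry steady-state flux (for count tests). Biomass fractions are mass
    fractions of glucose / glutamate / malate per tissue and must sum
    to 1.
    """

    n_filler_reactions: int = 10
    photons_per_atp: float = 1.0
    photons_per_nadph: float = 2.0
    atp_per_co2: float = 1.0
    nadph_per_co2: float = 2.0
    rbo_atp: float = 1.0
    nadph_per_no3: float = 4.0
    resp_atp_per_glc: float = 30.0
    leaf_fractions: Tuple[float, float, float] = (0.70, 0.20, 0.10)
    root_fractions: Tuple[float, float, float] = (0.60, 0.30, 0.10)
    proton_cost: int = 1

    def __post_init__(self):
        for fr in (self.leaf_fractions, self.root_fractions):
            if abs(sum(fr) - 1.0) > 1e-9 or min(fr) <= 0:
                raise NetworkValidationError(
                    "biomass mass fractions must be positive and sum to 1")
        if min(self.photons_per_atp, self.photons_per_nadph, self.atp_per_co2,
               self.nadph_per_co2, self.nadph_per_no3,
               self.resp_atp_per_glc) <= 0:
            raise NetworkValidationError(
                "energy stoichiometry parameters must be positive")
        if self.n_filler_reactions < 0:
            raise NetworkValidationError("filler count must be nonnegative")


@dataclass
class ToyBase:
    """Generator output: base network plus everything the builder needs."""

    network: MetabolicNetwork
    leaf_biomass: BiomassComposition
    root_biomass: BiomassComposition
    transports: List[TransportSpec]
    exchange_policy: Dict[str, Tuple[str, ...]]
    key_roles: Dict[str, str]
    spec: ToyModelSpec


def _composition(tissue: str, fractions: Sequence[float]) -> BiomassComposition:
    comps = {}
    for met, frac in zip(("Glc", "Glu", "Mal"), fractions):
        comps[met] = frac / MOLAR_MASS[met]
    return BiomassComposition(tissue, comps, dict(MOLAR_MASS))


def make_toy_base(spec: Optional[ToyModelSpec] = None,
                  seed: int = 0) -> ToyBase:
    """Generate the deterministic synthetic base network.

    The same seed always yields the same network (the seed only shuffles
    the wiring of the inert filler chain). Every non-exchange reaction is
    element-balanced; growth is feasible exactly when both photons and
    nitrate are available.
    """
    spec = spec or ToyModelSpec()
    s = spec
    mets = [MetaboliteSpec(mid, "c", mid in ("H2O", "H"), formula)
            for mid, formula in FORMULAS.items()]
    rxns: List[ReactionSpec] = [
        # exchanges (import-positive)
        ReactionSpec("Photon_tx", {"Photon": 1.0}, 0.0, 1.0e6),
        ReactionSpec("CO2_tx", {"CO2": 1.0}, -1.0e6, 1.0e6),
        ReactionSpec("O2_tx", {"O2": 1.0}, -1.0e6, 1.0e6),
        ReactionSpec("NO3_tx", {"NO3": 1.0}, 0.0, 1.0e6),
        # light reactions: photophosphorylation and water splitting
        ReactionSpec("LightATP",
                     {"Photon": -s.photons_per_atp, "ADP": -1.0, "ATP": 1.0},
                     0.0, 1.0e6),
        ReactionSpec("LightNADPH",
                     {"Photon": -s.photons_per_nadph, "NADP": -1.0,
                      "H2O": -1.0, "NADPH": 1.0, "O2": 0.5, "H": 2.0},
                     0.0, 1.0e6),
        # rubisco carboxylase: CO2 -> triose unit (CH2O)
        ReactionSpec("RBC",
                     {"CO2": -1.0, "ATP": -s.atp_per_co2,
                      "NADPH": -s.nadph_per_co2, "H": -4.0,
                      "TP": 1.0, "H2O": 1.0, "ADP": s.atp_per_co2,
                      "NADP": s.nadph_per_co2},
                     0.0, 1.0e6),
        # rubisco oxygenase: photorespiratory carbon loss
        ReactionSpec("RBO",
                     {"TP": -1.0, "O2": -1.0, "ATP": -s.rbo_atp,
                      "CO2": 1.0, "H2O": 1.0, "ADP": s.rbo_atp},
                     0.0, 1.0e6),
        # carbohydrate interconversion
        ReactionSpec("GlcSyn", {"TP": -6.0, "ATP": -1.0,
                                "Glc": 1.0, "ADP": 1.0}, 0.0, 1.0e6),
        ReactionSpec("SucSyn", {"Glc": -2.0, "ATP": -1.0,
                                "Suc": 1.0, "H2O": 1.0, "ADP": 1.0},
                     0.0, 1.0e6),
        ReactionSpec("SucDeg", {"Suc": -1.0, "H2O": -1.0, "Glc": 2.0},
                     0.0, 1.0e6),
        ReactionSpec("StarchSyn", {"Glc": -1.0, "ATP": -1.0,
                                   "Starch": 1.0, "H2O": 1.0, "ADP": 1.0},
                     0.0, 1.0e6),
        ReactionSpec("StarchDeg", {"Starch": -1.0, "H2O": -1.0, "Glc": 1.0},
                     0.0, 1.0e6),
        # catabolism: respiration and the oxidative pentose phosphate route
        ReactionSpec("Resp",
                     {"Glc": -1.0, "O2": -6.0, "ADP": -s.resp_atp_per_glc,
                      "CO2": 6.0, "H2O": 6.0, "ATP": s.resp_atp_per_glc},
                     0.0, 1.0e6),
        ReactionSpec("OPP",
                     {"Glc": -1.0, "H2O": -6.0, "NADP": -12.0,
                      "CO2": 6.0, "NADPH": 12.0, "H": 24.0},
                     0.0, 1.0e6),
        # organic acids
        ReactionSpec("MalSyn", {"Glc": -1.0, "CO2": -2.0, "Mal": 2.0},
                     0.0, 1.0e6),
        ReactionSpec("MalResp",
                     {"Mal": -1.0, "O2": -3.0, "ADP": -12.0,
                      "CO2": 4.0, "H2O": 3.0, "ATP": 12.0},
                     0.0, 1.0e6),
        ReactionSpec("CitSyn", {"Mal": -1.0, "TP": -2.0, "O2": -0.5,
                                "Cit": 1.0, "H2O": 1.0}, 0.0, 1.0e6),
        ReactionSpec("CitOX", {"Cit": -1.0, "NADP": -1.0,
                               "OX2": 1.0, "CO2": 1.0, "NADPH": 1.0,
                               "H": 2.0}, 0.0, 1.0e6),
        # nitrogen assimilation: nitrate reduction then GS/GOGAT
        ReactionSpec("NR", {"NO3": -1.0, "NADPH": -s.nadph_per_no3,
                            "H": -9.0, "NH3": 1.0, "H2O": 3.0,
                            "NADP": s.nadph_per_no3}, 0.0, 1.0e6),
        ReactionSpec("GS", {"Glu": -1.0, "NH3": -1.0, "ATP": -1.0,
                            "Gln": 1.0, "H2O": 1.0, "ADP": 1.0},
                     0.0, 1.0e6),
        ReactionSpec("GOGAT", {"Gln": -1.0, "OX2": -1.0, "NADPH": -1.0,
                               "H": -2.0, "Glu": 2.0, "NADP": 1.0},
                     0.0, 1.0e6),
        # generic maintenance sinks
        ReactionSpec("ATPase_tx", {"ATP": -1.0, "ADP": 1.0}, 0.0, 1.0e6),
        ReactionSpec("NADPHox_tx", {"NADPH": -1.0, "O2": -0.5, "H": -2.0,
                                    "NADP": 1.0, "H2O": 1.0}, 0.0, 1.0e6),
    ]
    # inert filler: a seeded chain of balanced isomerizations with no
    # source or sink, so no steady-state flux can traverse it
    rng = np.random.default_rng(seed)
    n_filler_species = s.n_filler_reactions + 1 if s.n_filler_reactions else 0
    for i in range(n_filler_species):
        mets.append(MetaboliteSpec(f"F{i}", "c", False, "C2H4O2"))
    order = rng.permutation(max(n_filler_species, 1))
    for k in range(s.n_filler_reactions):
        a, b = f"F{order[k]}", f"F{order[k + 1]}"
        rxns.append(ReactionSpec(f"Filler_{k}", {a: -1.0, b: 1.0},
                                 -1.0e6, 1.0e6))

    net = MetabolicNetwork(mets, rxns, id=f"toy_base_seed{seed}")
    imbalance = element_imbalances(net)
    if imbalance:
        raise NetworkValidationError(
            f"toy base is not element-balanced: {imbalance}")

    transports = [
        TransportSpec("Suc", "common_pool", proton_cost=s.proton_cost),
        TransportSpec("Gln", "common_pool", proton_cost=s.proton_cost),
        TransportSpec("NO3", "common_pool", proton_cost=s.proton_cost,
                      day_night_ratio_constrained=False),
        TransportSpec("Starch", "storage"),
        TransportSpec("Glc", "storage"),
        TransportSpec("Suc", "storage"),
        TransportSpec("Mal", "storage"),
        TransportSpec("Cit", "storage"),
        TransportSpec("NO3", "storage"),
        TransportSpec("Gln", "storage", direction="light_to_dark_only"),
    ]
    exchange_policy = {
        "Photon_tx": ("Leaf_Day",),
        "NO3_tx": ("Root_Day", "Root_Night"),
    }
    key_roles = {
        "photon": "Photon_tx", "co2": "CO2_tx", "o2": "O2_tx",
        "nitrate": "NO3_tx", "rbc": "RBC", "rbo": "RBO",
        "atpase": "ATPase_tx", "nadph_oxidase": "NADPHox_tx",
        "sucrose_met": "Suc", "nitrate_met": "NO3",
    }
    return ToyBase(
        net,
        _composition("Leaf", s.leaf_fractions),
        _composition("Root", s.root_fractions),
        transports, exchange_policy, key_roles, s,
    )


def build_toy_model(spec: Optional[ToyModelSpec] = None, seed: int = 0,
                    constraints: Optional[StandingConstraintConfig] = None,
                    ) -> DielPlantModel:
    """Expand the toy base into the constrained four-module diel model."""
    base = make_toy_base(spec, seed)
    model = expand_to_diel_multitissue(
        base.network, base.leaf_biomass, base.root_biomass, base.transports,
        exchange_policy=base.exchange_policy, key_roles=base.key_roles,
        allowed_cp=("Suc", "SO4", "NO3", "Pi", "Gln", "Glu"),
    )
    return apply_standing_constraints(model, constraints)


def element_imbalances(net: MetabolicNetwork,
                       skip: Sequence[str] = EXCHANGES,
                       tol: float = 1e-9) -> Dict[str, Dict[str, float]]:
    """Elemental (C/N/O/H/P/S) audit of every non-exchange reaction.

    Returns the offending reactions and their net element counts; empty
    when everything balances. Species with empty formulas (photons,
    energy-carrier tokens) contribute no atoms by construction.
    """
    formulas = {m.id: parse_formula(m.formula) for m in net.metabolites}
    bad: Dict[str, Dict[str, float]] = {}
    for rxn in net.reactions:
        if rxn.id in skip:
            continue
        net_atoms: Dict[str, float] = {}
        for mid, coef in rxn.stoichiometry.items():
            for element, count in formulas[mid].items():
                net_atoms[element] = net_atoms.get(element, 0.0) + coef * count
        residual = {e: v for e, v in net_atoms.items() if abs(v) > tol}
        if residual:
            bad[rxn.id] = residual
    return bad


def min_quantum_demand(spec: Optional[ToyModelSpec] = None) -> float:
    """Closed-form lower bound on the toy quantum demand.

    With carboxylase:oxygenase pinned at r:1, fixing one net CO2 runs the
    carboxylase r/(r-1) times and the oxygenase 1/(r-1) times, so the
    photon cost per net CO2 is at least

        [ r * (p_atp * atp_per_co2 + p_nadph * nadph_per_co2)
          + p_atp * rbo_atp ] / (r - 1),

    every downstream step only adding further energy demand.
    """
    s = spec or ToyModelSpec()
    r = 3.0  # default carboxylase:oxygenase ratio
    per_rbc = s.photons_per_atp * s.atp_per_co2 \
        + s.photons_per_nadph * s.nadph_per_co2
    return (r * per_rbc + s.photons_per_atp * s.rbo_atp) / (r - 1.0)


@dataclass(frozen=True)
class Scenario:
    """A named parameter set (plus perturbation schedule) for the toy runs."""

    name: str
    params: GrowthParams
    perturbations: Tuple[PerturbationEvent, ...] = ()
    expected: str = ""


def make_reference_scenarios(base_params: Optional[GrowthParams] = None,
                             ) -> List[Scenario]:
    """The two nitrate regimes and the three day-21 perturbation schedules.

    N_high starts with 50 mmol soil nitrate and N_low with 1.2 mmol; the
    perturbations reproduce herbivory (leaf biomass to 0.001 g on day
    21), fertilization (nitrate to 100 mmol on day 21) and shading
    (irradiance from 300 to 100 umol photons m-2 s-1 on day 21).
    """
    p = base_params or GrowthParams()
    n_low = replace(p, initial_nitrate=0.0012)
    n_high = replace(p, initial_nitrate=0.05)
    herbivory = (PerturbationEvent(21, "set_leaf_biomass", 0.001),)
    fertilize = (PerturbationEvent(21, "set_nitrate", 0.1),)
    shade = (PerturbationEvent(21, "set_irradiance", 100e-6),)
    return [
        Scenario("n_low", n_low,
                 expected="sigmoid growth into maturation; g_r < 0.5 early"),
        Scenario("n_high", n_high,
                 expected="sustained growth; higher mean g_r than n_low"),
        Scenario("herbivory_n_low", n_low, herbivory,
                 expected="leaf biomass drops to 0.001 g on day 21, "
                          "slow recovery, lower final leaf biomass"),
        Scenario("herbivory_n_high", n_high, herbivory,
                 expected="leaf biomass drops then recovers faster than n_low"),
        Scenario("fertilize_n_low", n_low, fertilize,
                 expected="late growth boost; higher final biomass than n_low"),
        Scenario("shade_n_high", n_high, shade,
                 expected="lower total biomass and lower mean g_r"),
        Scenario("shade_n_low", n_low, shade,
                 expected="lower total biomass under combined limitation"),
    ]
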