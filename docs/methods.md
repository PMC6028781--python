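# Methods

## Model and procedure

`dielfba` treats a growing plant as a sequence of daily steady states of
a four-module metabolic network (leaf/root × light/dark). Within a day,
metabolism is assumed to be at quasi-steady state: every internal
metabolite balances, with diel storage pools represented by irreversible
transfer reactions carrying material from one phase copy of a tissue to
the other (the standard diel-FBA construction). Between days, three slow
state variables evolve: leaf dry mass L_B, root dry mass R_B and the
soil nitrate pool S.

Each day is solved in two stages. First the LP maximizes whole-plant
biomass synthesis (the sum of the four module biomass fluxes) under the
day's resource caps, the maintenance equalities and the balanced-growth
partition row. Second, holding that optimum (to within a 10⁻⁹ relative
guard), total absolute flux is minimized — parsimonious FBA — to select
a canonical, enzymatically economical flux vector from the optimal face.
Remaining degeneracy (exactly equivalent routes, e.g. two storage
carbohydrates with identical cost) is not resolved further; consumers of
flux vectors should compare invariant quantities (objective, constrained
ratios, exchange totals), not arbitrary interior fluxes.

The balanced-growth partition follows the optimal-partitioning idea that
a plant allocates new biomass toward the organ acquiring the scarcer
resource. The leaf share is

    g_r = ln(PN_r) / [ ln(P_max/S) + L_B/R_B ],   PN_r = PLA·P_max/σN_max,

where P_max is the areal photon dose per light phase (irradiance ×
photoperiod), PLA = m·L_B the projected leaf area, and σN_max the
Michaelis–Menten nitrate uptake cap. Two groupings of this expression
are algebraically conceivable; we place L_B/R_B inside the denominator,
because the alternative (adding L_B/R_B outside the fraction) yields
g_r ≈ 26 at the reference initial leaf:root ratio of 25.8, violating
g_r ∈ [0, 1] and contradicting the root-favoring allocation expected at
that state. The heuristic mixes units inside its logarithms
(photon dose vs mol nitrate); it is used as the dimensionless rule it is,
without correction. g_r is clamped to [10⁻³, 1−10⁻³]: an exact 0 or 1
would force zero total growth through the partition equality, and the
regime where the raw value leaves [0, 1] is outside the heuristic's
validity (a domain error is raised when a logarithm argument or the
denominator is nonpositive).

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| V_max | 0.00336 | mol NO₃⁻ gDW(root)⁻¹ day⁻¹ | nitrate transporter kinetics |
| K_M | 4×10⁻⁴ | mol | transporter half-saturation (0.4 mmol) |
| irradiance | 300×10⁻⁶ | mol photons m⁻² s⁻¹ | reference growth light |
| photoperiod | 43 200 | s | 12-h light phase |
| m (PLA slope) | 0.03 | m² gDW⁻¹ | see below |
| ATP maintenance | 7.27 | mmol gDW⁻¹ day⁻¹ | heterotrophic culture estimate; 50 % per phase |
| NADPH maintenance | 2.56 | mmol gDW⁻¹ day⁻¹ | idem (ATP:NADPH ≈ 3:1) |
| nitrate floor | 10⁻⁶ | mol | residual pool keeping late days feasible |
| initial L:R ratio | 25.8 | – | cotyledon-stage estimate |
| initial total biomass | 5×10⁻⁵ | g | see below |
| initial nitrate | 1.2×10⁻³ (N_low) / 5×10⁻² (N_high) | mol | the two reference regimes |
| days | 6 → 36 | DAS | cotyledon opening to rosette maturity |
| phloem light:dark | 3:1 | – | sucrose/amino-acid export ratio |
| nitrate light:dark | 3:2 | – | uptake ratio |
| RBC:RBO | 3:1 | – | photorespiration ratio |
| g_r clamp | 10⁻³ | – | numerical guard (above) |

Two quantities have no published value and are deliberate choices of this
package. The **PLA slope m = 0.03 m² g⁻¹** is a realistic rosette
area-per-mass; dimensionally it sets the photon-limited exponential
growth rate (≈ m × photon dose / photon cost per gram), and at 0.03 the
low-nitrate scenario exhausts its 1.2 mmol pool inside the simulated
window, producing the full sigmoid (exponential phase → nitrate
exhaustion → maturation) the framework is meant to exhibit. The
**initial total biomass 5×10⁻⁵ g** (split 25.8:1) is a realistic
cotyledon-stage seedling dry mass; because maintenance costs are
equality-fixed per gram of tissue, the absolute scale also controls
whether a day-21 herbivory event (leaf reset to 0.001 g) leaves a plant
whose root maintenance the remaining leaf can still power — at this
scale it does. Both live in `GrowthParams` and can be overridden.

## The daily LP in detail

* **Nitrate cap.** One inequality row bounds σN_D + σN_N by
  min(σN_max, S): the kinetic cap, additionally limited by the nitrate
  actually present, so the post-update floor is pure bookkeeping and
  never a nitrate source. The 3:2 light:dark uptake split is a standing
  equality row.
* **Photon cap.** An upper bound on the single photon exchange
  (Leaf_Day): σP ≤ P_max · PLA, using the current irradiance (shading
  events lower it persistently).
* **Maintenance.** ATPase and NADPH-oxidase fluxes are equality-fixed
  (not lower-bounded) at 0.5 × rate × tissue mass per phase: the costs
  are requirements, and leaving them free upward would let the optimizer
  burn surplus photons meaninglessly.
* **Partition row.** (1−g_r)(σL_D+σL_N) − g_r(σR_D+σR_N) = 0, rebuilt
  each day with that day's g_r.
* **Ratio rows.** All fixed ratios are equality rows
  v_num − ratio·v_den = 0 added to the LP, composing freely with bounds.

## Numerical choices

The LP is solved with GLPK through cobrapy/optlang at a feasibility
tolerance of 10⁻⁹. The compiled problem works in **mmol (metabolite
fluxes) and mg (biomass fluxes) per phase** while the engine's state and
σ quantities are in mol and g: biomass composition coefficients are
mol/g = mmol/mg, so the stoichiometry is identical on both scales, and
on the mmol/mg scale seedling-sized problems (fluxes 10⁻⁵…10³) stay
well-conditioned for the simplex, which they do not at mol scale.
Parsimonious re-solves use the optlang forward/reverse variable split
(the nonnegative-part decomposition of each flux), a floor on the
primary objective with a 10⁻⁹ relative guard, and — in FVA — a total
flux cap of (1+10⁻⁶) × minimum, since exact equality is brittle.
Reported comparisons in the test suite use 10⁻⁶ relative tolerance.
Essentiality distinguishes *essential* (FVA interval excluding zero on
the unrestricted optimal space; exactly single-deletion lethality at the
day's optimum) from *forced* (the equality-fixed maintenance sinks,
whose pinned interval reflects their own bounds) and from *always
active* (nonzero across near-parsimonious optima — the robustness
reading of FVA under a minimum-total-flux secondary objective).

Degenerate inputs: S = 0 gives a zero uptake cap and (since the g_r
logarithms are undefined) the partition defaults to the root-favoring
clamp; zero tissue masses are rejected at the state level; an infeasible
day raises an error carrying the day index, the binding-cap diagnostics
and the trajectory so far — infeasibility under nitrate exhaustion is
instead prevented by the nitrate floor, never by relaxing other
constraints.

## The synthetic network

The built-in generator emits a single-tissue base network with ~24 core
reactions: photon capture split into photophosphorylation (1 photon/ATP)
and water splitting (2 photons/NADPH, releasing O₂), carboxylation (1
ATP + 2 NADPH per CO₂ → CH₂O unit), photorespiratory loss at the 3:1
carboxylase:oxygenase ratio, glucose/sucrose/starch interconversion,
malate and citrate chemistry, respiration (30 ATP/glucose), an oxidative
pentose-phosphate route (12 NADPH/glucose), nitrate reduction (4
NADPH/NO₃⁻) and a glutamine-synthetase/glutamate-synthase cycle, plus a
seeded chain of inert "filler" isomerizations that can carry no
steady-state flux (they pad reaction counts without changing optima).
Every non-exchange reaction is element-balanced over C/N/O/H, with water
and protons as external species and the energy carriers as atom-free
tokens. Phloem loading is modeled as an active proton pump charged at
one ATP per proton per molecule loaded: no pump stoichiometry is
canonical, and a cost paid in external protons alone would be free to
the LP. Biomass is three components — glucose 70/60 %, glutamate 20/30 %,
malate 10 % by mass for leaf/root — normalized to 1 g per unit flux.

With the default energy stoichiometry the theoretical minimum quantum
demand has the closed form (3×5 + 1)/2 = 8 photons per net CO₂ (three
carboxylations and one oxygenase turnover per two net CO₂), which every
simulated day must respect; the genome-scale values this bound stands in
for depend on the full network and are not toy-reproducible.

**What the toy does and does not show.** It exercises every mechanism of
the framework — module wiring, phloem and storage flux, diel energy
budgeting, the growth loop, perturbations, metrics, essentiality — and
its qualitative behavior (root-favored allocation under low nitrate,
sigmoid maturation, leaf-day nitrogen assimilation, AQ → 1 as nitrate
vanishes, negative correlation between root:leaf ratio and quantum
demand) mirrors the genome-scale regime. Passing tests therefore
validate mechanics and invariants, not quantitative agreement with any
real plant: absolute biomasses, quantum demands near 9 rather than ~16,
and the citrate/malate storage pattern (the toy's parsimonious optimum
stores glucose, its cheapest linker, rather than starch or night
citrate) are properties of the simplified chemistry.

## Known limitations

* One day is the smallest time step; no sub-daily kinetics.
* Nitrate is the only dynamically limited mineral; the partition
  heuristic takes exactly one diminishing and one fixed resource.
* No ion efflux from root to soil; uptake is capped, never reversed.
* Storage linkers carry no energetic cost (vacuolar transport is free),
  and stores do not persist across days (diel steady state).
* Maintenance scales linearly with tissue mass and is phase-symmetric.
* Gene–protein–reaction rules, gene deletions and network gap-filling
  are out of scope; SBML input is consumed as given.
* LP degeneracy beyond parsimonious selection is documented, not
  resolved; flux-level comparisons should stick to invariant quantities.
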