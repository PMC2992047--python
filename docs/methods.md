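# Methods

## Steady-state framework

Every computation operates on a stoichiometric model: metabolites
(internal or boundary), reactions with signed coefficient maps and flux
bounds `α_j ≤ v_j ≤ β_j` (mmol gDW⁻¹ h⁻¹; the growth reaction in h⁻¹),
and a single-reaction growth objective.  Internal metabolites obey
`Σ_j S_ij v_j = 0`; boundary species are excluded from the mass
balance.  Reactions are oriented so their physiological direction is
positive: uptakes import and secretions export with positive flux, so
yields are ratios of positive magnitudes.

Models persist in a small JSON dialect (documented in
`stoichmodel.py`); round trips are loss-free because bounds and
coefficients are always written explicitly as floats.  Validation
distinguishes hard errors (duplicate ids, dangling references,
inverted bounds, empty stoichiometries) from warnings (carbon
imbalance, orphan metabolites); solvers refuse models with errors.

## The synthetic yeast-core network

The generator (`toynet.build_core_model`) emulates glucose-limited
*S. cerevisiae* physiology with 32 lumped, carbon-closed reactions;
grafting the VG pathway (`augment_vg_pathway`) adds five conversions
and five secretion exchanges for a total of 42.  Design choices that
matter:

* **Overflow metabolism.**  Oxygen uptake is capped (`o2_cap`, default
  8 mmol gDW⁻¹ h⁻¹).  Below a critical glucose uptake the growth
  optimum is fully respiratory; above it the surplus is fermented to
  ethanol.  With default parameters the critical uptake is ≈2.8
  mmol gDW⁻¹ h⁻¹ (`find_critical_uptake`, bisection to 1e-4), between
  the respiratory reference's ceiling (1.0) and the default uptake
  bound (10.0), and below the measured chemostat uptakes (3.5–4.8), so
  the measured states are respiro-fermentative as observed.
* **Two acetyl-CoA pools.**  Biomass consumes cytosolic acetyl-CoA,
  which is reachable only through the pyruvate-decarboxylase bypass
  (PDC → acetaldehyde → acetate → ACS); the pyruvate-dehydrogenase
  pool feeds only the TCA cycle.  This reproduces the lethality of
  complete decarboxylase loss on glucose (aerobically and
  anaerobically) without gene–protein–reaction logic.
* **Decoupled pentose-phosphate lumps.**  An oxidative shunt
  (g6p → 6 CO₂ + 12 NADPH, the fully recycled lump) supplies NADPH
  independently of a non-oxidative transketolase lump
  (2 g6p → 3 e4p) supplying erythrose-4-phosphate.  A single combined
  lump would force NADPH production whenever e4p is drawn and make the
  measured states infeasible.
* **Ammonium assimilation.**  NADPH-dependent GDH1, NADH-dependent
  GDH2 and the ATP-consuming GS-GOGAT couple are all present
  (individually switchable).  Because the NADP-linked acetaldehyde
  dehydrogenase (ALD) is the obligatory acetate source, deleting GDH1
  strands an NADPH surplus that can only drain through the
  ATP+NADPH-consuming ACAR step of the VG pathway — the cofactor
  mechanism that makes the GDH1 deletion a high-adjustment,
  product-coupled target.
* **Acetaldehyde secretion** is allowed with a modest capacity
  (2 mmol gDW⁻¹ h⁻¹).  It gives the decarboxylase node headroom above
  the flux pinned by the measured ethanol and acetate rates; without
  it the "80 % of the identified upper bound" rule for the partial
  decarboxylase deletion would contradict the fixed ethanol rate and
  empty the polytope.
* **Biomass composition** (mmol per gDW): pyruvate 1, cytosolic
  acetyl-CoA 2, erythrose-4-phosphate 0.2, glutamate 3 (the nitrogen
  carrier; glutamate-family amino acids dominate cellular N), ATP 80
  (growth-associated maintenance), NADPH 0.2 — plus a non-growth ATP
  drain of 1 mmol gDW⁻¹ h⁻¹ enforced as a lower bound on the ATPase.
  These values were tuned, once, so that the network simultaneously
  satisfies the qualitative behaviours the fixture is required to
  show (overflow regimes, measured-state feasibility, knockout
  essentialities, the adjustment ordering of the GDH1 vs the partial
  PDC design, and the turnover trends); they are recorded in the model
  annotations.
* **Cofactor cycles.**  SAM is regenerated from SAH with a methyl-donor
  uptake (methionine is supplied in the reference medium) and ATP;
  UDP-glucose from glucose-6-phosphate, ATP and the UDP released by the
  glucosyltransferase.  SAM carries only its transferable methyl carbon
  in the carbon bookkeeping so methylation reactions close.

The generator is fully deterministic — the physiological states carry
measured means ± one standard deviation as intervals, and no fixture
construction involves randomness.

### What the fixture does and does not emulate

The network reproduces the *qualitative* physiology: overflow above a
critical uptake, decarboxylase essentiality, the NADPH-mediated
coupling of nitrogen metabolism to the product pathway, feasible
chemostat states at dilution rate 0.1 h⁻¹, and the turnover trends of
the pathway intermediates between the producer reference and the
partial-decarboxylase strain.  It does not reproduce genome-scale
quantities (reaction counts per FVA category, absolute yields), and
two behaviours differ from a genome-scale setting: (i) under the
hypothetical respiratory/respiro-fermentative references, pure
knockouts re-route surplus flux into the cheaper early pathway
secretions rather than into VG itself (the glucosyl moiety makes the
final step carbon-expensive at the margin), so discriminative R³
ranking uses the measured-state reference, whose fixed secretion rates
keep the whole pathway active; (ii) the doubly engineered strain's
PAC turnover rises in the toy (its forced NADPH surplus drains through
ACAR) where a genome-scale model has cheaper sinks.  Passing tests
therefore certify the algorithms and the stated qualitative
behaviours, not quantitative predictions for real strains.

## Solvers

All LPs go through scipy's HiGHS interface; results are deterministic
given fixed inputs.  Tolerances live in one configuration object
(`config.Tolerances`): steady-state feasibility 1e-6, comparisons
1e-6, FVA-category bound comparisons 1e-4, growth floor 1e-4 h⁻¹ for
viability, MA ε 1e-6 below which R³ is undefined, bisection 1e-4.

* **Reference FBA** maximizes growth, then pins growth at the optimum
  (±1e-9 relative slack) and minimizes `Σ|v|` via split variables to
  select a unique, physiologically parsimonious reference.  For the
  measured states growth is already fixed at the dilution rate, so the
  first stage only confirms feasibility.
* **MOMA** is solved by a primal active-set method for the strictly
  convex box-and-equality QP: on each working set the equality-
  constrained projection is obtained from its KKT system (least
  squares over `S_F S_Fᵀ`, tolerant of redundant rows), with exact
  line searches to the first blocking bound and multiplier-based
  constraint dropping.  The solution is verified against feasibility
  tolerances; an SLSQP fallback covers pathological cases (none occur
  on the shipped fixtures, and the test suite cross-checks the
  active-set optimum against an independent SLSQP solve).  The
  adjustment distance runs over the union of reactions; reactions
  missing on either side contribute with flux (or reference) zero.
* **FVA** runs two LPs per reaction; with `fix_growth` the growth rate
  is pinned to the state's rate (or the FBA optimum if free).
* **Minimum turnover** splits each reversible flux into nonnegative
  forward/reverse parts and minimizes `½ Σ_k |S_ik| (v_k⁺ + v_k⁻)`
  with the state's measured exchange rates fixed at their interval
  midpoints (the measured means) and growth at the dilution rate;
  unmeasured exchanges stay free within their bounds.  Minimization
  suppresses futile cycles around the metabolite, and the LP optimum
  is asserted against the definition evaluated on the support vector.

Degenerate inputs: an infeasible polytope raises a structured error
listing the non-default bounds in force; unbounded objectives name the
objective reactions; a glucose-starved model is infeasible (the
maintenance ATPase cannot run), which callers treat as zero growth.

## Design search

A design is a set of reaction knockouts plus capacity fractions.
Capacity fractions restrict a reaction's upper bound either to
`f·|v_ref|` (fraction of the reference flux — used when simulating a
partial enzyme deletion against a reference) or to `f·β` (fraction of
a previously identified upper bound — used when re-analysing measured
states).  Knockout evaluation is total: solver infeasibility becomes a
non-viable evaluation with BPCY 0, never an exception.

The exhaustive search enumerates all subsets up to size *k* and also
reports, per design, the bilevel-style verification interval: the
minimum and maximum product flux at the mutant's FBA growth optimum.
The genetic algorithm uses binary genomes over the candidate set
(internal, non-exchange, non-biomass, non-maintenance reactions),
tournament selection (size 2), uniform crossover (probability 0.8,
per-bit mix 0.5), per-bit mutation (default 1/L), elitism of one, and
a repair step clearing random excess bits beyond `max_knockouts`
(default 6); fitness is BPCY and every run is reproducible from its
mandatory seed.  Capacity-fraction designs participate in evaluation
and ranking but not in GA genomes.  R³ is normalized per reference
panel (the best design of each panel scores 100 %); designs with
MA < ε are phenotypically identical to the reference and are excluded
from R³ ranking rather than scored as infinite.

## Analysis workflow

For measured mutant states, knocked-out genes get zero bounds; a
partially deleted decarboxylase is handled by first identifying the
reaction's upper bound by FVA maximization under the mutant's measured
state and then re-constraining it to 80 % of that bound.  FVA ranges of
reference and mutant are classified into six categories — blocked
(zero in both), `a` (equal), `b` (mutant range contains the reference
range), `c` (contained), `d` (both bounds higher), `e` (both bounds
lower) — which provably partition all interval pairs; the mixed
wider-on-both-sides case counts as containment (`b`).  Turnover
comparison reports increase/decrease arrows when the change exceeds
`1e-4 · max(1, Φ_ref)`.

## Problem sizes

The shipped network has 42 reactions and 31 internal metabolites.  The
test suite enumerates knockout pairs over an eight-reaction candidate
subset and runs the genetic algorithm with populations of 8–20 for
4–15 generations; the full suite completes in well under a minute, and
the acceptance script (exhaustive panel over all 27 candidates plus a
seeded GA run) in a few seconds.
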