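"""Synthetic yeast-core network and physiological-state fixtures.

:func:`build_core_model` constructs a reduced central-carbon network of
baker's yeast with lumped, carbon-closed stoichiometries: glucose uptake,
glycolysis, an oxidative pentose-phosphate shunt (NADPH) and a
non-oxidative transketolase lump (erythrose-4-phosphate), the pyruvate
branch point (pyruvate decarboxylase towards ethanol/acetate, pyruvate
dehydrogenase towards the TCA cycle), oxidative phosphorylation with a
capped respiratory capacity, glycerol and acetate by-product formation,
three ammonium-assimilation routes (NADPH-dependent GDH1, NADH-dependent
GDH2 and the ATP-consuming GS-GOGAT couple), the shikimate route to
3-dehydroshikimate, SAM and UDP-glucose cofactor cycles, and a biomass
drain.  The capped respiratory capacity reproduces Crabtree-like overflow:
above a critical glucose uptake rate the growth-optimal flux distribution
ferments the surplus to ethanol.

Cytosolic and mitochondrial acetyl-CoA are separate pools: biomass can
only use the cytosolic pool, which is exclusively supplied through the
pyruvate-decarboxylase bypass (PDC -> acetaldehyde -> acetate -> ACS), so
a complete loss of decarboxylase activity abolishes growth on glucose —
as observed for decarboxylase-negative yeast.

:func:`make_state_spec` packages the physiological states used by the
workflows: the two hypothetical reference conditions (purely respiratory,
and glucose-excess respiro-fermentative) and the three chemostat states
(``measured_vg0/vg2/vg4``) whose exchange rates are the measured means
with one standard deviation on either side, at dilution rate 0.1 h^-1.

The generator is fully deterministic; there is no randomness anywhere in
fixture construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import DEFAULT_TOLERANCES, Tolerances
from .stoichmodel import (
    DEFAULT_BOUND,
    Metabolite,
    Reaction,
    StoichiometricModel,
    augment_vg_pathway,
)

#: Glucose-uptake ceiling of the respiratory reference state; chosen below
#: the fixture's critical uptake so growth is fully respiratory.
RESPIRATORY_GLUCOSE_UPPER = 1.0

#: Measured chemostat exchange rates (mmol gDW^-1 h^-1), mean +/- sd, at
#: dilution rate 0.1 h^-1, for the producer reference strain (vg0), the
#: pdc1 deletion (vg2) and the pdc1 gdh1 deletion with GDH2
#: overexpression (vg4).  Keys are exchange-reaction ids of the fixture.
MEASURED_RATES: dict[str, dict[str, tuple[float, float]]] = {
    "vg0": {
        "glucose_uptake": (3.9, 0.2),
        "ethanol_exchange": (4.3, 0.3),
        "glycerol_exchange": (0.026, 0.003),
        "acetate_exchange": (0.086, 0.006),
        "PAC_secretion": (0.12, 0.01),
        "PAL_secretion": (0.036, 0.008),
        "VG_secretion": (0.009, 0.003),
    },
    "vg2": {
        "glucose_uptake": (3.5, 0.3),
        "ethanol_exchange": (3.9, 0.3),
        "glycerol_exchange": (0.014, 0.004),
        "acetate_exchange": (0.079, 0.006),
        "PAC_secretion": (0.10, 0.01),
        "PAL_secretion": (0.040, 0.007),
        "VG_secretion": (0.011, 0.002),
    },
    "vg4": {
        "glucose_uptake": (4.8, 0.2),
        "ethanol_exchange": (6.1, 0.4),
        "glycerol_exchange": (0.10, 0.08),
        "acetate_exchange": (0.05, 0.003),
        "PAC_secretion": (0.087, 0.03),
        "PAL_secretion": (0.045, 0.003),
        "VG_secretion": (0.012, 0.001),
    },
}

#: Chemostat dilution rate (h^-1) of the measured states.
CHEMOSTAT_DILUTION_RATE = 0.1


@dataclass
class CoreModelParams:
    """Tunable physiology of the synthetic core network.

    Attributes
    ----------
    po_ratio:
        ATP formed per NADH oxidized in oxidative phosphorylation.
    o2_cap:
        Respiratory ceiling: upper bound of oxygen uptake
        (mmol gDW^-1 h^-1).  Chosen so that the default glucose uptake
        ceiling lies well above the critical (overflow) uptake rate.
    atp_maintenance:
        Non-growth-associated ATP drain (mmol gDW^-1 h^-1), enforced as a
        lower bound on the ATP-hydrolysis reaction.
    glucose_max_uptake:
        Default glucose uptake ceiling (mmol gDW^-1 h^-1); the
        respiro-fermentative reference runs against this bound.
    acald_secretion_cap:
        Capacity of acetaldehyde export (mmol gDW^-1 h^-1).  A modest
        nonzero capacity gives the pyruvate-decarboxylase node headroom
        above the flux the ethanol and acetate rates pin down, which is
        what the 80 %-of-upper-bound rule for a partial decarboxylase
        deletion restricts.
    biomass_coeffs:
        Precursor demand (mmol per gDW) of the biomass reaction, keyed by
        role: pyruvate, acetyl_coa (cytosolic), e4p, glutamate, atp,
        nadph.
    gdh_variants:
        Flags enabling the GDH1, GDH2 and GS-GOGAT ammonium-assimilation
        routes.
    """

    po_ratio: float = 1.5
    o2_cap: float = 8.0
    atp_maintenance: float = 1.0
    glucose_max_uptake: float = 10.0
    acald_secretion_cap: float = 2.0
    biomass_coeffs: dict[str, float] = field(
        default_factory=lambda: {
            "pyruvate": 1.0,
            "acetyl_coa": 2.0,
            "e4p": 0.2,
            "glutamate": 3.0,
            "atp": 80.0,
            "nadph": 0.2,
        }
    )
    gdh_variants: dict[str, bool] = field(
        default_factory=lambda: {"gdh1": True, "gdh2": True, "gs_gogat": True}
    )

    def validate(self) -> None:
        for name in ("po_ratio", "o2_cap", "atp_maintenance", "glucose_max_uptake"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.biomass_coeffs.get("atp", 0.0) <= 0:
            raise ValueError("biomass requires a positive ATP coefficient")
        carbon_roles = ("pyruvate", "acetyl_coa", "e4p", "glutamate")
        if not any(self.biomass_coeffs.get(r, 0.0) > 0 for r in carbon_roles):
            raise ValueError("biomass requires at least one carbon precursor")
        if any(c < 0 for c in self.biomass_coeffs.values()):
            raise ValueError("biomass coefficients must be nonnegative")


@dataclass
class PhysiologicalState:
    """A named set of exchange-rate and growth constraints.

    ``fixed_rates`` maps exchange-reaction ids to ``(lo, hi)`` intervals
    (measured mean +/- sd for chemostat states).  ``growth_rate`` fixes the
    growth reaction when set; ``None`` leaves growth free (to be
    maximized).  Interval ``None`` keeps the model's own bounds.
    """

    mode: str
    glucose_uptake: tuple[float, float] | None = None
    oxygen_uptake: tuple[float, float] | None = None
    growth_rate: float | None = None
    fixed_rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    dilution_rate: float | None = None

    def __post_init__(self):
        intervals = list(self.fixed_rates.values())
        if self.glucose_uptake is not None:
            intervals.append(self.glucose_uptake)
        if self.oxygen_uptake is not None:
            intervals.append(self.oxygen_uptake)
        for lo, hi in intervals:
            if lo > hi:
                raise ValueError(f"interval ({lo}, {hi}) has lo > hi")
        if self.mode == "measured" and not self.fixed_rates:
            raise ValueError("measured mode requires nonempty fixed_rates")


def _met(mid, name, carbon, external=False, compartment="c"):
    return Metabolite(id=mid, name=name, carbon_count=carbon,
                      is_external=external, compartment=compartment)


def build_core_model(params: CoreModelParams | None = None) -> StoichiometricModel:
    """Build the reduced yeast-core network (without the VG pathway).

    Every internal reaction is carbon-closed under the declared carbon
    counts (cofactors count zero carbon; SAM counts its transferable
    methyl carbon).  The returned model's ``annotations`` record the
    generator parameters and the declared reaction count.
    """
    p = params or CoreModelParams()
    p.validate()

    m = StoichiometricModel()
    m.metabolites = [
        # internal species
        _met("glc", "glucose", 6),
        _met("g6p", "glucose-6-phosphate", 6),
        _met("pep", "phosphoenolpyruvate", 3),
        _met("pyr", "pyruvate", 3),
        _met("acald", "acetaldehyde", 2),
        _met("etoh", "ethanol", 2),
        _met("glyc", "glycerol", 3),
        _met("ac", "acetate", 2),
        _met("accoa_c", "acetyl-CoA (cytosolic)", 2),
        _met("accoa_m", "acetyl-CoA (mitochondrial)", 2),
        _met("e4p", "erythrose-4-phosphate", 4),
        _met("akg", "2-oxoglutarate", 5),
        _met("glu", "glutamate", 5),
        _met("gln", "glutamine", 5),
        _met("dhs", "3-dehydroshikimate", 7),
        _met("nh4", "ammonium", 0),
        _met("o2", "oxygen", 0),
        _met("co2", "carbon dioxide", 1),
        _met("atp", "ATP", 0),
        _met("nadh", "NADH", 0),
        _met("nadph", "NADPH", 0),
        _met("ch3", "methyl donor unit", 1),
        _met("sam", "S-adenosylmethionine (methyl)", 1),
        _met("sah", "S-adenosylhomocysteine", 0),
        _met("udpg", "UDP-glucose", 6),
        _met("udp", "UDP", 0),
        # boundary species
        _met("glc_e", "glucose (medium)", 6, external=True, compartment="e"),
        _met("o2_e", "oxygen (medium)", 0, external=True, compartment="e"),
        _met("nh4_e", "ammonium (medium)", 0, external=True, compartment="e"),
        _met("ch3_e", "methyl donor (medium)", 1, external=True, compartment="e"),
        _met("co2_e", "carbon dioxide (off-gas)", 1, external=True, compartment="e"),
        _met("etoh_e", "ethanol (broth)", 2, external=True, compartment="e"),
        _met("glyc_e", "glycerol (broth)", 3, external=True, compartment="e"),
        _met("ac_e", "acetate (broth)", 2, external=True, compartment="e"),
        _met("acald_e", "acetaldehyde (broth)", 2, external=True, compartment="e"),
        _met("biomass_e", "biomass", None, external=True, compartment="e"),
    ]

    b = p.biomass_coeffs
    rxns = [
        # exchanges (positive flux = physiological direction)
        Reaction("glucose_uptake", {"glc_e": -1, "glc": 1},
                 name="glucose uptake", upper_bound=p.glucose_max_uptake),
        Reaction("oxygen_uptake", {"o2_e": -1, "o2": 1},
                 name="oxygen uptake (respiratory capacity)", upper_bound=p.o2_cap),
        Reaction("ammonium_uptake", {"nh4_e": -1, "nh4": 1}, name="ammonium uptake"),
        Reaction("methyl_uptake", {"ch3_e": -1, "ch3": 1},
                 name="methyl-donor (methionine) uptake"),
        Reaction("co2_exchange", {"co2": -1, "co2_e": 1}, name="CO2 evolution"),
        Reaction("ethanol_exchange", {"etoh": -1, "etoh_e": 1}, name="ethanol secretion"),
        Reaction("glycerol_exchange", {"glyc": -1, "glyc_e": 1}, name="glycerol secretion"),
        Reaction("acetate_exchange", {"ac": -1, "ac_e": 1}, name="acetate secretion"),
        Reaction("acetaldehyde_exchange", {"acald": -1, "acald_e": 1},
                 name="acetaldehyde secretion", upper_bound=p.acald_secretion_cap),
        # central carbon metabolism (lumped)
        Reaction("HXK", {"glc": -1, "atp": -1, "g6p": 1},
                 name="hexokinase", gene_tag="HXK2"),
        Reaction("GLYC", {"g6p": -1, "pep": 2, "nadh": 2, "atp": 1},
                 name="glycolysis (G6P to PEP, lumped)"),
        Reaction("PYK", {"pep": -1, "pyr": 1, "atp": 1},
                 name="pyruvate kinase", gene_tag="PYK1"),
        Reaction("PPP_OX", {"g6p": -1, "co2": 6, "nadph": 12},
                 name="oxidative pentose phosphate shunt (fully recycled, lumped)",
                 gene_tag="ZWF1"),
        Reaction("E4P_TKT", {"g6p": -2, "e4p": 3},
                 name="non-oxidative PPP to erythrose-4-phosphate (lumped)",
                 gene_tag="TKL1"),
        Reaction("GPD", {"g6p": -1, "atp": -1, "nadh": -2, "glyc": 2},
                 name="glycerol branch (lumped)", gene_tag="GPD1"),
        Reaction("PDC", {"pyr": -1, "acald": 1, "co2": 1},
                 name="pyruvate decarboxylase", gene_tag="PDC1"),
        Reaction("ADH", {"acald": -1, "nadh": -1, "etoh": 1},
                 name="alcohol dehydrogenase", gene_tag="ADH1"),
        Reaction("ALD", {"acald": -1, "ac": 1, "nadph": 1},
                 name="acetaldehyde dehydrogenase (NADP)", gene_tag="ALD6"),
        Reaction("ACS", {"ac": -1, "atp": -2, "accoa_c": 1},
                 name="acetyl-CoA synthetase", gene_tag="ACS1"),
        Reaction("PDH", {"pyr": -1, "accoa_m": 1, "co2": 1, "nadh": 1},
                 name="pyruvate dehydrogenase", gene_tag="PDA1"),
        Reaction("AKG_SYN", {"pyr": -1, "accoa_m": -1, "akg": 1, "nadh": 1},
                 name="anaplerosis + citrate to 2-oxoglutarate (lumped)"),
        Reaction("TCA", {"accoa_m": -1, "co2": 2, "nadh": 3, "atp": 1},
                 name="TCA cycle (lumped)"),
        Reaction("OXPHOS", {"o2": -1, "nadh": -2, "atp": 2 * p.po_ratio},
                 name="oxidative phosphorylation"),
        Reaction("SHIK", {"pep": -1, "e4p": -1, "dhs": 1},
                 name="shikimate route to 3-dehydroshikimate (lumped)",
                 gene_tag="ARO1"),
        Reaction("SAM_CYC", {"sah": -1, "ch3": -1, "atp": -1, "sam": 1},
                 name="SAM regeneration cycle", gene_tag="SAM2"),
        Reaction("UGP", {"g6p": -1, "atp": -1, "udp": -1, "udpg": 1},
                 name="UDP-glucose synthesis (lumped)", gene_tag="UGP1"),
        Reaction("ATPM", {"atp": -1},
                 name="ATP maintenance / hydrolysis",
                 lower_bound=p.atp_maintenance),
        Reaction(
            "BIOMASS",
            {
                "pyr": -b.get("pyruvate", 0.0),
                "accoa_c": -b.get("acetyl_coa", 0.0),
                "e4p": -b.get("e4p", 0.0),
                "glu": -b.get("glutamate", 0.0),
                "atp": -b.get("atp", 0.0),
                "nadph": -b.get("nadph", 0.0),
                "biomass_e": 1.0,
            },
            name="biomass formation (growth, h^-1)",
        ),
    ]
    if p.gdh_variants.get("gdh1", True):
        rxns.append(
            Reaction("GDH1", {"akg": -1, "nh4": -1, "nadph": -1, "glu": 1},
                     name="glutamate dehydrogenase (NADPH)", gene_tag="GDH1"))
    if p.gdh_variants.get("gdh2", True):
        rxns.append(
            Reaction("GDH2", {"akg": -1, "nh4": -1, "nadh": -1, "glu": 1},
                     name="glutamate dehydrogenase (NADH)", gene_tag="GDH2"))
    if p.gdh_variants.get("gs_gogat", True):
        rxns.append(
            Reaction("GS", {"glu": -1, "nh4": -1, "atp": -1, "gln": 1},
                     name="glutamine synthetase", gene_tag="GLN1"))
        rxns.append(
            Reaction("GOGAT", {"gln": -1, "akg": -1, "nadh": -1, "glu": 2},
                     name="glutamate synthase (NADH)", gene_tag="GLT1"))

    # drop zero coefficients that disabled biomass roles may have produced
    for r in rxns:
        r.stoichiometry = {k: v for k, v in r.stoichiometry.items() if v != 0.0}
    m.reactions = rxns
    m.objective = {"BIOMASS": 1.0}
    m.annotations = {
        "generator": "fluxdesigner.toynet.build_core_model",
        "reaction_count": len(rxns),
        "po_ratio": p.po_ratio,
        "o2_cap": p.o2_cap,
        "atp_maintenance": p.atp_maintenance,
        "glucose_max_uptake": p.glucose_max_uptake,
        "biomass_coeffs": dict(b),
    }
    return m


def build_vg_model(params: CoreModelParams | None = None) -> StoichiometricModel:
    """Core network with the VG pathway grafted on: the packaged fixture."""
    return augment_vg_pathway(build_core_model(params))


def find_critical_uptake(
    model: StoichiometricModel,
    tol: float | None = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> float:
    """Smallest glucose-uptake bound at which optimal growth needs ethanol.

    For a given uptake ceiling the growth optimum "requires" ethanol
    secretion when the minimum ethanol flux at the fixed optimal growth
    rate is nonzero.  The threshold is located by bisection (absolute
    tolerance ``tol``); if even the model's own uptake ceiling admits a
    fermentation-free optimum the sentinel ``math.inf`` is returned.
    """
    from . import solvers

    tol = tolerances.bisection if tol is None else tol
    glc = model.reaction("glucose_uptake")
    model.reaction("ethanol_exchange")  # precondition: both exchanges exist
    hi = glc.upper_bound

    def overflow_required(bound: float) -> bool:
        probe = model.copy()
        probe.reaction("glucose_uptake").upper_bound = bound
        try:
            sol = solvers.solve_fba(probe)
        except solvers.Infeasible:
            # below the uptake that sustains maintenance: no growth at all
            return False
        mu = sol.objective_value
        if mu <= tolerances.growth_floor:
            return False
        growth_rxn = probe.reaction(solvers.growth_reaction_id(probe))
        growth_rxn.lower_bound = mu - 1e-7
        growth_rxn.upper_bound = mu + 1e-9
        min_etoh = solvers.solve_fba(
            probe, objective={"ethanol_exchange": -1.0}
        )
        return -min_etoh.objective_value > 1e-5

    if not overflow_required(hi):
        return math.inf
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if overflow_required(mid):
            hi = mid
        else:
            lo = mid
    return hi


def make_state_spec(
    mode: str, params: CoreModelParams | None = None
) -> PhysiologicalState:
    """Return one of the packaged physiological states.

    ``respiratory``: ethanol secretion fixed to zero and glucose uptake
    capped below the fixture's critical uptake.  ``respiro_fermentative``:
    glucose at the fixture's default ceiling with oxygen capped, i.e. the
    glucose-excess overflow regime.  ``measured_vg0/vg2/vg4``: chemostat
    exchange rates as mean +/- sd intervals with growth fixed at the
    dilution rate.
    """
    p = params or CoreModelParams()
    if mode == "respiratory":
        return PhysiologicalState(
            mode="respiratory",
            glucose_uptake=(0.0, RESPIRATORY_GLUCOSE_UPPER),
            fixed_rates={"ethanol_exchange": (0.0, 0.0)},
        )
    if mode == "respiro_fermentative":
        return PhysiologicalState(
            mode="respiro_fermentative",
            glucose_uptake=(0.0, p.glucose_max_uptake),
            oxygen_uptake=(0.0, p.o2_cap),
        )
    if mode.startswith("measured_"):
        strain = mode.removeprefix("measured_")
        if strain not in MEASURED_RATES:
            raise ValueError(f"unknown state mode {mode!r}")
        fixed = {
            rxn: (mean - sd, mean + sd)
            for rxn, (mean, sd) in MEASURED_RATES[strain].items()
        }
        return PhysiologicalState(
            mode="measured",
            glucose_uptake=fixed["glucose_uptake"],
            growth_rate=CHEMOSTAT_DILUTION_RATE,
            fixed_rates=fixed,
            dilution_rate=CHEMOSTAT_DILUTION_RATE,
        )
    raise ValueError(f"unknown state mode {mode!r}")
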