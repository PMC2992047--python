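"""Core data types for stoichiometric metabolic networks.

This module defines the in-memory representation used by every computation
in the package (metabolites, reactions, models, flux distributions and
mutant designs), a small JSON dialect for persisting models, and the two
model transformations the workflows need: grafting the five-step vanillin
beta-D-glucoside (VG) pathway onto a host network, and applying a mutant
design (reaction knockouts and capacity restrictions) to a model.

Sign conventions
----------------
Every reaction is oriented so that its typical physiological direction is
positive.  Uptake exchanges import their substrate with positive flux and
secretion exchanges export with positive flux; yields are therefore ratios
of positive magnitudes.  Stoichiometric coefficients are negative for
consumed metabolites and positive for produced ones.

Model JSON dialect
------------------
Top-level keys: ``metabolites`` (list of ``{id, name, compartment,
external, carbon}``), ``reactions`` (list of ``{id, name, stoichiometry,
lb, ub, gene}``), ``objective`` (``{reaction-id: coefficient}``) and
``annotations``.  When bounds are omitted they default to ``(-1000, 1000)``
for entries flagged ``"reversible": true`` and ``(0, 1000)`` otherwise;
:func:`save_model` always writes bounds explicitly so round trips are
loss-free.  Growth-reaction flux is in h^-1 by declaration; all other
fluxes are mmol gDW^-1 h^-1.
"""

from __future__ import annotations

import copy as _copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .config import DEFAULT_TOLERANCES, Tolerances

DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """Raised when a model document cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    """A chemical species of the network.

    ``is_external`` species are boundary metabolites excluded from the
    steady-state mass balance.  ``carbon_count`` (atoms per molecule) is
    optional and only used by carbon-closure diagnostics.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    is_external: bool = False
    carbon_count: int | None = None


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative
    = consumed).  Bounds are mmol gDW^-1 h^-1 (h^-1 for the growth
    reaction); ``gene_tag`` optionally names the encoding gene.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_tag: str | None = None

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            name=self.name,
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gene_tag=self.gene_tag,
        )


@dataclass
class StoichiometricModel:
    """A metabolic network: metabolites, reactions and an objective.

    The implied stoichiometric matrix ``S`` has one row per non-external
    metabolite and one column per reaction; :meth:`stoichiometric_matrix`
    materialises it as a dense array (the networks handled here are small).
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    # -- lookup helpers -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"unknown metabolite {met_id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"unknown reaction {rxn_id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    def stoichiometric_matrix(self):
        """Return ``(S, metabolite_ids, reaction_ids)`` for internal rows."""
        import numpy as np

        mets = [m.id for m in self.internal_metabolites]
        met_index = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                i = met_index.get(met)
                if i is not None:
                    S[i, j] = coeff
        return S, mets, [r.id for r in self.reactions]

    def copy(self) -> "StoichiometricModel":
        return _copy.deepcopy(self)


@dataclass
class FluxDistribution:
    """A steady-state flux vector.

    ``residual`` is the maximum absolute steady-state violation of the
    vector on the model it was computed for.
    """

    fluxes: dict[str, float]
    objective_value: float | None = None
    residual: float = 0.0
    name: str | None = None

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        return self.fluxes.get(rxn_id, default)


@dataclass
class MutantDesign:
    """A strain design: reaction knockouts plus capacity restrictions.

    ``capacity_fractions`` maps reaction ids to a fraction f in (0, 1] of
    either the reference flux magnitude or the upper bound (the caller
    selects the semantics in :func:`apply_design`).
    """

    knockouts: frozenset[str] = frozenset()
    capacity_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.knockouts = frozenset(self.knockouts)
        overlap = self.knockouts & set(self.capacity_fractions)
        if overlap:
            raise ModelValidationError(
                f"design lists {sorted(overlap)} both as knockout and capacity target"
            )
        for rxn, f in self.capacity_fractions.items():
            if not (0.0 < f <= 1.0):
                raise ModelValidationError(
                    f"capacity fraction for {rxn!r} must be in (0, 1], got {f}"
                )

    @property
    def is_empty(self) -> bool:
        return not self.knockouts and not self.capacity_fractions

    def label(self) -> str:
        parts = [f"{r}-KO" for r in sorted(self.knockouts)]
        parts += [
            f"{int(round(f * 100))}%{r}"
            for r, f in sorted(self.capacity_fractions.items())
        ]
        return "+".join(parts) if parts else "reference"


@dataclass
class Diagnostic:
    """A single validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code}: {self.message}"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(
    model: StoichiometricModel, check_carbon: bool = True
) -> list[Diagnostic]:
    """Check all structural invariants of a model.

    Returns an empty list when every invariant holds.  Hard invariant
    violations (duplicate ids, dangling metabolite references, inverted
    bounds, empty stoichiometries, unknown objective keys) are reported
    with severity ``error``; carbon imbalance and degenerate rows/columns
    are ``warning`` diagnostics.

    Carbon closure is checked for every reaction whose participants all
    carry a ``carbon_count`` and none of which is external; reactions that
    touch an external species (exchanges, the biomass drain) are exempt.
    """
    diags: list[Diagnostic] = []
    met_ids = [m.id for m in model.metabolites]
    seen: set[str] = set()
    for mid in met_ids:
        if mid in seen:
            diags.append(Diagnostic("error", "duplicate-metabolite", mid))
        seen.add(mid)
    mets = {m.id: m for m in model.metabolites}

    seen = set()
    used_mets: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen:
            diags.append(Diagnostic("error", "duplicate-reaction", rxn.id))
        seen.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            diags.append(
                Diagnostic(
                    "error",
                    "inverted-bounds",
                    f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}",
                )
            )
        if not any(c != 0.0 for c in rxn.stoichiometry.values()):
            diags.append(
                Diagnostic(
                    "error", "empty-stoichiometry",
                    f"reaction {rxn.id} has no nonzero coefficient",
                )
            )
        for met in rxn.stoichiometry:
            used_mets.add(met)
            if met not in mets:
                diags.append(
                    Diagnostic(
                        "error", "unknown-metabolite",
                        f"reaction {rxn.id} references undeclared metabolite {met!r}",
                    )
                )
        if check_carbon:
            participants = [mets.get(m) for m in rxn.stoichiometry]
            if all(p is not None for p in participants) and not any(
                p.is_external for p in participants
            ):
                counts = [p.carbon_count for p in participants]
                if all(c is not None for c in counts):
                    net = sum(
                        coeff * mets[m].carbon_count
                        for m, coeff in rxn.stoichiometry.items()
                    )
                    if abs(net) > 1e-9:
                        diags.append(
                            Diagnostic(
                                "warning", "carbon-imbalance",
                                f"reaction {rxn.id} has net carbon {net:+g}",
                            )
                        )

    rxn_ids = {r.id for r in model.reactions}
    for obj_rxn in model.objective:
        if obj_rxn not in rxn_ids:
            diags.append(
                Diagnostic(
                    "error", "unknown-objective",
                    f"objective references undeclared reaction {obj_rxn!r}",
                )
            )
    for m in model.internal_metabolites:
        if m.id not in used_mets:
            diags.append(
                Diagnostic(
                    "warning", "orphan-metabolite",
                    f"metabolite {m.id} appears in no reaction",
                )
            )
    return diags


def _raise_on_errors(model: StoichiometricModel) -> None:
    errors = [d for d in validate_model(model, check_carbon=False) if d.severity == "error"]
    if errors:
        raise ModelValidationError("; ".join(d.message or d.code for d in errors))


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def load_model(path: str | Path) -> StoichiometricModel:
    """Read a model from the JSON dialect and validate its invariants."""
    path = Path(path)
    try:
        document = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    return model_from_dict(document)


def model_from_dict(document: Mapping) -> StoichiometricModel:
    """Build and validate a model from a parsed dialect document."""
    model = StoichiometricModel()
    try:
        for entry in document.get("metabolites", []):
            model.metabolites.append(
                Metabolite(
                    id=entry["id"],
                    name=entry.get("name", ""),
                    compartment=entry.get("compartment", "c"),
                    is_external=bool(entry.get("external", False)),
                    carbon_count=entry.get("carbon"),
                )
            )
        for entry in document.get("reactions", []):
            reversible = bool(entry.get("reversible", False))
            lb = entry.get("lb", -DEFAULT_BOUND if reversible else 0.0)
            ub = entry.get("ub", DEFAULT_BOUND)
            model.reactions.append(
                Reaction(
                    id=entry["id"],
                    name=entry.get("name", ""),
                    stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                    gene_tag=entry.get("gene"),
                )
            )
    except KeyError as exc:
        raise ModelFormatError(f"model document entry is missing key {exc}") from exc
    model.objective = {k: float(v) for k, v in document.get("objective", {}).items()}
    model.annotations = dict(document.get("annotations", {}))
    _raise_on_errors(model)
    return model


def model_to_dict(model: StoichiometricModel) -> dict:
    """Serialise a model to a dialect document (bounds always explicit)."""
    doc: dict = {"metabolites": [], "reactions": []}
    for m in model.metabolites:
        entry: dict = {"id": m.id, "name": m.name, "compartment": m.compartment,
                       "external": m.is_external}
        if m.carbon_count is not None:
            entry["carbon"] = m.carbon_count
        doc["metabolites"].append(entry)
    for r in model.reactions:
        entry = {
            "id": r.id,
            "name": r.name,
            "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
            "lb": float(r.lower_bound),
            "ub": float(r.upper_bound),
        }
        if r.gene_tag is not None:
            entry["gene"] = r.gene_tag
        doc["reactions"].append(entry)
    doc["objective"] = {k: float(v) for k, v in model.objective.items()}
    doc["annotations"] = dict(model.annotations)
    return doc


def save_model(model: StoichiometricModel, path: str | Path) -> None:
    """Write a model to the JSON dialect; refuses invalid models."""
    _raise_on_errors(model)
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# VG pathway augmentation
# ---------------------------------------------------------------------------

#: Default resolution of pathway roles to metabolite ids.
DEFAULT_VG_ID_MAP: dict[str, str] = {
    "3-DHS": "dhs",
    "ATP": "atp",
    "NADPH": "nadph",
    "SAM": "sam",
    "SAH": "sah",
    "UDP-glucose": "udpg",
    "UDP": "udp",
    "PAC": "pac",
    "PAL": "pal",
    "vanillic acid": "va",
    "vanillin": "van",
    "VG": "vg",
}

#: Carbon counts of the pathway species created on demand.  SAM is counted
#: as its transferable methyl carbon so methylation reactions close.
_VG_CARBON = {"PAC": 7, "PAL": 7, "vanillic acid": 8, "vanillin": 8, "VG": 14,
              "SAM": 1, "SAH": 0, "UDP-glucose": 6, "UDP": 0,
              "ATP": 0, "NADPH": 0}

#: Ids of the five heterologous conversions, in pathway order.
VG_PATHWAY_REACTIONS = ("3DSD", "ACAR", "hsOMT_a", "hsOMT_b", "UGT")

#: Ids of the secretion exchanges added alongside the conversions.
VG_SECRETION_REACTIONS = (
    "PAC_secretion", "PAL_secretion", "vanillate_secretion",
    "vanillin_secretion", "VG_secretion",
)


def augment_vg_pathway(
    model: StoichiometricModel,
    id_map: Mapping[str, str] | None = None,
) -> StoichiometricModel:
    """Graft the five-reaction vanillin beta-D-glucoside pathway.

    Adds exactly five irreversible conversions to the input model: 3-DHS
    dehydratase (3DSD), an aryl carboxylic acid reductase (ACAR, ATP- and
    NADPH-dependent), the O-methyltransferase on both the acid and the
    aldehyde substrate (hsOMT_a / hsOMT_b, SAM-dependent), and a UDP
    glucosyltransferase (UGT).  Secretion exchanges for the five pathway
    species (PAC, PAL, vanillic acid, vanillin, VG) are added in addition,
    since all intermediates are exportable.  The input model is not
    modified; the returned copy is valid.
    """
    roles = dict(DEFAULT_VG_ID_MAP)
    if id_map:
        roles.update(id_map)

    out = model.copy()
    present = [r for r in VG_PATHWAY_REACTIONS if out.has_reaction(r)]
    if present:
        raise ModelValidationError(
            f"pathway reactions already present: {present}"
        )
    if not out.has_metabolite(roles["3-DHS"]):
        raise ValueError(
            f"precursor role '3-DHS' does not resolve: no metabolite "
            f"{roles['3-DHS']!r} in model"
        )

    def ensure(role: str) -> str:
        met_id = roles[role]
        if not out.has_metabolite(met_id):
            out.metabolites.append(
                Metabolite(id=met_id, name=role, carbon_count=_VG_CARBON.get(role))
            )
        return met_id

    dhs = roles["3-DHS"]
    atp, nadph = ensure("ATP"), ensure("NADPH")
    sam, sah = ensure("SAM"), ensure("SAH")
    udpg, udp = ensure("UDP-glucose"), ensure("UDP")
    pac, pal = ensure("PAC"), ensure("PAL")
    va, van, vg = ensure("vanillic acid"), ensure("vanillin"), ensure("VG")

    conversions = [
        Reaction("3DSD", {dhs: -1, pac: 1},
                 name="3-dehydroshikimate dehydratase", gene_tag="3DSD"),
        Reaction("ACAR", {pac: -1, atp: -1, nadph: -1, pal: 1},
                 name="aryl carboxylic acid reductase", gene_tag="ACAR"),
        Reaction("hsOMT_a", {pac: -1, sam: -1, va: 1, sah: 1},
                 name="O-methyltransferase (acid substrate)", gene_tag="hsOMT"),
        Reaction("hsOMT_b", {pal: -1, sam: -1, van: 1, sah: 1},
                 name="O-methyltransferase (aldehyde substrate)", gene_tag="hsOMT"),
        Reaction("UGT", {van: -1, udpg: -1, vg: 1, udp: 1},
                 name="UDP-glucosyltransferase", gene_tag="UGT72E2"),
    ]
    secreted = [(pac, "PAC_secretion"), (pal, "PAL_secretion"),
                (va, "vanillate_secretion"), (van, "vanillin_secretion"),
                (vg, "VG_secretion")]
    secretions = []
    for met_id, rxn_id in secreted:
        if out.has_reaction(rxn_id):
            raise ModelValidationError(f"reaction id collision: {rxn_id}")
        ext_id = met_id + "_e"
        if not out.has_metabolite(ext_id):
            met = out.metabolite(met_id)
            out.metabolites.append(
                Metabolite(id=ext_id, name=met.name + " (extracellular)",
                           compartment="e", is_external=True,
                           carbon_count=met.carbon_count)
            )
        secretions.append(
            Reaction(rxn_id, {met_id: -1, ext_id: 1}, name=rxn_id.replace("_", " "))
        )

    out.reactions.extend(conversions)
    out.reactions.extend(secretions)
    _raise_on_errors(out)
    return out


# ---------------------------------------------------------------------------
# design application
# ---------------------------------------------------------------------------

def apply_design(
    model: StoichiometricModel,
    design: MutantDesign,
    reference: FluxDistribution | None = None,
    capacity_mode: str = "reference",
) -> StoichiometricModel:
    """Return a copy of the model with a mutant design applied.

    Knocked-out reactions get ``(0, 0)`` bounds.  Capacity-restricted
    reactions get their upper bound replaced by ``f * |v_ref|`` in
    ``"reference"`` mode (fraction of the flux carried in the reference
    distribution) or ``f * upper_bound`` in ``"upper_bound"`` mode.  All
    other bounds are untouched and the input model is not modified.
    """
    if capacity_mode not in ("reference", "upper_bound"):
        raise ValueError(f"unknown capacity mode {capacity_mode!r}")
    if capacity_mode == "reference" and design.capacity_fractions and reference is None:
        raise ValueError("capacity fractions in reference mode need a reference flux")

    out = model.copy()
    for rxn_id in design.knockouts:
        rxn = out.reaction(rxn_id)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    for rxn_id, f in design.capacity_fractions.items():
        rxn = out.reaction(rxn_id)
        if capacity_mode == "reference":
            cap = f * abs(reference.get(rxn_id, 0.0))
        else:
            cap = f * rxn.upper_bound
        rxn.upper_bound = cap
        if rxn.lower_bound > cap:
            rxn.lower_bound = cap
    return out
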