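"""Independent LP oracle built on COBRApy's GLPK interface.

Used only in tests, as a cross-check of the package's own scipy/HiGHS
solver layer: the two routes share no optimization code.
"""

from __future__ import annotations

from cobra import Metabolite as _CobraMetabolite
from cobra import Model as _CobraModel
from cobra import Reaction as _CobraReaction

from fluxdesigner.stoichmodel import StoichiometricModel


def to_cobra(model: StoichiometricModel) -> _CobraModel:
    out = _CobraModel("oracle")
    mets = {m.id: _CobraMetabolite(m.id) for m in model.internal_metabolites}
    rxns = []
    for r in model.reactions:
        cr = _CobraReaction(r.id, lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        cr.add_metabolites(
            {mets[k]: v for k, v in r.stoichiometry.items() if k in mets}
        )
        rxns.append(cr)
    out.add_reactions(rxns)
    return out


def cobra_max(model: StoichiometricModel, objective_reaction: str) -> float:
    """Maximum of a single-reaction objective, via GLPK."""
    cm = to_cobra(model)
    cm.objective = objective_reaction
    sol = cm.optimize()
    assert sol.status == "optimal", sol.status
    return float(sol.objective_value)
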