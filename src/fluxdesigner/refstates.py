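"""Reference flux distributions and packaged physiological fixtures.

Three named reference states drive the strain-design workflow:

* ``respiratory`` — purely oxidative growth at low glucose uptake, no
  ethanol formation (Reference 1);
* ``respiro_fermentative`` — glucose excess above the critical uptake,
  mixed respiration and alcoholic fermentation (Reference 2);
* ``measured_vg0`` — the producer reference strain's chemostat state at
  dilution rate 0.1 h^-1, constrained by measured exchange rates
  (Reference 3); ``measured_vg2`` and ``measured_vg4`` are the analogous
  states of the two engineered strains.

Reference flux vectors are obtained by growth-maximizing FBA with a
parsimonious tie-break; for the measured states growth is pinned at the
dilution rate, so the FBA step only confirms feasibility and the
parsimonious selection does the actual work.
"""

from __future__ import annotations

from .solvers import reference_fba
from .stoichmodel import FluxDistribution, StoichiometricModel
from .toynet import (
    CHEMOSTAT_DILUTION_RATE,
    MEASURED_RATES,
    CoreModelParams,
    PhysiologicalState,
    make_state_spec,
)

#: All packaged state names, in workflow order.
FIXTURE_STATE_MODES = (
    "respiratory",
    "respiro_fermentative",
    "measured_vg0",
    "measured_vg2",
    "measured_vg4",
)

#: Batch-cultivation physiology of the producer strains (metadata only;
#: batch dynamics are outside the steady-state framework).  Columns:
#: maximum specific growth rate (h^-1), biomass, ethanol and glycerol
#: yields on glucose (g/g).
BATCH_PHYSIOLOGY: dict[str, dict[str, float]] = {
    "VG0": {"mu_max": 0.14, "Y_sx": 0.10, "Y_eth": 0.23, "Y_gly": 0.05},
    "VG1": {"mu_max": 0.10, "Y_sx": 0.07, "Y_eth": 0.25, "Y_gly": 0.03},
    "VG2": {"mu_max": 0.20, "Y_sx": 0.14, "Y_eth": 0.23, "Y_gly": 0.07},
    "VG3": {"mu_max": 0.11, "Y_sx": 0.10, "Y_eth": 0.27, "Y_gly": 0.05},
    "VG4": {"mu_max": 0.17, "Y_sx": 0.17, "Y_eth": 0.25, "Y_gly": 0.07},
}

#: Chemostat VG yields on glucose (mg VG per g glucose) at D = 0.1 h^-1.
CHEMOSTAT_VG_YIELD_MG_PER_G: dict[str, float] = {
    "VG0": 4.0,
    "VG2": 5.6,
    "VG4": 4.16,
}

#: VG titers (mg/l) reached in low-dilution-rate chemostats (D = 0.015
#: h^-1), where respiration dominates and overflow is minimal.
LOW_DILUTION_VG_TITER_MG_PER_L: dict[str, float] = {
    "VG0": 250.0,
    "VG2": 500.0,
}


def list_fixture_states(
    params: CoreModelParams | None = None,
) -> list[PhysiologicalState]:
    """The five packaged physiological states, measured values as printed."""
    return [make_state_spec(mode, params) for mode in FIXTURE_STATE_MODES]


def build_reference(
    model: StoichiometricModel,
    state: PhysiologicalState | str,
    params: CoreModelParams | None = None,
) -> FluxDistribution:
    """Build the labelled reference flux distribution for a state.

    ``state`` may be a :class:`PhysiologicalState` or one of the packaged
    mode names.  Delegates to growth-maximizing FBA with the parsimonious
    tie-break; infeasibility raises with the violated intervals listed.
    """
    if isinstance(state, str):
        state = make_state_spec(state, params)
    ref = reference_fba(model, state)
    ref.name = state.mode
    return ref


__all__ = [
    "BATCH_PHYSIOLOGY",
    "CHEMOSTAT_DILUTION_RATE",
    "CHEMOSTAT_VG_YIELD_MG_PER_G",
    "FIXTURE_STATE_MODES",
    "LOW_DILUTION_VG_TITER_MG_PER_L",
    "MEASURED_RATES",
    "build_reference",
    "list_fixture_states",
]
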