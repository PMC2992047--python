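"""Numerical tolerances shared by every solver and report routine.

All feasibility and comparison decisions in the package go through a single
:class:`Tolerances` instance so that no module carries its own magic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Tolerances:
    """Package-wide numerical tolerances.

    Attributes
    ----------
    feasibility:
        Maximum absolute steady-state violation ``|S v|`` accepted in a
        flux distribution.
    comparison:
        Tolerance for equality comparisons between fluxes and bounds.
    category:
        Absolute tolerance used when comparing flux-variability bounds
        during range classification.
    growth_floor:
        Growth rates at or below this value (h^-1) count as "no growth"
        when deciding mutant viability.
    ma_epsilon:
        Metabolic adjustments below this value make the reward-risk ratio
        undefined (the mutant is phenotypically identical to the reference).
    bisection:
        Absolute tolerance of the critical-uptake bisection.
    """

    feasibility: float = 1e-6
    comparison: float = 1e-6
    category: float = 1e-4
    growth_floor: float = 1e-4
    ma_epsilon: float = 1e-6
    bisection: float = 1e-4


#: Default tolerance configuration used when none is supplied.
DEFAULT_TOLERANCES = Tolerances()
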