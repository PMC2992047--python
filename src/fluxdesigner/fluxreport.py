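"""Post-hoc comparison of mutant and reference flux phenotypes.

Flux-variability ranges of a mutant are compared per reaction with the
reference ranges and classified into six categories:

* ``blocked`` — the flux is zero in both conditions;
* ``a`` — identical ranges (no change);
* ``b`` — the mutant range contains the reference range (wider);
* ``c`` — the mutant range is contained in the reference range (narrower);
* ``d`` — both bounds shifted up (the mutant must carry more flux);
* ``e`` — both bounds shifted down.

The six cases partition all pairs of intervals.  Metabolite-centric
comparison uses the minimum-turnover LP per condition and reports a
qualitative arrow (increase / decrease / unchanged) per metabolite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .config import DEFAULT_TOLERANCES, Tolerances
from .design import DesignEvaluation
from .solvers import FluxRange, Infeasible, min_flux_sum
from .stoichmodel import StoichiometricModel

CATEGORY_LABELS = ("blocked", "a", "b", "c", "d", "e")


@dataclass
class TurnoverArrow:
    """Qualitative change of a metabolite's minimum turnover."""

    metabolite: str
    direction: str  # increase | decrease | unchanged
    ref_phi: float
    mut_phi: float


def classify_ranges(
    ref: Mapping[str, FluxRange],
    mut: Mapping[str, FluxRange],
    tol: float | None = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> dict[str, str]:
    """Classify each reaction's mutant range against the reference range.

    Bounds are compared with absolute tolerance ``tol``; the mixed case
    (mutant lower bound below and upper bound above the reference) counts
    as containment, category ``b``.
    """
    tol = tolerances.category if tol is None else tol
    if set(ref) != set(mut):
        missing = set(ref) ^ set(mut)
        raise ValueError(f"reaction sets differ: {sorted(missing)[:5]}...")

    out: dict[str, str] = {}
    for rxn in ref:
        r, m = ref[rxn], mut[rxn]
        if max(abs(r.lo), abs(r.hi), abs(m.lo), abs(m.hi)) <= tol:
            out[rxn] = "blocked"
            continue
        lo_cmp = 0 if abs(m.lo - r.lo) <= tol else (1 if m.lo > r.lo else -1)
        hi_cmp = 0 if abs(m.hi - r.hi) <= tol else (1 if m.hi > r.hi else -1)
        if lo_cmp == 0 and hi_cmp == 0:
            out[rxn] = "a"
        elif lo_cmp <= 0 and hi_cmp >= 0:
            out[rxn] = "b"
        elif lo_cmp >= 0 and hi_cmp <= 0:
            out[rxn] = "c"
        elif lo_cmp > 0 and hi_cmp > 0:
            out[rxn] = "d"
        else:  # lo_cmp < 0 and hi_cmp < 0
            out[rxn] = "e"
    return out


def compare_turnovers(
    model: StoichiometricModel,
    ref_state,
    mut_model: StoichiometricModel,
    mut_state,
    metabolites: Iterable[str],
    tol: float = 1e-4,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> list[TurnoverArrow]:
    """Minimum-turnover arrows of the mutant condition vs the reference.

    A change counts as increase/decrease when it exceeds
    ``tol * max(1, ref_phi)``; infeasibility is re-raised naming the
    offending condition.
    """
    arrows = []
    for met in metabolites:
        try:
            ref_phi = min_flux_sum(model, met, ref_state, tolerances=tolerances).phi_min
        except Infeasible as exc:
            raise Infeasible(
                f"reference condition infeasible while scoring {met!r}: {exc}",
                details=exc.details,
            ) from exc
        try:
            mut_phi = min_flux_sum(mut_model, met, mut_state, tolerances=tolerances).phi_min
        except Infeasible as exc:
            raise Infeasible(
                f"mutant condition infeasible while scoring {met!r}: {exc}",
                details=exc.details,
            ) from exc
        delta = mut_phi - ref_phi
        if abs(delta) > tol * max(1.0, abs(ref_phi)):
            direction = "increase" if delta > 0 else "decrease"
        else:
            direction = "unchanged"
        arrows.append(TurnoverArrow(met, direction, ref_phi, mut_phi))
    return arrows


# ---------------------------------------------------------------------------
# ratio helpers for measured fixture values
# ---------------------------------------------------------------------------

def percent_increase(mutant_value: float, reference_value: float) -> float:
    """Relative increase of a mutant quantity over the reference, in %."""
    if reference_value == 0:
        raise ValueError("reference value is zero")
    return (mutant_value - reference_value) / reference_value * 100.0


def fold_change(mutant_value: float, reference_value: float) -> float:
    """Ratio of a mutant quantity to the reference."""
    if reference_value == 0:
        raise ValueError("reference value is zero")
    return mutant_value / reference_value


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def designs_frame(evaluations: list[DesignEvaluation]) -> pd.DataFrame:
    rows = []
    for e in evaluations:
        rows.append(
            {
                "design": e.design.label(),
                "knockouts": ",".join(sorted(e.design.knockouts)),
                "capacity_fractions": ",".join(
                    f"{r}:{f:g}" for r, f in sorted(e.design.capacity_fractions.items())
                ),
                "growth": e.growth,
                "yield": e.yield_,
                "bpcy": e.bpcy,
                "ma": e.ma,
                "r3": "" if e.r3 is None else e.r3,
                "r3_normalized": "" if e.r3_normalized is None else e.r3_normalized,
                "viable": e.viable,
            }
        )
    columns = ["design", "knockouts", "capacity_fractions", "growth", "yield",
               "bpcy", "ma", "r3", "r3_normalized", "viable"]
    return pd.DataFrame(rows, columns=columns)


def categories_frame(
    ref: Mapping[str, FluxRange],
    mut: Mapping[str, FluxRange],
    categories: Mapping[str, str],
) -> pd.DataFrame:
    rows = [
        {
            "reaction": rxn,
            "ref_lo": ref[rxn].lo,
            "ref_hi": ref[rxn].hi,
            "mut_lo": mut[rxn].lo,
            "mut_hi": mut[rxn].hi,
            "category": categories[rxn],
        }
        for rxn in sorted(categories)
    ]
    return pd.DataFrame(
        rows, columns=["reaction", "ref_lo", "ref_hi", "mut_lo", "mut_hi", "category"]
    )


def turnover_frame(arrows: list[TurnoverArrow]) -> pd.DataFrame:
    rows = [
        {
            "metabolite": a.metabolite,
            "ref_phi": a.ref_phi,
            "mut_phi": a.mut_phi,
            "direction": a.direction,
        }
        for a in arrows
    ]
    return pd.DataFrame(rows, columns=["metabolite", "ref_phi", "mut_phi", "direction"])


def write_reports(
    out_dir: str | Path,
    evaluations: list[DesignEvaluation] | None = None,
    categories: tuple[Mapping[str, FluxRange], Mapping[str, FluxRange], Mapping[str, str]] | None = None,
    arrows: list[TurnoverArrow] | None = None,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write TSV reports and a provenance manifest to ``out_dir``.

    Emits ``designs.tsv``, ``fva_categories.tsv`` (reference and mutant
    bounds plus category per reaction), ``turnover.tsv`` and
    ``manifest.json``; empty inputs produce header-only files.  Re-running
    with identical inputs reproduces byte-identical TSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    frame = designs_frame(evaluations or [])
    path = out / "designs.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)

    if categories is not None:
        ref, mut, cats = categories
        frame = categories_frame(ref, mut, cats)
    else:
        frame = categories_frame({}, {}, {})
    path = out / "fva_categories.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)

    frame = turnover_frame(arrows or [])
    path = out / "turnover.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)

    path = out / "manifest.json"
    path.write_text(json.dumps(dict(manifest or {}), indent=1, sort_keys=True) + "\n",
                    encoding="utf-8")
    written.append(path)
    return written
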