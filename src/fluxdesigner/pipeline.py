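"""Configuration-driven orchestration of the two workflows.

``design``: build reference flux distributions for the requested
physiological modes, search knockout space (exhaustively and/or with the
genetic algorithm), score designs by BPCY / metabolic adjustment / R^3,
normalize R^3 within each reference panel and write ranked reports.

``analyze``: constrain the network with measured chemostat states, apply
mutant designs (gene knockouts plus the 80 %-of-upper-bound rule for the
partially deleted decarboxylase), run flux variability for reference and
mutant, classify per-reaction range changes and compare minimum
metabolite turnovers.

Both commands read a YAML configuration and emit TSV reports plus a
provenance manifest (config echo, seed, tolerances, version) into the
output directory.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from pathlib import Path
from typing import Mapping

import click
import yaml

from . import __version__
from .config import DEFAULT_TOLERANCES
from .design import GAParams, evaluate_design, exhaustive_search, normalize_r3, optgene_search
from .fluxreport import classify_ranges, compare_turnovers, write_reports
from .refstates import build_reference
from .solvers import apply_state, flux_variability
from .stoichmodel import (
    MutantDesign,
    StoichiometricModel,
    apply_design,
    load_model,
    save_model,
)
from .toynet import build_vg_model, make_state_spec

log = logging.getLogger("fluxdesigner")


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise click.UsageError(f"config {config} is not a mapping")
    return loaded


def _resolve_model(spec: str | None) -> StoichiometricModel:
    if spec in (None, "toy"):
        return build_vg_model()
    return load_model(spec)


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise click.UsageError(f"config is missing required key {key!r}")
    return cfg[key]


def _manifest(cfg: dict, seed: int | None) -> dict:
    return {
        "config": cfg,
        "seed": seed,
        "tolerances": dataclasses.asdict(DEFAULT_TOLERANCES),
        "version": __version__,
    }


def run_design(
    config: str | Path | Mapping,
    out: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Run the strain-design workflow; returns the artifact directory."""
    cfg = _load_config(config)
    model = _resolve_model(cfg.get("model", "toy"))
    modes = _require(cfg, "modes")
    product = cfg.get("product", "VG_secretion")
    substrate = cfg.get("substrate", "glucose_uptake")
    search = cfg.get("search", {})
    method = search.get("method", "exhaustive")
    if method not in ("exhaustive", "ga", "both"):
        raise click.UsageError(f"unknown search method {method!r}")
    seed = seed if seed is not None else cfg.get("seed", 0)
    out_dir = Path(out if out is not None else cfg.get("out", "fluxdesigner_design"))
    candidates = cfg.get("candidates")
    rank_by = search.get("rank_by", "r3")

    out_dir.mkdir(parents=True, exist_ok=True)
    for mode in modes:
        log.info("building reference for mode %s", mode)
        state = make_state_spec(mode)
        constrained = apply_state(model, state)
        reference = build_reference(constrained, state)
        evaluations = []
        if method in ("exhaustive", "both"):
            evaluations += exhaustive_search(
                constrained, reference, product, substrate,
                k=int(search.get("k", 1)), candidates=candidates,
                rank_by=rank_by)
        if method in ("ga", "both"):
            ga_cfg = dict(search.get("ga", {}))
            ga_cfg.setdefault("seed", seed)
            params = GAParams(**ga_cfg)
            evaluations += optgene_search(
                constrained, reference, product, substrate, params,
                candidates=candidates)
        for extra in cfg.get("capacity_designs", []):
            design = MutantDesign(capacity_fractions=dict(extra))
            evaluations.append(
                evaluate_design(constrained, design, reference, product, substrate))
        evaluations = normalize_r3(evaluations)
        evaluations.sort(
            key=lambda e: -1.0 if e.r3_normalized is None else e.r3_normalized,
            reverse=True)
        write_reports(out_dir / mode, evaluations=evaluations,
                      manifest=_manifest(cfg, seed) | {"mode": mode})
        log.info("mode %s: %d designs written", mode, len(evaluations))
    return out_dir


def run_analyze(
    config: str | Path | Mapping,
    out: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Run the measured-state flux-analysis workflow."""
    cfg = _load_config(config)
    model = _resolve_model(cfg.get("model", "toy"))
    ref_mode = cfg.get("reference_state", "measured_vg0")
    mutants = _require(cfg, "mutants")
    metabolites = cfg.get("metabolites", [])
    seed = seed if seed is not None else cfg.get("seed", 0)
    out_dir = Path(out if out is not None else cfg.get("out", "fluxdesigner_analyze"))
    out_dir.mkdir(parents=True, exist_ok=True)

    ref_state = make_state_spec(ref_mode)
    log.info("flux variability for reference state %s", ref_mode)
    ref_ranges = flux_variability(model, ref_state, fix_growth=True)

    for mutant in mutants:
        name = mutant.get("name", mutant["state"])
        mut_state = make_state_spec(mutant["state"])
        mut_model = model.copy()
        knockouts = mutant.get("knockouts", [])
        if knockouts:
            mut_model = apply_design(mut_model, MutantDesign(knockouts=set(knockouts)))
        fraction = mutant.get("pdc_fraction")
        if fraction is not None:
            pdc = mutant.get("pdc_reaction", "PDC")
            probe = apply_state(mut_model, mut_state)
            upper = flux_variability(probe, reactions=[pdc])[pdc].hi
            mut_model.reaction(pdc).upper_bound = fraction * upper
            log.info("%s: %s upper bound set to %.4g (%.0f%% of %.4g)",
                     name, pdc, fraction * upper, 100 * fraction, upper)
        mut_ranges = flux_variability(mut_model, mut_state, fix_growth=True)
        cats = classify_ranges(ref_ranges, mut_ranges)
        arrows = compare_turnovers(model, ref_state, mut_model, mut_state, metabolites)
        (out_dir / name).mkdir(parents=True, exist_ok=True)
        save_model(mut_model, out_dir / name / "mutant_model.json")
        write_reports(
            out_dir / name,
            categories=(ref_ranges, mut_ranges, cats),
            arrows=arrows,
            manifest=_manifest(cfg, seed) | {"mutant": name},
        )
        log.info("mutant %s analyzed (%d reactions, %d metabolites)",
                 name, len(cats), len(arrows))
    return out_dir


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="INFO", show_default=True,
              help="Logging verbosity (stderr).")
def cli(log_level: str) -> None:
    """Strain design and flux analysis on stoichiometric models."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.option("--config", required=True, type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def design(config: str, out: str | None, seed: int | None) -> None:
    """Search and rank knockout designs per reference state."""
    path = run_design(config, out=out, seed=seed)
    click.echo(f"design artifacts written to {path}")


@cli.command()
@click.option("--config", required=True, type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def analyze(config: str, out: str | None, seed: int | None) -> None:
    """Flux variability categories and turnover arrows vs a reference."""
    path = run_analyze(config, out=out, seed=seed)
    click.echo(f"analysis artifacts written to {path}")


if __name__ == "__main__":  # pragma: no cover
    cli()
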