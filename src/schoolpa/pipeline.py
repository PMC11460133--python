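"""End-to-end scenario pipeline.

Stages: generate the synthetic survey → keep school attendees → build
population margins → rake weights → baseline national estimates → one
scenario per intervention → scorecard → national costing → tables, figure
and a machine-readable run manifest.  Identical (config, seed) produce
byte-identical CSV outputs; a failed stage aborts the run and removes any
partial outputs.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import DETERMINANTS, RunConfig
from .costing import cost_intervention, load_default_tables
from .estimation import summarize_determinants
from .exceptions import SchoolPAError
from .interventions import InterventionSpec, rank_interventions, run_scenario
from .population import (
    apply_school_filter,
    generate_margins,
    generate_population,
    margin_variable,
    write_margins_csv,
    write_population_csv,
)
from .presets import illustrative_specs, published_delta_specs
from .raking import ipf_rake
from .reporting import demographic_table, render_estimates_figure, write_manifest

log = logging.getLogger("schoolpa")


@dataclass
class PipelineResult:
    participants: pd.DataFrame
    determinants: pd.DataFrame
    weights: object
    baseline: pd.DataFrame
    scenarios: list = field(default_factory=list)
    scorecard: pd.DataFrame | None = None
    costs: pd.DataFrame | None = None
    demographics: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


class StageError(SchoolPAError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return out
        return wrapped
    return deco


def _resolve_specs(config: RunConfig, participants, weights, baseline_means):
    if isinstance(config.interventions, str):
        if config.interventions in ("published_deltas", "published"):
            return published_delta_specs(participants, weights,
                                         baseline_means)
        if config.interventions == "illustrative":
            return illustrative_specs()
        if config.interventions == "none":
            return []
        raise SchoolPAError(
            f"unknown intervention preset {config.interventions!r}"
        )
    specs = list(config.interventions)
    for s in specs:
        if not isinstance(s, InterventionSpec):
            raise SchoolPAError(
                "interventions must be a preset name or InterventionSpec "
                "objects"
            )
    return specs


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full scenario model; optionally write the artifact bundle."""
    config.validate()
    config.population.seed = config.seed

    generate = _stage("generate")(generate_population)
    participants, determinants = generate(config.population)
    log.info("generate: %d participants surveyed", len(participants))

    filt = _stage("filter")(apply_school_filter)
    participants_f, determinants_f = filt(participants, determinants)
    log.info("filter: %d attend secondary school", len(participants_f))

    margins = _stage("margins")(generate_margins)(
        participants_f, config.raking_margins, config.population_total
    )
    memberships = pd.DataFrame({
        m.variable: margin_variable(participants_f, m.variable)
        for m in margins
    })
    raked = _stage("rake")(ipf_rake)(
        participants_f["base_weight"].to_numpy(), memberships, margins,
        tol=config.raking_tol, max_iter=config.raking_max_iter,
    )
    weights = raked.weights
    log.info("rake: converged=%s after %d cycles (deviation %.3g)",
             raked.converged, raked.n_iterations,
             raked.max_margin_deviation)

    baseline = _stage("estimate")(summarize_determinants)(
        participants_f, determinants_f, weights, "weighted", config.ci_level
    )
    baseline.insert(0, "scenario", "Baseline")
    unweighted = summarize_determinants(
        participants_f, determinants_f, None, "unweighted"
    )
    unweighted.insert(0, "scenario", "Baseline")
    baseline_means = dict(zip(baseline["determinant"], baseline["mean"]))

    specs = _stage("interventions")(_resolve_specs)(
        config, participants_f, weights, baseline_means
    )
    scenarios = []
    for spec in specs:
        res = _stage(f"scenario:{spec.name}")(run_scenario)(
            participants_f, determinants_f, weights, spec, config.ci_level
        )
        scenarios.append(res)
        log.info("scenario %s: eligible share %.3f", spec.name,
                 res.eligible_weight_share)

    scorecard = None
    if len(scenarios) >= 2:
        # rank unit determinants on mean change, bounded scores on percent
        # change of the mean — the scales the results are reported on
        improvements = pd.DataFrame({
            r.intervention: {
                det: (r.percent_change[det]
                      if det in ("physical_literacy", "social_support")
                      else r.delta[det])
                for det in DETERMINANTS
            }
            for r in scenarios
        }).loc[list(DETERMINANTS)]
        scorecard = _stage("scorecard")(rank_interventions)(improvements)

    costs = None
    cost_rows = []
    cpi, ppp = load_default_tables()
    for spec in specs:
        if spec.cost_inputs is None:
            continue
        cr = _stage(f"cost:{spec.name}")(cost_intervention)(
            spec.name, spec.cost_inputs, cpi, ppp,
            config.n_schools, config.students_per_school,
        )
        cost_rows.append({
            "intervention": cr.intervention,
            "per_school_nzd": cr.per_school_nzd,
            "per_student_nzd": cr.per_student_nzd,
            "national_nzd": cr.national_nzd,
        })
    if cost_rows:
        costs = pd.DataFrame(cost_rows)

    demographics = _stage("demographics")(demographic_table)(participants_f)

    manifest = {
        "schoolpa_version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "n_surveyed": int(len(participants)),
        "n_analytic": int(len(participants_f)),
        "raking_converged": bool(raked.converged),
        "raking_cycles": int(raked.n_iterations),
        "interventions": [s.name for s in specs],
    }

    result = PipelineResult(
        participants=participants_f, determinants=determinants_f,
        weights=weights, baseline=baseline, scenarios=scenarios,
        scorecard=scorecard, costs=costs, demographics=demographics,
        manifest=manifest,
    )

    if out_dir is not None:
        _write_bundle(result, margins, unweighted, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, margins, unweighted,
                  out_dir: Path) -> None:
    """Write all artifacts atomically: stage into a sibling directory and
    move into place only on success."""
    staging = out_dir.with_name(out_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        write_population_csv(staging / "population.csv",
                             result.participants, result.determinants,
                             result.weights)
        write_margins_csv(staging / "margins.csv", margins)
        result.baseline.to_csv(staging / "baseline_weighted.csv",
                               index=False)
        unweighted.to_csv(staging / "baseline_unweighted.csv", index=False)
        for res in result.scenarios:
            res.to_frame().to_csv(
                staging / f"scenario_{res.intervention}.csv", index=False
            )
        if result.scorecard is not None:
            result.scorecard.to_csv(staging / "scorecard.csv",
                                    index_label="determinant")
        if result.costs is not None:
            result.costs.to_csv(staging / "costs.csv", index=False)
        result.demographics.to_csv(staging / "demographics.csv",
                                   index=False)
        render_estimates_figure(
            result.baseline,
            [r.to_frame() for r in result.scenarios],
            staging / "estimates.svg",
        )
        write_manifest(staging / "manifest.json", result.manifest)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
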