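"""End-to-end pipeline: raw cohort measurements → components → VHI scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .io import Cohort
from .mechanics import stiffness_component
from .model import (
    AnalysisConfig,
    Bed,
    Component,
    ComponentValue,
    DegenerateDataError,
    InsufficientDataError,
    Variant,
    VHIResult,
)
from .reactivity import dilation_upper_bound, fit_logistic, hypoxic_component
from .scoring import components_frame, score_cohort

log = logging.getLogger("vhi")


@dataclass
class PipelineOutput:
    components: pd.DataFrame          # animal_id, bed, component, value
    logistic_fits: pd.DataFrame       # per dose-response series diagnostics
    mechanics_fits: pd.DataFrame      # per pressure series diagnostics
    results: dict[tuple[Bed, Variant], list[VHIResult]] = field(default_factory=dict)


def compute_components(cohort: Cohort) -> PipelineOutput:
    """Run the reactivity and mechanics stages over every raw series.

    Unfittable series (degenerate, unconverged, or rejected stress–strain
    fits) contribute no component and are recorded in the diagnostics.
    """
    components: list[ComponentValue] = list(cohort.mvd)
    lfits, mfits = [], []

    for series in cohort.dose_response:
        row = {"animal_id": series.animal_id, "bed": series.bed.value,
               "agonist": series.agonist.value}
        try:
            fit = fit_logistic(series)
        except (DegenerateDataError, InsufficientDataError) as exc:
            log.warning("logistic fit failed for %s: %s", series.animal_id, exc)
            lfits.append({**row, "min": None, "max": None, "log_ec50": None,
                          "sse": None, "converged": False})
            continue
        lfits.append({**row, "min": fit.lower_bound_um, "max": fit.upper_bound_um,
                      "log_ec50": fit.log_ec50, "sse": fit.residual_sse,
                      "converged": fit.converged})
        comp = dilation_upper_bound(fit, series.animal_id, series.bed, series.agonist)
        if comp is not None:
            components.append(comp)

    for challenge in cohort.hypoxia:
        components.append(hypoxic_component(challenge))

    for series in cohort.pressure_diameter:
        fit, comp = stiffness_component(series)
        mfits.append({"animal_id": series.animal_id, "bed": series.bed.value,
                      "sigma5": fit.sigma5_N_m2, "beta": fit.beta,
                      "r2": fit.r_squared, "n_points": len(fit.points),
                      "accepted": fit.accepted})
        if comp is not None:
            components.append(comp)

    return PipelineOutput(
        components=components_frame(components),
        logistic_fits=pd.DataFrame(
            lfits, columns=["animal_id", "bed", "agonist", "min", "max",
                            "log_ec50", "sse", "converged"]),
        mechanics_fits=pd.DataFrame(
            mfits, columns=["animal_id", "bed", "sigma5", "beta", "r2",
                            "n_points", "accepted"]),
    )


def run(cohort: Cohort, config: Optional[AnalysisConfig] = None, *,
        beds: Optional[list[Bed]] = None,
        variants: Optional[list[Variant]] = None) -> PipelineOutput:
    """Compute components then score every requested (bed, variant)."""
    config = config or AnalysisConfig()
    out = compute_components(cohort)
    for bed in beds or [config.bed]:
        for variant in variants or [config.variant]:
            out.results[(bed, variant)] = score_cohort(
                out.components, cohort.animals, variant, bed,
                pool_studies=config.pool_standards)
    return out
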