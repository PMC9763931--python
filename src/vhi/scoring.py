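"""Percent-of-ideal component scores and the composite VHI.

Each component value is scored against the "standard of health" — the mean
value in age-, bed- and study-matched untreated lean (LZR) controls:

* components that fall with disease (the three dilations and MVD):
  score = (measurement / standard) × 100
* the stiffness coefficient β, which rises with disease:
  score = 100 + (100 − (measurement / standard) × 100) = 200 − ratio×100,
  i.e. the relative excess over the standard counts as a deficit.

Scores are never clamped: a β more than twice the standard legitimately
produces a negative component score.  The VHI is the unweighted arithmetic
mean of the variant's component scores (3-component: ACh dilation, MVD, β;
5-component adds SNP and hypoxic dilation), so an all-healthy animal scores
100 by construction.

Two scoring modes are provided.  Per-animal mode (``score_cohort``) scores
every animal against its matched standard and is the primary mode.
Group-mean mode (``group_mean_vhi``) scores group mean values directly —
the mean-of-ratios vs ratio-of-means distinction makes it an approximation
to the per-animal group mean, but it is the only mode available when only
published group summaries exist.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnimalRecord,
    Bed,
    Component,
    ComponentValue,
    EmptyResultError,
    Group,
    IncompleteAnimalError,
    MissingStandardError,
    StandardOfHealth,
    VHIResult,
    Variant,
    VARIANT_COMPONENTS,
    VHIError,
)

log = logging.getLogger("vhi")


class Direction:
    DECREASES_WITH_DISEASE = "decreases_with_disease"
    INCREASES_WITH_DISEASE = "increases_with_disease"


#: Expected deviation of each component from the lean standard with disease.
COMPONENT_DIRECTION: dict[Component, str] = {
    Component.ACH_DILATION: Direction.DECREASES_WITH_DISEASE,
    Component.SNP_DILATION: Direction.DECREASES_WITH_DISEASE,
    Component.HYPOXIC_DILATION: Direction.DECREASES_WITH_DISEASE,
    Component.MVD: Direction.DECREASES_WITH_DISEASE,
    Component.STIFFNESS_BETA: Direction.INCREASES_WITH_DISEASE,
}


def standard_of_health(control_values: Sequence[float], study_id: str, bed: Bed,
                       age_weeks: int, component: Component) -> StandardOfHealth:
    """Mean of matched lean-control component values → the score denominator."""
    values = [float(v) for v in control_values]
    if not values:
        raise MissingStandardError(
            f"no lean controls for (study={study_id}, bed={bed.value}, "
            f"age={age_weeks}wk, component={component.value})")
    return StandardOfHealth(
        study_id=study_id, bed=bed, age_weeks=age_weeks, component=component,
        standard_value=float(np.mean(values)), n_controls=len(values),
    )


def component_score(measurement: float, standard: float, direction: str) -> float:
    """Percent-of-ideal score; unclamped (may exceed 100 or go negative)."""
    if standard <= 0:
        raise VHIError(f"standard of health must be positive, got {standard}")
    ratio_pct = measurement / standard * 100.0
    if direction == Direction.DECREASES_WITH_DISEASE:
        return ratio_pct
    if direction == Direction.INCREASES_WITH_DISEASE:
        return 100.0 + (100.0 - ratio_pct)
    raise VHIError(f"unknown component direction {direction!r}")


def compute_vhi(scores: Mapping[Component, float], variant: Variant, *,
                animal_id: str = "", bed: Bed = Bed.PERIPHERAL) -> VHIResult:
    """Unweighted mean of the variant's component scores.

    All required components must be present; an animal missing one is
    incomplete for that variant (it may still be complete for the other).
    """
    needed = VARIANT_COMPONENTS[variant]
    missing = needed - set(scores)
    if missing:
        raise IncompleteAnimalError(
            f"animal {animal_id or '<unnamed>'} lacks component(s) "
            f"{sorted(c.value for c in missing)} for {variant.value}")
    used = {c: float(scores[c]) for c in needed}
    return VHIResult(
        animal_id=animal_id, bed=bed, variant=variant,
        score_pct=sum(used.values()) / len(used),
        component_scores=used,
    )


# --------------------------------------------------------------------------
# cohort-level scoring

def components_frame(components: Iterable[ComponentValue]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"animal_id": c.animal_id, "bed": c.bed.value,
          "component": c.component.value, "value": c.value} for c in components],
        columns=["animal_id", "bed", "component", "value"],
    )


def compute_standards(components: pd.DataFrame, animals: Mapping[str, AnimalRecord],
                      *, pool_studies: bool = False) -> dict[tuple, StandardOfHealth]:
    """Standards of health from all LZR animals, keyed by
    (study_id, bed, age_weeks, component); with ``pool_studies`` the
    study_id key is collapsed to '*' (pooled lean means, logged)."""
    rows = []
    for _, r in components.iterrows():
        a = animals.get(r["animal_id"])
        if a is None or a.group is not Group.LZR:
            continue
        sid = "*" if pool_studies else a.study_id
        rows.append((sid, r["bed"], a.age_weeks, r["component"], r["value"]))
    if pool_studies:
        log.info("pooling lean controls across studies for standards")
    out: dict[tuple, StandardOfHealth] = {}
    if not rows:
        return out
    df = pd.DataFrame(rows, columns=["study_id", "bed", "age_weeks", "component", "value"])
    for key, g in df.groupby(["study_id", "bed", "age_weeks", "component"]):
        sid, bed, age, comp = key
        out[key] = standard_of_health(list(g["value"]), sid, Bed(bed), int(age),
                                      Component(comp))
    return out


def score_cohort(components: pd.DataFrame, animals: Mapping[str, AnimalRecord],
                 variant: Variant, bed: Bed, *,
                 standards: Optional[dict[tuple, StandardOfHealth]] = None,
                 pool_studies: bool = False) -> list[VHIResult]:
    """Per-animal VHI for every animal with a complete component set.

    Animals missing a required component (or whose study lacks a lean
    standard) are skipped with a warning — they may still be scored under
    the other variant.
    """
    if standards is None:
        standards = compute_standards(components, animals, pool_studies=pool_studies)
    sub = components[components["bed"] == bed.value]
    results: list[VHIResult] = []
    for aid, g in sub.groupby("animal_id"):
        a = animals.get(aid)
        if a is None:
            continue
        sid = "*" if pool_studies else a.study_id
        scores: dict[Component, float] = {}
        for _, r in g.iterrows():
            comp = Component(r["component"])
            key = (sid, bed.value, a.age_weeks, comp.value)
            std = standards.get(key)
            if std is None:
                continue
            scores[comp] = component_score(r["value"], std.standard_value,
                                           COMPONENT_DIRECTION[comp])
        try:
            results.append(compute_vhi(scores, variant, animal_id=aid, bed=bed))
        except IncompleteAnimalError as exc:
            log.debug("skipping incomplete animal: %s", exc)
    return results


def aggregate_vhi(results: Sequence[VHIResult]) -> float:
    """All-ages aggregate: mean over all animals pooled (n-weighted)."""
    if not results:
        raise EmptyResultError("cannot aggregate an empty result set")
    return float(np.mean([r.score_pct for r in results]))


def group_summary(results: Sequence[VHIResult], animals: Mapping[str, AnimalRecord]) -> pd.DataFrame:
    """Group × age summary of per-animal VHI: mean, SE, n."""
    rows = []
    for r in results:
        a = animals.get(r.animal_id)
        if a is None:
            continue
        rows.append({"group": a.group.value, "age_weeks": a.age_weeks,
                     "bed": r.bed.value, "variant": r.variant.value,
                     "vhi_pct": r.score_pct})
    df = pd.DataFrame(rows)
    if df.empty:
        raise EmptyResultError("no results matched any animal record")
    out = (
        df.groupby(["group", "age_weeks", "bed", "variant"])["vhi_pct"]
        .agg(mean="mean", n="count",
             se=lambda s: s.std(ddof=1) / math.sqrt(len(s)) if len(s) > 1 else float("nan"))
        .reset_index()
    )
    return out[["group", "age_weeks", "bed", "variant", "mean", "se", "n"]]


# --------------------------------------------------------------------------
# group-mean mode (published summaries only)

def group_mean_vhi(group_means: Mapping[Component, float],
                   standards: Mapping[Component, float],
                   variant: Variant) -> VHIResult:
    """VHI computed from group mean component values against standard means.

    This is the only calculation possible from published group summaries;
    it approximates the per-animal group mean (mean of ratios) by the ratio
    of means, component by component.
    """
    scores = {
        c: component_score(group_means[c], standards[c], COMPONENT_DIRECTION[c])
        for c in VARIANT_COMPONENTS[variant]
        if c in group_means and c in standards
    }
    return compute_vhi(scores, variant, animal_id="<group-mean>")
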