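"""Criterion and discriminant validity of the index.

Criterion validity: in diseased (obese Zucker) cohorts the index should
correlate negatively with plasma markers of disease severity — insulin and
TNF-α — while showing minimal correlation in healthy lean controls.
Animals are pooled across ages within a group (disease severity and the
biomarkers both progress with age, so the pooled correlation captures the
construct).

Discriminant validity: the index alone should separate lean controls,
untreated obese animals, and treated obese groups at matched ages.  The
published analysis names no specific test; Welch's two-sided t-test is used
here for each pairwise comparison (robust to unequal variance and group
size).  No multiple-testing correction is applied by default, mirroring the
original presentation; a Holm adjustment is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    AnimalRecord,
    Bed,
    Biomarker,
    BIOMARKER_FIELDS,
    Group,
    UndefinedCorrelationError,
    Variant,
    VHIResult,
)

log = logging.getLogger("vhi")


@dataclass(frozen=True)
class CriterionResult:
    group: Group
    bed: Bed
    variant: Variant
    biomarker: Biomarker
    pearson_r: float
    n: int
    p_value: float


@dataclass(frozen=True)
class DiscriminantResult:
    bed: Bed
    variant: Variant
    age_weeks: int
    group: Group
    comparison: str  # "vs_LZR" | "vs_OZR"
    p_value: float
    significant: bool


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need >=3 pairs, got {len(x)}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def criterion_validity(results: Sequence[VHIResult],
                       animals: Mapping[str, AnimalRecord],
                       biomarker: Biomarker,
                       groups: Optional[Sequence[Group]] = None) -> list[CriterionResult]:
    """Per-group correlation between the biomarker and the index, pooling ages.

    Groups with fewer than three complete (biomarker, VHI) pairs are skipped
    with a warning.
    """
    field = BIOMARKER_FIELDS[biomarker]
    by_group: dict[Group, list[tuple[float, float]]] = {}
    meta: dict[Group, tuple[Bed, Variant]] = {}
    for r in results:
        a = animals.get(r.animal_id)
        if a is None:
            continue
        marker = getattr(a, field)
        if marker is None:
            continue
        if groups is not None and a.group not in groups:
            continue
        by_group.setdefault(a.group, []).append((marker, r.score_pct))
        meta[a.group] = (r.bed, r.variant)
    out: list[CriterionResult] = []
    for group, pairs in sorted(by_group.items(), key=lambda kv: kv[0].value):
        if len(pairs) < 3:
            log.warning("criterion validity: group %s has only %d complete pairs; skipped",
                        group.value, len(pairs))
            continue
        xs, ys = zip(*pairs)
        r, p = pearson_r(xs, ys)
        bed, variant = meta[group]
        out.append(CriterionResult(group=group, bed=bed, variant=variant,
                                   biomarker=biomarker, pearson_r=r,
                                   n=len(pairs), p_value=p))
    return out


def welch_t(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value; identical constant samples give p=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return 1.0 if a[0] == b[0] else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def discriminant_validity(results: Sequence[VHIResult],
                          animals: Mapping[str, AnimalRecord],
                          alpha: float = 0.05, *,
                          holm: bool = False) -> list[DiscriminantResult]:
    """Pairwise group separation at each age using only the index.

    At each (age, bed, variant): every non-lean group is compared against
    the lean controls, and every treated group against the untreated obese
    group.  Cells with fewer than two animals are skipped.
    """
    cells: dict[tuple[int, str, str], dict[Group, list[float]]] = {}
    for r in results:
        a = animals.get(r.animal_id)
        if a is None:
            continue
        key = (a.age_weeks, r.bed.value, r.variant.value)
        cells.setdefault(key, {}).setdefault(a.group, []).append(r.score_pct)

    comparisons: list[tuple[tuple, Group, str, list[float], list[float]]] = []
    for key, groups_at_age in sorted(cells.items()):
        for group, scores in sorted(groups_at_age.items(), key=lambda kv: kv[0].value):
            refs = []
            if group is not Group.LZR:
                refs.append(("vs_LZR", Group.LZR))
            if group in (Group.OZR_EXERCISE, Group.OZR_CAPTOPRIL):
                refs.append(("vs_OZR", Group.OZR))
            for label, ref in refs:
                ref_scores = groups_at_age.get(ref)
                if ref_scores is None:
                    continue
                if len(scores) < 2 or len(ref_scores) < 2:
                    log.warning("discriminant validity: %s %s at %swk has n<2; skipped",
                                group.value, label, key[0])
                    continue
                comparisons.append((key, group, label, scores, ref_scores))

    pvals = [welch_t(s, ref) for _, _, _, s, ref in comparisons]
    if holm and pvals:
        pvals = list(multipletests(pvals, alpha=alpha, method="holm")[1])
    return [
        DiscriminantResult(
            bed=Bed(key[1]), variant=Variant(key[2]), age_weeks=key[0],
            group=group, comparison=label, p_value=p, significant=p < alpha,
        )
        for (key, group, label, _, _), p in zip(comparisons, pvals)
    ]
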