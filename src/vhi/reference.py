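"""Access to the packaged published group summaries (group-mean mode).

The packaged reference table carries the published per-component group
means, SEs and group sizes by vascular bed and age.  Because only group
summaries are published (no per-animal records), index values computed from
it use group-mean mode: each component score is the ratio of the group mean
to the lean-control mean — a ratio-of-means approximation to the per-animal
mean-of-ratios the original analysis performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .model import Bed, Component, Group, MissingStandardError, Variant, VHIResult
from .scoring import group_mean_vhi


@dataclass(frozen=True)
class ReferenceTable:
    """Published group summaries: means/SEs and n by (bed, group, age)."""

    components: dict  # bed -> group -> component -> age -> (mean, se)
    n: dict           # bed -> group -> age -> int
    biomarkers: dict  # group -> field -> age -> (mean, se)

    def mean(self, bed: Bed, group: Group, age_weeks: int, component: Component) -> float:
        try:
            return self.components[bed.value][group.value][component.value][age_weeks][0]
        except KeyError as exc:
            raise MissingStandardError(
                f"no reference value for ({bed.value}, {group.value}, "
                f"{age_weeks}wk, {component.value})") from exc

    def se(self, bed: Bed, group: Group, age_weeks: int, component: Component) -> float:
        return self.components[bed.value][group.value][component.value][age_weeks][1]

    def group_n(self, bed: Bed, group: Group, age_weeks: int) -> int:
        return int(self.n[bed.value][group.value][age_weeks])

    def ages(self, bed: Bed, group: Group) -> list[int]:
        return sorted(self.n[bed.value][group.value])

    def group_means(self, bed: Bed, group: Group, age_weeks: int) -> dict[Component, float]:
        by_comp = self.components[bed.value][group.value]
        return {Component(c): by_age[age_weeks][0]
                for c, by_age in by_comp.items() if age_weeks in by_age}

    # -- group-mean-mode index values ------------------------------------

    def vhi(self, bed: Bed, group: Group, age_weeks: int, variant: Variant,
            standard_group: Group = Group.LZR) -> VHIResult:
        """Group-mean-mode VHI against the lean-control means at that age."""
        return group_mean_vhi(
            self.group_means(bed, group, age_weeks),
            self.group_means(bed, standard_group, age_weeks),
            variant,
        )

    def aggregate_vhi(self, bed: Bed, group: Group, variant: Variant,
                      ages: Optional[Sequence[int]] = None) -> float:
        """All-ages aggregate: equal-weight mean of the per-age values."""
        if ages is None:
            ages = self.ages(bed, group)
        return float(np.mean([self.vhi(bed, group, a, variant).score_pct for a in ages]))


def load_reference() -> ReferenceTable:
    text = resources.files("vhi").joinpath("data/reference_cohort.yaml").read_text()
    raw = yaml.safe_load(text)
    return ReferenceTable(components=raw["components"], n=raw["n"],
                          biomarkers=raw["biomarkers"])
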