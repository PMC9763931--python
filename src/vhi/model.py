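"""Domain types and errors for the Vascular Health Index (VHI) pipeline.

The VHI is a composite, age-normalized score of microvascular health built
from three kinds of measurement on isolated resistance vessels and tissue:

* vessel reactivity — dilator responses to acetylcholine (ACh), sodium
  nitroprusside (SNP) and a hypoxic challenge;
* passive wall mechanics — the stiffness coefficient of the exponential
  circumferential stress–strain relation;
* network structure — microvessel density (MVD, vessels per mm²).

Each measurement is scored as a percentage of the matched healthy standard
(untreated lean Zucker rat controls of the same study, vascular bed and
age) and the scores are averaged, unweighted, into a 3- or 5-component
index per vascular bed (peripheral skeletal muscle vs. cerebral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence


# --------------------------------------------------------------------------
# errors

class VHIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VHIError):
    """Bad configuration: missing column, unknown option, malformed YAML."""


class ValidationError(VHIError):
    """A record violates a domain invariant (bad geometry, orphan row, ...)."""


class DegenerateDataError(VHIError):
    """Data carry no information for the requested fit (e.g. flat series)."""


class InvalidGeometryError(ValidationError):
    """Vessel geometry impossible: outer diameter not larger than inner."""


class AnchorMissingError(ValidationError):
    """Pressure series lacks the 5 mmHg anchor that defines zero strain."""


class InsufficientDataError(VHIError):
    """Too few observations for the requested operation."""


class MissingStandardError(VHIError):
    """No matched lean (LZR) controls to define the standard of health."""


class IncompleteAnimalError(VHIError):
    """Animal lacks a component required by the requested index variant."""


class UndefinedCorrelationError(VHIError):
    """Correlation undefined: one of the variables has zero variance."""


class EmptyResultError(VHIError):
    """An operation that requires a non-empty collection received none."""


# --------------------------------------------------------------------------
# enums

class Group(str, Enum):
    LZR = "LZR"
    OZR = "OZR"
    OZR_EXERCISE = "OZR_EXERCISE"
    OZR_CAPTOPRIL = "OZR_CAPTOPRIL"


class Bed(str, Enum):
    PERIPHERAL = "peripheral"
    CEREBRAL = "cerebral"


class Agonist(str, Enum):
    ACETYLCHOLINE = "acetylcholine"
    NITROPRUSSIDE = "nitroprusside"


class Component(str, Enum):
    ACH_DILATION = "ach_dilation"
    SNP_DILATION = "snp_dilation"
    HYPOXIC_DILATION = "hypoxic_dilation"
    MVD = "mvd"
    STIFFNESS_BETA = "stiffness_beta"


class Variant(str, Enum):
    THREE_COMPONENT = "three_component"
    FIVE_COMPONENT = "five_component"


#: Components entering each index variant.  The 3-component index uses the
#: most commonly collected measures; the 5-component adds the two extra
#: reactivity markers.
VARIANT_COMPONENTS: dict[Variant, frozenset[Component]] = {
    Variant.THREE_COMPONENT: frozenset(
        {Component.ACH_DILATION, Component.MVD, Component.STIFFNESS_BETA}
    ),
    Variant.FIVE_COMPONENT: frozenset(
        {
            Component.ACH_DILATION,
            Component.SNP_DILATION,
            Component.HYPOXIC_DILATION,
            Component.MVD,
            Component.STIFFNESS_BETA,
        }
    ),
}


class Biomarker(str, Enum):
    INSULIN = "insulin"
    TNFA = "tnfa"


BIOMARKER_FIELDS: dict[Biomarker, str] = {
    Biomarker.INSULIN: "insulin_ng_ml",
    Biomarker.TNFA: "tnfa_pg_ml",
}


def _require(cond: bool, msg: str, exc: type[VHIError] = ValidationError) -> None:
    if not cond:
        raise exc(msg)


# --------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class AnimalRecord:
    """One animal: identity, group assignment, age and plasma biomarkers.

    ``study_id`` identifies the original experiment whose lean controls
    define the standard of health for every animal of that study.
    Biomarkers may be missing (``None``); such animals are simply excluded
    from criterion-validity correlations.
    """

    animal_id: str
    group: Group
    age_weeks: int
    study_id: str
    mass_g: Optional[float] = None
    insulin_ng_ml: Optional[float] = None
    glucose_mg_dl: Optional[float] = None
    ntyr_ng_dl: Optional[float] = None
    tnfa_pg_ml: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.animal_id != "", "animal_id must be non-empty")
        _require(int(self.age_weeks) > 0, f"age_weeks must be positive, got {self.age_weeks}")
        for name in ("mass_g", "insulin_ng_ml", "glucose_mg_dl", "ntyr_ng_dl", "tnfa_pg_ml"):
            v = getattr(self, name)
            if v is not None:
                _require(
                    math.isfinite(v) and v > 0,
                    f"{name} must be strictly positive when present "
                    f"(animal {self.animal_id}, got {v})",
                )


@dataclass(frozen=True)
class DoseResponseSeries:
    """One vessel's diameter changes across agonist concentrations."""

    animal_id: str
    bed: Bed
    agonist: Agonist
    log_conc: tuple[float, ...]
    response_um: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_conc", tuple(float(x) for x in self.log_conc))
        object.__setattr__(self, "response_um", tuple(float(y) for y in self.response_um))
        _require(
            len(self.log_conc) == len(self.response_um),
            f"concentration and response lists differ in length (animal {self.animal_id})",
        )
        _require(
            len(set(self.log_conc)) >= 4,
            f"need >=4 distinct concentrations, got {len(set(self.log_conc))} "
            f"(animal {self.animal_id})",
            InsufficientDataError,
        )
        _require(
            all(a < b for a, b in zip(self.log_conc, self.log_conc[1:])),
            f"concentrations must be strictly increasing (animal {self.animal_id})",
        )


@dataclass(frozen=True)
class LogisticFit:
    """Parameters of the four-concentration logistic dose-response fit.

    ``upper_bound_um`` is the fitted maximal diameter change (the quantity
    that enters the index); ``log_ec50`` the log10 concentration of the
    half-maximal response.
    """

    lower_bound_um: float
    upper_bound_um: float
    log_ec50: float
    residual_sse: float
    converged: bool

    def __post_init__(self) -> None:
        _require(self.residual_sse >= 0, "residual SSE must be non-negative")
        if self.converged:
            _require(
                self.upper_bound_um >= self.lower_bound_um,
                "converged fit must have upper bound >= lower bound",
            )


@dataclass(frozen=True)
class HypoxicChallenge:
    """Dilation (μm) to a single reduced-PO₂ step (~135 → ~45 mmHg)."""

    animal_id: str
    bed: Bed
    dilation_um: float

    def __post_init__(self) -> None:
        _require(math.isfinite(self.dilation_um), f"dilation must be finite (animal {self.animal_id})")


ANCHOR_PRESSURE_MMHG = 5.0  # the "0 mmHg" intralumenal pressure point


@dataclass(frozen=True)
class PressureDiameterSeries:
    """Passive pressure–diameter relation under Ca²⁺-free conditions.

    The 5 mmHg point anchors the strain scale (it plays the role of
    0 mmHg: a truly unpressurised vessel would collapse).
    """

    animal_id: str
    bed: Bed
    pressure_mmHg: tuple[float, ...]
    inner_diameter_um: tuple[float, ...]
    outer_diameter_um: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pressure_mmHg", tuple(float(p) for p in self.pressure_mmHg))
        object.__setattr__(self, "inner_diameter_um", tuple(float(d) for d in self.inner_diameter_um))
        object.__setattr__(self, "outer_diameter_um", tuple(float(d) for d in self.outer_diameter_um))
        n = len(self.pressure_mmHg)
        _require(
            len(self.inner_diameter_um) == n and len(self.outer_diameter_um) == n,
            f"pressure/diameter lists differ in length (animal {self.animal_id})",
        )
        _require(
            all(a < b for a, b in zip(self.pressure_mmHg, self.pressure_mmHg[1:])),
            f"pressures must be strictly increasing (animal {self.animal_id})",
        )
        for p, idm, od in zip(self.pressure_mmHg, self.inner_diameter_um, self.outer_diameter_um):
            _require(
                idm > 0 and od > idm,
                f"outer diameter must exceed inner diameter at {p} mmHg "
                f"(animal {self.animal_id}: OD={od}, ID={idm})",
                InvalidGeometryError,
            )
        _require(
            ANCHOR_PRESSURE_MMHG in self.pressure_mmHg,
            f"series lacks the {ANCHOR_PRESSURE_MMHG:g} mmHg anchor (animal {self.animal_id})",
            AnchorMissingError,
        )

    @property
    def anchor_inner_diameter_um(self) -> float:
        i = self.pressure_mmHg.index(ANCHOR_PRESSURE_MMHG)
        return self.inner_diameter_um[i]


@dataclass(frozen=True)
class StressStrainPoint:
    pressure_mmHg: float
    strain: float
    stress_N_m2: float

    def __post_init__(self) -> None:
        _require(self.stress_N_m2 > 0, "stress must be positive")


@dataclass(frozen=True)
class WallMechanicsFit:
    """Exponential stress–strain fit σ = σ₅·exp(β·ε) on the log scale.

    β is the arterial stiffness coefficient; fits with r² ≤ 0.85 are
    rejected and contribute no stiffness component.
    """

    sigma5_N_m2: float
    beta: float
    r_squared: float
    points: tuple[StressStrainPoint, ...]

    def __post_init__(self) -> None:
        _require(self.sigma5_N_m2 > 0, "sigma5 must be positive")
        _require(math.isfinite(self.beta), "beta must be finite")
        _require(0.0 <= self.r_squared <= 1.0 + 1e-12, f"r² out of [0,1]: {self.r_squared}")

    @property
    def accepted(self) -> bool:
        return self.r_squared > 0.85


@dataclass(frozen=True)
class ComponentValue:
    """A raw component measurement for one (animal, bed, component)."""

    animal_id: str
    bed: Bed
    component: Component
    value: float
    units: str

    def __post_init__(self) -> None:
        _require(math.isfinite(self.value), f"component value must be finite (animal {self.animal_id})")
        if self.component is Component.MVD:
            _require(self.value > 0, f"MVD must be strictly positive (animal {self.animal_id})")


@dataclass(frozen=True)
class StandardOfHealth:
    """The denominator of a component score: mean over matched lean controls."""

    study_id: str
    bed: Bed
    age_weeks: int
    component: Component
    standard_value: float
    n_controls: int

    def __post_init__(self) -> None:
        _require(self.standard_value > 0, "standard of health must be positive")
        _require(self.n_controls >= 1, "standard needs at least one control")


@dataclass(frozen=True)
class VHIResult:
    """Per-animal composite score: unweighted mean of component scores (%)."""

    animal_id: str
    bed: Bed
    variant: Variant
    score_pct: float
    component_scores: Mapping[Component, float]

    def __post_init__(self) -> None:
        want = VARIANT_COMPONENTS[self.variant]
        got = frozenset(self.component_scores)
        _require(
            got == want,
            f"variant {self.variant.value} requires components "
            f"{sorted(c.value for c in want)}, got {sorted(c.value for c in got)}",
            IncompleteAnimalError,
        )
        mean = sum(self.component_scores.values()) / len(self.component_scores)
        _require(abs(self.score_pct - mean) <= 1e-9 * max(1.0, abs(mean)),
                 "score_pct must equal the mean of the component scores")


@dataclass
class AnalysisConfig:
    """Run configuration: variant, bed, ages, alpha, seed, column remapping."""

    variant: Variant = Variant.FIVE_COMPONENT
    bed: Bed = Bed.PERIPHERAL
    ages: Sequence[int] = ()
    alpha: float = 0.05
    rng_seed: int = 0
    columns: dict[str, dict[str, str]] = field(default_factory=dict)
    #: accept user-supplied pre-computed dilation upper bounds instead of
    #: fitting raw concentration series
    precomputed_dilation: bool = False
    #: pool lean controls across studies when study_id is absent
    pool_standards: bool = False

    def __post_init__(self) -> None:
        _require(0.0 < self.alpha < 1.0, f"alpha must lie in (0,1), got {self.alpha}",
                 ConfigurationError)
        self.variant = Variant(self.variant)
        self.bed = Bed(self.bed)
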