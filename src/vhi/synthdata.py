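"""Synthetic cohort generation with known ground truth.

The generator emulates the study design behind the index: group × age ×
vascular-bed cells of animals whose component values are normally
distributed with the published cell means and SDs (per-animal SD is
reconstructed from the printed standard errors as se·√n), truncated at zero
for the positive-only quantities.  For each animal it then *manufactures
raw measurement series that fit back to the drawn values*:

* dose–response series from the logistic model with the drawn dilation as
  the upper bound (plus optional Gaussian measurement noise);
* passive pressure–diameter series constructed so the mechanics pipeline
  returns exactly the drawn stiffness β: at every pressure the inner
  diameter solves σ(P, ID, WT) = σ₅·exp(β·ε(ID)), with the wall linked to
  the lumen by a conserved wall cross-sectional area (incompressible wall,
  OD² − ID² fixed at the 5 mmHg anchor);
* a single hypoxic dilation scalar and an MVD count, passed through.

A per-animal latent severity (standard normal) couples disease biomarkers
(insulin, TNF-α) to component deviations, giving the criterion-validity
correlations a known generating structure.  The default parameter table is
the packaged reference cohort (see ``vhi/data/reference_cohort.yaml``).
All randomness flows from one ``numpy`` Generator, so identical spec + seed
reproduce the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from . import io as vio
from .io import Cohort
from .mechanics import MMHG_TO_N_M2
from .model import (
    ANCHOR_PRESSURE_MMHG,
    Agonist,
    AnimalRecord,
    Bed,
    Component,
    ComponentValue,
    ConfigurationError,
    DoseResponseSeries,
    Group,
    HypoxicChallenge,
    PressureDiameterSeries,
    VHIError,
)
from .reactivity import LogisticModelParams, logistic_response

#: pressure protocol: the 5 mmHg "0 mmHg" anchor then 20 mmHg steps to 160
PRESSURE_PROTOCOL_MMHG: tuple[float, ...] = (5.0,) + tuple(float(p) for p in range(20, 161, 20))

#: log10 concentration grid of the dose–response protocol (1 nM – 1 μM)
DOSE_GRID: tuple[float, ...] = tuple(np.linspace(-9.0, -6.0, 7))

_BIOMARKER_FIELDS = ("mass_g", "insulin_ng_ml", "glucose_mg_dl", "ntyr_ng_dl", "tnfa_pg_ml")
#: biomarkers tied to the latent severity (the criterion variables)
_COUPLED_BIOMARKERS = frozenset({"insulin_ng_ml", "tnfa_pg_ml"})


class GenerationError(VHIError):
    """The generator could not construct a physical measurement series."""


@dataclass(frozen=True)
class CellSpec:
    """One group × age × bed cell: sample size and component (mean, se)."""

    group: Group
    age_weeks: int
    bed: Bed
    n: int
    components: Mapping[Component, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"cell {self.key} must have n >= 1")
        for comp, (mean, se) in self.components.items():
            if se < 0:
                raise ConfigurationError(f"cell {self.key}: negative SE for {comp.value}")
            if mean <= 0:
                raise ConfigurationError(f"cell {self.key}: non-positive mean for {comp.value}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.group.value, self.age_weeks, self.bed.value)

    def animal_sd(self, comp: Component) -> float:
        """Per-animal SD reconstructed from the printed SE: sd = se·√n."""
        _, se = self.components[comp]
        return se * math.sqrt(self.n)


@dataclass
class SyntheticCohortSpec:
    """Full generating specification for a synthetic cohort."""

    cells: list[CellSpec]
    #: (group, age) → biomarker field → (mean, se)
    biomarkers: dict[tuple[Group, int], dict[str, tuple[float, float]]] = field(default_factory=dict)
    #: severity → component deviation coupling per group, in [0, 1]
    component_coupling: dict[Group, float] = field(default_factory=dict)
    #: severity → insulin/TNF-α coupling per group, in [0, 1]
    biomarker_coupling: dict[Group, float] = field(default_factory=dict)
    rng_seed: int = 0
    #: Gaussian measurement noise added to dose–response points (μm)
    measurement_noise_um: float = 1.0
    #: anchor circumferential stress of generated passive series (N/m²)
    sigma5_N_m2: float = 2.0e3
    #: anchor inner-diameter range (μm); drawn uniformly per vessel
    id5_um_range: tuple[float, float] = (90.0, 110.0)

    def __post_init__(self) -> None:
        for g, c in {**self.component_coupling, **self.biomarker_coupling}.items():
            if not 0.0 <= c <= 1.0:
                raise ConfigurationError(f"coupling for {g} must lie in [0,1], got {c}")
        if self.sigma5_N_m2 <= 0:
            raise ConfigurationError("sigma5 must be positive")


# --------------------------------------------------------------------------
# spec loading

def _load_yaml_spec(raw: dict) -> SyntheticCohortSpec:
    cells: list[CellSpec] = []
    for bed_name, groups in raw.get("components", {}).items():
        bed = Bed(bed_name)
        for group_name, comps in groups.items():
            group = Group(group_name)
            n_by_age = raw.get("n", {}).get(bed_name, {}).get(group_name, {})
            ages = sorted({age for by_age in comps.values() for age in by_age})
            for age in ages:
                cell_comps = {
                    Component(c): (float(by_age[age][0]), float(by_age[age][1]))
                    for c, by_age in comps.items()
                    if age in by_age
                }
                if age not in n_by_age:
                    raise ConfigurationError(
                        f"no n for cell ({group_name}, {age}wk, {bed_name})")
                cells.append(CellSpec(group=group, age_weeks=int(age), bed=bed,
                                      n=int(n_by_age[age]), components=cell_comps))
    biomarkers: dict[tuple[Group, int], dict[str, tuple[float, float]]] = {}
    for group_name, fields_ in raw.get("biomarkers", {}).items():
        group = Group(group_name)
        for fname, by_age in fields_.items():
            for age, (mean, se) in by_age.items():
                biomarkers.setdefault((group, int(age)), {})[fname] = (float(mean), float(se))
    coupling = raw.get("coupling", {})
    return SyntheticCohortSpec(
        cells=cells,
        biomarkers=biomarkers,
        component_coupling={Group(g): float(v) for g, v in coupling.get("component", {}).items()},
        biomarker_coupling={Group(g): float(v) for g, v in coupling.get("biomarker", {}).items()},
    )


def load_spec(path: Path | str) -> SyntheticCohortSpec:
    """Load a cohort spec from a YAML file (same schema as the packaged one)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("cohort spec must be a YAML mapping")
    return _load_yaml_spec(raw)


def default_spec(bed: Optional[Bed] = None,
                 groups: Optional[Sequence[Group]] = None) -> SyntheticCohortSpec:
    """The packaged reference parameterization, optionally filtered."""
    text = resources.files("vhi").joinpath("data/reference_cohort.yaml").read_text()
    spec = _load_yaml_spec(yaml.safe_load(text))
    cells = [
        c for c in spec.cells
        if (bed is None or c.bed is bed) and (groups is None or c.group in groups)
    ]
    return replace(spec, cells=cells)


# --------------------------------------------------------------------------
# low-level draws

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      shift: np.ndarray | float = 0.0) -> np.ndarray | float:
    """mean + shift + sd·e with e ~ N(0,1), redrawn while non-positive."""
    value = mean + shift + sd * rng.standard_normal(np.shape(shift) or None)
    for _ in range(1000):
        bad = np.asarray(value <= 0)
        if not bad.any():
            break
        redraw = mean + np.asarray(shift) + sd * rng.standard_normal(bad.shape)
        value = np.where(bad, redraw, value)
    return value


def draw_component_values(spec: SyntheticCohortSpec, cell: CellSpec,
                          rng: np.random.Generator,
                          severity: Optional[np.ndarray] = None,
                          ) -> dict[Component, np.ndarray]:
    """Draw one value per animal and component for a cell.

    ``severity`` (one standard-normal latent per animal) shifts components
    toward disease — down for quantities that fall with disease, up for the
    stiffness coefficient — by ``coupling·sd·severity``, with the residual
    variance scaled so the total per-animal SD stays se·√n.
    """
    if severity is None:
        severity = np.zeros(cell.n)
    severity = np.asarray(severity, dtype=float)
    if severity.shape != (cell.n,):
        raise ConfigurationError(
            f"severity must have shape ({cell.n},), got {severity.shape}")
    rho = spec.component_coupling.get(cell.group, 0.0)
    out: dict[Component, np.ndarray] = {}
    for comp in sorted(cell.components, key=lambda c: c.value):
        mean, _ = cell.components[comp]
        sd = cell.animal_sd(comp)
        direction = 1.0 if comp is Component.STIFFNESS_BETA else -1.0
        shift = direction * rho * sd * severity
        resid_sd = sd * math.sqrt(1.0 - rho**2)
        out[comp] = np.atleast_1d(_truncated_normal(rng, mean, resid_sd, shift))
    return out


def draw_biomarkers(spec: SyntheticCohortSpec, group: Group, age_weeks: int,
                    n: int, rng: np.random.Generator,
                    severity: np.ndarray) -> dict[str, Optional[np.ndarray]]:
    """Draw plasma/body variables; insulin and TNF-α ride the severity latent."""
    table = spec.biomarkers.get((group, age_weeks))
    rho = spec.biomarker_coupling.get(group, 0.0)
    out: dict[str, Optional[np.ndarray]] = {}
    for fname in _BIOMARKER_FIELDS:
        if table is None or fname not in table:
            out[fname] = None
            continue
        mean, se = table[fname]
        sd = se * math.sqrt(n)
        if fname in _COUPLED_BIOMARKERS:
            shift = rho * sd * severity
            resid = sd * math.sqrt(1.0 - rho**2)
        else:
            shift = np.zeros(n)
            resid = sd
        out[fname] = np.atleast_1d(_truncated_normal(rng, mean, resid, shift))
    return out


# --------------------------------------------------------------------------
# raw-series manufacture

def make_dose_response(animal_id: str, bed: Bed, agonist: Agonist,
                       target_upper_um: float, rng: np.random.Generator, *,
                       noise_um: float = 0.0,
                       min_um_range: tuple[float, float] = (5.0, 15.0),
                       log_ec50_range: tuple[float, float] = (-7.8, -7.2),
                       ) -> DoseResponseSeries:
    """Seven-point logistic series whose fitted upper bound is the target.

    The lower bound and logEC50 are drawn from uniform priors; without
    noise the logistic fit returns the generating triple exactly.
    """
    if target_upper_um <= 0:
        raise GenerationError(f"target upper bound must be positive, got {target_upper_um}")
    params = LogisticModelParams(
        min=float(rng.uniform(*min_um_range)),
        max=float(target_upper_um),
        log_ec50=float(rng.uniform(*log_ec50_range)),
    )
    x = np.array(DOSE_GRID)
    y = np.asarray(logistic_response(params, x), dtype=float)
    if noise_um > 0:
        y = y + rng.normal(0.0, noise_um, size=y.shape)
    return DoseResponseSeries(animal_id=animal_id, bed=bed, agonist=agonist,
                              log_conc=tuple(x), response_um=tuple(y))


def make_pressure_series(animal_id: str, bed: Bed, target_beta: float,
                         sigma5_N_m2: float, id5_um: float, *,
                         pressures_mmHg: Sequence[float] = PRESSURE_PROTOCOL_MMHG,
                         ) -> PressureDiameterSeries:
    """Passive series consistent with σ = σ₅·exp(β·ε) at every pressure.

    The wall cross-sectional area is conserved as the vessel distends
    (incompressible wall): OD² − ID² is fixed by the anchor geometry, where
    the anchor wall thickness is chosen so the 5 mmHg stress equals σ₅.
    For each higher pressure the inner diameter is found by root bracketing;
    if no physical solution exists the series cannot be generated.
    """
    if not math.isfinite(target_beta):
        raise GenerationError("target beta must be finite")
    if sigma5_N_m2 <= 0 or id5_um <= 0:
        raise GenerationError("sigma5 and anchor diameter must be positive")
    if ANCHOR_PRESSURE_MMHG not in pressures_mmHg:
        raise GenerationError("pressure protocol must include the 5 mmHg anchor")

    # anchor wall thickness from σ₅ = P₅·ID₅/(2·WT₅)
    wt5 = ANCHOR_PRESSURE_MMHG * MMHG_TO_N_M2 * id5_um / (2.0 * sigma5_N_m2)
    od5 = id5_um + 2.0 * wt5
    area = od5**2 - id5_um**2  # conserved wall annulus (∝ cross-sectional area)

    def od_of(id_um: float) -> float:
        return math.sqrt(id_um**2 + area)

    def mismatch(id_um: float, p: float) -> float:
        wt = (od_of(id_um) - id_um) / 2.0
        geometric = p * MMHG_TO_N_M2 * id_um / (2.0 * wt)
        material = sigma5_N_m2 * math.exp(target_beta * (id_um - id5_um) / id5_um)
        return geometric - material

    inner: list[float] = []
    outer: list[float] = []
    for p in pressures_mmHg:
        if p == ANCHOR_PRESSURE_MMHG:
            inner.append(id5_um)
            outer.append(od5)
            continue
        lo = id5_um
        hi = id5_um * 1.2
        while mismatch(hi, p) > 0:
            hi *= 1.2
            if hi > 50.0 * id5_um:
                raise GenerationError(
                    f"no physical diameter at {p} mmHg for beta={target_beta} "
                    f"(animal {animal_id})")
        idp = brentq(mismatch, lo, hi, args=(p,), xtol=1e-10 * id5_um)
        inner.append(float(idp))
        outer.append(od_of(float(idp)))
    return PressureDiameterSeries(
        animal_id=animal_id, bed=bed,
        pressure_mmHg=tuple(float(p) for p in pressures_mmHg),
        inner_diameter_um=tuple(inner), outer_diameter_um=tuple(outer),
    )


# --------------------------------------------------------------------------
# whole-cohort generation

def generate_cohort(spec: SyntheticCohortSpec,
                    seed: Optional[int] = None) -> Cohort:
    """Generate a full in-memory cohort from the spec (deterministic in seed)."""
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    cohort = Cohort(animals={})
    for cell in sorted(spec.cells, key=lambda c: c.key):
        study_id = f"SYN-{cell.bed.value[:3].upper()}"
        severity = rng.standard_normal(cell.n)
        values = draw_component_values(spec, cell, rng, severity)
        markers = draw_biomarkers(spec, cell.group, cell.age_weeks, cell.n, rng, severity)
        for i in range(cell.n):
            aid = f"{cell.group.value}-{cell.bed.value[:3]}-{cell.age_weeks}w-{i:03d}"

            def marker(fname: str) -> Optional[float]:
                arr = markers[fname]
                return None if arr is None else float(arr[i])

            cohort.animals[aid] = AnimalRecord(
                animal_id=aid, group=cell.group, age_weeks=cell.age_weeks,
                study_id=study_id,
                mass_g=marker("mass_g"),
                insulin_ng_ml=marker("insulin_ng_ml"),
                glucose_mg_dl=marker("glucose_mg_dl"),
                ntyr_ng_dl=marker("ntyr_ng_dl"),
                tnfa_pg_ml=marker("tnfa_pg_ml"),
            )
            for comp, agonist in ((Component.ACH_DILATION, Agonist.ACETYLCHOLINE),
                                  (Component.SNP_DILATION, Agonist.NITROPRUSSIDE)):
                if comp in values:
                    cohort.dose_response.append(
                        make_dose_response(aid, cell.bed, agonist,
                                           float(values[comp][i]), rng,
                                           noise_um=spec.measurement_noise_um))
            if Component.HYPOXIC_DILATION in values:
                cohort.hypoxia.append(HypoxicChallenge(
                    animal_id=aid, bed=cell.bed,
                    dilation_um=float(values[Component.HYPOXIC_DILATION][i])))
            if Component.STIFFNESS_BETA in values:
                id5 = float(rng.uniform(*spec.id5_um_range))
                cohort.pressure_diameter.append(
                    make_pressure_series(aid, cell.bed,
                                         float(values[Component.STIFFNESS_BETA][i]),
                                         spec.sigma5_N_m2, id5))
            if Component.MVD in values:
                cohort.mvd.append(ComponentValue(
                    animal_id=aid, bed=cell.bed, component=Component.MVD,
                    value=float(values[Component.MVD][i]), units="#/mm²"))
    return cohort


def generate_cohort_csvs(spec: SyntheticCohortSpec, out_dir: Path | str,
                         seed: Optional[int] = None) -> vio.CohortPaths:
    """Generate a cohort and write the canonical CSV set to ``out_dir``."""
    return vio.write_cohort(generate_cohort(spec, seed=seed), out_dir)
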