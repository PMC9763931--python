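"""Tidy-CSV readers and writers for cohort measurement tables.

All inputs are long-format CSVs, one measurement per row.  Column names are
remappable through :class:`~vhi.model.AnalysisConfig.columns` (a mapping
``{table: {canonical_name: actual_name}}``); the canonical schemas are:

* ``animals.csv`` — animal_id, group, age_weeks, study_id, mass_g,
  insulin_ng_ml, glucose_mg_dl, ntyr_ng_dl, tnfa_pg_ml
* ``dose_response.csv`` — animal_id, bed, agonist, log_conc, response_um
* ``hypoxia.csv`` — animal_id, bed, dilation_um
* ``pressure_diameter.csv`` — animal_id, bed, pressure_mmHg, inner_um, outer_um
* ``mvd.csv`` — animal_id, bed, mvd_per_mm2

Measurements whose animal_id has no matching animal record are rejected
(orphans), with the offending ids reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .model import (
    Agonist,
    AnalysisConfig,
    AnimalRecord,
    Bed,
    ComponentValue,
    Component,
    ConfigurationError,
    DoseResponseSeries,
    EmptyResultError,
    Group,
    HypoxicChallenge,
    PressureDiameterSeries,
    ValidationError,
    VHIResult,
    Variant,
)

log = logging.getLogger("vhi")

ANIMAL_COLUMNS = (
    "animal_id", "group", "age_weeks", "study_id", "mass_g",
    "insulin_ng_ml", "glucose_mg_dl", "ntyr_ng_dl", "tnfa_pg_ml",
)
DOSE_RESPONSE_COLUMNS = ("animal_id", "bed", "agonist", "log_conc", "response_um")
HYPOXIA_COLUMNS = ("animal_id", "bed", "dilation_um")
PRESSURE_COLUMNS = ("animal_id", "bed", "pressure_mmHg", "inner_um", "outer_um")
MVD_COLUMNS = ("animal_id", "bed", "mvd_per_mm2")


@dataclass
class CohortPaths:
    animals: Path
    dose_response: Optional[Path] = None
    hypoxia: Optional[Path] = None
    pressure_diameter: Optional[Path] = None
    mvd: Optional[Path] = None

    @classmethod
    def from_dir(cls, d: Path | str) -> "CohortPaths":
        d = Path(d)

        def opt(name: str) -> Optional[Path]:
            p = d / name
            return p if p.exists() else None

        return cls(
            animals=d / "animals.csv",
            dose_response=opt("dose_response.csv"),
            hypoxia=opt("hypoxia.csv"),
            pressure_diameter=opt("pressure_diameter.csv"),
            mvd=opt("mvd.csv"),
        )


@dataclass
class Cohort:
    """In-memory cohort: typed animal records plus raw measurement series."""

    animals: dict[str, AnimalRecord]
    dose_response: list[DoseResponseSeries] = field(default_factory=list)
    hypoxia: list[HypoxicChallenge] = field(default_factory=list)
    pressure_diameter: list[PressureDiameterSeries] = field(default_factory=list)
    mvd: list[ComponentValue] = field(default_factory=list)

    def animals_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": a.animal_id,
                "group": a.group.value,
                "age_weeks": a.age_weeks,
                "study_id": a.study_id,
                "mass_g": a.mass_g,
                "insulin_ng_ml": a.insulin_ng_ml,
                "glucose_mg_dl": a.glucose_mg_dl,
                "ntyr_ng_dl": a.ntyr_ng_dl,
                "tnfa_pg_ml": a.tnfa_pg_ml,
            }
            for a in self.animals.values()
        ]
        return pd.DataFrame(rows, columns=list(ANIMAL_COLUMNS))


def _remap(df: pd.DataFrame, required: Iterable[str], mapping: dict[str, str],
           table: str) -> pd.DataFrame:
    """Rename user columns to canonical names and check presence."""
    inverse = {v: k for k, v in mapping.items()}
    df = df.rename(columns=inverse)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{table}: missing required column(s) {missing}; present: {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, cols: Iterable[str], table: str) -> pd.DataFrame:
    """Coerce measurement columns to float, reporting bad rows by line number."""
    bad: list[str] = []
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        for idx in df.index[coerced.isna() & df[c].notna()]:
            # +2: header line plus 1-based numbering
            bad.append(
                f"{table} line {idx + 2}: non-numeric {c}={df.at[idx, c]!r} "
                f"(animal {df.at[idx, 'animal_id']})"
            )
        df[c] = coerced
    if bad:
        raise ValidationError("; ".join(bad))
    return df


def read_animals(path: Path | str, columns: Optional[dict[str, str]] = None) -> dict[str, AnimalRecord]:
    df = pd.read_csv(path)
    df = _remap(df, ANIMAL_COLUMNS[:4], columns or {}, "animals")
    records: dict[str, AnimalRecord] = {}
    for idx, row in df.iterrows():
        aid = str(row["animal_id"])
        if aid in records:
            raise ValidationError(f"animals line {idx + 2}: duplicate animal_id {aid}")

        def opt(col: str) -> Optional[float]:
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        try:
            records[aid] = AnimalRecord(
                animal_id=aid,
                group=Group(str(row["group"])),
                age_weeks=int(row["age_weeks"]),
                study_id=str(row["study_id"]),
                mass_g=opt("mass_g"),
                insulin_ng_ml=opt("insulin_ng_ml"),
                glucose_mg_dl=opt("glucose_mg_dl"),
                ntyr_ng_dl=opt("ntyr_ng_dl"),
                tnfa_pg_ml=opt("tnfa_pg_ml"),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"animals line {idx + 2}: {exc}") from exc
    return records


def _check_orphans(ids: Iterable[str], animals: dict[str, AnimalRecord], table: str) -> None:
    orphans = sorted({i for i in ids if i not in animals})
    if orphans:
        raise ValidationError(
            f"{table}: {len(orphans)} orphan animal_id(s) with no animal record: {orphans}"
        )


def read_dose_response(path: Path | str, animals: dict[str, AnimalRecord],
                       columns: Optional[dict[str, str]] = None) -> list[DoseResponseSeries]:
    df = pd.read_csv(path)
    df = _remap(df, DOSE_RESPONSE_COLUMNS, columns or {}, "dose_response")
    df = _numeric(df, ["log_conc", "response_um"], "dose_response")
    df["animal_id"] = df["animal_id"].astype(str)
    _check_orphans(df["animal_id"], animals, "dose_response")
    out: list[DoseResponseSeries] = []
    for (aid, bed, agonist), g in df.groupby(["animal_id", "bed", "agonist"], sort=True):
        g = g.sort_values("log_conc")
        out.append(
            DoseResponseSeries(
                animal_id=aid,
                bed=Bed(bed),
                agonist=Agonist(agonist),
                log_conc=tuple(g["log_conc"]),
                response_um=tuple(g["response_um"]),
            )
        )
    return out


def read_hypoxia(path: Path | str, animals: dict[str, AnimalRecord],
                 columns: Optional[dict[str, str]] = None) -> list[HypoxicChallenge]:
    df = pd.read_csv(path)
    df = _remap(df, HYPOXIA_COLUMNS, columns or {}, "hypoxia")
    df = _numeric(df, ["dilation_um"], "hypoxia")
    df["animal_id"] = df["animal_id"].astype(str)
    _check_orphans(df["animal_id"], animals, "hypoxia")
    return [
        HypoxicChallenge(animal_id=str(r["animal_id"]), bed=Bed(r["bed"]),
                         dilation_um=float(r["dilation_um"]))
        for _, r in df.iterrows()
    ]


def read_pressure_diameter(path: Path | str, animals: dict[str, AnimalRecord],
                           columns: Optional[dict[str, str]] = None) -> list[PressureDiameterSeries]:
    df = pd.read_csv(path)
    df = _remap(df, PRESSURE_COLUMNS, columns or {}, "pressure_diameter")
    df = _numeric(df, ["pressure_mmHg", "inner_um", "outer_um"], "pressure_diameter")
    df["animal_id"] = df["animal_id"].astype(str)
    _check_orphans(df["animal_id"], animals, "pressure_diameter")
    bad = df.index[df["outer_um"] <= df["inner_um"]]
    if len(bad):
        msgs = [
            f"pressure_diameter line {i + 2}: OD={df.at[i, 'outer_um']} <= ID={df.at[i, 'inner_um']} "
            f"(animal {df.at[i, 'animal_id']})"
            for i in bad
        ]
        raise ValidationError("; ".join(msgs))
    out: list[PressureDiameterSeries] = []
    for (aid, bed), g in df.groupby(["animal_id", "bed"], sort=True):
        g = g.sort_values("pressure_mmHg")
        out.append(
            PressureDiameterSeries(
                animal_id=aid,
                bed=Bed(bed),
                pressure_mmHg=tuple(g["pressure_mmHg"]),
                inner_diameter_um=tuple(g["inner_um"]),
                outer_diameter_um=tuple(g["outer_um"]),
            )
        )
    return out


def read_mvd(path: Path | str, animals: dict[str, AnimalRecord],
             columns: Optional[dict[str, str]] = None) -> list[ComponentValue]:
    df = pd.read_csv(path)
    df = _remap(df, MVD_COLUMNS, columns or {}, "mvd")
    df = _numeric(df, ["mvd_per_mm2"], "mvd")
    df["animal_id"] = df["animal_id"].astype(str)
    _check_orphans(df["animal_id"], animals, "mvd")
    return [
        ComponentValue(animal_id=str(r["animal_id"]), bed=Bed(r["bed"]),
                       component=Component.MVD, value=float(r["mvd_per_mm2"]),
                       units="#/mm²")
        for _, r in df.iterrows()
    ]


def read_cohort(paths: CohortPaths, config: Optional[AnalysisConfig] = None) -> Cohort:
    """Read and validate a full cohort from a set of tidy CSVs."""
    config = config or AnalysisConfig()
    cols = config.columns
    animals = read_animals(paths.animals, cols.get("animals"))
    cohort = Cohort(animals=animals)
    if paths.dose_response is not None:
        cohort.dose_response = read_dose_response(paths.dose_response, animals,
                                                  cols.get("dose_response"))
    if paths.hypoxia is not None:
        cohort.hypoxia = read_hypoxia(paths.hypoxia, animals, cols.get("hypoxia"))
    if paths.pressure_diameter is not None:
        cohort.pressure_diameter = read_pressure_diameter(
            paths.pressure_diameter, animals, cols.get("pressure_diameter"))
    if paths.mvd is not None:
        cohort.mvd = read_mvd(paths.mvd, animals, cols.get("mvd"))
    log.info(
        "read cohort: %d animals, %d dose-response series, %d hypoxic challenges, "
        "%d pressure series, %d MVD values",
        len(animals), len(cohort.dose_response), len(cohort.hypoxia),
        len(cohort.pressure_diameter), len(cohort.mvd),
    )
    return cohort


def write_cohort(cohort: Cohort, out_dir: Path | str) -> CohortPaths:
    """Write a cohort back to the canonical CSV set (inverse of read_cohort)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = CohortPaths(
        animals=out / "animals.csv",
        dose_response=out / "dose_response.csv",
        hypoxia=out / "hypoxia.csv",
        pressure_diameter=out / "pressure_diameter.csv",
        mvd=out / "mvd.csv",
    )
    cohort.animals_frame().to_csv(paths.animals, index=False)
    pd.DataFrame(
        [
            {"animal_id": s.animal_id, "bed": s.bed.value, "agonist": s.agonist.value,
             "log_conc": x, "response_um": y}
            for s in cohort.dose_response
            for x, y in zip(s.log_conc, s.response_um)
        ],
        columns=list(DOSE_RESPONSE_COLUMNS),
    ).to_csv(paths.dose_response, index=False)
    pd.DataFrame(
        [{"animal_id": h.animal_id, "bed": h.bed.value, "dilation_um": h.dilation_um}
         for h in cohort.hypoxia],
        columns=list(HYPOXIA_COLUMNS),
    ).to_csv(paths.hypoxia, index=False)
    pd.DataFrame(
        [
            {"animal_id": s.animal_id, "bed": s.bed.value, "pressure_mmHg": p,
             "inner_um": di, "outer_um": do}
            for s in cohort.pressure_diameter
            for p, di, do in zip(s.pressure_mmHg, s.inner_diameter_um, s.outer_diameter_um)
        ],
        columns=list(PRESSURE_COLUMNS),
    ).to_csv(paths.pressure_diameter, index=False)
    pd.DataFrame(
        [{"animal_id": m.animal_id, "bed": m.bed.value, "mvd_per_mm2": m.value}
         for m in cohort.mvd],
        columns=list(MVD_COLUMNS),
    ).to_csv(paths.mvd, index=False)
    return paths


# --------------------------------------------------------------------------
# results

def write_results(results: Iterable[VHIResult], path: Path | str) -> None:
    """Write per-animal VHI results, one row per (animal, bed, variant)."""
    results = list(results)
    if not results:
        raise EmptyResultError("no VHI results to write")
    rows = []
    for r in results:
        row: dict[str, object] = {
            "animal_id": r.animal_id,
            "bed": r.bed.value,
            "variant": r.variant.value,
            "vhi_pct": r.score_pct,
        }
        for c in Component:
            row[f"score_{c.value}"] = r.component_scores.get(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results(path: Path | str) -> list[VHIResult]:
    df = pd.read_csv(path)
    out: list[VHIResult] = []
    for _, r in df.iterrows():
        scores = {
            c: float(r[f"score_{c.value}"])
            for c in Component
            if f"score_{c.value}" in df.columns and pd.notna(r[f"score_{c.value}"])
        }
        out.append(
            VHIResult(
                animal_id=str(r["animal_id"]),
                bed=Bed(r["bed"]),
                variant=Variant(r["variant"]),
                score_pct=float(r["vhi_pct"]),
                component_scores=scores,
            )
        )
    return out


# --------------------------------------------------------------------------
# config

def load_config(path: Path | str) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return AnalysisConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc
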