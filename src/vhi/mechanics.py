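"""Passive wall mechanics: stress, strain and the stiffness coefficient β.

From a passive (Ca²⁺-free) pressure–diameter series the module computes,
at each pressure step,

    WT = (OD − ID) / 2                       wall thickness, μm
    σ  = P·ID / (2·WT)                       circumferential stress, N/m²
    ε  = (ID − ID₅) / ID₅                    circumferential strain

with pressure converted at 1 mmHg = 1.334×10² N/m² and ID₅ the inner
diameter at the 5 mmHg anchor (the series' "0 mmHg" point — strain is zero
there by construction).  The stress–strain relation is then fit by ordinary
least squares on the log-linearized exponential model

    ln σ = ln σ₅ + β·ε

whose slope β quantifies arterial stiffness.  Fits with r² ≤ 0.85 are
rejected and emit no component.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    ANCHOR_PRESSURE_MMHG,
    Component,
    ComponentValue,
    DegenerateDataError,
    InsufficientDataError,
    InvalidGeometryError,
    PressureDiameterSeries,
    StressStrainPoint,
    WallMechanicsFit,
)

log = logging.getLogger("vhi")

#: unit conversion for intralumenal pressure
MMHG_TO_N_M2 = 1.334e2

#: acceptance threshold for the stress–strain fit (strict inequality)
R2_THRESHOLD = 0.85


def wall_thickness(od_um: float, id_um: float) -> float:
    """WT = (OD − ID)/2, μm; OD must strictly exceed ID."""
    if not (od_um > id_um > 0):
        raise InvalidGeometryError(
            f"need OD > ID > 0, got OD={od_um}, ID={id_um}")
    return (od_um - id_um) / 2.0


def circumferential_stress(pressure_mmHg: float, id_um: float, wt_um: float) -> float:
    """σ = P·ID/(2·WT) in N/m² (ID and WT share units, so their ratio is pure)."""
    if wt_um <= 0:
        raise InvalidGeometryError(f"wall thickness must be positive, got {wt_um}")
    if pressure_mmHg < 0:
        raise InvalidGeometryError(f"pressure must be non-negative, got {pressure_mmHg}")
    return pressure_mmHg * MMHG_TO_N_M2 * id_um / (2.0 * wt_um)


def circumferential_strain(id_um: float, id5_um: float) -> float:
    """ε = (ID − ID₅)/ID₅ relative to the anchor diameter (may be negative)."""
    if id5_um <= 0:
        raise InvalidGeometryError(f"anchor diameter must be positive, got {id5_um}")
    return (id_um - id5_um) / id5_um


def stress_strain_points(series: PressureDiameterSeries) -> list[StressStrainPoint]:
    """Compute (ε, σ) at every pressure step of a passive series."""
    id5 = series.anchor_inner_diameter_um
    pts: list[StressStrainPoint] = []
    for p, idm, od in zip(series.pressure_mmHg, series.inner_diameter_um,
                          series.outer_diameter_um):
        wt = wall_thickness(od, idm)
        pts.append(
            StressStrainPoint(
                pressure_mmHg=p,
                strain=circumferential_strain(idm, id5),
                stress_N_m2=circumferential_stress(p, idm, wt),
            )
        )
    return pts


def fit_stress_strain(points: Sequence[StressStrainPoint]) -> WallMechanicsFit:
    """OLS fit of ln σ = ln σ₅ + β·ε; r² reported on the log scale.

    Requires at least three points with positive stress and non-constant
    strain.  The returned fit carries ``accepted = r² > 0.85``; rejected
    fits should contribute no stiffness component.
    """
    if len(points) < 3:
        raise InsufficientDataError(
            f"stress–strain fit needs >=3 points, got {len(points)}")
    strain = np.array([p.strain for p in points], dtype=float)
    stress = np.array([p.stress_N_m2 for p in points], dtype=float)
    if np.any(stress <= 0):
        raise InvalidGeometryError("stress must be positive for the log-scale fit")
    if np.ptp(strain) == 0.0:
        raise DegenerateDataError("all strains equal; slope undefined")
    res = stats.linregress(strain, np.log(stress))
    r2 = float(res.rvalue) ** 2
    return WallMechanicsFit(
        sigma5_N_m2=float(math.exp(res.intercept)),
        beta=float(res.slope),
        r_squared=min(r2, 1.0),
        points=tuple(points),
    )


def stiffness_component(series: PressureDiameterSeries) -> tuple[WallMechanicsFit, Optional[ComponentValue]]:
    """Full mechanics pipeline for one vessel: points → fit → β component.

    Returns the fit (for diagnostics) and the component value, or ``None``
    when the fit is rejected (r² ≤ 0.85).
    """
    fit = fit_stress_strain(stress_strain_points(series))
    if not fit.accepted:
        log.warning("stress–strain fit rejected for animal %s (%s): r²=%.3f <= %.2f",
                    series.animal_id, series.bed.value, fit.r_squared, R2_THRESHOLD)
        return fit, None
    return fit, ComponentValue(
        animal_id=series.animal_id, bed=series.bed,
        component=Component.STIFFNESS_BETA,
        value=fit.beta, units="dimensionless",
    )
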