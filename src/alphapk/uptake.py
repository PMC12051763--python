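"""SUV-based prediction of ²¹²Pb uptake in lesions and organs.

At microdose activities the γ-camera signal is too sparse for direct
quantification of most structures, so expected ²¹²Pb concentrations are
projected from the baseline PSMA-PET SUVs: assuming the therapeutic
ligand distributes like the PET tracer, a structure with SUV_mean s in a
patient of weight W given a (decay-corrected) activity A carries

    concentration = s · A / W        (tissue density 1 g/mL)

with A in kBq and W in grams, giving kBq/mL.  Every estimate carries a
convention tag recording the decay-correction time and half-life mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import decay


@dataclass(frozen=True)
class LesionRecord:
    """One PSMA-PET lesion/organ row: location, CT dimensions, SUVs."""

    patient_id: str
    location: str
    suv_max: float
    suv_mean: float
    dimensions_cm: tuple[float, float, float] | None = None
    visible_on_gamma: bool | None = None

    def __post_init__(self) -> None:
        if self.suv_mean <= 0 or self.suv_max < self.suv_mean:
            raise ValueError("require suv_max >= suv_mean > 0")
        if self.dimensions_cm is not None and any(d <= 0 for d in self.dimensions_cm):
            raise ValueError("dimensions must be positive")


@dataclass(frozen=True)
class UptakeEstimate:
    """Predicted ²¹²Pb concentration and volume for one structure."""

    patient_id: str
    location: str
    concentration_kBq_mL: float
    volume_cm3: float
    decay_corrected_activity_MBq: float
    convention: str
    visible_on_gamma: bool | None = None

    def __post_init__(self) -> None:
        if self.concentration_kBq_mL < 0:
            raise ValueError("concentration must be non-negative")
        if self.volume_cm3 <= 0:
            raise ValueError("volume must be positive")


def suv_to_concentration(
    suv: float,
    administered_MBq: float,
    body_weight_kg: float,
    decay_dt_h: float = 0.0,
    half_life_mode: str = "physical",
    effective_half_life_h: float | None = None,
) -> float:
    """Convert an SUV to a predicted ²¹²Pb concentration in kBq/mL.

    The administered activity is decay-corrected over ``decay_dt_h``
    with the physical ²¹²Pb half-life (default) or a supplied effective
    half-life, then divided by body weight (density 1 g/mL) and scaled
    by the SUV.
    """
    if suv < 0:
        raise ValueError("SUV must be non-negative")
    if administered_MBq <= 0 or body_weight_kg <= 0:
        raise ValueError("administered activity and body weight must be positive")
    if half_life_mode == "physical":
        t_half = decay.PB212_HALF_LIFE_H
    elif half_life_mode == "effective":
        if effective_half_life_h is None:
            raise ValueError("effective mode requires effective_half_life_h")
        t_half = effective_half_life_h
    else:
        raise ValueError(f"unknown half-life mode {half_life_mode!r}")
    activity_kBq = administered_MBq * 1000.0 * decay.decay_factor(t_half, decay_dt_h)
    return suv * activity_kBq / (body_weight_kg * 1000.0)


def lesion_volume(
    dimensions_cm: tuple[float, float, float] | None,
    mode: str = "ellipsoid",
    override_cm3: float | None = None,
) -> float:
    """Volume (cm³) from CT dimensions: ellipsoid (π/6·abc), box (abc) or override."""
    if mode == "override":
        if override_cm3 is None:
            raise ValueError("override mode requires an explicit volume")
        return override_cm3
    if dimensions_cm is None:
        raise ValueError("volume unavailable: no dimensions and no override")
    a, b, c = dimensions_cm
    if mode == "ellipsoid":
        return math.pi / 6.0 * a * b * c
    if mode == "box":
        return a * b * c
    raise ValueError(f"unknown volume mode {mode!r}")


def build_uptake_table(
    lesions: list[LesionRecord],
    administered_MBq: dict[str, float],
    body_weight_kg: dict[str, float],
    default_body_weight_kg: float = 80.0,
    decay_dt_h: float = 3.0,
    half_life_mode: str = "physical",
    effective_half_life_h: float | None = None,
    volume_mode: str = "box",
    default_volume_cm3: float = 1.0,
) -> list[UptakeEstimate]:
    """Predict ²¹²Pb concentration and volume for each lesion/organ record.

    Per-record failures propagate as estimates with ``None`` replaced by
    raising only for table-level problems (a missing administered
    activity); records lacking dimensions fall back to
    ``default_volume_cm3``.  The convention tag records every assumption
    used for the row.
    """
    out: list[UptakeEstimate] = []
    for rec in lesions:
        if rec.patient_id not in administered_MBq:
            raise ValueError(f"no administered activity for patient {rec.patient_id}")
        weight = body_weight_kg.get(rec.patient_id, default_body_weight_kg)
        conc = suv_to_concentration(
            rec.suv_mean,
            administered_MBq[rec.patient_id],
            weight,
            decay_dt_h,
            half_life_mode,
            effective_half_life_h,
        )
        if rec.dimensions_cm is not None:
            vol = lesion_volume(rec.dimensions_cm, volume_mode)
        else:
            vol = default_volume_cm3
        t_half = (
            decay.PB212_HALF_LIFE_H
            if half_life_mode == "physical"
            else effective_half_life_h
        )
        act = administered_MBq[rec.patient_id] * decay.decay_factor(t_half, decay_dt_h)
        tag = (
            f"{half_life_mode} decay to {decay_dt_h} h; weight {weight} kg; "
            f"volume {volume_mode} ({default_volume_cm3} cm3 default)"
        )
        out.append(
            UptakeEstimate(
                patient_id=rec.patient_id,
                location=rec.location,
                concentration_kBq_mL=conc,
                volume_cm3=vol,
                decay_corrected_activity_MBq=act,
                convention=tag,
                visible_on_gamma=rec.visible_on_gamma,
            )
        )
    return out


def read_lesion_csv(path) -> list[LesionRecord]:
    """Read a lesion CSV (patient_id,location,dim_a_cm,dim_b_cm,dim_c_cm,suv_max,suv_mean,visible)."""
    df = pd.read_csv(path)
    records = []
    for r in df.itertuples(index=False):
        dims = (r.dim_a_cm, r.dim_b_cm, r.dim_c_cm)
        dimensions = None if any(pd.isna(d) for d in dims) else tuple(float(d) for d in dims)
        visible = None
        if isinstance(r.visible, str):
            visible = r.visible.strip().upper() == "Y"
        records.append(
            LesionRecord(
                patient_id=str(r.patient_id),
                location=str(r.location),
                suv_max=float(r.suv_max),
                suv_mean=float(r.suv_mean),
                dimensions_cm=dimensions,
                visible_on_gamma=visible,
            )
        )
    return records
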