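"""Blood-compartment processing and in-vivo stability assessment.

Whole-blood and plasma aliquots drawn after injection are counted on a
well counter (55–300 keV window) at least 12 h after sampling, by which
time the short-lived daughters have reached transient equilibrium with
²¹²Pb, so a single empirical calibration factor converts counts to
²¹²Pb activity.  The red-cell activity concentration follows from the
whole-blood/plasma pair and the hematocrit:

    A_rbc = (A_wb − (1 − HCT) · A_plasma) / HCT

Free ²¹²Pb binds to red blood cells, so A_rbc near (or below) zero is
the evidence that the ligand remains intact in circulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import PB212_HALF_LIFE_H, counting_window_correction

WHOLE_BLOOD_DENSITY_G_PER_ML = 1.06
PLASMA_DENSITY_G_PER_ML = 1.03

# seven Bi-212 half-lives; daughters are within ~1% of equilibrium
_EQUILIBRIUM_DELAY_H = 7 * 1.00917


@dataclass(frozen=True)
class BloodSample:
    """One well-counter record for a whole-blood or plasma aliquot.

    ``calibration`` is counts per (kBq·s) of ²¹²Pb at daughter
    equilibrium in the counting window; ``counting_delay_h`` and
    ``counting_duration_h`` are in hours (the protocol counts for
    40 min ≥ 12 h after sampling).
    """

    patient_id: str
    time_h: float
    sample_type: str  # "whole_blood" | "plasma"
    mass_g: float
    counting_delay_h: float
    counting_duration_h: float
    net_counts: float
    calibration: float
    hematocrit: float

    def __post_init__(self) -> None:
        if self.sample_type not in ("whole_blood", "plasma"):
            raise ValueError(f"unknown sample type {self.sample_type!r}")
        if self.mass_g <= 0:
            raise ValueError("sample mass must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.counting_delay_h < _EQUILIBRIUM_DELAY_H:
            warnings.warn(
                f"counting delay {self.counting_delay_h:.1f} h is below "
                f"{_EQUILIBRIUM_DELAY_H:.1f} h; daughters may not be at "
                "equilibrium and the calibration factor may bias the result",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PartitionResult:
    """Activity concentrations (kBq/mL at sampling time) for one draw.

    ``a_rbc`` is reported signed: negative values are measurement noise
    around zero and are themselves the stability evidence — they are
    never clipped.
    """

    patient_id: str
    time_h: float
    a_whole_blood: float
    a_plasma: float
    a_rbc: float
    plasma_wb_ratio: float


def mass_to_volume(mass_g: float, sample_type: str) -> float:
    """Convert aliquot mass to volume via fixed densities (1.06 / 1.03 g/mL)."""
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    if sample_type == "whole_blood":
        return mass_g / WHOLE_BLOOD_DENSITY_G_PER_ML
    if sample_type == "plasma":
        return mass_g / PLASMA_DENSITY_G_PER_ML
    raise ValueError(f"unknown sample type {sample_type!r}")


def activity_concentration(sample: BloodSample) -> float:
    """²¹²Pb activity concentration (kBq/mL) at sampling time.

    Counts are converted to a mean rate, calibrated to activity, decay-
    corrected over the counting delay and averaged-decay-corrected over
    the acquisition window, then divided by the aliquot volume.
    """
    if sample.calibration <= 0:
        raise ValueError("calibration must be positive")
    volume = mass_to_volume(sample.mass_g, sample.sample_type)
    if volume == 0:
        raise ValueError("zero sample volume")
    duration_s = sample.counting_duration_h * 3600.0
    mean_rate_kBq = sample.net_counts / (sample.calibration * duration_s)
    factor = counting_window_correction(
        sample.counting_delay_h, sample.counting_duration_h, PB212_HALF_LIFE_H
    )
    return mean_rate_kBq * factor / volume


def rbc_activity(a_wb: float, a_plasma: float, hct: float) -> float:
    """Red-blood-cell activity concentration from the partition identity.

    ``(a_wb − (1−hct)·a_plasma) / hct``; may legitimately be negative
    under measurement noise when true red-cell uptake is zero.
    """
    if not 0 < hct < 1:
        raise ValueError("hematocrit must lie in (0, 1)")
    return (a_wb - (1.0 - hct) * a_plasma) / hct


def partition_samples(samples: list[BloodSample]) -> list[PartitionResult]:
    """Pair whole-blood/plasma samples per (patient, time) and partition.

    Raises ``ValueError`` listing orphan records if any draw lacks its
    counterpart.
    """
    df = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "time_h": [s.time_h for s in samples],
            "sample_type": [s.sample_type for s in samples],
            "conc": [activity_concentration(s) for s in samples],
            "hct": [s.hematocrit for s in samples],
        }
    )
    results = []
    orphans = []
    for (pid, t), sub in df.groupby(["patient_id", "time_h"]):
        types = set(sub["sample_type"])
        if types != {"whole_blood", "plasma"}:
            orphans.append((pid, t, sorted(types)))
            continue
        a_wb = float(sub.loc[sub.sample_type == "whole_blood", "conc"].mean())
        a_pl = float(sub.loc[sub.sample_type == "plasma", "conc"].mean())
        hct = float(sub["hct"].iloc[0])
        results.append(
            PartitionResult(
                patient_id=pid,
                time_h=float(t),
                a_whole_blood=a_wb,
                a_plasma=a_pl,
                a_rbc=rbc_activity(a_wb, a_pl, hct),
                plasma_wb_ratio=a_pl / a_wb if a_wb > 0 else math.nan,
            )
        )
    if orphans:
        raise ValueError(f"unpaired blood samples: {orphans}")
    return results


def plasma_wb_ratio_stats(results: list[PartitionResult]) -> tuple[float, float]:
    """Mean and sample SD of the per-draw plasma : whole-blood ratio."""
    if not results:
        raise ValueError("no partition results")
    ratios = np.array([r.plasma_wb_ratio for r in results])
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return float(ratios.mean()), sd


def stability_verdict(
    results: list[PartitionResult], tolerance: float = 0.05
) -> dict:
    """Classify in-vivo stability from the red-cell partitioning.

    ``stable`` iff the mean red-cell concentration does not exceed
    ``tolerance`` (default 5%) of the mean whole-blood concentration;
    otherwise ``free_pb_suspected`` (free ²¹²Pb accumulates on red
    cells).  Returns the verdict with the summary statistics behind it.
    """
    if not results:
        raise ValueError("no partition results")
    mean_rbc = float(np.mean([r.a_rbc for r in results]))
    mean_wb = float(np.mean([r.a_whole_blood for r in results]))
    stable = mean_rbc <= tolerance * mean_wb
    n_below_zero = sum(r.a_rbc < 0 for r in results)
    return {
        "verdict": "stable" if stable else "free_pb_suspected",
        "mean_a_rbc_kBq_mL": mean_rbc,
        "mean_a_whole_blood_kBq_mL": mean_wb,
        "rbc_fraction_of_wb": mean_rbc / mean_wb if mean_wb > 0 else math.nan,
        "n_samples": len(results),
        "n_rbc_below_zero": n_below_zero,
        "tolerance": tolerance,
    }


def read_blood_csv(path) -> list[BloodSample]:
    """Read a blood-sample CSV (see ``BloodSample`` fields for columns)."""
    df = pd.read_csv(path)
    required = {
        "patient_id", "time_h", "sample_type", "mass_g", "delay_h",
        "duration_h", "net_counts", "calibration", "hct",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"blood CSV missing columns: {sorted(missing)}")
    return [
        BloodSample(
            str(r.patient_id), float(r.time_h), str(r.sample_type),
            float(r.mass_g), float(r.delay_h), float(r.duration_h),
            float(r.net_counts), float(r.calibration), float(r.hct),
        )
        for r in df.itertuples(index=False)
    ]
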