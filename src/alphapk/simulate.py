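"""Seeded synthetic-data generators for the full analysis pipeline.

The study's raw measurements (probe count rates, well-counter records,
phantom scans) are not published, so these generators emulate each input
table with the statistical structure the analysis assumes: mono-
exponential whole-body and blood clearance, hematocrit-partitioned
blood activity with an adjustable red-cell-binding fraction, lognormal
lesion SUVs, and a saturating monotone phantom contrast surface.  The
default cohort mirrors the study design: 3 patients, 9.6/9.5/9.0 MBq,
probe points at the protocol window midpoints with a fifth 2.4 h point
for patient 3.  Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import study
from .blood import BloodSample
from .clearance import ProbeMeasurement
from .decay import PB212_HALF_LIFE_H, counting_window_correction
from .detectability import ContrastObservation
from .uptake import LesionRecord


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic cohort; defaults mirror the study design."""

    n_patients: int = 3
    administered_MBq: tuple[float, ...] = (9.6, 9.5, 9.0)
    body_weights_kg: tuple[float, ...] = (80.0, 80.0, 62.0)
    true_effective_half_life_h: float = study.POOLED_EFFECTIVE_HALF_LIFE_H
    probe_times_h: tuple[float, ...] = study.PROBE_TIMES_H
    extra_probe_times_h: tuple[tuple[int, float], ...] = ((2, 2.4),)
    probe_noise_cv: float = 0.05
    probe_rate_per_MBq_cps: float = 50.0
    # blood panel
    blood_times_h: tuple[float, ...] = study.PROBE_TIMES_H
    blood_c0_kBq_mL: float = 2.0
    blood_half_life_h: float = study.POOLED_EFFECTIVE_HALF_LIFE_H
    hematocrit_mean: float = 0.41
    hematocrit_sd: float = 0.01
    rbc_binding_fraction: float = 0.0
    sample_mass_g: float = 1.05
    counting_delay_h: float = 12.0
    counting_duration_h: float = 2.0 / 3.0
    well_counter_calibration: float = 50.0  # counts per (kBq·s)
    # lesions
    n_lesions_per_patient: int = 3
    lesion_suv_logmean: float = 2.6  # lognormal median ≈ 13.5 SUV_max
    lesion_suv_logsd: float = 0.6
    lesion_dim_range_cm: tuple[float, float] = (0.6, 3.0)
    # phantom
    phantom_volumes_cm3: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 26.0)
    phantom_concs_kBq_mL: tuple[float, ...] = (2.0, 4.0, 6.0, 9.0, 13.0, 20.0)
    phantom_contrast_slope: float = 0.15  # contrast per kBq/mL at large volume
    phantom_half_volume_cm3: float = 1.0
    phantom_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if len(self.administered_MBq) < self.n_patients:
            raise ValueError("administered activities must cover all patients")
        if not 0 <= self.rbc_binding_fraction <= 1:
            raise ValueError("rbc binding fraction must lie in [0, 1]")
        for name in (
            "true_effective_half_life_h", "probe_rate_per_MBq_cps",
            "blood_c0_kBq_mL", "blood_half_life_h", "sample_mass_g",
            "well_counter_calibration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def patient_ids(self) -> list[str]:
        return [f"ID{i + 1:02d}" for i in range(self.n_patients)]

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def gen_probe_series(spec: CohortSpec) -> list[ProbeMeasurement]:
    """Whole-body probe series: rate ∝ 2^(−t/T_eff) with lognormal noise."""
    rng = np.random.default_rng(spec.seed)
    out: list[ProbeMeasurement] = []
    extras = dict(spec.extra_probe_times_h)
    for i, pid in enumerate(spec.patient_ids()):
        times = sorted(
            list(spec.probe_times_h) + ([extras[i]] if i in extras else [])
        )
        a0 = spec.administered_MBq[i] * spec.probe_rate_per_MBq_cps
        clean = a0 * 2.0 ** (-np.array(times) / spec.true_effective_half_life_h)
        noisy = clean * _lognormal_factors(rng, spec.probe_noise_cv, len(times))
        out.extend(
            ProbeMeasurement(pid, t, r) for t, r in zip(times, noisy)
        )
    return out


def gen_blood_panel(spec: CohortSpec) -> list[BloodSample]:
    """Paired whole-blood/plasma well-counter records.

    Plasma concentration follows a monoexponential curve; whole blood is
    ``(1−hct)·plasma + hct·rbc`` with ``rbc = binding·plasma``.  Counts
    are forward-simulated through the counting-window decay model with
    Poisson noise, so the analysis-side correction inverts them exactly
    in expectation.
    """
    rng = np.random.default_rng(spec.seed + 1)
    samples: list[BloodSample] = []
    for i, pid in enumerate(spec.patient_ids()):
        hct = float(np.clip(rng.normal(spec.hematocrit_mean, spec.hematocrit_sd), 0.2, 0.6))
        for t in spec.blood_times_h:
            c_plasma = spec.blood_c0_kBq_mL * 2.0 ** (-t / spec.blood_half_life_h)
            c_rbc = spec.rbc_binding_fraction * c_plasma
            c_wb = (1.0 - hct) * c_plasma + hct * c_rbc
            for stype, conc, density in (
                ("whole_blood", c_wb, 1.06),
                ("plasma", c_plasma, 1.03),
            ):
                volume_mL = spec.sample_mass_g / density
                activity_kBq = conc * volume_mL
                window = counting_window_correction(
                    spec.counting_delay_h, spec.counting_duration_h, PB212_HALF_LIFE_H
                )
                duration_s = spec.counting_duration_h * 3600.0
                mean_counts = (
                    activity_kBq / window * spec.well_counter_calibration * duration_s
                )
                counts = float(rng.poisson(mean_counts))
                samples.append(
                    BloodSample(
                        patient_id=pid,
                        time_h=t,
                        sample_type=stype,
                        mass_g=spec.sample_mass_g,
                        counting_delay_h=spec.counting_delay_h,
                        counting_duration_h=spec.counting_duration_h,
                        net_counts=counts,
                        calibration=spec.well_counter_calibration,
                        hematocrit=hct,
                    )
                )
    return samples


def gen_lesion_table(spec: CohortSpec) -> list[LesionRecord]:
    """Lesion records with lognormal SUV_max and SUV_mean below it."""
    rng = np.random.default_rng(spec.seed + 2)
    out: list[LesionRecord] = []
    lo, hi = spec.lesion_dim_range_cm
    for pid in spec.patient_ids():
        for k in range(spec.n_lesions_per_patient):
            suv_max = float(rng.lognormal(spec.lesion_suv_logmean, spec.lesion_suv_logsd))
            suv_mean = suv_max * float(rng.uniform(0.5, 0.7))
            dims = tuple(np.round(rng.uniform(lo, hi, 3), 1)) if rng.random() < 0.6 else None
            out.append(
                LesionRecord(
                    patient_id=pid,
                    location=f"lesion_{k + 1}",
                    suv_max=suv_max,
                    suv_mean=suv_mean,
                    dimensions_cm=dims,
                )
            )
    return out


def true_phantom_contrast(spec: CohortSpec, conc: float, vol: float) -> float:
    """Noise-free saturating contrast surface c·conc·vol/(vol+v₀)."""
    return spec.phantom_contrast_slope * conc * vol / (vol + spec.phantom_half_volume_cm3)


def gen_phantom_obs(spec: CohortSpec) -> list[ContrastObservation]:
    """Phantom sphere contrast grid with Gaussian noise (floored at 0)."""
    rng = np.random.default_rng(spec.seed + 3)
    out = []
    for v in spec.phantom_volumes_cm3:
        for c in spec.phantom_concs_kBq_mL:
            contrast = true_phantom_contrast(spec, c, v) + rng.normal(
                0.0, spec.phantom_noise_sd
            )
            out.append(ContrastObservation(v, c, max(contrast, 0.0)))
    return out


def probe_to_frame(series: list[ProbeMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in series],
            "time_h": [m.time_h for m in series],
            "net_rate_cps": [m.net_rate_cps for m in series],
            "duration_s": [m.duration_s for m in series],
        }
    )


def blood_to_frame(samples: list[BloodSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "time_h": [s.time_h for s in samples],
            "sample_type": [s.sample_type for s in samples],
            "mass_g": [s.mass_g for s in samples],
            "delay_h": [s.counting_delay_h for s in samples],
            "duration_h": [s.counting_duration_h for s in samples],
            "net_counts": [s.net_counts for s in samples],
            "calibration": [s.calibration for s in samples],
            "hct": [s.hematocrit for s in samples],
        }
    )


def lesions_to_frame(lesions: list[LesionRecord]) -> pd.DataFrame:
    rows = []
    for r in lesions:
        a, b, c = r.dimensions_cm if r.dimensions_cm else (None, None, None)
        rows.append(
            {
                "patient_id": r.patient_id,
                "location": r.location,
                "dim_a_cm": a,
                "dim_b_cm": b,
                "dim_c_cm": c,
                "suv_max": r.suv_max,
                "suv_mean": r.suv_mean,
                "visible": "" if r.visible_on_gamma is None
                else ("Y" if r.visible_on_gamma else "N"),
            }
        )
    return pd.DataFrame(rows)


def phantom_to_frame(obs: list[ContrastObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "volume_cm3": [o.sphere_volume_cm3 for o in obs],
            "conc_kBq_mL": [o.concentration_kBq_mL for o in obs],
            "contrast": [o.contrast for o in obs],
        }
    )


def write_cohort(spec: CohortSpec, out_dir) -> dict[str, str]:
    """Emit probe.csv, blood.csv, lesions.csv, phantom.csv and patients.yaml."""
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("probe.csv", probe_to_frame(gen_probe_series(spec))),
        ("blood.csv", blood_to_frame(gen_blood_panel(spec))),
        ("lesions.csv", lesions_to_frame(gen_lesion_table(spec))),
        ("phantom.csv", phantom_to_frame(gen_phantom_obs(spec))),
    ):
        path = out / name
        frame.to_csv(path, index=False)
        paths[name] = str(path)
    patients = {
        pid: {
            "administered_MBq": spec.administered_MBq[i],
            "body_weight_kg": spec.body_weights_kg[i]
            if i < len(spec.body_weights_kg)
            else study.DEFAULT_BODY_WEIGHT_KG,
        }
        for i, pid in enumerate(spec.patient_ids())
    }
    ppath = out / "patients.yaml"
    ppath.write_text(yaml.safe_dump({"patients": patients, "seed": spec.seed}))
    paths["patients.yaml"] = str(ppath)
    return paths
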