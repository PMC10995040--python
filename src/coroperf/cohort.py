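"""Reproducible synthetic cohorts: paired rest/stress measures and patients.

Emulates the structure of the paired adenosine database (a linear
rest→stress relation plus Gaussian measurement noise and a fraction of
gross outliers) and samples plausible middle-aged patient records, so the
whole pipeline is testable without any clinical download.  Covariates are
sampled uniformly within bounded ranges; noise is Gaussian.  All
randomness flows from the single cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .hyperemia import QUANTITIES, PairedMeasureSet, StressMapCoefficients
from .patient import PatientRecord, derive_all

__all__ = ["CohortSpec", "generate_paired_measures", "generate_patient"]

#: Stable per-quantity stream offsets so each quantity has its own substream.
_QUANTITY_STREAM = {"HR": 1, "P_sys": 2, "P_dia": 3}
_PATIENT_STREAM = 1000

#: Minimum sampled brachial pulse pressure [mmHg].
MIN_PULSE_PRESSURE = 20.0


def _default_noise_sd() -> dict[str, float]:
    # Measurement scatter comparable to the clinical dispersion: ~8 bpm for
    # HR, ~10/7 mmHg for systolic/diastolic pressure.
    return {"HR": 8.0, "P_sys": 10.0, "P_dia": 7.0}


def _default_rest_ranges() -> dict[str, tuple[float, float]]:
    return {"HR": (55.0, 90.0), "P_sys": (100.0, 160.0), "P_dia": (60.0, 100.0)}


def _default_patient_ranges() -> dict[str, tuple[float, float]]:
    return {
        "age": (40.0, 80.0),
        "height": (150.0, 190.0),
        "weight": (50.0, 110.0),
        "HR": (55.0, 90.0),
        "P_sys": (100.0, 160.0),
        "P_dia": (60.0, 100.0),
        "LV_mass": (100.0, 250.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for one synthetic cohort.

    ``truth`` holds the planted rest→stress lines; ``noise_sd`` the
    Gaussian measurement noise per quantity (native units);
    ``outlier_rate`` the fraction of records additionally shifted by
    ``±outlier_magnitude·noise_sd`` (gross recording errors).
    """

    n: int = 75
    seed: int = 0
    truth: StressMapCoefficients = field(default_factory=StressMapCoefficients.default)
    noise_sd: dict = field(default_factory=_default_noise_sd)
    outlier_rate: float = 0.1
    outlier_magnitude: float = 20.0
    rest_ranges: dict = field(default_factory=_default_rest_ranges)
    patient_ranges: dict = field(default_factory=_default_patient_ranges)

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError(f"cohort size must be >= 4, got {self.n}")
        if not 0.0 <= self.outlier_rate <= 0.3:
            raise ValidationError(f"outlier_rate must lie in [0, 0.3], got {self.outlier_rate}")
        pr = self.patient_ranges
        if not pr["P_sys"][0] >= pr["P_dia"][1]:
            raise ValidationError(
                "patient P_sys range must lie entirely above the P_dia range "
                "(otherwise sampled records could violate P_sys > P_dia)"
            )


def generate_paired_measures(spec: CohortSpec, quantity: str) -> PairedMeasureSet:
    """Sample one quantity's paired rest/stress set, fully seed-determined."""
    if quantity not in QUANTITIES:
        raise ValidationError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")
    rng = np.random.default_rng([spec.seed, _QUANTITY_STREAM[quantity]])
    lo, hi = spec.rest_ranges[quantity]
    rest = rng.uniform(lo, hi, size=spec.n)
    line = getattr(spec.truth, quantity)
    sd = spec.noise_sd[quantity]
    stress = line.alpha * rest + line.beta + rng.normal(0.0, sd, size=spec.n)
    is_outlier = rng.random(spec.n) < spec.outlier_rate
    signs = np.where(rng.random(spec.n) < 0.5, -1.0, 1.0)
    stress = stress + is_outlier * signs * spec.outlier_magnitude * sd
    return PairedMeasureSet(quantity, rest, stress)


def generate_patient(spec: CohortSpec, index: int) -> PatientRecord:
    """Sample one plausible resting patient record (seed and index determined).

    The record is guaranteed to pass validation and to admit an ordered
    waveform-timing chain; ranges that break the chain raise a diagnostic.
    """
    rng = np.random.default_rng([spec.seed, _PATIENT_STREAM + int(index)])
    r = spec.patient_ranges
    p_dia = float(rng.uniform(*r["P_dia"]))
    # systolic pressure sampled jointly so the pulse pressure stays at
    # least 20 mmHg — narrower pulse pressures are not physiological and
    # would not survive the brachial-to-aortic correction
    sys_lo = max(r["P_sys"][0], p_dia + MIN_PULSE_PRESSURE)
    if sys_lo >= r["P_sys"][1]:
        raise ValidationError(
            f"patient ranges leave no room for a {MIN_PULSE_PRESSURE} mmHg pulse pressure "
            f"at P_dia={p_dia:.1f} (index {index})"
        )
    record = PatientRecord(
        age=float(rng.uniform(*r["age"])),
        sex="male" if rng.random() < 0.5 else "female",
        height=float(rng.uniform(*r["height"])),
        weight=float(rng.uniform(*r["weight"])),
        HR=float(rng.uniform(*r["HR"])),
        P_sys=float(rng.uniform(sys_lo, r["P_sys"][1])),
        P_dia=p_dia,
        LV_mass=float(rng.uniform(*r["LV_mass"])),
        state="rest",
    )
    try:
        derive_all(record)
    except ValidationError as exc:
        raise ValidationError(
            f"patient ranges produced an invalid waveform for index {index}: {exc}"
        ) from exc
    return record
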