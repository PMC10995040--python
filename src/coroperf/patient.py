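"""Patient-level parameters of the 4-phase aortic pressure waveform.

From routine clinical measures (age, sex, height, weight, heart rate,
brachial systolic/diastolic pressure, left-ventricular mass) this module
derives every key time instant and pressure value of the piecewise aortic
pressure curve: the systolic shoulder, the reflected-wave peak, the aortic
incisura, the dicrotic notch, and the end-diastolic return.  All
coefficients of the literature regressions involved (diastolic/systolic
time ratio vs HR, IVRT vs age and indexed LV mass, augmentation index vs
age/HR/height, dicrotic-notch pressure vs mean pressure) are frozen
constants; re-fitting them is out of scope.

Units are clinical throughout: seconds, mmHg, bpm, cm, kg, grams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .errors import ValidationError

__all__ = [
    "IVCT_S",
    "K_UPSTROKE_MMHG_S",
    "PatientRecord",
    "WaveformTimings",
    "WaveformPressures",
    "diastolic_systolic_ratio",
    "systolic_duration",
    "body_surface_area",
    "lv_indexed_mass",
    "ivrt",
    "augmentation_index",
    "augmentation_pressure",
    "notch_pressure",
    "derive_all",
]

#: Isovolumic contraction time, fixed for adults [s].
IVCT_S = 0.05

#: Empirical slope of the systolic upstroke at the shoulder [mmHg/s].
K_UPSTROKE_MMHG_S = 75.0

#: Brachial-to-aortic systolic pressure drop [mmHg], by sex.
BRACHIAL_AORTIC_DROP_MMHG = {"male": 10.0, "female": 8.0}


@dataclass(frozen=True)
class PatientRecord:
    """One subject's routine clinical measures, at rest or under stress.

    Fields
    ------
    age : years
    sex : ``"male"`` or ``"female"``
    height : cm
    weight : kg
    HR : heart rate, beats/min
    P_sys, P_dia : brachial systolic/diastolic pressure, mmHg
    LV_mass : left-ventricular mass, g
    state : ``"rest"`` or ``"stress"``
    """

    age: float
    sex: str
    height: float
    weight: float
    HR: float
    P_sys: float
    P_dia: float
    LV_mass: float
    state: str = "rest"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.state not in ("rest", "stress"):
            raise ValidationError(f"state must be 'rest' or 'stress', got {self.state!r}")
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        for name in ("height", "weight", "LV_mass"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if not 20.0 < self.HR < 250.0:
            raise ValidationError(f"HR must lie in (20, 250) bpm, got {self.HR}")
        if not self.P_sys > self.P_dia > 0:
            raise ValidationError(
                f"pressures must satisfy P_sys > P_dia > 0, got P_sys={self.P_sys}, P_dia={self.P_dia}"
            )

    def replace(self, **kw) -> "PatientRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class WaveformTimings:
    """Key time instants of one cardiac cycle [s].

    ``T`` is the heartbeat period 60/HR; ``T_notch`` the systolic duration
    (dicrotic notch); ``T_sh`` the systolic shoulder at T_notch/3; ``T_peak``
    the reflected-wave arrival at T_notch/2; ``T_i`` the aortic incisura
    T_notch − IVRT; ``IVCT`` the isovolumic contraction time (0.05 s).
    """

    T: float
    T_notch: float
    T_sh: float
    T_peak: float
    T_i: float
    IVRT: float
    IVCT: float = IVCT_S

    def __post_init__(self) -> None:
        chain = [
            ("0 < T_sh", 0.0, self.T_sh),
            ("T_sh < T_peak", self.T_sh, self.T_peak),
            ("T_peak < T_i", self.T_peak, self.T_i),
            ("T_i < T_notch", self.T_i, self.T_notch),
            ("T_notch < T - IVCT", self.T_notch, self.T - self.IVCT),
            ("T - IVCT < T", self.T - self.IVCT, self.T),
        ]
        for name, lo, hi in chain:
            if not lo < hi:
                raise ValidationError(f"timing ordering violated: {name} (got {lo:.6g} >= {hi:.6g})")


@dataclass(frozen=True)
class WaveformPressures:
    """Key pressure values of the waveform [mmHg].

    ``delta_P`` is the augmentation pressure carried by the reflected wave;
    ``P_mean`` the simplified mean 0.5·(P_peak + P_min) feeding the notch
    regression.
    """

    P_min: float
    P_peak: float
    delta_P: float
    P_sh: float
    P_i: float
    P_notch: float
    P_mean: float

    def __post_init__(self) -> None:
        if self.delta_P < 0:
            raise ValidationError(f"delta_P must be >= 0, got {self.delta_P}")
        if not self.P_min < self.P_sh <= self.P_peak:
            raise ValidationError(
                f"pressure ordering violated: P_min < P_sh <= P_peak "
                f"(got {self.P_min}, {self.P_sh}, {self.P_peak})"
            )


def _check_hr(HR: float) -> None:
    if not 20.0 < HR < 250.0:
        raise ValidationError(f"HR must lie in (20, 250) bpm, got {HR}")


def diastolic_systolic_ratio(HR: float) -> float:
    """Diastolic/systolic time ratio R_ds as a quadratic in heart rate (bpm)."""
    _check_hr(HR)
    return 2.537e-4 * HR**2 - 0.057 * HR + 4.3


def systolic_duration(HR: float) -> float:
    """Systolic duration T_notch [s].

    The period splits as T = T_notch + T_dia with T_dia/T_notch = R_ds,
    hence T_notch = T / (1 + R_ds).
    """
    _check_hr(HR)
    T = 60.0 / HR
    return T / (1.0 + diastolic_systolic_ratio(HR))


def body_surface_area(height: float, weight: float) -> float:
    """Du Bois body surface area [m²] from height [cm] and weight [kg]."""
    if height <= 0 or weight <= 0:
        raise ValidationError("height and weight must be positive")
    return 0.007184 * height**0.725 * weight**0.425


def lv_indexed_mass(LV_mass: float, height: float, weight: float) -> float:
    """Left-ventricular indexed mass LVIM [g/m²] (Du Bois BSA)."""
    if LV_mass <= 0:
        raise ValidationError("LV_mass must be positive")
    return LV_mass / body_surface_area(height, weight)


def ivrt(age: float, LVIM: float, t_notch: float | None = None) -> float:
    """Isovolumic relaxation time [s] from the age-shifted LVIM regression.

    IVRT[ms] = 0.267·LVIM + 51.45 + 0.412·(age − 54).  If ``t_notch`` is
    given, the result is required to stay below T_notch/2 so that the
    incisura falls after the reflected-wave peak.
    """
    if age <= 0 or LVIM <= 0:
        raise ValidationError("age and LVIM must be positive")
    shift = 0.412 * (age - 54.0)
    ivrt_s = (0.267 * LVIM + 51.45 + shift) / 1000.0
    if t_notch is not None and not ivrt_s < t_notch / 2.0:
        raise ValidationError(
            f"IVRT={ivrt_s * 1e3:.1f} ms must be < T_notch/2={t_notch / 2 * 1e3:.1f} ms "
            "(otherwise the incisura would precede the systolic peak)"
        )
    return ivrt_s


#: Augmentation-index polynomial coefficients (intercept, age, age², HR, height).
_AIX_COEFFS = {
    "male": (79.70, 0.63, -0.002, -0.28, -0.39),
    "female": (56.28, 0.90, -0.005, -0.34, -0.24),
}


def augmentation_index(sex: str, age: float, HR: float, height: float) -> float:
    """Augmentation index [% of pulse pressure] from sex, age, HR and height."""
    if sex not in _AIX_COEFFS:
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    c0, c_age, c_age2, c_hr, c_h = _AIX_COEFFS[sex]
    return c0 + c_age * age + c_age2 * age**2 + c_hr * HR + c_h * height


def augmentation_pressure(record: PatientRecord, P_peak: float, P_min: float) -> float:
    """Augmentation pressure ΔP [mmHg] = AIx/100 · (P_peak − P_min).

    A negative augmentation index (young, tall subjects) is clamped to zero
    with a warning; the regression population is 40+ years old.
    """
    if not P_peak > P_min:
        raise ValidationError(f"P_peak must exceed P_min, got {P_peak} <= {P_min}")
    aix = augmentation_index(record.sex, record.age, record.HR, record.height)
    if aix < 0.0:
        warnings.warn(
            f"negative augmentation index ({aix:.2f}%) clamped to 0 "
            f"(age={record.age}, height={record.height} outside the regression population)",
            stacklevel=2,
        )
        aix = 0.0
    return aix / 100.0 * (P_peak - P_min)


def notch_pressure(P_peak: float, P_min: float) -> float:
    """Dicrotic-notch pressure [mmHg] regressed on the simplified mean pressure."""
    if not P_peak > P_min:
        raise ValidationError(f"P_peak must exceed P_min, got {P_peak} <= {P_min}")
    p_mean = 0.5 * (P_peak + P_min)
    return 1.1667 * p_mean - 12.629


def derive_all(record: PatientRecord) -> tuple[WaveformTimings, WaveformPressures]:
    """Derive every waveform timing and pressure from one patient record.

    Deterministic: identical records give bit-identical parameters.  Raises
    :class:`ValidationError` naming the violated inequality if the derived
    timings are not ordered.
    """
    T = 60.0 / record.HR
    T_notch = systolic_duration(record.HR)
    T_sh = T_notch / 3.0
    T_peak = T_notch / 2.0
    lvim = lv_indexed_mass(record.LV_mass, record.height, record.weight)
    IVRT = ivrt(record.age, lvim, t_notch=T_notch)
    T_i = T_notch - IVRT

    P_min = record.P_dia
    P_peak = record.P_sys - BRACHIAL_AORTIC_DROP_MMHG[record.sex]
    if not P_peak > P_min:
        raise ValidationError(
            f"aortic P_peak={P_peak} mmHg does not exceed P_min={P_min} mmHg "
            "(pulse pressure too small for the brachial-to-aortic correction)"
        )
    delta_P = augmentation_pressure(record, P_peak, P_min)
    P_sh = P_peak - delta_P
    P_mean = 0.5 * (P_peak + P_min)
    P_notch = notch_pressure(P_peak, P_min)
    # Incisura pressure from the augmentation parabola evaluated at T_i.
    a_II = (P_sh - P_peak) / (T_sh - T_peak) ** 2
    P_i = a_II * (T_i - T_peak) ** 2 + P_peak

    timings = WaveformTimings(T=T, T_notch=T_notch, T_sh=T_sh, T_peak=T_peak, T_i=T_i, IVRT=IVRT)
    pressures = WaveformPressures(
        P_min=P_min,
        P_peak=P_peak,
        delta_P=delta_P,
        P_sh=P_sh,
        P_i=P_i,
        P_notch=P_notch,
        P_mean=P_mean,
    )
    return timings, pressures
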