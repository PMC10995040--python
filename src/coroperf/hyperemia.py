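"""Rest-to-hyperemia mapping of heart rate and brachial pressures.

Adenosine-induced hyperemia raises heart rate and slightly lowers systolic
and diastolic pressure.  Each quantity maps linearly,
``X_stress = alpha * X_rest + beta``, with default coefficients frozen from
a 100-patient paired rest/stress clinical database.  The module also
implements the full re-derivation pipeline for any paired dataset:
interquartile-range cleaning of the per-record differences
``dX = X_rest − X_stress`` (records kept iff
``Q1 − f·IQR < dX < Q3 + f·IQR`` with fence factor f = 0.5), followed by
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .patient import PatientRecord

__all__ = [
    "QUANTITIES",
    "LinearMap",
    "StressMapCoefficients",
    "PairedMeasureSet",
    "CleaningReport",
    "rest_to_stress",
    "iqr_clean",
    "fit_linear",
    "fit_stress_mapping",
]

QUANTITIES = ("HR", "P_sys", "P_dia")

#: Default fence factor of the IQR cleaning rule (deliberately stricter
#: than the conventional 1.5; exposed as a knob).
DEFAULT_FENCE_FACTOR = 0.5


@dataclass(frozen=True)
class LinearMap:
    """One quantity's rest→stress line; ``R`` is the fit's Pearson correlation."""

    alpha: float
    beta: float
    R: float

    def __call__(self, x: float) -> float:
        return self.alpha * x + self.beta


@dataclass(frozen=True)
class StressMapCoefficients:
    """Per-quantity rest→stress linear maps (HR bpm, P_sys/P_dia mmHg)."""

    HR: LinearMap
    P_sys: LinearMap
    P_dia: LinearMap

    def __post_init__(self) -> None:
        for q in QUANTITIES:
            if getattr(self, q).alpha <= 0:
                raise ValidationError(f"alpha for {q} must be positive")

    @classmethod
    def default(cls) -> "StressMapCoefficients":
        """Coefficients from the 100-patient adenosine database."""
        return cls(
            HR=LinearMap(0.92, 26.00, 0.89),
            P_sys=LinearMap(0.73, 31.10, 0.78),
            P_dia=LinearMap(0.73, 21.25, 0.70),
        )

    def as_dict(self) -> dict:
        return {
            q: {"alpha": getattr(self, q).alpha, "beta": getattr(self, q).beta, "R": getattr(self, q).R}
            for q in QUANTITIES
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StressMapCoefficients":
        return cls(**{q: LinearMap(d[q]["alpha"], d[q]["beta"], d[q].get("R", float("nan"))) for q in QUANTITIES})


@dataclass(frozen=True)
class PairedMeasureSet:
    """Paired (rest, stress) measures of one quantity, in its native units."""

    quantity: str
    rest: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        rest = np.asarray(self.rest, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "rest", rest)
        object.__setattr__(self, "stress", stress)
        if rest.shape != stress.shape or rest.ndim != 1:
            raise ValidationError("rest and stress must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(rest)) and np.all(np.isfinite(stress))):
            raise ValidationError("paired measures must be finite")

    def __len__(self) -> int:
        return len(self.rest)

    @property
    def delta(self) -> np.ndarray:
        """Per-record difference dX = X_rest − X_stress."""
        return self.rest - self.stress

    def subset(self, idx) -> "PairedMeasureSet":
        return PairedMeasureSet(self.quantity, self.rest[idx], self.stress[idx])


@dataclass(frozen=True)
class CleaningReport:
    """Outcome of the IQR fence rule on one paired set."""

    quantity: str
    Q1: float
    Q3: float
    IQR: float
    fence_factor: float
    kept: np.ndarray
    removed: np.ndarray

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def rest_to_stress(
    record: PatientRecord, coeffs: StressMapCoefficients | None = None
) -> PatientRecord:
    """Map a resting patient record to its hyperemic counterpart.

    HR, P_sys and P_dia are transformed by their linear maps; all other
    fields are copied and the state flag flips to ``"stress"``.
    """
    if record.state != "rest":
        raise ValidationError("rest_to_stress expects a record with state='rest'")
    if coeffs is None:
        coeffs = StressMapCoefficients.default()
    hr = coeffs.HR(record.HR)
    p_sys = coeffs.P_sys(record.P_sys)
    p_dia = coeffs.P_dia(record.P_dia)
    if p_sys <= p_dia:
        raise ValidationError(
            f"mapped stress pressures degenerate: P_sys={p_sys:.1f} <= P_dia={p_dia:.1f} mmHg"
        )
    return record.replace(HR=hr, P_sys=p_sys, P_dia=p_dia, state="stress")


def iqr_clean(pairs: PairedMeasureSet, fence_factor: float = DEFAULT_FENCE_FACTOR) -> CleaningReport:
    """Flag unreliable records by the IQR fence rule on dX = X_rest − X_stress.

    Quartiles use linear interpolation between order statistics.  Fences
    are strict, exactly as printed: ``Q1 − f·IQR < dX < Q3 + f·IQR``.
    Degenerate case IQR = 0: the open interval would discard everything,
    including the bulk the rule is meant to keep, so records with
    dX equal to the collapsed quartile value are kept (in particular, all
    records are kept when every dX is identical).
    """
    if len(pairs) < 4:
        raise ValidationError(f"need at least 4 records for quartiles, got {len(pairs)}")
    dx = pairs.delta
    q1, q3 = np.percentile(dx, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    if iqr == 0.0:
        keep = dx == q1
    else:
        lo, hi = q1 - fence_factor * iqr, q3 + fence_factor * iqr
        keep = (dx > lo) & (dx < hi)
    idx = np.arange(len(pairs))
    return CleaningReport(
        quantity=pairs.quantity,
        Q1=float(q1),
        Q3=float(q3),
        IQR=float(iqr),
        fence_factor=fence_factor,
        kept=idx[keep],
        removed=idx[~keep],
    )


def fit_linear(pairs: PairedMeasureSet) -> LinearMap:
    """Ordinary least squares of X_stress on X_rest; R is Pearson's r."""
    if len(pairs) < 2:
        raise ValidationError("need at least 2 records to fit a line")
    if np.ptp(pairs.rest) == 0.0:
        raise ValidationError("x_rest has zero variance; slope is undefined")
    res = stats.linregress(pairs.rest, pairs.stress)
    return LinearMap(float(res.slope), float(res.intercept), float(res.rvalue))


def fit_stress_mapping(
    datasets: dict[str, PairedMeasureSet],
    fence_factor: float = DEFAULT_FENCE_FACTOR,
) -> tuple[StressMapCoefficients, dict[str, CleaningReport]]:
    """Clean then fit all three quantities; returns coefficients and reports."""
    missing = [q for q in QUANTITIES if q not in datasets]
    if missing:
        raise ValidationError(f"missing paired datasets for: {', '.join(missing)}")
    maps: dict[str, LinearMap] = {}
    reports: dict[str, CleaningReport] = {}
    for q in QUANTITIES:
        report = iqr_clean(datasets[q], fence_factor=fence_factor)
        reports[q] = report
        kept = datasets[q].subset(report.kept)
        if len(kept) < 3:
            raise ValidationError(f"{q}: fewer than 3 records remain after cleaning")
        maps[q] = fit_linear(kept)
    return StressMapCoefficients(**maps), reports
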