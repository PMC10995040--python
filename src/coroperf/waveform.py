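"""Piecewise-polynomial aortic and effective pressure waveforms.

The aortic root pressure over one heartbeat is built from four phases:

* **I — systolic upstroke** ``[0, T_sh]``: a cubic pinned at
  ``P(0) = P_min``, ``P(T_sh) = P_sh`` with slope ``k`` at the shoulder.
  Those are only three conditions on four coefficients; the system is
  closed with ``dP/dt(0) = 0``, which makes P_min a genuine minimum and
  the curve slope-free at the periodic seam.  This closure is a modelling
  choice of this package.
* **II — augmentation** ``[T_sh, T_i]``: a parabola with vertex
  ``(T_peak, P_peak)`` through the shoulder.
* **III — dicrotic notch** ``[T_i, T_notch]``: a parabola with vertex
  ``(T_notch, P_notch)`` matching phase II at the incisura.
* **IV — diastole** ``[T_notch, T]``: the line from the notch down to
  ``P_min``.

Derivative continuity is deliberately *not* enforced at the phase joints
(only at the shoulder, through ``k``): sharp variations such as the
incisura are physiological.

For computational models without cardiac contraction, the *effective*
pressure subtracts a surrogate of left-ventricular chamber pressure:
0.7·P_ar during ejection (leaving 0.3·P_ar driving coronary flow), zero in
mid-diastole, with quadratic bridges across the isovolumic relaxation and
contraction intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .patient import K_UPSTROKE_MMHG_S, WaveformPressures, WaveformTimings

__all__ = [
    "PiecewisePressure",
    "build_aortic_waveform",
    "build_effective_waveform",
    "find_peak_diastolic_time",
]

#: Value-continuity tolerance at interior breakpoints [mmHg].
CONTINUITY_TOL_MMHG = 1e-9


@dataclass(frozen=True)
class PiecewisePressure:
    """A periodically evaluable piecewise polynomial pressure curve.

    ``breakpoints`` is an ordered array covering [0, T]; segment ``i`` is
    the polynomial ``coeffs[i]`` (np.polyval convention, highest power
    first, in the global time variable) valid on
    ``[breakpoints[i], breakpoints[i+1]]``.
    """

    breakpoints: np.ndarray
    coeffs: tuple[tuple[float, ...], ...]
    period: float
    label: str  # "aortic" or "effective"

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        if bp[0] != 0.0 or abs(bp[-1] - self.period) > 1e-12:
            raise ValidationError("breakpoints must cover [0, T]")
        if np.any(np.diff(bp) <= 0):
            raise ValidationError("breakpoints must be strictly increasing")
        if len(self.coeffs) != len(bp) - 1:
            raise ValidationError("need one coefficient tuple per interval")
        if any(len(c) > 4 for c in self.coeffs):
            raise ValidationError("polynomial degree must be <= 3")
        # continuity at interior joints and periodicity at the seam
        for i in range(1, len(bp) - 1):
            left = np.polyval(self.coeffs[i - 1], bp[i])
            right = np.polyval(self.coeffs[i], bp[i])
            if abs(left - right) > CONTINUITY_TOL_MMHG:
                raise ValidationError(
                    f"discontinuity {left - right:.3e} mmHg at breakpoint t={bp[i]:.6g} s"
                )
        p0 = np.polyval(self.coeffs[0], 0.0)
        pT = np.polyval(self.coeffs[-1], self.period)
        if abs(p0 - pT) > CONTINUITY_TOL_MMHG:
            raise ValidationError(f"curve not periodic: P(0)={p0} vs P(T)={pT}")

    # -- evaluation -----------------------------------------------------

    def _segment_index(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        return np.clip(idx, 0, len(self.coeffs) - 1)

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t):
        """Pressure [mmHg] at time(s) ``t`` [s], reduced modulo the period."""
        t_arr = np.asarray(t, dtype=float)
        tm = np.mod(t_arr, self.period)
        idx = self._segment_index(np.atleast_1d(tm))
        out = np.empty_like(np.atleast_1d(tm))
        for i in np.unique(idx):
            sel = idx == i
            out[sel] = np.polyval(self.coeffs[i], np.atleast_1d(tm)[sel])
        return out[0] if t_arr.ndim == 0 else out.reshape(t_arr.shape)

    def derivative(self, t, side: str = "right") -> float:
        """Analytic derivative dP/dt [mmHg/s] at time ``t``.

        At a breakpoint the derivative may jump; ``side`` selects the
        owning segment ("left" evaluates the polynomial ending at ``t``).
        """
        tm = float(np.mod(t, self.period))
        if side == "left":
            i = int(np.searchsorted(self.breakpoints, tm, side="left")) - 1
            i = min(max(i, 0), len(self.coeffs) - 1)
        else:
            i = int(self._segment_index(np.asarray([tm]))[0])
        return float(np.polyval(np.polyder(np.asarray(self.coeffs[i], dtype=float)), tm))

    def sample(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Uniform samples (t, P) on [0, T], endpoint included."""
        if not 0.0 < dt <= self.period:
            raise ValidationError(f"dt must lie in (0, T], got {dt}")
        n = int(np.floor(self.period / dt)) + 1
        t = np.arange(n) * dt
        if t[-1] < self.period - 1e-12:
            t = np.append(t, self.period)
        return t, self.evaluate(t)

    def mean(self) -> float:
        """Time-average pressure over one period [mmHg] (exact integration)."""
        total = 0.0
        for i, c in enumerate(self.coeffs):
            anti = np.polyint(np.asarray(c, dtype=float))
            a, b = self.breakpoints[i], self.breakpoints[i + 1]
            total += np.polyval(anti, b) - np.polyval(anti, a)
        return float(total / self.period)

    def plot(self, ax=None, **kw):
        """Plot one period of the curve (matplotlib imported lazily)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, p = self.sample(self.period / 1000.0)
        ax.plot(t, p, **kw)
        ax.set_xlabel("time [s]")
        ax.set_ylabel("pressure [mmHg]")
        return ax


def _vertex_parabola(t_vertex: float, p_vertex: float, t_thru: float, p_thru: float) -> tuple:
    """Coefficients of a(t − t_vertex)² + p_vertex through (t_thru, p_thru)."""
    a = (p_thru - p_vertex) / (t_thru - t_vertex) ** 2
    return (a, -2.0 * a * t_vertex, a * t_vertex**2 + p_vertex)


def _line(t0: float, p0: float, t1: float, p1: float) -> tuple:
    m = (p1 - p0) / (t1 - t0)
    return (m, p0 - m * t0)


def build_aortic_waveform(
    timings: WaveformTimings,
    pressures: WaveformPressures,
    k: float = K_UPSTROKE_MMHG_S,
) -> PiecewisePressure:
    """Assemble the 4-phase aortic pressure curve P_ar.

    ``k`` [mmHg/s] is the upstroke slope at the systolic shoulder.
    """
    T, T_sh, T_peak, T_i, T_notch = (
        timings.T,
        timings.T_sh,
        timings.T_peak,
        timings.T_i,
        timings.T_notch,
    )
    P_min, P_sh, P_peak, P_notch = (
        pressures.P_min,
        pressures.P_sh,
        pressures.P_peak,
        pressures.P_notch,
    )
    if pressures.delta_P > 0 and not P_sh < P_peak:
        raise ValidationError("P_sh must be below P_peak when delta_P > 0")
    if not P_min < P_sh <= P_peak:
        raise ValidationError(f"need P_min < P_sh <= P_peak, got {P_min}, {P_sh}, {P_peak}")

    # Phase I cubic: P(0)=P_min, P'(0)=0 (closure), P(T_sh)=P_sh, P'(T_sh)=k.
    # With d=P_min, c=0: [T³ T²; 3T² 2T] [a b]ᵀ = [P_sh − P_min, k]ᵀ.
    A = np.array([[T_sh**3, T_sh**2], [3.0 * T_sh**2, 2.0 * T_sh]])
    a1, b1 = np.linalg.solve(A, np.array([P_sh - P_min, k]))
    phase1 = (float(a1), float(b1), 0.0, P_min)

    phase2 = _vertex_parabola(T_peak, P_peak, T_sh, P_sh)
    P_i = float(np.polyval(phase2, T_i))
    phase3 = _vertex_parabola(T_notch, P_notch, T_i, P_i)
    phase4 = _line(T_notch, P_notch, T, P_min)

    return PiecewisePressure(
        breakpoints=np.array([0.0, T_sh, T_i, T_notch, T]),
        coeffs=(phase1, phase2, phase3, phase4),
        period=T,
        label="aortic",
    )


#: Fraction of aortic pressure left to drive coronary flow during ejection.
EJECTION_DRIVING_FRACTION = 0.3


def build_effective_waveform(par: PiecewisePressure, timings: WaveformTimings) -> PiecewisePressure:
    """Effective inlet pressure P_eff = P_ar − P*_LV for non-contracting models.

    P*_LV = 0.7·P_ar during ejection [0, T_i]; zero in mid-diastole
    [T_notch, T − IVCT]; quadratic bridges (vertex at the interval end with
    higher pressure) across the isovolumic relaxation [T_i, T_notch] and
    contraction [T − IVCT, T] intervals.
    """
    if par.label != "aortic":
        raise ValidationError("build_effective_waveform expects an aortic curve")
    T, T_sh, T_i, T_notch, IVCT = timings.T, timings.T_sh, timings.T_i, timings.T_notch, timings.IVCT
    expected_bp = np.array([0.0, T_sh, T_i, T_notch, T])
    if par.breakpoints.shape != expected_bp.shape or not np.allclose(
        par.breakpoints, expected_bp, atol=1e-12
    ):
        raise ValidationError("aortic curve breakpoints do not match the supplied timings")

    f = EJECTION_DRIVING_FRACTION
    scaled1 = tuple(f * c for c in par.coeffs[0])  # [0, T_sh]
    scaled2 = tuple(f * c for c in par.coeffs[1])  # [T_sh, T_i]
    P_notch = float(par.evaluate(T_notch))
    ir = _vertex_parabola(T_notch, P_notch, T_i, f * float(par.evaluate(T_i)))
    mid = par.coeffs[3]  # P_eff = P_ar on [T_notch, T − IVCT]
    t_ic = T - IVCT
    ic = _vertex_parabola(t_ic, float(par.evaluate(t_ic)), T, f * float(par.evaluate(T)))

    return PiecewisePressure(
        breakpoints=np.array([0.0, T_sh, T_i, T_notch, t_ic, T]),
        coeffs=(scaled1, scaled2, ir, mid, ic),
        period=T,
        label="effective",
    )


def find_peak_diastolic_time(curve: PiecewisePressure, timings: WaveformTimings) -> float:
    """Time [s] of the pressure maximum on the diastolic window [T_notch, T].

    Exact: candidates are the window ends, the breakpoints inside it, and
    the interior critical points of each polynomial segment.
    """
    lo, hi = timings.T_notch, timings.T
    candidates = [lo, hi]
    for i, c in enumerate(curve.coeffs):
        a, b = curve.breakpoints[i], curve.breakpoints[i + 1]
        a, b = max(a, lo), min(b, hi)
        if a >= b:
            continue
        candidates.extend([a, b])
        roots = np.roots(np.polyder(np.asarray(c, dtype=float)))
        for r in roots:
            if abs(r.imag) < 1e-12 and a < r.real < b:
                candidates.append(float(r.real))
    vals = [float(curve.evaluate(min(t, hi - 1e-15))) for t in candidates]
    return float(candidates[int(np.argmax(vals))])
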