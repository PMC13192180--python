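"""Standard-curve math for plate assays and the LDH activity formula.

ELISA (e.g. IL-6, seven-point twofold series from 8000 pg/mL) and
Griess nitrite readouts (nine-point twofold series from an 80 µM high
standard) are quantified by fitting a linear or quadratic standard
curve to the OD readings and inverting it inside the calibrated range.
LDH enzymatic activity follows the endpoint formula

    activity = NADH generation (nmol) / (reaction time (min) x volume (mL))

in nmol·min⁻¹·mL⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StandardCurve",
    "LdhInput",
    "dilution_series",
    "fit_standard_curve",
    "invert_curve",
    "ldh_activity",
    "correct_reference",
]


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares standard curve OD = f(concentration).

    ``coefficients`` in descending degree (numpy polynomial order);
    inversion is only defined inside the calibrated ranges.
    """

    concentrations: np.ndarray
    ods: np.ndarray
    fit_kind: str  # linear | quadratic
    coefficients: np.ndarray
    residuals: np.ndarray

    @property
    def conc_range(self) -> tuple[float, float]:
        return float(self.concentrations.min()), float(self.concentrations.max())

    @property
    def od_range(self) -> tuple[float, float]:
        fitted = np.polyval(self.coefficients, self.concentrations)
        return float(fitted.min()), float(fitted.max())


@dataclass(frozen=True)
class LdhInput:
    nadh_nmol: float
    time_min: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.time_min <= 0 or self.volume_ml <= 0:
            raise ValueError("reaction time and volume must be positive")
        if self.nadh_nmol < 0:
            raise ValueError("NADH amount must be non-negative")


def dilution_series(high: float, n_points: int) -> np.ndarray:
    """Twofold dilution series [high, high/2, ..., high/2^(n-1)]."""
    if high <= 0:
        raise ValueError("high standard must be positive")
    if n_points < 1:
        raise ValueError("series needs at least one point")
    return high / (2.0 ** np.arange(n_points))


def correct_reference(od: np.ndarray, od_ref: np.ndarray) -> np.ndarray:
    """Reference-wavelength correction (e.g. 450 nm minus 540 nm)."""
    return np.asarray(od, dtype=float) - np.asarray(od_ref, dtype=float)


def fit_standard_curve(concs, ods, fit_kind: str = "linear") -> StandardCurve:
    """Least-squares linear or quadratic fit of OD against concentration.

    ``fit_kind='auto'`` picks quadratic only when it reduces the
    residual sum of squares by more than 20% relative to the linear fit.
    Background (sole-medium) OD is assumed already subtracted.
    """
    concs = np.asarray(concs, dtype=float)
    ods = np.asarray(ods, dtype=float)
    if concs.shape != ods.shape or concs.ndim != 1:
        raise ValueError("concentrations and ODs must be matching 1-D arrays")

    def _fit(degree: int):
        if concs.size < degree + 1:
            raise ValueError(f"need >= {degree + 1} points for degree-{degree} fit")
        if np.unique(concs).size < degree + 1:
            raise ValueError("rank-deficient design: too few distinct concentrations")
        coeffs = np.polyfit(concs, ods, degree)
        resid = ods - np.polyval(coeffs, concs)
        return coeffs, resid

    if fit_kind == "auto":
        c1, r1 = _fit(1)
        try:
            c2, r2 = _fit(2)
        except ValueError:
            c2, r2 = None, None
        if c2 is not None and np.sum(r2**2) < 0.8 * np.sum(r1**2):
            return StandardCurve(concs, ods, "quadratic", c2, r2)
        return StandardCurve(concs, ods, "linear", c1, r1)
    if fit_kind == "linear":
        coeffs, resid = _fit(1)
    elif fit_kind == "quadratic":
        coeffs, resid = _fit(2)
    else:
        raise ValueError("fit_kind must be 'linear', 'quadratic' or 'auto'")
    return StandardCurve(concs, ods, fit_kind, coeffs, resid)


def invert_curve(curve: StandardCurve, od: float, extrapolate: bool = False) -> float:
    """Concentration whose fitted OD equals ``od``.

    Linear curves invert in closed form; quadratic curves take the real
    root inside the calibrated concentration range and raise when both
    or neither root lies in range.  ODs outside the calibrated OD range
    raise unless ``extrapolate`` is set.
    """
    lo_od, hi_od = curve.od_range
    span = hi_od - lo_od
    if not extrapolate and not (lo_od - 0.05 * span <= od <= hi_od + 0.05 * span):
        raise ValueError(f"OD {od:g} outside calibrated range [{lo_od:g}, {hi_od:g}]")
    lo_c, hi_c = curve.conc_range
    if curve.fit_kind == "linear":
        a1, a0 = curve.coefficients
        if a1 == 0:
            raise ValueError("degenerate flat curve cannot be inverted")
        return (od - a0) / a1
    a2, a1, a0 = curve.coefficients
    roots = np.roots([a2, a1, a0 - od])
    real = roots[np.isclose(roots.imag, 0, atol=1e-9)].real
    tol = 0.05 * (hi_c - lo_c)
    in_range = [r for r in real if (lo_c - tol <= r <= hi_c + tol) or extrapolate]
    if len(in_range) == 0:
        raise ValueError(f"no real root in calibrated range for OD {od:g}")
    if len(np.unique(np.round(in_range, 9))) > 1:
        raise ValueError(f"ambiguous inversion: both roots in range for OD {od:g}")
    return float(in_range[0])


def ldh_activity(x: LdhInput) -> float:
    """LDH activity in nmol·min⁻¹·mL⁻¹ from the endpoint formula."""
    return x.nadh_nmol / (x.time_min * x.volume_ml)
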