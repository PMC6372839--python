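"""Absolute quantitation of extracellular metabolites.

Three routes, matching LC-MS and NMR practice:

1. linear calibration — a least-squares line through >= 2 standards of
   known concentration (typically four points), inverted for unknowns;
2. isotope-ratio internal standard — for analytes with nonlinear signal
   response, a fully 13C-labeled standard of known concentration is
   spiked in and concentration follows from the 12C/13C signal ratio,
   assuming equal instrument response of labeled and unlabeled forms;
3. NMR internal standard — per-proton-normalized integral ratio against
   a reference compound of known concentration.

Dilution factors multiply back to the undiluted concentration (e.g. a
1:100 glucose dilution scales the estimate 100-fold, versus the default
1:10 used for other metabolites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: linear fits with R^2 below this are flagged nonlinear and should use
#: the internal-standard route instead
LINEARITY_THRESHOLD = 0.98


class QuantitationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    analyte: str
    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    mode: str = "linear"

    @property
    def nonlinear(self) -> bool:
        return self.r_squared < LINEARITY_THRESHOLD


def fit_calibration(
    points, analyte: str = ""
) -> CalibrationCurve:
    """Ordinary least-squares line (free intercept) through calibration
    standards; ``points`` is a sequence of (concentration, signal)."""
    pts = [(float(c), float(s)) for c, s in points]
    if len(pts) < 2:
        raise QuantitationError("need at least 2 calibration points")
    conc = np.array([c for c, _ in pts])
    sig = np.array([s for _, s in pts])
    if (sig < 0).any():
        raise QuantitationError("calibration signals must be non-negative")
    if np.unique(conc).size < 2:
        raise QuantitationError("all calibration concentrations identical")
    fit = sps.linregress(conc, sig)
    r2 = float(fit.rvalue**2)
    curve = CalibrationCurve(
        analyte=analyte,
        points=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        conc_range=(float(conc.min()), float(conc.max())),
    )
    if curve.nonlinear:
        logger.warning(
            "calibration for %s is nonlinear (R^2 = %.4f < %.2f); use an "
            "internal-standard mode",
            analyte or "<analyte>",
            r2,
            LINEARITY_THRESHOLD,
        )
    return curve


def quantify_linear(
    signal: float, curve: CalibrationCurve, dilution: float = 1.0
) -> tuple[float, list[str]]:
    """Invert a linear calibration: dilution * (signal - intercept)/slope.

    Returns (concentration, flags); negative estimates are floored at 0
    with ``below_blank``, outside-the-standards results get
    ``extrapolated``.
    """
    if curve.mode != "linear":
        raise QuantitationError("curve is not in linear mode")
    if signal < 0:
        raise QuantitationError("signal must be non-negative")
    if dilution < 1:
        raise QuantitationError("dilution must be >= 1")
    if curve.slope == 0:
        raise QuantitationError("calibration slope is zero")
    flags: list[str] = []
    raw = (signal - curve.intercept) / curve.slope
    if raw < 0:
        flags.append("below_blank")
        raw = 0.0
    if not (curve.conc_range[0] <= raw <= curve.conc_range[1]):
        flags.append("extrapolated")
    return dilution * raw, flags


def quantify_isotope_ratio(
    parent: float,
    labeled_standard: float,
    standard_conc: float,
    dilution: float = 1.0,
) -> float:
    """Concentration from a spiked fully labeled internal standard:
    dilution * standard_conc * parent / labeled_standard. Assumes equal
    instrument response of the 12C and 13C forms. Returns NaN (with a
    warning) when the standard signal is zero."""
    if labeled_standard < 0 or parent < 0:
        raise QuantitationError("signals must be non-negative")
    if labeled_standard == 0:
        logger.warning("labeled standard signal is zero; concentration undefined")
        return float("nan")
    return dilution * standard_conc * parent / labeled_standard


def quantify_internal_standard_nmr(
    analyte_integral: float,
    reference_integral: float,
    reference_conc: float,
    analyte_protons: int,
    reference_protons: int,
) -> float:
    """NMR quantitation against an internal standard of known
    concentration: per-proton integral ratio times the reference
    concentration (mM in -> mM out)."""
    if analyte_protons < 1 or reference_protons < 1:
        raise QuantitationError("proton counts must be >= 1")
    if reference_integral <= 0:
        raise QuantitationError("reference integral must be positive")
    if analyte_integral < 0:
        raise QuantitationError("analyte integral must be non-negative")
    return (
        reference_conc
        * (analyte_integral / analyte_protons)
        / (reference_integral / reference_protons)
    )
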