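"""Ellman (DTNB) accessible-cysteine arithmetic.

DTNB reacts with solvent-accessible thiols to release TNB, whose absorbance
at 412 nm is proportional to thiol concentration. A calibration series of
free L-cysteine gives the slope ``a`` (absorbance per μM thiol); for a
protein sample of concentration ``c`` (μM) with total absorbance ``E``, the
average number of accessible cysteines per protein molecule is

    N_Cys = E / (a * c)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EllmanResult", "fit_dtnb_calibration", "count_accessible_cysteines"]


@dataclass(frozen=True)
class EllmanResult:
    """One accessible-cysteine determination."""

    absorbance: float          # E, at 412 nm
    slope: float               # a, absorbance per μM thiol
    concentration_um: float    # c, protein concentration in μM
    n_cys: float               # E / (a * c)


def fit_dtnb_calibration(
    concentrations_um, absorbances
) -> float:
    """Least-squares slope of absorbance against thiol concentration.

    A free intercept is included in the fit (blank drift is common even
    though Beer–Lambert implies zero intercept); only the slope is returned.
    """
    c = np.asarray(concentrations_um, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size:
        raise ValueError("concentration and absorbance lengths differ")
    if c.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.ptp(c) == 0:
        raise ValueError("degenerate design: all concentrations equal")
    slope, _intercept = np.polyfit(c, a, 1)
    return float(slope)


def count_accessible_cysteines(
    absorbance: float, slope: float, concentration_um: float
) -> EllmanResult:
    """Accessible cysteines per protein molecule, ``N_Cys = E/(a·c)``."""
    if slope <= 0:
        raise ValueError("calibration slope must be > 0")
    if concentration_um <= 0:
        raise ValueError("protein concentration must be > 0")
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    return EllmanResult(
        absorbance=absorbance,
        slope=slope,
        concentration_um=concentration_um,
        n_cys=absorbance / (slope * concentration_um),
    )
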