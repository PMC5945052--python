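"""Percent-steatosis quantification, NASH-CRN grade bins and the grade curve.

Percent macrosteatosis is the summed area of regions classified as macro fat
over the tissue area (background excluded, enclosed lumina included in the
denominator).  The semi-quantitative NASH-CRN steatosis grade bins percent
involvement as 0 (<5%), 1 (5-33%), 2 (33-66%), 3 (>66%); upper bounds close
on the left (33 -> grade 1, 66 -> grade 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue_mask import TissueMask
from .white_regions import WhiteRegion


@dataclass
class QuantResult:
    fat_area_px: int
    tissue_area_px: int

    @property
    def percent_steatosis(self) -> float:
        return 100.0 * self.fat_area_px / self.tissue_area_px


@dataclass
class GradeFit:
    coefficients: tuple[float, ...]  # highest degree first
    r_squared: float


def steatosis_fraction(fat_regions: list[WhiteRegion],
                       tissue: TissueMask) -> QuantResult:
    """Summed classified-fat area over tissue area."""
    denom = tissue.tissue_area_px
    if denom == 0:
        raise ZeroDivisionError(
            "tissue area is zero — check the tissue mask tolerance before "
            "quantifying steatosis")
    fat = sum(r.pixel_count for r in fat_regions)
    return QuantResult(fat_area_px=int(fat), tissue_area_px=denom)


def grade_from_percent(p: float) -> int:
    """NASH-CRN steatosis grade of a percent-involvement value."""
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"percent must lie in [0, 100], got {p}")
    if p < 5.0:
        return 0
    if p <= 33.0:
        return 1
    if p <= 66.0:
        return 2
    return 3


def fit_grade_curve(percents, grades, degree: int = 2,
                    invert: bool = False) -> GradeFit:
    """Least-squares polynomial of percent on grade (or the inverse).

    Default orientation regresses percent as a function of grade; pass
    ``invert=True`` for grade on percent.  R^2 = 1 - SS_res / SS_tot.
    """
    percents = np.asarray(percents, dtype=np.float64)
    grades = np.asarray(grades, dtype=np.float64)
    x, y = (percents, grades) if invert else (grades, percents)
    if x.size < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    if np.ptp(y) == 0:
        raise ValueError("constant response: R^2 is undefined")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return GradeFit(coefficients=tuple(float(c) for c in coeffs),
                    r_squared=1.0 - ss_res / ss_tot)
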