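"""Closed-form wet-lab assay computations.

Three small formulas accompany the experimental follow-up on a predicted
plant: MTT cell viability from plate absorbances, gallic-acid-equivalent
antioxidant capacity (GEAC) from paired IC50s, and IC50 estimation from a
dose–response series by straight-line least squares.  IC50 here is the
concentration at which the fitted line crosses a 50% response; extrapolation
outside the observed concentration range is refused rather than returned.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import InputValidationError, NonEstimableError

RESPONSE_KINDS = ("RSA", "viability")


@dataclass
class DoseResponse:
    """Dose–response series: (concentration in mg/mL, response in percent)."""

    points: list
    response_kind: str = "RSA"

    def __post_init__(self) -> None:
        if self.response_kind not in RESPONSE_KINDS:
            raise InputValidationError(
                f"response_kind must be one of {RESPONSE_KINDS}, got {self.response_kind!r}"
            )
        if len(self.points) < 2:
            raise InputValidationError("need at least 2 dose-response points")
        concs = [c for c, _ in self.points]
        if any(c < 0 for c in concs):
            raise InputValidationError("concentrations must be non-negative")
        if len(set(concs)) != len(concs):
            raise InputValidationError("concentrations must be distinct")


def cell_viability(abs_sample: float, abs_blank: float, abs_control: float) -> float:
    """Percent cell viability from MTT plate absorbances.

    ``100 * (abs_sample - abs_blank) / (abs_control - abs_blank)``.
    """
    denom = abs_control - abs_blank
    if denom == 0:
        raise InputValidationError(
            "abs_control equals abs_blank: viability denominator is zero"
        )
    return (abs_sample - abs_blank) / denom * 100.0


def geac(ic50_reference: float, ic50_sample: float) -> float:
    """Gallic-acid-equivalent antioxidant capacity, mg GA / g dry weight.

    ``IC50(gallic acid) / IC50(sample) * 1000``; scale-invariant in the pair.
    """
    if ic50_reference <= 0 or ic50_sample <= 0:
        raise InputValidationError("IC50 values must be positive")
    return ic50_reference / ic50_sample * 1000.0


def ic50_linear(dr: DoseResponse) -> float:
    """IC50 by ordinary least squares on response vs. concentration.

    Fits ``response = a + b * concentration`` and returns ``(50 - a) / b``,
    provided the crossing lies within the observed concentration range.
    A flat fit or an out-of-range crossing raises :class:`NonEstimableError`.
    """
    concs = [c for c, _ in dr.points]
    resps = [r for _, r in dr.points]
    fit = stats.linregress(concs, resps)
    if fit.slope == 0:
        raise NonEstimableError("dose-response slope is zero; IC50 non-estimable")
    c50 = (50.0 - fit.intercept) / fit.slope
    lo, hi = min(concs), max(concs)
    if not (lo <= c50 <= hi):
        raise NonEstimableError(
            f"fitted line reaches 50% at {c50:.4g} mg/mL, outside the observed "
            f"range [{lo:g}, {hi:g}]; refusing to extrapolate"
        )
    return c50
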