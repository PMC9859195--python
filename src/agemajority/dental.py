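"""Dental maturity indices: the third-molar maturity index and the seven-teeth gate.

The third-molar maturity index (I3M) of a lower third molar with open
root apices is the sum of the distances between the inner sides of the
open apices divided by the tooth length; when the apical ends of the
roots are completely closed, I3M = 0.  As the roots mature the open-apex
gaps shrink, so I3M decreases with age and reaches 0 at apex closure.

The seven left mandibular teeth (FDI 31-37, central incisor through
second molar) act as a binary gate: age-of-majority assessment proceeds
only once all seven roots are completely developed.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, model_validator

from .errors import InvalidMeasurementError

__all__ = [
    "ApexMeasurement",
    "SevenTeethAssessment",
    "MaturityBand",
    "SEVEN_TEETH_FDI",
    "compute_i3m",
    "teeth_complete",
    "i3m_band",
]

#: FDI numbers of the seven left mandibular teeth, central incisor to second molar.
SEVEN_TEETH_FDI: tuple[int, ...] = (31, 32, 33, 34, 35, 36, 37)


class ApexMeasurement(BaseModel, frozen=True):
    """Open-apex gap widths and tooth length for one tooth, in mm.

    ``open_apex_gaps`` lists the distance between the inner sides of
    each open apex; an empty list means all apices are closed.  A gap of
    exactly 0 is treated as closed.  The canonical lower third molar has
    two roots, but any number of gaps is accepted so single- or
    multi-rooted variants are computable (the index is a plain sum).
    """

    open_apex_gaps: tuple[float, ...] = ()
    tooth_length: float

    @model_validator(mode="after")
    def _check(self) -> "ApexMeasurement":
        if self.tooth_length <= 0:
            raise InvalidMeasurementError(
                f"tooth_length must be positive, got {self.tooth_length}"
            )
        for g in self.open_apex_gaps:
            if g < 0:
                raise InvalidMeasurementError(f"negative apex gap {g}")
        return self


class SevenTeethAssessment(BaseModel, frozen=True):
    """Apex-closure flags for the seven left mandibular teeth (FDI 31-37).

    Every flag must be a definite yes/no; a tooth that cannot be
    evaluated is an input error at this layer.
    """

    apices_closed: dict[int, bool]

    @model_validator(mode="after")
    def _check(self) -> "SevenTeethAssessment":
        keys = tuple(sorted(self.apices_closed))
        if keys != SEVEN_TEETH_FDI:
            raise InvalidMeasurementError(
                f"expected closure flags for FDI {SEVEN_TEETH_FDI}, got {keys}"
            )
        return self


class MaturityBand(str, Enum):
    """Third-molar maturity bands used by the decision flow.

    The thresholds 0.08 and 0.15 partition the non-negative axis once:
    values below 0.08 (including 0, closed apices) are the most mature
    band; 0.15 and above the least.  The boundary value 0.08 itself is
    assigned to the middle band — the less-adult reading, consistent
    with resolving doubt in the subject's favour.
    """

    BELOW_008 = "below_0.08"
    MID_008_015 = "0.08_to_0.15"
    AT_LEAST_015 = "at_least_0.15"


def compute_i3m(m: ApexMeasurement, closed_epsilon: float = 0.0) -> float:
    """Third-molar maturity index: sum of open-apex gaps over tooth length.

    Gaps no larger than ``closed_epsilon`` (default 0.0, i.e. exactly
    zero) are treated as closed; handling of digitisation noise beyond
    that is the caller's responsibility.  Returns exactly 0.0 when no
    gap remains open — there is no floating-point leakage from the
    division path.
    """
    open_gaps = [g for g in m.open_apex_gaps if g > closed_epsilon]
    if not open_gaps:
        return 0.0
    return sum(open_gaps) / m.tooth_length


def teeth_complete(t: SevenTeethAssessment) -> bool:
    """True iff the roots of all seven left mandibular teeth are closed."""
    return all(t.apices_closed[fdi] for fdi in SEVEN_TEETH_FDI)


def i3m_band(
    i3m: float, low_threshold: float = 0.08, high_threshold: float = 0.15
) -> MaturityBand:
    """Band a non-negative I3M value by the 0.08 / 0.15 thresholds.

    [0, low) -> BELOW_008; [low, high) -> MID_008_015; [high, inf) ->
    AT_LEAST_015.  The boundary ``low`` falls in the middle band (see
    :class:`MaturityBand`); ``high`` falls in the top band ("equal to or
    more than").
    """
    if i3m < 0:
        raise InvalidMeasurementError(f"I3M cannot be negative, got {i3m}")
    if low_threshold <= 0 or high_threshold <= low_threshold:
        raise InvalidMeasurementError(
            f"need 0 < low < high, got {low_threshold}, {high_threshold}"
        )
    if i3m < low_threshold:
        return MaturityBand.BELOW_008
    if i3m < high_threshold:
        return MaturityBand.MID_008_015
    return MaturityBand.AT_LEAST_015
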