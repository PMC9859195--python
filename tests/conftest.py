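"""Shared builders for assessment objects used across the suite."""

from __future__ import annotations

from typing import Optional

import pytest

from agemajority import (
    ApexMeasurement,
    ClavicleAssessment,
    HandAssessment,
    PhysicalExam,
    SevenTeethAssessment,
    SubjectAssessment,
    SEVEN_TEETH_FDI,
    ThirdMolarAssessment,
)


def make_teeth(closed: bool = True, open_fdi: tuple[int, ...] = ()) -> SevenTeethAssessment:
    return SevenTeethAssessment(
        apices_closed={f: closed and f not in open_fdi for f in SEVEN_TEETH_FDI}
    )


def make_molar(i3m: float, tooth_length: float = 15.0) -> ThirdMolarAssessment:
    """Assessable third molar whose measurement yields exactly ``i3m``."""
    gaps = () if i3m == 0 else (i3m * tooth_length,)
    return ThirdMolarAssessment(
        assessable=True,
        measurement=ApexMeasurement(open_apex_gaps=gaps, tooth_length=tooth_length),
    )


def make_subject(
    i3m: Optional[float] = None,
    clavicle_stage: Optional[int] = None,
    teeth: Optional[bool] = True,
    tanner: tuple[int, int] = (5, 5),
    abnormal: bool = False,
    molar_unassessable: bool = False,
    molar_missing: bool = False,
    hand_complete: Optional[bool] = None,
    sex: str = "m",
    subject_id: str = "s1",
) -> SubjectAssessment:
    if molar_missing:
        molar = None
    elif molar_unassessable:
        molar = ThirdMolarAssessment(assessable=False)
    elif i3m is not None:
        molar = make_molar(i3m)
    else:
        molar = None
    return SubjectAssessment(
        subject_id=subject_id,
        exam=PhysicalExam(
            sex=sex,
            tanner_pubic_hair=tanner[0],
            tanner_second_characteristic=tanner[1],
            abnormal_growth_signs=abnormal,
        ),
        hand=None if hand_complete is None else HandAssessment(complete=hand_complete),
        teeth=None if teeth is None else make_teeth(closed=teeth, open_fdi=() if teeth else (37,)),
        third_molar=molar,
        clavicle=(
            None
            if clavicle_stage is None
            else ClavicleAssessment(schmeling_stage=clavicle_stage)
        ),
    )


@pytest.fixture
def canonical_subjects() -> list[SubjectAssessment]:
    """The four printed-probability branch archetypes, in order."""
    return [
        make_subject(i3m=0.05, clavicle_stage=4, subject_id="clavicle-mature"),
        make_subject(i3m=0.05, clavicle_stage=2, subject_id="clavicle-immature"),
        make_subject(i3m=0.10, subject_id="mid-band"),
        make_subject(i3m=0.20, subject_id="high-band"),
    ]
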