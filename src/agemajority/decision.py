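"""The age-of-majority decision tree.

The flow formalised here decides, from multi-modality maturity
evidence, whether an undocumented young person has reached 18 years:

1. physical examination — visible signs of abnormal growth divert to an
   expert referral (indeterminate, minor age presumed);
2. Tanner gate — unless both recorded secondary sexual characteristics
   are at stage 5 the subject is presumed a minor;
3. seven-teeth gate — an orthopantomograph is required; if any of the
   seven left mandibular roots (FDI 31-37) is not completely developed
   the subject is a minor (empirically such subjects are under 16);
4. third molar — if assessable, its maturity index I3M is banded:
   below 0.08 the clavicle decides (Schmeling stage >= 4: adult with
   probability 99.9%; lower stage or no clavicle film: 96%); between
   0.08 and 0.15 the adult probability is 60%; at or above 0.15 it is
   16% — in both latter cases the subject is presumed a minor;
5. if the third molar is not assessable, the clavicle is studied
   directly (stage >= 4: adult at 99.9%; below stage 4 the clavicle is
   not informative — by default the outcome is indeterminate with the
   minor presumption, an alternative policy applies the 96% figure).

The branch probabilities are carried verbatim as percentages (99.9, 96,
60, 16); they are empirical conditionals, never re-derived.  The legal
principle *in dubio pro reo* shapes every default: doubt resolves in
the subject's favour.

The hand/wrist never enters the traversal: subjects with incomplete
hand/wrist maturity are under 16, so the seven-teeth gate (which such
subjects also fail) makes a wrist film redundant.
"""

from __future__ import annotations

from enum import Enum
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .dental import (
    ApexMeasurement,
    MaturityBand,
    SevenTeethAssessment,
    compute_i3m,
    i3m_band,
    teeth_complete,
)
from .geometry import CarpalRadiograph, compute_bo_ca, hand_complete_from_ratio

__all__ = [
    "Classification",
    "Leaf",
    "PhysicalExam",
    "HandAssessment",
    "ClavicleAssessment",
    "ThirdMolarAssessment",
    "SubjectAssessment",
    "DecisionConfig",
    "DecisionOutcome",
    "DEFAULT_CONFIG",
    "adult_probability_for_branch",
    "classify",
    "explain",
]


class Classification(str, Enum):
    MINOR = "MINOR"
    ADULT = "ADULT"
    PRESUMED_MINOR = "PRESUMED_MINOR"
    INDETERMINATE = "INDETERMINATE"


class Leaf(str, Enum):
    """Terminal nodes of the decision tree."""

    ABNORMAL_GROWTH_REFERRAL = "abnormal_growth_referral"
    TANNER_INCOMPLETE = "tanner_incomplete"
    TEETH_UNAVAILABLE = "teeth_unavailable"
    TEETH_INCOMPLETE = "teeth_incomplete"
    MOLAR_UNAVAILABLE = "molar_unavailable"
    I3M_LOW_CLAVICLE_MATURE = "i3m_low_clavicle_mature"
    I3M_LOW_CLAVICLE_IMMATURE = "i3m_low_clavicle_immature"
    I3M_MID = "i3m_mid"
    I3M_HIGH = "i3m_high"
    UNASSESSABLE_MOLAR_CLAVICLE_MATURE = "unassessable_molar_clavicle_mature"
    UNASSESSABLE_MOLAR_CLAVICLE_IMMATURE = "unassessable_molar_clavicle_immature"
    UNASSESSABLE_MOLAR_CLAVICLE_UNAVAILABLE = "unassessable_molar_clavicle_unavailable"


class PhysicalExam(BaseModel, frozen=True):
    """Tanner staging of two secondary sexual characteristics plus growth signs.

    The second characteristic is genital development in males and breast
    development in females; stage 5 is full sexual maturity.
    """

    sex: Literal["m", "f"]
    tanner_pubic_hair: int = Field(ge=1, le=5)
    tanner_second_characteristic: int = Field(ge=1, le=5)
    abnormal_growth_signs: bool = False


class HandAssessment(BaseModel, frozen=True):
    """Hand/wrist maturity, as a direct flag and/or a digitised radiograph.

    The flow uses the hand only as a complete/incomplete gate.  A
    supplied ``complete`` flag is authoritative; otherwise completeness
    derives from Bo/Ca (``bo_ca`` or computed from ``radiograph``)
    against a cutoff.
    """

    complete: Optional[bool] = None
    bo_ca: Optional[float] = None
    radiograph: Optional[CarpalRadiograph] = None

    def is_complete(self, cutoff: float = 1.0) -> Optional[bool]:
        if self.complete is not None:
            return self.complete
        ratio = self.bo_ca
        if ratio is None and self.radiograph is not None:
            ratio = compute_bo_ca(self.radiograph)
        if ratio is None:
            return None
        return hand_complete_from_ratio(ratio, cutoff)


class ClavicleAssessment(BaseModel, frozen=True):
    """Schmeling stage of medial clavicular epiphyseal ossification (1-5)."""

    schmeling_stage: int = Field(ge=1, le=5)


class ThirdMolarAssessment(BaseModel, frozen=True):
    """Left lower third molar: apex measurement, or the reason there is none.

    ``assessable`` is False when the tooth cannot be evaluated
    radiographically (agenesis, extraction, rotation, or positional
    irregularity); a measurement is present exactly when assessable.
    """

    assessable: bool
    measurement: Optional[ApexMeasurement] = None

    @model_validator(mode="after")
    def _check(self) -> "ThirdMolarAssessment":
        if self.assessable and self.measurement is None:
            raise ValueError("assessable third molar requires a measurement")
        if not self.assessable and self.measurement is not None:
            raise ValueError("unassessable third molar cannot carry a measurement")
        return self


class SubjectAssessment(BaseModel, frozen=True):
    """One person's full multi-modality evidence bundle."""

    subject_id: str
    exam: PhysicalExam
    hand: Optional[HandAssessment] = None
    teeth: Optional[SevenTeethAssessment] = None
    third_molar: Optional[ThirdMolarAssessment] = None
    clavicle: Optional[ClavicleAssessment] = None


class DecisionConfig(BaseModel, frozen=True):
    """Thresholds, branch probabilities, and policy switches.

    The probabilities are the empirical conditionals attached to each
    probability-bearing leaf, in percent, exactly as reported; the
    declaration threshold (default 95%) makes explicit which of them
    justify declaring adulthood (99.9 and 96) and which fall under the
    statutory minor presumption (60 and 16).

    ``unassessable_molar_immature_clavicle_policy`` resolves a genuine
    ambiguity: with no assessable third molar and a clavicle below
    stage 4, the conservative default returns an indeterminate outcome
    with the minor presumption (below stage 4 the clavicle cannot
    separate adults from minors — about 46% of such subjects were
    adults); the ``apply_96`` alternative applies the 96% figure as the
    summary flow suggests.
    """

    i3m_low_threshold: float = 0.08
    i3m_high_threshold: float = 0.15
    prob_clavicle_mature_percent: float = Field(default=99.9, ge=0, le=100)
    prob_clavicle_immature_percent: float = Field(default=96.0, ge=0, le=100)
    prob_mid_band_percent: float = Field(default=60.0, ge=0, le=100)
    prob_high_band_percent: float = Field(default=16.0, ge=0, le=100)
    adult_declaration_threshold_percent: float = Field(default=95.0, ge=0, le=100)
    unassessable_molar_immature_clavicle_policy: Literal[
        "indeterminate", "apply_96"
    ] = "indeterminate"

    @model_validator(mode="after")
    def _check(self) -> "DecisionConfig":
        if not 0 < self.i3m_low_threshold < self.i3m_high_threshold:
            raise ValueError(
                "need 0 < i3m_low_threshold < i3m_high_threshold, got "
                f"{self.i3m_low_threshold}, {self.i3m_high_threshold}"
            )
        return self


DEFAULT_CONFIG = DecisionConfig()

_STATUTE_NOTE = (
    "statutory presumption applied: pending determination of age the "
    "subject is considered a minor (in dubio pro reo)"
)
_STAGE3_NOTE = (
    "Schmeling stage 3 is not an approved estimation stage; treated as "
    "below stage 4 for branching"
)


class DecisionOutcome(BaseModel, frozen=True):
    """Leaf classification, adult probability where one exists, and audit trail.

    ``probability_is_lower_bound`` marks leaves whose reported figure is
    a floor ("more than 99.9%"); the machine value is still the printed
    number.  ``path`` lists every node traversed, ending at the leaf.
    """

    subject_id: str
    classification: Classification
    leaf: Leaf
    adult_probability_percent: Optional[float] = None
    probability_is_lower_bound: bool = False
    path: tuple[str, ...]
    evidence_used: tuple[str, ...]
    notes: str = ""


def adult_probability_for_branch(
    branch: Leaf | str, config: DecisionConfig = DEFAULT_CONFIG
) -> Optional[float]:
    """Adult probability (percent) attached to a leaf, or None for gate leaves.

    Raises ``ValueError`` for an unknown branch identifier.
    """
    leaf = Leaf(branch)
    table: dict[Leaf, Optional[float]] = {
        Leaf.ABNORMAL_GROWTH_REFERRAL: None,
        Leaf.TANNER_INCOMPLETE: None,
        Leaf.TEETH_UNAVAILABLE: None,
        Leaf.TEETH_INCOMPLETE: None,
        Leaf.MOLAR_UNAVAILABLE: None,
        Leaf.I3M_LOW_CLAVICLE_MATURE: config.prob_clavicle_mature_percent,
        Leaf.I3M_LOW_CLAVICLE_IMMATURE: config.prob_clavicle_immature_percent,
        Leaf.I3M_MID: config.prob_mid_band_percent,
        Leaf.I3M_HIGH: config.prob_high_band_percent,
        Leaf.UNASSESSABLE_MOLAR_CLAVICLE_MATURE: config.prob_clavicle_mature_percent,
        Leaf.UNASSESSABLE_MOLAR_CLAVICLE_IMMATURE: (
            config.prob_clavicle_immature_percent
            if config.unassessable_molar_immature_clavicle_policy == "apply_96"
            else None
        ),
        Leaf.UNASSESSABLE_MOLAR_CLAVICLE_UNAVAILABLE: None,
    }
    return table[leaf]


def _probability_outcome(
    s: SubjectAssessment,
    leaf: Leaf,
    prob: float,
    config: DecisionConfig,
    path: list[str],
    evidence: list[str],
    notes: list[str],
    lower_bound: bool = False,
) -> DecisionOutcome:
    """Resolve a probability-bearing leaf against the declaration threshold."""
    if prob >= config.adult_declaration_threshold_percent:
        classification = Classification.ADULT
    else:
        classification = Classification.PRESUMED_MINOR
        notes = notes + [_STATUTE_NOTE]
    return DecisionOutcome(
        subject_id=s.subject_id,
        classification=classification,
        leaf=leaf,
        adult_probability_percent=prob,
        probability_is_lower_bound=lower_bound,
        path=tuple(path + [leaf.value]),
        evidence_used=tuple(evidence),
        notes="; ".join(notes),
    )


def _gate_outcome(
    s: SubjectAssessment,
    leaf: Leaf,
    classification: Classification,
    path: list[str],
    evidence: list[str],
    notes: list[str],
) -> DecisionOutcome:
    return DecisionOutcome(
        subject_id=s.subject_id,
        classification=classification,
        leaf=leaf,
        adult_probability_percent=None,
        path=tuple(path + [leaf.value]),
        evidence_used=tuple(evidence),
        notes="; ".join(notes),
    )


def classify(
    s: SubjectAssessment, config: DecisionConfig = DEFAULT_CONFIG
) -> DecisionOutcome:
    """Traverse the decision tree for one subject.

    The traversal is deterministic and side-effect free; every valid
    assessment reaches exactly one leaf.  Merely-incomplete evidence
    never raises — a node that cannot proceed returns an INDETERMINATE
    outcome with an explanatory note.  The hand modality is never
    consulted (see module docstring).
    """
    path = ["physical_exam"]
    evidence = ["physical_exam"]

    if s.exam.abnormal_growth_signs:
        return _gate_outcome(
            s,
            Leaf.ABNORMAL_GROWTH_REFERRAL,
            Classification.INDETERMINATE,
            path,
            evidence,
            [
                "visible signs of abnormal growth: referral for expert "
                "evaluation; minor age presumed pending assessment"
            ],
        )

    path.append("tanner_gate")
    if min(s.exam.tanner_pubic_hair, s.exam.tanner_second_characteristic) < 5:
        return _gate_outcome(
            s,
            Leaf.TANNER_INCOMPLETE,
            Classification.PRESUMED_MINOR,
            path,
            evidence,
            [
                "secondary sexual characteristics not fully developed",
                _STATUTE_NOTE,
            ],
        )

    path.append("teeth_gate")
    if s.teeth is None:
        return _gate_outcome(
            s,
            Leaf.TEETH_UNAVAILABLE,
            Classification.INDETERMINATE,
            path,
            evidence,
            [
                "orthopantomograph required: the seven left mandibular "
                "teeth were not assessed; minor age presumed pending it"
            ],
        )
    evidence.append("teeth")
    if not teeth_complete(s.teeth):
        return _gate_outcome(
            s,
            Leaf.TEETH_INCOMPLETE,
            Classification.MINOR,
            path,
            evidence,
            ["at least one of the seven left mandibular roots is not closed"],
        )

    path.append("third_molar")
    if s.third_molar is None:
        return _gate_outcome(
            s,
            Leaf.MOLAR_UNAVAILABLE,
            Classification.INDETERMINATE,
            path,
            evidence,
            [
                "third molar not assessed (no measurement and no "
                "unassessability record); minor age presumed pending it"
            ],
        )
    evidence.append("third_molar")

    stage = s.clavicle.schmeling_stage if s.clavicle is not None else None
    stage3_notes = [_STAGE3_NOTE] if stage == 3 else []

    if s.third_molar.assessable:
        i3m = compute_i3m(s.third_molar.measurement)
        band = i3m_band(i3m, config.i3m_low_threshold, config.i3m_high_threshold)
        path.append(f"i3m_band:{band.value}")

        if band is MaturityBand.MID_008_015:
            return _probability_outcome(
                s, Leaf.I3M_MID, config.prob_mid_band_percent,
                config, path, evidence, [],
            )
        if band is MaturityBand.AT_LEAST_015:
            return _probability_outcome(
                s, Leaf.I3M_HIGH, config.prob_high_band_percent,
                config, path, evidence, [],
            )

        path.append("clavicle_gate")
        if stage is not None and stage >= 4:
            evidence.append("clavicle")
            return _probability_outcome(
                s, Leaf.I3M_LOW_CLAVICLE_MATURE,
                config.prob_clavicle_mature_percent,
                config, path, evidence, [], lower_bound=True,
            )
        notes = list(stage3_notes)
        if stage is not None:
            evidence.append("clavicle")
        else:
            notes.append("clavicle not imaged; probability for I3M < "
                         f"{config.i3m_low_threshold} applied without it")
        return _probability_outcome(
            s, Leaf.I3M_LOW_CLAVICLE_IMMATURE,
            config.prob_clavicle_immature_percent,
            config, path, evidence, notes,
        )

    # Third molar not assessable: the clavicle is studied directly.
    path.append("clavicle_gate")
    if stage is None:
        return _gate_outcome(
            s,
            Leaf.UNASSESSABLE_MOLAR_CLAVICLE_UNAVAILABLE,
            Classification.INDETERMINATE,
            path,
            evidence,
            [
                "third molar not assessable and clavicle not imaged; "
                "minor age presumed pending clavicle radiograph"
            ],
        )
    evidence.append("clavicle")
    if stage >= 4:
        return _probability_outcome(
            s, Leaf.UNASSESSABLE_MOLAR_CLAVICLE_MATURE,
            config.prob_clavicle_mature_percent,
            config, path, evidence, [], lower_bound=True,
        )
    if config.unassessable_molar_immature_clavicle_policy == "apply_96":
        return _probability_outcome(
            s, Leaf.UNASSESSABLE_MOLAR_CLAVICLE_IMMATURE,
            config.prob_clavicle_immature_percent,
            config, path, evidence, list(stage3_notes),
        )
    return _gate_outcome(
        s,
        Leaf.UNASSESSABLE_MOLAR_CLAVICLE_IMMATURE,
        Classification.INDETERMINATE,
        path,
        evidence,
        stage3_notes
        + [
            "clavicle below stage 4 cannot establish majority (about 46% "
            "of such subjects are adults)",
            _STATUTE_NOTE,
        ],
    )


def explain(o: DecisionOutcome) -> str:
    """Render an outcome as a human-readable report; round-trips all fields."""
    lines = [
        f"Subject: {o.subject_id}",
        f"Classification: {o.classification.value}",
        f"Leaf: {o.leaf.value}",
    ]
    if o.adult_probability_percent is not None:
        cmp = ">" if o.probability_is_lower_bound else "="
        lines.append(
            f"Probability of having reached 18 years: "
            f"{cmp} {o.adult_probability_percent}%"
        )
    else:
        lines.append("Probability of having reached 18 years: not quantified")
    lines.append("Path: " + " -> ".join(o.path))
    lines.append("Evidence used: " + ", ".join(o.evidence_used))
    if o.notes:
        lines.append("Notes: " + o.notes)
    return "\n".join(lines)
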