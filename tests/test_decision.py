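"""Decision-tree traversal: gates, branch probabilities, audit trail."""

import itertools

import pytest

from agemajority import (
    Classification,
    DecisionConfig,
    Leaf,
    adult_probability_for_branch,
    classify,
    explain,
)
from conftest import make_subject


@pytest.mark.parametrize(
    "kwargs, classification, prob, leaf",
    [
        (dict(i3m=0.05, clavicle_stage=4), Classification.ADULT, 99.9,
         Leaf.I3M_LOW_CLAVICLE_MATURE),
        (dict(i3m=0.05, clavicle_stage=5), Classification.ADULT, 99.9,
         Leaf.I3M_LOW_CLAVICLE_MATURE),
        (dict(i3m=0.05, clavicle_stage=2), Classification.ADULT, 96.0,
         Leaf.I3M_LOW_CLAVICLE_IMMATURE),
        (dict(i3m=0.05), Classification.ADULT, 96.0,
         Leaf.I3M_LOW_CLAVICLE_IMMATURE),  # no clavicle film: 96 still applies
        (dict(i3m=0.10), Classification.PRESUMED_MINOR, 60.0, Leaf.I3M_MID),
        (dict(i3m=0.08), Classification.PRESUMED_MINOR, 60.0, Leaf.I3M_MID),
        (dict(i3m=0.20), Classification.PRESUMED_MINOR, 16.0, Leaf.I3M_HIGH),
        (dict(i3m=0.15), Classification.PRESUMED_MINOR, 16.0, Leaf.I3M_HIGH),
        (dict(molar_unassessable=True, clavicle_stage=4), Classification.ADULT,
         99.9, Leaf.UNASSESSABLE_MOLAR_CLAVICLE_MATURE),
    ],
)
def test_probability_bearing_branches(kwargs, classification, prob, leaf):
    outcome = classify(make_subject(**kwargs))
    assert outcome.classification is classification
    assert outcome.adult_probability_percent == prob
    assert outcome.leaf is leaf
    assert outcome.path[-1] == leaf.value


@pytest.mark.parametrize(
    "kwargs, classification, leaf",
    [
        (dict(abnormal=True, i3m=0.05, clavicle_stage=4),
         Classification.INDETERMINATE, Leaf.ABNORMAL_GROWTH_REFERRAL),
        (dict(tanner=(4, 5), i3m=0.05, clavicle_stage=4),
         Classification.PRESUMED_MINOR, Leaf.TANNER_INCOMPLETE),
        (dict(tanner=(5, 3), i3m=0.05, clavicle_stage=4),
         Classification.PRESUMED_MINOR, Leaf.TANNER_INCOMPLETE),
        (dict(teeth=None, i3m=0.05), Classification.INDETERMINATE,
         Leaf.TEETH_UNAVAILABLE),
        (dict(teeth=False, i3m=0.05, clavicle_stage=5), Classification.MINOR,
         Leaf.TEETH_INCOMPLETE),
        (dict(molar_missing=True), Classification.INDETERMINATE,
         Leaf.MOLAR_UNAVAILABLE),
        (dict(molar_unassessable=True, clavicle_stage=2),
         Classification.INDETERMINATE, Leaf.UNASSESSABLE_MOLAR_CLAVICLE_IMMATURE),
        (dict(molar_unassessable=True), Classification.INDETERMINATE,
         Leaf.UNASSESSABLE_MOLAR_CLAVICLE_UNAVAILABLE),
    ],
)
def test_gate_branches_carry_no_probability(kwargs, classification, leaf):
    outcome = classify(make_subject(**kwargs))
    assert outcome.classification is classification
    assert outcome.adult_probability_percent is None
    assert outcome.leaf is leaf


def test_unassessable_molar_immature_clavicle_alternative_policy():
    config = DecisionConfig(unassessable_molar_immature_clavicle_policy="apply_96")
    outcome = classify(make_subject(molar_unassessable=True, clavicle_stage=2), config)
    assert outcome.classification is Classification.ADULT
    assert outcome.adult_probability_percent == 96.0


def test_schmeling_stage3_branches_low_but_is_flagged():
    outcome = classify(make_subject(i3m=0.05, clavicle_stage=3))
    assert outcome.leaf is Leaf.I3M_LOW_CLAVICLE_IMMATURE
    assert "stage 3" in outcome.notes


def test_declaration_threshold_splits_adult_from_presumption():
    strict = DecisionConfig(adult_declaration_threshold_percent=97.0)
    outcome = classify(make_subject(i3m=0.05, clavicle_stage=2), strict)
    assert outcome.classification is Classification.PRESUMED_MINOR
    assert outcome.adult_probability_percent == 96.0


def test_mature_clavicle_probability_is_lower_bound():
    outcome = classify(make_subject(i3m=0.05, clavicle_stage=4))
    assert outcome.probability_is_lower_bound
    outcome = classify(make_subject(i3m=0.05, clavicle_stage=2))
    assert not outcome.probability_is_lower_bound


def test_adult_probability_for_branch_table():
    assert adult_probability_for_branch(Leaf.I3M_LOW_CLAVICLE_MATURE) == 99.9
    assert adult_probability_for_branch("i3m_mid") == 60.0
    assert adult_probability_for_branch(Leaf.I3M_HIGH) == 16.0
    assert adult_probability_for_branch(Leaf.TEETH_INCOMPLETE) is None
    with pytest.raises(ValueError):
        adult_probability_for_branch("not_a_leaf")


def test_probability_non_increasing_in_i3m():
    probs = [
        classify(make_subject(i3m=v, clavicle_stage=2)).adult_probability_percent
        for v in (0.0, 0.05, 0.10, 0.14, 0.15, 0.50)
    ]
    assert probs == sorted(probs, reverse=True)
    assert probs[0] == 96.0 and probs[-1] == 16.0


_EVIDENCE_GRID = list(
    itertools.product(
        [False, True],  # abnormal
        [(5, 5), (4, 5)],  # tanner
        [True, False, None],  # teeth
        ["value_low", "value_mid", "value_high", "unassessable", None],  # molar
        [None, 1, 2, 3, 4, 5],  # clavicle
        ["indeterminate", "apply_96"],  # policy
    )
)


@pytest.mark.parametrize("hand", [None, True, False])
def test_hand_modality_never_affects_outcome(hand):
    """Exhaustive pairing: the wrist film is redundant at every branch."""
    i3m_by_kind = {"value_low": 0.05, "value_mid": 0.10, "value_high": 0.20}
    for abnormal, tanner, teeth, molar, clav, policy in _EVIDENCE_GRID:
        kwargs = dict(
            abnormal=abnormal,
            tanner=tanner,
            teeth=teeth,
            clavicle_stage=clav,
            molar_unassessable=molar == "unassessable",
            molar_missing=molar is None,
            i3m=i3m_by_kind.get(molar),
        )
        config = DecisionConfig(unassessable_molar_immature_clavicle_policy=policy)
        without = classify(make_subject(**kwargs), config)
        with_hand = classify(make_subject(hand_complete=hand, **kwargs), config)
        assert without == with_hand
        assert "hand" not in with_hand.evidence_used


def test_teeth_gate_dominates_all_other_evidence():
    for i3m, clav in itertools.product([None, 0.0, 0.05, 0.20], [None, 2, 4, 5]):
        kwargs = dict(teeth=False, clavicle_stage=clav)
        if i3m is not None:
            kwargs["i3m"] = i3m
        else:
            kwargs["molar_missing"] = True
        outcome = classify(make_subject(**kwargs))
        assert outcome.classification is Classification.MINOR
        assert outcome.leaf is Leaf.TEETH_INCOMPLETE


def test_traversal_is_deterministic_and_total():
    for abnormal, tanner, teeth, molar, clav, policy in _EVIDENCE_GRID:
        i3m = {"value_low": 0.05, "value_mid": 0.10, "value_high": 0.20}.get(molar)
        s = make_subject(
            abnormal=abnormal, tanner=tanner, teeth=teeth, clavicle_stage=clav,
            molar_unassessable=molar == "unassessable",
            molar_missing=molar is None, i3m=i3m,
        )
        config = DecisionConfig(unassessable_molar_immature_clavicle_policy=policy)
        first, second = classify(s, config), classify(s, config)
        assert first == second
        assert first.path[-1] == first.leaf.value
        if first.classification is Classification.ADULT:
            assert first.adult_probability_percent is not None
            assert (
                first.adult_probability_percent
                >= config.adult_declaration_threshold_percent
            )


def test_config_validation():
    with pytest.raises(ValueError):
        DecisionConfig(i3m_low_threshold=0.2, i3m_high_threshold=0.1)
    with pytest.raises(ValueError):
        DecisionConfig(prob_mid_band_percent=140)


def test_explain_round_trips_fields():
    minor = classify(make_subject(teeth=False, i3m=0.05))
    assert Leaf.TEETH_INCOMPLETE.value in explain(minor)

    adult = classify(make_subject(i3m=0.05, clavicle_stage=4))
    text = explain(adult)
    assert "99.9" in text and "clavicle" in text and "ADULT" in text

    indet = classify(make_subject(teeth=None))
    assert "orthopantomograph" in explain(indet)
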