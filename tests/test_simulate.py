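"""Cohort generator: determinism, hard bounds, latent-age semantics."""

import numpy as np
import pytest
from scipy import stats

from agemajority import (
    CalibrationError,
    SimulatorConfig,
    TruncatedNormal,
    observe,
    simulate_cohort,
)
from agemajority.simulate import (
    _simulate_arrays,
    _branch_masks,
    branch_conditionals,
    calibrate_simulator,
    cohort_rates,
)
from agemajority.decision import classify


def test_empty_cohort():
    assert simulate_cohort(SimulatorConfig(n_subjects=0)) == []


def test_seed_determinism_and_sensitivity():
    cfg = SimulatorConfig(n_subjects=50, seed=123)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    assert [s.model_dump() for s in a] == [s.model_dump() for s in b]
    c = simulate_cohort(cfg.model_copy(update={"seed": 124}))
    assert [s.model_dump() for s in a] != [s.model_dump() for s in c]


def test_enlarging_cohort_preserves_earlier_subjects():
    small = simulate_cohort(SimulatorConfig(n_subjects=40, seed=9))
    large = simulate_cohort(SimulatorConfig(n_subjects=90, seed=9))
    assert [s.model_dump() for s in small] == [s.model_dump() for s in large[:40]]


@pytest.mark.parametrize("seed", [0, 1, 99])
def test_hard_population_bounds(seed):
    """No seed can violate the three population constraints."""
    cohort = simulate_cohort(SimulatorConfig(n_subjects=4000, seed=seed))
    for s in cohort:
        obs = s.observed
        if not obs.hand.complete:
            assert s.true_age < 16.0
        if not all(obs.teeth.apices_closed.values()):
            assert s.true_age < 17.0
        if obs.clavicle.schmeling_stage >= 4:
            assert s.true_age >= 19.0


@pytest.mark.parametrize(
    "update",
    [
        {"hand_completion_age": TruncatedNormal(mean=15, sd=1, lower=13, upper=16.5)},
        {"teeth_completion_age": TruncatedNormal(mean=16, sd=1, lower=14, upper=17.5)},
        {"clavicle_stage4_age": TruncatedNormal(mean=20, sd=1, lower=18.0, upper=26)},
        {"age_range": (24.0, 14.0)},
        {"molar_unassessable_prob": 1.5},
    ],
)
def test_configs_violating_bounds_rejected(update):
    with pytest.raises(ValueError):
        SimulatorConfig(**update)


def test_observe_before_and_after_all_events():
    s = simulate_cohort(SimulatorConfig(n_subjects=1, seed=4))[0]
    young = observe(s, 10.0)
    assert not all(young.teeth.apices_closed.values())
    assert young.clavicle.schmeling_stage < 4
    assert not young.hand.complete

    old = observe(s, 40.0)
    assert all(old.teeth.apices_closed.values())
    assert old.hand.complete
    assert old.clavicle.schmeling_stage == 5
    if s.molar_assessable:
        from agemajority import compute_i3m

        assert compute_i3m(old.third_molar.measurement) == 0.0


def test_i3m_zero_exactly_from_closure_age_on():
    cohort = simulate_cohort(SimulatorConfig(n_subjects=20, seed=11))
    for s in cohort:
        if not s.molar_assessable:
            continue
        at_closure = observe(s, s.i3m_closure_at)
        assert at_closure.third_molar.measurement.open_apex_gaps == ()
        just_before = observe(s, s.i3m_closure_at - 0.05)
        assert sum(just_before.third_molar.measurement.open_apex_gaps) > 0


def test_i3m_trajectory_non_increasing():
    cohort = simulate_cohort(SimulatorConfig(n_subjects=10, seed=2))
    ages = np.linspace(14.0, 24.0, 60)
    from agemajority import compute_i3m

    for s in cohort:
        if not s.molar_assessable:
            continue
        values = [
            compute_i3m(observe(s, float(a)).third_molar.measurement) for a in ages
        ]
        assert all(x >= y - 1e-12 for x, y in zip(values, values[1:]))
        assert values[-1] == 0.0 or s.i3m_closure_at > 24.0


def test_observed_i3m_matches_latent_value():
    from agemajority import compute_i3m

    for s in simulate_cohort(SimulatorConfig(n_subjects=50, seed=3)):
        if s.molar_assessable:
            assert compute_i3m(s.observed.third_molar.measurement) == pytest.approx(
                s.i3m_value, abs=1e-12
            )


def test_unassessable_molar_independent_of_age():
    arr = _simulate_arrays(SimulatorConfig(n_subjects=50_000, seed=17))
    years = np.floor(arr["true_age"]).astype(int)
    table = np.array([
        [(years[arr["unassessable"]] == y).sum() for y in range(14, 24)],
        [(years[~arr["unassessable"]] == y).sum() for y in range(14, 24)],
    ])
    _, p, _, _ = stats.chi2_contingency(table)
    assert p > 0.01


def test_table1_age_mix_weights_years():
    arr = _simulate_arrays(
        SimulatorConfig(n_subjects=40_000, seed=5, age_distribution="table1")
    )
    years = np.floor(arr["true_age"]).astype(int)
    assert years.min() >= 14 and years.max() <= 22
    # year 16 (the heaviest stratum) must outnumber year 21 (the lightest)
    assert (years == 16).sum() > 2 * (years == 21).sum()


def test_branch_masks_agree_with_classifier():
    """The vectorised calibration path must mirror the decision tree exactly."""
    cfg = SimulatorConfig(n_subjects=3000, seed=21)
    cohort = simulate_cohort(cfg)
    masks = _branch_masks(_simulate_arrays(cfg))
    leaves = [classify(s.observed).leaf.value for s in cohort]
    for name, mask in masks.items():
        if name in ("clavicle_below_stage4", "i3m_low"):
            continue
        assert set(np.nonzero(mask)[0]) == {
            i for i, leaf in enumerate(leaves) if leaf == name
        }


def test_calibration_trivial_targets_satisfied_by_bounds():
    """Certainty targets implied by the hard age bounds need no search."""
    arr = _simulate_arrays(SimulatorConfig(n_subjects=20_000, seed=8))
    conds = branch_conditionals(arr)
    # clavicle stage >= 4 implies age >= 19 > 18: always adult
    assert conds["i3m_low_clavicle_mature"] == 100.0
    assert conds["unassessable_molar_clavicle_mature"] == 100.0
    # incomplete teeth imply age < 17 < 18: never adult (teeth gate)
    adult = arr["true_age"] >= 18.0
    incomplete = arr["true_age"] < arr["teeth_at"]
    assert not np.any(adult & incomplete)


def test_calibration_unknown_target_rejected():
    with pytest.raises(ValueError):
        calibrate_simulator(targets={"no_such_branch": 50.0})


def test_calibration_failure_reports_achieved_values():
    # an impossible target: the mature-clavicle branch is pinned at 100
    with pytest.raises(CalibrationError) as excinfo:
        calibrate_simulator(
            targets={"i3m_low_clavicle_mature": 50.0},
            config=SimulatorConfig(seed=2),
            n=2000,
            n_passes=1,
        )
    assert excinfo.value.achieved["i3m_low_clavicle_mature"] == 100.0


def test_cohort_rates_reports_unassessable_share():
    arr = _simulate_arrays(SimulatorConfig(n_subjects=20_000, seed=6))
    rates = cohort_rates(arr)
    assert rates["molar_unassessable_percent"] == pytest.approx(6.0, abs=0.5)
    assert rates["mature_clavicle_high_i3m_percent"] >= 0.0
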