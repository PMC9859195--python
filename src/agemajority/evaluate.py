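"""Branch-probability estimation and cohort summaries.

Given a cohort with known true ages (simulated, or user-supplied), this
module estimates the empirical conditional P(age >= 18 | decision
branch) per leaf with Wilson 95% confidence intervals, accounts for
misclassification in both directions, and produces sample-distribution
summaries (counts per age year x sex x modality).

Wilson score intervals are used rather than Wald because several
branches of interest are small (the rare mature-clavicle/high-I3M joint
event was a single subject in the reference sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel
from statsmodels.stats.proportion import proportion_confint

from .decision import (
    Classification,
    DecisionConfig,
    DecisionOutcome,
    DEFAULT_CONFIG,
    Leaf,
    SubjectAssessment,
    classify,
)
from .errors import UndefinedIntervalError

__all__ = [
    "LabeledCohort",
    "BranchProbabilityRow",
    "MisclassificationReport",
    "CohortSummary",
    "CLAVICLE_MARGINAL_BRANCH",
    "REFERENCE_BRANCH_PERCENTS",
    "wilson_interval",
    "estimate_branch_probabilities",
    "misclassification_report",
    "cohort_summary_table",
]

#: Identifier of the below-stage-4 clavicle marginal (not a tree leaf).
CLAVICLE_MARGINAL_BRANCH = "clavicle_below_stage4"

#: Published reference percentages per branch, for side-by-side display.
REFERENCE_BRANCH_PERCENTS: dict[str, float] = {
    Leaf.I3M_LOW_CLAVICLE_MATURE.value: 99.9,
    Leaf.I3M_LOW_CLAVICLE_IMMATURE.value: 96.0,
    Leaf.I3M_MID.value: 60.0,
    Leaf.I3M_HIGH.value: 16.0,
    Leaf.UNASSESSABLE_MOLAR_CLAVICLE_MATURE.value: 99.9,
    CLAVICLE_MARGINAL_BRANCH: 46.0,
}

#: A cohort with known ages: (assessment, true_age) pairs.
LabeledCohort = Sequence[tuple[SubjectAssessment, float]]

ADULT_AGE = 18.0


def wilson_interval(
    n_success: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Raises :class:`UndefinedIntervalError` when ``n == 0``.
    """
    if n == 0:
        raise UndefinedIntervalError("no trials: interval undefined")
    if not 0 <= n_success <= n:
        raise ValueError(f"need 0 <= n_success <= n, got {n_success}/{n}")
    low, high = proportion_confint(n_success, n, alpha=1 - confidence, method="wilson")
    # guard against 1-ulp fuzz at the boundaries: the interval must
    # contain the point estimate and stay inside [0, 1]
    p_hat = n_success / n
    return max(0.0, min(float(low), p_hat)), min(1.0, max(float(high), p_hat))


class BranchProbabilityRow(BaseModel, frozen=True):
    """One leaf's empirical adult proportion with its Wilson interval."""

    branch: str
    n: int
    n_adult: int
    p_hat: float
    ci_low: float
    ci_high: float
    reference_value_percent: Optional[float] = None


def _classify_cohort(
    cohort: LabeledCohort, config: DecisionConfig
) -> list[tuple[DecisionOutcome, float]]:
    return [(classify(s, config), age) for s, age in cohort]


def estimate_branch_probabilities(
    cohort: LabeledCohort,
    config: DecisionConfig = DEFAULT_CONFIG,
    confidence: float = 0.95,
) -> list[BranchProbabilityRow]:
    """Empirical P(adult | leaf) for every leaf reached by the cohort.

    One row per reached leaf, in tree order, plus the below-stage-4
    clavicle marginal (computed over every subject with a clavicle
    assessment, irrespective of the other gates) appended last.  An
    empty cohort yields an empty table.
    """
    rows: list[BranchProbabilityRow] = []
    outcomes = _classify_cohort(cohort, config)

    by_leaf: dict[str, list[bool]] = {}
    for outcome, age in outcomes:
        by_leaf.setdefault(outcome.leaf.value, []).append(age >= ADULT_AGE)

    for leaf in Leaf:
        flags = by_leaf.get(leaf.value)
        if not flags:
            continue
        n, n_adult = len(flags), int(sum(flags))
        lo, hi = wilson_interval(n_adult, n, confidence)
        rows.append(
            BranchProbabilityRow(
                branch=leaf.value,
                n=n,
                n_adult=n_adult,
                p_hat=n_adult / n,
                ci_low=lo,
                ci_high=hi,
                reference_value_percent=REFERENCE_BRANCH_PERCENTS.get(leaf.value),
            )
        )

    marginal_flags = [
        age >= ADULT_AGE
        for s, age in cohort
        if s.clavicle is not None and s.clavicle.schmeling_stage < 4
    ]
    if marginal_flags:
        n, n_adult = len(marginal_flags), int(sum(marginal_flags))
        lo, hi = wilson_interval(n_adult, n, confidence)
        rows.append(
            BranchProbabilityRow(
                branch=CLAVICLE_MARGINAL_BRANCH,
                n=n,
                n_adult=n_adult,
                p_hat=n_adult / n,
                ci_low=lo,
                ci_high=hi,
                reference_value_percent=REFERENCE_BRANCH_PERCENTS[CLAVICLE_MARGINAL_BRANCH],
            )
        )
    return rows


class MisclassificationReport(BaseModel, frozen=True):
    """Counts and rates of errors in both directions.

    Overestimation of age (a minor declared ADULT) is the error that
    must be avoided; every such case is flagged individually.
    Underestimation (an adult classified MINOR or PRESUMED_MINOR) does
    not disadvantage the subject but is still accounted for.
    """

    n_subjects: int
    n_adults: int
    n_minors: int
    adults_classified_minor: int
    minors_classified_adult: int
    adult_underestimation_rate: float
    minor_overestimation_rate: float
    flagged_overestimated: tuple[str, ...]


def misclassification_report(
    cohort: LabeledCohort, config: DecisionConfig = DEFAULT_CONFIG
) -> MisclassificationReport:
    """Compare classifications with true ages; flag every overestimated minor."""
    outcomes = _classify_cohort(cohort, config)
    n_adults = sum(1 for _, age in outcomes if age >= ADULT_AGE)
    n_minors = len(outcomes) - n_adults

    under = sum(
        1
        for o, age in outcomes
        if age >= ADULT_AGE
        and o.classification in (Classification.MINOR, Classification.PRESUMED_MINOR)
    )
    flagged = tuple(
        o.subject_id
        for o, age in outcomes
        if age < ADULT_AGE and o.classification is Classification.ADULT
    )
    return MisclassificationReport(
        n_subjects=len(outcomes),
        n_adults=n_adults,
        n_minors=n_minors,
        adults_classified_minor=under,
        minors_classified_adult=len(flagged),
        adult_underestimation_rate=under / n_adults if n_adults else 0.0,
        minor_overestimation_rate=len(flagged) / n_minors if n_minors else 0.0,
        flagged_overestimated=flagged,
    )


MODALITIES = ("hand", "teeth", "third_molar", "clavicle")


@dataclass
class CohortSummary:
    """Counts per (age year, sex, modality) in a sample-distribution table.

    ``frame`` has one row per age year and a two-level column index
    (modality, sex); ``totals`` is the column-sum row.
    """

    frame: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.frame.sum(axis=0)

    def total_for(self, modality: str) -> int:
        return int(self.totals[modality].sum())

    def cell(self, age_year: int, modality: str, sex: str) -> int:
        return int(self.frame.loc[age_year, (modality, sex)])

    def to_text(self) -> str:
        """Sample-distribution table as fixed-width text, with a Total row."""
        out = self.frame.copy()
        out.loc["Total"] = self.totals
        out.index.name = "Years"
        return out.to_string()

    @classmethod
    def from_counts(cls, counts: dict[int, dict[tuple[str, str], int]]) -> "CohortSummary":
        years = sorted(counts)
        cols = pd.MultiIndex.from_product([MODALITIES, ("m", "f")])
        frame = pd.DataFrame(0, index=years, columns=cols, dtype=int)
        for year, cells in counts.items():
            for key, v in cells.items():
                frame.loc[year, key] = v
        return cls(frame)


def _as_pairs(cohort) -> list[tuple[SubjectAssessment, float]]:
    pairs = []
    for item in cohort:
        if isinstance(item, tuple):
            pairs.append(item)
        else:  # SimulatedSubject-like
            pairs.append((item.observed, item.true_age))
    return pairs


def cohort_summary_table(cohort) -> CohortSummary:
    """Count modality availability per (age year, sex).

    Accepts (assessment, true_age) pairs or simulated subjects.  A
    modality counts as available when it is present in the assessment
    (for the third molar: present and radiographically assessable).
    An empty cohort yields an all-zero, row-less table.
    """
    pairs = _as_pairs(cohort)
    counts: dict[int, dict[tuple[str, str], int]] = {}
    for s, age in pairs:
        year = int(np.floor(age))
        cells = counts.setdefault(year, {})
        sex = s.exam.sex
        avail = {
            "hand": s.hand is not None,
            "teeth": s.teeth is not None,
            "third_molar": s.third_molar is not None and s.third_molar.assessable,
            "clavicle": s.clavicle is not None,
        }
        for modality, present in avail.items():
            if present:
                key = (modality, sex)
                cells[key] = cells.get(key, 0) + 1
    return CohortSummary.from_counts(counts)
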