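"""Readers and writers for subject records, cohorts, configs, and the packaged
sample-distribution fixture.

Subject exchange format (flat CSV, one row per subject):

``schema_version, subject_id, sex, tanner_pubic_hair, tanner_second,
abnormal_growth, hand_complete, bo_ca, teeth_31..teeth_37,
molar_assessable, molar_gaps, molar_tooth_length_mm, clavicle_stage,
true_age``

UTF-8, comma-separated, mandatory header, "." decimal separator; list
cells (the open-apex gaps) are semicolon-joined.  An empty cell means
the modality is absent; an explicit "NA" is rejected to avoid silent
coercion.  Unknown columns are rejected by name.  ``true_age`` is
optional and used only for evaluation.  The JSON dialect nests the full
assessment structure (including carpal polygons, as
``{"vertices": [[x, y], ...]}`` in mm) and shares the schema version.
"""

from __future__ import annotations

import csv
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .decision import (
    ClavicleAssessment,
    DecisionConfig,
    DecisionOutcome,
    HandAssessment,
    PhysicalExam,
    SubjectAssessment,
    ThirdMolarAssessment,
)
from .dental import SEVEN_TEETH_FDI, ApexMeasurement, SevenTeethAssessment
from .errors import FixtureIntegrityError, SchemaError
from .evaluate import CohortSummary, MODALITIES
from .simulate import SimulatedSubject, SimulatorConfig, observe

__all__ = [
    "SCHEMA_VERSION",
    "SUBJECT_COLUMNS",
    "read_subjects",
    "read_labeled_subjects",
    "write_subjects",
    "write_cohort",
    "read_cohort",
    "outcomes_to_frame",
    "write_outcomes",
    "load_decision_config",
    "save_decision_config",
    "load_simulator_config",
    "save_simulator_config",
    "load_table1_fixture",
]

SCHEMA_VERSION = "1.0"

_TEETH_COLUMNS = [f"teeth_{fdi}" for fdi in SEVEN_TEETH_FDI]

SUBJECT_COLUMNS: tuple[str, ...] = tuple(
    [
        "schema_version",
        "subject_id",
        "sex",
        "tanner_pubic_hair",
        "tanner_second",
        "abnormal_growth",
        "hand_complete",
        "bo_ca",
        *_TEETH_COLUMNS,
        "molar_assessable",
        "molar_gaps",
        "molar_tooth_length_mm",
        "clavicle_stage",
        "true_age",
    ]
)

_MANDATORY_COLUMNS = frozenset(
    ["schema_version", "subject_id", "sex", "tanner_pubic_hair", "tanner_second",
     "abnormal_growth"]
)

TABLE1_SHA256 = "49a1cb995db88959a8d2c678389c2444428fc93308f09efb7b16a47be0a85b00"


def _check_schema_version(version: str, row: Optional[int] = None) -> None:
    try:
        major = int(str(version).split(".")[0])
    except ValueError:
        raise SchemaError(f"unparseable schema_version {version!r}", row)
    if major > int(SCHEMA_VERSION.split(".")[0]):
        raise SchemaError(
            f"schema_version {version} is newer than supported {SCHEMA_VERSION}", row
        )


def _parse_bool(cell: str, column: str, row: int) -> bool:
    v = cell.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise SchemaError(f"column {column}: cannot parse boolean from {cell!r}", row)


def _cell(row_dict: dict, column: str, row: int) -> str:
    cell = (row_dict.get(column) or "").strip()
    if cell.upper() == "NA":
        raise SchemaError(
            f"column {column}: explicit 'NA' is rejected; leave the cell empty", row
        )
    return cell


def _subject_from_row(
    row_dict: dict, row: int
) -> tuple[SubjectAssessment, Optional[float]]:
    _check_schema_version(_cell(row_dict, "schema_version", row), row)
    subject_id = _cell(row_dict, "subject_id", row)
    if not subject_id:
        raise SchemaError("missing subject_id", row)

    sex = _cell(row_dict, "sex", row)
    if sex not in ("m", "f"):
        raise SchemaError(f"sex must be 'm' or 'f', got {sex!r}", row)

    def _stage(column: str) -> int:
        cell = _cell(row_dict, column, row)
        try:
            stage = int(cell)
        except ValueError:
            raise SchemaError(f"column {column}: not an integer: {cell!r}", row)
        if not 1 <= stage <= 5:
            raise SchemaError(f"column {column}: stage {stage} outside 1..5", row)
        return stage

    exam = PhysicalExam(
        sex=sex,
        tanner_pubic_hair=_stage("tanner_pubic_hair"),
        tanner_second_characteristic=_stage("tanner_second"),
        abnormal_growth_signs=_parse_bool(
            _cell(row_dict, "abnormal_growth", row), "abnormal_growth", row
        ),
    )

    hand = None
    hand_cell = _cell(row_dict, "hand_complete", row)
    bo_ca_cell = _cell(row_dict, "bo_ca", row)
    if hand_cell or bo_ca_cell:
        bo_ca = None
        if bo_ca_cell:
            bo_ca = float(bo_ca_cell)
            if bo_ca < 0:
                raise SchemaError(f"negative bo_ca {bo_ca}", row)
        hand = HandAssessment(
            complete=_parse_bool(hand_cell, "hand_complete", row) if hand_cell else None,
            bo_ca=bo_ca,
        )

    teeth_cells = [_cell(row_dict, c, row) for c in _TEETH_COLUMNS]
    teeth = None
    if any(teeth_cells):
        if not all(teeth_cells):
            raise SchemaError(
                "seven-teeth flags must be all present or all absent", row
            )
        teeth = SevenTeethAssessment(
            apices_closed={
                fdi: _parse_bool(cell, col, row)
                for fdi, col, cell in zip(SEVEN_TEETH_FDI, _TEETH_COLUMNS, teeth_cells)
            }
        )

    molar = None
    molar_cell = _cell(row_dict, "molar_assessable", row)
    if molar_cell:
        if _parse_bool(molar_cell, "molar_assessable", row):
            length_cell = _cell(row_dict, "molar_tooth_length_mm", row)
            if not length_cell:
                raise SchemaError(
                    "assessable third molar requires molar_tooth_length_mm", row
                )
            gaps_cell = _cell(row_dict, "molar_gaps", row)
            gaps = tuple(float(g) for g in gaps_cell.split(";") if g.strip() != "")
            if any(g < 0 for g in gaps):
                raise SchemaError(f"negative apex gap in {gaps_cell!r}", row)
            molar = ThirdMolarAssessment(
                assessable=True,
                measurement=ApexMeasurement(
                    open_apex_gaps=gaps, tooth_length=float(length_cell)
                ),
            )
        else:
            molar = ThirdMolarAssessment(assessable=False)

    clavicle = None
    clav_cell = _cell(row_dict, "clavicle_stage", row)
    if clav_cell:
        try:
            stage = int(clav_cell)
        except ValueError:
            raise SchemaError(f"clavicle_stage not an integer: {clav_cell!r}", row)
        if not 1 <= stage <= 5:
            raise SchemaError(f"clavicle_stage {stage} outside 1..5", row)
        clavicle = ClavicleAssessment(schmeling_stage=stage)

    age_cell = _cell(row_dict, "true_age", row)
    true_age = float(age_cell) if age_cell else None

    return (
        SubjectAssessment(
            subject_id=subject_id,
            exam=exam,
            hand=hand,
            teeth=teeth,
            third_molar=molar,
            clavicle=clavicle,
        ),
        true_age,
    )


def _read_rows(path: Union[str, Path], fmt: str):
    path = Path(path)
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            unknown = [c for c in header if c not in SUBJECT_COLUMNS]
            if unknown:
                raise SchemaError(f"unknown columns: {unknown}")
            missing = _MANDATORY_COLUMNS - set(header)
            if missing:
                raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
            yield from enumerate(reader, start=2)  # header is line 1
    elif fmt == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        _check_schema_version(doc.get("schema_version", ""))
        for i, entry in enumerate(doc.get("subjects", []), start=1):
            yield i, entry
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_subjects(
    path: Union[str, Path], format: str = "csv", strict: bool = True
):
    """Read subject assessments; order-preserving.

    With ``strict=True`` (default) the first malformed row raises a
    :class:`SchemaError` naming the row.  With ``strict=False`` returns
    ``(subjects, errors)`` where ``errors`` collects one
    :class:`SchemaError` per malformed row.
    """
    subjects: list[SubjectAssessment] = []
    errors: list[SchemaError] = []
    for row_no, entry in _read_rows(Path(path), format):
        try:
            if format == "csv":
                subject, _ = _subject_from_row(entry, row_no)
            else:
                subject = SubjectAssessment.model_validate(
                    {k: v for k, v in entry.items() if k != "true_age"}
                )
        except SchemaError as exc:
            if strict:
                raise
            errors.append(exc)
            continue
        except (ValueError, TypeError) as exc:
            wrapped = SchemaError(str(exc), row_no)
            if strict:
                raise wrapped from exc
            errors.append(wrapped)
            continue
        subjects.append(subject)
    if strict:
        return subjects
    return subjects, errors


def read_labeled_subjects(
    path: Union[str, Path], format: str = "csv"
) -> list[tuple[SubjectAssessment, float]]:
    """Read (assessment, true_age) pairs; every row must carry true_age."""
    pairs: list[tuple[SubjectAssessment, float]] = []
    for row_no, entry in _read_rows(Path(path), format):
        if format == "csv":
            subject, age = _subject_from_row(entry, row_no)
        else:
            subject = SubjectAssessment.model_validate(
                {k: v for k, v in entry.items() if k != "true_age"}
            )
            age = entry.get("true_age")
        if age is None:
            raise SchemaError("true_age required for a labeled cohort", row_no)
        pairs.append((subject, float(age)))
    return pairs


def _row_from_subject(
    s: SubjectAssessment, true_age: Optional[float] = None
) -> dict[str, str]:
    def b(v: Optional[bool]) -> str:
        return "" if v is None else ("true" if v else "false")

    row = {c: "" for c in SUBJECT_COLUMNS}
    row["schema_version"] = SCHEMA_VERSION
    row["subject_id"] = s.subject_id
    row["sex"] = s.exam.sex
    row["tanner_pubic_hair"] = str(s.exam.tanner_pubic_hair)
    row["tanner_second"] = str(s.exam.tanner_second_characteristic)
    row["abnormal_growth"] = b(s.exam.abnormal_growth_signs)
    if s.hand is not None:
        row["hand_complete"] = b(s.hand.complete)
        row["bo_ca"] = "" if s.hand.bo_ca is None else repr(s.hand.bo_ca)
    if s.teeth is not None:
        for fdi, col in zip(SEVEN_TEETH_FDI, _TEETH_COLUMNS):
            row[col] = b(s.teeth.apices_closed[fdi])
    if s.third_molar is not None:
        row["molar_assessable"] = b(s.third_molar.assessable)
        if s.third_molar.assessable:
            m = s.third_molar.measurement
            row["molar_gaps"] = ";".join(repr(g) for g in m.open_apex_gaps)
            row["molar_tooth_length_mm"] = repr(m.tooth_length)
    if s.clavicle is not None:
        row["clavicle_stage"] = str(s.clavicle.schmeling_stage)
    if true_age is not None:
        row["true_age"] = repr(true_age)
    return row


def write_subjects(
    items: Iterable[Union[SubjectAssessment, tuple[SubjectAssessment, float]]],
    path: Union[str, Path],
    format: str = "csv",
) -> None:
    """Write subjects (optionally with true ages) in a reader-accepted form."""
    pairs = [
        item if isinstance(item, tuple) else (item, None) for item in items
    ]
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=SUBJECT_COLUMNS)
            writer.writeheader()
            for s, age in pairs:
                writer.writerow(_row_from_subject(s, age))
    elif format == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "subjects": [
                {
                    **s.model_dump(mode="json"),
                    **({"true_age": age} if age is not None else {}),
                }
                for s, age in pairs
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Simulated cohorts
# ---------------------------------------------------------------------------

_LATENT_COLUMNS = (
    "subject_id", "true_age", "sex", "abnormal_growth", "tanner5_at",
    "hand_complete_at", "teeth_complete_at", "i3m_initial", "i3m_decay_rate",
    "i3m_closure_at", "clavicle_stage2_at", "clavicle_stage3_at",
    "clavicle_stage4_at", "clavicle_stage5_at", "molar_assessable",
    "tooth_length_mm", "i3m_value",
)


def cohort_to_frame(cohort: list[SimulatedSubject]) -> pd.DataFrame:
    """Flat one-row-per-subject frame: latent ages plus observed headline values."""
    records = []
    for s in cohort:
        rec = {c: getattr(s, c) for c in _LATENT_COLUMNS}
        o = s.observed
        rec.update(
            obs_tanner_stage=o.exam.tanner_pubic_hair,
            obs_hand_complete=o.hand.complete,
            obs_teeth_complete=all(o.teeth.apices_closed.values()),
            obs_clavicle_stage=o.clavicle.schmeling_stage,
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_cohort(
    cohort: list[SimulatedSubject], path: Union[str, Path], format: str = "csv"
) -> None:
    path = Path(path)
    if format == "csv":
        cohort_to_frame(cohort).to_csv(path, index=False)
    elif format == "json":
        doc = [s.model_dump(mode="json") for s in cohort]
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cohort(path: Union[str, Path], format: str = "csv") -> list[SimulatedSubject]:
    """Rebuild a simulated cohort from disk.

    The CSV carries the latent ages; observations are reconstructed
    through :func:`agemajority.simulate.observe`, which is a pure
    function of the latents, so the round trip is lossless.
    """
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        return [SimulatedSubject.model_validate(entry) for entry in doc]
    frame = pd.read_csv(path, float_precision="round_trip")
    cohort = []
    for rec in frame.to_dict("records"):
        partial = SimulatedSubject.model_construct(
            **{c: rec[c] for c in _LATENT_COLUMNS}, observed=None
        )
        observed = observe(partial, float(rec["true_age"]))
        cohort.append(
            SimulatedSubject(
                **{c: rec[c] for c in _LATENT_COLUMNS}, observed=observed
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def outcomes_to_frame(outcomes: Iterable[DecisionOutcome]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "subject_id": o.subject_id,
                "classification": o.classification.value,
                "leaf": o.leaf.value,
                "adult_probability_percent": o.adult_probability_percent,
                "probability_is_lower_bound": o.probability_is_lower_bound,
                "path": "|".join(o.path),
                "evidence_used": "|".join(o.evidence_used),
                "notes": o.notes,
            }
            for o in outcomes
        ]
    )


def write_outcomes(
    outcomes: list[DecisionOutcome], path: Union[str, Path], format: str = "csv"
) -> None:
    path = Path(path)
    if format == "csv":
        outcomes_to_frame(outcomes).to_csv(path, index=False)
    elif format == "json":
        doc = [o.model_dump(mode="json") for o in outcomes]
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

def load_decision_config(path: Union[str, Path]) -> DecisionConfig:
    return DecisionConfig.model_validate_json(Path(path).read_text(encoding="utf-8"))


def save_decision_config(config: DecisionConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(config.model_dump_json(indent=2) + "\n", encoding="utf-8")


def load_simulator_config(path: Union[str, Path]) -> SimulatorConfig:
    return SimulatorConfig.model_validate_json(Path(path).read_text(encoding="utf-8"))


def save_simulator_config(config: SimulatorConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(config.model_dump_json(indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Packaged sample-distribution fixture
# ---------------------------------------------------------------------------

def load_table1_fixture() -> CohortSummary:
    """The packaged reference sample-distribution table.

    Counts of radiographs per age year (14-22), sex, and anatomical
    region (hand/wrist, seven teeth, third molar, clavicle) in the
    reference sample.  The resource is checksum-verified and its stored
    Total row is cross-checked against the column sums.
    """
    resource = resources.files("agemajority").joinpath("data/table1.csv")
    raw = resource.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureIntegrityError(
            f"table1.csv checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    frame = pd.read_csv(resource.open("r"), index_col=0)
    totals = frame.loc["Total"]
    body = frame.drop(index="Total")
    body.index = body.index.astype(int)
    body.columns = pd.MultiIndex.from_tuples(
        [tuple(c.rsplit("_", 1)) for c in body.columns]
    )
    assert list(body.columns.get_level_values(0).unique()) == list(MODALITIES)
    summary = CohortSummary(body.astype(int))
    if not (summary.totals.values == totals.values.astype(int)).all():
        raise FixtureIntegrityError("table1.csv Total row does not match column sums")
    return summary
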