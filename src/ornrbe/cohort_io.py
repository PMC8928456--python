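"""On-disk cohort format: cohort table + per-patient voxel sample files.

Layout under a cohort directory::

    cohort.csv          one patient per row, booleans as 0/1
    manifest.csv        patient_id -> sample file
    samples/<id>.csv    columns volume_cc, dose_gy_rbe, let_kev_um

Floats are written with ``repr`` so a round trip is bit-exact.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import numpy as np

from .cohort import DoseLETSampleSet, PatientRecord

__all__ = ["write_cohort", "read_cohort", "CohortFormatError"]

_BOOL_FIELDS = (
    "chemo",
    "hypertension",
    "diabetes",
    "dental_extraction",
    "smoking_history",
    "current_smoker",
    "oropharynx_or_oral_cavity",
    "orn",
)

_COHORT_COLUMNS = (
    "patient_id",
    "modality",
    "age",
    "gender",
    "stage",
    "prescription_dose",
    *_BOOL_FIELDS,
    "orn_grade",
)

_SAMPLE_COLUMNS = ("volume_cc", "dose_gy_rbe", "let_kev_um")


class CohortFormatError(ValueError):
    """Malformed cohort file; message names file, line and column."""


def _fmt(x: float) -> str:
    return repr(float(x))


def write_cohort(
    records: list[PatientRecord], samples: list[DoseLETSampleSet], directory
) -> Path:
    """Write a cohort to ``directory``; returns the manifest path."""
    directory = Path(directory)
    sample_dir = directory / "samples"
    sample_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.patient_id: s for s in samples}
    missing = [r.patient_id for r in records if r.patient_id not in by_id]
    if missing:
        raise CohortFormatError(f"no sample set for patient(s): {missing[:5]}")

    with open(directory / "cohort.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COHORT_COLUMNS)
        for r in records:
            row = [
                r.patient_id,
                r.modality,
                _fmt(r.age),
                r.gender,
                r.stage,
                _fmt(r.prescription_dose),
            ]
            row += [str(int(getattr(r, f))) for f in _BOOL_FIELDS]
            row.append("" if r.orn_grade is None else str(r.orn_grade))
            w.writerow(row)

    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "sample_file"])
        for r in records:
            s = by_id[r.patient_id]
            rel = f"samples/{r.patient_id}.csv"
            with open(directory / rel, "w", newline="") as sfh:
                sw = csv.writer(sfh)
                sw.writerow(_SAMPLE_COLUMNS)
                for v, d, l in zip(s.volumes, s.doses, s.lets):
                    sw.writerow([_fmt(v), _fmt(d), _fmt(l)])
            w.writerow([r.patient_id, rel])
    return manifest


def _parse_float(value: str, path, line_no: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise CohortFormatError(
            f"{path}: line {line_no}, column {column!r}: not a number: {value!r}"
        ) from None


def _parse_bool(value: str, path, line_no: int, column: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise CohortFormatError(
        f"{path}: line {line_no}, column {column!r}: expected 0/1, got {value!r}"
    )


def _read_sample_file(path, patient_id: str) -> DoseLETSampleSet:
    vols, doses, lets = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != _SAMPLE_COLUMNS:
            raise CohortFormatError(
                f"{path}: line 1: expected header {list(_SAMPLE_COLUMNS)}, got {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise CohortFormatError(
                    f"{path}: line {line_no}: expected 3 columns, got {len(row)}"
                )
            v = _parse_float(row[0], path, line_no, "volume_cc")
            d = _parse_float(row[1], path, line_no, "dose_gy_rbe")
            l = _parse_float(row[2], path, line_no, "let_kev_um")
            if v <= 0:
                raise CohortFormatError(
                    f"{path}: line {line_no}, column 'volume_cc': "
                    f"voxel volume must be > 0, got {v}"
                )
            if d < 0 or l < 0:
                raise CohortFormatError(
                    f"{path}: line {line_no}: negative dose or LET"
                )
            vols.append(v)
            doses.append(d)
            lets.append(l)
    if not vols:
        raise CohortFormatError(f"{path}: no voxel rows")
    return DoseLETSampleSet(
        patient_id=patient_id,
        volumes=np.array(vols),
        doses=np.array(doses),
        lets=np.array(lets),
    )


def read_cohort(directory) -> tuple[list[PatientRecord], list[DoseLETSampleSet]]:
    """Read a cohort directory written by :func:`write_cohort`.

    Validates referential integrity (every patient has a sample file) and
    per-file invariants; raises :class:`CohortFormatError` naming the file,
    line and column of the first problem.
    """
    directory = Path(directory)
    cohort_path = directory / "cohort.csv"
    records: list[PatientRecord] = []
    with open(cohort_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != _COHORT_COLUMNS:
            raise CohortFormatError(
                f"{cohort_path}: line 1: expected header {list(_COHORT_COLUMNS)}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_COHORT_COLUMNS):
                raise CohortFormatError(
                    f"{cohort_path}: line {line_no}: expected "
                    f"{len(_COHORT_COLUMNS)} columns, got {len(row)}"
                )
            rec = dict(zip(_COHORT_COLUMNS, row))
            grade_raw = rec["orn_grade"]
            try:
                records.append(
                    PatientRecord(
                        patient_id=rec["patient_id"],
                        modality=rec["modality"],
                        age=_parse_float(rec["age"], cohort_path, line_no, "age"),
                        gender=rec["gender"],
                        stage=rec["stage"],
                        prescription_dose=_parse_float(
                            rec["prescription_dose"], cohort_path, line_no, "prescription_dose"
                        ),
                        **{
                            f: _parse_bool(rec[f], cohort_path, line_no, f)
                            for f in _BOOL_FIELDS
                        },
                        orn_grade=None if grade_raw == "" else int(grade_raw),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, CohortFormatError):
                    raise
                raise CohortFormatError(
                    f"{cohort_path}: line {line_no}: {exc}"
                ) from None

    manifest_path = directory / "manifest.csv"
    file_by_id: dict[str, str] = {}
    with open(manifest_path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader, None)
        for row in reader:
            if row:
                file_by_id[row[0]] = row[1]

    samples: list[DoseLETSampleSet] = []
    for r in records:
        rel = file_by_id.get(r.patient_id)
        if rel is None or not os.path.exists(directory / rel):
            raise CohortFormatError(
                f"{manifest_path}: no sample file for patient {r.patient_id!r}"
            )
        samples.append(_read_sample_file(directory / rel, r.patient_id))
    return records, samples
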