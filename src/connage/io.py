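"""File interfaces: delimited time courses, phenotype tables, connectivity arrays.

Formats (all UTF-8):

* time courses: one CSV per subject, frames x components, header row of
  component ids; TR and subject id live in the file name sidecar
  (``<subject_id>.csv`` + per-directory ``timecourses.json`` manifest);
* phenotypes: ``phenotypes.csv`` with subject_id, age, sex, site, diagnosis
  and the cognitive scores;
* static FNC: delimited square matrix CSV;
* dynamic FNC: ``.npy`` array container with a JSON sidecar recording the
  subject id and window specification.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import DynamicFNC, StaticFNC, WindowSpec
from .errors import InvalidInputError
from .synthetic import SyntheticCohort
from .timecourse import TimecourseMatrix

PHENOTYPE_COLUMNS = ("subject_id", "age", "sex", "site", "diagnosis")


# -- time courses -----------------------------------------------------------


def write_timecourse(ts: TimecourseMatrix, path) -> None:
    pd.DataFrame(ts.data, columns=list(ts.component_ids)).to_csv(path, index=False)


def read_timecourse(path, tr_seconds: float, subject_id: str | None = None
                    ) -> TimecourseMatrix:
    path = Path(path)
    frame = pd.read_csv(path)
    return TimecourseMatrix(
        data=frame.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id or path.stem,
        component_ids=tuple(frame.columns),
    )


def write_timecourse_dir(timecourses: list, out_dir) -> None:
    """One CSV per scan plus a manifest with TRs and subject order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ts in timecourses:
        write_timecourse(ts, out_dir / f"{ts.subject_id}.csv")
        manifest.append({"subject_id": ts.subject_id, "tr_seconds": ts.tr_seconds,
                         "n_frames": ts.frame_count})
    (out_dir / "timecourses.json").write_text(json.dumps(manifest, indent=1))


def read_timecourse_dir(in_dir) -> list:
    in_dir = Path(in_dir)
    manifest_path = in_dir / "timecourses.json"
    if not manifest_path.exists():
        raise InvalidInputError(f"no timecourses.json manifest in {in_dir}")
    manifest = json.loads(manifest_path.read_text())
    return [
        read_timecourse(in_dir / f"{e['subject_id']}.csv", e["tr_seconds"],
                        e["subject_id"])
        for e in manifest
    ]


# -- phenotypes -------------------------------------------------------------


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"phenotype table missing columns: {missing}")
    bad_age = table.loc[table["age"].isna(), "subject_id"].tolist()
    if bad_age:
        raise InvalidInputError(f"NaN ages for subjects: {bad_age}")
    return table


# -- connectivity -----------------------------------------------------------


def write_static_fnc(fnc: StaticFNC, path) -> None:
    np.savetxt(path, fnc.matrix, delimiter=",")


def read_static_fnc(path, subject_id: str | None = None) -> StaticFNC:
    path = Path(path)
    matrix = np.loadtxt(path, delimiter=",")
    return StaticFNC(matrix=matrix, subject_id=subject_id or path.stem)


def write_dynamic_fnc(dfnc: DynamicFNC, path) -> None:
    """Binary array container (.npy) + JSON sidecar (.json)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), dfnc.array)
    sidecar = {
        "subject_id": dfnc.subject_id,
        "n_windows": int(dfnc.n_windows),
        "window": dataclasses.asdict(dfnc.window),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_dynamic_fnc(path) -> DynamicFNC:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return DynamicFNC(
        array=np.load(path.with_suffix(".npy")),
        window=WindowSpec(**sidecar["window"]),
        subject_id=sidecar["subject_id"],
    )


# -- cohorts ---------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Time courses, phenotypes.csv, truth.csv and the resolved config YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_timecourse_dir(cohort.timecourses, out_dir / "timecourses")
    write_phenotypes(cohort.phenotypes, out_dir / "phenotypes.csv")
    cohort.truth.to_csv(out_dir / "truth.csv", index=False)
    (out_dir / "cohort.yaml").write_text(
        yaml.safe_dump(cohort.config.to_dict(), sort_keys=False)
    )


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("subject_id", "predicted_age") if c not in table.columns]
    if missing:
        raise InvalidInputError(f"predictions table missing columns: {missing}")
    return table
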