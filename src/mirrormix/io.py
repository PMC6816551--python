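"""Dataset schema, readers/writers, descriptive statistics and run manifests.

The canonical on-disk form is a pair of UTF-8 CSV files (``trials.csv``,
``participants.csv``) with the columns below; coordinates are metres in the
overhead plane, rotations degrees.  XLSX is supported read-only for
deposited-style workbooks, through an editable column mapping.  Nothing is
dropped silently: rows that fail validation are collected into a rejects
report and raised.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .layouts import Layout, nearest_landmark

__all__ = [
    "TRIAL_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "FAR_TARGET_ID",
    "Dataset",
    "SchemaError",
    "RowValidationError",
    "read_dataset",
    "write_dataset",
    "descriptives",
    "write_manifest",
]

FAR_TARGET_ID = -1  # sentinel: far targets carry no modelled geometry

TRIAL_COLUMNS = {
    "participant_id": "int64",
    "age_years": "float64",
    "environment": "object",
    "trial_index": "int64",
    "target_id": "int64",
    "response_x_m": "float64",
    "response_y_m": "float64",
    "rotation_deg": "float64",
    "trial_type": "object",
}

PARTICIPANT_COLUMNS = {
    "participant_id": "int64",
    "age_years": "float64",
    "vocabulary_raw": "float64",
    "daynight_time_s": "float64",
    "daynight_errors": "int64",
}

_NUMERIC_TRIAL = ["participant_id", "age_years", "trial_index", "target_id",
                  "response_x_m", "response_y_m", "rotation_deg"]
_NUMERIC_PART = ["participant_id", "age_years", "vocabulary_raw",
                 "daynight_time_s", "daynight_errors"]


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class RowValidationError(ValueError):
    """Some rows failed validation; ``rejects`` lists them with row numbers."""

    def __init__(self, message: str, rejects: pd.DataFrame):
        super().__init__(f"{message}\n{rejects.to_string(max_rows=20)}")
        self.rejects = rejects


@dataclass
class Dataset:
    """Trial-level responses plus the participant covariate table."""

    trials: pd.DataFrame
    participants: pd.DataFrame
    ground_truth: dict | None = None

    def equals(self, other: "Dataset") -> bool:
        t1 = self.trials.reset_index(drop=True)[list(TRIAL_COLUMNS)]
        t2 = other.trials.reset_index(drop=True)[list(TRIAL_COLUMNS)]
        p1 = self.participants.reset_index(drop=True)[list(PARTICIPANT_COLUMNS)]
        p2 = other.participants.reset_index(drop=True)[list(PARTICIPANT_COLUMNS)]
        return t1.equals(t2) and p1.equals(p2)

    def near_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] == "near"]

    def select_age(self, lo: float, hi: float, closed_top: bool = False) -> "Dataset":
        """Participants with age in [lo, hi) — or [lo, hi] for the top bracket."""
        a = self.trials["age_years"]
        mask = (a >= lo) & ((a <= hi) if closed_top else (a < hi))
        pa = self.participants["age_years"]
        pmask = (pa >= lo) & ((pa <= hi) if closed_top else (pa < hi))
        return Dataset(self.trials[mask].reset_index(drop=True),
                       self.participants[pmask].reset_index(drop=True),
                       self.ground_truth)


def _resolve_columns(df: pd.DataFrame, required: dict, mapping: dict | None,
                     what: str) -> pd.DataFrame:
    mapping = mapping or {}
    out = {}
    for canon in required:
        src = mapping.get(canon, canon)
        if src not in df.columns:
            raise SchemaError(f"{what}: missing required column {canon!r}"
                              f" (looked for {src!r})")
        out[canon] = df[src]
    return pd.DataFrame(out)


def _parse_float(series: pd.Series) -> pd.Series:
    """Correctly-rounded string→float64 parsing (unparseable → NaN)."""

    def conv(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv).astype(float)


def _coerce_and_validate(trials: pd.DataFrame, participants: pd.DataFrame,
                         validate_age: bool) -> Dataset:
    from .layouts import canonical_layout, CANONICAL_NAMES

    rejects = []

    t = trials.copy()
    for col in _NUMERIC_TRIAL:
        t[col] = _parse_float(t[col])
    bad = t[_NUMERIC_TRIAL].isna().any(axis=1)
    bad |= ~t["trial_type"].isin(["near", "far"])
    # near trials must reference a modelled target of their environment
    for env in t["environment"].dropna().unique():
        if env in CANONICAL_NAMES:
            ids = set(canonical_layout(env).target_ids)
            sel = (t["environment"] == env) & (t["trial_type"] == "near")
            bad |= sel & ~t["target_id"].isin(ids)
            far_sel = (t["environment"] == env) & (t["trial_type"] == "far")
            bad |= far_sel & (t["target_id"] != FAR_TARGET_ID)
    for row in t.index[bad.fillna(True)]:
        rejects.append({"table": "trials", "row": int(row),
                        "reason": "unparseable or inconsistent trial"})

    p = participants.copy()
    for col in _NUMERIC_PART:
        p[col] = _parse_float(p[col])
    pbad = p[_NUMERIC_PART].isna().any(axis=1)
    if validate_age:
        pbad |= ~p["age_years"].between(3.5, 8.5)
    for row in p.index[pbad]:
        rejects.append({"table": "participants", "row": int(row),
                        "reason": "unparseable covariates or age outside 3.5-8.5"})

    if rejects:
        raise RowValidationError("rows failed validation",
                                 pd.DataFrame(rejects))
    if len(t) == 0:
        raise SchemaError("empty trials table")
    t = t.astype(TRIAL_COLUMNS)[list(TRIAL_COLUMNS)]
    p = p.astype(PARTICIPANT_COLUMNS)[list(PARTICIPANT_COLUMNS)]
    orphan = ~t["participant_id"].isin(p["participant_id"])
    if orphan.any():
        raise RowValidationError(
            "trials reference unknown participants",
            pd.DataFrame({"table": "trials", "row": t.index[orphan].astype(int),
                          "reason": "unknown participant_id"}))
    return Dataset(t.reset_index(drop=True), p.reset_index(drop=True))


def read_dataset(path: str | Path, format: str = "csv",
                 mapping: dict | None = None,
                 validate_age: bool = True) -> Dataset:
    """Read and validate a dataset.

    ``csv``: ``path`` is a directory containing ``trials.csv`` and
    ``participants.csv``.  ``xlsx``: ``path`` is a workbook with sheets
    ``trials`` and ``participants`` (sheet and column names overridable via
    ``mapping``, keys ``sheet_trials``/``sheet_participants`` plus
    canonical-column → source-column entries).
    """
    path = Path(path)
    mapping = dict(mapping or {})
    if format == "csv":
        tfile, pfile = path / "trials.csv", path / "participants.csv"
        if not tfile.exists():
            raise SchemaError(f"missing {tfile}")
        if not pfile.exists():
            raise SchemaError(f"missing {pfile}")
        trials = pd.read_csv(tfile, dtype=str)
        participants = pd.read_csv(pfile, dtype=str)
    elif format == "xlsx":
        trials = pd.read_excel(path, sheet_name=mapping.pop("sheet_trials", "trials"),
                               dtype=str)
        participants = pd.read_excel(
            path, sheet_name=mapping.pop("sheet_participants", "participants"),
            dtype=str)
    else:
        raise ValueError(f"unknown format {format!r}")
    trials = _resolve_columns(trials, TRIAL_COLUMNS, mapping, "trials")
    participants = _resolve_columns(participants, PARTICIPANT_COLUMNS, mapping,
                                    "participants")
    gt = None
    if format == "csv" and (path / "ground_truth.json").exists():
        gt = json.loads((path / "ground_truth.json").read_text())
    ds = _coerce_and_validate(trials, participants, validate_age)
    ds.ground_truth = gt
    return ds


def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset to a directory of CSV files (plus ground truth JSON)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees float64 values survive the text roundtrip bit-exactly
    dataset.trials[list(TRIAL_COLUMNS)].to_csv(path / "trials.csv", index=False,
                                               float_format="%.17g")
    dataset.participants[list(PARTICIPANT_COLUMNS)].to_csv(
        path / "participants.csv", index=False, float_format="%.17g")
    if dataset.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(dataset.ground_truth, indent=1, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def descriptives(dataset: Dataset, layout: Layout,
                 age_range: tuple[float, float] | None = None,
                 closed_top: bool = False) -> pd.Series:
    """Descriptive accuracy summary of the near trials.

    Reports the correct-nearest-landmark count and rate with an exact binomial
    test against the environment's chance level, and the median Euclidean
    response error in metres.
    """
    ds = dataset.select_age(*age_range, closed_top=closed_top) if age_range else dataset
    near = ds.near_trials()
    if len(near) == 0:
        raise ValueError("no near trials in the selection")
    resp = near[["response_x_m", "response_y_m"]].to_numpy(float)
    true_lm = np.array([layout.target(t).landmark_id for t in near["target_id"]])
    resp_lm = np.array([nearest_landmark(layout, xy) for xy in resp])
    n_correct = int((resp_lm == true_lm).sum())
    n = len(near)
    pos = np.array([layout.target(t).position for t in near["target_id"]])
    err = np.linalg.norm(resp - pos, axis=1)
    test = binomtest(n_correct, n, p=layout.chance_p1, alternative="greater")
    return pd.Series({
        "n_trials": n,
        "n_landmark_correct": n_correct,
        "landmark_correct_rate": n_correct / n,
        "chance_level": layout.chance_p1,
        "binomial_p_value": test.pvalue,
        "median_error_m": float(np.median(err)),
    })


def write_manifest(out_path: str | Path, config: dict,
                   inputs: list[str | Path] = ()) -> Path:
    """Write a JSON manifest (config, seeds, version, input checksums)."""
    from . import __version__

    checksums = {}
    for f in inputs:
        f = Path(f)
        if f.is_file():
            checksums[str(f)] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {"package": "mirrormix", "version": __version__,
                "config": config, "input_sha256": checksums}
    out_path = Path(out_path)
    out_path.write_text(json.dumps(manifest, indent=1, default=_json_default))
    return out_path
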