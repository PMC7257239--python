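"""Domain types, validation and CSV I/O for interview-survey datasets.

A dataset is three tables linked by opaque identifiers:

* ``responses`` — one row per (fisher, photo) presentation: whether the fisher
  recognized the dolphin in the photo, the name they gave, how they recognized
  it, and the dolphin traits they perceived;
* ``fishers`` — interviewee covariates (age, fishing site, how they learned the
  cooperative fishing tactic, economic dependence on it);
* ``photos`` — covariates of the photographed dolphin (home range, encounter
  rate, foraging behavior class) plus, for synthetic data only, the true
  catalog name used by oracle checks.

All categorical values are canonical lowercase tokens; free-text names pass
through :func:`normalize_name`.  The reserved sentinel :data:`UNKNOWN` encodes
"no name given / don't know" and never counts as a name citation downstream.
"""

from __future__ import annotations

import os
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "RECOGNITION_METHODS",
    "SEX_LEVELS",
    "BEHAVIOR_LEVELS",
    "LEARNING_MODES",
    "DatasetError",
    "SchemaError",
    "IntegrityError",
    "DuplicationError",
    "ValidationError",
    "InterviewResponse",
    "FisherProfile",
    "DolphinPhoto",
    "Dataset",
    "normalize_name",
    "read_dataset",
    "write_dataset",
]

#: Reserved sentinel for "no name / don't know" answers.
UNKNOWN = "unknown"

RECOGNITION_METHODS = ("marks", "form", "none")
SEX_LEVELS = ("male", "female", "unknown")
BEHAVIOR_LEVELS = ("good", "bad", "unknown")
LEARNING_MODES = ("vertical", "horizontal", "individual")

RESPONSE_COLUMNS = [
    "fisher_id",
    "photo_id",
    "recognized",
    "name_given",
    "recognition_method",
    "perceived_sex",
    "perceived_age_years",
    "perceived_behavior",
]
FISHER_COLUMNS = ["fisher_id", "age_years", "fishing_site", "learning_mode", "dependence"]
PHOTO_COLUMNS = ["photo_id", "home_range", "encounter_rate", "behavior_class", "true_name"]


class DatasetError(ValueError):
    """Base class for dataset construction/validation failures."""


class SchemaError(DatasetError):
    """A required column is missing or a file cannot be parsed."""


class IntegrityError(DatasetError):
    """A response references a fisher or photo absent from its table."""


class DuplicationError(DatasetError):
    """The same (fisher, photo) presentation appears more than once."""


class ValidationError(DatasetError):
    """A row violates a declared domain invariant."""


def normalize_name(raw: object, synonyms: Mapping[str, str] | None = None) -> str:
    """Canonicalize a free-text dolphin name.

    Trims, lowercases and collapses internal whitespace.  Empty strings and
    missing values map to the :data:`UNKNOWN` sentinel, which maps to itself.
    An optional ``synonyms`` table (canonical -> canonical) merges spelling
    variants the caller knows about; it is applied after normalization.
    Idempotent by construction.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNKNOWN
    name = " ".join(str(raw).strip().lower().split())
    if not name:
        return UNKNOWN
    if synonyms and name in synonyms:
        name = normalize_name(synonyms[name])
    return name


@dataclass(frozen=True)
class InterviewResponse:
    """One fisher's reaction to one presented photo."""

    fisher_id: str
    photo_id: str
    recognized: bool
    name_given: str = UNKNOWN
    recognition_method: str = "none"
    perceived_sex: str = UNKNOWN
    perceived_age_years: float | None = None
    perceived_behavior: str = UNKNOWN


@dataclass(frozen=True)
class FisherProfile:
    """Interviewee covariates for the consensus model."""

    fisher_id: str
    age_years: int
    fishing_site: str
    learning_mode: str
    dependence: bool


@dataclass(frozen=True)
class DolphinPhoto:
    """Photographed-dolphin covariates for the recognition/concordance models."""

    photo_id: str
    home_range: float
    encounter_rate: float
    behavior_class: str
    true_name: str | None = None


def _require_columns(frame: pd.DataFrame, columns: list[str], table: str,
                     optional: tuple[str, ...] = ()) -> None:
    missing = [c for c in columns if c not in frame.columns and c not in optional]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _canonical_responses(frame: pd.DataFrame,
                         synonyms: Mapping[str, str] | None = None) -> pd.DataFrame:
    _require_columns(frame, RESPONSE_COLUMNS, "responses")
    out = frame.loc[:, RESPONSE_COLUMNS].copy()
    for col in ("fisher_id", "photo_id"):
        out[col] = out[col].astype(str).str.strip()
    out["recognized"] = out["recognized"].astype(int).astype(bool)
    out["name_given"] = [normalize_name(v, synonyms) for v in out["name_given"]]
    for col in ("recognition_method", "perceived_sex", "perceived_behavior"):
        out[col] = out[col].astype(str).str.strip().str.lower()
    out["perceived_age_years"] = pd.to_numeric(out["perceived_age_years"], errors="coerce")
    out = out.sort_values(["fisher_id", "photo_id"], kind="mergesort").reset_index(drop=True)
    return out


def _canonical_fishers(frame: pd.DataFrame) -> pd.DataFrame:
    _require_columns(frame, FISHER_COLUMNS, "fishers")
    out = frame.loc[:, FISHER_COLUMNS].copy()
    out["fisher_id"] = out["fisher_id"].astype(str).str.strip()
    out["age_years"] = out["age_years"].astype(int)
    for col in ("fishing_site", "learning_mode"):
        out[col] = out[col].astype(str).str.strip().str.lower()
    out["dependence"] = out["dependence"].astype(int).astype(bool)
    return out.sort_values("fisher_id", kind="mergesort").reset_index(drop=True)


def _canonical_photos(frame: pd.DataFrame) -> pd.DataFrame:
    _require_columns(frame, PHOTO_COLUMNS, "photos", optional=("true_name",))
    out = frame.copy()
    if "true_name" not in out.columns:
        out["true_name"] = UNKNOWN
    out = out.loc[:, PHOTO_COLUMNS]
    out["photo_id"] = out["photo_id"].astype(str).str.strip()
    out["home_range"] = out["home_range"].astype(float)
    out["encounter_rate"] = out["encounter_rate"].astype(float)
    out["behavior_class"] = out["behavior_class"].astype(str).str.strip().str.lower()
    out["true_name"] = [normalize_name(v) for v in out["true_name"]]
    return out.sort_values("photo_id", kind="mergesort").reset_index(drop=True)


@dataclass
class Dataset:
    """A validated interview survey: responses + fisher and photo covariates.

    Frames are canonicalized (lowercased categoricals, normalized names,
    id-sorted rows) and validated on construction; invalid inputs raise a
    :class:`DatasetError` subclass naming the offending rows.
    """

    responses: pd.DataFrame
    fishers: pd.DataFrame
    photos: pd.DataFrame
    synonyms: Mapping[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.responses = _canonical_responses(pd.DataFrame(self.responses), self.synonyms)
        self.fishers = _canonical_fishers(pd.DataFrame(self.fishers))
        self.photos = _canonical_photos(pd.DataFrame(self.photos))
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls,
                     responses: list[InterviewResponse],
                     fishers: list[FisherProfile],
                     photos: list[DolphinPhoto],
                     synonyms: Mapping[str, str] | None = None) -> "Dataset":
        return cls(
            responses=pd.DataFrame([vars(r) for r in responses], columns=RESPONSE_COLUMNS),
            fishers=pd.DataFrame([vars(f) for f in fishers], columns=FISHER_COLUMNS),
            photos=pd.DataFrame([vars(p) for p in photos], columns=PHOTO_COLUMNS),
            synonyms=synonyms,
        )

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        r, f, p = self.responses, self.fishers, self.photos

        if f["fisher_id"].duplicated().any():
            dup = sorted(f.loc[f["fisher_id"].duplicated(), "fisher_id"])
            raise DuplicationError(f"fishers: duplicate fisher_id(s) {dup}")
        if p["photo_id"].duplicated().any():
            dup = sorted(p.loc[p["photo_id"].duplicated(), "photo_id"])
            raise DuplicationError(f"photos: duplicate photo_id(s) {dup}")
        pairs = r[["fisher_id", "photo_id"]]
        if pairs.duplicated().any():
            dup = pairs.loc[pairs.duplicated()].to_records(index=False).tolist()
            raise DuplicationError(
                f"responses: photo presented more than once to the same fisher: {dup}")

        bad_f = sorted(set(r["fisher_id"]) - set(f["fisher_id"]))
        if bad_f:
            raise IntegrityError(f"responses reference unknown fisher_id(s) {bad_f}")
        bad_p = sorted(set(r["photo_id"]) - set(p["photo_id"]))
        if bad_p:
            raise IntegrityError(f"responses reference unknown photo_id(s) {bad_p}")

        def _domain(frame: pd.DataFrame, col: str, levels: tuple[str, ...], table: str) -> None:
            bad = sorted(set(frame[col]) - set(levels))
            if bad:
                raise ValidationError(f"{table}.{col}: invalid value(s) {bad}; allowed {levels}")

        _domain(r, "recognition_method", RECOGNITION_METHODS, "responses")
        _domain(r, "perceived_sex", SEX_LEVELS, "responses")
        _domain(r, "perceived_behavior", BEHAVIOR_LEVELS, "responses")
        _domain(f, "learning_mode", LEARNING_MODES, "fishers")
        _domain(p, "behavior_class", ("good", "bad"), "photos")

        unrec = r.loc[~r["recognized"]]
        if (unrec["name_given"] != UNKNOWN).any():
            bad = unrec.loc[unrec["name_given"] != UNKNOWN, ["fisher_id", "photo_id"]]
            raise ValidationError(
                f"responses: name given without recognition at {bad.to_records(index=False).tolist()}")
        if (unrec["recognition_method"] != "none").any():
            raise ValidationError("responses: recognition_method must be 'none' when not recognized")
        rec = r.loc[r["recognized"]]
        if (rec["recognition_method"] == "none").any():
            raise ValidationError("responses: recognized rows need a recognition_method (marks|form)")

        age = r["perceived_age_years"].dropna()
        if ((age < 0) | (age > 80)).any():
            raise ValidationError("responses.perceived_age_years outside [0, 80]")
        if ((f["age_years"] < 15) | (f["age_years"] > 100)).any():
            raise ValidationError("fishers.age_years outside [15, 100]")
        if (p["home_range"] <= 0).any():
            raise ValidationError("photos.home_range must be positive")
        if (p["encounter_rate"] < 0).any():
            raise ValidationError("photos.encounter_rate must be non-negative")

    # -- conveniences ---------------------------------------------------------

    @property
    def n_fishers(self) -> int:
        return len(self.fishers)

    @property
    def n_photos(self) -> int:
        return len(self.photos)

    def responses_for_photo(self, photo_id: str) -> pd.DataFrame:
        return self.responses.loc[self.responses["photo_id"] == photo_id]

    def responses_for_fisher(self, fisher_id: str) -> pd.DataFrame:
        return self.responses.loc[self.responses["fisher_id"] == fisher_id]

    def equals(self, other: "Dataset") -> bool:
        return (self.responses.equals(other.responses)
                and self.fishers.equals(other.fishers)
                and self.photos.equals(other.photos))


def read_dataset(responses_path: str | os.PathLike,
                 fishers_path: str | os.PathLike,
                 photos_path: str | os.PathLike,
                 synonyms: Mapping[str, str] | None = None) -> Dataset:
    """Read and validate the three CSV tables into a :class:`Dataset`.

    Raises :class:`SchemaError` for missing columns, :class:`IntegrityError`
    for dangling ids and :class:`DuplicationError` for repeated presentations.
    """
    frames = {}
    for key, path in (("responses", responses_path), ("fishers", fishers_path),
                      ("photos", photos_path)):
        try:
            frames[key] = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed CSV
            raise SchemaError(f"{key}: cannot parse {path}: {exc}") from exc
    return Dataset(responses=frames["responses"], fishers=frames["fishers"],
                   photos=frames["photos"], synonyms=synonyms)


def write_dataset(dataset: Dataset, out_dir: str | os.PathLike) -> tuple[Path, Path, Path]:
    """Write ``responses.csv``, ``fishers.csv`` and ``photos.csv`` under ``out_dir``.

    Output is canonical (id-sorted, 0/1 booleans, fixed float formatting) so
    that ``read_dataset`` round-trips to an equal :class:`Dataset` and repeated
    writes of the same dataset are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    r = dataset.responses.copy()
    r["recognized"] = r["recognized"].astype(int)
    f = dataset.fishers.copy()
    f["dependence"] = f["dependence"].astype(int)
    p = dataset.photos.copy()

    paths = (out / "responses.csv", out / "fishers.csv", out / "photos.csv")
    # default float formatting is shortest-roundtrip repr: exact re-read
    r.to_csv(paths[0], index=False)
    f.to_csv(paths[1], index=False)
    p.to_csv(paths[2], index=False)
    return paths
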