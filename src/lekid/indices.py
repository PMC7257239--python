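"""Per-photo Recognition Index (RI) and Concordance Index (CDI).

RI is the fraction of a photo's presentations that elicited a positive
recognition.  CDI measures naming agreement among the fishers who recognized
the photo: with nR positive recognitions carrying nN distinct canonical names,

    CDI = (nR - nN) / (nR - 1),

so CDI = 1 when every recognizer gives the same name and 0 when every
recognizer gives a different one.  CDI is undefined for nR <= 1 (the formula
divides by nR - 1); undefined values are reported as NaN and excluded from
summaries and downstream models.

A recognition without a name ("I know this dolphin but not its name") counts
toward nR and, under the default ``unknown_policy='category'``, contributes a
single shared pseudo-name to nN; ``'exclude'`` drops nameless recognitions
from the concordance count entirely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import UNKNOWN, Dataset

__all__ = [
    "UndefinedIndexError",
    "recognition_index",
    "name_counts",
    "concordance_index",
    "PhotoIndexTable",
    "photo_index_table",
]

UNKNOWN_POLICIES = ("category", "exclude")


class UndefinedIndexError(ValueError):
    """An index was requested for an empty collection of responses."""


def recognition_index(responses: pd.DataFrame) -> float:
    """RI = positive recognitions / presentations, over one photo's responses."""
    if len(responses) == 0:
        raise UndefinedIndexError("recognition index of zero presentations")
    return float(responses["recognized"].sum()) / float(len(responses))


def name_counts(responses: pd.DataFrame, unknown_policy: str = "category") -> Counter:
    """Multiset of canonical names among recognized responses.

    Under ``'category'`` the UNKNOWN sentinel appears as one shared category;
    under ``'exclude'`` nameless recognitions are dropped.
    """
    if unknown_policy not in UNKNOWN_POLICIES:
        raise ValueError(f"unknown_policy must be one of {UNKNOWN_POLICIES}")
    names = responses.loc[responses["recognized"], "name_given"]
    if unknown_policy == "exclude":
        names = names[names != UNKNOWN]
    return Counter(names)


def concordance_index(responses: pd.DataFrame, unknown_policy: str = "category") -> float:
    """CDI = (nR - nN)/(nR - 1); NaN when fewer than two countable recognitions."""
    counts = name_counts(responses, unknown_policy)
    n_r = sum(counts.values())
    n_n = len(counts)
    if n_r <= 1:
        return float("nan")
    return (n_r - n_n) / (n_r - 1)


def _modal_method(responses: pd.DataFrame) -> str:
    """Most frequent recognition method among recognized responses; tie -> marks."""
    methods = responses.loc[responses["recognized"], "recognition_method"]
    if len(methods) == 0:
        return "none"
    counts = methods.value_counts()
    top = counts.max()
    winners = set(counts[counts == top].index)
    return "marks" if "marks" in winners else counts.idxmax()


@dataclass
class PhotoIndexTable:
    """Per-photo index table plus its summary block."""

    frame: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def photo_index_table(dataset: Dataset,
                      high_cutoff: float = 0.5,
                      unknown_policy: str = "category") -> PhotoIndexTable:
    """Compute RI and CDI for every presented photo, with covariates attached.

    Parameters
    ----------
    dataset
        Validated interview dataset.
    high_cutoff
        Threshold splitting photos into high/low recognition and concordance
        groups (default 0.5).
    unknown_policy
        How nameless recognitions enter the concordance count; see module
        docstring.

    Returns
    -------
    PhotoIndexTable
        ``frame`` has one row per photo with >= 1 presentation (columns:
        photo_id, n_presented, nR, nN, RI, CDI, modal_recognition_method and
        the photo covariates); ``summary`` holds mean +/- sample SD of RI and
        of the defined CDIs, and the photo ids above/below the cutoff.
    """
    rows = []
    for photo_id, group in dataset.responses.groupby("photo_id", sort=True):
        counts = name_counts(group, unknown_policy)
        n_r = sum(counts.values())
        rows.append({
            "photo_id": photo_id,
            "n_presented": len(group),
            "nR": n_r,
            "nN": len(counts),
            "RI": recognition_index(group),
            "CDI": concordance_index(group, unknown_policy),
            "modal_recognition_method": _modal_method(group),
        })
    frame = pd.DataFrame(rows, columns=["photo_id", "n_presented", "nR", "nN", "RI",
                                        "CDI", "modal_recognition_method"])
    frame = frame.merge(
        dataset.photos[["photo_id", "home_range", "encounter_rate", "behavior_class"]],
        on="photo_id", how="left").sort_values("photo_id").reset_index(drop=True)

    ri = frame["RI"]
    cdi = frame["CDI"].dropna()
    summary = {
        "n_photos": int(len(frame)),
        "ri_mean": float(ri.mean()) if len(ri) else float("nan"),
        "ri_sd": float(ri.std(ddof=1)) if len(ri) > 1 else float("nan"),
        "cdi_mean": float(cdi.mean()) if len(cdi) else float("nan"),
        "cdi_sd": float(cdi.std(ddof=1)) if len(cdi) > 1 else float("nan"),
        "n_cdi_defined": int(len(cdi)),
        "n_cdi_undefined": int(frame["CDI"].isna().sum()),
        "high_ri_photos": frame.loc[frame["RI"] >= high_cutoff, "photo_id"].tolist(),
        "low_ri_photos": frame.loc[frame["RI"] < high_cutoff, "photo_id"].tolist(),
        "high_cdi_photos": frame.loc[frame["CDI"] >= high_cutoff, "photo_id"].tolist(),
        "low_cdi_photos": frame.loc[frame["CDI"] < high_cutoff, "photo_id"].tolist(),
        "high_cutoff": float(high_cutoff),
    }
    return PhotoIndexTable(frame=frame, summary=summary)
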