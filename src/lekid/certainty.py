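"""Per-name Certainty Index (CeI), popularity correction (CF) and CeIc.

Fishers reuse popular dolphin names across different photos.  For each
canonical name, CeI measures how concentrated its citations are on a single
photo:

    CeI = citations of the name to its modal photo / total citations.

Popular names are cited more often and so mechanically spread over more
photos; the correction factor CF = total citations / citations of the most
popular name rescales for popularity, and CeIc = CeI * CF.  CeIc <= CeI, with
equality exactly for (co-)most-popular names.

The table also aggregates, per name, the dolphin attributes fishers reported
when citing it (modal sex/behavior/recognition method, mean perceived age) —
the covariates of the certainty model.  A citation is one (fisher, photo)
response naming the dolphin; the UNKNOWN sentinel is never a name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import UNKNOWN, Dataset
from .indices import UndefinedIndexError

__all__ = ["certainty_index", "CertaintyTable", "corrected_certainty_table"]


def certainty_index(citations: dict[str, int]) -> tuple[float, str]:
    """CeI and modal photo from one name's photo -> citation-count mapping.

    Ties on the modal photo resolve to the lexicographically smallest id.
    """
    counts = {p: int(c) for p, c in citations.items() if c > 0}
    if not counts:
        raise UndefinedIndexError("certainty index of a never-cited name")
    total = sum(counts.values())
    top = max(counts.values())
    modal_photo = min(p for p, c in counts.items() if c == top)
    return top / total, modal_photo


def _modal_or_unknown(values: pd.Series) -> str:
    """Most frequent category; ties resolve to the UNKNOWN sentinel."""
    counts = values.value_counts()
    top = counts.max()
    winners = counts[counts == top].index
    return winners[0] if len(winners) == 1 else UNKNOWN


def _modal_method(values: pd.Series) -> str:
    """Modal recognition method; ties resolve to 'marks' (no unknown level)."""
    counts = values.value_counts()
    winners = set(counts[counts == counts.max()].index)
    return "marks" if len(winners) > 1 and "marks" in winners else counts.idxmax()


@dataclass
class CertaintyTable:
    """Per-name certainty table plus its summary block."""

    frame: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def corrected_certainty_table(dataset: Dataset) -> CertaintyTable:
    """CeI, CF and CeIc for every name cited in the dataset.

    Returns one row per canonical name with its citation counts, indices and
    aggregated perceived attributes; the summary reports mean +/- sample SD of
    CeI and CeIc.  Raises :class:`UndefinedIndexError` if the dataset contains
    no named recognition.
    """
    named = dataset.responses.loc[
        dataset.responses["recognized"] & (dataset.responses["name_given"] != UNKNOWN)]
    if len(named) == 0:
        raise UndefinedIndexError("no named recognitions in dataset")

    rows = []
    for name, group in named.groupby("name_given", sort=True):
        citations = group["photo_id"].value_counts().to_dict()
        cei, modal_photo = certainty_index(citations)
        ages = group["perceived_age_years"].dropna()
        rows.append({
            "name": name,
            "total_citations": int(len(group)),
            "modal_photo": modal_photo,
            "modal_photo_citations": int(citations[modal_photo]),
            "CeI": cei,
            "modal_sex": _modal_or_unknown(group["perceived_sex"]),
            "mean_perceived_age": float(ages.mean()) if len(ages) else float("nan"),
            "modal_behavior": _modal_or_unknown(group["perceived_behavior"]),
            "modal_method": _modal_method(group["recognition_method"]),
        })
    frame = pd.DataFrame(rows)
    max_citations = frame["total_citations"].max()
    frame["CF"] = frame["total_citations"] / max_citations
    frame["CeIc"] = frame["CeI"] * frame["CF"]
    frame = frame[["name", "total_citations", "modal_photo", "modal_photo_citations",
                   "CeI", "CF", "CeIc", "modal_sex", "mean_perceived_age",
                   "modal_behavior", "modal_method"]]

    summary = {
        "n_names": int(len(frame)),
        "cei_mean": float(frame["CeI"].mean()),
        "cei_sd": float(frame["CeI"].std(ddof=1)) if len(frame) > 1 else float("nan"),
        "ceic_mean": float(frame["CeIc"].mean()),
        "ceic_sd": float(frame["CeIc"].std(ddof=1)) if len(frame) > 1 else float("nan"),
        "most_popular_names": frame.loc[frame["total_citations"] == max_citations,
                                        "name"].tolist(),
        "total_citations": int(frame["total_citations"].sum()),
    }
    return CertaintyTable(frame=frame, summary=summary)
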