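"""Pairwise Consensus Index (CI) and per-fisher Average Consensus Index (ACI).

For a pair of fishers, CI is the fraction of jointly presented photos on which
both gave the same canonical (non-sentinel) name.  A match requires both to
have recognized the photo and named it identically; two "don't know" answers
do not match — mutual ignorance is not consensus.  The default denominator is
all photos presented to both fishers, so failing to recognize a shared photo
counts against consensus; ``denominator='recognized_both'`` restricts it to
photos both recognized.

ACI averages a fisher's CIs over *eligible* pairs — those sharing at least
``min_shared`` presented photos (default 3, the small-sample restriction under
which the study retained 26 of its 38 interviewees).  Fishers belonging to no
eligible pair are excluded from the ACI table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data import UNKNOWN, Dataset

__all__ = ["PairConsensus", "pairwise_ci", "pairwise_table", "AciTable", "aci_table"]

DENOMINATORS = ("presented_both", "recognized_both")


@dataclass(frozen=True)
class PairConsensus:
    """Consensus between one unordered pair of fishers."""

    fisher_a: str
    fisher_b: str
    n_shared: int          # photos presented to both (eligibility basis)
    n_both_recognized: int
    n_match: int
    ci: float              # NaN when the denominator is zero


def _pair_consensus(resp_a: pd.DataFrame, resp_b: pd.DataFrame,
                    a: str, b: str, denominator: str) -> PairConsensus:
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    merged = resp_a.merge(resp_b, on="photo_id", suffixes=("_a", "_b"))
    n_shared = len(merged)
    both = merged.loc[merged["recognized_a"] & merged["recognized_b"]]
    n_match = int(((both["name_given_a"] == both["name_given_b"])
                   & (both["name_given_a"] != UNKNOWN)).sum())
    denom = n_shared if denominator == "presented_both" else len(both)
    ci = n_match / denom if denom > 0 else float("nan")
    return PairConsensus(fisher_a=a, fisher_b=b, n_shared=n_shared,
                         n_both_recognized=len(both), n_match=n_match, ci=ci)


def pairwise_ci(dataset: Dataset, fisher_a: str, fisher_b: str,
                denominator: str = "presented_both") -> PairConsensus:
    """CI for one pair of fishers; symmetric in its arguments.

    Raises ``KeyError`` if either fisher id is unknown.  ``ci`` is NaN when
    the pair shares no (recognized, under ``recognized_both``) photos.
    """
    known = set(dataset.fishers["fisher_id"])
    for fid in (fisher_a, fisher_b):
        if fid not in known:
            raise KeyError(f"unknown fisher_id {fid!r}")
    return _pair_consensus(dataset.responses_for_fisher(fisher_a),
                           dataset.responses_for_fisher(fisher_b),
                           fisher_a, fisher_b, denominator)


def pairwise_table(dataset: Dataset, denominator: str = "presented_both") -> pd.DataFrame:
    """CI for every unordered fisher pair (columns fisher_a < fisher_b).

    Vectorized over (fisher x photo) incidence matrices; agrees with
    :func:`pairwise_ci` pair by pair.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    ids = sorted(dataset.fishers["fisher_id"])
    photo_ids = sorted(dataset.photos["photo_id"])
    f_idx = {fid: i for i, fid in enumerate(ids)}
    p_idx = {pid: i for i, pid in enumerate(photo_ids)}
    n_f, n_p = len(ids), len(photo_ids)

    presented = np.zeros((n_f, n_p), dtype=bool)
    recognized = np.zeros((n_f, n_p), dtype=bool)
    names = np.full((n_f, n_p), -1, dtype=np.int64)  # -1 = absent or sentinel
    codes, uniques = pd.factorize(dataset.responses["name_given"])
    unknown_code = {name: i for i, name in enumerate(uniques)}.get(UNKNOWN, -2)

    r = dataset.responses
    fi = r["fisher_id"].map(f_idx).to_numpy()
    pi = r["photo_id"].map(p_idx).to_numpy()
    presented[fi, pi] = True
    recognized[fi, pi] = r["recognized"].to_numpy()
    named = codes.copy()
    named[named == unknown_code] = -1
    names[fi, pi] = np.where(r["recognized"].to_numpy(), named, -1)

    rows = []
    for a, b in combinations(range(n_f), 2):
        shared = presented[a] & presented[b]
        both = shared & recognized[a] & recognized[b]
        match = both & (names[a] == names[b]) & (names[a] >= 0)
        n_shared = int(shared.sum())
        n_both = int(both.sum())
        n_match = int(match.sum())
        denom = n_shared if denominator == "presented_both" else n_both
        rows.append((ids[a], ids[b], n_shared, n_both, n_match,
                     n_match / denom if denom > 0 else float("nan")))
    return pd.DataFrame(rows, columns=["fisher_a", "fisher_b", "n_shared",
                                       "n_both_recognized", "n_match", "ci"])


@dataclass
class AciTable:
    """Per-fisher ACI table, the pairwise CI table behind it, and a summary."""

    frame: pd.DataFrame
    pairwise: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def aci_table(dataset: Dataset, min_shared: int = 3,
              denominator: str = "presented_both") -> AciTable:
    """Average Consensus Index per fisher under the shared-photo restriction.

    A pair is eligible iff it was presented at least ``min_shared`` common
    photos; a fisher enters the table iff it belongs to at least one eligible
    pair, with ACI the unweighted mean of its eligible pairwise CIs.  An empty
    result (no eligible pairs) is returned as an empty frame, not an error.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    pairs = pairwise_table(dataset, denominator)
    eligible = pairs.loc[(pairs["n_shared"] >= min_shared) & pairs["ci"].notna()]

    per_fisher: dict[str, list[float]] = {}
    for row in eligible.itertuples(index=False):
        per_fisher.setdefault(row.fisher_a, []).append(row.ci)
        per_fisher.setdefault(row.fisher_b, []).append(row.ci)

    rows = [{"fisher_id": fid, "ACI": float(np.mean(cis)), "n_pairs": len(cis)}
            for fid, cis in sorted(per_fisher.items())]
    frame = pd.DataFrame(rows, columns=["fisher_id", "ACI", "n_pairs"])
    frame = frame.merge(dataset.fishers, on="fisher_id", how="left")

    aci = frame["ACI"]
    summary = {
        "n_fishers_total": int(dataset.n_fishers),
        "n_fishers_included": int(len(frame)),
        "n_pairs_eligible": int(len(eligible)),
        "min_shared": int(min_shared),
        "denominator": denominator,
        "aci_mean": float(aci.mean()) if len(aci) else float("nan"),
        "aci_sd": float(aci.std(ddof=1)) if len(aci) > 1 else float("nan"),
        "aci_min": float(aci.min()) if len(aci) else float("nan"),
        "aci_max": float(aci.max()) if len(aci) else float("nan"),
    }
    return AciTable(frame=frame, pairwise=pairs, summary=summary)
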