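"""Rater-panel aggregation, agreement, and greedy panel optimization.

Ratings are held as a pandas DataFrame with rater ids as rows and note keys
(melody_id, note_index) as columns, integer values on the 0-3 salience scale.
A note a rater never marked is 0, not missing, matching the rating
interface's coding.

Agreement is summarized by Cronbach's alpha with raters as items and notes as
cases — identical to the consistency intraclass correlation ICC(C, k) — and
by the mean pairwise Pearson correlation across raters.  ``optimize_group``
greedily drops raters while alpha keeps increasing, yielding the "optimized
group" whose mean rating is the cleaner modeling target.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RatingError",
    "ReliabilityReport",
    "GroupSelection",
    "validate_ratings",
    "mean_ratings",
    "cronbach_alpha",
    "mean_pairwise_r",
    "reliability_report",
    "optimize_group",
    "write_ratings_csv",
    "read_ratings_csv",
]


class RatingError(ValueError):
    pass


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    vals = ratings.to_numpy()
    if np.isnan(vals).any():
        raise RatingError("rating matrix has missing cells (unmarked notes must be 0)")
    if not np.isin(vals, [0, 1, 2, 3]).all():
        bad = np.unique(vals[~np.isin(vals, [0, 1, 2, 3])])
        raise RatingError(f"ratings must be integers in 0..3; found {bad}")
    return ratings


def mean_ratings(ratings: pd.DataFrame, subset: list | None = None) -> pd.Series:
    """Per-note arithmetic mean across (a subset of) the panel — the overall
    measure of perceived accent used as the modeling target."""
    if subset is not None:
        if len(subset) == 0:
            raise RatingError("rater subset must be non-empty")
        missing = set(subset) - set(ratings.index)
        if missing:
            raise RatingError(f"unknown rater ids in subset: {sorted(missing)}")
        ratings = ratings.loc[list(subset)]
    return ratings.mean(axis=0)


def cronbach_alpha(ratings: pd.DataFrame) -> float:
    """Cronbach's alpha with raters as items and notes as cases:
    alpha = k/(k-1) * (1 - sum of per-rater variances / variance of the
    per-note sum).  Equals ICC(C, k)."""
    k = ratings.shape[0]
    if k < 2 or ratings.shape[1] < 2:
        raise RatingError("alpha needs >= 2 raters and >= 2 notes")
    vals = ratings.to_numpy(dtype=float)
    item_vars = vals.var(axis=1, ddof=1)
    total_var = vals.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise RatingError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def mean_pairwise_r(ratings: pd.DataFrame) -> float:
    """Mean Pearson correlation over all unordered rater pairs; constant
    raters are skipped (with a warning)."""
    vals = ratings.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise RatingError("pairwise correlation needs >= 2 raters")
    sd = vals.std(axis=1)
    keep = sd > 0
    if keep.sum() < vals.shape[0]:
        warnings.warn(
            f"{int((~keep).sum())} zero-variance rater(s) skipped in pairwise correlation"
        )
    if keep.sum() < 2:
        raise RatingError("fewer than 2 raters with variance; pairwise r undefined")
    corr = np.corrcoef(vals[keep])
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


@dataclass
class ReliabilityReport:
    alpha: float
    mean_pairwise_r: float
    per_rater_mean_r: dict
    n_raters: int
    n_notes: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "mean_pairwise_r": self.mean_pairwise_r,
                "per_rater_mean_r": self.per_rater_mean_r,
                "n_raters": self.n_raters,
                "n_notes": self.n_notes,
            },
            indent=1,
        )


def reliability_report(ratings: pd.DataFrame) -> ReliabilityReport:
    vals = ratings.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    per_rater = {}
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(vals)
    for i, rid in enumerate(ratings.index):
        others = [corr[i, j] for j in range(len(ratings)) if j != i and sd[j] > 0]
        per_rater[str(rid)] = float(np.nanmean(others)) if sd[i] > 0 and others else float("nan")
    return ReliabilityReport(
        alpha=cronbach_alpha(ratings),
        mean_pairwise_r=mean_pairwise_r(ratings),
        per_rater_mean_r=per_rater,
        n_raters=ratings.shape[0],
        n_notes=ratings.shape[1],
    )


@dataclass
class GroupSelection:
    removal_trace: list[tuple[object, float]]
    members: list
    alpha: float
    mean_pairwise_r: float
    initial_alpha: float = field(default=float("nan"))

    def to_json(self) -> str:
        return json.dumps(
            {
                "removal_trace": [[str(r), a] for r, a in self.removal_trace],
                "members": [str(m) for m in self.members],
                "alpha": self.alpha,
                "mean_pairwise_r": self.mean_pairwise_r,
                "initial_alpha": self.initial_alpha,
            },
            indent=1,
        )


def optimize_group(ratings: pd.DataFrame, min_size: int = 2) -> GroupSelection:
    """Greedy alpha maximization: repeatedly drop the rater whose omission
    raises Cronbach's alpha the most; stop when no omission helps (or when
    only ``min_size`` raters remain).  Ties go to the smallest rater id."""
    if ratings.shape[0] < 3:
        raise RatingError("group optimization needs >= 3 raters")
    members = list(ratings.index)
    current = cronbach_alpha(ratings)
    initial = current
    trace: list[tuple[object, float]] = []
    while len(members) > min_size:
        best_rater, best_alpha = None, current
        for rid in sorted(members, key=str):
            remaining = [m for m in members if m != rid]
            a = cronbach_alpha(ratings.loc[remaining])
            if a > best_alpha:
                best_rater, best_alpha = rid, a
        if best_rater is None:
            break
        members.remove(best_rater)
        current = best_alpha
        trace.append((best_rater, best_alpha))
    return GroupSelection(
        removal_trace=trace,
        members=members,
        alpha=current,
        mean_pairwise_r=mean_pairwise_r(ratings.loc[members]),
        initial_alpha=initial,
    )


# -- CSV --------------------------------------------------------------------
# rows = raters (first column rater_id), remaining columns "melody_id:note_index"


def write_ratings_csv(ratings: pd.DataFrame, path) -> None:
    out = ratings.copy()
    out.columns = [f"{m}:{i}" for m, i in out.columns]
    out.index.name = "rater_id"
    out.to_csv(path)


def read_ratings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="rater_id")
    try:
        cols = [(c.rsplit(":", 1)[0], int(c.rsplit(":", 1)[1])) for c in df.columns]
    except (IndexError, ValueError) as exc:
        raise RatingError(
            "ratings CSV columns must be 'melody_id:note_index'"
        ) from exc
    df.columns = pd.MultiIndex.from_tuples(cols, names=["melody_id", "note_index"])
    return validate_ratings(df)
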