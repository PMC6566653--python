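"""Feature-group ablation and per-subset / per-rater analyses.

The independent contribution of a feature group is the drop in
cross-validated R² when the group's columns are removed and the model refit:
ΔR²(g) = R²(full) − R²(without g).  Full and ablated models share identical
fold partitions (same seed), so each ΔR² is a paired comparison.  Because
groups overlap in what they explain, the five ΔR² values need not add up to
the full-model R².
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .predict import CvResult, PredictError, SvrConfig, cross_validate
from .reliability import RatingError

__all__ = [
    "AblationReport",
    "RaterModelReport",
    "group_contribution",
    "subset_analysis",
    "per_rater_models",
]


@dataclass
class AblationReport:
    full_r2: float
    delta_r2: dict[str, float]
    subset_label: str
    method: str
    seed: int
    n_notes: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "subset": self.subset_label,
                "method": self.method,
                "seed": self.seed,
                "n_notes": self.n_notes,
                "full_r2": self.full_r2,
                "delta_r2": self.delta_r2,
            },
            indent=1,
        )


def _cv(X, y, method, k, reps, seed, svr_config) -> CvResult:
    return cross_validate(
        X, y, method=method, k=k, reps=reps, seed=seed, svr_config=svr_config
    )


def group_contribution(
    X: pd.DataFrame,
    y,
    groups: dict[str, list[str]],
    method: str = "mlr",
    seed: int = 0,
    k: int = 10,
    reps: int = 10,
    svr_config: SvrConfig | None = None,
    subset_label: str = "all",
) -> AblationReport:
    """Cross-validated full-minus-reduced R² per feature group.

    A group whose columns are absent or all-zero contributes ΔR² = 0 (with a
    warning).  The same seed drives the fold partitions of the full and every
    reduced model.
    """
    assigned = [c for cols in groups.values() for c in cols]
    if len(assigned) != len(set(assigned)):
        raise PredictError("feature columns assigned to more than one group")
    full = _cv(X, y, method, k, reps, seed, svr_config)
    delta: dict[str, float] = {}
    for g, cols in groups.items():
        present = [c for c in cols if c in X.columns]
        informative = [c for c in present if X[c].to_numpy().std() > 0]
        if not informative:
            warnings.warn(f"group {g!r} has no informative columns; delta R2 = 0")
            delta[g] = 0.0
            continue
        reduced_cols = [c for c in X.columns if c not in cols]
        reduced = _cv(X[reduced_cols], y, method, k, reps, seed, svr_config)
        delta[g] = full.mean_r2 - reduced.mean_r2
    return AblationReport(
        full_r2=full.mean_r2,
        delta_r2=delta,
        subset_label=subset_label,
        method=method,
        seed=seed,
        n_notes=len(X),
    )


def subset_analysis(
    X: pd.DataFrame,
    y: pd.Series,
    labels: pd.Series,
    groups: dict[str, list[str]],
    method: str = "mlr",
    seed: int = 0,
    k: int = 10,
    reps: int = 10,
    svr_config: SvrConfig | None = None,
) -> list[AblationReport]:
    """Run the fit + ablation pipeline within each label subset (style or
    genre) independently; subsets too small for k folds (fewer than 5 notes
    per fold) are skipped."""
    reports = []
    for label in sorted(pd.unique(labels)):
        mask = (labels == label).to_numpy()
        if mask.sum() < 5 * k:
            warnings.warn(
                f"subset {label!r} has {int(mask.sum())} notes < 5k={5*k}; skipped"
            )
            continue
        reports.append(
            group_contribution(
                X[mask], np.asarray(y)[mask], groups,
                method=method, seed=seed, k=k, reps=reps,
                svr_config=svr_config, subset_label=str(label),
            )
        )
    return reports


@dataclass
class RaterModelReport:
    per_rater_r2: dict[str, float]
    per_rater_delta: dict[str, dict[str, float]]
    threshold: float
    membership_r_pb: float | None
    expertise_r: float | None
    r2_convention: str = "variance_ratio"

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_rater_r2": self.per_rater_r2,
                "per_rater_delta_r2": self.per_rater_delta,
                "threshold": self.threshold,
                "membership_point_biserial": self.membership_r_pb,
                "expertise_r": self.expertise_r,
                "r2_convention": self.r2_convention,
            },
            indent=1,
        )


def per_rater_models(
    X: pd.DataFrame,
    ratings: pd.DataFrame,
    groups: dict[str, list[str]],
    optimized_set: list | None = None,
    expertise: pd.Series | None = None,
    threshold: float = 0.20,
    method: str = "mlr",
    seed: int = 0,
    k: int = 10,
    reps: int = 10,
    svr_config: SvrConfig | None = None,
) -> RaterModelReport:
    """Model each rater's own ratings; run the group ablation only for raters
    with cross-validated R² above ``threshold``.

    Per-rater R² uses the variance-ratio convention (1 − SSE/SStot on
    out-of-fold predictions), which can be negative for raters the model
    cannot predict; the aggregate analyses keep the squared-correlation
    convention.  Also reports the point-biserial correlation between
    optimized-group membership and R², and the Pearson correlation of
    expertise with R².
    """
    per_r2: dict[str, float] = {}
    per_delta: dict[str, dict[str, float]] = {}
    for rid in ratings.index:
        yr = ratings.loc[rid].to_numpy(dtype=float)
        if yr.std() == 0:
            warnings.warn(f"rater {rid!r} is constant; skipped")
            continue
        cv = cross_validate(
            X, yr, method=method, k=k, reps=reps, seed=seed,
            svr_config=svr_config, r2_convention="variance_ratio",
        )
        per_r2[str(rid)] = cv.mean_r2
        if cv.mean_r2 > threshold:
            per_delta[str(rid)] = group_contribution(
                X, yr, groups, method=method, seed=seed, k=k, reps=reps,
                svr_config=svr_config, subset_label=f"rater:{rid}",
            ).delta_r2

    r_pb = None
    if optimized_set is not None:
        member = np.array([1.0 if rid in set(optimized_set) else 0.0 for rid in ratings.index
                           if str(rid) in per_r2])
        r2s = np.array([per_r2[str(rid)] for rid in ratings.index if str(rid) in per_r2])
        if len(set(member)) == 2 and len(member) >= 3:
            r_pb = float(stats.pointbiserialr(member, r2s).statistic)
        else:
            warnings.warn("optimized-group membership degenerate; point-biserial undefined")
    exp_r = None
    if expertise is not None:
        ex = np.array([float(expertise[rid]) for rid in ratings.index if str(rid) in per_r2])
        r2s = np.array([per_r2[str(rid)] for rid in ratings.index if str(rid) in per_r2])
        if np.std(ex) > 0 and np.std(r2s) > 0:
            exp_r = float(np.corrcoef(ex, r2s)[0, 1])
    return RaterModelReport(
        per_rater_r2=per_r2,
        per_rater_delta=per_delta,
        threshold=threshold,
        membership_r_pb=r_pb,
        expertise_r=exp_r,
    )
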