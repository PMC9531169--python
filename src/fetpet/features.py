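"""Per-patient volumetric/uptake feature matrix and grade-separation ranking.

Each patient contributes, per isocontour level (40/50/60/70 %SUVmax), the
isocontour volume, its intersection and union with the MRI target volume,
conformity index, Dice, added volume and percent volume increase, plus the
MRI target volume, SUVmax, and SURmax. A resampled random-forest analysis
then asks which features dominate the separation of tumors by WHO grade:
over many stratified 80% subsamples, a forest of grade on the features is
fitted and permutation importance is measured on the held-out 20%; the
report gives each feature's mean importance and how often it ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .concordance import ConcordanceTable
from .suvquant import UptakeMetrics

__all__ = [
    "FeatureMatrix",
    "assemble_features",
    "rank_features_by_grade",
    "compare_groups_ranksum",
]

LEVEL_COLUMNS = ("petvol_ml", "intersection_ml", "union_ml", "ci", "dice",
                 "added_volume_ml", "pct_increase")
PATIENT_COLUMNS = ("mrivol_ml", "suvmax", "surmax")


@dataclass
class FeatureMatrix:
    """Patients x features, with grade labels and a z-scaled copy.

    z-scaling uses the population standard deviation (ddof 0); constant
    columns are flagged and excluded from the scaled copy.
    """

    data: pd.DataFrame
    grade: pd.Series
    zscored: pd.DataFrame
    constant_columns: list[str]

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)


def assemble_features(tables: list[ConcordanceTable],
                      metrics: Mapping[str, UptakeMetrics],
                      grades: Mapping[str, int]) -> FeatureMatrix:
    """Join concordance tables, uptake metrics, and grades into one matrix.

    Every patient must be present in all three sources; the deterministic
    column order is, per ascending level, the seven overlap features, then
    mrivol_ml, suvmax, surmax.
    """
    patients = [t.patient for t in tables]
    missing = [p for p in patients if p not in metrics] + \
              [p for p in patients if p not in grades]
    if missing:
        raise ValueError(f"patients missing from metrics/grades: {sorted(set(missing))}")

    rows = {}
    for t in tables:
        row: dict[str, float] = {}
        for rec in sorted(t.records, key=lambda r: r.level_pct):
            tag = f"i{int(rec.level_pct)}"
            for col in LEVEL_COLUMNS:
                row[f"{col}_{tag}"] = getattr(rec, col)
        row["mrivol_ml"] = t.records[0].mrivol_ml
        m = metrics[t.patient]
        row["suvmax"] = m.suvmax
        row["surmax"] = m.surmax
        rows[t.patient] = row
    data = pd.DataFrame.from_dict(rows, orient="index")
    levels = sorted({r.level_pct for t in tables for r in t.records})
    order = [f"{col}_i{int(l)}" for l in levels for col in LEVEL_COLUMNS] + list(PATIENT_COLUMNS)
    data = data[order]
    if data.isna().any().any():
        raise ValueError("feature matrix contains missing values after assembly")

    sd = data.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    varying = [c for c in data.columns if c not in constant]
    zscored = (data[varying] - data[varying].mean()) / sd[varying]
    grade = pd.Series({p: int(grades[p]) for p in data.index}, name="grade")
    return FeatureMatrix(data=data, grade=grade, zscored=zscored,
                         constant_columns=constant)


def _permutation_importance(clf, X_test: np.ndarray, y_test: np.ndarray,
                            n_repeats: int, rng: np.random.Generator) -> np.ndarray:
    """Held-out permutation importance: accuracy drop when one column is
    shuffled, averaged over repeats. All permuted copies are stacked into a
    single predict call, which keeps the resampling loop fast."""
    n, k = X_test.shape
    stacks = []
    for j in range(k):
        for _ in range(n_repeats):
            Xp = X_test.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            stacks.append(Xp)
    preds = clf.predict(np.vstack([X_test] + stacks))
    baseline = float(np.mean(preds[:n] == y_test))
    perm = preds[n:].reshape(k, n_repeats, n)
    perm_acc = (perm == y_test[None, None, :]).mean(axis=(1, 2))
    return baseline - perm_acc


def rank_features_by_grade(fm: FeatureMatrix, n_resamples: int = 200,
                           seed: int = 0, n_estimators: int = 100,
                           subsample_fraction: float = 0.8,
                           n_permutation_repeats: int = 5) -> pd.DataFrame:
    """Resampled random-forest permutation-importance ranking by grade.

    Each resample draws a stratified ``subsample_fraction`` of patients
    without replacement, fits a random forest of grade on the (unscaled)
    features, and measures permutation importance on the held-out
    patients. Returns a frame indexed by feature with ``mean_importance``
    and ``top_rank_frequency`` (how often the feature ranked first),
    sorted by mean importance descending. Deterministic given the seed.
    """
    X = fm.data.to_numpy(float)
    y = fm.grade.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 grades to rank separating features")
    if counts.min() < 5:
        raise ValueError("need at least 5 patients per grade")

    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    importance_sum = np.zeros(n_feat)
    top_counts = np.zeros(n_feat)
    for _ in range(n_resamples):
        train_idx = []
        for cls in classes:
            members = np.flatnonzero(y == cls)
            k = max(1, int(np.floor(subsample_fraction * len(members))))
            k = min(k, len(members) - 1)  # keep at least one held-out per grade
            train_idx.extend(rng.choice(members, size=k, replace=False))
        train_idx = np.array(sorted(train_idx))
        test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
        rs = int(rng.integers(0, 2**31 - 1))
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=rs)
        clf.fit(X[train_idx], y[train_idx])
        imp = _permutation_importance(clf, X[test_idx], y[test_idx],
                                      n_permutation_repeats, rng)
        importance_sum += imp
        top_counts[int(np.argmax(imp))] += 1  # ties -> first in canonical order

    out = pd.DataFrame({
        "mean_importance": importance_sum / n_resamples,
        "top_rank_frequency": top_counts / n_resamples,
    }, index=fm.feature_names)
    out.index.name = "feature"
    return out.sort_values("mean_importance", ascending=False, kind="stable")


def compare_groups_ranksum(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) two-group comparison.

    Exact enumeration when n1 + n2 <= 12 with no ties; otherwise the
    normal approximation with tie-corrected variance (no continuity
    correction, so identical samples give p = 1 exactly).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = alternative.replace("_", "-")
    if alt not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    if x.size + y.size <= 12 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative=alt, method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative=alt, method="asymptotic",
                                 use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))
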