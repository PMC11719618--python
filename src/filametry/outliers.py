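"""Robust outlier screening and per-group descriptive summaries.

Colony f-measure distributions are right-skewed and occasionally salted
with gross measurement failures (mis-segmented images, neighbouring
colonies). Screening follows the Iglewicz-Hoaglin modified z-score

    M_i = 0.6745 * (x_i - median) / MAD,

with values |M_i| > 3.5 excluded. The MAD (median absolute deviation about
the median) makes the score location-scale robust; when MAD = 0 the scale
falls back to 1.253314 x the mean absolute deviation about the median, and
when that is also zero (all values identical) every score is 0.

Screening is applied once per experimental group (strain x compound x
concentration), a single pass with no iterative re-screening; an
``iterative`` mode that re-screens survivors until stable is available on
the estimator. ``summarize_groups`` then reports post-exclusion n, sample
mean and sample SD (n-1 denominator) per group.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin

__all__ = [
    "ModifiedZScoreFilter",
    "modified_z",
    "filter_outliers",
    "summarize_groups",
    "screen_table",
]

MAD_CONSISTENCY = 0.6745  # Phi^{-1}(0.75): MAD -> sigma for a normal
MEANAD_CONSISTENCY = 1.253314  # sqrt(pi/2): mean AD -> sigma fallback

GROUP_COLS = ("strain", "compound", "concentration_uM")


def modified_z(values: Sequence[float]) -> np.ndarray:
    """Iglewicz-Hoaglin modified z-scores of a sample.

    Requires at least 3 values (median/MAD are not meaningful for
    exclusion below that). Invariant under positive affine transforms.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 3:
        raise ValueError(f"need >= 3 values for modified z-scores, got {x.size}")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        return MAD_CONSISTENCY * dev / mad
    mean_ad = np.mean(np.abs(dev))
    if mean_ad > 0:
        return dev / (MEANAD_CONSISTENCY * mean_ad)
    return np.zeros_like(x)


def filter_outliers(
    values: Sequence[float], threshold: float = 3.5
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass modified z-score screening; returns (kept, removed).

    A value is removed when |M_i| strictly exceeds ``threshold``. No
    iterative re-screening: the scores are computed once on the full
    sample.
    """
    x = np.asarray(values, dtype=float)
    scores = modified_z(x)
    out = np.abs(scores) > threshold
    return x[~out], x[out]


class ModifiedZScoreFilter(BaseEstimator, OutlierMixin):
    """Modified z-score outlier detector with the sklearn outlier API.

    ``fit`` learns the robust centre (median) and scale from the training
    sample; ``predict`` labels values +1 (inlier) / -1 (outlier) at
    ``|M| > threshold``. ``fit_predict(X)`` therefore performs the
    single-pass screening; with ``iterative=True`` survivors are
    re-screened until the exclusion set stabilises.

    Parameters
    ----------
    threshold : float, default 3.5
        Exclusion cut on |M|, strict inequality.
    iterative : bool, default False
        Re-screen the kept values until no further exclusions.
    """

    def __init__(self, threshold: float = 3.5, iterative: bool = False):
        self.threshold = threshold
        self.iterative = iterative

    @staticmethod
    def _center_scale(x: np.ndarray) -> tuple[float, float]:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        if mad > 0:
            return med, mad / MAD_CONSISTENCY
        mean_ad = float(np.mean(np.abs(x - med)))
        if mean_ad > 0:
            return med, MEANAD_CONSISTENCY * mean_ad
        return med, np.inf  # all identical: nothing can score as an outlier

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 3:
            raise ValueError("need >= 3 values to fit the outlier filter")
        self.center_, self.scale_ = self._center_scale(x)
        self.n_features_in_ = 1
        return self

    def score_samples(self, X) -> np.ndarray:
        """Negative |modified z|: higher means more inlying."""
        x = np.asarray(X, dtype=float).ravel()
        return -np.abs((x - self.center_) / self.scale_)

    def predict(self, X) -> np.ndarray:
        return np.where(-self.score_samples(X) > self.threshold, -1, 1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        labels = self.fit(x).predict(x)
        if self.iterative:
            while True:
                kept = labels == 1
                if kept.sum() < 3:
                    break
                self.fit(x[kept])
                new = self.predict(x)
                new[~kept] = -1  # once excluded, stays excluded
                if np.array_equal(new, labels):
                    break
                labels = new
        return labels


def screen_table(
    table: pd.DataFrame,
    threshold: float = 3.5,
    group_cols: Sequence[str] = GROUP_COLS,
    value_col: str = "f",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-group screening to a measurement table.

    Returns (kept_table, exclusion_log). Groups with fewer than 3 raw
    values are passed through unscreened and appear in the log with a
    ``flagged`` marker. The exclusion log records colony_id, group keys,
    score and whether the value was excluded.
    """
    group_cols = [c for c in group_cols if c in table.columns]
    kept_parts, log_rows = [], []
    for key, grp in table.groupby(group_cols, sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        x = grp[value_col].to_numpy(dtype=float)
        if len(x) < 3:
            kept_parts.append(grp)
            for cid in grp.get("colony_id", pd.Series([""] * len(grp))):
                log_rows.append(
                    dict(zip(group_cols, key))
                    | {"colony_id": cid, "score": np.nan, "excluded": False, "flagged": True}
                )
            continue
        scores = modified_z(x)
        excl = np.abs(scores) > threshold
        kept_parts.append(grp.loc[~excl])
        ids = grp["colony_id"] if "colony_id" in grp else pd.Series([""] * len(grp), index=grp.index)
        for cid, sc, ex in zip(ids, scores, excl):
            log_rows.append(
                dict(zip(group_cols, key))
                | {"colony_id": cid, "score": float(sc), "excluded": bool(ex), "flagged": False}
            )
    kept = pd.concat(kept_parts, ignore_index=True) if kept_parts else table.iloc[:0]
    log = pd.DataFrame(log_rows)
    return kept, log


def summarize_groups(
    table: pd.DataFrame,
    threshold: float = 3.5,
    group_cols: Sequence[str] = GROUP_COLS,
    value_col: str = "f",
) -> pd.DataFrame:
    """Per-group descriptive summary after outlier exclusion.

    One row per (strain, compound, concentration): post-exclusion n,
    sample mean, sample SD (n-1 denominator), number excluded, and a
    ``flagged`` marker for groups too small to screen (< 3 raw values).
    """
    group_cols = [c for c in group_cols if c in table.columns]
    rows = []
    for key, grp in table.groupby(group_cols, sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        x = grp[value_col].to_numpy(dtype=float)
        flagged = len(x) < 3
        if flagged:
            kept = x
        else:
            kept, _ = filter_outliers(x, threshold)
        rows.append(
            dict(zip(group_cols, key))
            | {
                "n": len(kept),
                "mean_f": float(np.mean(kept)) if len(kept) else np.nan,
                "sd_f": float(np.std(kept, ddof=1)) if len(kept) >= 2 else np.nan,
                "n_excluded": len(x) - len(kept),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
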