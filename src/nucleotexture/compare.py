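"""Group statistics: mean ± SD per class and Mann–Whitney U per feature.

Each ROI is treated as an independent observation (pseudo-replication
across the ~100 ROIs per animal is acknowledged, not corrected — the
per-animal structure is carried in the feature table for users who want
a mixed model). The test is two-sided; p-values are reported raw and
Holm-adjusted. Undefined feature values (NaN correlation from
degenerate ROIs) are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "summarize_groups", "mann_whitney", "SUMMARY_COLUMNS"]

SUMMARY_COLUMNS = (
    "feature", "mean_ctrl", "sd_ctrl", "mean_aki", "sd_aki",
    "U", "p", "p_holm", "n_ctrl", "n_aki", "n_excluded",
)


@dataclass(frozen=True)
class GroupSummary:
    """Per-feature descriptive statistics and the two-group test."""

    feature: str
    mean_ctrl: float
    sd_ctrl: float
    mean_aki: float
    sd_aki: float
    u_statistic: float
    p_value: float
    p_holm: float
    n_ctrl: int
    n_aki: int
    n_excluded: int


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U for samples ``x`` vs ``y``.

    Returns (U, p) with U the statistic of ``x``. Exact enumeration when
    both samples have ≤ 12 observations and no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, family-wise error control)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def summarize_groups(features: pd.DataFrame, feature_columns: list[str] | None = None) -> list[GroupSummary]:
    """Summarize every feature column of a per-ROI feature table.

    ``features`` must carry a binary ``group`` column (1 = AKI,
    0 = control) and numeric feature columns. Raises ``ValueError`` if a
    group has fewer than two defined observations for some feature.
    """
    if "group" not in features.columns:
        raise ValueError("feature table must have a 'group' column")
    if feature_columns is None:
        skip = {"roi_id", "group", "animal_id"}
        feature_columns = [c for c in features.columns if c not in skip]

    ctrl = features[features["group"] == 0]
    aki = features[features["group"] == 1]

    rows = []
    for col in feature_columns:
        x = ctrl[col].to_numpy(dtype=float)
        y = aki[col].to_numpy(dtype=float)
        n_excluded = int(np.isnan(x).sum() + np.isnan(y).sum())
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"feature {col!r}: fewer than 2 defined observations in a group")
        u, p = mann_whitney(x, y)
        rows.append((col, x, y, u, p, n_excluded))

    p_holm = _holm(np.array([r[4] for r in rows]))
    out = []
    for (col, x, y, u, p, n_excluded), ph in zip(rows, p_holm):
        out.append(
            GroupSummary(
                feature=col,
                mean_ctrl=float(x.mean()),
                sd_ctrl=float(x.std(ddof=1)),
                mean_aki=float(y.mean()),
                sd_aki=float(y.std(ddof=1)),
                u_statistic=u,
                p_value=p,
                p_holm=float(ph),
                n_ctrl=len(x),
                n_aki=len(y),
                n_excluded=n_excluded,
            )
        )
    return out


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Render summaries as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            (s.feature, s.mean_ctrl, s.sd_ctrl, s.mean_aki, s.sd_aki,
             s.u_statistic, s.p_value, s.p_holm, s.n_ctrl, s.n_aki, s.n_excluded)
            for s in summaries
        ],
        columns=list(SUMMARY_COLUMNS),
    )
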