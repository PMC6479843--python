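"""Cohort summaries and Mann-Whitney group comparison.

Each feature is compared between hemiparetic (HP) and healthy-control (HC)
trials with the two-sided Mann-Whitney U test: exact permutation p-value
for small tie-free samples (n_a + n_b <= 16), normal approximation with tie
and continuity correction otherwise.  Differences are flagged significant
at p < 0.05.  No multiplicity correction is applied across the three
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ParameterError

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ("symmetry_dtw", "sampen", "stability_index")
EXACT_MAX_N = 16
ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Per-feature HP-vs-HC summary: means +/- SD, U and two-sided p."""

    feature_name: str
    mean_hp: float
    sd_hp: float
    mean_hc: float
    sd_hc: float
    u_statistic: float
    p_value: float
    n_hp: int
    n_hc: int
    n_dropped: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (of the first sample) and two-sided p-value.

    The exact permutation distribution is used when the pooled sample is
    small (<= 16) and tie-free; otherwise the normal approximation with tie
    correction and continuity correction.  ``U(a, b) + U(b, a) = n_a * n_b``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ParameterError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def summarize(
    features: pd.DataFrame,
    feature_columns=FEATURE_COLUMNS,
    per_subject: bool = False,
) -> list[GroupComparison]:
    """One :class:`GroupComparison` per feature column of a feature table.

    The table needs ``group`` in {HP, HC} plus the feature columns.  Rows
    with a missing value in a feature are excluded from that feature's
    comparison (the count is logged).  With ``per_subject=True`` trials are
    first averaged within subject, so each subject contributes one
    observation (trials of one subject are not independent).
    """
    if per_subject:
        features = (
            features.groupby(["subject_id", "group"], as_index=False)[list(feature_columns)]
            .mean()
        )
    groups = set(features["group"].unique())
    if not {"HP", "HC"} <= groups:
        raise ParameterError(f"feature table must contain both HP and HC rows, has {groups}")
    out: list[GroupComparison] = []
    for col in feature_columns:
        sub = features[["group", col]].dropna()
        n_dropped = len(features) - len(sub)
        if n_dropped:
            log.warning("%s: excluded %d rows with missing values", col, n_dropped)
        hp = sub.loc[sub["group"] == "HP", col].to_numpy()
        hc = sub.loc[sub["group"] == "HC", col].to_numpy()
        if hp.size == 0 or hc.size == 0:
            raise ParameterError(f"{col}: one group has no finite values")
        u, p = mann_whitney(hp, hc)
        out.append(
            GroupComparison(
                feature_name=col,
                mean_hp=float(np.mean(hp)),
                sd_hp=float(np.std(hp, ddof=1)) if hp.size > 1 else 0.0,
                mean_hc=float(np.mean(hc)),
                sd_hc=float(np.std(hc, ddof=1)) if hc.size > 1 else 0.0,
                u_statistic=u,
                p_value=p,
                n_hp=int(hp.size),
                n_hc=int(hc.size),
                n_dropped=n_dropped,
            )
        )
    return out


def comparison_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabular view of group comparisons (feature, means, SDs, p)."""
    return pd.DataFrame(
        [
            {
                "feature": c.feature_name,
                "hp_mean": c.mean_hp,
                "hp_sd": c.sd_hp,
                "hc_mean": c.mean_hc,
                "hc_sd": c.sd_hc,
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
            }
            for c in comparisons
        ]
    )
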