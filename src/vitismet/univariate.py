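"""Feature-wise group comparison and discriminatory-feature selection.

For every aligned spectral feature a two-sided t-test (Welch by default)
compares the resistant/partial-resistant and susceptible groups on the
variance-stabilized (glog) intensities; p-values are Benjamini-Hochberg
adjusted.  The fold change is the ratio of group mean intensities on the
normalized (pre-glog) scale, oriented resistant/susceptible so positive
log2FC means more abundant in the resistant group.  A feature is
discriminatory when adjusted p < alpha and |log2FC| >= fc_cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peaks import RESISTANT, SUSCEPTIBLE, FeatureMatrix, validate_metadata


def group_ttests(
    m: FeatureMatrix, meta: pd.DataFrame, equal_var: bool = False
) -> pd.DataFrame:
    """Per-feature two-sided t statistics and p-values (Welch unless equal_var).

    Features whose statistic is undefined (zero variance in both groups
    of size 2) get NaN p-values and are later excluded from FDR
    adjustment.
    """
    meta = validate_metadata(meta, m.sample_ids)
    groups = meta.set_index("sample_id")["group"]
    res_cols = [s for s in m.sample_ids if groups[s] == RESISTANT]
    sus_cols = [s for s in m.sample_ids if groups[s] == SUSCEPTIBLE]
    if len(res_cols) < 2 or len(sus_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = m.data[res_cols].to_numpy()
    b = m.data[sus_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    return pd.DataFrame({"t_statistic": t, "p_value": p},
                        index=pd.Index(m.feature_mz, name="feature_mz"))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unadjusted."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def univariate_stats(
    m_norm: FeatureMatrix,
    m_test: FeatureMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.01,
    fc_cut: float = 1.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Full per-feature statistics table.

    ``m_norm`` supplies the intensities for the fold change (normalized
    stage); ``m_test`` supplies the values the t-tests run on (glog or
    pareto stage).  Both must share the same features and samples.
    """
    if not np.array_equal(m_norm.feature_mz, m_test.feature_mz):
        raise ValueError("matrices have different feature sets")
    if m_norm.sample_ids != m_test.sample_ids:
        raise ValueError("matrices have different sample sets")
    meta = validate_metadata(meta, m_norm.sample_ids)
    groups = meta.set_index("sample_id")["group"]
    res_cols = [s for s in m_norm.sample_ids if groups[s] == RESISTANT]
    sus_cols = [s for s in m_norm.sample_ids if groups[s] == SUSCEPTIBLE]

    tests = group_ttests(m_test, meta, equal_var=equal_var)
    mean_res = m_norm.data[res_cols].mean(axis=1).to_numpy()
    mean_sus = m_norm.data[sus_cols].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore"):
        log2fc = np.log2(mean_res / mean_sus)

    stats_df = pd.DataFrame({
        "feature_mz": m_norm.feature_mz,
        "mean_resistant": mean_res,
        "mean_susceptible": mean_sus,
        "log2fc": log2fc,
        "t_statistic": tests["t_statistic"].to_numpy(),
        "p_value": tests["p_value"].to_numpy(),
    })
    stats_df["p_adjusted"] = bh_adjust(stats_df["p_value"])
    stats_df["discriminatory"] = (
        (stats_df["p_adjusted"] < alpha) & (stats_df["log2fc"].abs() >= fc_cut)
    ).fillna(False)
    return stats_df


def select_discriminatory(
    stats_df: pd.DataFrame, alpha: float = 0.01, fc_cut: float = 1.0
) -> pd.DataFrame:
    """Subset of features with adjusted p < alpha and |log2FC| >= fc_cut."""
    mask = (stats_df["p_adjusted"] < alpha) & (stats_df["log2fc"].abs() >= fc_cut)
    return stats_df[mask.fillna(False)].copy()


def summarize(stats_df: pd.DataFrame, alpha: float = 0.01, fc_cut: float = 1.0) -> dict:
    """Counts of tested, FDR-passing and fully discriminatory features."""
    tested = int(stats_df["p_value"].notna().sum())
    pass_fdr = int((stats_df["p_adjusted"] < alpha).sum())
    pass_both = int(((stats_df["p_adjusted"] < alpha)
                     & (stats_df["log2fc"].abs() >= fc_cut)).sum())
    return {"tested": tested, "passing_fdr": pass_fdr, "discriminatory": pass_both}
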