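"""Donor-blocked differential expression / accessibility and PCA overview.

Each donor contributes one sample per arm of a contrast, so a donor-blocked
(random-intercept) model reduces exactly to a paired t test on per-donor
log-CPM differences.  That paired test is used here: it is the canonical
special case of a donor-random-effect linear mixed model for this balanced
one-observation-per-cell design, and it is exact at small n.

Sign convention: log2fc < 0 means the feature is lower in ``treatment_a``
than in ``treatment_b``.  Multiple-testing correction is Benjamini-Hochberg
within each contrast (each contrast is its own inference family).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["normalize_log_cpm", "paired_contrast", "pca_overview"]


def normalize_log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2((count + 0.5) / library_size * 1e6), library size = column sum."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("library size must be positive for every sample")
    return np.log2((counts + 0.5).div(lib, axis=1) * 1e6)


def paired_contrast(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
    min_donors: int = 3,
) -> pd.DataFrame:
    """Paired (donor-blocked) t test of treatment_a vs treatment_b.

    For each feature, per-donor differences (arm a minus arm b) are formed
    at the stated timepoint; the statistic is the paired t with
    ``n_donors - 1`` degrees of freedom, and log2fc is the mean paired
    difference.  Donors missing one arm are dropped with a warning; fewer
    than ``min_donors`` complete donors refuses the contrast.  Features with
    zero-variance differences get p = 1 by convention.

    Returns a DataFrame indexed by feature with columns log2fc, stat,
    pvalue, qvalue, treatment_a, treatment_b, timepoint.
    """
    trt_a, trt_b, timepoint = contrast
    sub = design[design["timepoint"] == timepoint]
    arm_a = sub[sub["treatment"] == trt_a].set_index("donor")["sample_id"]
    arm_b = sub[sub["treatment"] == trt_b].set_index("donor")["sample_id"]
    if arm_a.index.has_duplicates or arm_b.index.has_duplicates:
        raise ValueError("multiple samples per donor per arm are not supported")
    donors = sorted(set(arm_a.index) & set(arm_b.index))
    dropped = sorted((set(arm_a.index) | set(arm_b.index)) - set(donors))
    if dropped:
        log.warning("dropping donors missing one arm of %s: %s", contrast, dropped)
    if len(donors) < min_donors:
        raise ValueError(
            f"contrast {contrast} refused: only {len(donors)} complete donors "
            f"(need >= {min_donors})"
        )
    diffs = (
        logcpm[arm_a.loc[donors].tolist()].to_numpy()
        - logcpm[arm_b.loc[donors].tolist()].to_numpy()
    )
    n = len(donors)
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    t[zero_var] = 0.0
    p[zero_var] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": mean,
            "stat": t,
            "pvalue": p,
            "qvalue": q,
            "treatment_a": trt_a,
            "treatment_b": trt_b,
            "timepoint": timepoint,
        },
        index=pd.Index(logcpm.index, name="feature_id"),
    )


def pca_overview(logcpm: pd.DataFrame, n_top: int = 1000) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over the top variable features.

    Features are ranked by variance across samples; the top ``n_top`` are
    centered per feature and decomposed by SVD.  Returns (sample x PC
    coordinates, per-PC variance ratios).
    """
    var = logcpm.var(axis=1)
    top = var.sort_values(ascending=False, kind="stable").index[: min(n_top, len(var))]
    x = logcpm.loc[top].to_numpy().T  # samples x features
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u * s
    denom = (x ** 2).sum()
    ratios = (s ** 2) / denom if denom > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=logcpm.columns, columns=cols), ratios
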