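"""Weighted co-expression network modules, eigengenes and enrichment.

Follows the standard weighted-network workflow: soft-threshold an unsigned
correlation network so it is approximately scale-free, convert adjacency to
topological overlap (TOM), cluster 1 - TOM by average linkage, cut the tree
statically, and summarize each module by its eigengene (first principal
component of the standardized module expression, sign-aligned with the
module mean profile).

The static cut is placed at ``cut_height_quantile`` times the maximum merge
height of the dendrogram (the cutreeStatic convention); clusters smaller
than ``min_module_size`` are left unassigned (module 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoexprModule",
    "adjacency",
    "pick_soft_power",
    "topological_overlap",
    "detect_modules",
    "module_treatment_coefficients",
    "enrich_modules_in_regions",
]

ODDS_RATIO_CAP = 1.0e6  # sentinel for infinite odds ratios


@dataclass
class CoexprModule:
    module_id: int
    gene_ids: list[str]
    eigengene: pd.Series  # per-sample


def adjacency(logcpm: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|**power (genes x genes)."""
    if len(logcpm) < 2:
        raise ValueError("network undefined for fewer than 2 genes")
    cor = np.corrcoef(logcpm.to_numpy())
    cor = np.nan_to_num(cor, nan=0.0)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit index over connectivity bins.

    Squared correlation of log10 p(k) vs log10 mean k, negated when the
    slope is positive: a degree distribution that *increases* with k is the
    opposite of scale-free and must not satisfy the target.
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    logp, logk = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        logp.append(np.log10(mask.mean()))
        logk.append(np.log10(k[mask].mean()))
    if len(logp) < 3:
        return 0.0
    r = np.corrcoef(logk, logp)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(-np.sign(r) * r ** 2)


def pick_soft_power(
    logcpm: pd.DataFrame,
    powers: range = range(1, 21),
    target_r2: float = 0.8,
) -> int:
    """Smallest soft power giving scale-free fit R^2 >= target, else argmax."""
    cor = np.corrcoef(logcpm.to_numpy()) if len(logcpm) >= 2 else None
    if cor is None:
        raise ValueError("network undefined for a single gene")
    cor = np.abs(np.nan_to_num(cor, nan=0.0))
    np.fill_diagonal(cor, 0.0)
    best_beta, best_r2 = None, -1.0
    for beta in powers:
        k = (cor ** beta).sum(axis=1)
        r2 = _scale_free_r2(k)
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
        if r2 >= target_r2:
            return int(beta)
    return int(best_beta)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij); TOM_ii = 1."""
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    logcpm: pd.DataFrame,
    power: int | str = 6,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
) -> list[CoexprModule]:
    """Detect co-expression modules by TOM-based average-linkage clustering.

    Modules are labelled 1..K in decreasing size order; genes in clusters
    below ``min_module_size`` (or when there are fewer genes than that) go
    to module 0.  Gene input order does not affect the partition: genes are
    processed in sorted-id order and scipy's linkage resolves equal-height
    merges deterministically on that ordering.
    """
    logcpm = logcpm.sort_index(kind="stable")
    gene_ids = list(logcpm.index)
    if len(gene_ids) < 2 or len(gene_ids) < min_module_size:
        eig = _eigengene(logcpm) if len(gene_ids) else pd.Series(dtype=float)
        return [CoexprModule(0, gene_ids, eig)]
    if power == "auto":
        power = pick_soft_power(logcpm)
    a = adjacency(logcpm, power)
    tom = topological_overlap(a)
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    heights = z[:, 2]
    cut = cut_height_quantile * heights.max() if heights.max() > 0 else 0.0
    labels = fcluster(z, t=cut, criterion="distance")

    by_label: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(i)
    big = sorted(
        (idx for idx in by_label.values() if len(idx) >= min_module_size),
        key=lambda idx: (-len(idx), gene_ids[idx[0]]),
    )
    modules: list[CoexprModule] = []
    assigned: set[int] = set()
    for mid, idx in enumerate(big, start=1):
        sub = logcpm.iloc[idx]
        modules.append(CoexprModule(mid, list(sub.index), _eigengene(sub)))
        assigned.update(idx)
    leftover = [i for i in range(len(gene_ids)) if i not in assigned]
    if leftover:
        sub = logcpm.iloc[leftover]
        modules.insert(0, CoexprModule(0, list(sub.index), _eigengene(sub)))
    return modules


def _eigengene(sub: pd.DataFrame) -> pd.Series:
    """First PC of standardized module expression, aligned with the mean profile."""
    x = sub.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=sub.columns)


def module_treatment_coefficients(
    modules: list[CoexprModule],
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
) -> pd.DataFrame:
    """Donor-paired regression of each eigengene on a treatment contrast.

    The coefficient is the mean within-donor eigengene difference
    (treatment_a minus treatment_b at the stated timepoint) with its
    standard error and two-sided paired-t p value.
    """
    trt_a, trt_b, timepoint = contrast
    sub = design[design["timepoint"] == timepoint]
    arm_a = sub[sub["treatment"] == trt_a].set_index("donor")["sample_id"]
    arm_b = sub[sub["treatment"] == trt_b].set_index("donor")["sample_id"]
    donors = sorted(set(arm_a.index) & set(arm_b.index))
    if len(donors) < 3:
        raise ValueError(f"contrast {contrast}: fewer than 3 complete donors")
    rows = []
    for mod in modules:
        d = (
            mod.eigengene[arm_a.loc[donors].tolist()].to_numpy()
            - mod.eigengene[arm_b.loc[donors].tolist()].to_numpy()
        )
        n = len(d)
        coef = d.mean()
        se = d.std(ddof=1) / np.sqrt(n)
        if se == 0:
            stat, p = 0.0, 1.0
            se = np.finfo(float).tiny
        else:
            stat = coef / se
            p = 2.0 * stats.t.sf(abs(stat), df=n - 1)
        rows.append((mod.module_id, trt_a, trt_b, timepoint, coef, se, p))
    return pd.DataFrame(
        rows,
        columns=["module_id", "treatment_a", "treatment_b", "timepoint", "coefficient", "se", "pvalue"],
    )


def enrich_modules_in_regions(
    modules: list[CoexprModule],
    region_genes: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact enrichment of each module in a gene set.

    The universe is the union of genes across all modules (including module
    0).  The Bonferroni cutoff is ``alpha / number of modules tested``
    (module 0 is not tested).  Infinite odds ratios are reported as the
    capped sentinel 1e6.
    """
    universe = set()
    for m in modules:
        universe.update(m.gene_ids)
    region = region_genes & universe
    tested = [m for m in modules if m.module_id != 0]
    cutoff = alpha / len(tested) if tested else alpha
    rows = []
    for m in tested:
        in_mod = set(m.gene_ids)
        a = len(in_mod & region)
        b = len(in_mod) - a
        c = len(region) - a
        d = len(universe) - a - b - c
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if not np.isfinite(orr):
            orr = ODDS_RATIO_CAP
        rows.append((m.module_id, a, len(in_mod), orr, p, p < cutoff))
    return pd.DataFrame(
        rows,
        columns=["module_id", "n_overlap", "n_module", "odds_ratio", "pvalue", "bonferroni_significant"],
    ).assign(bonferroni_cutoff=cutoff)
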