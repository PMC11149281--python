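"""Minimal stratified LD-score regression over chromatin annotations.

Per-variant GWAS chi-square statistics are regressed on annotation-specific
LD scores:

    E[chi2_j] = 1 + N * sum_c tau_c * l(j, c),      l(j, c) = sum_k r2(j, k) * a_c(k)

estimated by ordinary least squares of (chi2 - 1) on {N * l(j, c)} with an
unsuppressed constant term.  The normalized coefficient is

    tau*_c = tau_c * M * sd(a_c) / h2_hat,          h2_hat = sum_c tau_c * M * mean(a_c)

with standard errors from a delete-one jackknife over contiguous
(position-ordered) variant blocks, and a one-sided p value for coefficient
positivity from the normal upper tail.  Study-level estimates are combined
by inverse-variance-weighted meta-analysis.

Compared with the full stratified LD-score machinery this omits the large
external baseline annotation set: conditioning is on an all-accessible-peaks
annotation plus the constant, which preserves the inferential claim that
the treatment-response annotation carries signal beyond accessible
chromatin at large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, Peak

log = logging.getLogger(__name__)

__all__ = [
    "Annotation",
    "LdscFit",
    "build_topk_annotation",
    "annotation_from_peaks",
    "compute_ld_scores",
    "fit_sldsc",
    "ivw_meta",
]


@dataclass
class Annotation:
    name: str
    regions: list[GenomicInterval]

    def membership(self, variants: pd.DataFrame) -> np.ndarray:
        """Boolean per-variant vector: position inside some region."""
        idx = {}
        for iv in self.regions:
            idx.setdefault(iv.chrom, []).append((iv.start, iv.end))
        bounds = {}
        for chrom, ivs in idx.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            bounds[chrom] = np.array(merged, dtype=np.int64).ravel()
        member = np.zeros(len(variants), dtype=bool)
        for chrom, b in bounds.items():
            mask = (variants["chrom"] == chrom).to_numpy()
            pos = variants.loc[mask, "pos"].to_numpy()
            member[mask] = np.searchsorted(b, pos, side="right") % 2 == 1
        return member


@dataclass
class LdscFit:
    annotations: list[str]
    tau: np.ndarray
    tau_star: np.ndarray
    se: np.ndarray          # jackknife se of tau_star
    tau_se: np.ndarray      # jackknife se of tau
    p_onesided: np.ndarray  # positivity of tau_star

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "annotation": self.annotations,
                "tau": self.tau,
                "tau_star": self.tau_star,
                "se": self.se,
                "tau_se": self.tau_se,
                "p_onesided": self.p_onesided,
            }
        )


def build_topk_annotation(
    diff_acc: pd.DataFrame,
    peaks: list[Peak],
    k: int = 15_000,
    name: str = "top_downregulated",
) -> Annotation:
    """Annotation of the top-k most down-regulated open chromatin regions.

    Peaks are ranked by accessibility log2 fold change ascending (most
    negative first), ties by p value ascending then peak id; the first
    ``min(k, available)`` peak intervals form the annotation.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    by_id = {p.peak_id: p for p in peaks}
    ranked = (
        diff_acc.reset_index()
        .rename(columns={diff_acc.index.name or "index": "feature_id"})
        .sort_values(["log2fc", "pvalue", "feature_id"], kind="stable")
    )
    if k > len(ranked):
        log.info("k=%d exceeds %d available peaks; using all", k, len(ranked))
    chosen = ranked["feature_id"].head(min(k, len(ranked)))
    return Annotation(name, [by_id[f].interval for f in chosen if f in by_id])


def annotation_from_peaks(peaks: list[Peak], name: str) -> Annotation:
    return Annotation(name, [p.interval for p in peaks])


def compute_ld_scores(
    variants: pd.DataFrame,
    ld: pd.DataFrame,
    annotations: list[Annotation],
) -> pd.DataFrame:
    """l(j, c) = sum_k r2(j, k) * member_c(k), including the self term (r2=1)."""
    m = len(variants)
    vid = variants["variant_id"].tolist()
    idx = {v: i for i, v in enumerate(vid)}
    r2 = np.eye(m)
    for a, b, r in ld[["variant_a", "variant_b", "r2"]].itertuples(index=False):
        if a in idx and b in idx:
            r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = max(r2[idx[a], idx[b]], float(r))
    out = {}
    for ann in annotations:
        out[ann.name] = r2 @ ann.membership(variants).astype(float)
    return pd.DataFrame(out, index=pd.Index(vid, name="variant_id"))


def fit_sldsc(
    chi2: np.ndarray | pd.Series,
    n_gwas: int,
    ld_scores: pd.DataFrame,
    annotations: list[Annotation],
    variants: pd.DataFrame,
    n_blocks: int = 20,
) -> LdscFit:
    """OLS fit of (chi2 - 1) on per-annotation LD scores with jackknife errors.

    Variants are position-ordered and cut into ``n_blocks`` contiguous
    jackknife blocks; tau and tau* are recomputed with each block deleted
    to form delete-one jackknife standard errors.  Annotation standard
    deviations / means in the tau* normalization are taken over the panel.
    """
    chi2 = np.asarray(chi2, dtype=float)
    m = len(chi2)
    if m < n_blocks:
        raise ValueError(f"{m} variants < {n_blocks} jackknife blocks")
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    names = [a.name for a in annotations]
    member = np.column_stack([a.membership(variants).astype(float) for a in annotations])
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    x = np.column_stack(
        [n_gwas * ld_scores[n].to_numpy() for n in names] + [np.ones(m)]
    )[order]
    y = (chi2 - 1.0)[order]
    mem_sd = member.std(axis=0)
    mem_mean = member.mean(axis=0)

    def solve(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta, *_ = np.linalg.lstsq(x[mask], y[mask], rcond=None)
        tau = beta[:-1]
        h2 = float(np.sum(tau * m * mem_mean))
        denom = h2 if abs(h2) > 1e-300 else 1e-300
        return tau, tau * m * mem_sd / denom

    full = np.ones(m, dtype=bool)
    tau, tau_star = solve(full)
    blocks = np.array_split(np.arange(m), n_blocks)
    jk_tau = np.empty((n_blocks, len(names)))
    jk_star = np.empty((n_blocks, len(names)))
    for b, blk in enumerate(blocks):
        mask = full.copy()
        mask[blk] = False
        jk_tau[b], jk_star[b] = solve(mask)
    fac = (n_blocks - 1) / n_blocks
    tau_se = np.sqrt(fac * ((jk_tau - jk_tau.mean(axis=0)) ** 2).sum(axis=0))
    star_se = np.sqrt(fac * ((jk_star - jk_star.mean(axis=0)) ** 2).sum(axis=0))
    star_se = np.where(star_se > 0, star_se, np.finfo(float).tiny)
    p = stats.norm.sf(tau_star / star_se)
    return LdscFit(names, tau, tau_star, star_se, np.where(tau_se > 0, tau_se, np.finfo(float).tiny), p)


def ivw_meta(coefs: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Inverse-variance-weighted meta-analysis of (estimate, se) pairs.

    Returns (estimate, se, one-sided upper-tail p).  With equal standard
    errors the estimate is the arithmetic mean.
    """
    if not coefs:
        raise ValueError("no coefficients to meta-analyze")
    est = np.array([c[0] for c in coefs], dtype=float)
    se = np.array([c[1] for c in coefs], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(stats.norm.sf(pooled / pooled_se))
    return pooled, pooled_se, p
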