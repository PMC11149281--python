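"""Activity-by-contact enhancer-gene mapping.

The ABC score of a candidate element e for gene g in one condition is

    ABC(e, g) = A(e) * C(e, g) / sum_e' A(e') * C(e', g)

where A is element activity (geometric mean of depth-normalized ATAC and
H3K27ac signal), C is Hi-C contact between the element's bin and the TSS
bin (observed count plus a distance-matched power-law pseudocount), and the
sum runs over all candidate elements of g (midpoint within a window of the
TSS on the same chromosome).  Scores therefore sum to one per gene;
pairs at or above a score threshold are flagged "called".

Defaults (5 Mb window, 0.02 threshold, combined ATAC + H3K27ac activity,
power-law pseudocount floor at 1 Mb) follow the documented defaults of the
upstream ABC method and are all configurable.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right

import numpy as np
import pandas as pd

from .io_formats import ContactMap, GeneAnnot, Peak

__all__ = [
    "element_activity",
    "cpm",
    "condition_activity",
    "fit_powerlaw",
    "element_gene_contact",
    "build_abc_map",
    "condition_specific_pairs",
    "nearest_tss_baseline",
]


def element_activity(atac: np.ndarray | float, h3k27ac: np.ndarray | float) -> np.ndarray | float:
    """Geometric mean of depth-normalized ATAC and H3K27ac signal."""
    a = np.asarray(atac, dtype=float)
    k = np.asarray(h3k27ac, dtype=float)
    if np.any(a < 0) or np.any(k < 0):
        raise ValueError("activity inputs must be non-negative")
    out = np.sqrt(a * k)
    return float(out) if out.ndim == 0 else out


def cpm(counts: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Counts per million within each sample (column)."""
    total = counts.sum(axis=0)
    return counts / total * 1e6


def condition_activity(
    atac: pd.DataFrame,
    h3k27ac: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    use_h3k27ac: bool = True,
) -> pd.Series:
    """Per-element activity for one treatment_timepoint condition.

    ATAC is averaged (in CPM) over the condition's samples; H3K27ac is the
    condition's single CPM profile.  With ``use_h3k27ac=False`` activity is
    ATAC CPM alone.
    """
    trt, tp = condition.rsplit("_", 1)
    samples = design.loc[
        (design["treatment"] == trt) & (design["timepoint"] == tp), "sample_id"
    ].tolist()
    if not samples:
        raise ValueError(f"no samples for condition {condition!r}")
    atac_cpm = cpm(atac[samples]).mean(axis=1)
    if not use_h3k27ac:
        return atac_cpm
    if condition not in h3k27ac.columns:
        raise ValueError(f"no H3K27ac profile for condition {condition!r}")
    k27_cpm = cpm(h3k27ac[condition])
    return pd.Series(
        element_activity(atac_cpm.to_numpy(), k27_cpm.reindex(atac_cpm.index).to_numpy()),
        index=atac_cpm.index,
    )


# ---------------------------------------------------------------------------
# contact model


class PowerLawFitError(ValueError):
    pass


def fit_powerlaw(
    contacts: ContactMap | dict[str, ContactMap],
    bin_size: int,
    d_min: int = 10_000,
    d_max: int = 1_000_000,
    n_bins: int | None = None,
) -> tuple[float, float]:
    """Least-squares power-law fit of contact decay: count ~ c0 * d**(-gamma).

    The mean count per distance is computed over *all* bin pairs at that
    distance (absent pairs count as zero), which requires the number of bins
    per chromosome; when ``n_bins`` is not given it is inferred from the
    largest bin index present.  Returns ``(c0, gamma)`` from regressing
    log(mean count) on log(distance) over distances in [d_min, d_max].
    """
    maps = contacts if isinstance(contacts, dict) else {"": contacts}
    lo, hi = d_min // bin_size, d_max // bin_size
    if hi < lo:
        raise PowerLawFitError("empty distance range")
    tot = np.zeros(hi - lo + 1)
    npairs = np.zeros(hi - lo + 1)
    for cm in maps.values():
        if len(cm) == 0:
            continue
        nb = n_bins
        if nb is None:
            nb = max(j for (_, j), _c in cm.items()) + 1
        for (i, j), c in cm.items():
            d = j - i
            if lo <= d <= hi:
                tot[d - lo] += c
        d_arr = np.arange(lo, hi + 1)
        npairs += np.maximum(nb - d_arr, 0)
    ok = npairs > 0
    mean = np.zeros_like(tot)
    mean[ok] = tot[ok] / npairs[ok]
    d_bp = np.arange(lo, hi + 1) * bin_size
    use = (mean > 0) & (d_bp > 0)
    if use.sum() < 10:
        raise PowerLawFitError(
            "fewer than 10 distances with positive mean count in range; "
            "increase synthetic sequencing depth or widen the range"
        )
    slope, intercept = np.polyfit(np.log(d_bp[use]), np.log(mean[use]), 1)
    return float(np.exp(intercept)), float(-slope)


def element_gene_contact(
    element: Peak,
    gene: GeneAnnot,
    contacts: ContactMap,
    bin_size: int,
    powerlaw: tuple[float, float],
    pseudocount_frac: float = 1.0,
    pseudocount_floor_bp: int = 1_000_000,
) -> float:
    """Contact between an element and a gene's TSS bin.

    Observed count plus a pseudocount equal to ``pseudocount_frac`` times
    the fitted power-law expectation at ``pseudocount_floor_bp`` (the curve
    floor).  Same-bin pairs use the fitted value at one bin size in place
    of the observed count.  Trans pairs (different chromosomes) have
    contact zero.
    """
    if element.interval.chrom != gene.chrom:
        return 0.0
    c0, gamma = powerlaw
    bi = element.interval.midpoint // bin_size
    bj = gene.tss // bin_size
    pseudo = pseudocount_frac * c0 * pseudocount_floor_bp ** (-gamma)
    if bi == bj:
        return c0 * bin_size ** (-gamma)
    return contacts.query(bi, bj) + pseudo


# ---------------------------------------------------------------------------
# map construction


def build_abc_map(
    elements: list[Peak],
    genes: list[GeneAnnot],
    activity: pd.Series,
    contacts: dict[str, ContactMap],
    bin_size: int,
    condition: str = "",
    window_bp: int = 5_000_000,
    threshold: float = 0.02,
    powerlaw: tuple[float, float] | None = None,
    pseudocount_frac: float = 1.0,
    promoter_window_bp: int = 500,
) -> pd.DataFrame:
    """Score all candidate element-gene pairs in one condition.

    For every gene, candidates are the elements whose midpoint lies within
    ``window_bp`` of the TSS on the same chromosome.  Scores are normalized
    within the candidate set; pairs with score >= ``threshold`` are flagged
    ``called``.  An element overlapping the TSS +/- ``promoter_window_bp``
    is treated as the gene's promoter: it contributes to the normalizing
    denominator but is never reported as an enhancer pair.  Genes whose
    candidates all have zero activity x contact get all-zero scores
    (degenerate, nothing called).

    Returns a DataFrame with columns element_id, chrom, start, end,
    gene_id, activity, contact, abc_score, called, condition.
    """
    if powerlaw is None:
        powerlaw = fit_powerlaw(contacts, bin_size)
    act = activity.to_numpy(dtype=float)
    el_index = {e: i for i, e in enumerate(activity.index)}

    by_chrom: dict[str, list[Peak]] = {}
    for p in elements:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    mids: dict[str, list[int]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.interval.midpoint)
        mids[chrom] = [p.interval.midpoint for p in plist]

    rows = []
    for g in genes:
        plist = by_chrom.get(g.chrom, [])
        if not plist:
            continue
        m = mids[g.chrom]
        lo = bisect_left(m, g.tss - window_bp)
        hi = bisect_right(m, g.tss + window_bp)
        cand = plist[lo:hi]
        if not cand:
            continue
        cm = contacts.get(g.chrom)
        if cm is None:
            continue
        a = np.array([act[el_index[p.peak_id]] for p in cand])
        c = np.array(
            [element_gene_contact(p, g, cm, bin_size, powerlaw, pseudocount_frac) for p in cand]
        )
        score_raw = a * c
        total = score_raw.sum()
        scores = score_raw / total if total > 0 else np.zeros_like(score_raw)
        is_prom = np.array(
            [
                p.interval.start < g.tss + promoter_window_bp
                and g.tss - promoter_window_bp < p.interval.end
                for p in cand
            ]
        )
        for k, p in enumerate(cand):
            if is_prom[k]:
                continue
            rows.append(
                (
                    p.peak_id,
                    p.interval.chrom,
                    p.interval.start,
                    p.interval.end,
                    g.gene_id,
                    a[k],
                    c[k],
                    scores[k],
                    bool(total > 0 and scores[k] >= threshold),
                    condition,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "element_id", "chrom", "start", "end", "gene_id",
            "activity", "contact", "abc_score", "called", "condition",
        ],
    )


def called_pairs(abc: pd.DataFrame) -> set[tuple[str, str]]:
    return set(map(tuple, abc.loc[abc["called"], ["element_id", "gene_id"]].itertuples(index=False)))


def condition_specific_pairs(map_a: pd.DataFrame, map_b: pd.DataFrame) -> set[tuple[str, str]]:
    """Called pairs present in map_a and absent from map_b."""
    return called_pairs(map_a) - called_pairs(map_b)


def nearest_tss_baseline(
    elements: list[Peak], genes: list[GeneAnnot]
) -> list[tuple[str, str]]:
    """Pair each element with the gene whose TSS is nearest its midpoint.

    Ties are broken toward the smaller TSS coordinate, then the
    lexicographically smaller gene id.  Elements on chromosomes without
    genes are skipped.
    """
    by_chrom: dict[str, list[GeneAnnot]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
    out = []
    for p in elements:
        glist = by_chrom.get(p.interval.chrom)
        if not glist:
            continue
        mid = p.interval.midpoint
        best = min(glist, key=lambda g: (abs(g.tss - mid), g.tss, g.gene_id))
        out.append((p.peak_id, best.gene_id))
    return out
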