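"""GWAS risk variants vs enhancer maps: LD expansion, locus pruning,
overlap and rotation-based enrichment.

Top variants are expanded with their LD proxies (r2 > 0.8 by default,
including the variant itself), pruned into independent risk loci by the
greedy p-value-ordered clumping convention (variants with r2 > 0.1 to a
better lead join its locus), and loci are intersected with the called
enhancers of each condition at single-base resolution (a proxy position
inside a half-open enhancer interval suffices).

Enrichment per condition is tested against a circular-rotation null: the
condition's enhancer set is rotated within each chromosome by a uniform
random offset, preserving enhancer number, lengths and spacing, and the
locus-overlap count is recomputed per rotation.  Empirical p values carry
the plus-one correction and are Benjamini-Hochberg adjusted across
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicInterval

log = logging.getLogger(__name__)

__all__ = [
    "LdPanel",
    "Proxy",
    "RiskVariant",
    "RiskLocus",
    "expand_ld",
    "prune_to_loci",
    "overlap_loci_with_enhancers",
    "enrichment_per_condition",
]


@dataclass(frozen=True)
class Proxy:
    variant_id: str
    chrom: str
    pos: int  # 0-based
    r2: float


@dataclass
class RiskVariant:
    variant_id: str
    chrom: str
    pos: int  # 0-based
    pval: float
    proxies: list[Proxy] = field(default_factory=list)


@dataclass
class RiskLocus:
    locus_id: str
    member_variants: list[str]
    lead_variant: str


class LdPanel:
    """Pairwise r2 lookup plus variant positions.

    ``r2(v, v) = 1`` by definition; pairs absent from the table are 0.
    """

    def __init__(self, variants: pd.DataFrame, ld: pd.DataFrame):
        self.pos: dict[str, tuple[str, int]] = {
            r.variant_id: (r.chrom, int(r.pos))
            for r in variants.itertuples(index=False)
        }
        self.pval: dict[str, float] = {
            r.variant_id: float(r.pval) for r in variants.itertuples(index=False)
        }
        self._r2: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, set[str]] = {}
        for a, b, r in ld[["variant_a", "variant_b", "r2"]].itertuples(index=False):
            key = (a, b) if a <= b else (b, a)
            self._r2[key] = max(self._r2.get(key, 0.0), float(r))
            self._neighbors.setdefault(a, set()).add(b)
            self._neighbors.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)

    def neighbors(self, v: str) -> set[str]:
        return self._neighbors.get(v, set())

    def __contains__(self, v: str) -> bool:
        return v in self.pos


def expand_ld(
    variants: pd.DataFrame,
    panel: LdPanel,
    proxy_threshold: float = 0.8,
) -> list[RiskVariant]:
    """Annotate each top variant with all panel variants at r2 > threshold.

    The variant itself is always a proxy (r2 = 1).  Variants absent from
    the LD panel keep only themselves, with a logged warning.
    """
    out = []
    for row in variants.itertuples(index=False):
        vid = row.variant_id
        rv = RiskVariant(vid, row.chrom, int(row.pos), float(row.pval))
        rv.proxies.append(Proxy(vid, row.chrom, int(row.pos), 1.0))
        if vid not in panel:
            log.warning("variant %s absent from LD panel; proxies = {self}", vid)
        else:
            for nb in sorted(panel.neighbors(vid)):
                r = panel.r2(vid, nb)
                if r > proxy_threshold and nb in panel.pos:
                    chrom, pos = panel.pos[nb]
                    rv.proxies.append(Proxy(nb, chrom, pos, r))
        out.append(rv)
    return out


def prune_to_loci(
    variants: pd.DataFrame,
    panel: LdPanel,
    prune_threshold: float = 0.1,
) -> list[RiskLocus]:
    """Greedy p-ordered pruning into independent risk loci.

    Repeatedly take the unassigned variant with the smallest GWAS p value
    (ties by chrom then position) as a lead, and assign to its locus every
    unassigned variant with r2 > threshold to it.  The output is a
    partition of the input variants.
    """
    order = sorted(
        variants.itertuples(index=False),
        key=lambda r: (float(r.pval), r.chrom, int(r.pos)),
    )
    unassigned = {r.variant_id for r in order}
    loci: list[RiskLocus] = []
    for row in order:
        lead = row.variant_id
        if lead not in unassigned:
            continue
        members = [lead]
        unassigned.discard(lead)
        for other in sorted(unassigned):
            if panel.r2(lead, other) > prune_threshold:
                members.append(other)
        for m in members:
            unassigned.discard(m)
        loci.append(RiskLocus(f"locus_{len(loci):03d}", members, lead))
    return loci


# ---------------------------------------------------------------------------
# overlap


class _CoverageIndex:
    """Sorted merged-interval boundaries per chromosome for O(log n) point queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self.bounds: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.bounds[chrom] = np.array(merged, dtype=np.int64).ravel()

    def covered(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        b = self.bounds.get(chrom)
        if b is None or len(b) == 0:
            return np.zeros(len(pos), dtype=bool)
        return np.searchsorted(b, pos, side="right") % 2 == 1


def _enhancer_intervals(abc_pairs: pd.DataFrame) -> list[GenomicInterval]:
    called = abc_pairs.loc[abc_pairs["called"], ["chrom", "start", "end"]].drop_duplicates()
    return [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in called.itertuples(index=False)]


def overlap_loci_with_enhancers(
    loci: list[RiskLocus],
    expanded: list[RiskVariant],
    abc_pairs_by_condition: dict[str, pd.DataFrame],
    mhc_region: GenomicInterval | None = None,
) -> pd.DataFrame:
    """Per-locus, per-condition overlap with called ABC enhancers.

    Loci whose lead variant lies inside the configured MHC interval are
    dropped before testing.  A locus overlaps a condition if any proxy of
    any member lies within any called enhancer interval of that condition;
    the overlapping element ids and their linked genes are reported.
    """
    by_id = {rv.variant_id: rv for rv in expanded}
    kept = []
    for locus in loci:
        lead = by_id.get(locus.lead_variant)
        if lead is None:
            raise KeyError(f"lead variant {locus.lead_variant} missing from expansion")
        if mhc_region is not None and mhc_region.contains(lead.chrom, lead.pos):
            continue
        kept.append(locus)

    rows = []
    for condition, pairs in abc_pairs_by_condition.items():
        called = pairs[pairs["called"]]
        for locus in kept:
            hit_elements: list[str] = []
            hit_genes: list[str] = []
            for member in locus.member_variants:
                rv = by_id.get(member)
                if rv is None:
                    continue
                for pr in rv.proxies:
                    inside = called[
                        (called["chrom"] == pr.chrom)
                        & (called["start"] <= pr.pos)
                        & (pr.pos < called["end"])
                    ]
                    hit_elements.extend(inside["element_id"])
                    hit_genes.extend(inside["gene_id"])
            if hit_elements:
                rows.append(
                    (
                        locus.locus_id,
                        condition,
                        ",".join(sorted(set(hit_elements))),
                        ",".join(sorted(set(hit_genes))),
                    )
                )
    return pd.DataFrame(rows, columns=["locus_id", "condition", "element_ids", "gene_ids"])


def count_overlapping_loci(
    loci: list[RiskLocus],
    expanded: list[RiskVariant],
    index: _CoverageIndex,
    offset_by_chrom: dict[str, int] | None = None,
    chrom_len: int | None = None,
) -> int:
    """Number of loci with any proxy inside the (optionally rotated) enhancer set."""
    by_id = {rv.variant_id: rv for rv in expanded}
    n = 0
    for locus in loci:
        hit = False
        for member in locus.member_variants:
            rv = by_id.get(member)
            if rv is None:
                continue
            for pr in rv.proxies:
                pos = pr.pos
                if offset_by_chrom is not None:
                    pos = (pos - offset_by_chrom.get(pr.chrom, 0)) % chrom_len
                if index.covered(pr.chrom, np.array([pos]))[0]:
                    hit = True
                    break
            if hit:
                break
        if hit:
            n += 1
    return n


def enrichment_per_condition(
    loci: list[RiskLocus],
    expanded: list[RiskVariant],
    abc_pairs_by_condition: dict[str, pd.DataFrame],
    chrom_lengths: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    mhc_region: GenomicInterval | None = None,
) -> pd.DataFrame:
    """Circular-rotation enrichment of risk loci in each condition's enhancers.

    observed = number of (non-MHC) loci overlapping the condition's called
    enhancers; the null rotates the enhancer set within each chromosome by
    a uniform offset and recounts.  empirical p uses the plus-one rule and
    can therefore never be exactly zero.  Chromosomes shorter than the
    longest enhancer are left unrotated with a warning.
    """
    rng = np.random.default_rng(seed)
    by_id = {rv.variant_id: rv for rv in expanded}
    kept = [
        loc
        for loc in loci
        if not (
            mhc_region is not None
            and mhc_region.contains(by_id[loc.lead_variant].chrom, by_id[loc.lead_variant].pos)
        )
    ]
    # flatten proxies once: per chromosome, position and locus-index arrays
    n_loci = len(kept)
    flat: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    _pos: dict[str, list[int]] = {}
    _idx: dict[str, list[int]] = {}
    for li, loc in enumerate(kept):
        for member in loc.member_variants:
            rv = by_id.get(member)
            if rv is None:
                continue
            for pr in rv.proxies:
                _pos.setdefault(pr.chrom, []).append(pr.pos)
                _idx.setdefault(pr.chrom, []).append(li)
    for chrom in _pos:
        flat[chrom] = (
            np.array(_pos[chrom], dtype=np.int64),
            np.array(_idx[chrom], dtype=np.int64),
        )

    rows = []
    for condition in sorted(abc_pairs_by_condition):
        index = _CoverageIndex(_enhancer_intervals(abc_pairs_by_condition[condition]))
        max_len = 0
        for b in index.bounds.values():
            if len(b):
                max_len = max(max_len, int((b[1::2] - b[0::2]).max()))
        rotatable = {
            c: length for c, length in chrom_lengths.items() if length > max_len
        }
        for c in chrom_lengths:
            if c not in rotatable:
                log.warning("chromosome %s shorter than longest enhancer; rotation skipped", c)

        def count(offsets: dict[str, int]) -> int:
            hit = np.zeros(n_loci, dtype=bool)
            for chrom, (pos, locus_idx) in flat.items():
                if chrom in offsets:
                    p = (pos - offsets[chrom]) % chrom_lengths[chrom]
                else:
                    p = pos
                cov = index.covered(chrom, p)
                if cov.any():
                    hit[locus_idx[cov]] = True
            return int(hit.sum())

        observed = count({})
        perm_counts = np.empty(n_perm, dtype=int)
        for it in range(n_perm):
            offsets = {c: int(rng.integers(0, length)) for c, length in rotatable.items()}
            perm_counts[it] = count(offsets)
        p = (1.0 + np.sum(perm_counts >= observed)) / (1.0 + n_perm)
        rows.append((condition, observed, float(perm_counts.mean()), p))
    df = pd.DataFrame(rows, columns=["condition", "observed", "expected_mean", "empirical_p"])
    df["qvalue"] = multipletests(df["empirical_p"], method="fdr_bh")[1]
    return df
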