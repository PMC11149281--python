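"""Synthetic multi-omics study generator with planted ground truth.

Emulates the design of a drug-perturbation study of stimulated synovial
fibroblasts: six donors, a non-stimulated arm (NS), a stimulated non-treated
arm (NT) and four drug arms (one TNF inhibitor, three JAK inhibitors), each
profiled at two timepoints.  The generator produces, from a single seed,

* a toy genome (gene TSSs and candidate regulatory elements),
* binned Hi-C contacts with power-law distance decay and planted
  enhancer-promoter loops,
* ATAC (per sample) and H3K27ac (per condition) element counts with
  stimulation opening and drug-induced closing effects,
* gene expression counts with module-structured condition responses and
  donor random effects,
* a GWAS panel in LD blocks, with causal variants planted inside true
  enhancers, and per-study chi-square statistics generated under a
  polygenic annotation model.

Every planted fact is recorded in :class:`SyntheticTruth` so downstream
stages can be scored against a known answer.

Count noise is negative binomial with a fixed dispersion (variance
``mu + dispersion * mu**2``), matching overdispersed sequencing counts
without per-feature dispersion estimation.  Donor effects enter as
feature-by-donor Gaussian random intercepts and therefore cancel in paired
within-donor contrasts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ContactMap, GeneAnnot, GenomicInterval, Peak

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_hic",
    "simulate_activity_counts",
    "simulate_expression",
    "simulate_gwas",
    "simulate_all",
]

DRUGS = ("TNFi", "JAKi1", "JAKi2", "JAKi3")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic study.

    The defaults encode the study conditions the generator emulates: 6
    donors, NS/NT plus four drugs, two timepoints, a 2 x 10 Mb genome with
    300 genes and 1,500 candidate elements, Hi-C decay exponent 1 with
    8-fold loops, donor standard deviation 0.3 and a -1 (log2) drug effect.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len_bp: int = 10_000_000
    n_genes: int = 300
    n_elements: int = 1_500
    bin_size_bp: int = 5_000
    n_donors: int = 6
    treatments: tuple[str, ...] = ("NS", "NT") + DRUGS
    timepoints: tuple[str, ...] = ("24h", "7d")
    n_modules: int = 8
    n_variants: int = 120
    gamma: float = 1.0
    loop_boost: float = 8.0
    donor_sd: float = 0.3
    drug_effect: float = -1.0  # log2 scale, applied to closed elements

    # genome layout
    element_len_bp: int = 500
    anchor_offset_bp: tuple[int, int] = (10_000, 30_000)
    link_radius_bp: int = 100_000
    near_tss_frac: float = 0.6
    edge_margin_bp: int = 200_000

    # counts
    dispersion: float = 0.1
    stim_effect: float = 2.0  # log2, accessibility opening upon stimulation
    peak_base_mean: float = 8.0
    enhancer_base_mean: float = 200.0
    k27_base_mean: float = 1.0
    k27_enhancer_mean: float = 200.0
    gene_base_mean: float = 200.0
    expr_stim_effect: float = 2.5
    expr_stim_frac: float = 0.6  # fraction of genes induced by stimulation
    module_amplitude: float = 1.0

    # Hi-C
    hic_c0: float = 200_000.0
    hic_max_dist_bp: int = 1_000_000

    # drug-closing truth structure
    n_responsive_bg: int = 300
    closed_anchored_per_class: int = 30
    closed_bg_per_class: int = 45
    closed_anchored_pan: int = 20
    closed_bg_pan: int = 30
    n_decoupled: int = 5

    # GWAS / LD
    ld_block_size: int = 4
    n_causal_blocks: int = 15
    n_element_bg_blocks: int = 10  # blocks in open chromatin outside enhancers
    proxy_span_bp: int = 2_000
    proxy_r2_range: tuple[float, float] = (0.9, 1.0)
    causal_in_enhancers: bool = True
    n_gwas: int = 50_000
    n_studies: int = 2
    tau_target: float = 1.0e-5
    tau_all: float = 2.0e-6

    def __post_init__(self) -> None:
        for name in (
            "n_chrom", "chrom_len_bp", "n_genes", "bin_size_bp", "n_donors",
            "n_modules", "ld_block_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_elements < 0 or self.n_variants < 0:
            raise ValueError("counts must be non-negative")
        if self.gamma <= 0 or self.loop_boost <= 0:
            raise ValueError("gamma and loop_boost must be positive")
        if self.n_elements and self.n_elements < self.n_genes:
            raise ValueError("need at least one element per gene")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chrom))

    @property
    def donors(self) -> tuple[str, ...]:
        return tuple(f"D{i + 1}" for i in range(self.n_donors))

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(f"{t}_{tp}" for t in self.treatments for tp in self.timepoints)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Planted ground truth behind one synthetic dataset."""

    true_links: set[tuple[str, str]]
    module_of_gene: dict[str, int]
    causal_variants: set[str]
    drug_closed_elements: dict[str, set[str]]
    tau_true: dict[str, float]
    stim_responsive: set[str] = field(default_factory=set)
    anchor_of_gene: dict[str, str] = field(default_factory=dict)
    decoupled_genes: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SimConfig
    genes: list[GeneAnnot]
    elements: list[Peak]
    design: pd.DataFrame
    atac: pd.DataFrame
    h3k27ac: pd.DataFrame
    expression: pd.DataFrame
    contacts: dict[str, ContactMap]
    variants: pd.DataFrame
    ld: pd.DataFrame
    chi2: pd.DataFrame
    truth: SyntheticTruth


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(stage,)))
    )


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return np.rint(mean).astype(int)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


# ---------------------------------------------------------------------------
# genome layout


class _Placer:
    """Rejection-samples disjoint element intervals avoiding TSS bins."""

    def __init__(self, config: SimConfig, tss_by_chrom: dict[str, np.ndarray]):
        self.cfg = config
        self.placed: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chroms}
        bs = config.bin_size_bp
        self.tss_bins = {
            c: set((p // bs).tolist()) for c, p in tss_by_chrom.items()
        }

    def ok(self, chrom: str, start: int, end: int) -> bool:
        cfg = self.cfg
        if start < 0 or end > cfg.chrom_len_bp:
            return False
        bs = cfg.bin_size_bp
        if any(b in self.tss_bins[chrom] for b in range(start // bs, (end - 1) // bs + 1)):
            return False
        for s, e in self.placed[chrom]:
            if start < e and s < end:
                return False
        return True

    def put(self, chrom: str, start: int, end: int) -> None:
        self.placed[chrom].append((start, end))


def simulate_genome(config: SimConfig) -> tuple[list[GeneAnnot], list[Peak], SyntheticTruth]:
    """Lay out TSSs and candidate elements; plant enhancer-gene truth.

    TSSs are uniform within each chromosome (inside an edge margin).  One
    "anchored" enhancer is placed 10-30 kb from every gene; these are the
    genome's active enhancers.  The remaining elements are background
    candidate peaks, placed so that overall ~60% of elements fall within
    100 kb of some TSS.  No element overlaps a Hi-C bin containing a TSS,
    and elements are pairwise disjoint.

    A true regulatory link is planted for every (active enhancer, gene)
    pair within ``link_radius_bp``; all true links receive Hi-C loops.
    Drug-closing truth assigns subsets of elements to TNFi-specific,
    JAKi-shared and pan-drug closing classes.
    """
    cfg = config
    rng = _rng(cfg, 0)
    genes: list[GeneAnnot] = []
    tss_by_chrom: dict[str, np.ndarray] = {}
    per_chrom = np.full(cfg.n_chrom, cfg.n_genes // cfg.n_chrom)
    per_chrom[: cfg.n_genes % cfg.n_chrom] += 1
    gi = 0
    for chrom, n in zip(cfg.chroms, per_chrom):
        lo, hi = cfg.edge_margin_bp, cfg.chrom_len_bp - cfg.edge_margin_bp
        pos = np.sort(rng.integers(lo, hi, size=n))
        tss_by_chrom[chrom] = pos
        for p in pos:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneAnnot(f"gene_{gi:04d}", chrom, int(p), strand))
            gi += 1

    placer = _Placer(cfg, tss_by_chrom)
    half = cfg.element_len_bp // 2
    raw: list[tuple[str, int, int, str | None]] = []  # chrom, start, end, anchor gene

    if cfg.n_elements == 0:
        truth = _plant_truth(cfg, genes, [], rng)
        return genes, [], truth

    # anchored active enhancers, one per gene
    lo_off, hi_off = cfg.anchor_offset_bp
    for g in genes:
        placed = False
        for _ in range(200):
            off = int(rng.integers(lo_off, hi_off + 1)) * (1 if rng.random() < 0.5 else -1)
            mid = g.tss + off
            s, e = mid - half, mid + cfg.element_len_bp - half
            if placer.ok(g.chrom, s, e):
                placer.put(g.chrom, s, e)
                raw.append((g.chrom, s, e, g.gene_id))
                placed = True
                break
        if not placed:
            raise ValueError(
                "element density infeasible: could not place anchored enhancer "
                f"near {g.gene_id}"
            )

    # background elements: near-TSS quota, then uniform
    n_bg = cfg.n_elements - cfg.n_genes
    n_near = max(0, int(round(cfg.near_tss_frac * cfg.n_elements)) - cfg.n_genes)
    for i in range(n_bg):
        placed = False
        for _ in range(500):
            if i < n_near:
                g = genes[int(rng.integers(len(genes)))]
                off = int(rng.integers(1_000, cfg.link_radius_bp + 1))
                mid = g.tss + off * (1 if rng.random() < 0.5 else -1)
                chrom = g.chrom
            else:
                chrom = cfg.chroms[int(rng.integers(cfg.n_chrom))]
                mid = int(rng.integers(half, cfg.chrom_len_bp - half))
            s, e = mid - half, mid + cfg.element_len_bp - half
            if placer.ok(chrom, s, e):
                placer.put(chrom, s, e)
                raw.append((chrom, s, e, None))
                placed = True
                break
        if not placed:
            raise ValueError("element density infeasible: background placement failed")

    order = sorted(range(len(raw)), key=lambda i: (raw[i][0], raw[i][1]))
    elements: list[Peak] = []
    anchor_of_gene: dict[str, str] = {}
    for new_id, i in enumerate(order):
        chrom, s, e, anchor = raw[i]
        pid = f"el_{new_id:04d}"
        elements.append(Peak(GenomicInterval(chrom, s, e), pid))
        if anchor is not None:
            anchor_of_gene[anchor] = pid

    truth = _plant_truth(cfg, genes, elements, rng, anchor_of_gene)
    return genes, elements, truth


def _plant_truth(
    cfg: SimConfig,
    genes: list[GeneAnnot],
    elements: list[Peak],
    rng: np.random.Generator,
    anchor_of_gene: dict[str, str] | None = None,
) -> SyntheticTruth:
    anchor_of_gene = anchor_of_gene or {}
    anchored = set(anchor_of_gene.values())
    gene_by_id = {g.gene_id: g for g in genes}

    # true links: every active (anchored) enhancer regulates every gene
    # whose TSS lies within the link radius
    true_links: set[tuple[str, str]] = set()
    for el in elements:
        if el.peak_id not in anchored:
            continue
        for g in genes:
            if g.chrom == el.interval.chrom and abs(el.interval.midpoint - g.tss) <= cfg.link_radius_bp:
                true_links.add((el.peak_id, g.gene_id))

    # module membership: balanced random partition
    gene_ids = [g.gene_id for g in genes]
    perm = rng.permutation(len(gene_ids))
    module_of_gene: dict[str, int] = {}
    for m, chunk in enumerate(np.array_split(perm, cfg.n_modules), start=1):
        for idx in chunk:
            module_of_gene[gene_ids[idx]] = m

    # stimulation-responsive elements: all anchored enhancers plus a
    # background subset
    bg_ids = [p.peak_id for p in elements if p.peak_id not in anchored]
    n_bg_resp = min(cfg.n_responsive_bg, len(bg_ids))
    bg_resp = set(rng.choice(bg_ids, size=n_bg_resp, replace=False).tolist()) if n_bg_resp else set()
    responsive = anchored | bg_resp

    # drug-closing classes (subsets of responsive elements)
    anch_list = sorted(anchored)
    bg_list = sorted(bg_resp)
    rng.shuffle(anch_list)
    rng.shuffle(bg_list)

    def take(lst: list[str], n: int) -> set[str]:
        out = set(lst[:n])
        del lst[:n]
        return out

    tnfi = take(anch_list, cfg.closed_anchored_per_class) | take(bg_list, cfg.closed_bg_per_class)
    jaki = take(anch_list, cfg.closed_anchored_per_class) | take(bg_list, cfg.closed_bg_per_class)
    pan = take(anch_list, cfg.closed_anchored_pan) | take(bg_list, cfg.closed_bg_pan)
    drug_closed = {
        "TNFi": tnfi | pan,
        "JAKi1": jaki | pan,
        "JAKi2": jaki | pan,
        "JAKi3": jaki | pan,
    }
    drug_closed = {d: s for d, s in drug_closed.items() if d in cfg.treatments}

    # decoupled genes: expression responds to TNFi but the anchored
    # enhancer stays open (tests direction-consistency logic downstream)
    untouched = [g for g in gene_by_id if anchor_of_gene.get(g) in (set(anch_list))]
    rng.shuffle(untouched)
    decoupled = {"TNFi": set(untouched[: cfg.n_decoupled])} if "TNFi" in cfg.treatments else {}

    return SyntheticTruth(
        true_links=true_links,
        module_of_gene=module_of_gene,
        causal_variants=set(),
        drug_closed_elements=drug_closed,
        tau_true={"drug_closed": cfg.tau_target, "all_elements": cfg.tau_all},
        stim_responsive=responsive,
        anchor_of_gene=anchor_of_gene,
        decoupled_genes=decoupled,
    )


# ---------------------------------------------------------------------------
# Hi-C


def expected_hic_count(config: SimConfig, distance_bp: float) -> float:
    """Expected (non-loop) contact count at a given genomic distance.

    ``c0 * (d + d0) ** -gamma`` with ``d0 = bin_size``; the offset keeps the
    self-bin expectation finite.
    """
    return config.hic_c0 * (distance_bp + config.bin_size_bp) ** (-config.gamma)


def simulate_hic(
    config: SimConfig,
    genes: list[GeneAnnot],
    elements: list[Peak],
    truth: SyntheticTruth,
) -> dict[str, ContactMap]:
    """Draw Poisson contact counts around a power-law decay, with loops.

    Bin pairs spanning a planted true link have their expectation multiplied
    by ``loop_boost``.  Only intra-chromosomal pairs up to
    ``hic_max_dist_bp`` are emitted; zero draws are dropped (sparse triplet
    convention, absent pairs read back as zero).
    """
    cfg = config
    rng = _rng(cfg, 1)
    bs = cfg.bin_size_bp
    n_bins = cfg.chrom_len_bp // bs
    max_d = cfg.hic_max_dist_bp // bs

    gene_by_id = {g.gene_id: g for g in genes}
    el_by_id = {p.peak_id: p for p in elements}
    loops: dict[str, set[tuple[int, int]]] = {c: set() for c in cfg.chroms}
    for el_id, g_id in truth.true_links:
        el, g = el_by_id[el_id], gene_by_id[g_id]
        bi, bj = el.interval.midpoint // bs, g.tss // bs
        loops[g.chrom].add((min(bi, bj), max(bi, bj)))

    out: dict[str, ContactMap] = {}
    for chrom in cfg.chroms:
        counts: dict[tuple[int, int], float] = {}
        for d in range(0, max_d + 1):
            lam = expected_hic_count(cfg, d * bs)
            i = np.arange(n_bins - d)
            draws = rng.poisson(lam, size=n_bins - d)
            nz = draws > 0
            counts.update(zip(zip(i[nz].tolist(), (i[nz] + d).tolist()), draws[nz].astype(float).tolist()))
        # redraw loop pairs at boosted expectation
        for (bi, bj) in sorted(loops[chrom]):
            if bj - bi > max_d:
                continue
            lam = expected_hic_count(cfg, (bj - bi) * bs) * cfg.loop_boost
            c = float(rng.poisson(lam))
            if c > 0:
                counts[(bi, bj)] = c
            else:
                counts.pop((bi, bj), None)
        cm = ContactMap(bs)
        cm._counts = counts
        out[chrom] = cm
    return out


# ---------------------------------------------------------------------------
# counts


def make_design(config: SimConfig) -> pd.DataFrame:
    rows = [
        (f"{d}_{t}_{tp}", d, t, tp)
        for d in config.donors
        for t in config.treatments
        for tp in config.timepoints
    ]
    return pd.DataFrame(rows, columns=["sample_id", "donor", "treatment", "timepoint"])


def simulate_activity_counts(
    config: SimConfig,
    elements: list[Peak],
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ATAC counts per element x sample and H3K27ac per element x condition.

    log2 expected count = baseline + stimulation opening (responsive
    elements, stimulated arms) + drug closing (closed elements under their
    drug, both timepoints) + donor random intercept; negative binomial
    noise.  H3K27ac has one profile per condition (no donor axis), with the
    same systematic effects.
    """
    cfg = config
    rng = _rng(cfg, 2)
    design = make_design(cfg)
    el_ids = [p.peak_id for p in elements]
    anchored = set(truth.anchor_of_gene.values())
    n_el = len(el_ids)

    base = np.where(
        [e in anchored for e in el_ids], cfg.enhancer_base_mean, cfg.peak_base_mean
    ).astype(float)
    resp = np.array([e in truth.stim_responsive for e in el_ids])
    closed = {
        d: np.array([e in truth.drug_closed_elements.get(d, set()) for e in el_ids])
        for d in cfg.treatments
        if d in DRUGS
    }
    donor_eff = rng.normal(0.0, cfg.donor_sd, size=(n_el, cfg.n_donors))
    donor_idx = {d: i for i, d in enumerate(cfg.donors)}

    log2mu = np.empty((n_el, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        mu = np.log2(base)
        if row.treatment != "NS":
            mu = mu + cfg.stim_effect * resp
        if row.treatment in closed:
            mu = mu + cfg.drug_effect * closed[row.treatment]
        log2mu[:, j] = mu + donor_eff[:, donor_idx[row.donor]]
    atac = pd.DataFrame(
        _nbinom(rng, 2.0 ** log2mu, cfg.dispersion),
        index=pd.Index(el_ids, name="feature_id"),
        columns=design["sample_id"].tolist(),
    )

    k27_base = np.where(
        [e in anchored for e in el_ids], cfg.k27_enhancer_mean, cfg.k27_base_mean
    ).astype(float)
    cond_cols = list(cfg.conditions)
    k27_log2mu = np.empty((n_el, len(cond_cols)))
    for j, cond in enumerate(cond_cols):
        trt = cond.rsplit("_", 1)[0]
        mu = np.log2(k27_base)
        if trt != "NS":
            mu = mu + cfg.stim_effect * resp
        if trt in closed:
            mu = mu + cfg.drug_effect * closed[trt]
        k27_log2mu[:, j] = mu
    h3k27ac = pd.DataFrame(
        _nbinom(rng, 2.0 ** k27_log2mu, cfg.dispersion),
        index=pd.Index(el_ids, name="feature_id"),
        columns=cond_cols,
    )
    return atac, h3k27ac, design


def simulate_expression(
    config: SimConfig,
    genes: list[GeneAnnot],
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Gene x sample expression counts with module condition profiles.

    Each module has a latent response profile over the treatment x timepoint
    conditions (profiles are mutually orthogonal; the first module carries a
    designed TNFi-preferential repression pattern).  Genes load positively
    on their module's profile; a global stimulation axis separates NS from
    stimulated arms; genes whose anchored enhancer closes under a drug
    inherit that drug's effect, as do the planted decoupled genes.
    """
    cfg = config
    rng = _rng(cfg, 3)
    design = make_design(cfg)
    conditions = list(cfg.conditions)
    n_cond = len(conditions)
    # module profiles: first row is a TNFi-repression contrast, the rest
    # random Gaussian; all rows are Gram-Schmidt orthogonalized against the
    # constant, the global stimulation axis and each other, then scaled to
    # unit sd.  Orthogonality to the stimulation indicator keeps module
    # structure identifiable: modules are defined as response variation
    # beyond the shared activation program
    if cfg.n_modules > n_cond - 2:
        raise ValueError("cannot build orthogonal profiles: too many modules")
    trt_of = [c.rsplit("_", 1)[0] for c in conditions]
    stim_axis = np.array([0.0 if t == "NS" else 1.0 for t in trt_of])
    stim_axis = stim_axis - stim_axis.mean()
    profiles = np.zeros((cfg.n_modules, n_cond))
    profiles[0] = [-1.0 if t == "TNFi" else 0.0 for t in trt_of]
    if cfg.n_modules > 1:
        profiles[1:] = rng.normal(size=(cfg.n_modules - 1, n_cond))
    for m in range(cfg.n_modules):
        v = profiles[m] - profiles[m].mean()
        v = v - (v @ stim_axis) / (stim_axis @ stim_axis) * stim_axis
        for k in range(m):
            v = v - (v @ profiles[k]) / (profiles[k] @ profiles[k]) * profiles[k]
        sd = v.std()
        if sd < 1e-12:
            raise ValueError("degenerate module profile")
        profiles[m] = v / sd

    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    mod_idx = np.array([truth.module_of_gene[g] - 1 for g in gene_ids])
    loading = rng.uniform(0.7, 1.3, size=n_genes)
    # stimulation induces a subset of genes; depth normalization removes any
    # shift common to all genes, so the activation signature must be
    # heterogeneous to be visible in normalized data
    stim_w = rng.uniform(0.5, 1.5, size=n_genes) * (
        rng.random(n_genes) < cfg.expr_stim_frac
    )
    donor_eff = rng.normal(0.0, cfg.donor_sd, size=(n_genes, cfg.n_donors))
    donor_idx = {d: i for i, d in enumerate(cfg.donors)}
    cond_idx = {c: i for i, c in enumerate(conditions)}

    # drug inheritance: gene responds to drug D iff its anchored enhancer is
    # closed by D, or it is a planted decoupled responder
    inherits = {
        d: np.array(
            [
                truth.anchor_of_gene.get(g) in truth.drug_closed_elements.get(d, set())
                or g in truth.decoupled_genes.get(d, set())
                for g in gene_ids
            ]
        )
        for d in cfg.treatments
        if d in DRUGS
    }

    log2mu = np.empty((n_genes, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        cond = f"{row.treatment}_{row.timepoint}"
        mu = np.log2(cfg.gene_base_mean) + cfg.module_amplitude * loading * profiles[mod_idx, cond_idx[cond]]
        if row.treatment != "NS":
            mu = mu + cfg.expr_stim_effect * stim_w
        if row.treatment in inherits:
            mu = mu + cfg.drug_effect * inherits[row.treatment]
        log2mu[:, j] = mu + donor_eff[:, donor_idx[row.donor]]
    return pd.DataFrame(
        _nbinom(rng, 2.0 ** log2mu, cfg.dispersion),
        index=pd.Index(gene_ids, name="feature_id"),
        columns=design["sample_id"].tolist(),
    )


# ---------------------------------------------------------------------------
# GWAS panel


def simulate_gwas(
    config: SimConfig,
    elements: list[Peak],
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Variant panel in LD blocks, pairwise r2 table, and per-study chi2.

    The panel is block-diagonal: within-block r2 is drawn from
    ``proxy_r2_range``, cross-block r2 is zero (absent from the table).
    ``n_causal_blocks`` blocks are anchored inside drug-closed active
    enhancers (when ``causal_in_enhancers``); the rest are placed outside
    any element.  Per-study chi-square statistics follow the polygenic
    annotation model: chi2_j = z_j^2 with
    z_j ~ Normal(0, sqrt(1 + N * sum_c tau_c * l(j, c))),
    where l(j, c) are LD scores of the planted annotations ("drug_closed"
    and "all_elements") computed on this same panel.

    Updates ``truth.causal_variants`` with the lead variant of each causal
    block.
    """
    cfg = config
    rng = _rng(cfg, 4)
    n_blocks = max(1, cfg.n_variants // cfg.ld_block_size)
    sizes = np.full(n_blocks, cfg.ld_block_size)
    sizes[: cfg.n_variants - sizes.sum()] += 1 if cfg.n_variants > sizes.sum() else 0

    anchored = set(truth.anchor_of_gene.values())
    closed_any = set().union(*truth.drug_closed_elements.values()) if truth.drug_closed_elements else set()
    causal_homes = sorted(anchored & closed_any)
    el_by_id = {p.peak_id: p for p in elements}

    bounds: dict[str, np.ndarray] = {}
    for p in elements:
        bounds.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    bounds = {
        c: np.array(sorted(ivs), dtype=np.int64).ravel() for c, ivs in bounds.items()
    }

    def in_any_element(chrom: str, pos) -> bool | np.ndarray:
        b = bounds.get(chrom)
        if b is None or len(b) == 0:
            return np.zeros(np.size(pos), dtype=bool) if np.ndim(pos) else False
        hit = np.searchsorted(b, pos, side="right") % 2 == 1
        return hit if np.ndim(pos) else bool(hit)

    n_causal = min(cfg.n_causal_blocks, len(causal_homes)) if cfg.causal_in_enhancers else 0
    homes = rng.choice(causal_homes, size=n_causal, replace=False).tolist() if n_causal else []
    # background open-chromatin blocks: anchored in elements that are neither
    # active enhancers nor drug-closed (keeps the two S-LDSC annotations
    # distinguishable on the panel)
    bg_homes_pool = sorted(
        p.peak_id for p in elements if p.peak_id not in anchored and p.peak_id not in closed_any
    )
    n_el_bg = (
        min(cfg.n_element_bg_blocks, len(bg_homes_pool), max(0, n_blocks - n_causal))
        if cfg.causal_in_enhancers
        else 0  # null panels are fully uniform, independent of the element landscape
    )
    bg_homes = rng.choice(bg_homes_pool, size=n_el_bg, replace=False).tolist() if n_el_bg else []

    records = []
    ld_rows = []
    causal_ids: set[str] = set()
    vi = 0
    for b in range(n_blocks):
        if b < n_causal:
            iv = el_by_id[homes[b]].interval
            chrom = iv.chrom
            anchor = int(rng.integers(iv.start, iv.end))
        elif b < n_causal + n_el_bg:
            iv = el_by_id[bg_homes[b - n_causal]].interval
            chrom = iv.chrom
            anchor = int(rng.integers(iv.start, iv.end))
        else:
            # with planted causals, the remaining blocks avoid elements so the
            # annotation classes stay separable; under the no-enrichment null
            # (causal_in_enhancers=False) placement is uniform, independent of
            # the element landscape, which is the exchangeability null of the
            # rotation test
            for _ in range(1000):
                chrom = cfg.chroms[int(rng.integers(cfg.n_chrom))]
                anchor = int(rng.integers(cfg.proxy_span_bp, cfg.chrom_len_bp - cfg.proxy_span_bp))
                if not cfg.causal_in_enhancers or not in_any_element(chrom, anchor):
                    break
        block_ids = []
        for k in range(sizes[b]):
            if k == 0:
                pos = anchor
                pval = 10.0 ** (-rng.uniform(8, 12)) if b < n_causal else 10.0 ** (-rng.uniform(5, 7))
            else:
                pos = int(np.clip(anchor + rng.integers(-cfg.proxy_span_bp, cfg.proxy_span_bp + 1), 0, cfg.chrom_len_bp - 1))
                pval = 10.0 ** (-rng.uniform(6, 9)) if b < n_causal else 10.0 ** (-rng.uniform(4, 6))
            vid = f"rs{vi:05d}"
            vi += 1
            block_ids.append(vid)
            records.append((vid, chrom, pos + 1, pval, b))
            if k == 0 and b < n_causal:
                causal_ids.add(vid)
        lo, hi = cfg.proxy_r2_range
        for i in range(len(block_ids)):
            for j in range(i + 1, len(block_ids)):
                ld_rows.append((block_ids[i], block_ids[j], float(rng.uniform(lo, hi))))

    variants = pd.DataFrame(records, columns=["variant_id", "chrom", "pos1", "pval", "block"])
    variants["pos"] = variants["pos1"] - 1
    ld = pd.DataFrame(ld_rows, columns=["variant_a", "variant_b", "r2"])

    # chi2 under the annotation model, LD scores from this same panel
    m = len(variants)
    r2 = np.eye(m)
    idx = {v: i for i, v in enumerate(variants["variant_id"])}
    for a, bb, r in ld.itertuples(index=False):
        r2[idx[a], idx[bb]] = r2[idx[bb], idx[a]] = r

    member = {}
    closed_ivs = [el_by_id[e].interval for e in sorted(closed_any)]
    member["drug_closed"] = np.array(
        [any(iv.contains(c, p) for iv in closed_ivs) for c, p in zip(variants["chrom"], variants["pos"])]
    )
    member["all_elements"] = np.array(
        [in_any_element(c, p) for c, p in zip(variants["chrom"], variants["pos"])]
    )
    sigma2 = np.ones(m)
    for name, mem in member.items():
        sigma2 = sigma2 + cfg.n_gwas * truth.tau_true.get(name, 0.0) * (r2 @ mem.astype(float))
    sigma2 = np.maximum(sigma2, 1e-8)
    chi2 = pd.DataFrame(
        {f"study{s + 1}": rng.normal(0.0, np.sqrt(sigma2)) ** 2 for s in range(cfg.n_studies)},
        index=pd.Index(variants["variant_id"], name="variant_id"),
    )
    truth.causal_variants = causal_ids
    return variants.drop(columns=["block"]), ld, chi2


def simulate_all(config: SimConfig) -> SyntheticDataset:
    """Generate the full study from one seed (fully deterministic)."""
    genes, elements, truth = simulate_genome(config)
    contacts = simulate_hic(config, genes, elements, truth)
    atac, h3k27ac, design = simulate_activity_counts(config, elements, truth)
    expression = simulate_expression(config, genes, truth)
    variants, ld, chi2 = simulate_gwas(config, elements, truth)
    return SyntheticDataset(
        config=config,
        genes=genes,
        elements=elements,
        design=design,
        atac=atac,
        h3k27ac=h3k27ac,
        expression=expression,
        contacts=contacts,
        variants=variants,
        ld=ld,
        chi2=chi2,
        truth=truth,
    )
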