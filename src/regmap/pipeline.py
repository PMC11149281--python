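"""End-to-end orchestration of the analysis stages.

``run_all`` executes simulate -> differential analysis -> co-expression
modules -> ABC map -> risk overlap -> drug targets -> heritability, each
stage reading its inputs from, and writing its outputs to, the run
directory's declared file formats.  Every artifact is listed in a manifest
with a content hash; reruns with the same config and seed reproduce the
hashes.

Stage randomness is funnelled through per-stage generators derived from the
master seed by stable spawning, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc_map, coexpr, diffexpr, risk, sldsc, targets
from .io_formats import (
    GenomicInterval,
    closed1_to_halfopen0,
    read_contacts,
    read_counts,
    read_design,
    read_genes,
    read_ld_table,
    read_peaks,
    read_variants,
    write_bed,
    write_contacts,
    write_counts,
    write_design,
    write_genes,
    write_ld_table,
    write_variants,
)
from .synthetic import DRUGS, SimConfig, SyntheticDataset, simulate_all

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "write_dataset", "load_dataset"]


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class AbcParams:
    window_bp: int = 5_000_000
    threshold: float = 0.02
    use_h3k27ac: bool = True
    pseudocount_frac: float = 1.0


@dataclass
class RiskParams:
    proxy_threshold: float = 0.8
    prune_threshold: float = 0.1
    n_perm: int = 500
    mhc: list | None = None  # [chrom, start1, end1] in 1-based closed coords


@dataclass
class ModuleParams:
    min_module_size: int = 30
    cut_height_quantile: float = 0.99
    power: int | str = 6  # "auto" invokes the scale-free criterion


@dataclass
class HeritParams:
    # the method's real-data convention is the top 15,000 downregulated
    # regions; the pipeline default is scaled to the bundled synthetic peak
    # set (10% of 1,500 elements) so the annotation stays a strict subset
    top_k: int = 150
    n_blocks: int = 20


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "regmap_out"
    timepoint: str = "24h"
    expr_q_max: float = 0.05
    acc_q_max: float = 0.05
    sim: dict = field(default_factory=dict)
    abc: AbcParams = field(default_factory=AbcParams)
    risk: RiskParams = field(default_factory=RiskParams)
    modules: ModuleParams = field(default_factory=ModuleParams)
    herit: HeritParams = field(default_factory=HeritParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        top = {f.name for f in dataclasses.fields(cls)}
        _check_keys(d, top, "pipeline config")
        kwargs = dict(d)
        for key, sub in (
            ("abc", AbcParams), ("risk", RiskParams),
            ("modules", ModuleParams), ("herit", HeritParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                _check_keys(kwargs[key], {f.name for f in dataclasses.fields(sub)}, key)
                kwargs[key] = sub(**kwargs[key])
        if "sim" in kwargs:
            _check_keys(kwargs["sim"], {f.name for f in dataclasses.fields(SimConfig)}, "sim")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# dataset file interface


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> list[Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ds.config
    paths = []

    def p(name: str) -> Path:
        path = out / name
        paths.append(path)
        return path

    write_genes(ds.genes, p("genes.tsv"))
    write_bed(ds.elements, p("elements.bed"))
    write_design(ds.design, p("design.tsv"))
    write_counts(ds.atac, p("atac_counts.tsv"))
    write_counts(ds.h3k27ac, p("h3k27ac_counts.tsv"))
    write_counts(ds.expression, p("expression_counts.tsv"))
    for chrom, cm in ds.contacts.items():
        write_contacts(cm, p(f"contacts_{chrom}.tsv"))
    write_variants(ds.variants, p("variants.tsv"))
    write_ld_table(ds.ld, p("ld.tsv"))
    ds.chi2.to_csv(p("chi2.tsv"), sep="\t")
    with open(p("meta.json"), "w") as fh:
        json.dump(
            {
                "bin_size_bp": cfg.bin_size_bp,
                "chrom_lengths": {c: cfg.chrom_len_bp for c in cfg.chroms},
                "treatments": list(cfg.treatments),
                "timepoints": list(cfg.timepoints),
            },
            fh,
            indent=1,
        )
    return paths


def load_dataset(datadir: str | Path) -> dict:
    d = Path(datadir)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    contacts = {
        chrom: read_contacts(d / f"contacts_{chrom}.tsv", meta["bin_size_bp"])
        for chrom in meta["chrom_lengths"]
        if (d / f"contacts_{chrom}.tsv").exists()
    }
    return {
        "meta": meta,
        "genes": read_genes(d / "genes.tsv"),
        "elements": read_peaks(d / "elements.bed", "bed"),
        "design": read_design(d / "design.tsv"),
        "atac": read_counts(d / "atac_counts.tsv"),
        "h3k27ac": read_counts(d / "h3k27ac_counts.tsv"),
        "expression": read_counts(d / "expression_counts.tsv"),
        "contacts": contacts,
        "variants": read_variants(d / "variants.tsv"),
        "ld": read_ld_table(d / "ld.tsv"),
        "chi2": pd.read_csv(d / "chi2.tsv", sep="\t", index_col=0),
    }


# ---------------------------------------------------------------------------
# stages


def stage_diff(data: dict, cfg: PipelineConfig, outdir: Path) -> dict:
    design = data["design"]
    expr_log = diffexpr.normalize_log_cpm(data["expression"])
    acc_log = diffexpr.normalize_log_cpm(data["atac"])
    treatments = [t for t in data["meta"]["treatments"] if t in DRUGS]
    diff_expr, diff_acc = {}, {}
    for t in treatments:
        diff_expr[t] = diffexpr.paired_contrast(expr_log, design, (t, "NT", cfg.timepoint))
        diff_acc[t] = diffexpr.paired_contrast(acc_log, design, (t, "NT", cfg.timepoint))
        diff_expr[t].to_csv(outdir / f"diffexpr_{t}_vs_NT.tsv", sep="\t")
        diff_acc[t].to_csv(outdir / f"diffacc_{t}_vs_NT.tsv", sep="\t")
    stim = diffexpr.paired_contrast(expr_log, design, ("NT", "NS", cfg.timepoint))
    stim.to_csv(outdir / "diffexpr_NT_vs_NS.tsv", sep="\t")
    coords, ratios = diffexpr.pca_overview(expr_log)
    coords.assign().to_csv(outdir / "pca_coordinates.tsv", sep="\t", index_label="sample_id")
    pd.Series(ratios, name="variance_ratio").to_csv(outdir / "pca_variance.tsv", sep="\t", index_label="pc")
    return {"expr_log": expr_log, "acc_log": acc_log, "diff_expr": diff_expr, "diff_acc": diff_acc}


def stage_modules(data: dict, cfg: PipelineConfig, outdir: Path, expr_log: pd.DataFrame) -> list:
    mods = coexpr.detect_modules(
        expr_log,
        power=cfg.modules.power,
        min_module_size=cfg.modules.min_module_size,
        cut_height_quantile=cfg.modules.cut_height_quantile,
    )
    assign = pd.DataFrame(
        [(g, m.module_id) for m in mods for g in m.gene_ids],
        columns=["gene_id", "module_id"],
    ).sort_values("gene_id")
    assign.to_csv(outdir / "module_assignment.tsv", sep="\t", index=False)
    eig = pd.DataFrame({f"M{m.module_id}": m.eigengene for m in mods})
    eig.to_csv(outdir / "module_eigengenes.tsv", sep="\t", index_label="sample_id")
    coefs = []
    for t in [t for t in data["meta"]["treatments"] if t in DRUGS]:
        coefs.append(coexpr.module_treatment_coefficients(mods, data["design"], (t, "NT", cfg.timepoint)))
    pd.concat(coefs, ignore_index=True).to_csv(outdir / "module_treatment_coefficients.tsv", sep="\t", index=False)
    return mods


def stage_abc(data: dict, cfg: PipelineConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    meta = data["meta"]
    bin_size = meta["bin_size_bp"]
    powerlaw = abc_map.fit_powerlaw(
        data["contacts"], bin_size,
        n_bins=min(meta["chrom_lengths"].values()) // bin_size,
    )
    maps = {}
    for trt in meta["treatments"]:
        for tp in meta["timepoints"]:
            cond = f"{trt}_{tp}"
            activity = abc_map.condition_activity(
                data["atac"], data["h3k27ac"], data["design"], cond,
                use_h3k27ac=cfg.abc.use_h3k27ac,
            )
            m = abc_map.build_abc_map(
                data["elements"], data["genes"], activity, data["contacts"], bin_size,
                condition=cond, window_bp=cfg.abc.window_bp, threshold=cfg.abc.threshold,
                powerlaw=powerlaw, pseudocount_frac=cfg.abc.pseudocount_frac,
            )
            maps[cond] = m
            m.to_csv(outdir / f"abc_map_{cond}.tsv", sep="\t", index=False)
            called = m[m["called"]]
            from .io_formats import Peak
            write_bed(
                [
                    Peak(GenomicInterval(r.chrom, r.start, r.end), r.element_id)
                    for r in called[["chrom", "start", "end", "element_id"]]
                    .drop_duplicates()
                    .itertuples(index=False)
                ],
                outdir / f"abc_called_{cond}.bed",
            )
    return maps


def stage_risk(data: dict, cfg: PipelineConfig, outdir: Path, maps: dict[str, pd.DataFrame]) -> tuple:
    panel = risk.LdPanel(data["variants"], data["ld"])
    expanded = risk.expand_ld(data["variants"], panel, cfg.risk.proxy_threshold)
    loci = risk.prune_to_loci(data["variants"], panel, cfg.risk.prune_threshold)
    mhc = None
    if cfg.risk.mhc:
        chrom, s1, e1 = cfg.risk.mhc
        mhc = closed1_to_halfopen0(chrom, int(s1), int(e1))
    overlap = risk.overlap_loci_with_enhancers(loci, expanded, maps, mhc)
    overlap.to_csv(outdir / "risk_overlap.tsv", sep="\t", index=False)
    seed = int(np.random.SeedSequence(cfg.seed, spawn_key=(5,)).generate_state(1)[0] % (2**31))
    enrich = risk.enrichment_per_condition(
        loci, expanded, maps, data["meta"]["chrom_lengths"],
        n_perm=cfg.risk.n_perm, seed=seed, mhc_region=mhc,
    )
    enrich.to_csv(outdir / "risk_enrichment.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(l.locus_id, l.lead_variant, ",".join(sorted(l.member_variants))) for l in loci],
        columns=["locus_id", "lead_variant", "members"],
    ).to_csv(outdir / "risk_loci.tsv", sep="\t", index=False)
    return loci, expanded, overlap, enrich


def stage_targets(cfg: PipelineConfig, outdir: Path, diff_expr, diff_acc, overlap, maps) -> pd.DataFrame:
    calls = targets.call_drug_targets(
        diff_expr, diff_acc, overlap, maps,
        expr_q_max=cfg.expr_q_max, acc_q_max=cfg.acc_q_max,
    )
    calls.to_csv(outdir / "drug_target_calls.tsv", sep="\t", index=False)
    class_map = {t: ("TNFi" if t == "TNFi" else "JAKi") for t in diff_expr}
    summary, _sets = targets.summarize_by_drug_class(calls, class_map)
    summary.to_csv(outdir / "drug_class_summary.tsv", sep="\t", index=False)
    return calls


def stage_herit(data: dict, cfg: PipelineConfig, outdir: Path, diff_acc: dict) -> pd.DataFrame:
    elements = data["elements"]
    all_peaks = sldsc.annotation_from_peaks(elements, "all_elements")
    rows = []
    fits = []
    for trt, da in diff_acc.items():
        ann = sldsc.build_topk_annotation(da, elements, k=min(cfg.herit.top_k, len(da)), name=f"top_down_{trt}")
        scores = sldsc.compute_ld_scores(data["variants"], data["ld"], [ann, all_peaks])
        per_study = []
        for study in data["chi2"].columns:
            fit = sldsc.fit_sldsc(
                data["chi2"][study].to_numpy(), 50_000, scores, [ann, all_peaks],
                data["variants"], n_blocks=cfg.herit.n_blocks,
            )
            df = fit.as_frame().assign(treatment=trt, study=study)
            fits.append(df)
            per_study.append((float(fit.tau_star[0]), float(fit.se[0])))
        est, se, p = sldsc.ivw_meta(per_study)
        rows.append((trt, est, se, p))
        with open(outdir / f"herit_annotation_{trt}.bed", "w") as fh:
            for iv in ann.regions:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    pd.concat(fits, ignore_index=True).to_csv(outdir / "herit_fits.tsv", sep="\t", index=False)
    meta = pd.DataFrame(rows, columns=["treatment", "tau_star_meta", "se", "p_onesided"])
    meta.to_csv(outdir / "herit_meta.tsv", sep="\t", index=False)
    return meta


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; return the artifact manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    stage_names = []
    try:
        stage_names.append("simulate")
        sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
        ds = simulate_all(sim_cfg)
        datadir = outdir / "data"
        write_dataset(ds, datadir)
        data = load_dataset(datadir)

        stage_names.append("diffexpr")
        diff = stage_diff(data, cfg, outdir)

        stage_names.append("coexpr_modules")
        stage_modules(data, cfg, outdir, diff["expr_log"])

        stage_names.append("abc_map")
        maps = stage_abc(data, cfg, outdir)

        stage_names.append("risk_overlap")
        _loci, _expanded, overlap, _enrich = stage_risk(data, cfg, outdir, maps)

        stage_names.append("drug_targets")
        stage_targets(cfg, outdir, diff["diff_expr"], diff["diff_acc"], overlap, maps)

        stage_names.append("heritability")
        stage_herit(data, cfg, outdir, diff["diff_acc"])
    except Exception:
        log.error("pipeline failed in stage %s; partial outputs retained in %s", stage_names[-1], outdir)
        raise

    manifest = {
        "stages": stage_names,
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
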