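import numpy as np
import pandas as pd
import pytest

from regmap.io_formats import ContactMap
from regmap.risk import LdPanel
from regmap.synthetic import (
    SimConfig,
    expected_hic_count,
    make_design,
    simulate_activity_counts,
    simulate_all,
    simulate_genome,
    simulate_gwas,
    simulate_hic,
)

SMALL = SimConfig(
    seed=11, n_genes=60, n_elements=300, n_variants=40,
    n_responsive_bg=60, closed_anchored_per_class=8, closed_bg_per_class=10,
    closed_anchored_pan=4, closed_bg_pan=6, n_causal_blocks=5, n_element_bg_blocks=3,
)


class TestGenome:
    def test_counts_and_determinism(self):
        genes, elements, truth = simulate_genome(SimConfig(seed=1))
        assert len(genes) == 300 and len(elements) == 1500
        g2, e2, t2 = simulate_genome(SimConfig(seed=1))
        assert [g.tss for g in genes] == [g.tss for g in g2]
        assert [p.interval for p in elements] == [p.interval for p in e2]
        assert truth.true_links == t2.true_links

    def test_no_elements(self):
        genes, elements, truth = simulate_genome(SimConfig(seed=1, n_elements=0))
        assert elements == [] and len(genes) == 300

    def test_elements_disjoint_and_avoid_tss_bins(self):
        genes, elements, _ = simulate_genome(SMALL)
        bs = SMALL.bin_size_bp
        tss_bins = {(g.chrom, g.tss // bs) for g in genes}
        by_chrom = {}
        for p in elements:
            iv = p.interval
            for b in range(iv.start // bs, (iv.end - 1) // bs + 1):
                assert (iv.chrom, b) not in tss_bins
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(SimConfig(seed=1, n_genes=50, n_elements=20_000, chrom_len_bp=1_000_000, edge_margin_bp=10_000))

    def test_true_links_within_radius(self):
        genes, elements, truth = simulate_genome(SMALL)
        gene_by_id = {g.gene_id: g for g in genes}
        el_by_id = {p.peak_id: p for p in elements}
        for el_id, g_id in truth.true_links:
            el, g = el_by_id[el_id], gene_by_id[g_id]
            assert el.interval.chrom == g.chrom
            assert abs(el.interval.midpoint - g.tss) <= SMALL.link_radius_bp
        # every gene is anchored to one active enhancer
        assert set(truth.anchor_of_gene) == {g.gene_id for g in genes}
        # drug-closed elements respond to stimulation
        for closed in truth.drug_closed_elements.values():
            assert closed <= truth.stim_responsive


class TestHic:
    def test_self_bin_expectation_finite(self):
        cfg = SimConfig(seed=1)
        lam0 = expected_hic_count(cfg, 0)
        assert np.isfinite(lam0)
        assert lam0 == pytest.approx(cfg.hic_c0 * cfg.bin_size_bp ** -cfg.gamma)

    def test_distance_decay_matches_closed_form(self, dataset):
        # empirical mean count over all pairs at distance d vs d'=2d should
        # match the power-law ratio within Monte-Carlo error
        cfg = dataset.config
        bs = cfg.bin_size_bp
        n_bins = cfg.chrom_len_bp // bs
        loops = set()
        gene_by = {g.gene_id: g for g in dataset.genes}
        el_by = {p.peak_id: p for p in dataset.elements}
        for el_id, g_id in dataset.truth.true_links:
            el, g = el_by[el_id], gene_by[g_id]
            bi, bj = sorted((el.interval.midpoint // bs, g.tss // bs))
            loops.add((g.chrom, bi, bj))

        def mean_count(d):
            vals = []
            for chrom, cm in dataset.contacts.items():
                for i in range(n_bins - d):
                    if (chrom, i, i + d) not in loops:
                        vals.append(cm.query(i, i + d))
            return np.mean(vals), np.std(vals) / np.sqrt(len(vals)), len(vals)

        d1, d2 = 10, 20  # bins
        m1, se1, n1 = mean_count(d1)
        m2, se2, n2 = mean_count(d2)
        assert n1 >= 1000 and n2 >= 1000
        exp1 = expected_hic_count(cfg, d1 * bs)
        exp2 = expected_hic_count(cfg, d2 * bs)
        assert abs(m1 - exp1) < 3 * se1
        assert abs(m2 - exp2) < 3 * se2

    def test_loop_pairs_boosted(self, dataset):
        cfg = dataset.config
        bs = cfg.bin_size_bp
        gene_by = {g.gene_id: g for g in dataset.genes}
        el_by = {p.peak_id: p for p in dataset.elements}
        ratios = []
        for el_id, g_id in dataset.truth.true_links:
            el, g = el_by[el_id], gene_by[g_id]
            bi, bj = sorted((el.interval.midpoint // bs, g.tss // bs))
            if bj - bi == 0:
                continue
            base = expected_hic_count(cfg, (bj - bi) * bs)
            ratios.append(dataset.contacts[g.chrom].query(bi, bj) / base)
        mean_ratio = np.mean(ratios)
        # Poisson mean of boosted counts over ~1000 loops
        assert mean_ratio == pytest.approx(cfg.loop_boost, rel=0.1)


class TestActivityCounts:
    def test_degenerate_noise_equals_rounded_expectation(self):
        cfg = SMALL.replace(dispersion=0.0, donor_sd=0.0)
        genes, elements, truth = simulate_genome(cfg)
        atac, k27, design = simulate_activity_counts(cfg, elements, truth)
        anchored = set(truth.anchor_of_gene.values())
        el0 = elements[0].peak_id
        base = cfg.enhancer_base_mean if el0 in anchored else cfg.peak_base_mean
        ns_cols = design.loc[design.treatment == "NS", "sample_id"]
        assert (atac.loc[el0, ns_cols] == round(base)).all()

    def test_unstimulated_baseline_equal_across_treatments(self):
        cfg = SMALL.replace(dispersion=0.0, donor_sd=0.0)
        genes, elements, truth = simulate_genome(cfg)
        atac, k27, design = simulate_activity_counts(cfg, elements, truth)
        # a non-responsive element has identical expected counts in every arm
        quiet = next(
            p.peak_id for p in elements if p.peak_id not in truth.stim_responsive
        )
        assert atac.loc[quiet].nunique() == 1

    def test_drug_closing_recovered_by_sign_test(self, dataset):
        cfg = dataset.config
        design = dataset.design
        closed = sorted(dataset.truth.drug_closed_elements["TNFi"])
        tnfi = design[(design.treatment == "TNFi") & (design.timepoint == "24h")]
        nt = design[(design.treatment == "NT") & (design.timepoint == "24h")]
        t_mean = dataset.atac.loc[closed, tnfi.sample_id].mean(axis=1)
        n_mean = dataset.atac.loc[closed, nt.sample_id].mean(axis=1)
        # planted -1 log2 closing: the large majority of closed elements drop
        assert (t_mean < n_mean).mean() > 0.9


class TestExpression:
    def test_determinism(self):
        a = simulate_all(SMALL)
        b = simulate_all(SMALL)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.atac, b.atac)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        assert dict(a.contacts["chr1"].items()) == dict(b.contacts["chr1"].items())

    def test_module_partition_covers_genes(self, dataset):
        assert set(dataset.truth.module_of_gene) == {g.gene_id for g in dataset.genes}
        sizes = pd.Series(dataset.truth.module_of_gene).value_counts()
        assert len(sizes) == dataset.config.n_modules


class TestGwas:
    def test_null_mean_chi2_near_one(self):
        # tau = 0 everywhere: chi2 is a central chi-square(1); pool >= 10,000 draws
        cfg = SMALL.replace(tau_target=0.0, tau_all=0.0)
        genes, elements, truth = simulate_genome(cfg)
        draws = []
        rep = 0
        while len(draws) < 10_000:
            c = cfg.replace(seed=100 + rep)
            _v, _l, chi2 = simulate_gwas(c, elements, truth)
            draws.extend(chi2.to_numpy().ravel().tolist())
            rep += 1
        mean = np.mean(draws[:10_000])
        assert abs(mean - 1.0) < 3 * np.sqrt(2.0 / 10_000)

    def test_causal_variants_inside_linked_enhancers(self, dataset):
        el_by = {p.peak_id: p for p in dataset.elements}
        linked_elements = {e for e, _g in dataset.truth.true_links}
        v = dataset.variants.set_index("variant_id")
        assert dataset.truth.causal_variants
        for vid in dataset.truth.causal_variants:
            chrom, pos = v.loc[vid, "chrom"], v.loc[vid, "pos"]
            homes = [
                e for e in linked_elements if el_by[e].interval.contains(chrom, pos)
            ]
            assert len(homes) == 1  # exactly one containing enhancer

    def test_ld_symmetric_and_self_unity(self, dataset):
        panel = LdPanel(dataset.variants, dataset.ld)
        v = dataset.variants["variant_id"]
        assert panel.r2(v.iloc[0], v.iloc[0]) == 1.0
        a, b = dataset.ld.iloc[0][["variant_a", "variant_b"]]
        assert panel.r2(a, b) == panel.r2(b, a) > 0


def test_full_generation_fast_and_deterministic_hashes():
    import time

    t0 = time.time()
    ds = simulate_all(SimConfig(seed=5))
    elapsed = time.time() - t0
    assert elapsed < 60.0
    assert len(ds.design) == 6 * 6 * 2
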