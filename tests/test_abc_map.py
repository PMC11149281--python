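import numpy as np
import pandas as pd
import pytest

from regmap import abc_map
from regmap.abc_map import (
    PowerLawFitError,
    build_abc_map,
    condition_specific_pairs,
    element_activity,
    element_gene_contact,
    fit_powerlaw,
    nearest_tss_baseline,
)
from regmap.io_formats import ContactMap, GeneAnnot, GenomicInterval, Peak


class TestActivity:
    def test_geometric_mean(self):
        assert element_activity(4.0, 9.0) == pytest.approx(6.0)
        assert element_activity(0.0, 123.4) == 0.0

    def test_matches_elementwise_recomputation(self, rng):
        a = rng.uniform(0, 50, size=200)
        k = rng.uniform(0, 50, size=200)
        out = element_activity(a, k)
        brute = np.array([np.sqrt(x * y) for x, y in zip(a, k)])
        np.testing.assert_allclose(out, brute)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            element_activity(-1.0, 2.0)


class TestPowerLaw:
    def test_exact_recovery_noiseless(self):
        # counts laid down exactly as c0 * d**-1 over every pair
        bs, n_bins, c0 = 5000, 400, 1e5
        cm = ContactMap(bs)
        for d in range(1, 250):
            lam = c0 * (d * bs) ** -1.0
            for i in range(n_bins - d):
                cm.add(i, i + d, lam)
        c0_fit, gamma_fit = fit_powerlaw(cm, bs, n_bins=n_bins)
        assert gamma_fit == pytest.approx(1.0, abs=1e-6)
        assert c0_fit == pytest.approx(c0, rel=1e-6)

    def test_simulated_gamma_within_tolerance(self, dataset, powerlaw_fit):
        assert abs(powerlaw_fit[1] - dataset.config.gamma) < 0.15

    def test_empty_matrix_errors(self):
        with pytest.raises(PowerLawFitError):
            fit_powerlaw(ContactMap(5000), 5000, n_bins=100)


class TestContact:
    PL = (1000.0, 1.0)  # c0, gamma

    def _peak(self, chrom, mid):
        return Peak(GenomicInterval(chrom, mid - 250, mid + 250), "el")

    def test_same_bin_uses_fitted_value(self):
        cm = ContactMap(5000)
        cm.add(2, 2, 99.0)
        el = self._peak("chr1", 12_000)
        gene = GeneAnnot("g", "chr1", 13_000)
        c = element_gene_contact(el, gene, cm, 5000, self.PL)
        assert c == pytest.approx(1000.0 * 5000 ** -1.0)

    def test_absent_pair_is_pseudocount_only(self):
        cm = ContactMap(5000)
        el = self._peak("chr1", 2_500)
        gene = GeneAnnot("g", "chr1", 52_500)  # 50 kb away
        c = element_gene_contact(el, gene, cm, 5000, self.PL)
        assert c == pytest.approx(1000.0 * 1_000_000 ** -1.0)

    def test_trans_is_zero(self):
        cm = ContactMap(5000)
        cm.add(0, 10, 50)
        el = self._peak("chr1", 2_500)
        gene = GeneAnnot("g", "chr2", 52_500)
        assert element_gene_contact(el, gene, cm, 5000, self.PL) == 0.0

    def test_dense_toy_matches_hand_lookup(self, rng):
        bs = 1000
        cm = ContactMap(bs)
        counts = {}
        for i in range(10):
            for j in range(i, 10):
                c = float(rng.integers(1, 100))
                cm.add(i, j, c)
                counts[(i, j)] = c
        pseudo = self.PL[0] * 1_000_000 ** -self.PL[1]
        for bi in range(10):
            for bj in range(10):
                el = Peak(GenomicInterval("chr1", bi * bs + 100, bi * bs + 900), "e")
                gene = GeneAnnot("g", "chr1", bj * bs + 500)
                got = element_gene_contact(el, gene, cm, bs, self.PL)
                if bi == bj:
                    assert got == pytest.approx(self.PL[0] * bs ** -self.PL[1])
                else:
                    key = (min(bi, bj), max(bi, bj))
                    assert got == pytest.approx(counts[key] + pseudo)


class TestBuildMap:
    def _simple_world(self, activities, mids, tss=500_000):
        elements = [
            Peak(GenomicInterval("chr1", m - 250, m + 250), f"e{i}")
            for i, m in enumerate(mids)
        ]
        genes = [GeneAnnot("g0", "chr1", tss)]
        activity = pd.Series(activities, index=[p.peak_id for p in elements])
        contacts = {"chr1": ContactMap(5000)}
        return elements, genes, activity, contacts

    def test_single_candidate_scores_one(self):
        elements, genes, activity, contacts = self._simple_world([5.0], [450_000])
        m = build_abc_map(elements, genes, activity, contacts, 5000, powerlaw=(1000.0, 1.0))
        assert len(m) == 1
        assert m.abc_score.iloc[0] == pytest.approx(1.0)
        assert bool(m.called.iloc[0])

    def test_equal_contact_activity_ratio(self):
        # two elements equidistant from the TSS with activities 4 and 1
        elements, genes, activity, contacts = self._simple_world(
            [4.0, 1.0], [450_000, 550_000]
        )
        m = build_abc_map(elements, genes, activity, contacts, 5000, powerlaw=(1000.0, 1.0))
        scores = m.set_index("element_id").abc_score
        assert scores["e0"] == pytest.approx(0.8)
        assert scores["e1"] == pytest.approx(0.2)

    def test_zero_activity_degenerate(self):
        elements, genes, activity, contacts = self._simple_world(
            [0.0, 0.0], [450_000, 550_000]
        )
        m = build_abc_map(elements, genes, activity, contacts, 5000, powerlaw=(1000.0, 1.0))
        assert (m.abc_score == 0).all()
        assert not m.called.any()

    def test_promoter_excluded_but_normalizes(self):
        # element overlapping the TSS is dropped from output yet absorbs score mass
        elements, genes, activity, contacts = self._simple_world(
            [4.0, 4.0], [500_100, 550_000]
        )
        m = build_abc_map(elements, genes, activity, contacts, 5000, powerlaw=(1000.0, 1.0))
        assert list(m.element_id) == ["e1"]
        assert m.abc_score.iloc[0] < 1.0

    def test_monotonicity_in_activity(self, rng):
        mids = sorted(rng.integers(300_000, 700_000, size=8).tolist())
        base = rng.uniform(1, 10, size=8)
        elements, genes, activity, contacts = self._simple_world(base.tolist(), mids)
        m0 = build_abc_map(elements, genes, activity, contacts, 5000, powerlaw=(1000.0, 1.0))
        bumped = activity.copy()
        bumped["e3"] *= 3.0
        m1 = build_abc_map(elements, genes, bumped, contacts, 5000, powerlaw=(1000.0, 1.0))
        s0 = m0.set_index("element_id").abc_score
        s1 = m1.set_index("element_id").abc_score
        assert s1["e3"] >= s0["e3"]

    def test_per_gene_normalization_on_synthetic_map(self, abc_nt):
        sums = abc_nt.groupby("gene_id").abc_score.sum()
        # promoter elements never occur in the synthetic layout, so sums are
        # exactly the per-gene normalization
        assert (np.abs(sums - 1.0) < 1e-9).all()


class TestConditionSpecific:
    def _map(self, pairs):
        return pd.DataFrame(
            [(e, g, True) for e, g in pairs], columns=["element_id", "gene_id", "called"]
        )

    def test_identical_maps_empty(self):
        m = self._map([("e1", "g1"), ("e2", "g1")])
        assert condition_specific_pairs(m, m) == set()

    def test_disjoint_maps_all(self):
        a = self._map([("e1", "g1"), ("e2", "g2")])
        b = self._map([("e3", "g3")])
        assert condition_specific_pairs(a, b) == {("e1", "g1"), ("e2", "g2")}

    def test_five_pair_example(self):
        a = self._map([("e1", "g1"), ("e2", "g1"), ("e3", "g2"), ("e4", "g2"), ("e5", "g3")])
        b = self._map([("e2", "g1"), ("e4", "g2")])
        assert condition_specific_pairs(a, b) == {("e1", "g1"), ("e3", "g2"), ("e5", "g3")}


class TestNearestTss:
    def test_simple_and_tie(self):
        genes = [GeneAnnot("gA", "chr1", 100), GeneAnnot("gB", "chr1", 200)]
        el = Peak(GenomicInterval("chr1", 130, 150), "e")  # mid 140
        assert nearest_tss_baseline([el], genes) == [("e", "gA")]
        el_tie = Peak(GenomicInterval("chr1", 140, 160), "t")  # mid 150: equidistant
        assert nearest_tss_baseline([el_tie], genes) == [("t", "gA")]

    def test_matches_exhaustive_search(self, rng):
        genes = [
            GeneAnnot(f"g{i}", "chr1", int(p))
            for i, p in enumerate(rng.integers(0, 1_000_000, size=40))
        ]
        elements = [
            Peak(GenomicInterval("chr1", int(s), int(s) + 100), f"e{i}")
            for i, s in enumerate(rng.integers(0, 1_000_000, size=60))
        ]
        got = dict(nearest_tss_baseline(elements, genes))
        for p in elements:
            mid = p.interval.midpoint
            best = min(genes, key=lambda g: (abs(g.tss - mid), g.tss, g.gene_id))
            assert got[p.peak_id] == best.gene_id


def test_abc_predicts_expression_better_than_nearest_tss(dataset, abc_nt):
    """Called ABC partners explain planted expression responses better than
    the nearest-TSS baseline (directional check on the drug-closing effect)."""
    truth = dataset.truth
    closed = truth.drug_closed_elements["TNFi"]
    called = abc_nt[abc_nt.called]
    abc_genes = set(called[called.element_id.isin(closed)].gene_id)
    nt_pairs = nearest_tss_baseline(dataset.elements, dataset.genes)
    nt_genes = {g for e, g in nt_pairs if e in closed}
    # genes that truly inherit the TNFi effect through their anchored enhancer
    true_resp = {
        g for g, e in truth.anchor_of_gene.items() if e in closed
    } | truth.decoupled_genes.get("TNFi", set())

    def f1(pred):
        if not pred:
            return 0.0
        tp = len(pred & true_resp)
        prec, rec = tp / len(pred), tp / len(true_resp)
        return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)

    assert f1(abc_genes) > f1(nt_genes)
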