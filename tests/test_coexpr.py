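import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regmap.coexpr import (
    ODDS_RATIO_CAP,
    detect_modules,
    enrich_modules_in_regions,
    module_treatment_coefficients,
    pick_soft_power,
    topological_overlap,
)
from regmap.diffexpr import normalize_log_cpm


class TestSoftPower:
    def test_independent_genes_need_high_power(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(
            rng.normal(size=(150, 40)), index=[f"g{i}" for i in range(150)]
        )
        assert pick_soft_power(x) >= 6

    def test_block_structure_needs_small_power(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=(2, 40))
        rows = []
        for i in range(100):
            rows.append(latent[i % 2] + rng.normal(0, 0.05, size=40))
        x = pd.DataFrame(rows, index=[f"g{i}" for i in range(100)])
        assert pick_soft_power(x) <= 6

    def test_single_gene_errors(self):
        with pytest.raises(ValueError):
            pick_soft_power(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"]))


class TestTom:
    def test_complete_graph_all_ones(self):
        a = np.ones((3, 3))
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom, np.ones((3, 3)))

    def test_empty_graph_identity(self):
        tom = topological_overlap(np.zeros((4, 4)))
        np.testing.assert_allclose(tom, np.eye(4))

    def test_matches_brute_force_double_loop(self, rng):
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = topological_overlap(a)
        k = a.sum(axis=1)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(6)) + a[i, j]
                den = min(k[i], k[j]) + 1 - a[i, j]
                assert tom[i, j] == pytest.approx(num / den)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        a = rng.uniform(0, 1, size=(20, 20))
        a = (a + a.T) / 2
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom, tom.T)
        assert np.all(np.diag(tom) == 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestDetectModules:
    def _two_block_data(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(size=(2, 60))
        rows = [latent[i % 2] + rng.normal(0, 0.01, size=60) for i in range(80)]
        return pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(80)])

    def test_two_copy_blocks_recovered(self):
        x = self._two_block_data()
        mods = detect_modules(x, power=6)
        real = [m for m in mods if m.module_id > 0]
        assert len(real) == 2
        got = {frozenset(m.gene_ids) for m in real}
        want = {
            frozenset(g for i, g in enumerate(x.index) if i % 2 == 0),
            frozenset(g for i, g in enumerate(x.index) if i % 2 == 1),
        }
        assert got == want

    def test_eigengene_sign_aligned_with_module_mean(self, dataset):
        logcpm = normalize_log_cpm(dataset.expression)
        for m in detect_modules(logcpm):
            if m.module_id == 0 or len(m.gene_ids) < 2:
                continue
            sub = logcpm.loc[m.gene_ids]
            z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1), axis=0)
            assert np.corrcoef(m.eigengene, z.mean(axis=0))[0, 1] > 0

    def test_partition_invariant_to_gene_order(self):
        x = self._two_block_data()
        shuffled = x.sample(frac=1.0, random_state=5)
        a = {frozenset(m.gene_ids): m.module_id for m in detect_modules(x, power=6)}
        b = {frozenset(m.gene_ids): m.module_id for m in detect_modules(shuffled, power=6)}
        assert a == b

    def test_too_few_genes_single_unassigned(self):
        x = self._two_block_data().iloc[:10]
        mods = detect_modules(x, power=6, min_module_size=30)
        assert [m.module_id for m in mods] == [0]

    def test_eigengene_first_pc_optimality(self, dataset):
        # the eigengene captures at least as much standardized variance as
        # any single gene profile used as the module summary
        logcpm = normalize_log_cpm(dataset.expression)
        mods = [m for m in detect_modules(logcpm) if m.module_id > 0]
        m = mods[0]
        sub = logcpm.loc[m.gene_ids]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1), axis=0).to_numpy()
        eig = m.eigengene.to_numpy()
        eig = eig / np.linalg.norm(eig)
        explained_eig = ((z @ eig) ** 2).sum()
        for i in range(z.shape[0]):
            u = z[i] / np.linalg.norm(z[i])
            assert explained_eig >= ((z @ u) ** 2).sum() - 1e-9


class TestModuleCoefficients:
    def test_hand_computed_six_donor_fixture(self):
        design = pd.DataFrame(
            [
                (f"D{d}_{t}_24h", f"D{d}", t, "24h")
                for d in range(6)
                for t in ("NT", "TNFi")
            ],
            columns=["sample_id", "donor", "treatment", "timepoint"],
        )
        rng = np.random.default_rng(3)
        eig = pd.Series(rng.normal(size=12), index=design.sample_id.tolist())
        from regmap.coexpr import CoexprModule

        mod = CoexprModule(1, ["g1"], eig)
        out = module_treatment_coefficients([mod], design, ("TNFi", "NT", "24h"))
        d = np.array(
            [eig[f"D{i}_TNFi_24h"] - eig[f"D{i}_NT_24h"] for i in range(6)]
        )
        assert out.coefficient.iloc[0] == pytest.approx(d.mean())
        assert out.se.iloc[0] == pytest.approx(d.std(ddof=1) / np.sqrt(6))
        t_ref, p_ref = stats.ttest_1samp(d, 0.0)
        assert out.pvalue.iloc[0] == pytest.approx(p_ref)

    def test_constant_eigengene_zero_coefficient(self):
        design = pd.DataFrame(
            [
                (f"D{d}_{t}_24h", f"D{d}", t, "24h")
                for d in range(4)
                for t in ("NT", "TNFi")
            ],
            columns=["sample_id", "donor", "treatment", "timepoint"],
        )
        from regmap.coexpr import CoexprModule

        eig = pd.Series(1.0, index=design.sample_id.tolist())
        out = module_treatment_coefficients([CoexprModule(1, [], eig)], design, ("TNFi", "NT", "24h"))
        assert out.coefficient.iloc[0] == 0.0
        assert out.pvalue.iloc[0] == 1.0

    def test_planted_tnfi_module_has_negative_tnfi_coefficient(self, dataset):
        """The module carrying the planted TNFi-repression profile gets a
        clearly negative TNFi coefficient and a near-zero JAKi one."""
        logcpm = normalize_log_cpm(dataset.expression)
        mods = detect_modules(logcpm)
        truth = dataset.truth
        tnfi_genes = {g for g, m in truth.module_of_gene.items() if m == 1}
        target = max(
            (m for m in mods if m.module_id > 0),
            key=lambda m: len(set(m.gene_ids) & tnfi_genes),
        )
        assert len(set(target.gene_ids) & tnfi_genes) / len(target.gene_ids) > 0.8
        tnfi = module_treatment_coefficients([target], dataset.design, ("TNFi", "NT", "24h"))
        jaki = module_treatment_coefficients([target], dataset.design, ("JAKi1", "NT", "24h"))
        assert tnfi.coefficient.iloc[0] < 0 and tnfi.pvalue.iloc[0] < 0.01
        assert abs(jaki.coefficient.iloc[0]) < abs(tnfi.coefficient.iloc[0]) / 3


class TestEnrichment:
    def _modules(self, groups):
        from regmap.coexpr import CoexprModule

        return [
            CoexprModule(i + 1, list(g), pd.Series(dtype=float))
            for i, g in enumerate(groups)
        ]

    def test_module_equal_to_region_set(self):
        mod1 = {f"a{i}" for i in range(10)}
        mod2 = {f"b{i}" for i in range(40)}
        mods = self._modules([mod1, mod2])
        out = enrich_modules_in_regions(mods, mod1)
        row = out[out.module_id == 1].iloc[0]
        assert row.odds_ratio == ODDS_RATIO_CAP
        assert row.pvalue < row.bonferroni_cutoff
        assert bool(row.bonferroni_significant)

    def test_toy_table_matches_hypergeometric_tail(self):
        # 2x2 table (8,2;10,80): two-sided Fisher p by pmf enumeration
        mods = self._modules([set(f"m{i}" for i in range(8)) | set(f"x{i}" for i in range(2))])
        region = set(f"m{i}" for i in range(8)) | set(f"r{i}" for i in range(10))
        universe_pad = [set(f"x{i}" for i in range(2)) | set(f"r{i}" for i in range(10)) | set(f"u{i}" for i in range(80))]
        mods += self._modules(universe_pad)  # second module completes the universe
        out = enrich_modules_in_regions(mods, region)
        p_fisher = out[out.module_id == 1].pvalue.iloc[0]
        # independent enumeration of the hypergeometric two-sided tail
        M, n, N = 100, 18, 10  # universe, region genes, module size
        pmf = [stats.hypergeom.pmf(k, M, n, N) for k in range(N + 1)]
        p_obs = pmf[8]
        p_ref = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
        assert p_fisher == pytest.approx(p_ref, rel=1e-6)

    def test_uniform_regions_nominally_calibrated(self, rng):
        universe = [f"g{i}" for i in range(400)]
        mods = self._modules(
            [set(universe[i * 50 : (i + 1) * 50]) for i in range(8)]
        )
        hits = 0
        tests = 0
        for _ in range(200):
            region = set(rng.choice(universe, size=60, replace=False))
            out = enrich_modules_in_regions(mods, region)
            hits += (out.pvalue < 0.05).sum()
            tests += len(out)
        # Fisher's exact is conservative on discrete tables: nominal rate
        # stays at or below ~5%
        assert 0.005 < hits / tests < 0.07
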