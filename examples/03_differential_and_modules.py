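"""Donor-paired differential analysis, PCA and co-expression modules.

The paired contrast forms per-donor log-CPM differences between two arms,
so donor-level variation cancels exactly; co-expression modules are
detected from a topological-overlap network and summarized by eigengenes.
"""

from regmap import coexpr, diffexpr
from regmap.synthetic import SimConfig, simulate_all

ds = simulate_all(SimConfig(seed=1))
expr_log = diffexpr.normalize_log_cpm(ds.expression)

coords, ratios = diffexpr.pca_overview(expr_log, n_top=300)
print(f"PC1 variance ratio: {ratios[0]:.2f} (separates stimulated from non-stimulated)")

res = diffexpr.paired_contrast(expr_log, ds.design, ("TNFi", "NT", "24h"))
n_sig = int((res.qvalue <= 0.05).sum())
print(f"genes modulated by the TNFi vs non-treated at 24h (q <= 0.05): {n_sig}")

mods = coexpr.detect_modules(expr_log)
real = [m for m in mods if m.module_id > 0]
print(f"detected modules: {len(real)} (planted: {ds.config.n_modules})")

coefs = coexpr.module_treatment_coefficients(mods, ds.design, ("TNFi", "NT", "24h"))
coefs = coefs[coefs.module_id > 0].sort_values("coefficient")
top = coefs.iloc[0]
print(
    f"most TNFi-repressed module: M{int(top.module_id)} "
    f"(coefficient {top.coefficient:.2f}, p {top.pvalue:.1e})"
)
# One planted module carries a TNFi-preferential repression profile; its
# eigengene drops specifically in the TNFi arm, which is what the large
# negative coefficient reports.
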