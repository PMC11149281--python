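# regmap

Integrative analysis of how anti-cytokine drugs act on the regulatory
genome of activated synovial fibroblasts — the stromal cells of the joint
lining that drive inflammation in rheumatoid arthritis. Starting from
count-level multi-omics (ATAC-seq peaks, H3K27ac, RNA-seq, binned Hi-C) of
a donor-paired perturbation design (non-stimulated, stimulated non-treated,
a TNF inhibitor and three JAK inhibitors, two timepoints), the package:

1. runs **donor-paired differential analysis** of expression and chromatin
   accessibility, with a PCA overview of the top variable genes;
2. detects **co-expression modules** (soft-thresholded correlation network,
   topological overlap, tree cut, eigengenes) and their treatment
   responses, plus Fisher-exact enrichment of modules in gene sets;
3. builds an **activity-by-contact (ABC) enhancer–gene map** per condition:

   ```
   ABC(e, g) = A(e) · C(e, g) / Σ_e' A(e') · C(e', g)
   ```

   with activity `A = sqrt(ATAC_CPM · H3K27ac_CPM)` and contact `C` the
   Hi-C count between the element and TSS bins plus a fitted power-law
   pseudocount; pairs with score ≥ 0.02 within a 5 Mb window are called;
4. overlaps **GWAS risk variants** with called enhancers after LD expansion
   (r² > 0.8) and greedy locus pruning (r² > 0.1), and tests per-condition
   enrichment against a circular-rotation null;
5. calls **drug-targeted risk enhancer–gene pairs** — risk enhancers whose
   linked gene is significantly modulated by a drug, flagged
   direction-consistent when chromatin also closes — and summarizes them by
   drug class (TNFi vs JAKi, unanimity rule);
6. fits a **minimal stratified LD-score regression**,
   `E[χ²_j] = 1 + N Σ_c τ_c ℓ(j,c)`, on treatment-response chromatin
   annotations (top-k most down-regulated regions per drug, adjusted for
   all accessible chromatin), with block-jackknife errors and
   inverse-variance-weighted meta-analysis of normalized coefficients (τ*)
   across GWAS studies.

A fully specified **synthetic multi-omics generator** with planted ground
truth (enhancer–gene loops, module memberships, drug-closed elements,
causal variants, heritability coefficients) makes every stage testable
without any external data. Real data at the same count/peak/contact level
can be supplied through the documented TSV/BED/triplet formats.

## Worked example

```python
from regmap import abc_map
from regmap.synthetic import SimConfig, simulate_all

ds = simulate_all(SimConfig(seed=1))
c0, gamma = abc_map.fit_powerlaw(ds.contacts, 5000, n_bins=2000)
activity = abc_map.condition_activity(ds.atac, ds.h3k27ac, ds.design, "NT_24h")
amap = abc_map.build_abc_map(ds.elements, ds.genes, activity, ds.contacts,
                             5000, condition="NT_24h", powerlaw=(c0, gamma))
```

Running `python examples/02_abc_enhancer_map.py` prints:

```
fitted contact decay: count ~ 166690 * d^-0.99 (simulated gamma = 1.0)
called pairs: 1347; planted links: 1245
recall: 1.00, false discovery rate: 0.08
pairs specific to the stimulated map vs non-stimulated: 34
```

The fitted decay exponent recovers the simulated value, the called pairs
recover every planted enhancer–gene loop with 8% false discovery, and a
small set of pairs is specific to the stimulated chromatin state.
`examples/04_risk_variants_and_targets.py` continues the analysis:

```
120 top variants pruned to 30 independent risk loci
loci overlapping stimulated enhancers: 15 (rotation null expects 0.7, empirical p = 9.99e-04)
drug-target calls on risk enhancers: 112
drug_class  n_called  n_specific  n_shared
      JAKi        10           0        10
      TNFi        33          23        10
```

Fifteen loci — exactly the planted causal blocks — land in called
enhancers where the rotation null expects fewer than one, and the
class summary separates TNFi-specific from JAKi-specific risk-enhancer
suppression. The other scripts in `examples/` walk through simulation,
differential analysis + modules, and heritability partitioning.

## Command line

A thin CLI wraps the same library calls:

```bash
regmap demo --outdir demo_out --seed 1     # full synthetic run, one command
regmap simulate --seed 1 --outdir data     # just the dataset
regmap run-all --config my_config.yaml     # every stage from one YAML config
```

`run-all` echoes its config, writes every table in documented formats and
records a manifest of artifact content hashes; reruns with the same seed
reproduce the hashes.

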