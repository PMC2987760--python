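# countersig

Exact statistics for **drug–disease signature reversal**: does a drug's
transcriptional signature oppose a disease's? `countersig` maps a drug gene
set to the disease species through a homology table, pools multi-study
directional disease signatures, tests the drug set for enrichment in the
disease-upregulated list and depletion in the downregulated list with exact
hypergeometric probabilities, extracts the *counteracting commonality*
genes (disease-up ∩ drug-hit — the candidate therapeutic mediators), and
scans a pathway collection for their over-representation against the
disease-upregulated background.

It was built for the comparative-transcriptomics design in which a fly
model's PTZ-downregulated genes are compared against pooled Down-syndrome
brain signatures, but every stage is generic: plain gene-symbol lists in, a
two-column homology TSV, standard GMT pathway files.

The core statistic, for a universe of N genes with K in the category and a
sample of n containing k category members:

    P[X = k] = C(K, k) C(N−K, n−k) / C(N, n)

with enrichment judged by P[X ≥ k] and depletion by P[X ≤ k]. All three
conventions are always reported; significance calls use the tails by
default, while `convention="point"` reproduces values published from legacy
spreadsheet point-mass calculations. See `docs/methods.md` for the model,
conventions and limitations.

Because the original studies' supplementary gene lists are not
redistributable, the package ships an exact-planting **synthetic
generator**: it fabricates drug lists, study signatures, homology tables
and GMT collections with any feasible cardinalities planted exactly, so the
published counts are exercised end-to-end without downloads.

## Worked example

```python
from countersig import (
    generate_bundle, published_example_config, venn_counts,
    directional_overlap_test, scan_pathways,
)

bundle = generate_bundle(published_example_config(seed=1))
print(venn_counts(bundle.pooled, bundle.drug_mapped).as_tuple())

up, down = directional_overlap_test(bundle.pooled, bundle.drug_mapped)
print(f"up: k={up.counts.k} p_upper={up.p_upper:.4f} -> {up.call.value}")
print(f"down: k={down.counts.k} p_lower={down.p_lower:.4f} -> {down.call.value}")

for r in scan_pathways(bundle.commonality, bundle.pooled.up,
                       bundle.collection, convention="point")[:3]:
    print(f"{r.pathway}: K={r.background_hits} k={r.foreground_hits} "
          f"p_point={r.p_point:.4f} hits={','.join(r.hit_genes)}")
```

prints

```
(716, 419, 301, 56, 41, 16)
up: k=41 p_upper=0.0131 -> enriched
down: k=16 p_lower=0.0220 -> depleted
NK_cytotoxicity_like: K=5 k=3 p_point=0.0072 hits=DSG00422,DSG00529,DSG00669
Arginine_proline_like: K=7 k=3 p_point=0.0209 hits=DSG00405,DSG00437,DSG00547
ErbB_signaling_like: K=7 k=3 p_point=0.0209 hits=DSG00156,DSG00471,DSG00570
```

Reading: of 716 pooled disease genes (419 up, 301 down), 56 are drug
homologs; 41 of them sit in the up list — more than the 32.8 expected by
chance (upper-tail p = 0.013, enriched) — and only 16 in the down list
(lower-tail p = 0.022, depleted): the drug signature counteracts the
disease's. The scan then finds the 41 commonality genes over-represented in
several planted pathways; point-mass p-values shown for legacy
comparability.

The same run from the shell:

```sh
countersig simulate --out bundle/ --seed 1
countersig pipeline --config bundle/config.yaml
```

writes `report.json`, `overlap.tsv`, `enrichment.tsv`,
`commonality_genes.txt` and `run.log` under `bundle/results/`. See
`examples/` for one short script per capability and `countersig --help`
for the `overlap`, `enrich`, `scan`, `pipeline` and `simulate` subcommands.

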