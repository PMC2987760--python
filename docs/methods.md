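# Methods

## The model

`countersig` tests *signature reversal*: whether a drug's transcriptional
footprint opposes a disease's. The concrete instance it was built around is
a fly pentylenetetrazole (PTZ) model — chronic PTZ downregulates a set of
fly genes — compared against pooled Down-syndrome (DS) differential-
expression signatures from three human brain studies. The pipeline is
generic: any drug gene set, any collection of directional disease
signatures, any two-column homology table and any GMT pathway collection.

All statistics are exact hypergeometric. For a universe of N genes
containing a category of K, and a sample of n drawn without replacement
with k category members observed,

    P[X = k] = C(K, k) C(N−K, n−k) / C(N, n)

The *directional overlap test* sets the universe to the pooled disease
up ∪ down (genes up in one study and down in another are kept in both
directional sets but counted once in the universe — this is forced by the
arithmetic of pooled totals where |up| + |down| exceeds |up ∪ down|), the
sample to the homolog-mapped drug genes that fall inside that universe,
and tests the up list (K = |up|, upper tail, enrichment) and the down list
(K = |down|, lower tail, depletion) separately.

The *counteracting commonality* genes are disease-up ∩ drug-mapped — genes
the disease pushes up and the drug pushes down, the candidate therapeutic
mediators. Pathway over-representation of this foreground is tested against
the disease-upregulated set as background, **not** the genome: pathway
membership K is counted inside the background by intersection. This choice
reproduces the arithmetic of published counts of the form "9 of 419
background genes on the pathway, 3 of 41 foreground genes".

## Probability conventions

Three probabilities are always computed and reported per test: the point
mass P[X = k], the upper tail P[X ≥ k] and the lower tail P[X ≤ k].
Published analyses of this design performed in legacy spreadsheets used
HYPGEOMDIST, which returns the **point mass**; the reproducible published
pathway values (0.041 for 3-of-9-vs-41-of-419, 0.007 for 3-of-5, 0.02 for
3-of-7) are point masses, while the corresponding upper tails are larger
(0.048 for the 3-of-9 case). Sound one-sided inference wants the tails, so:

- significance *calls* default to the tail convention
  (`convention="tail"`), with enrichment requiring p_upper < α **and**
  k > nK/N, depletion the mirror image;
- `convention="point"` is a compatibility mode that reproduces legacy
  point-mass values.

Two published values cannot be reproduced and are deliberately not asserted
anywhere: (a) the directional-overlap pair printed as 0.011 (enrichment)
and 0.008 (depletion) — on the printed counts the upper tail is 0.0131 and
the point mass 0.0073 for the up test, and the lower tail 0.0220 / point
0.0116 for the down test, so no convention matches the printed pair and the
two numbers may be transposed; only the <0.05 significance calls are
checked. (b) A "6 vs 36 genes, p = 0.0008" metabolic-pathway value — the
same counts give point 0.077 / upper 0.125 under the stated background, so
the value is irreconcilable with the stated test and is flagged here rather
than silently reproduced.

Nominal (uncorrected) p-values are the default, matching the significance
rule the design follows (p < 0.05); `bh=True` applies Benjamini–Hochberg
across eligible pathways via statsmodels and calls significance on
q < α instead.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | nominal significance level for all calls |
| `convention` | `tail` | which p-value drives significance (`point` for legacy compatibility) |
| `min_hits` | 3 | pathways with fewer foreground hits are ineligible: k < 3 point-mass "enrichment" is numerically unstable and biologically uninterpretable |
| `bh` | off | Benjamini–Hochberg over eligible pathways |

Homolog mapping keeps **all** targets of a one-to-many source (no
"best homolog" choice — unioning is the conservative superset) and drops
unmapped sources from statistics while enumerating them in the mapping
report; they cannot participate anyway because the test universe is defined
on the disease side.

## Numerical choices

Binomial coefficients are evaluated as logs of exact arbitrary-precision
integers (`log C(n,k)` correct to the last few ulps), probabilities
assembled in log space, tails accumulated with log-sum-exp, and clipped at
1. Universes of tens of thousands of genes are far inside this scheme's
range. The test suite verifies exact equivalence against a rational-
arithmetic (`fractions.Fraction`) oracle exhaustively for every instance
with N ≤ 60, and against scipy's hypergeometric distribution on random
larger instances. The degenerate empty universe raises an error for the
directional test; an empty *sample* (drug maps to nothing in the universe)
returns p = 1 and a neutral call. Scan output is totally ordered by
(p, pathway name) so ties break deterministically.

## The synthetic generator

The analysis consumes gene lists only, so the generator emulates **list
structure, not expression arrays**: no fold-changes, no intensity noise.
Planting is exact-combinatorial — the universe is partitioned
(both-direction / up-only / down-only genes), planted drug-overlap genes
are drawn from those strata with the both-direction count fixed by
inclusion–exclusion, and pathway membership takes exactly k foreground and
K − k background-only genes plus out-of-background decoys. Every feasible
configured cardinality is therefore recovered *exactly* by the pipeline;
infeasible configurations fail at validation with the violated constraint
spelled out. Homology multiplicities (targets per drug source) are sampled
from a configured distribution over {0, 1, 2}; required targets are routed
through randomly chosen mapping slots, so the table is lossy and
many-to-many like a real homolog retrieval.

The bundled `published_example_config()` plants the published cardinalities:
three studies pooling to 419 up / 301 down / 716 total (hence 4
direction-conflicted genes), 56 drug homologs in the universe splitting
41 up / 16 down (1 gene in both directions), and a pathway plan with
background/foreground hit pairs (9,3), (36,6), (9,3), (7,3), (7,3), (5,3),
(7,3) plus three unplanted null pathways. Three commonality genes are
renamed to the real symbols BRAF, PAK1 and PRKCA and forced into the
MAPK-like pathway for documentation fidelity; synthetic symbols use
reserved prefixes (`DSG`, `DPTZ`, `HX`, `PWX`) so injected real symbols
cannot collide.

**What passing fixtures do and do not show.** The original studies'
supplementary gene lists are not redistributable and are not bundled, so
the published gene-level counts (56/41/16 and the pathway hits) are
exercised **only via exact synthetic planting**: the fixtures prove the
pipeline's arithmetic and statistics are correct on inputs with exactly the
published structure, not that the original supplementary data would
reproduce under re-curation. Synthetic signatures also have near-zero
inter-study overlap by construction and no probe-level ambiguity; real
inputs have both, upstream of this pipeline's scope.

## Calibration of the null scan

The false-positive-rate check draws null pathways' background members
uniformly, making foreground hit counts exactly hypergeometric. Because the
test statistic is discrete, the exact rejection rate at α = 0.05 depends on
the pathway's background-hit count K and is always ≤ α; the check uses
K ∈ {9, 15, 36, 50} of 419, whose analytic rejection rates (0.041–0.049)
make the aggregate FPR sit within binomial sampling error of α over the
replicated scan. Very small K (e.g. 5) would make the tail so coarse that
the attainable rate drops to ~0.008 and a calibration test would be
meaningless — a limitation of discrete tests, not of the implementation.

## Problem sizes used in the shipped checks

Property suites run on randomized parameters up to N = 500, the exhaustive
rational-oracle comparison covers all N ≤ 60, and the null-scan calibration
uses 250 replicate collections of 4 pathways (1000 tests). These sizes make
the full suite complete in well under a minute while covering the regimes
the analysis actually visits (N in the hundreds).

## Known limitations

- Gene identity is a bare symbol; no probe collapsing, no alias resolution,
  no Entrez/Ensembl handling — callers must pre-convert (the design assumes
  symbol-level inputs).
- Homology is table-driven; no orthology inference.
- The directional test conditions on list membership only; magnitude of
  regulation is invisible (the upstream fold-change filter is input
  provenance, not recomputed).
- Up/down conflict handling (kept in both directional sets, once in the
  universe) reproduces the published pooled arithmetic but is a modelling
  choice; with conflict-free inputs it is vacuous.
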