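# mutlike

Discovery and calling of a **TP53-mutant-like** subgroup in TP53-wild-type
acute myeloid leukemia (AML) from bulk expression data.

A fraction of AML patients carry a wild-type *TP53* gene yet behave
clinically and molecularly like *TP53*-mutant disease (suppressed TP53
signaling, stem-cell-like programs, poor survival, drug resistance) —
in part through a high ratio of the truncated ΔNp73 isoform of TP73 to the
full-length TAp73 isoform. `mutlike` implements the computational machinery
to find and characterize that subgroup, for computational biologists who
want a reproducible, testable version of the procedure:

- **Signature derivation** — per-cohort Mann-Whitney differential
  expression (mutant vs wild-type), Benjamini-Hochberg correction, and the
  intersection of the top-20%-by-fold-change up-regulated genes across
  cohorts.
- **Single-sample GSEA (ssGSEA)** — implemented from first principles:
  ES = Σᵢ [P_in(i) − P_out(i)] with |rank|^α weighting (α = 0.75), plus
  preranked GSEA with a gene-permutation null, NES, nominal p and FDR q.
- **Subgroup calling** — Spearman-correlation hierarchical clustering of
  per-sample enrichment profiles over a differentially enriched gene-set
  panel; the cluster anchored by status-mutant samples defines the
  mut-like calls; within-group bootstrap (B = 1000) with optimism-corrected
  group differences validates the enrichment separation.
- **Stratification statistics** — ΔNp73/TAp73 isoform ratios, median-split
  dichotomization, 2^−ΔΔCt qPCR quantification, Kaplan-Meier / log-rank /
  Cox survival analysis, Fisher-z correlation intervals.
- **Counts processing** — CPM normalization and the "CPM > 1 in at least
  half the samples of some condition" expressed-gene filter.
- **ZIP synergy** — zero-interaction-potency scoring of two-drug dose
  grids from 4PL monotherapy fits (> +10 synergistic, < −10 antagonistic).
- **Synthetic data** — seeded generators that plant a mut-like subgroup
  (~22% of wild-type samples), an up-regulated program, hazard-ordered
  survival, isoform-ratio separation and dose-response grids, so every
  stage is testable against known truth without downloads.

## Worked example

```python
import json
import pandas as pd
from mutlike.simulate import simulate_two_cohorts, simulate_gene_sets
from mutlike.cohort import derive_signature_from_cohorts, classify_cohort
from mutlike.datatypes import AnalysisConfig

# two synthetic cohorts (200 samples x 2,000 genes each) sharing a planted
# 100-gene mutant program; ~10% TP53-mutant, 22% of wild-type are mut-like
cohorts = simulate_two_cohorts(seed=0)
deriv = derive_signature_from_cohorts([(e, c) for e, c, _ in cohorts])
print("signature genes:", len(deriv.signature.genes))

expr, clinical, truth = cohorts[0]
panel = simulate_gene_sets(34, deriv.signature, expr.gene_ids,
                           seed=1, n_program_subsets=30)
result = classify_cohort(expr, clinical, panel,
                         AnalysisConfig(bootstrap_b=1000, seed=0))
print("summary:", json.dumps(result.summary(), indent=2))
d = result.bootstrap["differences"]["mut-like - wt"]
print("mut-like vs wt ES difference: %.1f (95%% CI %.1f-%.1f)"
      % (d["corrected"], d["ci_low"], d["ci_high"]))
```

prints

```
signature genes: 103
summary: {
  "n_samples": 200,
  "counts": {
    "wt": 140,
    "mut-like": 40,
    "mut": 20
  },
  "mut_cluster": 1,
  "mutlike_fraction_of_wt": 0.2222222222222222
}
mut-like vs wt ES difference: 250.1 (95% CI 243.7-255.3)
```

The derived signature recovers the planted program (103 genes, including
96+% of the planted 100); the call labels 40 of 180 wild-type samples
mut-like (22.2%, matching the planted fraction — here all 40 are exactly
the planted samples), and the bootstrap separates mut-like from wild-type
enrichment decisively.

The same pipeline is exposed as a CLI:

```sh
mutlike simulate cohort --seed 1 --out work/cohort
mutlike simulate gmt    --seed 1 --out work/panel
mutlike classify --expr work/cohort/expression.tsv \
    --clinical work/cohort/clinical.csv --gmt work/panel/sets.gmt \
    --boot 1000 --seed 1 --out work/result
mutlike survival --clinical work/cohort/clinical.csv \
    --strata work/result/labels.tsv --cox --out work/surv
```

Every run writes a `manifest.json` (inputs' checksums, resolved config,
seed, version) sufficient to replay deterministic stages byte-for-byte.
Other subcommands: `project`, `gsea`, `derive-signature`, `filter-counts`,
`synergy`.

## Documentation

See `docs/methods.md` for the models, parameter defaults, numerical
conventions, what the synthetic generators do and do not emulate, and known
limitations.
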