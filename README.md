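# massmap

Two-stage microbial association mapping with advanced FDR control.

Given a samples × taxa relative-abundance table (raw counts are normalized
at load time), a Greengenes-style taxonomy, an optional rooted phylogenetic
tree and a sample trait (binary or continuous, with covariates), `massmap`:

1. fits the covariate-only null trait model once;
2. screens taxonomic groups at an upper rank (default: family) with an
   omnibus permutation group test — the minP combination of an adaptive
   sum-of-powered-score test (aSPU) and kernel quadratic-form tests over
   Bray-Curtis / UniFrac distances — or with a shared-coefficient
   "aggregated" test;
3. applies Benjamini-Hochberg (BH) to the group p-values, carries only the
   discovered groups to the target rank, score-tests their member taxa with
   residual permutation, and controls the overall FDR with hierarchical BH
   (HBH) or selected subset testing (SST).

A one-stage benchmark path (score test on every taxon + plain BH) and a
Dirichlet-multinomial simulation benchmark (with PAM-clustered signal
assignment and empirical FDR/TPR/ROC evaluation) are included.

## CLI

Two-stage analysis on TSV inputs:

```bash
massmap run \
  --abundance abundance.tsv --taxonomy taxonomy.tsv --tree tree.nwk \
  --metadata metadata.tsv --trait ABH --trait-type binary --covariates sex,age \
  --screen-rank family --method omiat --fdr-procedure hbh \
  --q 0.05 --permutations 100000 --seed 1 --out results/
```

Writes `screening.tsv` (group id, raw/adjusted p, discovered flag),
`target.tsv` (taxon id, group, raw p, adjusted p, rejected flag) and
`run_log.json`. A `key=value` config file can pre-set any option
(`--config run.cfg`); command-line flags override it.

Simulation benchmark:

```bash
massmap simulate --preset scenario1_large --reps 100 --permutations 999 \
  --seed 7 --out sim/
```

Presets cover same-direction and mixed-direction effect scenarios at three
effect sizes plus sensitivity settings (5% signal fraction; 50 medoid
clusters).

## Python API

```python
from massmap import (
    load_abundance, load_taxonomy, load_tree, load_metadata,
    filter_taxa, RunConfig, run_massmap, write_results,
)

trait, sample_ids = load_metadata("metadata.tsv", "ABH", ["sex", "age"], "binary")
ab = load_abundance("abundance.tsv", orientation="auto", known_samples=sample_ids)
tax = load_taxonomy("taxonomy.tsv")
from massmap.data import align_samples
ab, trait, _ = align_samples(ab, trait, sample_ids)
ab = filter_taxa(ab, tax, min_rank="family", min_prevalence=3, min_mean_ra=0.001)
result = run_massmap(ab, tax, trait, RunConfig(seed=1), tree=load_tree("tree.nwk"))
write_results(result, "results/")
```

Lower-level building blocks (`fit_null`, `permutation_pvalues`, `aspu_test`,
`omirkat_test`, `omiat_test`, `aggregated_test`, `bh_adjust`, `hbh`, `sst`,
`sample_dm_counts`, `pam_cluster`, `run_benchmark`, ...) are exported from
the package root.

## Notes

- Permutation p-values use the (1 + b)/(1 + B) estimator and are floored at
  1/(B+1); floored values are flagged in `target.tsv`.
- One shared permutation ensemble per run drives every component test, so
  minP combinations are well-defined and runs reproduce bit-identically
  from a single seed.
- Discovery uses the strict rule `adjusted p < q` (configurable).
- Relative abundances are used as-is: no zero replacement, no within-group
  re-normalization (a flag exposes the latter).
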