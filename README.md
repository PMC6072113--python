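# cernet

Inference and downstream analysis of cancer-associated competing-endogenous-RNA
(ceRNA) interaction networks from matched multi-omics matrices (miRNA / mRNA /
lncRNA expression, gene-level copy number, promoter methylation, TF
expression), plus a synthetic-data generator so the whole pipeline is testable
without any external download.

The pipeline has three inference steps and two downstream stages:

1. **Putative network** (`putative_net`) — restrict aggregated
   miRNA→RNA interaction tables to differentially expressed regulators and
   targets.
2. **Regulator selection** (`regulator_select`) — per RNA, repeated
   10-fold-CV LASSO at the one-standard-error λ over candidate miRNAs plus
   (for mRNAs) own CNA, promoter methylation, and candidate TF expression;
   covariates selected in >75% of 100 runs are screened by a 500-resample
   percentile bootstrap CI (must contain the median coefficient and exclude
   0); miRNAs with negative median coefficient become edges. An OLS variant
   (`ols_select`) is available.
3. **ceRNA inference** (`cerna_infer`) — candidate RNA pairs share ≥1
   selected miRNA; filters: Pearson r ≥ 0.5 with p < 0.05, a
   BH-adjusted hypergeometric shared-regulator test, and sensitivity
   correlation SC = Corr − PC(·|shared miRNAs) with SC > 0, partial-correlation
   p < 0.05, and an empirical SC p-value from 1000 random same-size miRNA
   draws. The SC stage can be deactivated; a correlation-only baseline is
   included.
4. **Network analysis** (`net_analysis`) — log-log power-law degree fit,
   multilevel (Louvain) modules, hypergeometric gene-set enrichment of
   modules, hub calling, overlap counting against external interaction sets.
5. **Evaluation** (`evaluation`) — knockdown-based Ratio Fold Change and
   network accuracy (% of downstream genes with RFC < 1).

Supporting modules: `core_io` (typed readers/writers for TSV matrices,
interaction lists, GMT, annotations, segments), `preprocess` (CPM filter,
log2(x+0.001) + z-normalization, promoter-window methylation aggregation,
segment→gene CNA, BH adjustment, a simple two-group DE surrogate), and
`synth_data` (planted linear-Gaussian generator with ceRNA groups, decoy
edges, and knockdown simulation).

## CLI

```sh
# write a synthetic fixture set (scenarios: recovery, null, cerna, perturb)
cernet simulate --scenario cerna --seed 1 --out fixtures/

# run every stage on a scenario; variants: full, only_mirna, ols,
# no_sc_filter, correlation_baseline
cernet run-all --scenario cerna --variant full --seed 1 --out run/ \
    --n-runs 50 --n-bootstrap 200

cernet summarize run/
cernet evaluate --edges run/network_edges.tsv --perturbations fixtures/perturbations.tsv
```

`run-all` writes per-stage TSVs (`step1_putative.tsv`, `step2_selected.tsv`,
`step3_pairs.tsv`, `network_nodes.tsv`, ...) plus `provenance.json`
(config, seed, per-stage counts). Runs are byte-identical under a fixed
config and seed. A YAML config file (`--config`) can set any stage option
(`lasso:`, `cerna:`, `variant:`, ...); command-line flags override it.

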