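# cupronet

Network-controllability analysis of tumour expression cohorts: find the
genes a gene-regulatory network cannot be controlled without, ask whether
they carry prognostic information, and package the answer as survival
signatures, mutation contrasts, and a penalized Cox risk score.

## Who this is for

Computational biologists studying how a curated gene programme — the
motivating case is cuproplasia, copper-dependent cell growth — relates to
cancer prognosis, starting from tumour/normal expression matrices, clinical
follow-up, a protein-interaction table and somatic mutation calls.  Every
stage is a plain function over validated tabular containers, with a thin
CLI for file-in/file-out runs, and a seeded synthetic-cohort generator so
the whole chain can be exercised and benchmarked without any external data.

## The method

1. **Differential expression.**  Per gene, tumour vs normal Welch t-test on
   log2(count + 1); Benjamini–Hochberg across genes; called when
   adjusted p ≤ 0.05 and |log2FC| ≥ 1.
2. **Network construction.**  For the DEGs present in the interaction
   database, Pearson correlation r over the tumour cohort for every pair,
   p from t = r·√((n−2)/(1−r²)); BH over all pairs; keep adjusted p ≤ 0.05;
   refine by intersection with the database.  Each kept pair becomes an
   antiparallel directed edge pair.
3. **Controllability.**  The minimum driver node set (MDNS) of a directed
   network on N nodes has size max(N − |M*|, 1), with M* a maximum matching
   of the bipartite lift (out-copies vs in-copies).  A node is *critical*
   when deleting it increases the MDNS of the remaining network.
4. **Signatures.**  Critical nodes ∩ curated gene list, screened by
   univariate Cox (Wald p ≤ 0.05), assigned up/down direction by majority
   vote across cancer types.  Patients are stratified either by spectral
   clustering on a locally scaled kernel over squared Euclidean distances,
   or by the median-dichotomized high/low pattern rule (subtypes 1/2/3);
   groups are compared with log-rank tests and Kaplan–Meier curves.
5. **Mutations.**  SNVs are reduced to pathogenic calls (deleterious class,
   VAF > 0.1, FILTER PASS, REVEL in a pathogenic band), combined with
   homozygous CNV events into mutant/WT status, and contrasted by log-rank.
6. **Risk score.**  Univariate-Cox prefilter, then lasso-Cox with the
   penalty chosen by 10-fold cross-validated partial-likelihood deviance
   (one-standard-error rule).  The risk score is the linear predictor
   Σᵢ βᵢxᵢ; discrimination on a held-out cohort is the IPCW time-dependent
   AUC at chosen horizons, with coefficients frozen.

## Worked example

Simulate a cohort with planted structure (three regulatory stars, three
chains, six prognostic critical genes) and run the chain:

```bash
cupronet simulate --seed 7 --outdir cohort/
cupronet de      --expr cohort/expression.tsv --cond cohort/condition.tsv --out degs.tsv
cupronet network --expr cohort/expression.tsv --cond cohort/condition.tsv \
                 --degs degs.tsv --db cohort/interactions.tsv --out net.tsv
cupronet control --net net.tsv --out critical.tsv
```

```
56 differentially expressed genes of 150 tested
network: 36 nodes, 30 edges
MDNS size 12; 21 critical node(s)
```

The reconstructed network matches the 30 planted interactions exactly, and
the 21 critical nodes are the planted star hubs and chain genes
(`cohort/truth.json` holds the ground truth).  Stratifying patients on
three harmful critical genes separates survival, and a risk model built on
the six prognostic genes discriminates events:

```bash
cupronet stratify --expr cohort/expression.tsv --cond cohort/condition.tsv \
                  --genes G0000,G0012,G0026 --k 2 --seed 7 --out subtypes.tsv
cupronet survdiff --subtypes subtypes.tsv --surv cohort/survival.tsv
cupronet risk-train --expr cohort/expression.tsv --cond cohort/condition.tsv \
                    --surv cohort/survival.tsv \
                    --genes G0000,G0006,G0012,G0020,G0026,G0033,G0090,G0091,G0092,G0093 \
                    --seed 7 --out model.json
cupronet risk-validate --model model.json --expr cohort/expression.tsv \
                    --cond cohort/condition.tsv --surv cohort/survival.tsv --horizons 365,1095
cupronet mutations --maf cohort/mutations.maf.tsv --cnv cohort/cnv.tsv \
                    --genes G0000,G0006,G0020,G0021,G0026 --surv cohort/survival.tsv
```

```
chi2 = 15.2342 (df 1), p = 9.5e-05
selected 6 gene(s) at lambda 0.1274: G0000, G0006, G0012, G0020, G0026, G0033
AUC at t=365: 0.832
AUC at t=1095: 0.815
158 pathogenic SNVs; 157 mutant patient(s); log-rank p = 0.000652
```

The log-rank p-value says the two expression clusters have genuinely
different survival; the lasso keeps exactly the six planted prognostic
genes and drops the four noise candidates; the AUCs (here on the training
cohort, so optimistic) quantify how well the risk score ranks patients who
die by each horizon; the mutation contrast recovers the planted hazard of
pathogenic mutations.  The same operations are available as library calls
(`cupronet.pipeline.run_pipeline` bundles steps 1–4).

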