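# implinet

Implication-rule coexpression networks for differential biomarker
discovery, with prognostic (Cox risk score, Kaplan–Meier) and diagnostic
(nearest-neighbour) validation.

## The problem

Smoking reshapes the way genes co-express in lung tumors, not just how much
each gene is expressed. A gene whose coordination with core signaling
pathways (EGF, EGFR, MET, KRAS, E2F3, E2F5) appears specifically in smokers
is a candidate marker for smoking-driven disease even when its mean level
changes little. `implinet` is a tested, reusable implementation of that
idea for transcriptomics: it induces logical coexpression relations between
gene pairs, contrasts the smoker and non-smoker networks, selects the genes
coupled to *every* hub in the group-specific components, and then asks the
two clinical questions that matter — does the signature stratify survival,
and can it separate cancer from normal tissue?

## The model

Expression is dichotomized against frozen training-set means. For each gene
pair's 2×2 state table, six implication rules (A⇒B, A⇒¬B, ¬A⇒B, ¬A⇒¬B,
A⇔B, A⇔¬B) are scored by the prediction-logic *del* statistic

    ∇ = 1 − V/K,

the proportionate reduction of the observed error-cell rate V relative to
its independence expectation K, together with the rule's scope (premise
coverage). Rules are kept when one-sided z-tests of precision and scope
pass α = 0.05, and the maximum-∇ rule defines the edge:

    z = (N·K − N·V) / √(N·K·(1−K)).

Differential components are pairs with an edge in one smoking group and
none in the other, validated in an independent cohort (same rule type
significant, still group-specific) with training means reused unchanged.
Signature genes are the non-hub genes with validated group-specific edges
to all six hubs. The validated network is evaluated against GMT/interaction
annotations (precision TP/(TP+FP), q-value FP/(TP+FP), permutation FDR over
shuffled test labels, subsampling stability), and the signature feeds a Cox
risk score with a frozen 3-year-ROC (Youden) cutoff, log-rank–tested
Kaplan–Meier stratification, a multivariate Cox table against clinical
covariates, and a 1-NN cancer/normal classifier with odds ratios. See
`docs/methods.md` for formulas, defaults and limitations.

## Worked example

The synthetic generator plants a known smoking-specific implication
structure (6 smoker + 1 non-smoker signature genes coupled to 6 hubs,
survival effects, decoy annotations), so the whole pipeline runs without
any download:

```python
from implinet.pipeline import run_full_pipeline, synthetic_preset

run_full_pipeline(synthetic_preset(seed=3, out_dir="run"))
print(open("run/summary.txt").read())
```

```
Differential implication-network analysis
=========================================
training samples              300 (150 smokers)
survival screen (Cox p<0.05)    30
smoking screen (t-test p<0.05)  10
network genes (incl. 6 hubs)   16
edges: smoker net             81
edges: non-smoker net         36
differential edges            69 (+13 type-changed)
validated edges               46
signature genes               4 (3 smoker / 1 non-smoker)
  SMK01, SMK04, SMK06, NSM01
```

Reading this: of 207 genes, 30 pass the univariate Cox survival screen and
10 of those also differ between smokers and non-smokers; with the 6 hubs
they form a 16-gene network universe. 69 pair relations are group-specific
in training, 46 replicate in the independent test cohort, and 4 genes —
all planted, no background decoys — retain validated edges to every hub
(the strict presence/absence differential rule trades recall for
specificity; see `docs/methods.md`). `run/evaluation.json` from the same
run reports `network_precision = 1.0` (all 24 signature-network edges are
annotated truth pairs), `fdr = 0.869` under 200 label permutations with
decoy annotations that mark a random pair positive at rate 0.1 (so a null
network's expected precision is 0.1, q ≈ 0.9), and `stability = 0.962`
over 20 runs on 80% training subsamples. `run/prognosis.json` shows the
frozen risk score splitting both cohorts (log-rank p ≈ 1e-20 on test) with
a significant χ² association between risk group and smoking.

The same stages are scriptable from the shell:

```bash
implinet simulate --seed 1 --out-dir cohort/
implinet run-all --synthetic --seed 1 --out-dir run/
implinet prognosis --expression cohort/expression.tsv \
    --clinical cohort/clinical.tsv --signature SMK01,SMK02,NSM01 \
    --out-dir prog/
```

File formats are plain text throughout: expression TSV/GCT 1.2, clinical
TSV, GMT gene sets, two-column interactions, SIF networks.

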