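# ernascope

Enhancer RNAs (eRNAs) — transcripts produced from active enhancers — mark
regulatory elements that are switched on in a tissue. In tumors, comparing
eRNA expression between cancer and matched normal samples, linking eRNAs
to the protein-coding genes they plausibly regulate, and clustering
patients by their functional-eRNA profile yields molecular subtypes with
distinct genomic alteration patterns and clinical outcomes.

`ernascope` is an analysis pipeline that takes an enhancer catalog built
from two annotation sources, raw read-count matrices for enhancer regions
and genes over paired tumor/normal samples, copy-number segments, a
somatic mutation table and clinical follow-up, and produces:

- the transcribed-eRNA census (counts > 1 in more than 10% of tumor or
  normal samples) with exonic/intronic/intergenic classification;
- paired differential expression (Wilcoxon signed-rank, BH-FDR) and the
  per-sample *global eRNA expression* statistic with subgroup and
  genome-instability associations;
- a genome-wide eRNA-gene Spearman co-expression network
  (|rho| >= 0.2, FDR < 0.05) with cis enrichment within 1 Mbp, driver
  gene-set over-representation and a from-scratch preranked GSEA;
- **functional eRNA-gene pairs** via a three-criterion cascade — DE eRNA
  (|log2FC| >= 2, FDR < 0.05), positive cis correlation within 1 Mbp,
  direction-matched DE gene above 0.5 TPM — plus copy-number-activated
  calls (locus amplified in >= 10% of tumors, expression tracking copy
  number, gene association independent of the gene's own copy number via
  partial Spearman);
- from-scratch resampled **consensus clustering** of tumor samples over
  the functional-eRNA profile (1 - Pearson distance, Ward linkage,
  pItem = pFeature = 0.7) with CDF-area k selection;
- cluster-outcome association: Cox proportional hazards adjusted for age,
  gender and smoking, Kaplan-Meier curves and log-rank tests for OS, DFI
  and PFI.

Because real cohorts of this kind are not redistributable, the package
ships a first-class synthetic-cohort generator (`ernascope.simulate`) that
plants every effect the pipeline detects — DE eRNAs, cis-correlated target
genes, CNA-driven eRNAs, expression subtypes with graded mutation and
copy-number burden, and a high-hazard cluster — with truth tables, so the
whole pipeline is testable end to end. See `docs/methods.md` for models,
parameters and design choices.

## Worked example

Run the numbered drivers from the repository root (each is a thin wrapper
over a pipeline stage; outputs accumulate under `results/analysis/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_annotate.py
...
python analysis/10_survival.py
```

or equivalently in one shot, via the CLI:

```bash
ernascope all --simulate --seed 1 -o results/analysis
```

With seed 1 the drivers print, among other things:

```
catalog: 169 enhancers supported by both sources
transcribed eRNAs: 144 (138 intergenic, carried forward)
eRNA DE: 20 up / 10 down at |log2FC|>=2, FDR<0.05 (of 138 transcribed intergenic eRNAs)
global eRNA expression, tumor vs normal (signed-rank): p = 1.67e-11
cis enrichment (<=1 Mbp): ER = 47.41, p = 1.07e-20
  CGC: ER = 7.84, p = 5.35e-12
functional eRNAs: 30 (20 up, 10 down) from 84 evaluated cis-candidate pairs
vs planted truth: recall 1.00, precision 1.00
CNA-activated eRNAs: 5 of 20 up-calls
consensus CDF area by k: ... k=3: area 0.676, delta 0.481 <- chosen
log-rank OS: chi2 = 6.35, p = 0.0419
```

Reading this: of 200 simulated enhancer candidates, 169 survive the
two-source filter; 138 intergenic enhancers are transcribed and enter the
analysis. The 30 planted functional pairs are recovered exactly (20 up,
10 down), all 5 planted copy-number-driven eRNAs are flagged with no false
flags, consensus clustering picks k = 3 and reproduces the planted
subtypes, and the subtypes separate in survival. Fold-change, correlation
and enrichment values for every feature and pair are in the TSVs under
`results/analysis/`.

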