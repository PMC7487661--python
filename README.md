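# tfnetminer

Discovering the lncRNA and protein-coding targets of a transcription
factor, its co-regulatory partners, and the functional modules of its
regulatory network — with the clinical qPCR statistics used to validate
a candidate lncRNA.

## The problem

A transcription factor (TF) such as KLF5 binds gene promoters and
drives expression programs in tumours.  Which long non-coding RNAs
(lncRNAs) and protein-coding genes (PCGs) does it regulate in
colorectal cancer, which other TFs co-operate with it, and do any of
its lncRNA targets matter clinically?  `tfnetminer` implements that
analysis as a tested, reusable pipeline:

1. **Differential expression** — per-gene Welch *t*-tests of tumour
   groups against normal tissue, Benjamini–Hochberg FDR, and a strict
   consensus: *q* < 0.05 in both comparisons with a consistent
   direction, intersected with an external evidence list.
2. **Target calling** — ChIP-Seq peaks mapped onto strand-aware
   promoter windows (−2000..+200 bp of the TSS, half-open
   coordinates); a gene is bound if a peak overlaps its promoter in
   ≥ 2 of the ChIP samples; targets = bound ∩ consensus-differential,
   with lncRNA targets refined by co-expression support.  Peak
   length/signal summaries and bound-region FASTA + GC content are
   exported for downstream motif analysis.
3. **Co-factor enrichment** — the two-step hypergeometric method.
   Step 1 scores every profile in a pool of TF ChIP-Seq target sets for
   overlap with the focal targets,

   $$p=\sum_{s=N_s}^{\min(N_c,N_k)}\frac{\binom{N_k}{s}\binom{N_T-N_k}{N_c-s}}{\binom{N_T}{N_c}},$$

   keeping profiles with *p* < 0.01, most significant 50.  Step 2
   applies the same upper-tail test to profiles-per-TF within that
   selection (universe = the pool); a TF is called a co-factor when
   *p* < 0.01 and it contributes ≥ 3 significant profiles.
4. **Network modules** — TF→target, ≥2-of-3-dataset co-expression and
   PPI edges are assembled into a regulatory network; Markov
   clustering (MCL, inflation 2.0, expansion 2 — implemented in the
   package) finds modules, which are kept at ≥ 25 genes and annotated
   by hypergeometric gene-set enrichment with BH FDR.  A single
   lncRNA's function is predicted from its co-expressed partners
   (guilt by association).
5. **Clinical statistics** — qPCR ΔCt (= Ct_target − Ct_reference;
   smaller = higher expression) and 2^−ΔΔCt fold changes; paired
   *t*-test for tumour vs adjacent normal tissue; Mann–Whitney
   rank-sum; pooled-variance *t*-tests and one-way ANOVA computed
   directly from published (n, mean, SD) summary triplets; Pearson
   correlation; rank-based ROC AUC.

A first-class synthetic-data module (`tfnetminer.synth`) generates
every input with known planted structure — planted differential genes,
promoter-bound targets, one co-factor TF, clique modules and clinical
group effects — so each stage is tested by truth recovery without any
external data.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on the
synthetic study data:

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_differential_expression.py
python analysis/03_chip_targets.py
python analysis/04_cofactors.py
python analysis/05_network_modules.py
python analysis/06_clinical_stats.py
```

Output (seed 0):

```
consensus: 51 up, 45 down -> results/de_table.tsv
planted-truth recovery: 96/120 (0 false positives)
6 lncRNA targets (3 high-confidence) and 9 PCG targets
  lncRNA: 26 peaks, mean length 261 bp, mean signal 12.9
  PCG: 40 peaks, mean length 260 bp, mean signal 12.6
  bound regions mean GC: 0.65 -> results/regions.fa
called co-factors: COF1
2 modules of >= 25 genes (sizes [39, 38], converged=True); planted-truth ARI = 1.000
  module 2: top term MOD1_PROCESS (q = 6.4e-35)
tumor vs paired normal: mean ddCt = -1.08 (fold change 2.12), paired t(110) = -5.26, p = 7.3e-07
diagnostic AUC (tumor vs normal dCt): 0.640
covariates associated with expression (p < 0.05):
  invasion: p = 0.000785
  metastasis: p = 0.00152
```

Reading this: 96 of the 120 planted differential genes survive the
strict two-comparison consensus with no false calls; every planted
promoter-bound gene that is also differential becomes a target; the
planted co-factor `COF1` is the only TF called; MCL recovers both
planted modules exactly (adjusted Rand index 1.0) and their planted
gene-set labels rank first; and the clinical stage detects the planted
tumour up-regulation (negative ΔΔCt ⇒ ~2-fold higher expression) and
the planted invasion/metastasis effects.

The same stages are exposed as a CLI (`tfnetminer synth|de|targets|
cofactor|network|predict-function|clinstats`) for use on real data in
the documented file formats.

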