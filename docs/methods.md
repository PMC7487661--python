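# Methods

## Pipeline model and assumptions

The pipeline treats TF regulation as a three-way intersection problem:
a gene is a candidate target when (i) the TF binds its promoter
reproducibly, (ii) the gene is differentially expressed in disease, and
(iii) for lncRNAs, the gene is embedded in the disease co-expression
network near protein-coding targets.  All coordinates are 0-based,
half-open (BED convention) on a single reference sequence; genes are
represented by their TSS, biotype and strand only — promoter and flank
windows are derived, and no gene-body end coordinate is modelled, so
region summaries use TSS ± extension windows rather than gene bodies.

### Differential expression

Expression is analysed on the log2 scale.  Each gene gets a two-sided
Welch *t*-test per case group against normal (Welch rather than pooled
because group variances are not assumed equal; a `equal_var` flag
restores the pooled test), and Benjamini–Hochberg adjustment within
each comparison.  Genes with zero variance in both groups and equal
means are inert (p = 1, direction "up" by convention).  The consensus
rule is strict by default — significant in *both* comparisons with the
same direction, and present with that direction in the external
evidence list; a documented `either` mode relaxes the first condition.
The strict reading loses some power (at the default study conditions
about 80% of planted genes survive both BH-adjusted comparisons) but
calls essentially no false positives, which fits its purpose of
feeding high-confidence genes into target calling.

### Target calling

Promoter windows are strand-aware: −2000..+200 bp of the TSS (mirrored
on the minus strand), truncated at position 0.  A ChIP sample supports
a gene when at least one peak overlaps its window by ≥ 1 bp (a
`min_overlap` parameter raises the bar); genes supported by ≥ 2 samples
pass.  Binding-region summaries and FASTA export for motif discovery
use a separate symmetric TSS ± 2000 bp window (`extension`), kept
distinct from the calling window on purpose: calling is asymmetric
around the promoter, region mapping is symmetric around the TSS.  GC
fraction excludes ambiguous bases from numerator and denominator.

### Two-step co-factor enrichment

The upper-tail hypergeometric probability is computed in log space
(lgamma binomial coefficients, logsumexp) and clipped to (0, 1]; exact
integer enumeration is used as the oracle in tests up to universe 60,
and scipy's survival function as an independent cross-check at larger
sizes.  Step 1 ranks profiles by ascending p (ties broken by profile
id for reproducibility), filters at α = 0.01 *before* truncating to
the top 50 — the selection keeps the most significant profiles, which
is the only reading under which the subsequent over-representation
step is meaningful.  Step 2 re-uses the same tail test on the profile
urn (universe = pool size, draws = selected set, category = the TF's
profiles) and calls a TF at p < 0.01 with ≥ 3 significant profiles.
The gene universe is configurable (per-biotype or joint); the analysis
scripts use the joint universe because the synthetic target set mixes
biotypes.

### Markov clustering

MCL is implemented directly: self-loops of weight 1, column-stochastic
normalisation, then expansion (matrix power 2) alternating with
inflation (elementwise power 2.0 and renormalisation) and pruning of
entries below 1e-5, until the largest entry change falls below 1e-8
(non-convergence at 100 iterations returns the current clustering with
a warning).  Clusters are read from attractor rows; attractor systems
sharing attractors are merged, and a node attracted by several systems
goes to the lowest cluster index, so the result is a partition.
Co-expression edges enter the matrix unweighted by default (support
weighting is a flag).  Module detection runs with the focal TF node
removed: the TF is connected to every target by construction, and on
networks of this size such a hub funnels all flow into one cluster —
verified against an independent dense reference implementation, which
shows the same behaviour, i.e. it is a property of the algorithm on
hub-dominated graphs, not of this implementation.  The module-size
threshold is ≥ 25 genes (inclusive reading of the published cutoff),
renumbered by descending size.

### Gene-set enrichment and function prediction

Module annotation uses the same upper-tail hypergeometric engine
(universe = clustered genes by default, configurable), BH across terms,
q < 0.05.  lncRNA function prediction takes the PCG partners
co-expressed with the lncRNA in ≥ 2 of 3 datasets and reports the top
10 terms of the partner enrichment unfiltered by FDR, so a ranking is
available even for weak signals.

### Clinical statistics

ΔCt = Ct_target − Ct_reference; smaller ΔCt means higher expression,
and ROC direction follows that convention (score = −ΔCt for the
positive/tumour class).  Association tables computed from per-group
(n, mean, SD) triplets use the pooled-variance *t*-test by default —
the convention that reproduces published association-table p-values;
Welch is available behind a flag.  One-way ANOVA from summaries takes
the between-group sum of squares about the weighted grand mean and
within-group sum of squares Σ(nᵢ−1)sᵢ²; groups of n = 1 contribute no
within-group variance.  The rank-sum test enumerates exactly for
groups of ≤ 8 without cross-group ties and otherwise uses the
tie-corrected normal approximation.  Degenerate inputs (all paired
differences zero, both SDs zero) are flagged rather than silently
assigned a statistic.  Association-table p-values are reported raw,
without multiplicity adjustment across covariates, matching how such
tables are conventionally published.

## Synthetic study conditions

The generator's defaults define the study conditions; every downstream
recovery test consumes only the generated files and the truth objects
written next to them.

| parameter | default | rationale |
|---|---|---|
| genes / lncRNA fraction | 1000 / 0.20 | enough genes for stable FDR behaviour at desk scale; lncRNA share of an annotated transcriptome |
| chromosome | 6 Mb, evenly spaced TSS | keeps promoter windows disjoint so decoy peaks can be placed strictly outside them |
| samples per expression group | 10 | typical cohort-subset size; gives the *t*-test realistic power |
| planted DE genes / effect / noise | 120 / ±2 log2 units / SD 1.0 | a clear but not saturating effect: per-comparison BH power ≈ 0.9 |
| planted targets | 40, half drawn from the DE set | the DE∩bound intersection is non-trivial in both directions |
| ChIP samples / rule | 5 / bound in ≥ 2 | matches the reproducibility rule the pipeline implements |
| peak length / signal | N(260, 40) bp / N(13, 3) | realistic narrow-peak scale |
| profile pool | 500 profiles, background 30–120 targets each | large enough for step-2 counting statistics, desk-scale runtime |
| planted co-factor | 6 profiles, each covering 70% of planted targets | a TF with clear but imperfect target sharing |
| peak GC / background GC | 0.65 / 0.40 | GC-box-binding TF chemistry vs an A/T-balanced genome |
| planted modules | cliques of 30 and 28 genes (1 lncRNA each), each edge in ≥ 2 of 3 datasets | just above the 25-gene module threshold; the support rule is exercised by construction |
| clinical cohort | n = 111; group sizes mirror a published association table | reproduces the published cohort structure exactly |
| clinical effects | tumour shift −1.0 ΔCt; M1 −1.66; invasion-stage shifts | the planted effects the association stage must find |
| clinical noise | patient effect SD 1.4 + residual SD 1.4 | tumour ΔCt SD ≈ 2.0 across patients, while paired tissues share the patient effect — the correlation that makes a paired design informative |

What the generator does **not** emulate: read-level data and peak
calling, count-based expression (values are Gaussian on the log scale,
so count-model DE methods are out of scope by design), batch and
copy-number effects, overlapping genes or multiple chromosomes, qPCR
amplification-efficiency variation.  Passing recovery tests therefore
demonstrates the correctness of the statistical machinery and interval
logic under the stated generative model, not robustness to artefacts
real datasets carry.

## Numerical and design notes

- All randomness flows through per-component seed streams of one
  `SynthConfig.seed`; fixed seed ⇒ byte-identical output files.
- The hypergeometric tail returns exactly 1.0 whenever the observed
  overlap is at or below the support minimum (the certain event),
  avoiding spurious 1−ε values.
- BH adjustment delegates to statsmodels (`fdr_bh`) after validating
  the input range; summary *t*-tests delegate to scipy after handling
  the zero-variance degeneracies scipy leaves as NaN.
- `assign_binding` is independent of the ordering of samples, files
  and peaks; `select_targets` is invariant under shuffling of its
  input lists; both are property-tested.
- Problem sizes in tests and the acceptance script (20 recovery seeds,
  100 null seeds for co-factor calibration, 20 calibration seeds for
  DE, 3 seeds for module recovery) were chosen as the smallest sizes
  at which the binomial uncertainty of the checked rates is comfortably
  below the asserted margins.

## Known limitations

- The consensus DE rule's power depends on the BH threshold chain; at
  the default conditions ~20% of planted genes are missed.  This is a
  property of the strict rule, not a defect; the `either` mode trades
  false-positive control for power.
- MCL module detection on very small hub-dominated networks requires
  removing the hub (see above); on networks of thousands of nodes the
  hub's per-edge flow is negligible and the choice is immaterial.
- The clinical generator plants additive covariate shifts with
  independently permuted covariates, so it cannot represent correlated
  clinical variables (e.g. invasion stage and TNM stage are independent
  here, unlike in real cohorts).
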