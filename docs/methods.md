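# Methods

`epimark` re-implements, as a tested and reusable pipeline, an integrative
ChIP-seq/RNA-seq analysis that attributes treatment-induced transcriptional
changes to the redistribution of histone marks at enhancers and promoters.
Because raw data for studies of this kind are rarely released, every stage is
exercised on synthetic count-level data with planted, machine-readable truth;
this note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The analysis model

The pipeline operates entirely at the count level (no reads): per-peak ChIP
count matrices for four histone marks (H3K27ac, H3K4me1, H3K9me2, H3K27me3),
per-gene expression counts, a TSS table, a promoter-capture interaction map
(promoter anchor, linked gene ids, distal anchor), and binned H3K9me2
coverage. All coordinates are 0-based half-open; chromosome names are opaque
strings.

Stages:

1. **Differential calling** (`differential`). Counts are normalised with
   TMM-style factors (trimmed mean of M-values: 30% trim on log-ratios, 5%
   on intensities, inverse-variance weights, reference = sample whose upper
   quartile is closest to the mean upper quartile; factors scaled to
   geometric mean 1). Each feature is tested treatment-vs-control under a
   negative-binomial model, and calls use two gates: FDR < 0.1 (Benjamini-
   Hochberg, applied separately per mark x contrast) and |log2FC| > 0.3 for
   ChIP; expression calling uses the FDR gate alone. log2FC is the log2
   ratio of normalised group means with a prior count of 0.5.

2. **Annotation** (`annotation`). A peak overlapping a promoter window —
   within 1000 bp of an annotated TSS, i.e. the interval
   [tss-1000, tss+1001) — is a promoter element of the overlapped gene(s);
   otherwise a peak overlapping the distal anchor of an interaction record
   is an enhancer element of that record's genes (promoter status takes
   precedence); peaks matching neither stay unannotated and are counted
   with the enhancers as "outside promoters". Nearest-gene lookup
   (midpoint-to-TSS, ties broken by gene id) exists only for the gene-set
   annotation path and is never used for expression integration, which
   relies on the physical interaction map.

3. **Integration** (`integration`). Per treatment, the genes linked to
   differential H3K27ac peaks are cross-tabulated against the
   differentially expressed genes over the universe of genes present in the
   expression matrix (after removing all-zero genes), and tested with a
   two-sided Fisher's exact test. Regulatory elements are built by merging
   overlapping enhancer anchors (gene links unioned) and grouping promoter
   peaks per gene; each element's per-treatment activation status follows
   the H3K27ac rule — any gained peak and no lost one = activated, the
   converse = repressed, both = ambiguous. The activation matrix keeps
   elements regulated in at least one treatment; by default a row must also
   carry a gene that is a DEG somewhere (configurable), since the analysis
   ties elements to transcriptional modulation.

4. **KDD analysis** (`kdd`). Broad H3K9me2 domains are called per
   chromosome as runs of bins with robust z-score (median/MAD x 1.4826)
   above a threshold, merged across gaps of at most 2 bins and filtered at
   50 kb. Control and treatment domains are matched 1:1 greedily by
   overlap; a domain "changes" if |log2 size ratio| > 0.2 or it is
   unmatched. Whether DEGs concentrate around changed domains is tested by
   permuting which genes carry the DEG label (preserving gene density),
   with p = (1 + #{null >= observed})/(n_perm + 1).

5. **Similarity and ORA** (`similarity`). Sample distances are
   1 - Spearman correlation on log-CPM (prior 0.5) over the top-500
   variance features; embeddings use Torgerson classical MDS with a
   deterministic sign convention. Over-representation of a gene list in
   user-supplied gene sets is a one-sided hypergeometric upper tail,
   BH-corrected across sets, significant at FDR < 0.05.

## The differential test statistic

The engine deliberately avoids wrapping an external differential package so
that its calibration can be audited end to end; it is a simple two-group NB
procedure, not a GLM.

*Dispersion.* Per-feature method-of-moments estimates come from
Var(k/s) = mu/s + alpha*mu^2 using pooled within-group residual variance,
floored at 1e-4. Their 25% trimmed mean is bias-calibrated by a parametric
bootstrap: null NB data are regenerated at the observed feature means and
sample scalings, the trimmed-mean shrinkage of the re-estimated dispersions
is measured, and the observed trimmed mean is divided by that ratio (an
analytic chi-square factor under-corrects because the NB variance estimator
is over-dispersed relative to chi-square). `estimate_dispersion` also
provides moderated per-feature values (shrinkage weight
n_prior/(n_prior + residual df), n_prior = 10). Testing uses
max(common, moderated) per feature: symmetric use of per-feature estimates
lets features whose dispersion is under-estimated by chance — which
correlates with an extreme observed split — reach inflated significance,
while the one-sided rule still protects against genuine per-feature
overdispersion.

*p-values.* The ratio of normalised group means is referred to the ratio of
independent Gamma variables whose shapes match each group mean's squared CV
under the null (Poisson part + dispersion part), i.e. a Beta tail, doubled
on the smaller side. A normal-reference Wald statistic with the same
variance was rejected after measurement: the log of an NB group mean at 2-3
replicates has a heavier-than-normal tail precisely in the far-quantile
region where the BH step-up operates, which inflates the false-call rate on
null data by a factor of 2-4. Two refinements keep the tail honest:

- features with pooled mean below 100 use an exact discrete tail, modelling
  each group sum as a moment-matched NB and enumerating the control sum
  (atoms at the observed value are included in both tails, the usual mildly
  conservative convention of discrete tests);
- the pooled mean is a nuisance parameter whose estimation noise makes a
  plug-in tail anti-conservative at low counts, so tails are evaluated at a
  2-SE lower bound of the pooled mean; the adjustment vanishes as counts
  grow.

Calibration was verified against large Monte Carlo simulations of the exact
generative model (tail probabilities agree within ~5%) and on 100 all-null
datasets (probability of any BH rejection 0.08, at or below the theoretical
0.10 of a perfectly calibrated test).

Known limitations: no covariates or batch terms; the common-dispersion
assumption matches the generator but real ChIP data show dispersion trends
with abundance; the prior count biases extreme log2FCs toward zero.

## The synthetic data generator

The generator emulates the study design: an untreated control plus four
treatments, at least two replicates each, four marks. Genes sit on a 5 kb
grid; per mark a configurable fraction of peaks (default 0.3) is placed
inside promoter windows and the rest distal, rejection-sampled away from
every promoter window, so annotation can be scored exactly. Half of the
distal H3K27ac peaks (default) become interaction anchors linked to a
same-chromosome gene. Counts are NB with a common dispersion: count ~
NB(L_j * q_i * 2^(s * effect * planted), alpha), with lognormal baselines
q_i (log-mean log 200, log-sd 1), uniform relative library sizes in
[0.7, 1.3], and symmetric +/- planted shifts. A gene linked to a planted
H3K27ac shift becomes a true DEG with the matching sign with probability
`couple_prob`; independent background DEGs are added at rate
`frac_deg_background`. H3K9me2 tracks are standard-normal bins with
domains elevated by `kdd_signal` (default 3 SD); in treatments a fraction
of domains shrinks or grows by `kdd_effect` of its length.

Defaults are "study-shaped" — 5 conditions x 2 replicates x 4 marks, 2,000
peaks per mark, 2,000 genes, frac_dp 0.05, effect 1.5 log2 units,
dispersion 0.1 — chosen for testability at desk scale; no depth or
effect-size characteristics of real libraries are claimed.
Everything planted is written to `truth.json`.

What the generator does *not* emulate: read-level artefacts (GC,
fragment-length, mappability), dispersion-abundance trends, correlated
peaks, spike-ins, batch structure, and any real genome annotation. Passing
recovery tests therefore demonstrates the correctness and calibration of
the inference machinery under its stated model, not performance on real
libraries.

## Evaluation experiments (`benchmarks`, `scripts/acceptance.py`)

Problem sizes were chosen so the battery runs in about a minute on one
core:

- *Null false-call control*: 20 all-null datasets (2,000 peaks, 3v3,
  dispersion 0.1); reported as the mean fraction of features falsely called
  at the FDR<0.1 + |log2FC|>0.3 gate, with the per-seed call counts and the
  any-rejection mean alongside (on an all-null dataset the V/max(R,1)
  statistic degenerates to a 0/1 indicator and is dominated by Monte Carlo
  noise at 20 seeds).
- *Recovery*: 3 datasets with 5% planted peaks at |log2FC| = 1.5.
- *Integration*: one strong-coupling dataset (couple_prob 1, effect 2.0,
  dispersion 0.05, 3 replicates, 1,000 peaks/1,000 genes); activation
  agreement is scored over element x treatment pairs where truth or
  prediction is non-unchanged.
- *KDD*: domain recovery on 20 planted 100 kb domains at +3 SD; calibration
  of the DEG-proximity test on 200 datasets with random DEG labels at
  n_perm = 200, KS-tested against U(0,1). The calibration genome is sized
  so domain flanks cover ~25-30% of genes and 150/1,000 genes are DEGs,
  keeping the discrete statistic's atoms small relative to the KS
  resolution.
- *MDS*: 20 treatment-shaped datasets; the check asks whether every
  same-condition replicate pair are mutual nearest neighbours in a k = 4
  embedding — five condition centroids span at most four dimensions, so
  this is the faithful MDS geometry; a 2-D scatter is its visualisation and
  can superimpose separated clusters.
- *End to end*: the default study-shaped configuration through `run-all`
  twice, asserting byte-identical outputs (run.log excluded; data files
  carry no timestamps).

## Numerical and design choices

- Fisher's exact test and the ORA tail are computed in exact integer /
  rational arithmetic (numerators over a common binomial denominator), so
  tie handling in the two-sided ≤-comparison is exact and no floating-point
  tolerance is needed; results are converted to float at the end.
- BH adjustment wraps the standard step-up implementation with input
  validation; ties and original order are preserved.
- KDD caller default z-threshold is 1.5: at 1.0, ~16% of background bins
  exceed threshold and 2-gap merging strings them into spurious >= 50 kb
  domains at genome scale; 1.5 suppresses these while recovering +3 SD
  domains with Jaccard > 0.95. All caller parameters are exposed.
- MDS axis signs are fixed (largest-magnitude loading positive) so
  embeddings are reproducible; negative eigenvalues are clipped at zero.
- The pipeline's gene universe for the Fisher test is all genes in the
  expression matrix after the all-zero filter; "outside promoters" counts
  enhancer-linked plus unannotated peaks, so the two fractions always sum
  to 1.
- When no gene-set file is supplied, the ORA stage uses positional gene
  sets (consecutive blocks of 50 genes per chromosome) purely to exercise
  the machinery; they carry no biological meaning.
- Determinism: a single `numpy` Generator seeded from the config drives the
  generator in a fixed draw order; the permutation test and the pipeline
  take explicit seeds; identical config + seed gives byte-identical files.
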