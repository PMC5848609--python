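# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `chromdyn` pipeline.
Conditions are labelled SS (serum-starved, basal) and TPO
(cytokine-stimulated); the design is two conditions x two replicates
throughout.

## Differential counting engine

Counts for region *i* in sample *j* are modelled as
`y_ij ~ NB(mu_ij, alpha_i)` with `mu_ij = s_j q_ic(j)` and variance
`mu + alpha mu^2`.

* **Size factors** `s_j`: DESeq-style median-of-ratios, computed on 10-kb
  background bins after discarding the top 10% most abundant bins
  (dominated by peaks), renormalised to geometric mean 1. Multiplying one
  sample's counts by *c* moves its factor by `c^((m-1)/m)` and every other
  factor by `c^(-1/m)` — the behaviour the unit tests pin down.
* **Dispersions** `alpha_i`: method-of-moments on normalized counts pooled
  within condition, shrunk toward the mean of the region's log-abundance
  bin (20 quantile bins) with weight `n/(n + n0)`, `n0 = 10`, floored at
  0.01. Empirical-Bayes moderation in the edgeR/DESeq2 sense is
  deliberately out of scope; calibration is enforced by simulation tests
  instead.
* **Wald test**: closed-form delta-method Wald on
  `log(q_TPO + 0.5) - log(q_SS + 0.5)` with
  `var(log q_c) = 1/((q_c + 0.5) sum_j s_j) + alpha sum_j s_j^2 / (sum_j s_j)^2`,
  two-sided normal reference. This vectorises over 10^4–10^5 windows in
  milliseconds where per-window IRLS GLM fits would not fit the test
  budget; null simulations (KS against uniform, empirical FDR on all-null
  genomes) bound the miscalibration this approximation could introduce.
  Regions with zero counts everywhere report `p = 1, lfc = 0`. An optional
  per-region natural-log offset (log region length for TADs and SEs)
  shifts reported abundances, not the test.
* **Region merging**: windows below mean normalized count 5 are dropped;
  the rest are clustered by transitive adjacency within `max_gap = 100`
  bp; each cluster's p-value is the Simes combination
  `min_i m p_(i) / i`; clusters are BH-corrected and called at
  `q <= 0.01`. Direction is the sign of the abundance-weighted mean LFC;
  clusters whose significant members disagree in sign are flagged
  discordant and excluded from the gain/loss sets. The DAR summit is the
  midpoint of the most abundant member window.
* Window geometry 1 kb, merge gap 100 bp gives a median merged-DAR length
  in the few-kb range on default synthetic data. Gene-level calls use the
  same machinery at `q <= 1e-3`.

## Synthetic data

The generator emulates every modality the pipeline consumes on a
2 x 20 Mb genome (defaults: 40 TADs, 400 genes, 600 enhancers, 10-kb Hi-C
bins, 1-kb ChIP windows) with planted ground truth. Key choices, each made
once:

* **Layout.** TADs tile each chromosome exactly (boundaries on Hi-C bin
  edges), so every element has a unique host TAD. TSSs keep >= 2 kb
  spacing and enhancers >= 1 kb spacing and >= 3 kb from TSSs, so element-
  level labels are unambiguous for overlap-based features. Restriction
  fragments tile the genome with ~4-kb mean length (HindIII-like).
* **Differential structure.** 30% of DHS elements are differential
  (gain:loss = 1:2, echoing the dominance of deacetylation); planted
  |log2 FC| ~ max(0.5, N(1.5, 0.65)). Each non-neutral TAD (25% induced,
  25% repressed) imposes its direction on member DARs with probability
  0.8, creating the TAD-level clustering the domain analyses detect. The
  magnitude spread 0.65 balances two planted-effect analyses: enough
  rank variation for the CRU correlation test to have power, while
  keeping the weak tail small enough that DAR recall at the default depth
  stays above 0.8.
* **ChIP counts.** Simulated on non-overlapping 1-kb windows (overlapping
  sliding windows would double-count simulated reads). Background windows
  get mean 2 (below the analysis abundance floor, as diffuse non-peak
  signal); the remaining depth (default 1.5e6 reads/sample) concentrates
  on DHS-marked windows. True size factors (1.0, 1.15, 0.9, 1.05) distort
  per-sample depths; the pipeline must recover them.
* **Hi-C.** Poisson counts around
  `lambda(i,j) = 60 (|i-j|+1)^(-1) * 2^[same TAD] * boost^[planted pair]`;
  Poisson rather than NB keeps the SIMA resampling null well defined and
  matches common practice for binned contacts. Both conditions share
  `lambda` — the invariant-architecture regime — so between-condition
  comparisons are null by construction.
* **Capture Hi-C.** Each promoter draws Poisson(13) interacting fragments
  (PIRs); 45% of draws target DAR-hosting fragments within capture range
  (PIRs of differentially transcribed promoters are enriched for DARs via
  the TAD-level clustering). Frequencies follow the Hi-C surface at
  fragment resolution scaled to read-count magnitude; scores are
  `6 + log2((freq+1)/(expected+1)) + N(0, 0.5)`, so most generated
  records clear the significance threshold of 5, as CHiCAGO-style output
  would. In **rewired mode**, 10% of the units the downstream test
  examines (differentially transcribed promoters with >= 5 DAR-containing
  PIRs) have their TPO frequency track the planted acetylation fold
  change deterministically — the alternative hypothesis for the CRU
  permutation test.
* **Sequences and TF peaks.** Uniform ACGT background, one class-specific
  consensus per class (a GAS-like motif for gains, an E-box-like motif
  for losses) embedded with probability 0.8 plus shared ETS/RUNX/GATA
  motifs; six TF peak sets overlap their associated class with
  sensitivity 0.85 and specificity 0.9 (MYC and pSTAT1 with gains; MYB,
  LYL1 and uSTAT5 with losses; CTCF class-neutral). Hi-C features carry
  no class signal by construction.

What passing tests show — and what they do not: the generator has no
mappability or GC bias, no input-chromatin background structure, no
read-level error, uniform base composition, and independent replicates
with a single dispersion; recovery and calibration results on it certify
the statistical machinery, not performance on real sequencing data.

## Domain analyses

Homotypic spacing uses summit-to-summit distances to the nearest
same-class DAR; the null permutes class labels over the fixed DAR
positions (preserving the spatial point pattern) and pools `n_perm`
rounds; one-sided rank-sum tests observed < null. TAD and SE differential
calls reuse the counting engine on summed member windows with log-length
offsets. Gene-to-TAD assignment is by TSS containment only.

## Hi-C and SIMA

ICE balancing iterates `W <- W / (b b^T)` with `b` the normalized row
sums of unmasked bins until their coefficient of variation drops below
1e-4, then rescales to the input's mean marginal (mass preserved up to a
scalar). Insulation uses a 10-bin square crossing each bin, log2 relative
to the chromosome geometric mean; boundaries are local minima with
prominence >= 0.1, found with standard peak detection. The compartment
signal is the leading eigenvector of the O/E correlation matrix, oriented
by an external covariate (e.g. enhancer density).

SIMA's observed statistic per domain is the mean normalized contact over
unordered bin pairs of the region set (intra mode) or over pairs spanning
two same-class domains within 20 Mb (inter mode). Each of `n_rand`
(default 1000) null draws places equally many length-matched intervals
uniformly in the same domain(s), without inter-interval overlap
constraints. Strength = observed / null mean. The signed-rank test
against 1 is **one-sided for enrichment**: the strength ratio is
right-skewed with null median slightly below 1, and a two-sided test
would flag spurious "depletion". Between-condition comparison is a
two-sided rank-sum on per-domain strengths. Domains shorter than their
regions' total length are skipped with a warning.

## Cis-regulatory units

A CRU is a promoter with >= 5 distinct significant PIRs (score >= 5 in
either condition) overlapping at least one DAR. The tested family is
restricted to differentially transcribed promoters — these are the loci
whose regulation the question concerns. Member acetylation LFC is
computed from normalized window counts restricted to the fragment ∩ DAR
intersection (the fold change at the target DARs, undiluted by unrelated
marked windows elsewhere in the ~4-kb fragment); interaction LFC from the
per-condition frequencies, both with pseudocount 0.5. The permutation
null scrambles interaction LFCs across all members genome-wide (keeping
every unit's acetylation vector and size fixed), recomputes each unit's
Spearman r per round, and reports `p = (1 + #{|r_null| >= |r_obs|}) /
(1 + n_perm)` with BH at 5%. Within-chromosome scrambling is available as
a flag. The implementation draws all permutation rounds as one
vectorised batch (Spearman via closed-form rank moments), so 10^4 rounds
cost seconds; that resolution matters because a unit with *m* members can
never beat `2/m!` under label scrambling, and BH thresholds in a family
of tens of units sit near 1e-3.

## Super-enhancers

Enhancers outside TSS ± 2.5 kb are stitched within 12.5 kb; stitched
regions are ranked by summed basal signal minus an optional input-control
track (zero when absent). On the rank curve with both axes scaled to
[0, 1], the cutoff is the tangent point of a slope-1 line from below
(`argmin(y - x)`); everything beyond it is a super-enhancer. This form is
robust to local noise in the sorted signal where a first-crossing rule on
pointwise slopes is not, and it is invariant to positive scaling of the
signal. Differential SE calls use 1% FDR to match the DAR/TAD analyses.

## Predictive modelling

Features: reverse-complement-collapsed k-mer frequencies (k = 2..4), DNA
shape summaries from a user-supplied pentamer table, PWM hit counts with
per-PWM thresholds at the 0.999 quantile of the analytic null score
distribution (dynamic programming over discretised position score
distributions, grid 0.05, threshold backed off by the accumulated
rounding bound so true top scores are never lost), binary TF peak
overlap, and per-condition anchored Hi-C row sums. Learning:
stratified 80/20 split, L1 logistic regression (liblinear, class-weight
balanced, fixed solver seed for determinism) with the penalty chosen by
stratified CV and the 1-SE rule (strongest penalty within one standard
error of the best mean log-loss), repeated over independent resplits;
AUC is always reported on the held-out split. Stability selection
refits on bootstrap resamples at the CV-chosen penalty; a feature's
stability is its nonzero-coefficient frequency, its sign the majority
coefficient sign. A random forest under the same split protocol serves
as the model-family cross-check. Standardisation always uses
training-split statistics only.

## Pipeline and reproducibility

`run_pipeline` executes counts → DARs → genes → domains/TADs → Hi-C/SIMA
→ SEs → CRUs → predictor, writing per-stage TSVs, `summary.json` and a
run log. One global seed is fanned out into named per-stage substreams
(`SeedSequence([seed, stage_id])`), so any stage can be rerun in
isolation with identical results; the whole pipeline is bit-reproducible
under a fixed seed. Resampling sizes in the packaged test-suite and
acceptance runs (e.g. 200–500 SIMA draws, 1–2 x 10^4 CRU permutations,
single-chromosome 5–10 Mb genomes for repeated-run calibration loops)
are chosen to give stable statistics at minute-scale runtimes; all are
parameters, and larger values only tighten the Monte-Carlo error.

## Known limitations

* The Wald test's normal reference is approximate at very low counts;
  the abundance floor (mean normalized count >= 5) keeps the tested set
  in the regime where the null simulations show calibration.
* The permutation test's resolution is bounded by member-count
  factorials; units with exactly 5 members cannot reach family-wise
  significance at usual family sizes, so detected couplings concentrate
  in better-connected promoters.
* SIMA assumes exchangeability of uniform placements within a domain; a
  strongly position-dependent coverage bias inside domains would require
  a matched-null refinement.
* Trans-chromosomal contacts, loop calling, input-subtraction of control
  ChIP, and empirical-Bayes dispersion moderation are out of scope.
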