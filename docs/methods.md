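# Methods

This note documents the models and numerical choices behind cistronet, what
the synthetic-data generator does and does not emulate, and the known
limitations of each stage.

## Compendium filtering, imputation, standardization

The gene-selection rule requires good expression dynamics in at least one
of the two two-channel platforms (absent in < 20 % of samples and standard
deviation above the platform's 25th-percentile cutoff), a minimum presence
level in the other (< 50 % absent), and a probeset on the oligonucleotide
chip. The standard-deviation cutoffs are *recomputed from the data at hand*
rather than hard-coded: published values of 0.50 and 0.43 for such cutoffs
are instances computed on a particular compendium, not constants of the
method. The percentile populations include every gene with at least two
present values on the platform; genes entirely absent from a platform
(absent fraction 1.0) are excluded from that platform's percentile
population and, as the formula dictates, can never be selected.

All standard deviations use the sample (n−1) form, consistent with
z-standardization mapping (1, 2, 3) → (−1, 0, 1).

k-NN imputation (default k = 15, configurable) replaces a masked cell with
the unweighted mean, at that sample, of the k nearest genes by Euclidean
distance over mutually present samples; a neighbor must itself be present
at the target sample. This is implemented directly rather than through a
generic imputer because the distance must be the plain Euclidean distance
over the shared support — rescaling by the missing fraction would reorder
neighbors for genes with different absent patterns. Present cells are never
modified, so imputation followed by per-platform z-standardization is fully
deterministic.

Each platform is standardized separately and the blocks concatenated
column-wise; genes selected by the rule are expected on all three platforms
(the rule itself forbids selecting a gene entirely absent from either
two-channel platform, and requires an oligo probeset), with any remaining
oligo absent calls imputed within that platform.

## Pair features

* Protein-class score: +1 when both genes carry the same class, −1 when
  both carry different classes, missing when either is unclassified.
* Czekanowski–Dice: 2c/(a+b) on GO term sets; missing (not 0) when either
  set is empty.
* Information-content similarity: Lin's measure
  2·IC(MICA)/(IC(t₁)+IC(t₂)) with IC(t) = −ln(cumulative corpus frequency /
  root frequency), combined across two term sets by best-match averaging.
  The GO-similarity literature offers several variants (Resnik, Lin,
  Jiang–Conrath, graph-based); Lin with best-match averaging was chosen as
  the bounded-[0,1] default and is configurable in principle via `TermDAG`.
* Both GO features are computed per namespace (biological process and
  molecular function) and averaged over namespaces where both genes are
  annotated; the cellular-component namespace is not used.
* Intergenic distance is the gap length in transcription order
  (1-based inclusive coordinates): abutting genes have distance 0, overlaps
  are negative. On the minus strand the upstream gene is the one with the
  larger coordinates.
* Expression correlation is the Pearson r of the two standardized
  concatenated profiles; missing when a gene failed selection.

Missing-feature policy for classification: features are standardized on the
training data, missing values are then encoded as 0 (the feature mean) and
a 0/1 presence indicator is appended for every feature that can be missing.
This keeps every same-strand pair scorable genome-wide, including pairs
with no annotation at all.

## Operon classifier

The classifier is a maximum-margin kernel machine (linear or RBF; C = 1,
RBF γ = 1/(n_features · Var), both grid-searchable) trained on the
imbalanced KOP/NOP set as-is; optional class weighting sits behind a
config flag. Evaluation is seeded, stratified 10-fold cross-validation with
per-fold ROC curves built from decision scores; AUC is computed as the
Mann–Whitney probability (ties ½) and cross-checked in the tests against
trapezoidal integration of the empirical ROC. Classifier comparisons use a
one-tailed paired t-test over the ten fold AUCs, with the conventions:
all-zero differences → p = 0.5; zero-variance nonzero differences → p = 0
or 1 by sign. A pair is called co-transcribed only for strictly positive
decision scores; runs of positive pairs are chained transitively into
transcription units, and strand or contig changes always break a unit.

## Mutual-information network

Profiles are copula-transformed (ranks scaled into (0,1)), which makes the
estimator exactly invariant under strictly monotone transforms of either
profile. Joint and marginal densities are Gaussian-kernel estimates and MI
is the sample mean of log(f_xy/(f_x·f_y)), clamped at zero.

Bandwidth: Silverman's two-dimensional rule on the copula scale with a 0.5
shrink factor and boundary reflection at 0 and 1. The shrink and the
reflection are deliberate: the copula support is compact and its marginals
are uniform, so the unshrunk rule-of-thumb (derived for Gaussian-like data)
oversmooths badly — on a ρ = 0.9 bivariate Gaussian at n = 524 (true MI
0.8304 nats) the unshrunk estimator is biased by about −0.17 nats, the
shrunk reflected one by about −0.05. The factor is exposed as `bw_factor`.
Because ranks of a tie-free profile are a permutation of 1..n, all pairwise
kernel matrices are gathers of one precomputed base matrix, which is what
makes genome-scale scoring (tens of thousands of pairs) cheap.

The MI significance threshold for a target p-value is calibrated by a
permutation null (profile pairs with one member randomly permuted;
default 10⁵ permutations) with an exponential tail fitted to the upper
decile, log P(MI > m) = α − m/λ, and extrapolated — necessary because
p = 10⁻⁹ lies far below any attainable permutation resolution. The
extrapolation is validated in the tests on a synthetic exponential null
with known scale.

Only regulator-incident pairs are scored, matching the use of a
transcription-factor list in relevance-network practice; consequently every
triangle of the thresholded graph contains at least two regulators. DPI
pruning evaluates all triangles against the original thresholded edge set
and deletes marked edges afterwards, making the result order-independent;
the removal condition is strict (MI_ij < (1−ε)·min of the other two), so an
edge exactly at the boundary, or duplicated-regulator ties, survive.

The regulator degree distribution is fitted by ordinary least squares on
log p(k) vs log k over nonzero-probability degrees — the simple log-log
form in which such exponents are conventionally reported — not by
maximum-likelihood power-law machinery; the fit is exact on exact power-law
histograms but is a descriptive summary, not a rigorous tail estimator.

## Module characterization

Enrichment: one-sided Fisher exact tests of member-vs-universe term counts,
where a cistron's annotation is the union over its member genes and the
universe is every cistron in the analysis matrix (not only networked
cistrons; configurable). Protein-class and GO schemes are tested and
q-valued separately, then intersected only at shortlisting. q-values follow
Storey's procedure with π₀ chosen by the bootstrap over a λ grid
(0–0.90 step 0.05, 100 bootstraps); forcing π₀ = 1 reproduces
Benjamini–Hochberg exactly, which the tests use as an oracle.

Motif discovery is a single-motif ZOOPS (zero-or-one occurrence per
sequence) EM against a 0-order background, width range 6–24, 20 seeded
restarts per width, Dirichlet pseudocount 0.1, site-call posterior
threshold 0.5. The EM maximizes the penalized observed-data likelihood and
the implementation asserts the objective is non-decreasing at every
iteration. The significance score is a chi-square tail probability of the
model-vs-background log-likelihood ratio, Bonferroni-corrected for widths
and candidate start positions, handled in log10 to avoid underflow. This is
*not* MEME's internal E-value: the decision rule only ever compares the
same statistic on real versus letter-shuffled inputs (minimum over five
shuffled runs, strict less-than), so any monotone significance score
applied identically is faithful to that rule.

Upstream regions are the 300 bp immediately 5′ of a cistron's leader gene,
strand-aware, clipped at contig ends and not truncated at upstream coding
sequence. The background model is the pooled mononucleotide composition of
all predicted cistrons' upstream regions.

A module is shortlisted when it has at least one enriched term
(p < 10⁻⁴ at FDR ≤ 0.01) *and* a significant motif with a site called in
every member's upstream region; modules enriched in both a protein class
and a GO term are reported as a separate dual shortlist.

## Synthetic-data generator

Defaults (the study conditions for all recovery tests): 1000 genes in
operons of geometric mean length 2 on one contig; within-operon gaps of
mean 20 bp vs 150 bp at operon boundaries; 60 regulator cistrons with
Poisson(8) targets each; 200 samples split 70/70/60 across the three
platforms; per-gene noise sd 0.3 around the cistron latent profile (the
hub→target dependency carries additional noise sd 0.25); 25 % of links
nonlinear (quadratic or sigmoidal — included so that MI has something
Pearson correlation cannot see); 5 % absent calls; oligo probesets for 90 %
of genes; protein-class and GO sharing within operons at 0.72 (matching
the reported fraction of known operon pairs sharing a protein class);
conservation Poisson(12) inside operons vs Poisson(1) at boundaries;
8-bp module motifs planted at 0.9 per-column identity in every member's
300-bp upstream window, on a background of A 0.153, C 0.351, G 0.347,
T 0.149. Sub-seeds per stage are derived from the master seed by fixed
offsets, so any stage can be regenerated in isolation.

What the generator does *not* emulate, and hence what passing recovery
tests do not show about real data:

* Within-operon co-expression is cleaner than in real compendia (where
  only ~35 % of known operon pairs show r > 0.7): single-feature
  classifiers can saturate near AUC 1.0 at some seeds, compressing the
  margin between the combined model and the best single feature.
* Hub degrees are Poisson, not scale-free, so the degree power-law fit on
  synthetic networks is a smoke test only; the exponent recovery is
  validated on constructed exact power-law histograms instead.
* No functional coherence is planted across a hub's targets, so module
  enrichment on synthetic runs is null by construction; the enrichment
  code is validated against exhaustive hypergeometric enumeration.
* No dye bias, array artifacts, or time-course autocorrelation.

## Problem sizes

Recovery tests and the acceptance script run the generator at its default
scale (1000 genes, 200 samples, 60 regulators) with 2×10⁴ permutations for
the MI threshold; the pipeline default is 10⁵. Motif power/specificity
replicates use 12 sequences of 300 bp, width range 6–10 and 5 EM restarts —
discovery power at these settings is saturated (real-vs-shuffle margins of
several orders of magnitude), and the full 6–24/20-restart defaults remain
in force for pipeline runs.

## Known limitations

* The MI estimator's residual negative bias (~0.05 nats at n = 524,
  ρ = 0.9) is acceptable for thresholding but not for absolute MI
  reporting at high dependency.
* The permutation-to-10⁻⁹ extrapolation assumes an exponential null tail;
  heavy-tailed deviations would shift the effective significance level.
* Tied expression values fall back to a slower per-pair MI path and, with
  many ties, weaken the copula argument.
* Upstream windows of adjacent cistrons can overlap on a dense genome; the
  generator plants motifs without collision detection, so rare plantings
  can overwrite one another.
* The operon chainer assumes a gene belongs to exactly one unit; it cannot
  represent nested or overlapping transcripts.
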