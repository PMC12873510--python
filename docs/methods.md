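# Methods

`orthocompare` implements a cross-species comparative transcriptomics
pipeline for two independently evolved pitcher plant lineages: tissue- and
condition-resolved bulk RNA-seq of dissected pitcher parts under a water
control and a prey-mimic (mealworm extract) feeding treatment, integrated
across species through orthogroups. This note documents the statistical
models, the numerical choices, what the synthetic testbed does and does
not emulate, and the known limitations.

## Normalization

Between-sample normalization uses the trimmed mean of M-values (TMM).
For sample *s* against a reference *r*, per-gene log ratios
M_g = log2((y_gs/N_s)/(y_gr/N_r)) and average log intensities
A_g = (1/2) log2((y_gs/N_s)(y_gr/N_r)) are computed over genes with
positive counts in both samples. The most extreme 30% of M and 5% of A
(by average ranks, both tails jointly) are discarded, and the factor is
2 to the precision-weighted mean of the remaining M, with weights from
the binomial delta method, w_g = (N_s − y_gs)/(N_s y_gs) + (N_r − y_gr)/(N_r y_gr).
The reference sample is the one whose 75th-percentile count fraction is
closest to the mean of those fractions. Factors are rescaled to
geometric mean 1 within each normalization group; if all M are below
1e-6 in magnitude the factor is 1 exactly. Each species is normalized
independently: downstream cross-species comparisons are set-based
(orthogroup memberships), never direct value comparisons, so no
cross-species factor coupling is needed.

FPKM is count / (effective library size / 10^6) / (length / 10^3), with
effective library size = raw column sum x TMM factor. Genes with total
count below 1 across all samples are removed before normalization.

## Differential expression

DEGs are called per tissue (fed vs control) with a single-pass
negative-binomial likelihood-ratio test:

- Per-gene dispersions come from method-of-moments on within-condition
  residuals of library-size-scaled counts, phi = (s² − m)/m², pooled over
  the two conditions by residual degrees of freedom, then shrunk toward
  the 12.5%-trimmed-mean common dispersion with weight df/(df + 20) and
  floored at 1e-4. The prior df of 20 roughly balances a 12-sample
  design's 10 residual df against the stability of the common estimate.
- Means are fitted by Fisher scoring with a log link and effective
  library sizes as offsets, dispersion held fixed; the equal-means null
  is compared to per-condition means against chi-squared with 1 df.
- log2 fold change is computed on per-million normalized means with
  pseudo-count 0.5 (finite at zero counts; exactly invariant to global
  count rescaling).
- Benjamini–Hochberg correction is applied within each tissue (the
  analysis unit), and genes are called up/down at FDR < 0.05 (strict)
  and |log2FC| >= 1.0 (inclusive).

This engine is a deliberately simple stand-in for iterative
DEG-elimination normalization pipelines; externally produced DEG tables
can be supplied through the same table schema and flow through all
downstream stages unchanged.

## Orthogroup-level feeding response

Gene-level calls are lifted to hierarchical orthogroups (resolved at the
node representing the two species' most recent common ancestor) by
majority vote of member DEGs: ns genes do not vote; up wins on a strict
majority, likewise down; a nonzero tie is a conflict; no voters means no
response. Ties are conflicts because a tie is not a majority. Genes
absent from a DEG table count as ns with a warning (configurable to an
error). Orthogroups containing genes from fewer than 30% of the declared
species (ceiling on the count) are dropped at parse time.

## Set similarity with a constrained permutation null

The Jaccard coefficient JC = |A∩B| / |A∪B| (0 when both sets are empty)
measures overlap between two orthogroup sets, e.g. the consistently
upregulated orthogroups of one tissue in each species, or the orthogroup
contents of two SOM clusters. Significance comes from a permutation
null: each "side" (a species/tissue, or one species' clustering) has a
universe — for DEG comparisons, all hierarchical orthogroups with at
least one tested gene of that species; for SOM comparisons, all
orthogroups with at least one clustered gene. Each draw applies one
uniformly random bijection of each side's universe onto itself to all of
that side's observed sets jointly. A bijection preserves set sizes and
co-membership and cannot assign one orthogroup to two mutually exclusive
categories, so contradictory assignments (the same orthogroup both up-
and downregulated in one tissue) are impossible by construction rather
than by rejection sampling.

p = (r + 1)/(n + 1) where r counts draws with JC >= JC_observed
(n = 10,000 by default). The +1 correction gives an unbiased,
never-zero Monte-Carlo p; a `p_literal` flag reports the plain r/n
variant instead. "Exceeds" is implemented as >=, the conservative
reading. BH correction is applied per matrix (the up-matrix, the
down-matrix, and the cluster-pair matrix are separate families, matching
per-panel reporting). Side-specific random streams are derived from the
master seed and the side key, so a side permutes identically regardless
of which pairs reference it; duplicated pairs therefore get identical
p-values. In a shared universe the null intersection distribution is
exactly hypergeometric, which the test suite verifies by chi-squared
goodness of fit, and on universes of up to 7 elements the Monte-Carlo p
is checked against exhaustive enumeration.

## SOM clustering

Genes for clustering are the top 10% by coefficient of variation
(sample sd / mean, across tissue x condition mean FPKM) among genes with
maximal mean FPKM above 1; ties at the cutoff break lexicographically by
gene id so the selection is deterministic, and the selection size is
exactly ceil(0.10 x n_eligible). Profiles are mean-centered and
variance-scaled per gene (constant rows dropped).

The map is a batch SOM on a 3 x 4 hexagonal grid (rows r, columns c at
x = c + 0.5·(r mod 2), y = r·sqrt(3)/2; nearest neighbors at distance
1.0). Per epoch, every gene is assigned to its best-matching unit
(minimal Euclidean distance, ties to the lowest unit index) and each
codebook vector is replaced by the neighborhood-weighted mean of the
assigned data, with a Gaussian neighborhood exp(−d²/(2σ²)) truncated to
zero beyond the current radius σ. The radius decays linearly from
two-thirds of the grid diameter to 0.5 over 100 epochs; because the
final radius is below the unit spacing, the last epochs are exact Lloyd
(k-means) steps, which makes the total quantization error provably
non-increasing once the radius is frozen — an untruncated Gaussian does
not have this guarantee, which is why truncation was chosen. The
codebook is initialized from a seeded sample of distinct data rows drawn
in canonical (sorted-gene-id) order, so the partition is invariant to
input row order. A unit left with no weight is relocated to the gene
currently worst represented by its BMU — the standard k-means
empty-cluster repair; simply retaining the stale codebook lets units die
permanently after the annealing phase (two units that collapse to
identical codebooks would otherwise starve one of them forever via the
tie rule), and the relocation cannot increase quantization error, so the
frozen-radius monotonicity is preserved. Because batch SOM shares
k-means' sensitivity to initialization, training runs four seeded
restarts and keeps the map with the lowest final quantization error;
the whole procedure is deterministic given the seed. Epoch count,
radius schedule, restart count and grid size are configurable; the
defaults are conventional choices.

Cross-species cluster matching converts every cluster to its orthogroup
set (orthogroups with at least one member gene in the cluster; genes in
no orthogroup are excluded and logged) and tests all 12 x 12 cluster
pairs with the constrained permutation machinery above, BH over the 144
pairs.

## Convergence-candidate screen

A nonhierarchical orthogroup qualifies as a convergence candidate when
it contains, from each species, at least one gene that is upregulated in
a configured gland tissue (FDR < 0.05 and log2FC > 1, both strict on
this route — note the deliberate asymmetry with the DEG status rule's
inclusive |log2FC| >= 1) or assigned to a configured gland-specific SOM
cluster. The pipeline derives gland clusters as the units whose mean
z-profile peaks in the gland tissue; explicit cluster ids can be
configured instead. The nonhierarchical flavor is used because
hierarchical orthogroups can split distantly related branch pairs into
separate groups. Convergence statistics themselves (omega_C, the protein
convergence rate, and O_C^N, the count of amino-acid-changing convergent
substitutions) are externally computed inputs; the screen keeps records
with omega_C > 3.0 and O_C^N > 3.0, strict on both.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: two species, six dissected
pitcher tissues each (the Cephalotus-style and Nepenthes-style lists,
matched positionally, with the lower pitcher wall and digestive zone as
the gland-bearing pair), 4 control and 8 fed replicates, 5000 genes per
species, and orthogroups in both OrthoFinder-style flavors (3000 groups,
60% strict 1:1; 10% of hierarchical groups merged pairwise into coarser
nonhierarchical groups).

Counts are negative binomial with mean
baseline_g x tissue_profile_g,t x condition_effect_g,t,c x libsize_s / mean libsize
and per-gene dispersion log-uniform on 0.05–0.3 (conventional bulk
RNA-seq values; the study reports no estimates). Baselines are
log-normal (median 50 counts), library sizes uniform on 0.8–1.2 million,
gene lengths log-uniform on 300–10,000 bp.

Planted structure:

- Tissue-specific modules. Exactly 8.5% of each species' genes are
  strongly tissue-specific — deliberately inside the 10% CV selection
  quota, so the whole planted class is recovered by the selection and
  the remaining slots go to the strongest feeding-response genes, as in
  real data. Each specific gene peaks in one tissue with amplitude
  12 x 2^U(−0.5, 0.5) (8.5–17-fold; strongly specific, as
  digestive-fluid enzyme genes are in real pitchers, and ranking above
  the CV of planted feeding responses). Twelve profile classes match the
  SOM grid: modules 0–5 are constitutively specific to tissue m; modules
  6–11 peak in tissue m−6 but are feeding-attenuated (2^−2 in the fed
  condition of the peak tissue, recorded in the truth table as a planted
  down response — mirroring the study's observation of broad feeding
  repression of tissue-specific genes such as photosynthesis genes).
  Module identities cycle round-robin so planted modules are
  equal-sized. 90% of tissue-specific 1:1 ortholog pairs share both the
  module and the amplitude (conserved tissue specificity); the rest draw
  independently. The class structure (size within the quota, amplitudes
  above the feeding-response CV range, conserved amplitudes) makes
  cross-species co-clustering of conserved pairs a structural property
  of the testbed rather than a sampling accident, which is what lets
  recovery failures be attributed to the pipeline.
- Feeding responses. Per tissue, 5% of genes receive a multiplicative
  fed-condition effect with |log2 effect| uniform on 1.5–2.5 and random
  sign (2.8–5.7-fold, typical feeding-response magnitudes). 150
  one-to-one orthogroups are planted upregulated, and 60 downregulated,
  in both species' gland tissues with a shared effect size (the
  conserved feeding response); 30 orthogroups per species get
  opposite-sign effects in two paralogs to exercise the conflict call.
- Randomness. One stream per species derived from the master seed (so
  regenerating or renaming one species never perturbs the other) plus a
  structural stream for the cross-species skeleton. Regeneration with
  the same seed is bit-identical.

`truth_sets` converts planted gene effects to expected orthogroup calls
with the same majority rule as the pipeline, providing the oracle for
end-to-end recovery tests.

Not emulated: read-level noise and mapping ambiguity, GC/length biases,
batch effects, correlated gene networks beyond the block modules,
unbalanced ortholog conservation between clades, and any sequence
evolution (the convergence statistics consumed by the screen are
synthesized as half-normal null draws in the acceptance script, labelled
as such). Passing tests on this testbed demonstrate that the pipeline's
inference machinery recovers known signal under the declared noise
model; they do not certify performance on real libraries whose noise
violates these assumptions.

## Numerical choices and degenerate inputs

- Dispersion floor 1e-4; Fisher scoring runs up to 60 damped iterations
  from the pooled-mean start; all-zero genes get mean 0 and contribute
  zero log-likelihood terms (0·log 0 = 0).
- BH is computed by the step-up minimum-accumulation form; inputs
  outside [0, 1] raise a domain error.
- Welch's t with zero variance in both groups and equal means is defined
  as t = 0, p = 1 (and infinite t, p = 0 for unequal means).
- CV of an all-zero row is 0; rows with zero variance are dropped before
  z-scaling with a warning.
- Empty orthogroup sets give JC 0 and p 1; p has floor 1/(n+1).
- TSV writers emit 6 significant digits, sorted rows, fixed column
  order; re-running a stage is byte-identical.
- Sub-seeds: stage or side seeds are crc32(label) mixed with the master
  seed, kept below 2^31.

## Problem sizes

Default end-to-end runs use 5000 genes per species, 10,000 permutations
per set pair and 100 SOM epochs; the test suite's statistical checks use
2000–5000 genes and 20 replicate seeds for calibration, sizes chosen to
hold Monte-Carlo error well below the tested margins.

## Known limitations

- The NB LRT uses plug-in dispersions (no uncertainty propagation), so
  raw p-values are mildly liberal at few replicates; BH operates on
  whatever the test produces. The published analysis used a different
  DEG engine; numerical agreement with it is not claimed, and precomputed
  tables can be substituted.
- The SOM is a batch implementation with a truncated Gaussian
  neighborhood; it is not numerically identical to any particular
  published SOM package, and cluster identities are arbitrary up to
  relabeling.
- Whether the published CV selection used replicate-level or mean FPKM
  is not documented; means are the default here and replicate-level
  values are accepted by the same function.
- The permutation null conditions on the observed set sizes and
  universes; it does not model uncertainty in the DEG calls themselves.
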