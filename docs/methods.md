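# Methods

## The model

`otuspace` treats an OTU table as a bipartite interaction network
between samples and taxa and does all downstream analysis in an
embedding of that network.

**Edge weights.** Raw relative abundances span four or more orders of
magnitude between dominant and rare taxa; a walker biased by raw
abundance would only ever visit the dominant OTUs of each sample. The
weighting therefore standardises within each OTU: with `μ_j` and `σ_j`
the mean and standard deviation of `log10 r_ij` over the `n_j` samples
where OTU *j* occurs, the weight is the z-score shifted to 4 and clamped
to [1, 7] (7 at z ≥ 3, 1 at z ≤ −3, both boundaries closed; no edge when
`r_ij = 0`). `σ_j` uses the population form (1/n_j); a `ddof=1` flag
gives the sample form. When `σ_j = 0` (a constant-abundance or
singleton OTU) the z-score is undefined; such an OTU shows no deviation
from its own mean, so every presence gets the midpoint weight 4.

**Walks and embedding.** Walks start at every OTU node and alternate
OTU → sample → OTU (the bipartite graph enforces the metapath); each
step picks a neighbour with probability proportional to edge weight.
Defaults are 100 walks per OTU of 100 cycles each (1 + 2·cycles tokens
per walk); the test fixture uses 20 × 20, which is enough for a
60-sample cohort. Tokens are namespaced (`O:` / `S:`) so identifiers
never collide across node types. Skip-gram with negative sampling is
trained directly on the walk sentences with word2vec conventions
(smoothed-unigram noise distribution with exponent 0.75, per-position
random window shrink, linearly decaying learning rate, single-threaded
— hence bit-reproducible for a fixed corpus and seed). Defaults:
d = 128, window 7, 5 negatives, min_count 1 (ultra-rare OTUs must be
embedded), 5 epochs, initial learning rate 0.025. Since the walks
already realise the metapath, heterogeneous skip-gram reduces to
standard skip-gram on namespaced tokens; an optional type-aware mode
draws negatives only from the context token's node type.

**Vector norms.** Skip-gram norms grow with token frequency, which for
sample nodes reflects degree and edge weights, not community
composition. At desk scale this norm noise dominates raw Euclidean
distances (empirically it flips local-aggregation detection from clear
to absent on identical corpora). `embedder.aligned_matrix` therefore
unit-normalises vectors by default before any distance analysis;
distances remain Euclidean, now on the unit sphere where they are
monotone in cosine similarity. Raw vectors are available with
`normalize=False`.

## Local aggregation

For a sub-attribute with member set D, `SAND(s) = min over other
members of ‖x_s − x_m‖₂` and ASAND is the mean of the m smallest SANDs
with `m = max(1, floor(0.10 · |D|))` (the floor keeps the statistic
defined for small groups; ties at the cutoff resolve by stable sample
order). The LAI permutation test redraws the |D| member labels
uniformly over all samples (group size preserved), recomputes ASAND,
and reports the fraction of permutations with `ASAND_perm ≤ ASAND_real`
— ties count, so the plain estimator can be exactly 0; a
`continuity=True` mode gives the (1+b)/(1+m) proper p-value instead.
Under a label-independent null the LAI is approximately Uniform(0, 1),
which the test suite checks by calibration. The scan excludes the "NA"
sub-attribute and groups below 10 members by default and reports rows
sorted by LAI. No multiple-testing correction is applied across a scan;
the LAI values are raw.

Power at small cohort sizes is intrinsically limited: with groups of
10–20 members, m = 1–2, so the statistic is essentially the closest
member pair. It detects a sub-attribute only when its members form a
cluster tighter than any comparable structure in the background — which
is also the regime the statistic is meant for (distinct community
states such as disease subpopulations).

## IMETA

Taxo-Embedding multiplies each OTU's frozen embedding row by the
sample's log-scaled abundance of that OTU. Log scaling maps absence to
exactly 0 and presence to `log10 r − log10 r_floor` > 0, with `r_floor`
the smallest detectable abundance (1/depth); absent OTUs therefore
contribute nothing to the kernel sums, matching the weighted-sum
semantics. A raw `log10 r` mode exists for sensitivity analysis. Each
of the three convolution kernels is a length-k weight vector over OTUs;
kernel c outputs `Σ_j a_jc x_j E_j ∈ R^d`, the outputs are flattened
(n_kernels · d = 384 components at d = 128), the sample's own embedding
vector can optionally be appended (off by default), and a dense sigmoid
head yields the class probability. Training minimises binary
cross-entropy with Adam (lr 1e-3, 50 epochs, batch 64, early stopping
on validation F1 with patience 10), after up-sampling the minority
class to balance; a full-batch plain-gradient-descent mode exists for
optimisation sanity checks. All gradients are analytic (the model is
bilinear in (A, E) and linear in the head) and are verified against
finite differences in the tests. The end-to-end twin shares the
architecture with a trainable, randomly initialised embedding matrix —
exactly k·d more trainable parameters.

**Importance scores.** Negating one kernel column together with its
dense-weight block leaves the model's function unchanged, so the sign
pattern of the kernels across OTUs is a gauge choice and signed means
across kernels can cancel arbitrarily. The default importance is
therefore the mean of the absolute kernel parameters per OTU, which is
invariant to that gauge; the signed-mean-then-absolute-value convention
is available as `mode="signed_mean"` but is meaningful only when the
trained kernels happen to align. On synthetic tasks with five
discriminative OTUs among 500, the default recovers all five in the top
ranks; the signed mean recovers them only sporadically.

## Synthetic data

The generator emulates the shape of a large gut-microbiome survey:
each OTU belongs to one of a few guilds; each sample mixes guilds with
Dirichlet weights; presence of a common OTU is Bernoulli with
probability proportional to its guild's weight (capped at 0.9);
log10 abundance is base + 2·guild-weight + N(0, 0.5) with per-OTU base
~ N(−3, 0.8); half the OTUs are ultra-rare, planted in exactly one or
two samples with a higher base (−2.5), reproducing the
low-prevalence/decent-abundance tail of real surveys; reads are
multinomial at fixed depth 30,000 (comfortably above the 10,000-read
screen, so fixtures survive filtering).

A *planted* attribute must mark a genuinely aggregated group.
Thresholding one guild's weight under a single symmetric Dirichlet does
not achieve that at 60 samples — every guild corner is equally tight,
so permutation sets always contain pairs as close as the real members
(verified empirically; LAI stays near uniform). The generator therefore
supports a *marker community state*: a minority of samples
(`marker_fraction`) draws its guild weights from a concentrated
`marker_alpha` Dirichlet dominated by the marker guild, while the
background uses concentrations > 1 for the remaining guilds (a smooth
mixture with no secondary corners). The planted attribute thresholds
the marker-guild weight and so flags exactly that coherent state — the
enterotype / disease-state pattern the aggregation statistic targets.
Null attributes are drawn independently of everything.

The canned fixture (`fixture_small`, seed fixed) is 60 samples × 300
OTUs, 3 guilds, background Dirichlet (0.2, 2.5, 2.5), marker state
(20, 1.5, 1.5) at fraction 0.18, one planted and three null attributes.
What passing tests show: the pipeline separates planted structure from
null at this scale and the statistics are calibrated. What they do not
show: robustness to real-data features the generator omits — batch
effects, compositional biases between sequencing runs, taxonomic
correlation structure within guilds, and cohorts orders of magnitude
larger.

## Numerical and design notes

- Depth filter is strictly greater-than (default 10,000 reads);
  prevalence filter is ≥ 2 samples, counted after the sample filter.
  Both thresholds are parameters, so a distinct-OTU-count reading of
  "depth" is also expressible.
- Edge weights are stored in double precision, never rounded.
- Dead-end walk nodes truncate the walk (logged); they cannot occur on
  a prevalence-filtered network.
- Per-walk RNG substreams are spawned deterministically from the corpus
  seed, so corpora are reproducible regardless of generation order.
- Metrics with zero denominators are NaN, never 0; averaging over
  repeats skips NaN and logs that it did.
- Classifier experiments use repeated stratified 80/20 splits (5
  repeats by default) for all models, IMETA and baselines alike.
- Baseline hyperparameters are fixed (linear SVM C=1; logistic
  regression C=0.1, L1; random forest depth 5, 100 trees; all
  class-balanced) and deliberately not re-tuned.
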