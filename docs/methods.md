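# Methods

## Model and procedure

`stableclust` treats cell-type identification as a model-selection problem
over k-means clusterings of a 2-D t-SNE embedding of the cell-cell
Euclidean distance matrix. Two selection criteria are used in sequence: the
number of clusters k is chosen by the average silhouette over repeated
embeddings, and the final partition is chosen among candidate k-means runs
by its robustness to noise resampling. The method assumes that cell types
form compact, roughly isotropic groups in the embedded space — k-means'
implicit model — and that technical variation acts like small perturbations
that a real grouping survives.

### Preprocessing

Genes with zero counts in every cell are removed ("not expressed" means
exactly zero; no epsilon threshold). No cell filtering, normalisation or
batch correction is performed. Expression is transformed as
M′ = log₂(M + 1) before distances are computed. Because log₂(x + 1) = 0 iff
x = 0, filtering and transforming commute; filtering is applied first. The
transform can be disabled (`log_transform=False` / `--no-log-transform`)
for inputs that are already on a suitable scale.

### Embedding

Distances are Euclidean on the log-transformed profiles. t-SNE is run in
precomputed-distance mode (scikit-learn, random initialisation, single
thread) so runs are deterministic given a seed. The output dimension is
l = 2 by default (configurable ≥ 2). The t-SNE perplexity defaults to 30
and is automatically lowered to floor((n_cells − 1)/3) — kept strictly
below (n_cells − 1)/3 — for small datasets; learning rate and iteration
count are scikit-learn's defaults. These embedding hyper-parameters are a
reproducibility caveat: silhouette curves, and hence the selected k, can
shift with them, which is exactly why k is averaged over repeats.

### Choosing k

The distance matrix is embedded `n_tsne_repeats` times (default 50), repeat
r with seed `base_seed + r`. Per repeat, k-means (k-means++, 10 restarts)
is run for every k in [k_min, k_max] (default [2, 20], truncated to
n_cells − 1 with a warning) and scored by mean silhouette on the embedded
coordinates — the clustering space — not on the original distances. Ties
in the per-repeat arg-max go to the smaller k (parsimony). The final k is
the mean of the per-repeat choices rounded half away from zero (so a mean
of 3.5 yields 4); the half-case convention is arbitrary but documented and
fixed. A point in a singleton cluster receives silhouette 0, the
conventional finite extension of the formula.

### Stability selection

On a fresh embedding (seeded past the k-selection repeats, so no embedding
is reused), `n_candidates` k-means clusterings (default 20) are generated
with seeded initialisations and each is scored with `n_resamplings`
(default 1000) perturbation rounds. Each round replaces
round(0.05 · n_cells) distinct cells — half-away-from-zero rounding,
minimum one cell enforced — chosen uniformly without replacement, with
points drawn uniformly from the axis-aligned bounding box of the embedded
coordinates expanded by 10% per side. Replacement is in place: the dataset
size is constant, and the replaced cells simply become noise for that
round. The perturbed data is re-clustered with the same k; each original
cluster is compared with every resampled cluster by the Jaccard
coefficient after removing the noise cells from both sides, and is
preserved when its best match is ≥ 0.75 (inclusive). Matching is
one-directional (original → best resampled); no bipartite assignment is
attempted, so two original clusters may match the same resampled cluster.
Per-cluster stability is the preservation rate; overall stability is the
unweighted mean over clusters; the arg-max candidate wins, earliest
candidate on ties.

k-means on candidates and resamples uses k-means++ initialisation with 10
restarts, freshly seeded per run. Plain single-restart random
initialisation would make k-means itself the dominant source of
instability — on well-separated data roughly three-quarters of random
initialisations converge to a bad local optimum, capping measured
stability far below 1 even when the partition is unambiguous. With ++
restarts, the noise injection is the only perturbation being measured,
which is the quantity of interest. `resample_init="random"` restores the
plain behaviour for comparison.

## Validation metrics

ARI, AMI and V-measure are implemented directly from their defining sums
over the contingency table, not delegated: the exact expected mutual
information E{MI} is evaluated as the triple sum over cells (i, j) and
feasible overlaps n_ij ∈ [max(1, a_i + b_j − n), min(a_i, b_j)] with the
hypergeometric weight computed via log-gamma, so no factorial overflows.
AMI uses max-entropy normalisation. Entropies are in nats (base option
provided); AMI, homogeneity, completeness and V are base-invariant ratios.
Degenerate conventions: ARI of two trivial identical partitions
(denominator zero) is 1; AMI of two single-cluster partitions is 1;
completeness is 1 when H(K) = 0; the homogeneity guard is H(C|K) = 0. The
test suite cross-checks every metric against brute-force oracles
(pair-counting ARI, exhaustive fixed-margin enumeration of E{MI} for
n ≤ 8, direct entropy sums) and against scikit-learn.

## Synthetic data

The simulator emulates clustered scRNA-seq data with a log-normal cluster
model: a baseline log₂ expression programme per gene (Normal(4, 1.5²)),
per-cluster shifts of ±separability × σ_within on a random 20% of genes
("markers", σ_within = 1 on the log scale), per-cell Gaussian noise,
mapping to the count scale by round(2^x − 1) clipped at zero, independent
Bernoulli dropout (default rate 0.3), and an optional fraction of genes
silenced entirely to exercise the gene filter (every non-silenced gene is
guaranteed expression in at least one cell so that this fraction controls
the all-zero gene count exactly). `separability` is therefore a
signal-to-noise ratio: 0 makes all clusters identically distributed, 10
makes them essentially disjoint.

The generator reproduces the features the pipeline actually consumes —
cluster structure, dropout zeros, unexpressed genes, a log-scale mean-shift
signal — but not library-size variation, gene-gene correlation, counts'
mean-variance relationship, batch effects or rare subpopulations. Passing
tests therefore demonstrate correctness of the algorithm and its
implementation under the stated generative model, not performance on real
tissues.

## Numerical choices and problem sizes

Defaults follow the full operating point (50 repeats, k ∈ [2, 20], 20
candidates, 1000 resamplings, 5% noise, 0.75 threshold).
`PipelineConfig.fast()` (10 repeats, k ≤ 10, 5 candidates, 50 resamplings)
is the package's desk-scale profile; the test suite and the acceptance
script use it on 150-cell, 500-gene simulations, where one full pipeline
run takes a few seconds and the silhouette/stability signals are already
saturated. Seeds propagate explicitly: repeat r of k-selection uses
base_seed + r, the final embedding uses base_seed + n_repeats, and
candidate/resample seeds are drawn from a seeded generator, so every run
is bit-reproducible from the report JSON, which records all of them.

## Known limitations

- t-SNE hyper-parameters (perplexity, learning rate, iterations) influence
  the embedding and are not themselves selected; only k is averaged over
  embedding stochasticity.
- The stability score is computed on one embedding; structure that appears
  in only some embeddings is invisible to the candidate stage.
- One-directional Jaccard matching can rate a clustering stable when two
  of its clusters merge in the resampled solution only if each still finds
  a ≥ 0.75 match; the 0.75 threshold makes this rare but not impossible.
- Runtime grows roughly quadratically with cell count (distance matrix and
  t-SNE); the method targets datasets of hundreds to a few thousand cells.
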