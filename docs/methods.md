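# Methods

## Scope and data model

`micronet` analyses genus-level sample × taxon count tables with per-sample
metadata (group, timepoint, negative-control flag).  Counts are treated as
compositional: all inference goes through log-ratios (clr, SparCC) or
presence/absence (Jaccard), never raw proportions.  The package consumes a
count table; upstream read processing (denoising, taxonomy, collapsing) is
out of scope, as are phylogeny-dependent diversity metrics and
reference-database functional prediction.

## Synthetic data generator

The generator draws, per sample, basis log-abundances from a multivariate
normal with unit per-taxon variances, per-taxon means uniform on
`logmean_range` (default (0, 3)), and a planted correlation matrix;
closes them to fractions by softmax; draws a sequencing depth (negative
binomial with mean `depth`, default 20 000, dispersion 0.2; exact when
dispersion is 0); and observes multinomial counts.  This
logistic-normal–multinomial model is exactly the generative family SparCC
assumes, which makes parameter recovery a meaningful test surface.

**Planted structure.**  Taxa are split into near-equal modules (default 30
taxa, 3 modules).  Candidate edges are Bernoulli draws, probability
`p_within` = 0.1 inside modules and `p_between` = 0.01 across.  Edge signs
derive from latent per-taxon polarities (edge sign = product of endpoint
polarities); the polarity-flip rate is calibrated so the expected fraction
of negative planted edges equals `neg_frac` (default 0.3).  Balanced signs
matter: with arbitrary per-edge signs, frustrated triangles make
correlation targets of ±0.8 jointly infeasible, and any PSD projection
must shrink them far below the nominal value — the recovery contract would
be unattainable by construction.  With balanced signs a rank-one
representation exists and targets of any magnitude < 1 are feasible.

**PSD construction.**  Unplanted entries are filled by distance decay,
ρ_ij = polarity_i · polarity_j · corr^d(i,j) with d the path length in the
planted graph (the Markov completion, exactly PSD on trees).  Any residual
negative eigenvalues are repaired by eigenvalue clipping and rescaling to
unit diagonal, alternated with restoration of the planted entries; the
final pass is a plain clip-and-rescale, so the output is PSD to 1e−12.  At
the default density the completion is already PSD and planted entries are
preserved exactly at ±0.8.

**Study layout.**  The default study has four arms — control/cancer ×
16/22 dpi with 7, 9, 7 and 8 samples — each with its own planted network
over a shared taxon set, plus four water-template negative controls
dominated by 3 contaminant taxa (present in all controls at 200–2000
reads, and as 1–20-read carry-over in 10% of true samples).

**What the generator does not emulate:** taxonomic zero-inflation beyond
what the log-normal tails produce (at 20 000 reads most taxa are detected
in every sample, so presence/absence metrics like Jaccard carry little
signal on default synthetic data — the pipeline handles the fully
degenerate case by reporting a vacuous PERMANOVA with p = 1), sequencing
error, chimeras, batch effects, and phylogenetic structure.  Passing tests
demonstrate correctness of the inference chain under its own model
assumptions, not performance on real stool samples.

## Preprocessing

- **Contaminant flagging** follows the prevalence logic of
  decontam: per taxon, a 2×2 presence table (controls vs true samples) is
  scored by the chi-squared statistic without continuity correction; the
  score is the upper-tail probability when control prevalence exceeds
  true-sample prevalence and 1 otherwise, and taxa with score < 0.1
  (decontam's default threshold) are removed before all downstream
  analysis.  Degenerate margins (taxon everywhere or nowhere) score 1.
- **Filtering** keeps taxa with ≥ 10 total reads AND non-zero in ≥ 30% of
  samples; both bounds inclusive (strict less-than removal).
- **clr** uses log(count + 0.5) centered per sample (pseudocount 0.5, the
  ALDEx2 convention); rows sum to zero to 1e−9.
- **Differential abundance** is the Dirichlet Monte-Carlo scheme: per
  instance, sample proportions ~ Dirichlet(counts + 0.5), clr-transform,
  per-taxon Kruskal–Wallis across the two groups; the reported p is the
  expectation over 128 instances, BH-adjusted across taxa.  The
  Kruskal–Wallis statistic is computed by a vectorized tie-corrected rank
  implementation (cross-checked against scipy.stats.kruskal).

## SparCC

`variation_matrix` uses the n−1-denominator sample variance of
log-ratios, computed from the log-abundance covariance.  The basis-variance
system has matrix (D−2)I + J on row sums of t; excluded pairs are removed
from both the coefficients and the row sums.  Negative solutions are
floored at 1e−6 so correlations stay defined.  Exclusion follows the
original reference defaults: per round, the single strongest remaining
pair is excluded while its |ρ| exceeds 0.1, for at most 10 rounds; a taxon
can never lose its last partner (the round stops instead).  The full
estimator draws per-sample fractions from Dirichlet(counts + 1) (20
resamples) and aggregates by the elementwise median, clipped to [−1, 1]
with unit diagonal.  Fewer than 4 taxa is an error: the basis system is
unidentifiable below D = 4.

Under the default planted fixture (30 taxa, 16 planted edges at ±0.8, 300
samples) the median estimate attenuates to ≈ 0.78 — the sparsity
approximation biases ω upward when a non-negligible fraction of pairs is
truly correlated; the exclusion iteration reduces but does not remove this.

## Networks, topology, keystones

Edges require |ρ| strictly above the threshold (0.75; core 0.95); isolated
taxa are dropped from the graph.  All structural metrics use |weight| or
the unweighted graph — signed weights appear only as edge attributes —
because modularity, clustering and eigenvector centrality are not defined
for negative weights in the conventions this mirrors.  Louvain runs with
seed 0 and resolution 1.0, communities ordered by size; diameter is the
unweighted diameter of the largest connected component (ties between
equal-size components resolve to the widest); clustering is the mean local
coefficient on the unweighted graph.

Eigenvector centrality is computed by power iteration on A + I (the shift
preserves eigenvectors and guarantees convergence on bipartite graphs,
where plain iteration oscillates), tolerance 1e−10, at most 1000
iterations, then max-normalized so the top node scores 1.  On disconnected
graphs the vector localizes on the dominant component; other components
receive ≈ 0.

A taxon is keystone iff ubiquitous in the condition, mean clr ≥ 0.35, and
eigenvector centrality ≥ 0.75.  Both cutoffs are inclusive and compared
with a 1e−9 guard so representation error cannot exclude a value sitting
exactly on the boundary.

## Robustness

Connectivity loss is 1 − R/R₀ over ordered mutually reachable pairs,
with R₀ from the intact graph — removed nodes therefore contribute their
full pair count to the loss.  Attacks remove every node, recording loss
per step; ties in degree/betweenness break lexicographically by node id
for determinism; cascading recomputes betweenness on the surviving graph
before each removal.  The summary statistic is the removed fraction at
which loss first reaches the 0.80 target.  Random attacks report the mean
and percentile 2.5/97.5 bounds over 100 independent replicates.

Node addition attaches each new node by one unit-weight edge to a
uniformly chosen existing node (previously added nodes included);
preferential attachment and more edges per node are available.  LCC and
APL are recorded after every addition; APL averages unweighted shortest
paths over mutually reachable ordered pairs and is NaN when no pair is
connected.  Per k ∈ {100, 300, 500, 700, 1000} and 5 replicates, the
change from the un-grown baseline is tested with an exact two-sided
Wilcoxon signed-rank test (normal approximation above n = 25; all-zero
difference vectors define p = 1), BH-adjusted across the (k, metric)
family.

On 20 scale-free fixtures (Barabási–Albert, n = 200, m = 2) the measured
mean removal fractions are ≈ 0.11 (cascading), 0.13 (degree), 0.14
(betweenness), 0.46 (random): cascading is decisively the most damaging
strategy and random the least, while the two one-shot targeted strategies
are statistically tied, with degree marginally ahead on this graph family.

Graph internals in the simulation loops (betweenness, components, path
lengths) run through igraph for speed; the graphs themselves are networkx
objects, and the test suite cross-checks the igraph-backed results against
networkx and against brute-force enumeration on all graphs with ≤ 7 nodes.

## Diversity

Rarefaction subsamples each sample to the minimum sample total (or a given
depth) without replacement via multivariate hypergeometric draws.
Observed features counts non-zero taxa.  Jaccard distances come from
presence/absence sets, with two empty samples at distance 0.  PERMANOVA
partitions the squared-distance sum into among/within components; the
permutation p uses the +1 correction, and a distance matrix with zero
total variance yields a vacuous test (F = NaN, p = 1).

## Pipeline and reproducibility

`run_pipeline` executes: contaminant flagging → removal → filtering →
rarefied alpha/beta diversity with a 4-arm PERMANOVA → per-arm SparCC,
networks (0.75 and 0.95), topology, keystones → pairwise differential
abundance (between groups per timepoint, within group across timepoints) →
the robustness battery, and writes TSV/GraphML/GEXF/JSON artifacts plus a
manifest (config hash, seed, version).  All randomness derives from one
root seed through named per-stage streams, so reruns with the same seed
are byte-identical (GEXF export strips the writer's embedded date; the
config hash excludes the output directory, which is a location rather than
an analysis parameter).  The default problem sizes — 30 taxa, 31 samples,
20 SparCC resamples, 100 bootstrap attacks, the full k-list with 5
replicates — complete in about two minutes on one CPU.

## Known limitations

- SparCC magnitude estimates attenuate as planted-edge density grows; the
  package reports medians over resamples but no standard errors.
- Keystone abundance uses the clr scale, so the 0.35 cutoff is only
  meaningful relative to a given table's composition.
- Connectivity-loss attacks are node-based; edge-removal attacks and
  weighted shortest paths are not implemented.
- PERMANOVA assumes exchangeability under the null; no strata/blocking.
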