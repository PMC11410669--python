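# Methods

`germdrop` re-implements, as a tested library, the computational procedures
used to build a single-cell expression atlas of germinating *Arabidopsis*
embryos from a two-ecotype droplet experiment: genotype demultiplexing of
droplets, bulk-RNA-seq correction for the protoplast (dissociation)
artifact, the single-cell QC/clustering/marker workflow, and bulk-signature
identity scoring. Everything is exercisable on a bundled synthetic-data
generator whose ground truth is the package's acceptance surface.

## Genotype demultiplexing

In a 50/50 mixture of two ecotypes (e.g. Col-0 and Cvi-0), a real single
cell carries SNP-informative UMIs from one genotype only; doublets and
ambient background carry both. Read-level allele observations are first
collapsed per (barcode, UMI) by majority vote — exact ties are discarded so
no molecule is double-counted — giving per-barcode counts (n_A, n_B). Each
barcode is embedded at (log10(n_A+1), log10(n_B+1)); the log10 transform
compresses the heavy-tailed count range and makes radii of 0.15–0.5
meaningful.

Calling is two-stage density clustering:

1. **Background separation.** DBSCAN at `eps_background` (default 0.4, the
   mid-germination setting; per-sample values of 0.15–0.5 are exposed).
   The cluster whose centroid has the smallest total UMI count — not the
   one nearest the origin, which fails when no barcode sits exactly there —
   is the ambient background. Zero-count barcodes are always background.
2. **Genotype resolution.** DBSCAN at `eps_margin` (default 0.3) on the
   remaining barcodes. Each cluster is classified by its mean allele
   balance f = mean(n_A/(n_A+n_B)): f ≥ 1−δ → genotype A, f ≤ δ →
   genotype B, otherwise doublet (δ = 0.2 by default). Stage-2 noise is
   left unassigned. A deeply sequenced barcode (min(n_A, n_B) ≥ 10) with
   balanced alleles inside a singlet arm is rescued as a doublet.

The DBSCAN itself is written here and kept deterministic: a point is core
iff its **closed** eps-ball contains ≥ `min_pts` points (itself included),
clusters grow from cores in input order, and border points join the first
core cluster that reaches them. `min_pts` defaults to 10 — background
clouds contain thousands of droplets, and the sensitivity to this choice is
small because the decision boundaries are density chasms, not gradients.
The staged eps semantics are this package's explicit definition; the
balance margin δ and `min_pts` are likewise package choices, since only the
eps values are conventionally reported.

## Bulk differential expression (NB-GLM engine)

Protoplast isolation induces a stress response that must be identified and
removed. The engine fits, per gene, a negative-binomial GLM with log link
and `var = μ + φμ²`:

- **Normalization.** TMM factors (reference = sample whose upper-quartile
  CPM is closest to the mean; 30% M-trim, 5% A-trim,
  inverse-asymptotic-variance weights; rescaled to geometric mean 1), with
  log effective library sizes as offsets. logCPM uses a prior count of 0.5.
- **Dispersion.** A common φ maximizes the summed Cox–Reid adjusted profile
  log-likelihood (−½ log det X'WX removes the bias from profiling out the
  mean parameters; without it φ is underestimated by roughly the ratio of
  residual to total df and the LRT becomes anticonservative). The search is
  golden-section on log φ over [1e-6, 10]. Tagwise values maximize each
  gene's adjusted profile likelihood plus a shared prior term weighted at
  10 residual-df equivalents, shrinking single-gene estimates toward the
  common value.
- **Fitting.** IRLS, vectorized across genes, tolerance 1e-8 on relative
  deviance change, ≤ 50 iterations, step-halving on deviance increases;
  genes that still fail are flagged and excluded from calls. All-zero genes
  are dropped before fitting (degenerate likelihood).
- **Testing.** Likelihood-ratio tests of nested designs against χ² with
  df = rank difference; Benjamini–Hochberg FDR per contrast family (the
  family is all genes within one contrast — stated explicitly because
  "FDR" alone does not pin it down).

Dissociation-responsive genes: full model `~ time + protoplast` vs reduced
`~ time`, significant iff FDR < 1% and estimated |log2FC| ≥ 1.5 (the
threshold is applied to the estimate, not via a threshold test). Positive
log2FC means higher in protoplasts.

**Discordance.** Developmental coherence of dissociated material is
audited by calling per-interval time effects (FDR 5%, |log2FC| ≥ 1.5)
separately in the whole-tissue and protoplast arms and reporting, per
successive time interval, 100 × (genes called up in one arm and down in
the other) / (genes called up or down in at least one arm). The
denominator choice is this package's definition. Note the numerator
requires a confident call in *both* arms while the denominator needs one,
so under low power the statistic is biased conservative; at the
generator's default bulk noise the planted discordant fraction is
recovered within a few points.

**Time signatures.** Each time point is contrasted against the average of
the others on TMM logCPM with an ordinary linear model (group-means
coding, pooled residual variance, two-sided t, BH per contrast); genes
differentially expressed (FDR < 5%, |log2FC| > 1.5) at more than one time
point are filtered out, making the per-time lists disjoint. The moderated
(empirical-Bayes, precision-weighted) machinery used upstream of this
filter in the original workflow is deliberately replaced by plain t-tests:
the unique-time filter is the load-bearing step, and with ≥ 3 replicates
of deep bulk libraries the moderation changes little.

## Single-cell pipeline

Cells (typically the demultiplexed singlets of the genotype of interest,
plus a total-UMI floor of 100) pass through:

1. **QC.** Remove cells whose log10 total counts or log10 genes detected
   fall more than 3 MADs (scaled by 1.4826) below the median; strict
   inequality, so an all-identical input removes nothing. Genes with zero
   total count are dropped (the minimal reading of an average-count
   threshold of zero).
2. **Normalization.** Library-size factors rescaled to mean 1, then
   log2(count/factor + 1). Pool-based deconvolution factors were not
   re-implemented — they belong to cited external machinery — and at the
   generator's moderate ambient levels library-size factors recover the
   same clusters.
3. **HVGs.** Per-gene variance is decomposed against a LOWESS (tricube,
   span 0.3, no robustness iterations) trend of variance on mean,
   evaluated at each gene's mean and floored at 0; a gene is highly
   variable iff biological variance = total − trend > 0.
4. **PCA.** Top-30 components of the centered HVG submatrix by exact SVD;
   sign fixed by making the largest-magnitude loading positive.
5. **SNN graph.** kNN (k = 10, Euclidean, self excluded, distance ties by
   cell index); edge iff two cells share a neighbour or list each other;
   weight = Jaccard of the two kNN sets augmented with their own cells.
6. **Louvain.** Two-phase modularity maximization at resolution 1.0; the
   sweep order is one seeded shuffle per level, local moves repeat until
   no gain > 1e-12, then the graph is aggregated. Determinism is exact
   given (input, seed).
7. **Markers.** Per cluster vs rest, two-sided Wilcoxon rank-sum with
   normal approximation and tie correction (no continuity correction);
   reported genes have p < 0.01 and positive log2FC of mean normalized
   expression (pseudocount 1e-9). Clusters with < 3 cells are skipped.

Batch integration (mutual-nearest-neighbour correction) is out of scope;
the generator emits single-batch data.

## Scoring and the correlation audit

**Module scores.** Genes are cut into 25 equal-size bins by average
normalized expression; each signature gene draws 100 control genes from
its bin (with replacement when the bin is small), and the score is mean
signature expression minus the mean over the pooled control draws per
cell. Pooling controls (rather than averaging per-gene control means) is
equivalent in expectation with lower variance. Bin/control counts follow
the scheme's convention since no values are conventionally printed; both
are exposed.

**Pseudobulk audit.** Per-group integer count sums (exactly conserving
totals) are converted to logCPM (prior 0.5) and Pearson-correlated with
the matching whole-tissue bulk profiles over the shared gene universe,
with and without removing the dissociation-responsive set. In the
simulated design — cells carry the dissociation response because they are
protoplasts; the whole-tissue arm does not — exclusion raises r at every
time point in essentially all seeded runs.

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults define the study conditions: 3,000 cells over
12/24/48 h, three expression states whose proportions shift across
germination (0.70/0.20/0.10 → 0.30/0.50/0.20 → 0.10/0.30/0.60), a 50/50
two-genotype mix, 5% doublets, 2,000 empty droplets, mean ambient fraction
2% (Beta with concentration 20), log-normal library sizes (median 2,000
UMIs, σ = 0.3), NB dispersion 0.2 for droplets, 5% of UMIs
genotype-informative, 0.5% allele error.

- State profiles: Gamma(0.5, 2) means per gene; 20 exclusive markers per
  state, 16-fold enriched in the home state and near-silent elsewhere.
- Droplets: expected expression (1−ρ)·state + ρ·ambient, where ambient is
  the proportion-weighted mean profile of the droplet's time point;
  doublets sum two cells' draws (droplet physics) and emit alleles by fair
  coin per UMI; empty droplets draw ~5% of a cell library from ambient
  alone. All doublets are treated as genotype-mixed, matching the design
  intent of flagging mixed-SNP droplets.
- Bulk pair: deep libraries (3×10⁶, σ = 0.1), NB dispersion 0.01
  (biological CV 0.1, the convention for isogenic model-organism
  replicates — bulk replicates are far less dispersed than droplets),
  3 replicates per time × arm. 30% of genes carry temporal effects: half
  are single-time spikes (|log2| in [2.0, 2.4], chosen so the spiked
  time's contrast clears 1.5 while the induced −δ/2 contrasts at other
  times stay clear of it), half follow interval walks of ±U[1.5, 4].
  Effects are planted only on genes with baseline relative expression
  ≥ 0.1 — a response on a silent gene is unobservable at any depth.
  Protoplast samples add fixed signed log2 fold-changes (|log2FC| in
  [2, 4]) to 100 genes, identical across time points; an optional fraction
  of time-effect genes can have their temporal shifts sign-inverted in the
  protoplast arm to exercise the discordance statistic. The time-signature
  truth is derived from the realized contrasts (|time-vs-rest| > 1.5 at
  exactly one time), so it is consistent with the caller's definition
  rather than with the spiking mechanism.

Not emulated: positional SNPs or read sequences (allele observations are
per-UMI records), batch effects between replicates, cell-cycle or
continuous trajectories (states are discrete), UMI sequencing errors
beyond the allele flip. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical model, not robustness to every
artifact of real droplet chemistry.

## Numerical choices and problem sizes

IRLS: tolerance 1e-8, ≤ 50 iterations, ≤ 8 step-halvings, linear predictor
clipped to ±40. Dispersion bracket [1e-6, 10]; tagwise grid of 41
log-spaced points. kNN and Louvain tie-breaks as above. The bundled
checks run at the study's simulated scale — 5,000 droplets for
demultiplexing, 2,000 genes × 18 samples for the bulk engine, 3,000 cells
for clustering, 50 repeated 400-cell runs for the audit — which keeps the
full suite around a minute of CPU while leaving every recovery margin
wide.

## Known limitations

- Gene-level calls are not bit-identical to the originally cited R tools:
  dispersion shrinkage uses a fixed 10-df prior rather than
  quantile-adjusted empirical Bayes, signatures use plain t-tests, and
  size factors are library-size based. The statistical behaviour (FDR
  control, power, recovered sets) is what is reproduced and tested.
- The demultiplexer assumes exactly two genotypes and UMI-level input; it
  does not read alignments or VCFs.
- The discordance statistic is conservative under low power (see above).
- Louvain optimizes modularity greedily; only on the enumerable 8-node
  fixture is global optimality asserted.
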