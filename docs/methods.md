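# Methods

## Model and assumptions

`modscape` rests on two assumptions about RNA-modification maps:

1. most modifications (and many detection artifacts) are deposited in a
   characteristic sequence context, because writer enzymes and chemical
   processes interact with local sequence; and
2. the k-mers observed around real sites occupy a tiny, structured
   corner of k-mer space, so a mixture of writer-specific contexts
   appears as a mixture of dense regions once sequence similarity is
   turned into spatial proximity.

Each site contributes one window of `2*flank+1` bases centered on the
modified base in sense orientation (minus-strand windows are
reverse-complemented).  Windows are one-hot encoded over A,C,G,T
(U→T internally), embedded in 2-D with UMAP, and partitioned by
density with HDBSCAN.  Per-cluster position weight matrices then
summarise what each cluster is: `p = (counts + pseudocount) /
(n + 4*pseudocount)`.

The method is deliberately position-*sensitive*: two sequences sharing
a motif at different offsets land in different clusters.  That is a
feature (it is what makes phase detection possible) and a limitation
(inputs with many phases dilute each motif across clusters; the
sliding-window mode below is the escape hatch).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `flank` (k = 2·flank+1) | 10 (k = 21) | ±10 nt covers the footprint of known writer complexes; k is configurable over odd 11–51 |
| ambiguity policy | `drop` | windows containing N are removed rather than imputed — fractional encoding would fabricate signal |
| UMAP `n_neighbors` / `min_dist` / metric / seed | 15 / 0.1 / euclidean / 42 | the reducer's own conventions; all echoed into the run manifest |
| HDBSCAN `min_cluster_size` | 20 | smallest motif family worth reporting; raise for large maps |
| `flag_background` `z_cutoff` | 3.5 | robust-outlier cutoff (MAD z-score) for the background filter, see below |
| histogram mode `bins` / `density_quantile` / connectivity | 512 / 0.90 / 8 | approximate clustering for very large maps; bins with weight ≥ the quantile of nonzero bin weights are foreground |
| phase matching `min_center_freq` | 0.8 | a cluster is called phased only when the target base reaches 80% at some offset within ±2 |
| consensus thresholds | include 0.25 / dominant 0.8 | IUPAC degeneracy rules for consensus strings |
| winscore `width` / `min_input_rpkm` | 50 nt / 1 | windows failing the input-coverage floor are unreliable ratios and are dropped |
| sliding-window `min_total_ic` | 8 bits | a motif cluster must carry the equivalent of ≥4 fully conserved positions (see below) |

## Background filtering (denoising)

Random-background k-mers have no self-affinity: the expected one-hot
distance between a background window and *any* other window equals the
background-pair expectation, so the nearest neighbors of a background
record are motif records, and UMAP embeds a substantial fraction of
background *inside* motif clusters, where no 2-D density criterion can
remove them.  The density signal that distinguishes them survives only
in the encoded space: the mean distance to the 15 nearest encoded
neighbors is markedly larger for background records.

`flag_background` therefore computes that quantity per record and flags
records exceeding the robust z-score cutoff (median + 3.5 MAD-scaled
deviations).  Flagged records keep their coordinates but are forced to
the noise label in hard-clustering pipeline runs.  On a homogeneous
input the distance distribution has no outlier tail and nothing is
flagged; in soft (complete-assignment) mode the filter is skipped
because every record must receive a cluster.  On the standard
three-family benchmark the filter removes ~85% of planted background
with no loss of motif-bearing records.

## Phase matching

Detection chemistries whose signal is displaced from the modified base
(typically by −1..+1) split one motif into several phase-shifted
clusters.  For each cluster the PWM frequency of the target base is
examined at offsets −2..+2 from the window center; the offset with the
highest frequency ≥ `min_center_freq` is the cluster's phase (ties:
smaller |offset|, then negative).  Sites of matched clusters are
shifted by the phase in sense orientation (a minus-strand site moves
genomically by the negated offset) and re-extracted — which is
provably identical to sliding the old window.  Clusters centered on
other bases are left untouched rather than force-matched.

## Spiked analysis

K-mers of known modified positions are appended (multiplicity 1,
immutably flagged) before embedding.  After clustering, the spike
content of each cluster annotates it by modification type; clusters
without spikes and without winscore support are artifact candidates.
Spike flags never merge with genuine records during duplicate
collapsing.

## Sliding-window mode

When motif position is unknown, input sequences are tiled into short
overlapping windows (default 20 nt, step 1) which are embedded and
clustered like k-mers.  A cluster is a motif cluster when its PWM
carries ≥ `min_total_ic` bits.  The default of 8 bits is the
information of four fully conserved positions; clusters of mutually
overlapping background windows accumulate up to ~7 bits of
finite-sample IC at typical cluster sizes, so the threshold must sit
above that floor.  A sequence is called motif-positive when at least
`max(1, ceil(vote_threshold * n_windows))` of its windows fall in motif
clusters; the false-call rate is strongly threshold-dependent (on the
bundled benchmark, vote thresholds 0.1→0.3 trade a 100%→75% hit rate
against a 28%→3% false-call rate), and callers should tune
`vote_threshold` to their precision needs.  Motif-cluster PWMs are
offset-aligned (exhaustive search minimising mean symmetrized
per-position KL on ≥4 overlapping positions) and single-link grouped
into consensus families.

## winscore

Each gene's transcript-coordinate coverage (BED12 exon blocks
concatenated, minus-strand reversed) is tiled into non-overlapping
50-nt windows and scored as
`log2((MeanWinIP/MedianGeneIP)/(MeanWinControl/MedianGeneControl))`.
Gene medians are taken over all transcript positions including zeros
(configurable to covered-only); genes with a zero median in either
track are dropped with a warning instead of dividing by zero.  Window
input RPKM is computed from coverage sums with a read-length divisor
(default 50) and a library size either supplied or estimated from the
control track.  Score distributions between clusters are compared with
the two-sample two-sided Kolmogorov–Smirnov test.

## Quality metrics

*Outgroup–ingroup score*: distances of each point to its own group
centroid (ingroup) and to every other group's centroid (outgroup) are
pooled across groups; the score is CV(outgroup)/CV(ingroup) with
population SD (ddof 0).  Both conventions — pooling and ddof — are
recorded in `MetricReport.params` since either could be defined
per-group.  The score is invariant under translation, rotation and
uniform scaling.

*Boundary score*: fraction of points whose 50 nearest neighbors (self
excluded) contain more than 10% foreign labels.

*Precision/recall* use majority matching: a cluster belongs to its
plurality truth class; noise records belong to no cluster but count in
class sizes (heavy clustering noise therefore depresses recall).  The
per-class view pools clusters sharing a majority class.  *ARI* is
computed from the pair-counting contingency-table definition.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the pipeline
assumes: motif families as IUPAC patterns or PWMs planted at controlled
phases with i.i.d. background flanks, exact class counts via
largest-remainder allocation, phase-shifted site tables with a matching
genome (both strands), and Poisson IP/control coverage with planted
enrichment folds.  It does **not** emulate sequencing error,
bisulfite-conversion artifacts, transcriptome-biased base composition,
correlated flanks (RNA structure), or overlapping genes.  Passing tests
therefore demonstrate the machinery is correct under the stated mixture
model, not that any particular biological dataset will separate as
cleanly; real maps typically need per-dataset reducer and cluster
parameters.

The standard benchmark mixture is 8,000 21-mers: three families at
70/20/10% of the motif-bearing 90% (a degenerate RRACH family and two
exact 5-mer families) plus 10% uniform-random background, with six
known-m6A spike-ins.  The phase benchmark is 3,000 RRACH sites shifted
uniformly over −1/0/+1.  These sizes keep a full desk run under a
minute per stage on one CPU while leaving cluster sizes large enough
for stable PWMs.

## Numerical choices and degenerate inputs

- Rows are canonically sorted by sequence before reduction, so
  embeddings are independent of record order; coordinates are restored
  to input order afterwards.
- Cluster ids are renumbered consecutively in order of first member, so
  labels are stable under record permutation.
- Soft assignment routes each HDBSCAN noise point to the cluster of its
  nearest clustered point; the attached membership vectors are
  normalised inverse centroid distances (an approximation — the exact
  HDBSCAN membership vector is not exposed by the scikit-learn
  implementation).
- Point-in-polygon uses the even-odd ray-casting rule with boundary
  points counted inside; degeneracy means collinear vertices (a
  self-intersecting polygon can have zero signed area and is legal).
- KL divergences are symmetrized (½[KL(p‖q)+KL(q‖p)], base 2) and
  pseudocount-regularized (default 0.01); zero probabilities without a
  pseudocount raise instead of returning ±inf.
- Sites closer than `flank` to a contig edge are skipped and counted,
  never padded; the same policy applies after phase shifts.
- Ties in phase inference and PWM alignment prefer the smaller
  |offset|, then the negative one.

## Known limitations

- Cluster counts on real data are parameter-dependent; no automatic
  hyperparameter search (e.g. DBCV-guided) is included.
- The background filter assumes background is a minority without
  sequence preference; structured artifacts (poly-A tracts, repeats)
  form their own clusters and must be recognised downstream (spikes,
  winscore, inspection).
- Only the UMAP+HDBSCAN combination is bundled; the reducer and
  clusterer contracts are pluggable but no alternative backends beyond
  PCA (for fast deterministic tests) are shipped.
- Soft membership vectors are approximate (see above).
- ≥3-D projections are accepted by the reducer contract but untested
  surface; all downstream geometry uses the first two dimensions.
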