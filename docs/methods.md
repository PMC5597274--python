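# Methods

## The problem

Coating cardiovascular implants with collagen type IV (Col IV) accelerates
re-endothelialization, but full-length ECM proteins are impractical to
manufacture.  An alternative is a short peptide that selectively *recruits*
Col IV from blood — binding it more strongly than ubiquitous off-target
proteins such as collagen type I (Col I) and serum albumin (Alb).
Tripeptides are attractive because they are cheap to synthesize at scale and
cannot fold into confounding secondary structure, but the full tripeptide
space (20³ = 8000 sequences) exceeds what a cellulose-membrane SPOT
microarray can hold.  `pepfocus` implements the clustering-assisted focused
screening strategy for this problem: cluster the complete sequence space by
physicochemical similarity, screen only a diversity-covering subset, and
analyse the screen at the cluster level so that a selective *cluster* —
not just isolated hits — can be identified.

## Library design

Every tripeptide is encoded as a 39-dimensional vector: 13 amino-acid
indices (isoelectric point, van der Waals volume, secondary-structure
propensities, stability contributions, hydropathy, turn frequency,
helix/strand free energies, polarity, side-chain interaction, residue
abundance; accessions in `docs/provenance.md`) evaluated at each of the
three positions, N-terminus first.  Features are labelled `{p}A-{i}`
(position p, index i), position-major, so exported heat maps read in the
conventional orientation.

The 8000 × 39 matrix is clustered by average-linkage (UPGMA) agglomeration
and the dendrogram is cut into K = 50 flat clusters by removing the 49
highest merges.  Ten representatives are then drawn uniformly without
replacement from each cluster with a seeded generator, giving the
500-peptide focused library, joined on each array by the 20 homotrimers
(AAA … YYY) as internal controls.

### Distance metric and scaling — an open design point

The clustering tool originally used for this design reports a tree, not a
metric, and the literature leaves both the distance and any feature
standardization unstated.  Both are therefore configuration options
(`metric`: `euclidean`, `pearson`, `uncentered_pearson`;
`scale_features`: on/off).  The package default is **Euclidean distance on
raw (unscaled) features**, chosen after sweeping all six metric × scaling
combinations against the two design constraints the screen itself fixes:

* the 50-cluster cut must give every cluster ≥ 10 members, so that
  10 representatives per cluster total exactly 500 — with z-scaled
  Euclidean features the cut produces a singleton cluster (491
  representatives); raw-feature Euclidean yields minimum cluster size 12;
* the cluster containing the reported Col IV-selective peptides should be a
  small cluster, ~2% of the library — under the default it holds WNY and
  WAY with 120/8000 = 1.5% (rounds to 2%); under z-scaled Euclidean the
  WNY cluster holds 5.45%.

Raw-feature clustering also matches the original tool's behaviour of
operating directly on the supplied values.  The trade-off is that
large-magnitude indices (e.g. stability in kJ/mol) dominate raw Euclidean
distances; users probing alternative readings can flip `scale_features`.

### Clustering implementation

UPGMA is implemented in the package (not delegated) because the flat
partition depends on the exact merge order, which requires a pinned
tie-break rule: ties merge the lexicographically smallest
(older-id, newer-id) pair, with ids assigned in creation order.  The
tripeptide lattice makes exact distance ties *common* (hundreds of tied
pairs per step), so this rule is load-bearing, not cosmetic.  The
implementation keeps a full symmetric distance matrix with cached
nearest-neighbour values, compacts the matrix geometrically as clusters
die, and runs the complete 8000-leaf clustering in a few seconds.  It is
validated merge-for-merge against an O(n³) brute-force rescan oracle (tie
rule included) and against an independent library implementation for merge
heights on tie-free data.  Cluster numbering (1..K by smallest leaf index)
is internal to this artifact; cluster labels from other software or reports
cannot be assumed to correspond, which is why selective clusters are always
identified by *content* (membership), never by label.

## Synthetic screen

No spot-level scan data is publicly available for this assay, so the screen
is emulated by an explicit generative model (module `array_sim`), which is
first-class, tested code:

* **Layout** — 3 arrays × triplicate spots of the 520 peptides
  (500 library + 20 controls), 1560 spots per array, positions independently
  permuted per array (seeded).  Every library peptide yields 9 replicate
  spots.
* **Latent affinities** — each peptide q has a base log-affinity
  base(q) ~ N(0, σ_base²) shared across channels plus channel-specific
  noise η(q,c) ~ N(0, σ_channel²); the shared component is what produces
  the strong between-channel cluster correlations seen in real screens.
  One feature-space cluster is *planted* as selective:
  μ(q, ColIV) = base + δ_target and μ(q, ColI) = μ(q, Alb) =
  base − δ_offtarget, exactly.
* **Observation** — log I = b_c + μ(q,c) + a(array,c) + ε(spot), with
  per-array offsets a ~ N(0, σ_array²) and spot noise ε ~ N(0, σ_spot²);
  intensities are exp of this (log-normal: positive and heteroskedastic,
  as fluorescence data are).

Defaults (log-intensity units): σ_base = 0.5, σ_channel = 0.1,
σ_array = 0.1, σ_spot = 0.2, δ_target = δ_offtarget = 1.0, baseline
b_c = 6.0 for all channels.  The effect size of 1.0 log-units (~2.7-fold)
represents a clearly selective binder over ~22% spot-level noise; σ_array
models modest membrane-to-membrane variation removed downstream by
normalization.  Planting at cluster level (the whole feature-space cluster
shifts, not individual peptides) makes recovery a joint test of clustering
and analysis: the screen succeeds only if physicochemical clustering really
concentrates the selective phenotype.

What the generator does **not** model: carry-over between sequential
hybridizations of the three proteins on the same membranes, fluorophore
labelling-efficiency differences, scanner saturation, spatial gradients
within a membrane, and spot-segmentation artefacts.  Passing recovery tests
therefore demonstrates that the analysis chain is correct and well-powered
under the stated noise model — not that the model captures every failure
mode of a physical screen.

## Selectivity analysis

1. Replicate spots are pooled per (peptide, channel) across arrays
   (n = 9 by default) and summarized by mean and SD.
2. Peptide means are z-scored *within each channel* over library peptides
   (mean 0, SD 1); controls are transformed with the library parameters but
   excluded from them.  A per-array normalization variant is available by
   configuration; the default pools first because replicate pooling
   precedes normalization in the only explicit description of the original
   procedure.
3. Cluster box-plot summaries: median, quartiles, SD and mean of member
   representatives' normalized means per channel, plus an "All" row.
4. Leave-one-out correlation diagnostic: Pearson r between two channels
   over the 50 cluster means, recomputed with each cluster excluded.  A
   selective cluster is the point whose removal *raises* r — it is the
   exception to the shared binding trend.
5. Per-peptide calls: two-sample equal-variance Student t (df = n₁+n₂−2) of
   the target channel's normalized replicates against each non-target
   channel (replicates normalized with their channel's library
   parameters; pooled n = 9 per channel rather than array-averaged n = 3,
   matching the replicate count the screen reports per peptide).  A peptide
   is *selective* iff its target mean exceeds both non-target means and
   both p-values are below α = 0.01.  P-values are deliberately
   uncorrected, mirroring screening practice of raw p < 0.01 at this stage;
   Benjamini–Hochberg is available but off by default.
6. Cluster ranking: clusters are ordered by the *sum of ranks* of two
   signals — the median-intensity margin (target median minus the larger
   non-target median) and the mean LOO correlation gain across both channel
   pairs.  Rank-sum combination was chosen over a weighted sum because the
   two signals live on incommensurate scales (normalized intensity units
   vs. correlation deltas); ties resolve toward the larger margin.  With a
   single cluster the LOO component is undefined and the margin alone
   decides.

Degenerate cases are pinned down: identical replicate samples give t = 0,
p = 1; zero pooled variance with unequal means reports p = 0 with a
warning; constant rows are rejected by correlation distances with the
offending peptide named; undersized clusters contribute all their members
as representatives with a logged warning.

## Recovery experiments

`run_recovery` repeats design → simulate → analyse over a seed list
(clustering computed once; representative choice, planted-cluster choice,
affinities, layout and noise re-randomized per seed) and reports the
fraction of seeds in which the planted cluster ranks first, plus
peptide-level sensitivity/specificity of the selectivity calls against the
planted truth.  Under default conditions the planted cluster is recovered
in ≥ 95 of 100 seeds with both LOO correlations rising on its exclusion in
every successful run; `power_curve` shows recovery is monotone in effect
size, saturating at δ ≥ 2.0 and collapsing to chance at δ = 0.

One calibration subtlety: the planted invariant μ(ColI) = μ(Alb) holds
*exactly*, so even at δ = 0 the "planted" cluster lacks channel noise and
is marginally less likely than 1/K to top the ranking.  The null
calibration check is therefore stated as the binomial confidence interval
of the observed null rate covering 1/K, which it does.

Problem sizes used by the shipped experiments: the full 8000-peptide
clustering for all design quantities; 100 seeds for the default and null
recovery experiments; 40 seeds per point on the five-point effect grid
{0, 0.25, 0.5, 1.0, 2.0}.

## Cluster profiling

For any cluster the package reports the members × 39 scaled-feature heat
map, per-feature mean/SD profiles, residue composition (percentages over
all 3 × members positions, summing to 100, with optional residue groups
such as {R,K} or {F,Y,W}), and pairwise profile comparisons ranked by
standardized mean difference with a per-position aggregate that highlights
which sequence position discriminates two clusters most.  Composition is
reported as raw frequencies only; grouped interpretive summaries are left
to the user because grouped percentages are ambiguous without a stated
denominator.

## Known limitations

* The default metric/scaling choice reproduces the design's structural
  constraints, but no configuration makes all four reported selective
  peptides co-cluster; the selective cluster is identified by its modal
  content (2–3 of the four, always including WNY or WRF).
* Latent affinities are independent of the feature vectors except through
  the planted shift; real physicochemistry presumably couples them, which
  would make clustering *more* informative, so recovery estimates here are
  conservative in that one respect while the unmodelled assay artefacts cut
  the other way.
* The t-test treats the 9 replicates as independent; the shared per-array
  offsets induce mild within-array correlation (ignored, as in the
  original analysis).
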