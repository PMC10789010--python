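# Methods

`nuptscan` detects and characterizes nuclear plastid DNA sequences
(NUPTs): stretches of a nuclear genome derived from, and still alignable
to, the chloroplast genome. This note records the models and procedures
the package implements, the parameters that matter, what the synthetic
data generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Detection

NUPTs are operationally defined as high-scoring local alignments (HSPs)
between the plastid genome (query) and the nuclear assembly (subject).
Each surviving HSP is one NUPT; adjacent HSPs are never merged, so counts
and occupied-bp totals follow the alignment-level convention (overlapping
nuclear hits double-count; this matches how whole-genome plastid fractions
are usually reported from summed alignment lengths).

The built-in aligner is a desk-scale seed-and-extend search:

- exact-word seeding (default word size 9) of both query orientations;
- word seeds collapsed into maximal exact runs per diagonal; a diagonal
  becomes a candidate when it carries two runs within a 40-bp window
  (two-hit rule) or one exact run of >= 14 bp; nearby diagonals
  (|shift| <= 20, subject gap <= 150 bp) are chained into one candidate
  so small indels do not split alignments;
- the core between the outermost seeds is aligned exactly; when query and
  subject cores have equal length and the edit distance certifies the
  ungapped reading optimal, a columnwise comparison is used, otherwise an
  edit-distance alignment path (edlib) provides the match/mismatch/gap
  accounting;
- ends are extended by ungapped X-drop (X = 40, scores +1/-2) alternating
  with a small banded affine-gap DP (window 64, band 8, gaps 5 + 2g) that
  lets the extension hop across end-proximal indels;
- hits are rescored with +1 match / -2 mismatch / 5+2g gaps; e-values use
  the ungapped Karlin-Altschul formula with lambda solved exactly for the
  scoring scheme at uniform base composition (for +1/-2,
  lambda = ln((3+sqrt(21))/2) ~ 1.3328) and the published K = 0.621. The
  search space is query length x summed subject length. Agreement with
  NCBI BLASTN statistics is deliberately not promised; users can feed real
  BLAST 12-column tabular output instead, which is parsed and normalized
  to the same internal representation (0-based half-open intervals,
  forward-strand coordinates plus a strand flag).

In tests the aligner is checked against a full Smith-Waterman oracle
(Biopython's PairwiseAligner with identical scoring): on planted-fragment
pairs the reported identity agrees within 1 point and all endpoints within
5 bp.

Low-complexity filtering uses the classic DUST triplet statistic: per
64-bp window, sum c_t (c_t - 1)/2 over overlapping trinucleotide counts,
divided by (window - 3); windows scoring > 2.0 merge into maximal masked
regions. Hits whose query interval is >= 50% masked are dropped, as are
alignments shorter than 30 bp (the shortest credible NUPTs reported in
real data are ~33 bp). Only the query (plastid) side is masked, the same
side a `-dust`-style option masks.

## Inverted-repeat redundancy

Plastid genomes are quadripartite (LSC - IRA - SSC - IRB) with IRB the
reverse complement of IRA, so one nuclear integrant whose donor lies in
the IR yields two hits — one per IR copy — at the same nuclear locus.
`find_inverted_repeats` locates the longest exact inverted-repeat pair by
seeding shared 24-mers between the sequence and its reverse complement,
grouping seeds by anti-diagonal (the invariant of the pairing
x <-> C - x) and extending exactly; extension stops at the first mismatch
on each side independently, so IRs that differ by internal SNPs are
recovered as their largest exact block and a user-supplied annotation file
overrides detection when needed.

Duplicates are identified by projecting IRB donor coordinates onto IRA via
the mirror transform (an involution) and grouping hits that share a
nuclear interval-equivalence class (reciprocal overlap >= 0.9) and a
mirrored donor start (+/- 50 bp). One copy per group is retained — the
IRA-side one, ties broken by lower nuclear start — a deterministic,
documented choice where either copy would be defensible. Genome fractions
are reported both raw and deduplicated; the deduplicated fraction can
never exceed the raw one.

## Episodic-age model

Under a molecular clock, percent identity to the extant plastid genome is
a relative-age proxy: the lower the identity, the older the integrant.
Discrete bursts of plastid-to-nucleus transfer appear as components of a
univariate Gaussian mixture over identity values.

`GaussianMixture1D` is a sklearn-style estimator fitting the mixture by
EM with responsibilities computed in log space, a variance floor
(default sd >= 1e-3) preventing collapse onto duplicated values (ties at
100% identity are common), and a restart strategy: means initialized at
the quantiles (2i-1)/(2k) plus jittered variants, 20 starts by default.
Starts are first scouted for 150 iterations, then the best is polished to
convergence (|delta loglik| < 1e-10 or 2000 iterations). The
log-likelihood trace is retained and checked non-decreasing. The EM inner
loop is a compiled (numba) kernel shared by every code path. An
independent cross-check against scikit-learn's GaussianMixture on the
same data is part of the test suite; the implementation never delegates
to it.

The number of components is chosen by a sequential parametric-bootstrap
likelihood-ratio test of k vs k+1 (default k_max = 9, alpha = 0.01):
simulate B datasets from the fitted k-component model, refit both models
on each, and compare the observed statistic 2(ll_{k+1} - ll_k), clipped
at zero, against the bootstrap distribution with
p = (1 + #{boot >= obs}) / (B + 1) (never exactly zero). Bootstrap refits
are warm-started — the k-fit at the generating parameters, the (k+1)-fit
at a split of the dominant component — with lighter controls (200
iterations, tol 1e-6). This matters: under-optimized (k+1) refits shrink
the bootstrap null and inflate significance, spuriously favouring extra
components. The warm-started null was calibrated against fully-optimized
reference refits (3 cold restarts, 1000 iterations, tol 1e-8) on both
null-shaped and mixture-shaped data and reproduces the same decisions;
extra starts changed replicate log-likelihoods by < 0.03, negligible on
the statistic's scale. A significance level >= 1 never splits (k = 1), the
degenerate reading of "stop when p >= alpha".

NUPTs are assigned to an episode when their maximum posterior reaches
0.95, else labelled unassigned; for k = 2 the lower-mean component is
episode I (older) and the higher episode II (younger). All controls
(k_max, B, alpha, threshold, EM controls) are configurable; the pipeline
default B = 200 keeps desk-scale runs fast, while the CLI default
(B = 1000) matches common practice for final analyses.

## Spatial statistics

- Clusters: two or more non-overlapping NUPTs on one chromosome whose
  consecutive end-to-start gaps are < 5 kb (strictly; a gap of exactly
  5000 breaks the chain). A record overlapping the previous chain member
  closes that chain and starts its own. The implementation is validated
  against an exhaustive chain oracle on random instances.
- Collinearity of a cluster with its plastid donor order is quantified by
  Kendall's tau between nuclear rank order and donor-start rank order;
  |tau| = 1 means perfectly collinear in either orientation. Donor starts
  are the stored forward-strand plastid coordinates for members of either
  strand; since |tau| is orientation-invariant, an inverted but
  order-preserving cluster scores -1 and still counts as collinear by
  magnitude (the "collinear" label uses |tau| >= 0.8, configurable).
- Size-vs-identity and cluster-identity-vs-size correlations use
  tie-corrected Kendall/Spearman statistics (scipy); cluster correlations
  run separately on episode-pure clusters and return an undefined sentinel
  below 3 clusters.
- Density tracks tile each sequence with fixed windows (defaults 500 kb
  nuclear, 100 bp plastid-donor) and count any-overlap, so window sums can
  exceed record counts. Donor peaks are windows above mean + 3 sd of the
  per-episode track (peaks are a feature of the older episode's donor
  distribution); adjacent hot windows merge, and each peak reports the
  records whose donor midpoint falls inside.
- Flanking GC: per NUPT, the GC% of its concatenated 100-bp flanks,
  excluding positions inside any NUPT interval and N bases; the
  background is the GC% of every 100-bp window tiling the genome free of
  NUPT intervals and their flanks (deterministic tiling rather than
  random sampling avoids resampling variance). Two-sided Mann-Whitney U
  tests (asymptotic, tie-corrected) compare each episode's flank values
  with the background.

## Synthetic data generator

The generator builds the study conditions every stage is scored against:

- a quadripartite plastid (default 20 kb with 2-kb IRs; LSC:SSC = 4:1)
  carrying two A/T-only decoy regions of 200 and 350 bp packed near the
  LSC start — these emulate the low-complexity regions that produce
  spurious alignments in real searches;
- a nuclear genome of i.i.d. background at GC 0.357 (default 4 x 2.5 Mb);
- 1000 planted insertions from two episodes: episode I (identity
  N(79.05, 3^2), log-normal sizes with median 127 bp, sigma 1.37,
  n = 200) and episode II (identity N(93.1, 2^2), median 778 bp,
  sigma 1.50, n = 800). Identity dispersions (3 and 2) are a package
  choice keeping the components separable yet overlapping enough to
  produce an unassigned class. Size laws are calibrated so the medians
  match the published per-episode medians; means (326/2384 bp) follow
  from the log-normal shape. Sizes are truncated to [33 bp, longest clean
  donor region];
- fragments are mutated per-site (substitution probability
  1 - identity/100, uniform over the three alternatives, so realized
  identity is unbiased) with rare indels (5e-4 per bp, geometric lengths
  capped at 3), then written over background slices on a random strand,
  so truth coordinates equal final assembly coordinates;
- donors avoid decoys and are snapped wholly inside or outside an IR
  copy, which makes the planted IR-duplicate count an exact oracle for
  the redundancy stage; decoy "hits" are planted separately as
  near-identical copies of the decoy regions, labelled as such;
- 20% of insertions are placed in episode-pure chains with gaps uniform
  on [0, 4999] bp (the cluster ground truth); two nuclear hotspots
  receive geometrically-many extra young-episode insertions; two 200-bp
  donor windows in the LSC act as donor hotspots for 2 x 45 old-episode
  insertions (~45% of episode I, matching the published share);
  an optional fragmentation mode splits a configurable fraction of
  insertions into 2-4 collinear pieces — an extrapolation used to
  exercise collinearity, since no generative model of post-insertion
  decay is established;
- insertion sites carry an episode-specific GC halo (episode I 0.364,
  episode II 0.323 over 150 bp, against the 0.357 background), matching
  the direction and magnitude of the published flanking-GC contrast.

A 2-Mb genome cannot hold 1000 insertions under these size laws within
the generator's own packing bound (planted bp < 20% of the genome), so
the default end-to-end genome is 10 Mb; all rates and laws above are
otherwise the study conditions. Everything derives from one seed; equal
seeds give byte-identical FASTA/TSV outputs.

What the generator does **not** emulate: repeat landscapes and
transposable elements, context-dependent mutation (e.g. CpG), assembly
errors, post-insertion rearrangements beyond the optional fragmentation
mode, and GC heterogeneity beyond the planted halos. Passing recovery
tests therefore demonstrate correctness of the pipeline's logic under
clean, known conditions — not robustness to every property of real
assemblies.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; 1-based inclusive BLAST
  coordinates are converted at the I/O boundary (minus-strand subjects
  encoded by reversed coordinates). A 1-bp minus-strand subject interval
  is unrepresentable in the tabular dialect and reads back as plus.
- EM raises on fewer than 5k observations or zero-variance input;
  correlations return NaN sentinels on constant input; donor-peak
  detection returns no peaks on a flat track (sd = 0); flank analysis
  raises when no NUPT-free background window exists.
- The non-overlap packing bound (planted bp < 20% of nuclear bp) and
  bounded placement retries turn pathological configurations into clear
  errors advising longer chromosomes.
- Reported problem sizes: end-to-end runs use the 10-Mb default genome;
  bootstrap selection uses B = 200 replicates; the mixture-recovery
  checks use n = 4631 samples, and bootstrap calibration 40 null runs at
  n = 1000.

## Known limitations

- E-values are ungapped-regime approximations with a fixed K; they rank
  hits correctly and gate obvious noise but are not NCBI-exact.
- The aligner is designed for desk-scale genomes (tens of Mb); it holds
  per-chromosome k-mer arrays in memory and is not a general-purpose
  replacement for BLAST on large assemblies.
- Only query-side low-complexity masking is performed; artifacts arising
  purely from nuclear-side low complexity would require subject masking.
- IR detection is exact-match based; highly diverged IR copies should be
  supplied via an annotation file.
- With k other than 2 the episode labels are generic component names;
  the biological episode-I/II interpretation is specific to the
  two-component case.
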