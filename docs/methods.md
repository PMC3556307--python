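# Methods

## Problem and model

The package identifies ultraconserved elements (UCEs): genomic segments
100% identical between two species above a length threshold. Because exact
identity across distant taxa is the signal, the method is gap-free and
alignment-free at the discovery stage — it is a maximal-exact-match (MEM)
enumeration problem, not an alignment problem. Everything downstream
(merging, clustering, enrichment, motifs) characterizes the discovered
elements; the phylogeny stage situates the species being compared.

## Masking

Exact matching is catastrophically confounded by repeats: a shared
microsatellite is identical between any two genomes. Genomes are therefore
hard-masked (bases → `N`; `N` matches nothing, including `N`) before
discovery, and discovered elements are re-scanned afterwards.

* **Tandem detector** — exact arrays only: an interval is reported when a
  unit of period ≤ `max_period` repeats ≥ `min_copies` times (last copy may
  be partial) over ≥ `min_span` bp, maximal per period, with intervals
  contained in longer reported intervals dropped. Defaults
  `max_period=6, min_copies=4, min_span=24` catch microsatellites and
  homopolymers while leaving random sequence untouched.
* **Low-complexity detector** — union of 64 bp windows whose mononucleotide
  Shannon entropy is < 1.5 bits, merged. Random DNA sits near 2 bits, so
  false masking of background is rare; homopolymers (0 bits) and two-letter
  alternations (1 bit) are caught.
* Exactness is a deliberate trade: approximate/homology-based repeat
  detection (TRF with mismatches, Repbase libraries) is out of scope, and
  users needing that sensitivity can stack an external BED mask.
* **Second round** — each discovered match is re-scanned by both detectors
  on its own sequence, trimmed to its longest unmasked run, and dropped if
  the run falls below the length threshold. Trimming (rather than wholesale
  discarding) retains elements that merely border a repeat.

## MEM discovery

A generalized suffix array is built over `a | b | revcomp(b)` with a unique
integer symbol at every scaffold separator and every non-ACGT base, so
matches can neither span scaffolds nor touch masked bases. The array is
built by numpy prefix doubling (O(n log n) sort rounds), the LCP array by
Kasai's algorithm. Every pair of suffixes — one from `a`, one from
`b`/`revcomp(b)` — with pairwise LCP ≥ L and differing preceding symbols is
exactly one MEM, reported with `maxmatch` semantics (joint maximality,
non-unique occurrences included). Enumeration scans maximal runs of the
suffix array with consecutive LCP ≥ L; on masked genomes these runs are
short, making enumeration output-bound. An unmasked high-copy repeat makes
its run quadratic — which is precisely why masking precedes discovery.
Minus-strand records carry the forward-strand interval of `b` whose reverse
complement equals the `a` substring. For a genome compared against itself,
trivial identity/palindromic self-matches at identical coordinates are
suppressed.

The ≥50 bp and ≥30 bp thresholds are run as separate tracks and never
pooled.

## UCR merging

Per species, intervals from all pairwise comparisons are merged by
connected components of the overlap relation (overlap = sharing ≥1 base;
book-ended intervals stay separate). The result is a fixpoint — idempotent,
order-invariant, base-conserving — carrying the union of partner species
and up to 50 bp flanks, truncated (not discarded) at scaffold ends.
Retaining truncated-flank elements maximizes the set entering clustering.

## Clustering and embedding

* **Similarity** — Smith–Waterman local alignment (match +2, mismatch −3,
  gap cost 5 + 2·length — the classic blastn scheme) with Karlin–Altschul
  statistics (λ = 0.625, K = 0.41): bit = (λ·raw − ln K)/ln 2,
  E = m·n·2^(−bit). Each pair is aligned forward–forward and
  forward–revcomp and the better strand kept, so reverse-complement
  element families cluster together. The edge weight is the *score
  density* (bits per alignment column); edge existence is gated at
  E ≤ 1e−5. The gate is a design choice — density alone has no natural
  zero — and is configurable.
* **MCL** — expansion (matrix squaring) alternated with inflation
  (entrywise power 2.0, column renormalization) on a column-stochastic
  matrix with self-loops set to each node's maximum incident weight;
  entries < 1e−5 pruned per iteration; convergence when the maximum entry
  change < 1e−6 (cap 200 iterations, warning on non-convergence). Clusters
  are the connected components of the converged nonzero structure; nodes
  attracted to several systems go to the lowest-indexed cluster. These
  mirror the canonical MCL defaults.
* **MCE** — 5-mer frequency vectors (forward strand, windows containing
  non-ACGT skipped, normalized) are compared by Euclidean distance; the
  distance matrix is replaced by geodesic distances along its minimum
  spanning tree (the minimum curvilinear kernel) and decomposed by SVD
  *without centering*; coordinates are the top-d left singular vectors
  scaled by √singular values. Euclidean distance on normalized frequencies
  is the simplest metric consistent with the feature choice; a
  correlation-based kernel would be a reasonable alternative.

## Domain enrichment

Genes whose interval lies within 100 kb (interval gap, inclusive at the
boundary; overlap = distance 0) of any member UCR form the "nearby" set; the
pool is every gene of every species represented in the cluster. The
upper-tail hypergeometric probability uses gene-level domain counts: a gene
carrying a domain multiple times counts once, keeping D ≤ G and the urn
model coherent. Clusters with fewer than 10 nearby genes are skipped. Raw
p-values are primary (display filter p < 0.05 and d ≥ 3);
Benjamini–Hochberg values are an extra column. The tail probabilities are
computed with scipy's hypergeometric survival function and validated in the
tests against exhaustive draw enumeration.

## Motif overrepresentation

The cluster representative is a center-star consensus: the member with the
highest summed pairwise local-alignment score is the center, others are
globally aligned to it, and each center column takes the majority symbol
(gap-majority columns dropped, base ties alphabetical; insertions relative
to the center are not represented). The background is exactly 10 kb of
100 bp segments sampled uniformly from unmasked sequence, each species
contributing in proportion to its share of the cluster (largest-remainder
rounding makes the quotas sum exactly). Every 8-mer occurring in the
representative is scored with the upper-tail binomial F(x|n,p) with
n = L − 8 + 1 overlapping-window trials and p estimated from background
counts with add-one smoothing, p = (c+1)/(N−k+2) — a finite 10 kb
background undersamples the 65,536 possible 8-mers, and an unsmoothed zero
count would make the statistic degenerate. Counting is forward-strand, per
the single-sequence trial model. The report threshold is p < 1e−4.

## Phylogeny

Families are concatenated into a supermatrix (one tree for the species
set, the standard choice when per-gene trees are not the object). Pairwise
distances are maximum-likelihood under the JTT model — published
exchangeabilities and equilibrium frequencies, rate-normalized so distances
are substitutions/site — with uniform rates across sites, pairwise gap
deletion, and bounded 1-D optimization on [0, 10] (saturated pairs return
t_max with a warning). Trees are Saitou–Nei neighbor-joining with
Q-criterion ties broken by lowest taxon-index pair; negative branch-length
estimates are clamped to zero with the excess moved to the sibling.
Bootstrap support resamples supermatrix columns with replacement
(implemented as site-pattern weights, so each replicate costs one weighted
count pass per pair) and reports the percentage of replicates containing
each internal bipartition of the full-data tree.

## Synthetic data: what it does and does not emulate

The generator writes i.i.d. background with a single GC parameter — no
higher-order Markov structure — so k-mer statistics stay analytically
checkable. Elements are written over the background (coordinates fixed),
substitutions are the only mutation type (discovery is gap-free, so indels
would only obscure the truth model), and tandem repeats are perfect arrays.
By default the planter writes distinct boundary bases around each copy
(strand-aware, in the element's frame): without this, each boundary base
matches by chance with probability 1/4 and the maximal match would
routinely overrun the planted coordinates, making "exact-coordinate
recovery" untestable. One global seed fans out to per-stage streams by a
named sub-seed scheme (CRC32 of the stage name), so any stage reproduces in
isolation.

Consequently, passing tests demonstrate algorithmic correctness on a
realistic signal/noise geometry, not robustness to real-genome artifacts:
assembly gaps, repeat families with internal divergence, GC isochores, gene
structure, or indel evolution are all absent by design.

## Problem sizes and numerical choices

The benchmark study is three 1 Mb genomes (4 × 250 kb scaffolds), 50 exact
elements of 50–300 bp over mixed strands and species subsets, and 20
tandem arrays per species — large enough that chance 50 bp identities are
essentially impossible (expected count ≈ n²·4^−50 ≪ 1) while the whole
discovery run stays under a minute. Clustering validation uses two planted
families of eight ≈3%-divergent copies with independent 50 bp flanks;
phylogeny validation uses 6-taxon trees with internal branches (0.07–0.3
subst/site) long enough for decisive bootstrap. The test suite runs
bootstrap at 100 replicates; the analysis driver and acceptance script use
the full 500.

Floating-point notes: alignment scores with the default integer-valued
parameters are exact in double precision, so DP traceback can compare
scores with equality; MCL convergence is measured as max-entry change;
the JTT eigendecomposition symmetrizes π^½Qπ^−½ against roundoff before
`eigh`.

## Known limitations

* MEM enumeration is worst-case quadratic inside a single ≥L-repeat run of
  the suffix array; acceptable only because masking precedes discovery.
* The Smith–Waterman stage is exact DP over all pairs — O(n²·m²) per
  clustering run — appropriate at thousands of UCRs, not millions.
* Karlin–Altschul parameters are fixed constants, not estimated from the
  scoring scheme and composition.
* The center-star consensus does not represent insertions relative to the
  center and is order-stable only through its tie-break rules.
* No GO enrichment, no TF-name assignment for 8-mers, no ortholog
  detection: domain tables, motif join keys, and pre-computed single-copy
  families are the interfaces to those external resources.
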