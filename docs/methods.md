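# Methods

`foxotarget` implements the three computational analyses used to
characterize a list of FOXO/DAF-16 direct-target genes in *C. elegans*:
gene-set overlap enrichment against a fixed genome universe, IUPAC
consensus-motif scanning of 1 kb promoter windows, and topology profiling of
an undirected protein-interaction network. A synthetic-data module generates
seeded stand-ins for every input with recorded ground truth, so the whole
pipeline is exercised without downloads.

## Overlap enrichment (hypergeometric model)

Two gene sets of sizes *m* and *n*, drawn independently from an *N*-gene
universe, share *k* genes. Under the null, the overlap count *X* is
hypergeometric, and the enrichment p-value is the upper tail

    P(X >= k) = sum_{i=k}^{min(m,n)} C(m,i) C(N-m, n-i) / C(N,n)
              = 1 - sum_{i=0}^{k-1} ...

with expectation *mn/N* (the "random chance" baseline reported next to every
observed overlap).

Numerical choices:

- Binomial coefficients are evaluated through `log Γ` (scipy's `gammaln`);
  no floating-point factorials. At *N* = 20000 the largest terms overflow
  `float64` by hundreds of orders of magnitude in linear space.
- The tail is summed directly over `i = k .. min(m, n)` via log-sum-exp
  rather than as `1 − Σ_{i<k}`: for the tiny tails typical of these
  comparisons the direct sum keeps full relative precision, while the
  complement form loses everything to cancellation. The two forms agree to
  1e-12 wherever both are well-conditioned (tested).
- `P(X >= 0)` is exactly 1.0; results are clamped to [0, 1]; a feasible
  observed overlap always yields a strictly positive p-value. Upstream
  reports that print "p = 0" should be read as "below reporting precision";
  this package always emits the computed tail (e.g. 3.4e-10 rather than 0).
- *N* defaults to 20000, the conventional approximation for the number of
  protein-coding genes in the *C. elegans* genome; it is a parameter
  everywhere.

Exclusions: when one comparison list contributed members to the target list
itself, those genes are removed from **both** sets before sizing (the
109-target list shrinks to 95 when 14 of its members came from the study
being compared against). `compute_overlap(..., exclude=...)` generalizes
this as a flag rather than a one-off adjustment.

Identifier handling is whitespace-trim plus case-fold only. No alias or
ortholog resolution is attempted — mapping between species identifiers is a
curation task, not a computation this package can do from a gene list.

## Two-sample Kolmogorov–Smirnov test

`ks_two_sample` computes the exact statistic
D = sup_x |F̂₁(x) − F̂₂(x)| by evaluating both one-sided ECDF limits at every
pooled data point (ties therefore handled exactly), and the two-sided
p-value from the asymptotic Kolmogorov distribution

    Q(λ) = 2 Σ_{j≥1} (−1)^{j−1} exp(−2 j² λ²),   λ = sqrt(n₁n₂/(n₁+n₂)) · D

with the series truncated once terms fall below 1e-12. The exact
small-sample permutation distribution is not used (a permutation oracle
cross-checks the asymptotic p in the tests). Identical samples return
D = 0, p = 1.

Calibration: with two continuous samples of 50 the asymptotic test rejects
at the nominal 5% level about 4.3% of the time (2,000-replicate check in the
acceptance suite). On heavily tied integer data — network degrees — the KS
test is *conservative*: the attainable values of D are coarse and the
continuous null distribution overstates them, so the null rejection rate
drops to roughly 1.5–2.5% for groups of ~150 and essentially 0% for groups
of ~60. This is a property of applying KS to discrete features, not of the
implementation; significant p-values on degree comparisons are if anything
understated.

## Promoter motif scanning

Motifs are fixed-width words over the 15-letter IUPAC alphabet. The scanner
slides every motif over every window position of the supplied promoter
(encoded as 4-bit base masks, so a window matches iff the bitwise AND is
non-zero at every offset — vectorized with numpy), reports all matches
including overlapping and self-overlapping ones, and is a pure function of
(sequence, motif list).

Conventions, chosen where the field has no single standard:

- **Coordinates.** A hit's `start` is the 1-based offset of its first base
  from the 5' end of the supplied window. For a window that ends at the TSS,
  `upstream_distance(start, L, w) = L − start − w + 2` converts to
  "distance upstream of the TSS" for readers who prefer that convention.
- **Strand.** The scan is forward-strand only; reverse-orientation sites are
  found by listing both orientation words explicitly, which is how the
  default motif sets are written: DBE = {GTAAACA, TGTTTAC},
  DAE = {TGATAAG, CTTATCA}, degenerate DBE = {RTAAAYA, TRTTTAY}
  (R = A/G, Y = C/T). For these palindrome-paired sets a separate
  reverse-complement pass would double-count.
- **Unknown bases.** A sequence `N` matches no IUPAC code, including
  consensus `N` — masked regions can never produce hits.
- Both orientations are listed for the degenerate DBE so that loose mode is
  a strict superset of strict mode gene-wise, matching its purpose of
  asking "how many more genes qualify under a looser definition".

Classification is per gene: DBE-positive iff any DBE-set motif hits the
promoter, DAE-positive likewise; the four categories
(DBE_only / DAE_only / both / neither) partition the gene set.

FASTA input goes through Biopython's `SeqIO`; records are upper-cased, `U`
mapped to `T`, non-1 kb records kept with a logged warning, duplicate ids
rejected.

## Network topology

The interaction network is an undirected simple graph (networkx `Graph`
underneath): self-loops dropped, duplicate and reversed-duplicate edges
collapsed, counts logged. An optional third edge-list column (interaction
type: physical / genetic / predicted) is accepted and ignored — all measures
are type-blind.

Per-node measures:

- **Degree** K_i: number of distinct interaction partners.
- **Coreness**: largest K such that the node survives K-core peeling
  (recursively removing all nodes of degree < K until every remaining node
  has degree ≥ K). Implemented as iterative peeling with a recomputed-degree
  work queue; the result is independent of removal order (tested over 100
  shuffled input orders, and against networkx's `core_number` and a
  per-K brute-force oracle).
- **Target-neighbor ratio**: |neighbors ∩ targets| / K_i, the fraction of a
  node's partners that are themselves targets — high values among targets
  mean the targets interact with each other. Undefined for isolated nodes
  (flagged `None`/NaN and excluded from group means).

`compare_groups` summarizes three groups — all network nodes, targets in the
network, and optionally targets ∩ subgroup — and attaches to the target
summary a per-feature KS comparison of targets vs all other network nodes.
Group means cover only members present in the network; absent targets are
counted and logged, never imputed. If the targets are the whole network the
KS comparison is skipped with a logged notice.

## Synthetic data

The generators emulate the study's inputs with planted, machine-checkable
structure. All randomness flows from an explicit integer seed through
`numpy.random.default_rng`; identical parameters give byte-identical files.
Each dataset carries a ground-truth JSON sidecar sufficient to verify every
downstream claim without regeneration.

- **Overlap pairs**: an *N*-identifier universe, an *m*-set and an *n*-set
  with exactly *k* shared members. Defaults mirror the study's comparison
  sizes (e.g. 681 vs 109 with k = 17 in N = 20000).
- **Promoters**: i.i.d. nucleotide backgrounds at a configurable GC fraction
  (default 0.5, the uniform composition under which the closed-form
  background hit rate (L−w+1)·4^(−w) holds), with concrete motif words
  planted at stated offsets. The background is redrawn until it contains no
  accidental occurrence of any spiked word *or its reverse complement* —
  the scanners search both orientation words, so exactness must cover both —
  making planted counts exact by construction. Real promoters are not
  i.i.d. (they have composition bias, repeats and shared regulatory
  elements), so passing tests certify the scanner, not genomic hit-rate
  estimates.
- **Planted-hub networks**: Chung–Lu expected-degree sampling. Every node
  gets weight equal to its expected degree (background mean, times a
  multiplier for targets); pair {i, j} is an edge with probability
  w_i w_j / Σw, and target–target odds are further scaled by a within-target
  bias. This makes the planted degree ratio analytically controllable;
  it does not reproduce the heavy-tailed degree distribution or clustering
  of real interactomes, so recovery results speak to the measures and
  tests, not to any particular biological network.

## Problem sizes used in the validation suite

The acceptance checks run the enumeration oracle over every parameter tuple
with N ≤ 14, 100 random graphs of ≤ 50 nodes for the k-core oracle, 1,000
spiked plus 1,000 motif-free 1 kb promoters for scanner recovery and
background rate, 2,000 KS null replicates at n = 50, and 50 seeded
600-node/60-target planted-hub networks (multiplier 3, bias 2) for
signal recovery. The generator null-calibration check uses 1,500-node /
150-target networks over 200 seeds, the size at which the tie-conservatism
of KS on degrees still leaves a measurable rejection rate (see above).

## Known limitations

- The real study inputs (WormBase v220 promoter sequences, the authors'
  7,219-node interaction network, curated longevity gene lists) are not
  publicly deposited; network-dependent figures (group means such as
  17.77 vs 11.85, motif-positive gene counts) are therefore reproduced in
  *pattern* on planted synthetic data, not in value. The printed-parameter
  overlap statistics are reproduced exactly.
- The KS p-value is asymptotic; for very small samples (< ~10 per group) a
  permutation test would be preferable.
- Motif scanning covers only the supplied window; elements outside it are
  invisible by design. Position weight matrices and motif discovery are out
  of scope.
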