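# Methods

Models, assumptions and parameter choices for each `gigasm` module. Defaults
quoted here are the library defaults; every one of them is an explicit
keyword argument and can be overridden per call.

## Simulators (`fixtures`)

All simulation is driven by a single `SimConfig` dataclass and a seeded
`numpy` generator, so every fixture is reproducible from `(config, seed)`
alone and ships with ground-truth tables (repeat copy coordinates, contig
origins, misjoin offsets, Hi-C pair provenance).

- **Genome.** Uniform i.i.d. background sequence; repeat families are a
  random consensus of the configured length, with each inserted copy
  mutated by substitution at the family divergence rate. Insertions extend
  the chromosome (no background is overwritten), keeping bp arithmetic
  exact.
- **Reads.** Lengths are normal (mean/sd configurable, truncated at a
  minimum); positions uniform; strands uniform. Errors are
  **substitution-only** — no indels — so read coordinates map linearly to
  genome coordinates and per-base truth tracks stay exact. This is the one
  deliberate simplification of the read model; the downstream annotation
  logic only consumes alignment intervals, so indel realism adds nothing to
  what the pipeline can be tested on.
- **Contigs.** A chromosome tiling broken at uniform positions subject to a
  minimum segment length; misjoins are planted by concatenating segments
  from different chromosomes, recording the junction offset.
- **Hi-C pairs.** Cis separations follow a power-law decay with
  configurable exponent; a configurable fraction of pairs is uniform trans
  background. Pair endpoints are emitted in upper-triangular order.

## Read-level repeat annotation (`repeatreads`)

Exhaustive all-vs-all comparison of reads is quadratic and infeasible at
giant-genome scale, so annotation is sample-based:

1. **Sample** every N-th read (deterministic, order-stable) — default
   `sample_fraction` chosen per dataset.
2. **Depth threshold.** Align all reads to the sample; a sampled-read base
   is repetitive when its alignment depth is **strictly greater than
   4 × expected coverage**, where expected coverage is
   (total read bp × sample fraction) / genome size. The factor 4 separates
   the unique-coverage mode from multi-copy pileups while tolerating
   coverage fluctuations; the strict inequality makes the boundary
   testable.
3. **Transitive transfer.** Repeat intervals on sampled reads are lifted
   through read-vs-read alignments onto all overlapping reads
   (strand-aware, clipped to the alignment span). Transfer is single-hop:
   sample → neighbor, which equals the brute-force closure whenever the
   sample itself covers every repeat copy.

Intervals shorter than `min_len` (default 50 bp) are discarded; adjacent
intervals are merged.

## Hi-C contact maps and misjoin detection (`hicmap`)

- **Binning** is fixed-width per contig; coordinates are 1-based inclusive;
  a same-bin pair increments its diagonal cell once. The default bin size
  is genome/2000 clamped to [1 kb, 1 Mb].
- **Balancing** is vanilla coverage (VC): divide by row and column sums.
  Zero-coverage bins are left untouched rather than producing NaNs.
- **Misjoin scan.** For each candidate boundary bin, sum contacts crossing
  it within a window (default 5 bins each side), excluding a **guard of 1
  bin** around the boundary so that the short-range diagonal — which is
  always strong — does not mask a junction. The score is the crossing sum
  divided by the contig's median crossing sum; a boundary is called when
  the score falls below `threshold` (default 0.25) **and** the depletion is
  Poisson-significant (`P(X <= crossing | mean = median) < 1e-5`), which
  suppresses calls on sparse contigs where a low count is expected by
  chance. Calls localize to within ±2 bins of the true junction: a
  zero-contact junction produces a flat score plateau and the first bin of
  the plateau is reported.
- **Breaking** splits sequences at called positions, names pieces
  `<parent>.<i>`, and returns an offset mapping so pairs can be lifted onto
  the broken layout.

## Scaffolding (`scaffolder`)

Agglomerative, seeded clustering on normalized inter-contig linkage
(contacts / product of contig bin counts), followed by per-cluster ordering
and orientation.

- **Seeding** picks one contig per target chromosome by **bottleneck
  linkage**: the strength of the weakest edge on the best path between two
  contigs (computed via the maximum spanning tree). Direct linkage alone
  mis-seeds when two large contigs from the same chromosome happen to share
  few direct contacts; the bottleneck path through intervening contigs is
  robust to that.
- **Assignment** joins a contig to a seed cluster when its linkage to that
  cluster is at least `ratio` (default 3.0) times its linkage to any other
  and exceeds `min_linkage` (default: 5th percentile of nonzero linkages);
  ambiguous contigs stay unassigned rather than contaminating a cluster.
- **Eviction** re-tests each member leave-one-out against its own cluster
  versus the alternatives and evicts misfits.
- **Merge/split.** Clusters are merged when their inter-cluster linkage
  exceeds `merge_ratio` (0.5) of the weaker intra-cluster linkage, and a
  cluster is split at the best prefix of its Fiedler-vector (spectral)
  ordering when the cut linkage falls below `split_ratio` (0.1). The
  assign → evict → merge/split loop runs to a state fixpoint.
- **Ordering/orientation** maximizes adjacent end-to-end contact: contact
  between the last `end_window` bins (default 5) of one contig and the
  first of the next. Small clusters are solved exhaustively over signed
  permutations; larger ones use the spectral order refined by local moves.
  The final layout is canonicalized (lexicographically smaller of the two
  reversals) so output is deterministic to the byte. Note that a contig
  with no more bins than `end_window` has identical head and tail windows,
  making its orientation arbitrary.
- **Output.** AGP 2.1 with 100-bp `N` gaps, gap type `scaffold`, evidence
  `proximity_ligation`, linkage `yes`; FASTA with reverse-complemented
  minus-strand components; N50 defined as the largest L such that pieces of
  length ≥ L sum to at least half the total.

## Genome size (`genomesize`)

- **c-value conversion** at 978 Mb per pg.
- **k-mer spectrum.** Size = total k-mers / homozygous-peak depth. The
  error trough is the first rise of the histogram; the peak is located by a
  5-bin smoothed mode and then refined as the **count-weighted centroid**
  over ±12 bins around the mode, which is far less quantized than the raw
  argmax. Histograms are canonical-k-mer based (strand-invariant). A
  monotone-decreasing spectrum (no peak) raises rather than returning a
  garbage estimate.
- **Alignment fraction**: assembly size / fraction of read bp absorbed.
- **Brownian-motion ancestral states.** The BM model on a tree makes the
  ancestral-state ML problem a generalized least squares / graph Laplacian
  linear system: internal states solve `L_II x = -L_IT t`. σ² is the REML
  estimate from the phylogenetically independent contrasts; standard
  errors come from `σ² · (L_II)⁻¹`. Branch lengths must be positive and
  every tip must have a value. `branch_rates` reports (child − parent) /
  branch length in Mb per Myr. `simulate_bm` exists to check calibration:
  over replicated simulations the root estimate is unbiased and the
  nominal 95% interval covers at the stated rate.

## Repeat landscapes (`replandscape`)

- **K2P.** Kimura two-parameter distance
  `K = -½ ln((1−2p−q)√(1−2q))` from transition (p) and transversion (q)
  proportions; domain-checked (K(0,0) = 0, monotone in p, undefined when
  `1−2p−q ≤ 0`).
- **80/80 rule.** A copy is kept when alignment length ≥ 80 bp **and**
  identity ≥ 80% — both boundaries inclusive.
- **Landscape table.** Masked bp binned by integer percent divergence;
  binning conserves total masked bp exactly (divergences above the last
  bin overflow into it, with a warning).
- **Composition PCA** centers genome × TE-class fraction vectors and
  projects onto principal axes with a deterministic sign convention.
- **TE expression** is normalized reads per kb of element per million
  mapped reads.

## Synteny (`synteny`)

Each (scaffold, linkage-group) cell of the marker contingency table is
collapsed to a 2×2 table and tested one-sided for enrichment. The
implementation uses the identity that the one-sided Fisher exact p-value
**is** the hypergeometric upper tail,
`P(X ≥ a)` with `X ~ Hypergeom(n, a+c, a+b)`, which vectorizes over all
cells at once; equality with explicit enumeration is verified in the test
suite over every 2×2 table with grand total ≤ 30 (max abs difference
~3 × 10⁻¹⁶). Optional Benjamini–Hochberg adjustment; cells in all-zero
rows/columns get NaN p and are never significant. The balanced diagonal
`[[5,0],[0,5]]` gives the textbook p = 1/252. Dotplot coordinates rank
markers by (scaffold, position) against linkage-group index.

## Validation problem sizes

The acceptance tests (and `scripts/acceptance.py`) exercise, among others:
repeat recovery on a 500-kb genome with a 300-bp × 50-copy family at 10×;
transfer-vs-brute-force equality on ≤ 200 reads; misjoin scanning on 20
contigs with 5 planted joins; scaffolding of 3 chromosomes cut into 60
contigs from 50,000 pairs (ARI = 1, |Kendall τ| ≥ 0.9, byte-identical AGP
across reruns); K2P against a 50-digit-precision oracle; BM root bias and
interval coverage over 200 replicates of 50-tip trees; and k-mer sizing of
a 100-kb repeat-free genome at 20× to within 5%. The full suite runs in
about one minute on a single CPU.
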