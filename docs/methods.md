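# Methods

This note documents the models, parameter choices and numerical conventions
behind each stage, what the synthetic-data generators do and do not emulate,
and the known limitations.

## RNA secondary structure

**Model.** Pseudoknot-free secondary structures are scored by an additive
nearest-neighbor loop model at 37 °C: stacking energies for all 36 ordered
pairs of the six admissible base pairs (AU, UA, GC, CG, GU, UG); hairpin,
bulge and internal-loop initiation tables indexed by unpaired length with
Jacobson–Stockmayer log extrapolation (1.75·RT·ln(n/n_max)) beyond the
tabulated range; an affine multiloop term a + b·(branches+1) + c·unpaired
with a = 3.4, b = 0.4, c = 0.4 kcal/mol; and a terminal penalty of
0.5 kcal/mol charged once per AU/GU pair side not continued by a direct
stack. Watson–Crick stack values follow the published nearest-neighbor
measurements to two decimals; wobble-involving stacks use representative
weaker values (two tandem-wobble motifs are destabilizing). The tables ship
as a versioned JSON data file (`data/nn_energies.json`) and are configuration,
not constants. The minimum hairpin loop is 3 nt; lone pairs are allowed; the
empty structure has energy 0, so the reported MFE is never positive.

The defining scorer is `structure_energy`, a loop decomposition of an
arbitrary nested pair set. The dynamic program (`fold_mfe`) computes the
minimum of exactly that function, which is what the test suite asserts
against an independent brute-force enumerator.

**Suboptimal enumeration.** All structures within an energy window of the MFE
are enumerated by an energy-bounded backtrack over an unambiguous grammar
(external / paired / multiloop-interior matrices, multiloop segments
decomposed by their first branch), so each structure is produced exactly once
and the enumeration is complete within the window. An exhaustive enumerate-
then-filter approach was rejected because GC-rich 22-mers have structure
spaces far larger than their within-window subsets. The default window is 5%
of |MFE| with a floor of 1.0 kcal/mol, echoing the percent-type suboptimality
ceiling of classic MFE servers; it is configurable everywhere. Ties in the
sorted structure list break lexicographically by dot-bracket. The dot plot is
the pair-frequency matrix over retained structures.

**Problem sizes.** Oracle-equivalence tests run exhaustively over all 21,844
sequences of length ≤ 7 (base-pairing first becomes possible at length 5) and
over seeded random samples at lengths 8–16; suboptimal-window properties use
100 random 22-mers. These sizes keep the brute-force reference itself exact
while exercising every loop type.

## CpG islands

Statistics follow the standard sliding-window definition: window 200 bp,
step 1 bp; GC% = 100·(#C+#G)/N; Obs/Exp = #CpG·N/(#C·#G) with N the window
length. CpG dimers are counted with overlap (every position i with
`seq[i:i+2] == "CG"`); only dimers fully inside the window count. A window
with no C or no G has Obs/Exp defined as 0 rather than NaN so summaries stay
total (such a window can never qualify anyway). Windows containing N are
emitted with a `skipped` flag and excluded from island calling and from
min/max summaries.

Islands are maximal merged ranges of qualifying windows (GC% > 50 and
Obs/Exp > 0.6, both strict), where windows merge if their 200-bp spans
overlap or touch — a single failing window between two overlapping passing
windows does not split an island. Every island therefore spans at least one
window length, satisfying the >200 bp characteristic by construction.
Reports round to 2 decimals; full precision is kept internally.

## Triplex search

The microRNA is treated as a triplex-forming oligonucleotide binding an
ungapped, full-length register on the purine-rich strand of duplex DNA
(20–22 nt microRNAs; no bulged triplexes). Both the given promoter strand and
its complement are tested as the purine strand, in both orientations;
coordinates are always reported on the given strand. Canonical triplets are
U·A:T, C·G:C, G·G:C, A·A:T (parallel / Hoogsteen / "direct") and A·A:T,
U·A:T, G·G:C (antiparallel / reverse Hoogsteen / "indirect"); the protonated
C·G:C triplet is admitted without pH modeling.

**Scoring.** Published per-triplet tables for this class of scan are not
available, so the package defines its own: weight +8 per canonical and −8
per non-canonical triplet; energy −8 canonical, +4 non-canonical. These were
calibrated once against the retention thresholds the analysis uses
(hit score > 140 and hit energy < −140, strict, jointly applied): a perfect
22-mer register scores 176 / −176 and passes, and any register with three or
more non-canonical triplets fails both thresholds. The tables and thresholds
are configuration. Hits are sorted by score descending.

**Grading.** The null model is the best-register score of seeded
dinucleotide-preserving shuffles (Altschul–Erikson Eulerian-walk shuffle) of
the third strand against the same duplex, default 1,000 samples. The
empirical percentile of a hit is the fraction of null scores at or below it;
grades are 5/4/3/2 at the 99th/95th/90th/75th percentiles, else 1. Only the
top anchor (grade 5 = 99th percentile) is externally fixed; the lower
cutpoints extend it on conventional percentile breaks.

## Event networks

Somatic events arrive as a TSV export (gene, stage, variant type, optional
antecedent-of link); live database queries are out of scope. The stage
vocabulary is fixed to six labels (early, late, relapse, metastatic,
drug-induced, drug-resistance) and the variant vocabulary to six types
(mutation, methylation, LOH, CNV-loss, CNV-gain, alteration); unknown tokens
are errors, not silently kept. Duplicate gene rows merge by set union.
Temporal queries use breadth-first shortest paths with lexicographic
neighbor order for determinism. Interaction-network composition is the
percentage of total edge weight per interaction kind (weights default to 1),
summing to 100 within 1e-9.

The published composition percentages for this kind of network do not quite
sum to 100 (43.83 + 26.28 + 14.23 + 10.14 + 3.89 + 2.62 = 100.99); the demo
edge list uses a consistent renormalized weight set (predicted = 1.63%) and
the discrepancy is documented here rather than resolved.

## Synthetic data

The generators are pure functions of (seed, params) and return planted truth
alongside each artifact.

* **Hairpin RNAs** (20–22 nt, matching mature microRNA lengths): a planted
  stem around a 3–5 nt A/U loop with random flanks. Default stems are G/C so
  the planted helix dominates; flanks are A/U-biased (80%) so competing
  helices are rare — the recovery contract (the MFE structure contains at
  least stem−1 planted pairs) holds across seeds with GC stems. A `c_free`
  mode builds the whole molecule over {A, U, G} (A·U and wobble G·U stems)
  so the RNA can also serve as a reverse-Hoogsteen third strand; such stems
  are weak, which is physically faithful and gives the shallow landscapes
  with several near-optimal folds that the demo uses.
* **CpG promoters** (600 bp): the island block is assembled from shuffled
  tokens (planted CG dimers plus single bases) with a short calibration loop
  so realized GC lands within 5 points and Obs/Exp within ~5% of the
  request. The background is a first-order chain with the C→G transition
  damped to a target Obs/Exp (default 0.3) — an i.i.d. background at any GC
  fraction has Obs/Exp ≈ 1 and would defeat the planting; real vertebrate
  bulk DNA is likewise CpG-depleted.
* **Triplex promoters**: each requested site is planted as the exact
  given-strand purine tract forming an all-canonical register with the third
  strand in the requested orientation, on a GC-poor pyrimidine-biased
  background. A repair pass then guarantees specificity by construction:
  every non-planted (register, orientation, strand) combination is checked
  with an independent canonical-triplet counter and background bases are
  mutated until none reaches L−2 canonical triplets (the minimum that could
  pass the thresholds). Third strands whose planted tract itself induces a
  passing register in another combination — e.g. poly-U, whose A-tract is
  canonical in both orientations, or any C-free strand whose purine-class
  string is palindromic — are rejected as orientation-ambiguous rather than
  silently planted. Antiparallel sites require C-free third strands because
  no canonical reverse-Hoogsteen triplet exists for C.
* **Event tables / edge lists** encode the CRC facts the stage queries are
  expected to surface (APC early-stage with the APC→TP53→TCF7L2 chain; GNAS
  metastatic; KRAS early/late/drug-resistance with CASP8→KRAS→PIK3CA; EGFR
  drug-induced/drug-resistance) plus seeded filler genes in a reserved
  namespace that never collides with the seven target genes, and edges
  covering all six interaction kinds.

What the generators do **not** emulate: real promoter base composition beyond
GC/CpG targets, chromatin or methylation state, transcript-isoform choice for
the TSS, bulged or mismatched triplexes, and genome-scale background
complexity. Passing recovery tests therefore demonstrates correctness of the
statistics and scans, not sensitivity/specificity on real genomes.

## Pipeline determinism

Stage order is fold → CpG → triplex → events; stages are independently
runnable since they share no intermediate state beyond promoter sequences.
Every report directory carries per-stage logs with the package version, a
SHA-256 hash of the canonical config, the seed, stage parameters and input
checksums — and no timestamps, so identical configs reproduce byte-identical
reports. In the pipeline, shuffled grading backgrounds are computed only for
(microRNA, promoter) pairs that have retained hits, which keeps full runs in
seconds at the default background size of 1,000.

## Promoter conventions

Coordinates are 0-based half-open internally; BED is native and GFF3 start
coordinates are converted on read. The TSS is the first transcribed base and
is excluded from the upstream window: plus-strand promoters are
`[tss−600, tss)`, minus-strand promoters the reverse complement of
`[tss+1, tss+601)`. A window truncated by a contig edge is returned shorter
with a logged warning; a window entirely off-contig is an error. N bases are
tolerated in promoters but any CpG window or triplex register containing N
is skipped. When a gene has multiple transcripts the annotation row is taken
as given.

## Known limitations

* The folding energy tables are representative, not a complete published
  parameter set (no dangles, terminal mismatches, or special small-loop
  tables); predicted ΔG values are internally consistent but not comparable
  to tabulated server outputs digit-for-digit.
* Triplex scoring is a per-triplet additive heuristic; it models neither
  pH-dependent C·G:C protonation nor triplex thermodynamics.
* The enumeration-based suboptimal folder targets short RNAs (≲ 60 nt);
  structure counts grow quickly with window width on longer inputs.
* Event networks are only as complete as the supplied table; no inference is
  performed beyond path queries on the stated links.
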