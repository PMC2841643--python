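# Methods

`metaprof` re-creates, as a tested pipeline over synthetic data, the standard
desk analyses applied to low-diversity chemotrophic (e.g. geothermal spring)
shotgun metagenomes: similarity-based taxonomic binning with fragment
recruitment, alignment-free compositional clustering, candidate gene
extraction, pathway-level functional scoring, and a curated marker-gene
screen. This note documents the models, the parameters that matter, and the
design choices made where the procedures admit more than one reading.

## Synthetic communities

Real data for these analyses are Sanger-style shotgun reads from communities
dominated by a small number of relatively homogeneous populations. The
generator emulates exactly the features those analyses exploit and nothing
more:

* **Genomes** are drawn from a GC setpoint (i.i.d. bases) or an order-k
  Markov chain over A/C/G/T (default k = 3). Distinct GC setpoints give
  genomes separable oligonucleotide signatures, which is the property the
  composition analysis keys on.
* **References at controlled divergence** come from a substitution-only
  mutation model: each site flips with probability *d* to a uniformly chosen
  other base. With no indels, expected pairwise identity is exactly 1 − *d*,
  which keeps the identity-band and binning oracles analytic. Indels,
  rearrangements and horizontal transfer are deliberately out of scope.
* **Reads** are mated pairs from opposite ends of ~2 kb inserts, mean
  trimmed length 800 bp (SD 60), with i.i.d. substitution errors. The error
  rate default (0.005/base) is a free parameter of the simulator — chosen as
  a plausible trimmed-Sanger figure, not taken from any measurement — so the
  identity of a read against its own diverged reference is
  ≈ (1 − d)(1 − 0.005).
* **Contigs** are error-free genome slices with a spread of lengths; they
  stand in for assembler output. Chimeric contigs are not modelled, so
  composition-PCA results here bound what clean assemblies can do, not what
  misassemblies do.
* **Planted pathway studies** generate a pathway database (shared-reaction
  pool plus exact duplicate variants), plant per-sample reaction content,
  and emit per-sample protein hit tables: every encoded reaction gets
  1 + Poisson(1) unique query translations with signal bit scores from a
  normal(120, 30) truncated above 55 (so signal always clears the bit-50
  floor by construction); noise consists of decoy hits appended to signal
  queries (exercising the 20 %-of-top window) and stand-alone spurious
  queries with bit scores from normal(35, 10), mostly below the floor.
  Per sample, 40 spurious queries is the default. Each sample also gets a
  noise-free `ref_<sample>` column with identical planted content — the
  analogue of a sequenced reference genome whose pathway complement matches
  the community — used by the clustering checks.
* **Marker studies** plant known marker copies plus three documented decoy
  classes (same-family different member, homolog with a different function,
  short fragments).

Every generator is deterministic given its seed; the pipeline fans one
global seed out to per-stage `numpy.random.SeedSequence` children so stages
can be re-run in isolation.

Because the simulator omits indels, chimeras, realistic Sanger error
profiles and uneven strain mixtures, passing tests demonstrate the
correctness of the computations and their behaviour under controlled signal
and noise — not performance on field data.

### Fixture aligner

Hit tables are normally an input (12-column tabular format). When a fixture
needs one, a small semi-global aligner built on `edlib` aligns each read
against each reference on both strands, converts the extended CIGAR into
matches/mismatches/gaps, scores match +1, mismatch/gap −2, and maps scores
to bit scores with the classic ungapped nucleotide-search parameters
(λ = 1.28, K = 0.46), E = |q|·|DB|·2^(−bit). It ranks and thresholds hits
correctly on fixtures; it is not a general search tool.

## Taxonomic binning and recruitment

A read is assigned to the subject of its best hit (highest bit score) among
hits with E-value strictly below 10⁻¹⁰; ties break by lower E-value, then
lexicographic subject id, so assignments are reproducible. Reads whose hits
all fail the threshold are Unassigned. Identity bands are half-open
`[e_k, e_{k+1})` with the top band closed at 100; default edges
47/50/60/70/80/90/95/100 span the conventional 47–100 % reporting range
(band boundaries are configurable since published figures rarely print
theirs). Coverage is defined as Σ alignment length / reference length —
alignment columns including gaps; no published consensus formula exists, so
the definition is stated here and used consistently. Community summary
tables report fractions over all reads *and* over assigned reads, since
published percentages are ambiguous about the denominator.

## Composition PCA

Profiles count every overlapping word of lengths 1..L (default L = 5, 1364
features), skipping windows containing N, normalized within each word
length so different lengths contribute comparably. Words are counted on the
given strand by default; an optional reverse-complement-collapsed mode pools
each word with its complement. Features are centred and scaled to unit
variance before PCA (raw frequencies differ by orders of magnitude between
word lengths); a covariance-mode flag (`standardize=False`) exists because
either convention is defensible. PCA uses a full deterministic SVD and each
component's sign is fixed by making its largest-magnitude loading positive,
giving order-invariant, reproducible coordinates. Separation of labelled
contig sets is quantified by silhouette and by adjusted Rand index against
k-means at k = number of classes.

## Gene candidates and dereplication

Candidate ORFs are maximal stop-free codon runs in all six frames
(bacterial/archaeal code, table 11), reported when ≥ 30 aa (a repo default;
no published cutoff exists for this step) and flagged partial when they
run into a read edge without a delimiting stop — start codons are not
required, since fragments routinely truncate genes. A start-requiring mode
is available behind a flag. Note the flags follow the run-on definition
strictly: a candidate at the 5′ read edge is partial even if it happens to
begin with ATG. Downstream consensus gene prediction with external tools is
intentionally not reproduced; candidates flow directly to scoring.

Dereplication is a greedy longest-first incremental clusterer: each
sequence joins the first earlier representative with global (end-to-end)
identity ≥ the threshold (matches / alignment columns, via edlib), else
founds a cluster. This reproduces the CD-HIT idea, not its engineering; a
shared-k-mer prescreen (applied only at thresholds ≥ 0.9, where it cannot
change results in practice) keeps it desk-scale.

## Pathway scoring

The scoring chain and its two equations:

* **Filtered hit list** (per query translation): retain hits with bit score
  **strictly** above 50 and ≥ 0.8 × the top score. Boundary semantics
  (strict floor, inclusive window) are a documented choice; published
  descriptions don't print them. Proteins associated with reactions only
  through partial EC numbers are suppressed whenever any fully-associated
  protein clears the floor; the window's top score is computed over the
  surviving candidate set (this ordering is the only one under which a
  strong partial-EC hit cannot silently empty the list).
* **Reaction hit counts**: a reaction's count in a sample is the number of
  distinct query translations whose filtered list touches it — three
  proteins of one reaction hit by one query still count once.
* **Specificity weight**: w_i = (n_totrxn,i / n_unirxn,i) / n_pw,i, where
  n_pw,i counts pathways containing reaction i, n_totrxn,i their total
  reaction count with multiplicity, and n_unirxn,i their unique reactions.
  A reaction private to one pathway has w = 1. For a reaction whose
  containing pathways are identical copies, n_totrxn/n_unirxn = n_pw and
  w stays 1 at any copy number — duplicate pathway *variants* carry no
  penalty — while sharing across genuinely different pathways discounts the
  reaction (two otherwise-disjoint 5-reaction pathways: w = (10/9)/2 ≈ 0.56).
  One caveat the test suite makes explicit: duplicating a single pathway
  *can* move the weights of reactions it shares with pathways of different
  size; no function of these three counts can be invariant under arbitrary
  single-pathway duplication (the duplicated pathway's size is not
  recoverable from them). The invariances that are theorems — and tested —
  are: weights outside the duplicated pathway never move; reactions private
  to identical copies keep w = 1; duplicating the entire database changes
  nothing.
* **Completeness**: C_j = Σ_{i∈R_j} w_i·I_i / Σ_{i∈R_j} w_i with I_i = 1
  when reaction i has ≥ 1 hit. C_j ∈ [0, 1], equals 1 iff all reactions are
  present, and is monotone in the indicators. Both formulas live behind
  single functions so an alternative algebra is a one-line change.
* **Activity**: the median unique-hit count over *all* reactions of the
  pathway, zero-count reactions included (the even case takes the mean of
  the central pair). Reading "reactions in a given pathway" as the full
  reaction set is a documented choice; excluding zero-count reactions would
  inflate sparse pathways.
* **Key-pathway selection**: pathways with < 5 reactions are dropped
  (completeness mode only by default — whether the size filter applied to
  activity analyses is unstated, so it is a flag), samples are observations
  and pathways variables, and a pathway's contribution is the
  variance-weighted sum of squared loadings on the top three components
  ("contribution" admits several formalizations; this one reduces to
  variance explained attributable to the pathway). The top 15 are kept,
  then near-duplicates (reaction sets differing by ≤ 1 element) collapse to
  the higher-contribution member — an automated version of a curation step
  usually done by hand.
* **Two-way clustering**: average linkage; Euclidean distance for
  completeness matrices, Pearson correlation distance (1 − r) on
  log(1 + x)-transformed values for activity matrices. A zero-variance row
  under the Pearson metric gets the maximal distance 2 to everything and is
  logged.

## Marker screen

Candidates are environmental sequences hitting a registry query at
E < 10⁻¹⁰ (one candidate per sequence × gene symbol, best E-value). Each is
validated against its best reverse annotation, modelled as a supplied
table — the pipeline never calls an external search service. The rejection
rules operationalize judgments that are usually made by eye, so each is a
label comparison that gets logged for audit: (i) the reverse label is a
different member of the query's protein family; (ii) its function differs
from the query's process (e.g. a generic Mo-pterin oxidoreductase hit by a
specific sulfur-reductase query); (iii) the label is on a configurable
mis-annotation blacklist (shipped empty — no published enumeration exists).
Candidates covering less than 30 % of the query length (a repo default; the
concern is documented in the field but unquantified) are rejected as too
short to assign. Count tables report distinct confirmed sequences per
process × sample with a complete zero-filled frame.

## Problem sizes and numerics

The shipped study scales: four 40-kb genomes (GC 0.30/0.45/0.60/0.70),
references at 5 % divergence, 2,000 read pairs per community, 200 contigs
above 1.5 kb, 50-pathway databases over five samples plus five matched
reference-genome columns, and five-sample marker plants. These sizes make
every stage's truth recovery measurable in minutes on one core while
keeping the statistics stable (binomial SE on binning accuracy at n = 4000
is ≈ 0.3 %). All tolerance-bearing comparisons in the tests use either
exact equality (closed-form fixtures: coverage 3.2×, noise-free recovery)
or bounds derived from binomial/permutation reasoning stated alongside the
test. Frequencies are summed in float64; within-length frequency sums are
checked to 1e-9. Division-by-zero corners (empty pathways, zero-variance
PCA features, flat Pearson rows) are either rejected with messages or
handled by the documented conventions above.

## Known limitations

* The fixture aligner's E-values are calibrated only loosely; they rank
  correctly but should not be compared with values from a real search tool.
* The greedy clusterer is quadratic in cluster count; it is meant for
  thousands of translations, not millions.
* Marker rules ii/iii are only as good as the supplied reverse annotations
  and blacklist; on real data these encode expert judgment.
* Published headline figures from field studies of this kind (site-specific
  marker counts, community percentages, per-genome coverages) depend on the
  original reads and era-specific reference databases and are not
  reproduced here; the pipeline instead proves its operations on planted
  truth.
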