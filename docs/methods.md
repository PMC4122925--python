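# Methods

This note documents the models, conventions and numerical choices behind
`archpan`, in the order the pipeline runs. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Gene finding and validation

ORFs are defined stop-to-stop in all six frames, with the first downstream
start codon (ATG/GTG/TTG) opening the CDS and the stop codon included in the
coordinates; frames truncated at the insert boundary are kept without a
terminal stop. Translation uses the bacterial/archaeal/plastid code
(table 11); ambiguous bases translate to X. Coordinates are 0-based
half-open on the forward strand in memory and convert to 1-based inclusive
in the GFF-like feature table, which keeps the block/synteny index
arithmetic off-by-one-free while staying interoperable. The default minimum
is 30 aa.

Validation accepts a candidate when its best database hit has
*e* ≤ 1e−10 (inclusive), or *e* ≤ 1e−5 when the only evidence is a
motif/profile source; hitless candidates shorter than 100 aa are dropped as
small orphans, and candidates overlapping structural-RNA annotations are
removed. Structural-RNA detection is delegated to an input annotation track
rather than predicted: covariance-model tRNA/rRNA search is external to the
method's substance. With no hit table, all candidates pass flagged as
provisional. The matching step between an ORF scan and an independent
gene-finder is not algorithmically specifiable from its description, so a
single deterministic ORF convention stands in for the consensus.

## Composition profiles

k-mer z-scores compare the observed count of word `w = n1..nk` with its
expectation under the maximal-order Markov null fitted to the same sequence:
`E = N(n1..nk−1)·N(n2..nk)/N(n2..nk−1)`,
`V = E·(N(core)−N(prefix))·(N(core)−N(suffix))/N(core)²`,
`z = (obs − E)/√V`. Counting is strand-symmetric: words are counted on the
sequence and on its reverse complement and summed (equivalently, the
"doubled sequence" without artificial junction words), because a fosmid's
cloning orientation is arbitrary. Words with `N(core) = 0` or `V ≤ 0` carry
z = 0 and a flag. Both k = 4 (default reporting) and k = 5 are supported by
the same formula. For k = 2 the core is the empty word and the null reduces
to mononucleotide composition.

PCA is run on the covariance of centered profiles (correlation available via
`scale=True`; which of the two the original display used is not
recoverable, covariance is the default). Component signs are fixed so the
largest-magnitude loading is positive, making embeddings deterministic.

QT clustering of per-fosmid taxon-percentage profiles follows the
quality-threshold definition literally: repeatedly extract the largest
subset whose maximum pairwise Euclidean distance is at most the diameter
(default 30 percentage points), ties broken by lowest realized diameter and
then smallest member id. The largest such subset is a maximum clique of the
threshold graph, so the implementation enumerates cliques exactly rather
than using the seed-growth heuristic; the cost is exponential in the worst
case but negligible at per-library fosmid counts, and the exact semantics is
what the brute-force subset oracle in the tests checks.

## Ortholog clusters and pangenome classes

Clusters are connected components of the gene graph with edges for hit
pairs passing *e* ≤ 1e−5, identity ≥ 30% and coverage ≥ 70% of the shorter
gene (single-linkage semantics; the published description leaves the exact
thresholds implicit, so these standard values are declared as defaults and
exposed as configuration). Cluster ids are ordered by smallest member id,
making the operation permutation-invariant.

Classes: *archaeal core* requires presence in every reference genome of both
lineage panels; *lineage-specific core* requires presence in all, or all but
`allow_missing`, same-lineage references — `allow_missing` defaults to 1 for
a panel of three or more genomes (tolerating a single-lineage loss) and 0
for a single composite reference; everything else, families with only 1–3
database homologs, and families with homologs only outside Archaea fall to
*shell*; a singleton with no homologs at all is an *orphan*. The presence
rule takes precedence over the 1–3-hit rule, so a family present in two of
three same-lineage references is lineage core regardless of its database
hit count.

HGT percentages use total OG clusters **plus orphan genes** as the
denominator — the only arithmetic under which the published count matrices
reproduce their reported total percentages (601/2514 and 1431/4820).
Rounding is half-up to one decimal and happens only at the report layer.
Under this arithmetic the thaumarchaeal late fraction is 12.4%, not the
12.6% printed alongside the source matrix; the package reports the
matrix-derived 12.4 and documents the discrepancy rather than matching it.

Genome equivalents are the arithmetic mean, over designated single-copy
marker families, of each family's gene count in the fosmid set, reported to
one decimal; an rRNA-based count can be carried alongside.

## Tree inference and the transfer verdict

Alignment columns with strictly more than 20% gaps are removed before
inference. Families with fewer than four sequences are excluded. The
default tree engine is neighbor joining on Poisson-corrected distances
(`d = −ln(1−p)`, mismatch fraction capped at 0.95 to keep saturated pairs
finite), with supports as the fraction of bootstrap replicates (default
100, column-resampled) containing each internal bipartition; ties in the Q
matrix break at the first index so topologies are reproducible. The engine
is deliberately simple — the method under test is the topology-reading
rule, not tree inference — and externally computed Newick trees are
accepted unchanged.

The verdict rules operationalize a manual tree-inspection protocol, so all
cutoffs are explicit and configurable:

* minimum support for a decision edge: 0.8 ("reasonable support");
* criterion 1 (*nested_in_phylum*): the supported monophyletic query clade's
  smallest enclosing clade with ≥5 non-query leaves is ≥90% bacterial and
  ≥80% a single named phylum. Several enclosing clades can tie at the
  minimal non-query leaf count (one per direction around the query's
  attachment in the unrooted tree); the transfer is called when **any**
  minimal enclosing clade passes, and the donor comes from the purest
  passing one. This resolves the tie that a purely lexicographic choice
  would decide arbitrarily;
* criterion 2 (*isolated_among_bacteria*): the tree carries ≥10 bacterial
  leaves from ≥3 named phyla, and either no other archaeal leaf exists or
  every path from the query clade to another archaeal leaf crosses ≥2
  supported edges whose query-side non-query leaves are majority-bacterial.
  The donor phylum stays unassigned unless criterion 1 also held;
* exclusions: fewer than 4 informative non-query leaves; or archaea and
  bacteria present but no supported edge isolates ≥3 non-query leaves at
  ≥90% single-domain purity ("intermixed without supported structure");
* a query that is non-monophyletic, or monophyletic only without support,
  is *unresolved*; anything else is *native*.

All checks are defined on unrooted bipartitions (leaf edges carry support
1), so verdicts are invariant under re-rooting and leaf reordering, and
raising the support threshold can only demote calls (never native → hgt).
`call_hgt_exhaustive` re-derives the same rules by literal enumeration over
every bipartition and is the oracle the optimized engine is tested against
on all small trees. Unresolved and excluded families count as non-HGT in
the summary, keeping the transfer estimate conservative by construction.

Timing: a transfer in a lineage-core family predates the lineage's
diversification (*early*); one in a shell family postdates it (*late*); an
HGT verdict on an archaeal-core family contradicts the core definition and
is flagged as a conflict instead of timed.

## Synteny statistics

Blocks are maximal runs of contiguous same-origin genes along a fosmid,
over five classes (archaeal core, lineage core, early HT, late HT, other);
block length is measured in genes, the unit the definitions use. Each
interior block contributes one unordered flank-class pair to the
bounding-couple matrix (k(k+1)/2 = 15 categories for five classes);
terminal blocks have at most one flank, are excluded, and are tallied
separately so totals remain auditable — the source phrasing does not define
an edge convention and exclusion is the conservative reading. Couples are
counted per block by default (per-gene counting is a flag; the original
wording "any synteny block (or gene)" is ambiguous). The couple matrix is
row-normalized and clustered by average-linkage on Euclidean distances,
rows pre-sorted by label for deterministic agglomeration.

## Codon usage and CAI

The usage table counts codons over a ribosomal-protein reference set
(premature-internal-stop genes skipped, trailing stops excluded), smooths
unseen codons to 0.5 counts, and sets relative adaptiveness
`w(c) = count(c)/max count among synonyms`. CAI is the geometric mean of
`w` over a gene's codons excluding Met, Trp and stops; a gene of only
modal codons scores exactly 1. The smoothing constant is a declared
convention (the standard implementation's documented default), not an
inference. Three reference tables are supported: per lineage and pooled.
Codon-usage PCA embeds genes as 59-dimensional within-family synonymous
frequency vectors (64 codons minus 3 stops, ATG, TGG) through the shared
PCA operation.

## The synthetic community

The generator emulates the study design, not sequencing physics: two
archaeal lineages (defaults: GC 47.13% and 54.82%, eight genomes each,
~36,178-bp mean insert length), six origin classes in configurable
proportions (defaults mirror the published class matrix; markers and
ribosomal families are flagged inside the archaeal-core allocation so the
planted proportions stay exact), and bacterial donor phyla with weights
(defaults: Proteobacteria 0.40, Actinobacteria 0.25, Firmicutes 0.20,
Cyanobacteria 0.15). Class and donor assignment use largest-remainder
rounding rather than multinomial draws, so the planted composition matches
the configuration exactly; carrier patterns are random (early transfers in
all or all-but-one genomes, late transfers in a strict subset, orphans in
one).

Proteins evolve by a Jukes–Cantor-like process on the 20-letter alphabet
(per-site substitution probability `1 − exp(−b)` per branch of length `b`);
scaffold branch lengths (strain 0.05, query stem 0.30, within-phylum 0.15,
phylum stem 0.45) were chosen so NJ on ~150-residue alignments recovers the
planted query placement in ≥90% of families, which the suite verifies.
Within-lineage strain divergence is a parameter, not a constant, since no
empirical figure exists for it. Nucleotide sequences are back-translated
with a lineage-specific codon table whose within-family weights
`∝ exp(λ·GC(codon))` are solved (by bisection on λ) so expected coding GC
matches the configured target; the achievable range is roughly 0.26–0.74.
Because *every* gene — including transfers — is back-translated with host
usage, recent transfers are fully ameliorated, which reproduces the
observed absence of codon-usage and CAI signal by origin class; the
generator cannot, by design, model partially ameliorated transfers. Genes
are tiled on random strands with 20–200-bp spacers at lineage GC; fosmid
boundaries cut at gene boundaries around Normal(mean, 0.05·mean) lengths,
and a genome tail shorter than 40% of the mean merges into the previous
fosmid rather than emitting an implausibly short insert.

What the generator does **not** emulate — read-level sequencing error,
assembly and chimerism, indels (alignments are gap-free by construction, so
the gap-trimming path is exercised by dedicated tests rather than the
simulator), paralogy, partially ameliorated transfers, and realistic
database incompleteness. Passing end-to-end tests therefore demonstrates
that the statistical machinery recovers planted signal under the stated
evolutionary model, not that the thresholds are optimal for noisy real
libraries.

## Problem sizes and determinism

The default validation scale is 200 families (two lineages × 100, eight
genomes each) with 100 bootstrap replicates per family tree — small enough
to run end-to-end in well under a minute per stage on one CPU while leaving
the binomial error on a 25% planted transfer fraction at ±3 points (1 σ),
comfortably inside the ±5-point acceptance band. All randomness flows from
a single seed through `numpy.random.default_rng`; a fixed seed reproduces
the fosmid FASTA byte-for-byte and every downstream table exactly.

## Known limitations

* The verdict rules are one faithful operationalization of a manual
  protocol; their thresholds are not claimed to reproduce per-gene published
  calls on the original libraries.
* QT clustering's exact-clique semantics is exponential in adversarial
  inputs; for large n with permissive diameters, the seed-growth heuristic
  of the original algorithm would be the pragmatic substitute.
* `shared_hgt_with_outgroup` without trees degrades to a homology-only
  count, which is an upper bound.
* The dataset-dependent observables of the original study (library GC,
  insert-length means, marker-based genome equivalents of 16.5/9.3, donor
  percentages, the soil-relative overlap count) require the deposited
  fosmids and external genomes; the operations that compute them are
  implemented and tested on synthetic data only.
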