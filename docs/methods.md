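# Methods

This note documents the models, rules and numerical choices behind
`diagmark`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reading was defensible.

## The marker model

The package implements discovery and application of **dominant bi-allelic
species-diagnostic markers**. A marker is a genomic site (one base, or two
adjacent bases inherited on one read) at which all sampled reads of a
target species carry one allele and no read of any contrast species carries
it. Each marker is turned into an allele-specific PCR trio: a
species-positive forward primer ending 3′ on the diagnostic allele, a
species-negative forward ending on the non-target allele, and one common
reverse primer. Scoring is band presence/absence: one allele copy suffices
for a band, so a heterozygous F1 hybrid of the two target species shows the
bands of both assays — hybrid detection falls out of dominance.

The limits of the model are inherited honestly: generations beyond F1
segregate, so an F2 or backcross shows whatever bands its inherited alleles
produce and detection capability decays per Mendelian expectation; and a
dominant nuclear marker cannot identify the maternal parent, so every
hybrid verdict carries a "maternal parent undetermined" caveat.

## Synthetic data generator

The generator reproduces the study design around the markers so that every
downstream stage is testable without external data.

* **Genome.** Random i.i.d. contigs at a configurable GC fraction (default
  0.45, typical of fish genomes). `make_ddrad_reference` additionally
  engineers exactly one selectable SphI..BstYI cassette per contig (default
  duplex fragment 360 bp, inside the 340–490 bp adapter-inclusive window)
  and scrubs all other recognition matches, so fragment locations are known
  and unique — convenient for planting variants at read-covered offsets.
* **Species.** Equal-length haplotype homologs of the shared contigs;
  divergence exists only at planted substitution records. A record carries
  a `fixedness` ∈ [0,1]: fixed diagnostic sites use 1.0; a
  partially-segregating site (the case of a non-target species in which the
  negative-primer allele is carried by only a fraction of individuals) uses
  the carrier frequency, with an explicit non-carrier background allele.
  Carrier status is drawn once per individual, and a carrier is homozygous
  — this matches per-specimen validation counts, which score individuals,
  not chromosomes. Indels are not modeled.
* **Ploidy.** Individuals are diploid: two haplotype copies per contig, an
  F1 carrying exactly one copy from each parent. Sturgeon functional ploidy
  is complex and the real assays treat markers as dominant presence/absence,
  which a diploid model reproduces; higher ploidy would only add allele
  copies, which dominance ignores.
* **Digestion.** Recognition sites are IUPAC patterns (SphI `GCATGC`,
  cut offset 5; BstYI `RGATCY`, cut offset 1) matched on both strands.
  Fragment boundaries span the *duplex-inclusive* extent, from the lower to
  the upper of the two strand cuts (the bottom-strand cut derived by
  palindromic symmetry). This choice, rather than a single top-strand cut
  point, is what makes the downstream residual-site check meaningful: after
  adapter ligation a read entering a fragment from an SphI junction always
  begins `CATGC`, and from a BstYI junction `GATCY`, in either fragment
  orientation. Overhang chemistry beyond that (which strand protrudes) is
  irrelevant downstream and not modeled. Only mixed-end fragments are
  retained (standard double-digest chemistry: only those receive both
  adapters), and only those with adapter-inclusive length (fragment + 80 bp)
  inside 340–490 bp.
* **Reads.** 125 bp paired ends: read 1 = 6 nt sample barcode + fragment
  prefix from the SphI side; read 2 = reverse complement of the BstYI end.
  Exactly `coverage` pairs per fragment per haplotype copy (so a
  homozygote's site depth is 2×coverage) — deterministic depth keeps the
  coverage threshold of the caller exactly controllable in tests.
  Sequencing error is i.i.d. substitution-only at a configurable rate
  (default 0); quality strings are constant Q30, since the preprocessing
  model discards rather than corrects low-quality data. Barcodes are
  generated with pairwise Hamming distance ≥3 so that one-mismatch
  demultiplexing is provably unambiguous.
* **Not emulated:** PCR duplicates, adapter-ligation failures, chimeras,
  indel errors, coverage overdispersion, paralogy, and the occasional
  non-specific high-molecular-weight PCR band seen on real gels. Passing
  tests on this generator therefore demonstrate the correctness of the
  pipeline's logic under its stated model, not robustness to every real
  ddRAD artifact; the fixedness-tolerance and binding-rule knobs exist for
  real-data brittleness but default to the strict settings.

## Preprocessing

A pair is kept iff: exactly one barcode lies within 1 mismatch of the
read-1 prefix (two or more in range → ambiguous, discarded); read 1 starts
with the SphI residual and read 2 with the BstYI residual (IUPAC-aware);
neither mate contains an uncalled base; and both mates are clipped to a
fixed 110 bp (3′ excess only). Filtering is pair-level — if either mate
fails, the pair is discarded — the conservative reading when downstream
mapping treats mates independently but site validation is inherently
paired. The N check runs before clipping (a 3′ N still marks a bad read).
Counts are conserved: assigned + discarded = input, with per-reason tallies.

## Mapping and reference updating

The mapper is a deliberately transparent seed-and-extend engine: exact
21-mer seeds (three staggered offsets per read, both strands; a single
substitution cannot evade all three on a 48 bp+ read) propose candidate
diagonals, each expanded by ±gap-length; candidates are scored with match
+1, mismatch −2, and a flat −3 for one gap run of length ≤3 (both
gap-in-read and gap-in-reference, split position optimized via prefix
sums). A read is accepted at its best-scoring placement iff that placement
is unique (ties → "ambiguous", excluded from pileups, which keeps paralogs
out of diagnostics) and at least 90% of the read aligns as matches. The
cost parameters mirror the published mapping configuration; the engine
itself is validated against a brute-force all-positions oracle in the test
suite, since the original commercial implementation's internals are not
reproducible.

Contig post-processing does one round, before calling: contigs with no
mapped reads are removed, and every covered position is replaced by the
strict-majority base among covering reads of the *reference species only* —
updating on pooled species would erase exactly the fixed differences the
pipeline is looking for. Ties keep the original base (deterministic; any
other tie-break would inject information the reads do not contain). The
update is a fixed point: recomputing majorities from the same alignments
changes nothing.

Pileups count per-species allele depths per position; dinucleotide spans
use read-phased pair counts — a pair is counted only when a single read
covers both positions — so a merged two-base allele is an observed
haplotype, never an artifact of stacking two columns.

## Variant calling

At minimum per-species depth 32 (the threshold is per species: "all reads
of species X" is only meaningful at adequate depth in each X), a site is
called when all target reads carry one allele (up to a discordance
tolerance, default 0) and no contrast read carries it (same tolerance).
Two rule variants are distinguished by the reference contig: the
reference-carrying rule (target allele equals the reference base — the
natural case when the reference genome was assembled from the target
species) and the reference-absent rule. Adjacent called sites merge into a
dinucleotide variant only when the pair counts phase cleanly under the same
fixedness conditions; the merged call replaces its two constituents (a
two-base 3′ anchor is strictly stronger for primer design). The non-target
allele is the pooled-majority contrast allele. Raising the depth threshold
can only remove calls; raising the tolerance can only add them.

Putative diagnostics are screened in hybrid read sets: a variant passes iff
the hybrid shows at least one read of each allele at the span (the screen
is presence-based; observed real hybrid depths as low as 9/7 justify the
permissive default, configurable upward). `detection_capability(k, n)` =
100·k/n reports, to one decimal, the fraction of non-target individuals in
which the species-negative assay amplifies — the probability that a hybrid
with that species is detectable rather than silently classified as pure.

## Primer design

Forwards are built on the plus strand with the variant at the 3′ terminus;
lengths 18–25 nt, amplicons 100–300 bp (bracketing the fixture panel's
geometry). In single-nucleotide mode the penultimate base of *both*
forwards is substituted to mismatch every observed template allele at that
position, preferring purine:purine mispairs (the most destabilizing class)
with a fixed A<C<G<T tie-break; both forwards are modified for symmetry, so
positive-vs-non-target and negative-vs-target each present exactly two
3′-terminal mismatches while the matched pairings present at most the one
artificial mismatch. In dinucleotide mode the two terminal bases already
guarantee the double mismatch and nothing is modified.

The common reverse must sit in a conserved window: no species' aligned
reads may show any non-reference allele at any covered window position
(uncovered positions count as conserved — nothing observed segregates
there); when no conserved window exists in range the design fails with an
explicit diagnosis rather than emitting a fragile primer. Candidates are
ranked by the trio's worst |Tm − 60 °C|, then by a G/C 3′ end on the
reverse, then by amplicon length; ranking is fully deterministic.
Tm uses nearest-neighbor thermodynamics with unified parameters (50 mM
monovalent salt, 250 nM primer, via Biopython), with the Wallace rule
available as a cross-check; annealing temperature is reported as the trio
mean Tm − 3 °C, a common heuristic. No hairpin/cross-dimer screening is
performed — the binding model downstream is mismatch-combinatorial, not
thermodynamic.

## In-silico PCR and classification

A primer site binds iff the 3′-terminal base matches, at most one mismatch
falls in the terminal 2-base window, and at most two mismatches occur over
the whole primer. These thresholds are the minimal model consistent with
the design logic above: the artificial penultimate mismatch alone must not
block extension on target (one window mismatch → bind), while
terminal-plus-penultimate must (two window mismatches → no bind). Both
primers are searched on both template strands; a product forms when a
forward-type and a reverse-type site face each other within a maximum
product size (default 1500 bp; anything larger is treated as the
non-specific smear it would be on a gel), and product length is the span
between the two 5′ ends. Amplification is binary — no efficiency or cycle
modeling — and dominant over a genotype's haplotypes.

The decision table is total over the 16 possible four-band patterns.
Evaluation order: pure species 1 (P₁+,N₁−,P₂−,N₂+); pure species 2
(mirror); any P₁+∧P₂+ → F1 of the targets; P+ with its own N+ and the
other P− → hybrid with an untyped species; all-P− with both N+ → other
species; all-P− with only N₁+ → other species with the species-2-negative
site absent, carrying the caveat that a hybrid with species 2 cannot be
excluded (for a species with negative-site carrier frequency *f*, the miss
rate of such hybrids is 1−*f*); all four absent → assay failure; anything
else → inconclusive. Verdict labels are generic (species 1/species 2) and
bound to concrete names by the panel; the shipped fixture binds species 1
to *H. huso* and species 2 to *A. ruthenus*.

## Fixture panel and synthetic templates

The two-locus sturgeon panel (153 bp and 247 bp assays) and its per-species
validation counts ship as TSV fixtures. The loci's true flanking sequence
is not public; `synthetic_locus_template` therefore reconstructs only the
primer-binding geometry — forward site (restoring a plausible true
penultimate base where the primer carries the deliberate mismatch),
deterministic random filler of the right length, reverse-complemented
common-primer site, short invented flanks — and is labelled synthetic
wherever it appears. Product sizes on these templates equal the declared
assay lengths exactly; nothing else about the templates is biological.

## Problem sizes and determinism

The test suite and the acceptance script run fully seeded simulations at
deliberately compact scales: the end-to-end discovery world uses 20 contigs
of 600 bp, one individual per species plus one F1, and 20 read pairs per
fragment per haplotype (site depth 40, comfortably above the calling
threshold of 32); the assay-specificity experiment uses 120 target and 100
non-target individuals, matching the largest published validation cohort;
the size-selection bound uses a 200 kb random genome. These sizes make
every property exactly checkable while keeping a full run in seconds; all
randomness derives from a single seed, and identical seeds give
byte-identical outputs.

## Known limitations

* The binding rule is combinatorial, not thermodynamic: it cannot rank
  partial destabilization, and primer-dimer or off-target amplification
  beyond the mismatch thresholds is invisible to it.
* The caller's strict fixedness (tolerance 0) is brittle on real data with
  sequencing error; the tolerance knob exists but shifts the
  false-positive/false-negative balance and is deliberately off by default.
* Mapping of highly repetitive references degrades to "ambiguous" reads and
  silently shrinks usable depth; this is by design (paralog safety) but
  means depleted pileups, not wrong calls.
* The diploid model understates allele-copy diversity in polyploids;
  dominance makes band predictions robust to this, but simulated read
  ratios (e.g. 50:50 in an F1) are idealized.
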