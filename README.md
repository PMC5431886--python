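# diagmark

Species-diagnostic dominant nuclear DNA markers from ddRAD-style reads, and
in-silico identification of pure species and their F1 hybrids from PCR band
patterns.

`diagmark` is aimed at conservation geneticists and molecular ecologists who
need simple presence/absence PCR assays that distinguish two closely related
species — the motivating system is the sturgeons *Huso huso* (beluga) and
*Acipenser ruthenus* (sterlet) and their aquaculture hybrid, the bester —
from each other, from related species, and from their interspecific hybrids.
Because the markers are **dominant and bi-allelic** (a band is present if at
least one allele copy is carried), a heterozygous F1 hybrid shows the bands
of both parental assays, which is exactly what makes hybrids detectable.

## What the package does

The pipeline re-implements a complete marker-discovery and assay-application
workflow:

1. **simdata** — seeded simulation of the whole study: a shared contig set,
   per-species haplotypes with planted fixed variants (single-nucleotide and
   adjacent dinucleotide substitutions, plus partially-segregating sites),
   diploid individuals and F1 hybrids, SphI+BstYI double digestion with
   340–490 bp adapter-inclusive size selection, and 125 bp barcoded
   paired-end reads with configurable substitution error.
2. **readproc** — demultiplexing (non-ambiguous barcodes, ≤1 mismatch),
   residual restriction-site validation on both mates, removal of reads with
   uncalled bases, and fixed clipping to 110 bp.
3. **refmap** — a transparent seed-and-extend read mapper (mismatch cost 2,
   at most one gap of length ≤3, ≥90% of the read aligned, unique best
   placement), removal of zero-coverage contigs, majority-base reference
   correction, and per-species pileups with read-phased dinucleotide counts.
4. **diagvar** — combinatorial fixed-variant calling: a site is diagnostic
   for species *t* against contrasts *C* when, at depth ≥32 in every
   species, **all** reads of *t* carry an allele that **no** read of any
   species in *C* carries; adjacent phased sites merge into dinucleotide
   variants; putative diagnostics are screened for heterozygosity in hybrid
   read sets.
5. **primerdesign** — ARMS-style allele-specific trios: a species-positive
   forward ending 3′ on the diagnostic allele, a species-negative forward
   ending on the non-target allele, and a common reverse in a conserved
   window. In single-nucleotide mode the penultimate 3′ base of both
   forwards is deliberately made non-complementary to every observed
   template, so a non-matching template always faces **two** 3′-terminal
   mismatches (no extension) while the matching template faces only the one
   tolerated artificial mismatch. Melting temperatures use nearest-neighbor
   thermodynamics (50 mM Na⁺, 250 nM primer); multiplex compatibility is
   checked across trios.
6. **ispcr** — in-silico PCR under an explicit binding rule (3′-terminal
   base must match, ≤1 mismatch in the terminal 2-base window, ≤2 overall)
   and the band-pattern decision table: with positive/negative assays
   (P₁,N₁) and (P₂,N₂) for the two species,
   (P₁+,N₁−,P₂−,N₂+) → pure species 1, (P₁−,N₁+,P₂+,N₂−) → pure species 2,
   P₁+ and P₂+ → F1 hybrid of the targets, P+ with its own N+ → hybrid with
   an untyped species, both P− with both N+ → other species, and both P−
   with only one N+ → other species whose negative-primer site is absent
   (a hybrid with the second target cannot be excluded).

The published two-locus sturgeon panel (153 bp *H. huso* assay, 247 bp
*A. ruthenus* assay) ships as a fixture together with its per-species
validation counts.

## Worked example

The demo configuration simulates three species (*A. ruthenus*, *H. huso*,
*A. baerii*) plus one bester-type F1 over four contigs, with one planted
dinucleotide diagnostic (AG vs CT) and one single-nucleotide diagnostic
(C vs G):

```bash
diagmark run --outdir demo --seed 1
```

`variants.tsv` then contains the two recovered diagnostics (depth 40 in
every species, the dinucleotide called under the reference-carrying rule,
the single nucleotide under the reference-absent rule):

```
#contig	start_1based	end_1based	span	target_allele	non_target_allele	target_species	rule	depths
140238	166	167	2	AG	CT	A_ruthenus	reference_carrying	A_baerii:40;A_ruthenus:40;H_huso:40
216845	166	166	1	C	G	H_huso	reference_absent	A_baerii:40;A_ruthenus:40;H_huso:40
```

and `identification.tsv` classifies every sample from its band pattern with
the trios designed from those variants (`dv1_*` is the *A. ruthenus* assay,
`dv2_*` the *H. huso* assay):

```
#sample_id	bands	product_bp	verdict	caveats
ab1	dv1_A_ruthenus_p-,dv1_A_ruthenus_n+,dv2_H_huso_p-,dv2_H_huso_n+	128,103	other_species	-
ar1	dv1_A_ruthenus_p+,dv1_A_ruthenus_n-,dv2_H_huso_p-,dv2_H_huso_n+	128,103	pure_species_1	-
be1	dv1_A_ruthenus_p+,dv1_A_ruthenus_n+,dv2_H_huso_p+,dv2_H_huso_n+	128,128,103,103	f1_hybrid_of_targets	maternal parent undetermined
hh1	dv1_A_ruthenus_p-,dv1_A_ruthenus_n+,dv2_H_huso_p+,dv2_H_huso_n-	128,103	pure_species_2	-
```

The F1 shows all four bands (one allele copy suffices for a band), and the
hybrid screen confirms both alleles of every diagnostic in its reads
(`hybrid_screen.tsv`: `pass` at both loci). Hybrid calls always carry the
maternal-parent caveat: a dominant nuclear marker cannot tell which parent
was the mother.

The same machinery answers tabletop questions directly:

```python
>>> from diagmark import detection_capability
>>> detection_capability(23, 40)   # negative-assay carriers in A. stellatus
57.5
```

i.e. a hybrid between the sterlet and a species in which the negative-primer
site segregates at 23/40 escapes detection in 42.5% of cases.

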