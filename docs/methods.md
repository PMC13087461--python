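# Methods

## Overview

The package re-creates, at desk scale and on fully synthetic data, the two
computational analyses of a CRISPR-Cas9/AAV6 HDR gene-correction
experiment: (i) AAV integration-site detection from Cas9-enriched
long-read libraries aligned to a combined host+vector reference, and
(ii) quantification of editing outcomes (HDR knock-in, NHEJ indels,
off-target background) from a three-primer PCR assay and amplicon
sequencing.  All coordinates are 0-based half-open internally; 1-based
coordinates appear only at SAM boundaries (SA-tag positions), and BED
output is 0-based half-open.

## Vector and allele models

The donor vector is modelled as `ITR + 5'HA + cDNA + polyA + 3'HA + ITR`
with segment coordinates derived from the concatenation.  Defaults: 145 bp
ITRs (the AAV2 convention), 1-kb homology arms copied from the host locus,
a 1.7-kb cDNA and a 0.2-kb polyA as uniform-random stand-ins — real vector
internals are not needed by any algorithm here, only the segment geometry,
and all lengths are configurable.

Alleles at the target locus are explicit sequences: WT is the host
chromosome; NHEJ carries one small indel within ±20 bp of the cut (default
a 3-bp deletion at the cut); HDR is
`host[..ha5_end) + cDNA + polyA + host[ha3_start..)` — homology arms are
genomic, so the knock-in allele contains no ITR.  The cut site is placed
between protospacer bases 17 and 18 (3 bp 5' of the NGG PAM), the standard
blunt SpCas9 cut.  Silent mutations (default two, PAM-proximal) are applied
at protospacer offsets on the knock-in allele so it can no longer be
re-cut; the model tracks the mutated protospacer so tests can verify the
Hamming distance equals the number of mutations.

## Synthetic data generator

The generator emulates the two sequencing experiments and writes truth
annotations alongside every read, which is what makes the callers testable
without an external aligner.

*Long-read library.* Genome copies are drawn from the population's outcome
classes (defaults WT 0.48 / NHEJ 0.32 / HDR 0.20, chosen so that overall
HDR is ~20% and indel-bearing alleles are ~40% of the non-HDR compartment
the upper-band assay sequences).  Each copy's molecules are sheared by a
Poisson process (mean 10 kb), cleaved in vitro at a guide array tiling any
vector sequence present (segment midpoints of ITRs, homology arms and
cDNA), and retained with probability 0.9 if Cas9-cut versus 0.9/20
otherwise (capture bias 20 — a fixture choice; real enrichment yields are
not published).  Reads inherit a truth record of aligned blocks and
junctions; sequencing errors are applied per base (substitution 0.02,
insertion 0.005, deletion 0.005 — nanopore-like; no homopolymer or signal
modelling).  The truth SAM encodes each chimeric read as primary +
supplementary records with soft-clipped CIGARs and SA tags exactly per the
SAM spec, so the junction caller consumes it like any aligner output.  An
optional re-alignment with an external aligner is deliberately out of
scope: the truth SAM already exercises every parsing path.

Random (non-targeted) integrations are clonal direct insertions of a
configurable vector subinterval (default the ITR-containing 3' end, the
common ITR-mediated mode).  Episomal vector molecules are added per genome
copy at a Poisson rate (default 0, mirroring the 21-day washout; positive
values are used as negative controls — such reads align vector-only and
must never produce an integration site).

*Amplicon pools.* Reads are drawn from weighted allele amplicon sequences.
The amplicon error model defaults to a substitution-dominated short-read
profile (sub 2×10⁻³, ins/del 10⁻⁴ per base): the band-sequencing assay is
short-read/Sanger, not nanopore, and an indel-rich long-read profile would
contaminate a ±5 bp indel window with ~10% sequencing artefacts — a
property of the instrument, not of the assay being emulated.  Both profiles
are plain `ErrorModel` values and can be swapped freely.

All operations draw from a single explicitly seeded `numpy` generator;
identical seeds give byte-identical FASTQ/SAM.

## Junction calling

Defaults: mapQ ≥ 20, aligned block ≥ 200 bp, read gap ≤ 100 bp between
paired blocks, ≤ 50 bp read overlap tolerated (microhomology) before a
chimera is skipped as ambiguous, 50 bp single-linkage merge distance, and
a minimum support of 1 read (a single-read site is reportable; stricter
calling via `min_support`).  These are declared choices for ~2–3% error
long reads — the original analysis publishes no thresholds — and are all
exposed through `RunConfig`/CLI flags.  The junction coordinate convention
is the reference base adjacent to the breakpoint on each side; site
classification uses a 100 bp window around the homology-arm span.

## Editing quantification

In-silico PCR requires primer binding with ≤ 1 mismatch and an exact
3'-terminal trinucleotide (a PCR-specificity proxy), and reports convergent
products of 50–3500 bp.  The 3.5 kb cap reproduces the short-product
amplification bias of the gel: the outer-primer product on the knock-in
allele (~4.4 kb in the fixture geometry) does not amplify, so a mixed
population yields exactly two bands (~2.5 kb WT/NHEJ, ~1.6 kb HDR).  Band
intensity from sequencing data is the read count per product class
(assignment by nearest predicted length within 15%); an optional molar
correction divides intensities by product length before the ratio (off by
default, since gel densitometry was mass-based).

The banded global aligner scores match 2, mismatch −4, gap open −6,
extend −1 (a length-k gap costs −6−k); the band is centred on the main
diagonal and widened by the read/reference length difference, with an
error if the band cannot contain a global path.  Tie-breaks are
deterministic: diagonal over gap, gap-in-read (D) over gap-in-reference
(I).  The inner loop is compiled with numba; the test suite checks banded
scores against an independent unbanded dynamic-programming oracle.

Indel calling declares a read positive when an I/D run ≥ 1 bp overlaps the
±5 bp cut window (a CRISPResso-like convention; the window is
configurable).  Junction-fidelity verification aligns reads to the
knock-in allele's homology-arm junction region (± flank), builds a
majority-vote consensus per reference column, and calls the junction
precise when the consensus has zero indels and no more than the allowed
mismatches; reads without the genomic flank (episomal vector) fall below
the identity floor and are excluded.

## Off-target screen

Candidates are enumerated by exhaustive Hamming scan of both strands for
NGG-adjacent 20-mers (PAM exact apart from the N; mismatches counted in
the protospacer only; the known on-target is excluded).  No risk-scoring
model (CFD/MIT-style) is implemented — annotation comes from an optional
user feature table and defaults to "unannotated".  Screening applies the
cut-window indel caller at each site's predicted cut (between matched
bases 17/18) and flags sites above a 0.1% background threshold, the
background level the assay is expected to resolve.

## Problem sizes and numerical choices

The default scenario uses a 100 kb locus chromosome plus a 60 kb second
chromosome, 800-read long-read libraries, and 2,000–5,000-read amplicon
pools — sizes chosen so each analysis completes in seconds while leaving
all estimators in their well-behaved binomial regimes (recovery tests use
3σ binomial tolerances).  Degenerate inputs are defined rather than
accidental: zero amplicon reads is an empty (valid) pool; a screened site
with no reads yields a `no-data` row; an all-zero band table is an error;
clustering an empty event list returns an empty site list.

## What passing tests do and do not show

The generator reproduces the *structure* of the real experiments (chimeric
reads with SA tags, enrichment geometry, allele mixtures, band sizes), not
their biology: uniform-random genomes have no repeats or homology between
loci, error models are i.i.d. per base, PCR has no thermodynamics, and
enrichment has no sequence bias.  Passing tests therefore demonstrate the
correctness of the coordinate arithmetic, calling logic and estimators
under the stated models — not performance on real nanopore data, where
repeat-mediated mismapping and concatemeric vector forms are the dominant
hard cases and are explicitly out of scope.

## Known limitations

* Vector concatemers and rearranged episomes are not modelled; each
  integration inserts one contiguous vector subinterval.
* The junction caller reports breakpoints only; no assembly, SV/CNV
  calling or breakpoint-sequence reconstruction.
* Minus-strand guide loci are supported in the data model but the bundled
  scenario only exercises plus-strand targets end to end.
* The χ²/binomial test tolerances assume independent reads; PCR duplicate
  structure is not simulated.
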