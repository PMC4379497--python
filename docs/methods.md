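# Methods

## The problem this package models

Transposon cassettes carrying a splice acceptor, stop codons and a
polyadenylation signal act as *gene traps* when inserted into an intron in
the sense orientation of the host transcript. When the intron lies between
two protein-coding exons, recombinase-mediated cassette exchange (RMCE) can
replace the gene-trap payload with an artificial exon —
SA–linker–EGFP-FlAsH-StrepII-TEV-3xFlag–linker–SD — that splices into the
mRNA and yields an internally GFP-tagged fusion protein. Whether the fusion
is in frame depends on the *intron phase*: the number of coding nucleotides
transcribed upstream of the intron modulo 3. Three versions of the donor
cassette exist, one per phase.

`mimictrap` implements the desk-side computations of such a screen:

1. deriving introns, intron classes and phases from gene models;
2. classifying insertion points by feature category, gene-trap orientation
   and isoform coverage;
3. designing the RMCE conversion (cassette phase, tag residue, fusion mass,
   protein-domain overlap, orientation PCR readout);
4. curating a collection under spacing and redundancy rules;
5. mapping inverse-PCR flank reads back to insertion coordinates;
6. the screen's summary statistics;

plus a synthetic-data generator that produces all inputs with known ground
truth, so the whole pipeline is testable without external data.

## Coordinate and boundary conventions

All genomic coordinates are 1-based, fully closed (the GFF3 convention);
interval containment uses closed arithmetic throughout. BED export converts
to 0-based half-open at the boundary only.

An insertion point sits *between* plus-strand bases `position` and
`position + 1`. A point falling exactly on an exon/intron boundary is
assigned to the intron: a cassette landing on the junction interrupts
splicing. This single deterministic rule is applied identically by the
interval classifier and the per-base oracle.

Intron class is per transcript: *coding* iff CDS nucleotides exist on both
sides of the gap within that transcript; otherwise 5′/3′ UTR by position in
transcription order, or *noncoding* for CDS-less transcripts. Phases are
always recomputed from the models; phase fields in input GFF3 are ignored.

Transcripts whose CDS length is not a multiple of 3, or whose CDS escapes
their exons, are retained but flagged frame-invalid and excluded from
phase, coverage and design computations. The isoform denominator everywhere
is the set of frame-valid CDS-bearing transcripts — transcript isoforms,
not distinct protein sequences.

## Classification rules

Per gene, the point category is the highest-priority per-transcript
category under `coding_intron > coding_exon > utr5_intron > utr5_exon >
utr3 > noncoding_intron`; per-transcript detail is retained. For ncRNA
genes, intronic hits are `noncoding_intron` and exonic hits `ncRNA_gene`.
The promoter category covers points within 500 bp (configurable) upstream
of the 5′-most transcript start and outside every transcript span;
downstream points are not included.

Gene-trap orientation is simply element strand == gene strand; the
mutagenicity prediction is loss-of-function for sense coding-intron hits
and neutral for antisense ones.

Metal classes partition coverage fractions f over (0, 1]: gold at f = 1
(equivalently, the insertion lies in a constitutive coding intron), silver
at 0.5 < f < 1, bronze at f ≤ 0.5. Exactly half the isoforms is bronze —
silver requires *more than* 50%. Gold is orientation-agnostic; orientation
is reported separately.

## Trap design

The cassette phase is the phase shared by the most taggable isoforms, ties
broken toward the lowest phase; isoforms with a different phase (or no
coding intron at the point) are reported untagged. The tag lands after the
last complete codon before the intron (`upstream CDS nt // 3`). Base
protein mass is the average-isotope molecular weight of the translated CDS
(Biopython); the fusion adds a constant tag mass, default 35.0 kDa, as a
parameter rather than a computed value because the cassette's protein
sequence is a configurable input here. A tag after residue r interrupts a
domain [s, e] iff s ≤ r < e — insertion after the final residue leaves the
domain intact. Exon skipping is not modelled: designs assume full inclusion
of the artificial exon.

The orientation PCR assay is simulated with exact-match primer binding: a
reaction amplifies iff its two primers occur in convergent orientation
within a maximum product size. With flanking primers MiL-F/MiL-R pointing
inward and cassette primers Tag-F/Tag-R pointing outward on the cassette
sense strand, a correctly oriented cassette amplifies (MiL-F × Tag-R) and
(MiL-R × Tag-F), a flipped one the complementary pair, and any other
pattern is indeterminate. The truth table follows from the constructed
locus geometry, not from a lookup.

## Collection selection

Selection is a deterministic two-pass batch ranking. Genic pass, per gene:
candidates are ordered by category priority, then isoform coverage
descending, then position; the top is kept (`first_hit`). Additional
candidates are kept when their category differs (`different_part`) or
their tagged-isoform set is not a subset of any kept set
(`differential_isoforms`); tandem-array genes keep exactly one
representative. Intergenic pass, in coordinate order: a site is kept iff
it is more than 20 kb (configurable) from every already-selected site,
genic or intergenic. Gaps larger than the 40 kb coverage goal are reported
per chromosome, measured point-to-point and against chromosome ends.

Batch ranking makes the output a pure function of the candidate set, which
is the reproducible choice for re-analysis; it is *not* monotone under
candidate addition, because a newly added candidate of equal category and
superset isoform coverage displaces a previously kept one by design. The
sequential screen that the rules emulate is monotone; that behaviour is
available as `arrival_order` mode, where candidates are ranked by input
order and appending candidates never revokes earlier selections.

## Flank mapping

The mapper is a desk-scale exact aligner, not a production tool: a k-mer
seed (default k = 15) from the element-proximal end of the read, exact
full-length verification on both strands, and a unique call iff exactly one
placement survives. Element strand is inferred from which element end the
read abuts and which strand it matched. An optional Hamming-distance-1 mode
tolerates a single substitution. Reads always run 5′→3′ from the junction
outward; the reported insertion position is the plus-strand base
immediately 5′ of the junction, matching the insertion-table convention.
For error-free reads of length ≥ 2k drawn from unique sequence, recovery of
planted coordinates and strands is exact by construction, and this is
enforced by round-trip tests.

## Statistics

Percentages are reported as rounded integers with numerator and denominator
always retained, so every printed figure is reproducible from its counts.
The two-category goodness-of-fit test is Pearson's chi-square against an
even split, 1 df, no Yates correction — the convention that reproduces the
screen's printed p-values (26 vs 62: p ≈ 1e-4; 14 vs 12: p ≈ 0.7). The
chi-square tail was checked against exact enumeration of the statistic's
null distribution; agreement is within 1e-2 for clearly unbalanced counts
at totals ≥ 60, but the continuous approximation is crude near the null and
at small totals (e.g. 14 vs 6: exact 0.115 vs chi-square 0.074), so the
enumeration cross-check is asserted only in the tail regime where the
screen's comparisons live. The adult-only CNS expression fraction is
reported with both denominators (tested-subset and whole-screen) since
either rounding basis is defensible.

Percent knockdown is `100 × (control − treated) / control`. The
olfactory-learning performance index is the mean over two reciprocal-odor
sessions of (conditioned-odor avoiders − unconditioned-odor avoiders) /
total. Quantal content is mean EJP / mean mEJP, with nonlinear-summation
correction assumed already applied to the input means (the correction
itself is out of scope).

## The synthetic generator

The generator emulates the *structure* that the pipeline's decisions depend
on, not sequence realism. Defaults (2 chromosomes × 150 kb, 12 genes,
1–3 isoforms, exons 120–300 bp, introns 80–200 bp, intergenic gaps
2–6 kb) keep a full run under a second while exercising every code path;
the per-line characterization rates default to the screen's observed
fractions (92% gene-trap lethality in sense orientation, 72% reversion on
tagging, 77% retained function, 84% larval CNS expression, 95% unfixed
detectability) over 200 lines.

Design choices worth knowing:

* **Deterministic feasibility.** The mix of gene kinds (ncRNA genes,
  nested antisense pairs, plain coding genes) is computed from the
  configured fractions as fixed counts and only shuffled by the seed; the
  first three coding genes span isoform counts 1–3 and one always carries a
  5′UTR exon. Every feature-category quota is therefore satisfiable for any
  seed. The three intron phases cycle deterministically across genes.
* **Alternative introns by retention.** Isoform k > 1 retains one internal
  coding intron, merging its flanking exons. Retained introns sit at
  phase-0 junctions with lengths divisible by 3 and are filled with
  stop-free codons whose first codon starts GT (valine) and last ends AG,
  so both the spliced and retained isoforms translate cleanly and the
  intron still carries canonical splice dinucleotides. Never-retained
  introns get plain GT..AG ends.
* **Dual-gene coding introns.** A nested-pair gene is a host with one
  widened coding intron containing a complete antisense gene, so points in
  the inner gene's coding introns are coding-intron calls for two genes at
  once — at least one such planting is drawn whenever pairs exist.
* **Independent ground truth.** Planted labels come from a per-base
  brute-force oracle (`mimictrap.oracle`) that labels every transcript base
  by scanning, shares no interval arithmetic with the classifier under
  test, and re-derives phases by counting CDS bases one at a time.
* **Characterization outcomes are independent Bernoulli draws** respecting
  logical structure (reversion only for gene-trap-lethal rows, adult CNS
  status only for L3-negative rows, unfixed imaging only for a tested
  subset). No correlation structure is modelled because only marginal
  rates are specified.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: insertion-site bias (plantings are uniform over
eligible points, with no TA target-site preference or duplication),
realistic splice-site motifs beyond the GT..AG bookkeeping, codon usage,
repeat content (outside deliberately constructed repeat fixtures, flank
uniqueness is near-certain), UTR-only isoform diversity, trans-splicing,
and annotation errors other than the frame-invalid flags the parser
produces.

## Numerical and degenerate-input conventions

Empty GFF3 inputs yield an annotation with zero genes; empty insertion sets
yield empty reports and one coverage gap per chromosome. Zero-total counts,
non-positive control means, and zero mEJP means raise errors rather than
propagating NaNs. Phase-choice ties break to the lowest phase; selection
ties break by position then insertion id, so all outputs are reproducible
byte-for-byte under a fixed seed. Masses are average-isotope kDa; fusion
mass is exactly base + tag by construction.

## Problem sizes

Default test and verification runs use 12-gene (or 6–8-gene) genomes on
150 kb chromosomes, about 50 insertions per genome, 20 genomes for the
recovery suites, and 5 000 lines for rate-recovery checks — sizes chosen so
the whole suite and the acceptance script each complete in well under a
minute on one CPU while keeping binomial checks at 3-standard-error
resolution.

## Known limitations

The flank mapper is exact-match (±1 mismatch optionally) and unsuitable for
real reads; the PCR simulation ignores thermodynamics and mispriming; the
selection rules are one consistent reading of a curation policy described
in prose; genome-scale collection counts depend on the real insertion
dataset and a specific annotation release and are deliberately out of
scope.
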