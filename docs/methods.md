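# Methods

`rdscan` formalizes a locus- and variant-level characterization workflow for
reading-disorder (RD) candidate genetics: positional colocalization of
candidate loci with human-specific genomic features, qualitative selection
inference on candidate variants, discovery of novel candidate loci from
sub-significant GWAS associations filtered through pleiotropic loci, and
simple expression-pattern statistics. This note records the model choices,
parameter meanings and defaults, numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Coordinates and overlap model

All coordinates are 1-based inclusive internally — the convention of every
printed coordinate in the curated candidate tables — with BED (0-based
half-open) converted only at the I/O boundary. Chromosome names are
normalized to `chr`-prefixed canonical forms (`MT` → `chrM`); anything
outside `chr1..chr22, chrX, chrY, chrM` is rejected rather than guessed.

Colocalization is plain positional overlap: two intervals colocalize iff
they share at least one base on the same chromosome. No minimum-overlap
fraction is applied, and point variants are tested as 1-bp intervals
`[pos, pos]`. The distance between non-overlapping same-chromosome intervals
is defined as (later start) − (earlier end), so abutting inclusive intervals
are at distance 1; this convention reproduces the published variant-to-
element gap of 27,498 bp for rs6910825 and is used consistently for
nearest-element search. Cross-chromosome distances are undefined and raise.

Overlap queries run on per-chromosome interval trees (`intervaltree`); the
index carries a contract, enforced by property tests, that its answers equal
a brute-force scan on any query.

## Locus annotation rules

A locus *carries a human-specific feature* iff at least one overlapped
element in the eight human-specific track classes (PSIregion, hsGene, hsCRE,
hsCRE–hsGene, HAR, CRE–HAR, MHS, CRE–MHS) is itself flagged human-specific.
Tracks may contain primate-only units (e.g. primate-specific transcription
units within the PSIregion class); these record an overlap but do not
qualify — the reading that makes *DYX1C1* the single familial exception.

Cortical-morphology membership is decided by case-insensitive gene-symbol
match against the 780-gene cortical surface-area/thickness list, not by
interval overlap: the published counts treat cortical membership as
gene-level identity.

The *glial* qualifier is true iff any matched element regulates expression
in a neuroglial cell type; the default glial set is {Astrocyte,
Oligodendrocyte, OPC, Microglia} and is configurable. Cell-type (hence
glial) information lives on the cis-regulatory element classes (hsCRE,
hsCRE–hsGene, CRE–HAR, CRE–MHS, hsGene); plain HAR/MHS elements carry none,
so the report's HAR and MHS columns pool each class with its CRE companion
track.

Group summaries report raw proportions with half-up rounding to one decimal
(matching the published "90.9%"). A locus overlapping k elements of one
track counts once for proportions; element multiplicities are retained in
the per-track hit sets for reporting. No enrichment testing against a
genomic background is performed — the workflow reports proportions only.

## Chi-square comparison, and a documented discrepancy

`compare_groups` runs Pearson's chi-square on a 2×2 table via
`scipy.stats.chi2_contingency`, without continuity correction by default and
with Yates correction behind a flag; tests cross-check it against the closed
form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)). A zero margin is an error.

The published familial-vs-GWAS pleiotropy comparison prints X² = 4.65
(p = 0.03). No 2×2 table derivable from the published counts reproduces
this: 0/11 familial vs 19/42 GWAS colocalizations gives X² ≈ 7.757
uncorrected and ≈ 5.915 with Yates correction. The counting unit behind the
printed 4.65 is not reconstructible, so this package documents both of its
own formulas, exposes both corrections, and does not treat 4.65 as a
reference value.

## Variant profiling

Selection direction is inferred qualitatively from population minor-allele
frequencies: modern human-specific variants arose first in African
populations, so `freq_eur − freq_afr > δ` is called positive selection in
Europe and the reverse negative, with δ (`delta_min`) defaulting to 0.001.
The comparison in the source analyses is qualitative; δ is this package's
tolerance, kept small and configurable. Frequencies are taken exactly as
supplied (dbSNP per-population minor-allele frequencies); no re-polarization
by ancestral allele is attempted. Absent frequencies yield an indeterminate
call with a warning — a printed 0.0000 is a real frequency and is never
conflated with missing.

Allele age in generations converts to years at 25 years/generation. CADD
scores are carried through for reporting only; low deleteriousness is a
causality caveat in the source analyses, not a filter, so the CLI offers an
optional `--cadd-min` marker column instead of a hard cutoff.

Nearest-element search considers human-specific elements within a 500-kb
window (the vicinity convention used to link regulatory elements to genes;
configurable), with ties broken by (distance, start, track class) for
reproducible reports. The published observation that all 14 characterized
variants lie within 28 kb of their element is treated as an observed bound
verified over that table, not a search constraint. Containing-locus
assignment resolves multi-hits by source priority familial > GWAS and raises
on unresolved ties.

## Discovery cascade

Associations are retained iff p < 1e-6 — strictly, per the published
wording, so a p exactly at the cutoff is excluded. Retained SNPs are
assigned to pleiotropic loci by point-in-interval containment (no LD
clumping or window extension), restricted by default to loci replicated in
cognitive traits. Candidates from multiple studies merge by locus identity:
a locus hit by either study appears once with all supporting SNPs. Gene
assignment comes from the pleiotropic-locus table's gene column (loci
without one are "intergenic"); protein-coding status is an input list, never
inferred. The gene-family route (e.g. Semaphorins) is the same locus-level
characterization run on a user-supplied gene-to-interval table — no
family-specific code. Whether the original analysis deduplicated SNPs shared
by both GWAS sources is unknown; merged-by-locus semantics makes the
candidate count insensitive to that choice whenever shared SNPs fall in the
same loci.

Report flags use the published vocabulary: "No", a PSIregion subtype label
(e.g. hsInsert), or "Yes, glia"/"Yes, not glia". A candidate carries
human-specific features iff any of its PSIregion/hsCRE/HAR/MHS flags is not
"No".

## Expression statistics

Developmental stages are classed by label unit — post-conception weeks
(`pcw`) are prenatal, months (`mos`) infancy, years (`yrs`) later life —
rather than numeric age cutoffs; "1 yrs" onward counts as later. The
early-uplift score is

    log2((mean(prenatal ∪ infancy) + ε) / (mean(later) + ε)),

with ε = 0.01 RPKM (configurable) stabilizing logs of zero. A score of ~3–4
corresponds to the three-to-four log2-magnitudes early uplift seen for the
strongest early-development candidates. No binary "uplifted" call is made by
default; the threshold is left to the user.

Cell-type expression flags use the dot-plot convention: expressed iff the
fraction of cells expressing is ≥ 5% (inclusive). The human-restricted call
— expressed in human and in no non-human primate with an entry — is a
deliberately simple presence/absence surrogate for published human-specific
differential-expression calls and is labeled as such; it reproduces no
differential-expression statistics.

## Synthetic data

The generator emulates the *structure* of every input class on a toy genome
of three 10-Mb chromosomes — large enough for gap placement, small enough
for brute-force oracles — with all randomness from one seeded generator
(byte-identical outputs under a fixed seed). Defaults: 60 elements per
track of length 500–5,000 bp; locus counts 11 familial and 42 GWAS (the
real candidate-set sizes) plus 60 pleiotropic loci scaled to the toy
genome (the real 431 would saturate it); planted overlap fraction 0.5;
100 variants with a ±0.05 frequency shift; 1,000 associations with 20
planted sub-significant hits (p log-uniform in [1e-12, 1e-7]) inside 5
cognitive-replicated host loci and background p ≥ 1e-5; 20 genes of which 8
carry a planted log2 early/later ratio of 3 with 10% multiplicative noise
truncated at zero; 12 planted human-restricted gene/cell-type pairs.

Planted placement is direct, not rejection sampling: overlap loci are drawn
across a chosen human-specific element and non-overlap loci inside
element-free gaps, so recovery by the pipeline is exact by construction
(the binomial tolerance in tests covers boundary effects only). Because
generated pleiotropic loci may overlap one another, a planted association
can legitimately fall inside more than one cognitive-replicated locus; the
truth manifest therefore records *every* locus containing a planted hit, and
discovery is required to recover exactly that set. Planted p-values avoid
the exact 1e-6 cutoff except in the dedicated boundary fixture.

What the generator does **not** emulate: real annotation density, linkage
disequilibrium, allele-frequency spectra, gene models, or any biological
correlation between tracks. Passing tests on synthetic data demonstrate the
pipeline's logic (filtering, containment, counting, scoring, determinism),
not biological conclusions about real RD candidates; the desk-scale curated
tables provide the real-data anchors.

## Degenerate inputs and numerical conventions

Empty tracks are valid and yield no hits; an empty annotation set (or a
group with no members) has no defined percentage and raises. Duplicate
rsIDs keep the first occurrence with a warning. Missing numeric annotation
is stored as absent, never 0. Malformed table rows report file and line
number. Percentage rounding is half-up; threshold comparisons follow the
semantics stated above (fraction-expressing inclusive at 5%, sub-significance
strictly below 1e-6).

## Problem sizes

The analysis drivers and test suite run the full simulate → annotate →
summarize → discover → expression chain on the default toy configuration
(113 loci, 480 elements, 1,000 associations, 20 genes); randomized
cross-checks use 1,000 elements × 1,000 queries per seed for the overlap
oracle and 20 independent generator seeds for end-to-end discovery. These
sizes were chosen so every oracle can be brute force.

## Known limitations

* The full-scale recomputation of the published group proportions
  (90.9/100/89.3) and of the real nine-locus discovery requires the original
  supplementary interval tables and two externally hosted GWAS
  summary-statistic downloads; the pipeline implements the computation (see
  the `data/external/` layout in the acceptance test) but ships only the
  desk-scale published tables.
* Selection direction is a two-population frequency comparison, not a
  selection statistic (no iHS/F_ST); allele ages and CADD scores are
  ingested, never computed.
* No genome-build conversion: all inputs are assumed GRCh38.
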