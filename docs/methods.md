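# Methods

## Scope and data model

The package post-processes TE annotations of the kind RepeatMasker
produces: one record per annotated copy with an alignment score, percent
divergence from the family consensus, genomic coordinates, strand, and a
slash-delimited class/family label. Coordinates are kept 1-based
inclusive internally — the native convention of the `.out` format — and
converted to 0-based half-open only inside the interval arithmetic, so
parse → write → parse is bit-faithful on every field. Running external
annotators (RepeatMasker, RepeatModeler, LTR/LINE discovery tools) is out
of scope; their outputs are this package's inputs.

Records with divergence at or above 75% lie outside the domain of the
Jukes-Cantor correction. They are parsed with a warning and retained —
they still occupy sequence and belong in coverage — but are excluded from
age estimation and tallied in the landscape footer.

## Taxonomy

Classification uses an ordered rule table (case-insensitive glob patterns
on the class/family string and, optionally, the repeat name; first match
wins; anything unmatched is `Unclassified`). The default table encodes
the avian TE taxonomy: CR1, R2 and RTE LINE clades (everything else
`OtherLINE`), ERV1 / ERV2 / ERV3 LTR clades with RepBase's `ERVK` mapped
to ERV2 and `ERVL` to ERV3 (everything else `OtherLTR`), SINEs, and DNA
transposons including Helitrons. Because class strings vary across
library versions, the table is an editable TSV, not code.

## Coverage accounting

Annotators emit overlapping hits, so "percent of the genome" requires
attributing each base exactly once. Overlaps are resolved by alignment
score — the record with the higher Smith-Waterman score keeps the shared
bases; ties go to the earlier start, then input order — which mirrors the
annotator's own masking precedence. The accounting is therefore
conservative and internally consistent by construction: per-clade bp sum
exactly to type totals, the grand total never exceeds the genome length,
and masked + unmasked bp equal it exactly. The tests verify the
implementation base-for-base against an independent per-base sweep that
assigns every position to the highest-priority covering record.
Percentages are printed to two decimals; full precision is kept
internally.

## Age estimation

Observed divergence D is taken as printed in the annotation, CpG sites
included, with no CpG adjustment — which can make ages look somewhat
older. The correction and conversion are, in percent units,

    K = -300/4 * ln(1 - D * 4/300),      t = (K/100) / (2 r)

with r the species' neutral substitution rate per site per year. K ≥ D
always, K → D as D → 0, and the formula diverges as D → 75%. Each record
is aged independently from its own divergence, including fragments that
share a linkage id — fragment divergences are separate observations of
the same insertion, and aging them separately avoids inventing a joint
estimator the data model does not support.

Landscapes bin each record's raw span (bp) by its age in uniform
half-open [lo, hi) bins, default width 5 My, and report
100 × bp / genome length per class per bin. Raw spans (not
overlap-resolved spans) are used here deliberately: the landscape
describes the divergence distribution of the annotated copies, whereas
the coverage report describes masked bases; the two uses are documented
as intentionally different. The y-axis normalizes by total genome
length, not by total TE content. Summed over bins, each class's landscape
equals its raw coverage among aged records — a conservation property the
tests assert on every input.

## Library redundancy and the 80-80 rule

Two sequences are directly linked when their best local alignment
(match +1, mismatch −1, gap open −5, gap extend −1; both strands;
configurable) exceeds 80% identity and covers more than 80% of "their
length". Both thresholds are strict (">"), following the rule's wording.
"Their length" is read as the shorter sequence, so fragments are
absorbed into their parent family — the behavior redundancy removal
needs; `coverage_of="longer"` or `"both"` are available. Identity counts
matches over all alignment columns, gap columns included. Families are
the connected components of the link graph (single linkage, chosen
because the rule defines a pairwise relation, not a centroid); the
representative is the longest member (ties: lexicographically smallest
identifier), which best preserves the family's consensus span. The
statistic is computed on a canonical ordering of each pair, making it
exactly symmetric; alignments run through Biopython's `PairwiseAligner`,
and the tests check score-exact agreement with an independent full-matrix
Gotoh dynamic program, plus partition-exact agreement of the clustering
with brute-force all-pairs single linkage.

## Intactness screening

ORFs are ATG-to-stop spans in all six frames under the standard genetic
code, reported longest first, with lengths in aa excluding the stop; a
stop-to-stop mode is available where the ATG requirement is too strict.
ORF translations are aligned locally (BLOSUM62, gap open −11, extend −1)
against user-supplied reference proteins.

For LINEs: ORF2 is the longest ORF whose translation hits a reverse-
transcriptase reference (identity ≥ 0.25 over ≥ 200 aligned aa; both
configurable — these acceptance thresholds are package defaults, chosen
permissive because references may be distant homologs). The RT is called
intact when a single ORF's alignment covers ≥ 90% of a reference, i.e.
the RT span is uninterrupted by stops or frameshifts; this operationalizes
"intact RT" as in-frame coverage, an interpretation the user can tighten
or relax. ORF1 is any other ORF ≥ 100 aa upstream of ORF2 on the same
strand. The ladder is: full (ORF1 and ORF2 > 600 aa, strict) >
ORF2-only > ORF1-only > intact-RT-only > defective.

For ERVs: a domain is present when some ORF translation aligns to a
reference labeled ENV, GAG or POL (the label is read from the reference
identifier) and the matched span on the element strictly exceeds 480,
500 or 800 aa respectively; all three present ⇒ full ERV, at least one ⇒
partial, none ⇒ defective. Reference domain sequences are user-supplied;
the synthetic fixtures include stand-in reference proteins, labelled as
such.

## Synthetic data

The generator emulates the pipeline's inputs with full ground truth.

*Genomes.* Copies of a consensus are mutated under the Jukes-Cantor
process — substitutions only, all changes equally likely, so a planted
substitution level K (percent) yields an expected observed divergence
D = 75·(1 − e^(−4K/300)) — then placed without overlap at random
positions and strands in a random background. Planting at a true age
t uses K = 2rt, the inverse of the aging equation. The emitted
annotation carries each copy's realized divergence rounded to two
decimals (the text format's precision), and realized, not expected,
divergence drives the recovery tests. No indels are generated by
default, so realized divergence is the sole driver of estimated age; the
non-overlapping placement keeps generation independent of the overlap
resolver, which is exercised by separately constructed fixtures.

*Libraries.* Families are a random founder plus members diverged by a
chosen K (default 5%, comfortably inside the 80% identity threshold) and
optional truncated fragments; distinct families are independent random
sequences. A deterministic probe pair with evenly spaced mismatches
pins the identity threshold: every window of the pair has the same local
identity, so no sub-alignment can sneak above it.

*Elements.* ORFs of exact aa length are planted by back-translating
generated proteins with a stop-free codon table; spacers between ORFs
use a two-letter alphabet (T/C) that contains no ATG and no stop on
either strand, so planted reading frames are exactly the ones detected.
The stand-in RT reference is embedded verbatim in RT-bearing ORF2s, and
each ERV domain is a prefix of its reference protein, so matched spans
equal planted lengths exactly — including the deliberate boundary probes
(ORF2 of exactly 600 aa, POL of exactly 800 aa) that must not count as
full.

Identical config and seed give byte-identical outputs.

## What the synthetic tests do and do not show

Passing against generator truth demonstrates that the arithmetic,
thresholds, and bookkeeping are correct under the stated models. Real
annotations differ: divergence estimates embed alignment error and CpG
hypermutability, copies are nested and fragmented, libraries contain
chimeric models, and real RT/domain references are distant homologs
rather than embedded prefixes. Results on real genomes inherit those
caveats, and whole-genome tallies additionally depend on the annotator
and library versions used upstream.

## Numerical and design notes

- Problem sizes in the tests and the acceptance script (100 kb mutation
  checks, a 2.4 Mb genome with 200 × 10 kb copies, 20 libraries of ≤ 50
  sequences, 30 planted elements) are chosen to give tight sampling error
  at desk scale — e.g. the binomial error of observed divergence at
  100 kb is under 0.1 percentage points.
- Copies planted at exactly 15 My sit on a 5-My bin edge; estimated ages
  scatter symmetrically about it, so the modal landscape bin is whichever
  of the two adjacent bins received more mass. The acceptance check
  therefore accepts a modal bin whose closed interval touches 15 My.
- Optimal local alignments can be tie-ambiguous. The DP oracle therefore
  asserts exact score equality but identity/coverage only to 0.02, and
  the clustering fixtures keep pair similarities well away from the 0.80
  thresholds so that merge decisions are unambiguous.
- `jukes_cantor_K` uses `log1p` for accuracy at small D; domain checks
  are strict (`D < 75`).
- Age landscapes place an age exactly on a bin edge into the upper bin
  (half-open binning), and the last bin is extended to catch floating-
  point edge spill.

## Known limitations

- No Kimura-2-parameter or CpG-adjusted distances; no mutation-rate
  estimation.
- No `.align`/`.cat` annotation dialects, no GFF output, no
  per-chromosome coverage breakdowns.
- No HMM-based domain search, de novo repeat discovery, or LTR structure
  detection; screening quality is bounded by the supplied references.
- The generator does not model TE nesting, fragmentation, or indels
  (an indel-free mutation model is a simplification, not a claim about
  real repeat evolution).
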