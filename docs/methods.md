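# Methods

## Scope and data model

`rnasnv` operates on single-end short mRNA reads that have already been
mapped — once against a reference genome and once against a spliced
transcript library — by any mapper that emits SAM.  All internal coordinates
are 0-based half-open; SAM, pileup text and the gold-standard table convert
at the file boundary (1-based).  An alignment is a set of sorted,
non-overlapping reference blocks whose total length equals the read length;
gaps between blocks are splice skips (`N` CIGAR operations).  Insertions,
deletions and soft clips are out of scope: the supported alignments are
ungapped apart from splices, which matches the mappers this workflow is
designed around, and unsupported CIGAR operations fail loudly rather than
silently shifting coordinates.

Base qualities default to Phred+33; `--quality-offset 64` supports older
Illumina encodings, and qualities that go negative under the chosen offset
are reported as a configuration error rather than clamped.  Lane identity
comes from a per-file label when given, else from the record's read group.

## Coordinate transfer and merging

A transcript-space alignment covering mature-mRNA interval
$[t_s, t_e)$ is lifted to the genome by projecting the interval through the
transcript's exon map, emitting one genomic block per exon touched.  For a
minus-strand transcript, transcript base 0 is the last genomic base of the
last exon, so the projected interval is flipped, the read's strand toggles,
and bases/qualities/masks are reverse-complemented/reversed into genome
orientation.  The transfer preserves aligned length exactly and is inverted
by the exon map's genome-to-transcript direction; both properties are
enforced by tests over random exon structures on both strands.

Reads hitting several isoforms are collapsed *before* the merge decision:
if every hit lifts to the same (chromosome, strand, block structure), the
read is genuinely unique and one representative is kept.  Collapse demands
identical block structure, not mere overlap — overlap would merge
paralog-like near-hits that genuinely are ambiguous.

The merge decision table is keyed by each side's mapping status (unique /
multiple / unmapped) and, for dual-unique reads, agreement.  Agreement is
defined as same chromosome, strand and leftmost genomic position; block
structures may differ (a genome mapper reports a junction-spanning read as
a soft-clipped or contiguous alignment, the lifted transcript alignment as
spliced blocks), so strict start equality is the robust common denominator.
On an agreeing dual-unique read the genome-side record is emitted, since it
is the mapper's original genomic alignment; on one-sided uniqueness the
unique side is emitted.  Hard merging keeps (unique, unique, agree),
(unique, unmapped) and (unmapped, unique); soft merging adds
(unique, multiple) and (multiple, unique).  Row-by-row this makes the
hard-kept set a subset of the soft-kept set, which is also tested on
randomised inputs.  Reads unmapped on both sides are tallied and dropped.

## The genotype model

The posterior over the ten unordered diploid genotypes is prior times a
product of per-base likelihoods (README gives the formulas).  Numerical
choices:

* All accumulation is in log space with a max-subtraction normalisation;
  products of hundreds of terms of order $10^{-3}$ underflow doubles.
* $\varepsilon$ is capped at $\varepsilon_{\max} = 0.75$ so that
  $1-\varepsilon$ and $\tfrac12-\varepsilon/3$ remain positive at quality
  0.  The cap is defensive only: observations below quality 2 are discarded
  before they reach the model.
* Ties at equal posterior resolve to homozygous reference first, then
  lexicographically — the conservative no-variant outcome.  With zero
  observations the posterior equals the prior, all four homozygotes tie,
  and the reference genotype wins; no call is emitted at uncovered or
  N-reference loci.
* `variant_posterior` is $1 - P(\{\text{ref},\text{ref}\} \mid R)$, the
  quantity swept when trading sensitivity against specificity.
* The prior ignores strand, position, transition/transversion asymmetry
  and catalogue membership: a deliberately uniform model in which the data,
  through the quality scores, does all the work.

Two implementations coexist: a per-column reference implementation
(`genotype_posteriors`) and a vectorised path over column-compressed
observation arrays (`call_variants_from_store`) used at simulation scale.
They are held equal to $10^{-9}$ relative tolerance by tests, and the
reference path itself is checked against a direct probability-space
enumeration written independently in the test suite.

## Curation filters

*Aligned-read trimming* masks the first 1 and last 10 sequencing cycles of
each aligned read (defaults; both configurable).  Counting is in read
orientation because the degradation mechanism — de-phasing — is a function
of the sequencing cycle, so on reverse-strand alignments the trailing trim
lands on the genomic left end.  Alignments keep their coordinates: bases
sequenced correctly in the trimmed region already did their job anchoring
the mapping, and removing them from the raw read instead would change where
reads map.  The mask survives SAM round trips via a private `XM:Z`
bitstring tag.

*Start-locus cap*: at most $x$ reads are retained per (chromosome, start,
strand) key.  Strand is part of the key because opposite-strand reads
starting at one position cannot be PCR copies of each other.  Under the
cap, the $x$ reads with highest mean base quality survive, ties broken by
read id, making the result independent of input order and idempotent.

*Lane support and minimum-count vetoes* act on calls, not on observations:
they veto a variant call whose non-reference alleles lack support in the
required number of distinct lanes (or the required total count) but leave
the posterior itself untouched.  Applying them to the raw observations
would silently change the model's input, which is not what a veto is.  The
veto is per non-reference allele of the called genotype.

*Mismatch profile*: the per-cycle fraction of aligned reads mismatching the
reference, ignoring trim masks (the diagnostic is meant to justify the trim
parameters, so it must see the untrimmed data).

## Evaluation

Two scoring modes, both defined only at gold-standard loci.  Genotyping: TP
when the exact gold genotype is called at a non-reference locus; FP when
the call asserts an allele the (homozygous) gold genotype does not contain;
a gold heterozygote called homozygous-in-gold, or any uncalled locus, is
neutral, because losing one allele to coverage is not a calling error.  A
gold heterozygote called with a third allele (e.g. gold AC, call GG) is
counted as a genotyping FP — the printed rules do not cover this corner and
a genuinely wrong allele is being asserted.  Detection: TP when any variant
is flagged at a non-reference gold locus, FP when one is flagged at a
homozygous-reference gold locus.  Hence a hom-alt locus called heterozygous
is a detection TP but a genotyping FP.

Accuracy curves sweep the minimum `variant_posterior`; both TP and FP
counts are non-increasing in the threshold by construction.  Per-exon
average coverage is aligned-bases-overlapping / exon-length, with a helper
converting RPKM to coverage ($\text{cov} = \text{RPKM} \cdot T \cdot L
\cdot 10^{-9}$ for $T$ mapped reads of length $L$).  Coverage-binned
accuracy assigns each gold locus to the first containing exon (sorted
order) and, unlike curve scoring, counts uncalled/miscalled gold variants
as false negatives; bin edges are user-supplied.

## The simulator

The generator emulates: a random genome; non-overlapping genes of 1–10
exons on both strands; planted variants at rate $h$ (default 0.001) in
exonic sequence, a third of them homozygous non-reference (roughly the
population expectation for a diploid against a reference); reads of 33 bp
in 7 lanes (the era's typical run geometry) sampled from transcripts
proportionally to lognormal expression weights; a fair haplotype coin per
read; per-cycle qualities on a linear 5'→3' ramp (default 34→20); errors
replacing a base with one of the other three uniformly; exact-copy PCR
duplicates at a configurable rate; and optional pooling of several
individuals simulated on one genome.

Two deliberate idealisations matter for interpreting green tests.  First,
reads are emitted with their *true* alignments (in both transcript and
genomic coordinates), so mapping error is excluded by construction: passing
tests validate merging, filtering, genotyping and evaluation, not a
mapper.  Second, the reported quality and the injected error rate coincide
by default (a perfectly calibrated instrument).  Real 3' de-phasing
produces *miscalibrated* qualities — the instrument claims more accuracy
than it delivers — and that is the regime in which trimming helps; the
`true_error_5prime`/`true_error_3prime` knobs decouple the injected error
profile from the reported qualities to reproduce it, and
`true_error_shape` (an exponent on the cycle fraction; 1 = linear) lets the
injected errors concentrate sharply in the final cycles, the way real
de-phasing does — a linear ramp spreads miscalibration over mid-read cycles
that a trailing trim deliberately leaves alone.  With calibrated
qualities the Bayesian model simply absorbs 3' errors and trimming shows no
benefit, which is itself a correct prediction of the model.

Everything derives from one integer seed; identical configurations are
byte-identical across runs.

## Problem sizes in the shipped checks

The parameter-recovery check plants ~1000 variants (planting rate 0.01 over
~100 kb of exonic sequence across 100 transcripts — the rate is raised
above the default $h$ so the variant count, which is what the check is
about, is reached on a desk-scale genome) and samples 140k reads of
constant q=30 under uniform expression, giving ~44× mean exonic coverage.
Accuracy is measured at planted loci with pileup depth ≥ 20: transcript
ends cannot reach full depth because a read must start within one
read-length of the end to cover it, so a global depth floor is structurally
unattainable under transcript sampling.  The curation check uses 21k reads
whose reported quality is a constant 34 while the true error rate rises
from 0.1% to 15% with shape exponent 5 (so errors concentrate in the last
~8 cycles), plus 40% PCR duplication; the pooling check simulates three
individuals of 18k reads each.  These sizes keep the whole suite and the acceptance script
in the tens of seconds while leaving the measured effects far above noise.

## Known limitations

No indels, no paired-end awareness, no phasing, no quality recalibration,
no somatic (paired-sample) model, and no discovery of unannotated splice
junctions: a read from an unannotated junction would simply fail to map in
this framework's inputs.  The multiple-mapping status of input reads is
taken from mapper tags (NH/X0) or repeated read ids; if a mapper reports
only one alignment of a multi-hit read with no tag, that read is
misclassified as unique.  Pileup text input reconstructs observations but
not the originating reads, so read-level filters must be applied before
pileup generation.
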