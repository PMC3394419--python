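"""Accuracy evaluation of variant calls against a gold-standard genotype set.

Two scoring modes mirror the two questions one can ask of a caller:

* **detection** — was a variant flagged at this locus?  A true positive is a
  gold heterozygous or homozygous non-reference locus where the caller flags
  any variant; a false positive is a gold homozygous-reference locus flagged
  as variant.
* **genotyping** — was the exact genotype recovered?  A true positive is a
  gold non-reference locus called with exactly the gold genotype; a false
  positive is a homozygous gold locus where the call asserts an allele the
  gold genotype does not contain (calling a heterozygote at a homozygous
  non-reference locus is therefore a detection TP but a genotyping FP: an
  inexistent reference allele is asserted).

A gold heterozygote called homozygous-in-gold, or not called at all, is
*neutral* — absence of coverage for one allele is not the caller's error.
Sensitivity/specificity trade-off curves sweep the minimum posterior
probability of carrying a non-reference genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats_io import AlignedRead, ReferenceGenome, TranscriptModel
from .genotyper import Genotype, GenotypeCall

GoldSet = Mapping[Tuple[str, int], Genotype]


@dataclass(frozen=True)
class CallClassification:
    mode: str  # detection | genotyping
    status: str  # true_positive | false_positive | neutral


def classify_genotyping(
    gold: Genotype, call: Optional[GenotypeCall], reference_base: str
) -> CallClassification:
    """Score one gold-standard locus under the exact-genotype rule."""
    hom_ref = Genotype.homozygous(reference_base)
    called = call.genotype if call is not None else None
    if called == gold:
        status = "neutral" if gold == hom_ref else "true_positive"
    elif called is None:
        status = "neutral"
    elif gold.is_homozygous:
        # any differing call asserts an allele absent from a homozygous gold
        status = "false_positive"
    else:
        # gold heterozygous: homozygous-in-gold is a coverage artifact;
        # asserting a third allele is a genuine miscall
        in_gold = all(a in gold for a in called.alleles)
        status = "neutral" if in_gold else "false_positive"
    return CallClassification("genotyping", status)


def classify_detection(
    gold: Genotype, call: Optional[GenotypeCall], reference_base: str
) -> CallClassification:
    """Score one gold-standard locus under the variant-detected rule."""
    hom_ref = Genotype.homozygous(reference_base)
    flagged = call is not None and call.is_variant
    if gold == hom_ref:
        status = "false_positive" if flagged else "neutral"
    else:
        status = "true_positive" if flagged else "neutral"
    return CallClassification("detection", status)


_CLASSIFIERS = {"detection": classify_detection, "genotyping": classify_genotyping}


def classify_all(
    calls: Iterable[GenotypeCall],
    gold: GoldSet,
    mode: str = "genotyping",
    reference: Optional["ReferenceGenome"] = None,
) -> Dict[Tuple[str, int], CallClassification]:
    """Classify every gold locus given the call set (absent call = no call)."""
    classify = _CLASSIFIERS[mode]
    by_locus = {(c.chromosome, c.position): c for c in calls}
    out = {}
    for locus, genotype in gold.items():
        call = by_locus.get(locus)
        ref = _reference_base(locus, call, reference)
        if ref is None:
            # no call and no reference context: nothing to score
            out[locus] = CallClassification(mode, "neutral")
            continue
        out[locus] = classify(genotype, call, ref)
    return out


def _reference_base(
    locus: Tuple[str, int],
    call: Optional[GenotypeCall],
    reference: Optional["ReferenceGenome"],
) -> Optional[str]:
    if call is not None:
        return call.reference_base
    if reference is not None:
        base = reference.base(*locus)
        return base if base in "ACGT" else None
    return None


@dataclass
class AccuracyCurve:
    """(threshold, TP, FP) triples from a sweep over the variant-posterior cutoff."""

    mode: str
    points: List[Tuple[float, int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["threshold", "true_positives", "false_positives"])


def accuracy_curve(
    calls: Sequence[GenotypeCall],
    gold: GoldSet,
    thresholds: Sequence[float],
    mode: str = "genotyping",
) -> AccuracyCurve:
    """Sweep the minimum variant posterior and count TP/FP at each cutoff.

    At each threshold only calls with ``variant_posterior >= threshold``
    survive; each gold locus is then scored under the chosen mode.  Both
    counts are non-increasing in the threshold.
    """
    if not gold:
        raise ValueError("empty gold-standard set")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    classify = _CLASSIFIERS[mode]
    gold_calls = [
        (c, gold[(c.chromosome, c.position)])
        for c in calls
        if (c.chromosome, c.position) in gold
    ]
    points = []
    for threshold in thresholds:
        tp = fp = 0
        for call, genotype in gold_calls:
            kept = call if call.variant_posterior >= threshold else None
            status = classify(genotype, kept, call.reference_base).status
            tp += status == "true_positive"
            fp += status == "false_positive"
        points.append((float(threshold), tp, fp))
    return AccuracyCurve(mode, points)


@dataclass
class ExonCoverage:
    chromosome: str
    start: int
    end: int
    average_coverage: float


def exon_average_coverage(
    reads: Iterable[AlignedRead],
    exons: Iterable[Tuple[str, int, int]],
) -> List[ExonCoverage]:
    """Mean reads-per-base over each exon, from aligned block overlap."""
    exons = list(exons)
    for chrom, start, end in exons:
        if end <= start:
            raise ValueError(f"zero-length exon {chrom}:{start}-{end}")
    # difference-array coverage per chromosome
    maxima: Dict[str, int] = {}
    events: Dict[str, List[Tuple[int, int]]] = {}
    for read in reads:
        if not read.is_mapped:
            continue
        for s, e in read.blocks:
            events.setdefault(read.reference_name, []).append((s, e))
            maxima[read.reference_name] = max(maxima.get(read.reference_name, 0), e)
    for chrom, start, end in exons:
        maxima[chrom] = max(maxima.get(chrom, 0), end)
    coverage: Dict[str, np.ndarray] = {}
    for chrom, evs in events.items():
        diff = np.zeros(maxima[chrom] + 1, dtype=np.int64)
        for s, e in evs:
            diff[s] += 1
            diff[e] -= 1
        coverage[chrom] = np.cumsum(diff)[:-1]
    out = []
    for chrom, start, end in exons:
        cov = coverage.get(chrom)
        mean = float(cov[start:end].mean()) if cov is not None else 0.0
        out.append(ExonCoverage(chrom, start, end, mean))
    return out


def rpkm_to_coverage(rpkm: float, total_mapped_reads: int, read_length: int) -> float:
    """Average per-base coverage implied by an RPKM expression value.

    RPKM = reads on the exon / (exon length in kb * mapped reads in
    millions); multiplying back and spreading ``read_length`` bases per read
    over the exon gives coverage = RPKM * total_reads * read_length * 1e-9,
    independent of the exon length.
    """
    return rpkm * total_mapped_reads * read_length * 1e-9


def assign_to_exons(
    gold: GoldSet, exon_coverages: Sequence[ExonCoverage]
) -> Dict[Tuple[str, int], Optional[ExonCoverage]]:
    """First containing exon (in sorted order) per gold locus, None if intergenic."""
    ordered = sorted(exon_coverages, key=lambda e: (e.chromosome, e.start, e.end))
    out: Dict[Tuple[str, int], Optional[ExonCoverage]] = {}
    for chrom, pos in gold:
        hit = None
        for exon in ordered:
            if exon.chromosome == chrom and exon.start <= pos < exon.end:
                hit = exon
                break
        out[(chrom, pos)] = hit
    return out


def coverage_binned_accuracy(
    calls: Sequence[GenotypeCall],
    gold: GoldSet,
    exon_coverages: Sequence[ExonCoverage],
    bin_edges: Sequence[float],
    mode: str = "genotyping",
    reference: Optional["ReferenceGenome"] = None,
) -> pd.DataFrame:
    """TP/FP/FN percentages for gold variant loci grouped by exon coverage.

    Each gold locus is assigned the average coverage of the first exon
    containing it and dropped into ``bin_edges``-defined bins (loci in no
    exon land in an ``unassigned`` bin).  Unlike curve scoring, a gold
    variant locus that is uncalled or miscalled counts here as a false
    negative, so within a bin TP% + FN% = 100 over gold variant loci, with
    FP% expressed relative to the same denominator.
    """
    classifications = classify_all(calls, gold, mode=mode, reference=reference)
    assignment = assign_to_exons(gold, exon_coverages)
    edges = np.asarray(bin_edges, dtype=float)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    rows = {label: {"tp": 0, "fp": 0, "fn": 0, "gold_variants": 0} for label in labels}
    rows["unassigned"] = {"tp": 0, "fp": 0, "fn": 0, "gold_variants": 0}
    by_locus = {(c.chromosome, c.position): c for c in calls}
    for locus, genotype in gold.items():
        exon = assignment[locus]
        if exon is None:
            label = "unassigned"
        else:
            idx = int(np.digitize(exon.average_coverage, edges)) - 1
            if idx < 0 or idx >= len(labels):
                label = "unassigned"
            else:
                label = labels[idx]
        row = rows[label]
        status = classifications[locus].status
        call = by_locus.get(locus)
        ref = _reference_base(locus, call, reference)
        # without any reference context an uncovered locus is assumed variant
        # (gold tables in this toolkit normally list variant loci only)
        is_gold_variant = ref is None or genotype != Genotype.homozygous(ref)
        if is_gold_variant:
            row["gold_variants"] += 1
            if status == "true_positive":
                row["tp"] += 1
            else:
                row["fn"] += 1
        if status == "false_positive":
            row["fp"] += 1
    records = []
    for label, row in rows.items():
        n = row["gold_variants"]
        records.append(
            {
                "bin": label,
                "gold_variants": n,
                "tp_pct": 100.0 * row["tp"] / n if n else 0.0,
                "fp_pct": 100.0 * row["fp"] / n if n else 0.0,
                "fn_pct": 100.0 * row["fn"] / n if n else 0.0,
            }
        )
    return pd.DataFrame.from_records(records)
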