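"""Data-curation filters for aligned RNA-seq reads and variant calls.

Second-generation sequencing has systematic error structure that breaks the
random-error assumption of any probabilistic caller:

* base-calling errors accumulate toward the 3' end of reads (de-phasing);
  :func:`mismatch_profile` diagnoses this and :func:`trim_alignment` masks
  the affected cycles of each *aligned* read (the alignment itself keeps its
  coordinates, so correctly sequenced bases still anchored the mapping);
* PCR amplification can produce many copies of one fragment;
  :func:`start_locus_filter` caps the number of reads retained per
  (chromosome, start, strand) key;
* errors can be correlated within a sequencing lane;
  :func:`lane_support_filter` vetoes variant calls whose alternative allele
  is not seen in enough distinct lanes, and :func:`min_alt_count_filter`
  applies the simpler total-count threshold.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import AlignedRead, PileupColumn, ReferenceGenome
from .genotyper import GenotypeCall


@dataclass
class FilterConfig:
    """Curation parameters; ``None`` switches a filter off."""

    trim_leading: int = 1
    trim_trailing: int = 10
    max_reads_per_start: Optional[int] = None
    min_lanes: Optional[int] = None
    min_alt_observations: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("trim_leading", "trim_trailing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("max_reads_per_start", "min_lanes", "min_alt_observations"):
            value = getattr(self, name)
            if value is not None and value < 1:
                raise ValueError(f"{name} must be >= 1 or None")


def trim_alignment(
    read: AlignedRead, trim_leading: int = 1, trim_trailing: int = 10
) -> AlignedRead:
    """Mask the first ``trim_leading`` and last ``trim_trailing`` sequenced bases.

    Counting is in read orientation (sequencing cycles, 5'->3'), so on a
    reverse-strand alignment the trailing trim lands on the genomic left end.
    Alignment coordinates and blocks are untouched.  Returns a new read.
    """
    n = read.read_length
    cycle_mask = np.ones(n, dtype=bool)
    cycle_mask[:trim_leading] = False
    if trim_trailing:
        cycle_mask[n - trim_trailing:] = False
    if not cycle_mask.any():
        warnings.warn(
            f"read {read.read_id}: trimming {trim_leading}+{trim_trailing} masks "
            f"all {n} bases",
            stacklevel=2,
        )
    if read.strand == "-":
        cycle_mask = cycle_mask[::-1]
    return dataclasses.replace(read, mask=read.mask & cycle_mask, qualities=read.qualities.copy())


def trim_all(
    reads: Iterable[AlignedRead], trim_leading: int = 1, trim_trailing: int = 10
) -> List[AlignedRead]:
    return [
        trim_alignment(r, trim_leading, trim_trailing) if r.is_mapped else r
        for r in reads
    ]


def start_locus_filter(
    reads: Iterable[AlignedRead], max_reads_per_start: Optional[int]
) -> List[AlignedRead]:
    """Keep at most ``x`` reads per (chromosome, start, strand) key.

    Suppresses PCR amplification artifacts and, as a side effect, normalises
    the extreme coverage of highly expressed transcripts.  Under the cap, the
    ``x`` reads with highest mean base quality survive, ties broken by read
    id, so the outcome is independent of input order.  ``None`` disables.
    """
    reads = list(reads)
    if max_reads_per_start is None:
        return reads
    groups: Dict[Tuple[str, int, str], List[AlignedRead]] = {}
    unmapped: List[AlignedRead] = []
    for read in reads:
        if not read.is_mapped:
            unmapped.append(read)
            continue
        groups.setdefault((read.reference_name, read.start, read.strand), []).append(read)
    kept: List[AlignedRead] = []
    for key in sorted(groups):
        ranked = sorted(
            groups[key], key=lambda r: (-float(r.qualities.mean()), r.read_id)
        )
        kept.extend(ranked[:max_reads_per_start])
    kept.sort(key=lambda r: (r.reference_name, r.start, r.strand, r.read_id))
    return kept + unmapped


def _allele_observations(column: PileupColumn, allele: str):
    return [o for o in column.observations if o.base == allele]


def lane_support_filter(
    call: GenotypeCall, column: PileupColumn, min_lanes: Optional[int]
) -> bool:
    """Veto a variant call unless every called non-reference allele is seen in
    at least ``min_lanes`` distinct lanes.  Non-variant calls always pass."""
    if min_lanes is None or not call.is_variant:
        return True
    for allele in set(call.genotype.alleles):
        if allele == call.reference_base:
            continue
        lanes = {o.lane_id for o in _allele_observations(column, allele)}
        if len(lanes) < min_lanes:
            return False
    return True


def min_alt_count_filter(
    call: GenotypeCall, column: PileupColumn, min_alt_observations: Optional[int]
) -> bool:
    """Veto a variant call unless every called non-reference allele was observed
    at least ``min_alt_observations`` times (lanes ignored)."""
    if min_alt_observations is None or not call.is_variant:
        return True
    for allele in set(call.genotype.alleles):
        if allele == call.reference_base:
            continue
        if len(_allele_observations(column, allele)) < min_alt_observations:
            return False
    return True


@dataclass
class MismatchProfile:
    """Fraction of aligned reads mismatching the reference, per sequencing cycle."""

    fractions: np.ndarray  # indexed by cycle, 5'->3'
    counts: np.ndarray  # aligned reads contributing at each cycle

    def __len__(self) -> int:
        return len(self.fractions)


def mismatch_profile(
    reads: Iterable[AlignedRead], reference: ReferenceGenome
) -> MismatchProfile:
    """Per-cycle mismatch fractions of a set of aligned reads.

    In the absence of any positional bias this profile is flat; a sharp rise
    toward the 3' end is the de-phasing signature that motivates aligned-read
    trimming.  The diagnostic ignores trimming masks (it is meant to be run
    before deciding trim parameters) but skips N bases on either side.
    """
    mismatches: np.ndarray = np.zeros(0, dtype=np.int64)
    totals: np.ndarray = np.zeros(0, dtype=np.int64)
    for read in reads:
        if not read.is_mapped:
            continue
        n = read.read_length
        if n > len(totals):
            mismatches = np.pad(mismatches, (0, n - len(mismatches)))
            totals = np.pad(totals, (0, n - len(totals)))
        ref = np.concatenate(
            [
                np.frombuffer(
                    reference.fetch(read.reference_name, s, e).encode("ascii"), dtype="S1"
                )
                for s, e in read.blocks
            ]
        ).astype("U1")
        obs = np.frombuffer(read.bases.encode("ascii"), dtype="S1").astype("U1")
        usable = (obs != "N") & (ref != "N")
        cycles = read.cycles()
        np.add.at(totals, cycles[usable], 1)
        np.add.at(mismatches, cycles[usable & (obs != ref)], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals > 0, mismatches / np.maximum(totals, 1), 0.0)
    return MismatchProfile(fractions=fractions, counts=totals)
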