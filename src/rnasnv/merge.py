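"""Merging of genome-space and transcript-space alignments.

mRNA reads are mapped twice: against the reference genome and against a
spliced transcript library.  Transcript alignments are first transferred to
absolute genomic coordinates through each transcript's exon map (splicing the
alignment when it spans an exon junction, reverse-complementing for minus-
strand transcripts), and hits to several isoforms of one gene that land on
the same genomic location are collapsed into a single unique alignment.
The two sides are then reconciled read by read under one of two rule sets:

* **hard** merging keeps a read only when it is unique on both references
  and the two alignments agree, or unique on one reference and unmapped on
  the other;
* **soft** merging additionally keeps reads that are unique on one reference
  and multiply mapped on the other (the unique alignment is kept).

All other combinations are discarded.  Agreement means same chromosome,
same strand and same leftmost genomic position; on an agreeing dual-unique
read the genome alignment is emitted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formats_io import AlignedRead, TranscriptModel, reverse_complement, sort_reads


class MergeMode(enum.Enum):
    HARD = "hard"
    SOFT = "soft"


@dataclass
class ReadMappingPair:
    """One read's mapping outcome on the two references."""

    read_id: str
    genome_status: str  # unique | multiple | unmapped
    transcript_status: str
    genome_alignment: Optional[AlignedRead] = None
    transferred_alignment: Optional[AlignedRead] = None

    def __post_init__(self) -> None:
        if (self.genome_alignment is not None) != (self.genome_status == "unique"):
            raise ValueError(f"{self.read_id}: genome alignment present iff unique")
        if (self.transferred_alignment is not None) != (self.transcript_status == "unique"):
            raise ValueError(f"{self.read_id}: transcript alignment present iff unique")


def transfer_to_genome(alignment: AlignedRead, model: TranscriptModel) -> AlignedRead:
    """Lift a transcript-space alignment to genomic coordinates.

    The alignment's interval on the transcript is projected through the exon
    map, producing one genomic block per exon touched.  For a minus-strand
    transcript the read lands on the opposite genomic strand and its bases
    are reverse-complemented (qualities and mask reversed) into genome
    orientation.  Aligned length is preserved.
    """
    if alignment.reference_name != model.transcript_id:
        raise ValueError(
            f"alignment {alignment.read_id} is on {alignment.reference_name}, "
            f"not {model.transcript_id}"
        )
    t_start, t_end = alignment.start, alignment.end
    blocks = model.genomic_blocks(t_start, t_end)  # raises if out of range
    if model.strand == "-":
        strand = "-" if alignment.strand == "+" else "+"
        bases = reverse_complement(alignment.bases)
        qualities = alignment.qualities[::-1].copy()
        mask = alignment.mask[::-1].copy()
    else:
        strand = alignment.strand
        bases = alignment.bases
        qualities = alignment.qualities.copy()
        mask = alignment.mask.copy()
    return AlignedRead(
        read_id=alignment.read_id,
        lane_id=alignment.lane_id,
        reference_name=model.chromosome,
        strand=strand,
        blocks=blocks,
        bases=bases,
        qualities=qualities,
        mapping_status=alignment.mapping_status,
        mask=mask,
    )


def collapse_isoform_hits(
    alignments: Sequence[AlignedRead],
) -> Tuple[str, Optional[AlignedRead]]:
    """Collapse a read's multiple transcript hits already lifted to the genome.

    Hits to different isoforms of one gene often describe the same genomic
    location; if every alignment shares chromosome, strand and identical
    block structure, the read is genuinely unique and one representative is
    kept.  Otherwise the read is multiply mapped.
    """
    if not alignments:
        raise ValueError("collapse_isoform_hits: empty alignment list")
    first = alignments[0]
    signature = (first.reference_name, first.strand, first.blocks)
    for aln in alignments[1:]:
        if (aln.reference_name, aln.strand, aln.blocks) != signature:
            return ("multiple", None)
    rep = first
    if rep.mapping_status != "unique":
        rep = AlignedRead(
            read_id=rep.read_id,
            lane_id=rep.lane_id,
            reference_name=rep.reference_name,
            strand=rep.strand,
            blocks=rep.blocks,
            bases=rep.bases,
            qualities=rep.qualities.copy(),
            mapping_status="unique",
            mask=rep.mask.copy(),
        )
    return ("unique", rep)


def alignments_agree(genome_alignment: AlignedRead, transferred: AlignedRead) -> bool:
    """True iff same chromosome, same strand and same leftmost position."""
    return (
        genome_alignment.reference_name == transferred.reference_name
        and genome_alignment.strand == transferred.strand
        and genome_alignment.start == transferred.start
    )


def _category(pair: ReadMappingPair) -> str:
    if pair.genome_status == "unique" and pair.transcript_status == "unique":
        agree = alignments_agree(pair.genome_alignment, pair.transferred_alignment)
        return f"unique/unique/{'agree' if agree else 'disagree'}"
    return f"{pair.genome_status}/{pair.transcript_status}"


#: Decision table: category -> (kept under hard, kept under soft, which side).
_DECISIONS: Dict[str, Tuple[bool, bool, str]] = {
    "unique/unique/agree": (True, True, "genome"),
    "unique/unique/disagree": (False, False, "-"),
    "unique/multiple": (False, True, "genome"),
    "unique/unmapped": (True, True, "genome"),
    "multiple/unique": (False, True, "transcript"),
    "multiple/multiple": (False, False, "-"),
    "multiple/unmapped": (False, False, "-"),
    "unmapped/unique": (True, True, "transcript"),
    "unmapped/multiple": (False, False, "-"),
    "unmapped/unmapped": (False, False, "-"),
}

MERGE_CATEGORIES: Tuple[str, ...] = tuple(_DECISIONS)


def merge_decision(
    pair: ReadMappingPair, mode: MergeMode
) -> Tuple[Optional[AlignedRead], str]:
    """Apply the decision table to one read; returns (kept alignment or None, category)."""
    category = _category(pair)
    keep_hard, keep_soft, side = _DECISIONS[category]
    keep = keep_hard if mode is MergeMode.HARD else keep_soft
    if not keep:
        return (None, category)
    kept = pair.genome_alignment if side == "genome" else pair.transferred_alignment
    return (kept, category)


def build_pairs(
    genome_reads: Iterable[AlignedRead],
    transcript_reads: Iterable[AlignedRead],
    models: Iterable[TranscriptModel],
) -> List[ReadMappingPair]:
    """Pair up the two mapping runs of one read set.

    Transcript-side alignments are transferred to genomic coordinates and
    isoform-collapsed before status classification, so a read hitting several
    isoforms of one gene enters the decision table as transcript-unique.
    """
    model_by_id = {m.transcript_id: m for m in models}
    genome: Dict[str, List[AlignedRead]] = {}
    for read in genome_reads:
        genome.setdefault(read.read_id, []).append(read)
    transcript: Dict[str, List[AlignedRead]] = {}
    for read in transcript_reads:
        transcript.setdefault(read.read_id, []).append(read)

    pairs: List[ReadMappingPair] = []
    for read_id in sorted(set(genome) | set(transcript)):
        g_alns = [r for r in genome.get(read_id, []) if r.is_mapped]
        if not g_alns:
            g_status, g_aln = "unmapped", None
        elif len(g_alns) > 1 or g_alns[0].mapping_status == "multiple":
            g_status, g_aln = "multiple", None
        else:
            g_status, g_aln = "unique", g_alns[0]

        t_alns = [r for r in transcript.get(read_id, []) if r.is_mapped]
        if not t_alns:
            t_status, t_aln = "unmapped", None
        else:
            transferred = []
            for aln in t_alns:
                model = model_by_id.get(aln.reference_name)
                if model is None:
                    raise KeyError(
                        f"read {read_id}: transcript {aln.reference_name} "
                        "missing from the annotation"
                    )
                transferred.append(transfer_to_genome(aln, model))
            t_status, t_aln = collapse_isoform_hits(transferred)
            if t_status == "unique" and len(t_alns) == 1 and t_alns[0].mapping_status == "multiple":
                # mapper flagged more hits than we saw; trust the flag
                t_status, t_aln = "multiple", None
        pairs.append(
            ReadMappingPair(
                read_id=read_id,
                genome_status=g_status,
                transcript_status=t_status,
                genome_alignment=g_aln,
                transferred_alignment=t_aln,
            )
        )
    return pairs


def merge_run(
    genome_reads: Iterable[AlignedRead],
    transcript_reads: Iterable[AlignedRead],
    models: Iterable[TranscriptModel],
    mode: MergeMode,
) -> Tuple[List[AlignedRead], Dict[str, int]]:
    """Full merge of one lane: pair, decide, sort; returns (kept reads, counts).

    ``counts`` tallies every decision-table category seen plus ``kept``.
    The output has at most one record per read id and is coordinate-sorted.
    """
    counts: Dict[str, int] = {cat: 0 for cat in MERGE_CATEGORIES}
    counts["kept"] = 0
    kept: List[AlignedRead] = []
    for pair in build_pairs(genome_reads, transcript_reads, models):
        alignment, category = merge_decision(pair, mode)
        counts[category] += 1
        if alignment is not None:
            if alignment.mapping_status != "unique":
                alignment.mapping_status = "unique"
            kept.append(alignment)
            counts["kept"] += 1
    return (sort_reads(kept), counts)
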