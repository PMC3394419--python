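"""Readers, writers and core containers for the toolkit's file formats.

Everything internal is 0-based, half-open; SAM, pileup text and gold-standard
tables are 1-based at the file boundary.  SAM parsing and writing go through
pysam; FASTA through Biopython.  Supported formats:

* SAM alignments (mapped reads against a genome or a transcript library),
* FASTA reference sequences,
* a tab-separated transcript annotation (transcript, gene, chromosome,
  strand, comma-separated ``start-end`` exon intervals),
* a plain-text pileup (one line per covered locus),
* a tab-separated gold-standard genotype table (chromosome, position,
  two-letter genotype).
"""

from __future__ import annotations

import array
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyper import MIN_BASE_QUALITY, Genotype

PathOrStream = Union[str, Path, IO[str]]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-value -> base code (A=0 C=1 G=2 T=3, anything else 4)
_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i

#: Placeholder contig length used when a headerless SAM needs a synthesised @SQ line.
_DEFAULT_CONTIG_LENGTH = 2 ** 29


class SamFormatError(ValueError):
    """A malformed or unsupported SAM record."""


class AnnotationError(ValueError):
    """An invalid transcript annotation record."""


class GoldStandardError(ValueError):
    """An invalid gold-standard genotype record."""


class ConfigurationError(ValueError):
    """An invalid I/O configuration (e.g. unknown quality encoding)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """One read's alignment in reference coordinates.

    ``blocks`` are sorted, non-overlapping half-open intervals whose total
    length equals the read length (gaps between blocks are splice skips).
    ``bases`` and ``qualities`` are stored in reference orientation, as in SAM;
    for a reverse-strand read, sequencing cycle 0 is therefore the last base.
    ``mask`` flags which bases may feed the genotyper (trimming clears it).
    """

    read_id: str
    lane_id: str
    reference_name: str
    strand: str  # "+" or "-"
    blocks: Tuple[Tuple[int, int], ...]
    bases: str
    qualities: np.ndarray
    mapping_status: str = "unique"  # unique | multiple | unmapped
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if self.mask is None:
            self.mask = np.ones(len(self.bases), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")
        if self.mapping_status not in ("unique", "multiple", "unmapped"):
            raise ValueError(f"bad mapping status: {self.mapping_status!r}")
        if len(self.qualities) != len(self.bases) or len(self.mask) != len(self.bases):
            raise ValueError(f"read {self.read_id}: bases/qualities/mask length mismatch")
        if np.any(self.qualities < 0):
            raise ValueError(f"read {self.read_id}: negative quality score")
        if self.mapping_status != "unmapped":
            total = 0
            prev_end = None
            for s, e in self.blocks:
                if e <= s:
                    raise ValueError(f"read {self.read_id}: empty block [{s},{e})")
                if prev_end is not None and s < prev_end:
                    raise ValueError(f"read {self.read_id}: blocks overlap or are unsorted")
                prev_end = e
                total += e - s
            if total != len(self.bases):
                raise ValueError(
                    f"read {self.read_id}: block length {total} != read length {len(self.bases)}"
                )

    @property
    def is_mapped(self) -> bool:
        return self.mapping_status != "unmapped"

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def read_length(self) -> int:
        return len(self.bases)

    def reference_positions(self) -> np.ndarray:
        """Genomic position of every base, in storage (reference) order."""
        return np.concatenate([np.arange(s, e) for s, e in self.blocks])

    def cycles(self) -> np.ndarray:
        """Sequencing cycle (5'->3' read offset) of every base, in storage order."""
        n = self.read_length
        c = np.arange(n)
        return c if self.strand == "+" else c[::-1].copy()


@dataclass
class TranscriptModel:
    """A transcript's spliced structure: chromosome, strand, ordered exons.

    Defines the bijection between transcript coordinates (0-based along the
    mature mRNA, 5'->3') and genomic coordinates.  For a reverse-strand
    transcript, transcript base 0 is the *last* genomic base of the last exon.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: strand must be '+' or '-'")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        self.exons = tuple(exons)
        self._cumulative = np.cumsum([0] + [e - s for s, e in exons])

    @property
    def length(self) -> int:
        return int(self._cumulative[-1])

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def genomic_blocks(self, t_start: int, t_end: int) -> Tuple[Tuple[int, int], ...]:
        """Project transcript interval [t_start, t_end) to genomic blocks.

        Blocks are returned in genomic order regardless of strand.
        """
        if not 0 <= t_start < t_end <= self.length:
            raise ValueError(
                f"{self.transcript_id}: interval [{t_start},{t_end}) outside "
                f"transcript of length {self.length}"
            )
        if self.strand == "-":  # flip into genomic-order mature coordinates
            t_start, t_end = self.length - t_end, self.length - t_start
        blocks = []
        for (s, e), offset in zip(self.exons, self._cumulative[:-1]):
            lo = max(t_start, int(offset))
            hi = min(t_end, int(offset) + (e - s))
            if lo < hi:
                blocks.append((s + lo - int(offset), s + hi - int(offset)))
        return tuple(blocks)

    def genomic_position(self, t: int) -> int:
        """Genomic coordinate of transcript base ``t``."""
        (block,) = self.genomic_blocks(t, t + 1)
        return block[0]

    def transcript_position(self, genomic: int) -> int:
        """Transcript coordinate of genomic base ``genomic`` (must be exonic)."""
        for (s, e), offset in zip(self.exons, self._cumulative[:-1]):
            if s <= genomic < e:
                u = int(offset) + genomic - s
                return u if self.strand == "+" else self.length - 1 - u
        raise ValueError(f"{self.transcript_id}: position {genomic} is not exonic")

    def spliced_sequence(self, genome: "ReferenceGenome") -> str:
        """Mature mRNA sequence (reverse-complemented for '-' transcripts)."""
        seq = "".join(genome.fetch(self.chromosome, s, e) for s, e in self.exons)
        return seq if self.strand == "+" else reverse_complement(seq)


@dataclass
class BaseObservation:
    """One aligned base spanning a locus."""

    base: str
    quality: int
    lane_id: str
    read_position: int  # sequencing cycle, 5'->3'
    read_start: int  # genomic start of the source read

    def __post_init__(self) -> None:
        if self.base not in "ACGTN":
            raise ValueError(f"bad observed base {self.base!r}")
        if self.quality < 0:
            raise ValueError("negative quality")


@dataclass
class PileupColumn:
    """All usable base observations spanning one genomic locus."""

    chromosome: str
    position: int  # 0-based
    reference_base: str
    observations: List[BaseObservation] = field(default_factory=list)

    @property
    def coverage(self) -> int:
        return len(self.observations)


class ReferenceGenome:
    """In-memory reference sequences with per-base and interval access.

    Missing chromosomes or out-of-range positions yield ``N`` (with a one-time
    warning per chromosome) rather than an error, so pileups over partially
    covered references still stream.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        self._arrays: Dict[str, np.ndarray] = {}
        self._warned: set = set()

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ReferenceGenome":
        with open(path) as handle:
            return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")})

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self._seqs

    @property
    def chromosomes(self) -> List[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def sequence(self, chromosome: str) -> str:
        return self._seqs[chromosome]

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        seq = self._seqs.get(chromosome)
        if seq is None:
            self._warn(chromosome)
            return "N" * (end - start)
        if start < 0 or end > len(seq):
            self._warn(chromosome)
            return "".join(self.base(chromosome, p) for p in range(start, end))
        return seq[start:end]

    def base(self, chromosome: str, position: int) -> str:
        seq = self._seqs.get(chromosome)
        if seq is None or not 0 <= position < len(seq):
            self._warn(chromosome)
            return "N"
        return seq[position]

    def fetch_array(self, chromosome: str, positions: np.ndarray) -> np.ndarray:
        """Reference base at each of an array of positions (``N`` if unavailable)."""
        seq = self._seqs.get(chromosome)
        if seq is None:
            self._warn(chromosome)
            return np.full(len(positions), "N")
        arr = self._arrays.get(chromosome)
        if arr is None:
            arr = np.frombuffer(seq.encode("ascii"), dtype="S1").astype("U1")
            self._arrays[chromosome] = arr
        out = np.full(len(positions), "N")
        ok = (positions >= 0) & (positions < len(arr))
        if not ok.all():
            self._warn(chromosome)
        out[ok] = arr[positions[ok]]
        return out

    def _warn(self, chromosome: str) -> None:
        if chromosome not in self._warned:
            self._warned.add(chromosome)
            warnings.warn(
                f"reference base unavailable on {chromosome!r}; emitting N",
                stacklevel=3,
            )


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _as_text(source: PathOrStream) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    with open(source) as handle:  # type: ignore[arg-type]
        return handle.read()


def parse_sam(
    source: PathOrStream,
    lane_id: Optional[str] = None,
    quality_offset: int = 33,
) -> List[AlignedRead]:
    """Parse a SAM file or stream into :class:`AlignedRead` records.

    ``lane_id`` labels every read from this file; when absent, the record's
    read group (RG tag) is used, else ``"lane1"``.  ``quality_offset`` selects
    the FASTQ quality encoding (33 for Sanger/modern Illumina, 64 for
    2009-era Illumina).  Mapping status is ``unmapped`` for the unmapped flag,
    ``multiple`` when an NH/X0 tag reports more than one hit or when the same
    read id occurs on several mapped records, else ``unique``.  A header is
    optional; missing @SQ lines are synthesised.  Only M/=/X, N and H CIGAR
    operations are supported (the toolkit's alignments are ungapped apart
    from splices).
    """
    if quality_offset not in (33, 64):
        raise ConfigurationError(f"unknown quality encoding offset {quality_offset}")
    text = _as_text(source)
    lines = text.splitlines()
    has_sq = any(line.startswith("@SQ") for line in lines)
    if not has_sq:
        refs: List[str] = []
        seen = set()
        for line in lines:
            if line.startswith("@") or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) > 2 and fields[2] != "*" and fields[2] not in seen:
                seen.add(fields[2])
                refs.append(fields[2])
        header = "".join(f"@SQ\tSN:{r}\tLN:{_DEFAULT_CONTIG_LENGTH}\n" for r in refs)
        text = header + text

    reads: List[AlignedRead] = []
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as tmp:
        tmp.write(text)
        tmp_path = tmp.name
    try:
        with pysam.AlignmentFile(tmp_path, "r", check_sq=False) as sam:
            for record_no, rec in enumerate(sam, start=1):
                try:
                    reads.append(_convert_record(rec, lane_id, quality_offset))
                except ConfigurationError:
                    raise
                except ValueError as exc:
                    raise SamFormatError(f"SAM record {record_no}: {exc}") from exc
    finally:
        os.unlink(tmp_path)

    # duplicated read ids among mapped records imply multiple mapping
    counts: Dict[str, int] = {}
    for read in reads:
        if read.is_mapped:
            counts[read.read_id] = counts.get(read.read_id, 0) + 1
    for read in reads:
        if read.is_mapped and counts.get(read.read_id, 0) > 1:
            read.mapping_status = "multiple"
    return reads


def _convert_record(
    rec: "pysam.AlignedSegment", lane_id: Optional[str], quality_offset: int
) -> AlignedRead:
    lane = lane_id
    if lane is None:
        lane = rec.get_tag("RG") if rec.has_tag("RG") else "lane1"
    bases = (rec.query_sequence or "").upper()
    quals = (
        np.array(rec.query_qualities, dtype=np.int16)
        if rec.query_qualities is not None
        else np.zeros(len(bases), dtype=np.int16)
    )
    if quality_offset == 64:
        quals = quals - 31  # pysam decodes as Phred+33; re-base to Phred+64
        if len(quals) and quals.min() < 0:
            raise ConfigurationError(
                f"read {rec.query_name}: qualities below 0 under Phred+64; "
                "wrong --quality-offset?"
            )
    mask = None
    if rec.has_tag("XM"):
        tag = rec.get_tag("XM")
        if isinstance(tag, str) and set(tag) <= {"0", "1"} and len(tag) == len(bases):
            mask = np.frombuffer(tag.encode(), dtype="S1") == b"1"

    if rec.is_unmapped:
        return AlignedRead(
            read_id=rec.query_name,
            lane_id=lane,
            reference_name="*",
            strand="+",
            blocks=(),
            bases=bases,
            qualities=quals,
            mapping_status="unmapped",
            mask=mask,
        )

    blocks: List[Tuple[int, int]] = []
    pos = rec.reference_start
    for op, length in rec.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op == 3:  # N: splice skip
            pos += length
        elif op == 5:  # H: hard clip, no bases stored
            continue
        else:
            raise ValueError(f"unsupported CIGAR operation {'MIDNSHP=XB'[op]}")

    status = "unique"
    for tag in ("NH", "X0"):
        if rec.has_tag(tag) and int(rec.get_tag(tag)) > 1:
            status = "multiple"
    return AlignedRead(
        read_id=rec.query_name,
        lane_id=lane,
        reference_name=rec.reference_name,
        strand="-" if rec.is_reverse else "+",
        blocks=tuple(blocks),
        bases=bases,
        qualities=quals,
        mapping_status=status,
        mask=mask,
    )


def check_sorted(reads: Iterable[AlignedRead]) -> None:
    """Raise if mapped reads are not sorted by (chromosome, position)."""
    last: Optional[Tuple[str, int]] = None
    for read in reads:
        if not read.is_mapped:
            continue
        key = (read.reference_name, read.start)
        if last is not None and key < last:
            raise ValueError(
                f"alignments not sorted: read {read.read_id} at "
                f"{key[0]}:{key[1] + 1} after {last[0]}:{last[1] + 1}"
            )
        last = key


def sort_reads(reads: Iterable[AlignedRead]) -> List[AlignedRead]:
    """Sort by chromosome and position; unmapped reads go last."""
    return sorted(
        reads,
        key=lambda r: (not r.is_mapped, r.reference_name, r.start if r.is_mapped else 0, r.read_id),
    )


def _cigar_string(read: AlignedRead) -> str:
    parts = []
    prev_end = None
    for s, e in read.blocks:
        if prev_end is not None:
            parts.append(f"{s - prev_end}N")
        parts.append(f"{e - s}M")
        prev_end = e
    return "".join(parts)


def write_sam(
    reads: Sequence[AlignedRead],
    path: Union[str, Path],
    reference_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write reads to a SAM file, coordinate-sorted input required.

    Lane identity goes to the RG tag (with @RG header lines), a ``multiple``
    mapping status to an NH:i:2 tag, and any non-trivial trimming mask to a
    private XM:Z bitstring tag so a later stage can recover it.
    """
    check_sorted(r for r in reads if r.is_mapped)
    lengths: Dict[str, int] = dict(reference_lengths or {})
    for read in reads:
        if read.is_mapped:
            lengths[read.reference_name] = max(lengths.get(read.reference_name, 0), read.end)
    lanes = sorted({read.lane_id for read in reads})
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(lengths[name])} for name in sorted(lengths)],
        "RG": [{"ID": lane} for lane in lanes],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.bases
            seg.query_qualities = array.array("B", [int(q) for q in read.qualities])
            tags = [("RG", read.lane_id)]
            if read.is_mapped:
                seg.flag = 16 if read.strand == "-" else 0
                seg.reference_name = read.reference_name
                seg.reference_start = read.start
                seg.mapping_quality = 0 if read.mapping_status == "multiple" else 60
                seg.cigarstring = _cigar_string(read)
                if read.mapping_status == "multiple":
                    tags.append(("NH", 2))
            else:
                seg.flag = 4
            if read.mask is not None and not read.mask.all():
                tags.append(("XM", "".join("1" if m else "0" for m in read.mask)))
            seg.set_tags(tags)
            out.write(seg)


# ---------------------------------------------------------------------------
# Observation store and pileup
# ---------------------------------------------------------------------------


class ObservationStore:
    """Column-compressed base observations, sorted by position per chromosome.

    Holds, for every usable aligned base (unmasked, quality >= 2, not N),
    parallel arrays of genomic position, base code, quality, lane code,
    sequencing cycle and source-read start.  Feeds both the vectorised
    genotyping path and per-column :class:`PileupColumn` construction.
    """

    def __init__(self) -> None:
        self.lane_names: List[str] = []
        self._lane_codes: Dict[str, int] = {}
        self._data: Dict[str, Dict[str, np.ndarray]] = {}

    @classmethod
    def from_reads(
        cls, reads: Iterable[AlignedRead], min_quality: int = MIN_BASE_QUALITY
    ) -> "ObservationStore":
        store = cls()
        buffers: Dict[str, Dict[str, list]] = {}
        for read in reads:
            if not read.is_mapped:
                continue
            lane = store._lane_codes.setdefault(read.lane_id, len(store.lane_names))
            if lane == len(store.lane_names):
                store.lane_names.append(read.lane_id)
            codes = _BASE_CODE[np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8)]
            keep = read.mask & (read.qualities >= min_quality) & (codes < 4)
            if not keep.any():
                continue
            pos = read.reference_positions()[keep]
            buf = buffers.setdefault(
                read.reference_name,
                {"pos": [], "base": [], "qual": [], "lane": [], "cycle": [], "start": []},
            )
            buf["pos"].append(pos.astype(np.int64))
            buf["base"].append(codes[keep])
            buf["qual"].append(read.qualities[keep].astype(np.int16))
            buf["lane"].append(np.full(keep.sum(), lane, dtype=np.int32))
            buf["cycle"].append(read.cycles()[keep].astype(np.int32))
            buf["start"].append(np.full(keep.sum(), read.start, dtype=np.int64))
        for chrom, buf in buffers.items():
            arrays = {k: np.concatenate(v) for k, v in buf.items()}
            order = np.argsort(arrays["pos"], kind="stable")
            store._data[chrom] = {k: v[order] for k, v in arrays.items()}
        return store

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._data)

    @property
    def total_observations(self) -> int:
        return sum(len(d["pos"]) for d in self._data.values())

    def arrays(self, chromosome: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        d = self._data[chromosome]
        return d["pos"], d["base"], d["qual"]

    def _slice(self, chromosome: str, lo: int, hi: int) -> Dict[str, np.ndarray]:
        return {k: v[lo:hi] for k, v in self._data[chromosome].items()}

    def column(
        self, chromosome: str, position: int, reference: Optional[ReferenceGenome] = None
    ) -> PileupColumn:
        """The pileup column at one locus (empty if uncovered)."""
        ref_base = reference.base(chromosome, position) if reference else "N"
        col = PileupColumn(chromosome, position, ref_base)
        if chromosome not in self._data:
            return col
        pos = self._data[chromosome]["pos"]
        lo, hi = np.searchsorted(pos, [position, position + 1])
        s = self._slice(chromosome, int(lo), int(hi))
        for b, q, ln, cy, st in zip(s["base"], s["qual"], s["lane"], s["cycle"], s["start"]):
            col.observations.append(
                BaseObservation("ACGT"[b], int(q), self.lane_names[ln], int(cy), int(st))
            )
        return col

    def columns(self, reference: ReferenceGenome) -> Iterator[PileupColumn]:
        """Iterate sorted pileup columns over every covered locus."""
        for chrom in self.chromosomes:
            pos = self._data[chrom]["pos"]
            if len(pos) == 0:
                continue
            upos, starts = np.unique(pos, return_index=True)
            bounds = np.append(starts, len(pos))
            ref_bases = reference.fetch_array(chrom, upos)
            for i, p in enumerate(upos):
                col = PileupColumn(chrom, int(p), str(ref_bases[i]))
                s = self._slice(chrom, int(bounds[i]), int(bounds[i + 1]))
                for b, q, ln, cy, st in zip(
                    s["base"], s["qual"], s["lane"], s["cycle"], s["start"]
                ):
                    col.observations.append(
                        BaseObservation("ACGT"[b], int(q), self.lane_names[ln], int(cy), int(st))
                    )
                yield col


def build_pileup(
    reads: Iterable[AlignedRead],
    reference: ReferenceGenome,
    min_quality: int = MIN_BASE_QUALITY,
) -> Iterator[PileupColumn]:
    """Pileup columns over every covered locus of coordinate-sorted reads.

    Masked bases (from trimming), bases below ``min_quality`` (the model
    discards quality 0 and 1 calls) and N bases never become observations.
    """
    store = ObservationStore.from_reads(reads, min_quality=min_quality)
    return store.columns(reference)


def write_pileup(columns: Iterable[PileupColumn], sink: PathOrStream) -> None:
    """Write pileup text: chrom, 1-based pos, ref base, then one
    ``base:quality:lane:readpos:readstart`` field per observation (readstart
    1-based)."""
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink  # type: ignore[arg-type]
    try:
        for col in columns:
            obs = "\t".join(
                f"{o.base}:{o.quality}:{o.lane_id}:{o.read_position}:{o.read_start + 1}"
                for o in col.observations
            )
            line = f"{col.chromosome}\t{col.position + 1}\t{col.reference_base}"
            handle.write(line + ("\t" + obs if obs else "") + "\n")
    finally:
        if own:
            handle.close()


def parse_pileup(source: PathOrStream) -> Iterator[PileupColumn]:
    """Parse the pileup text format written by :func:`write_pileup`."""
    text = _as_text(source)
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"pileup line {line_no}: expected at least 3 fields")
        col = PileupColumn(fields[0], int(fields[1]) - 1, fields[2])
        for token in fields[3:]:
            base, qual, lane, readpos, readstart = token.rsplit(":", 4)
            col.observations.append(
                BaseObservation(base, int(qual), lane, int(readpos), int(readstart) - 1)
            )
        yield col


# ---------------------------------------------------------------------------
# Transcript annotation
# ---------------------------------------------------------------------------


def parse_transcript_annotation(source: PathOrStream) -> List[TranscriptModel]:
    """Parse the tab-separated transcript table.

    Columns: transcript_id, gene_id, chromosome, strand, exons as
    comma-separated ``start-end`` half-open 0-based intervals (any order in
    the file; the model is canonically sorted).  Lines starting with ``#``
    are comments.
    """
    models: List[TranscriptModel] = []
    for line_no, line in enumerate(_as_text(source).splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 5:
            raise AnnotationError(f"line {line_no}: expected 5 columns, got {len(fields)}")
        tid, gid, chrom, strand, exon_field = fields
        exons = []
        try:
            for token in exon_field.split(","):
                s, e = token.split("-")
                exons.append((int(s), int(e)))
        except ValueError as exc:
            raise AnnotationError(f"{tid}: bad exon field {exon_field!r}") from exc
        models.append(TranscriptModel(tid, gid, chrom, strand, tuple(exons)))
    return models


def write_transcript_annotation(
    models: Iterable[TranscriptModel], sink: PathOrStream
) -> None:
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink  # type: ignore[arg-type]
    try:
        for m in models:
            exons = ",".join(f"{s}-{e}" for s, e in m.exons)
            handle.write(f"{m.transcript_id}\t{m.gene_id}\t{m.chromosome}\t{m.strand}\t{exons}\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# Gold standard genotypes
# ---------------------------------------------------------------------------


def parse_gold_standard(source: PathOrStream) -> Dict[Tuple[str, int], Genotype]:
    """Parse the gold-standard table: chromosome, 1-based position, genotype.

    Positions come back 0-based; genotypes are canonical unordered pairs
    (``CA`` equals ``AC``).  A duplicated position with a conflicting
    genotype is an error.
    """
    gold: Dict[Tuple[str, int], Genotype] = {}
    for line_no, line in enumerate(_as_text(source).splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise GoldStandardError(f"line {line_no}: expected 3 columns")
        chrom, pos_str, gt_str = fields
        try:
            genotype = Genotype.from_string(gt_str)
        except ValueError as exc:
            raise GoldStandardError(f"line {line_no}: {exc}") from exc
        key = (chrom, int(pos_str) - 1)
        if key in gold and gold[key] != genotype:
            raise GoldStandardError(
                f"line {line_no}: conflicting genotype at {chrom}:{pos_str}"
            )
        gold[key] = genotype
    return gold


def write_gold_standard(
    gold: Mapping[Tuple[str, int], Genotype], sink: PathOrStream
) -> None:
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink  # type: ignore[arg-type]
    try:
        for (chrom, pos), genotype in sorted(gold.items()):
            handle.write(f"{chrom}\t{pos + 1}\t{genotype}\n")
    finally:
        if own:
            handle.close()
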