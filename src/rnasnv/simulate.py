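"""Synthetic RNA-seq data with known ground truth.

The generator emulates the structure of a single-end Illumina RNA-seq
experiment on a diploid sample: a random genome carrying multi-exon
transcripts on both strands, planted heterozygous/homozygous variants at a
configurable rate in exonic sequence, reads sampled from transcripts in
proportion to uneven expression levels (hence uneven coverage), per-cycle
Phred qualities with an optional 3'-degrading ramp, PCR duplicate reads,
several lanes, and optionally pooled reads from several simulated
individuals.

Reads are emitted with their *true* alignments, in both transcript and
genomic coordinates, so the merging and genotyping stages can be exercised
without running a mapper.  The reported per-cycle quality and the true
injected error rate can be decoupled (``true_error_*``) to emulate the
miscalibrated 3' qualities that de-phasing produces on real instruments;
by default the injected error rate is exactly the one the qualities claim.

Everything is driven by one integer seed; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formats_io import (
    AlignedRead,
    ReferenceGenome,
    TranscriptModel,
    sort_reads,
)
from .genotyper import Genotype
from .merge import transfer_to_genome

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults emulate a 2009-era Illumina mRNA run: 33 bp single-end reads in
    seven lanes, heterozygosity rate 0.001, and base qualities degrading
    toward the 3' end.  ``true_error_5prime``/``true_error_3prime`` override
    the *injected* per-cycle error probability; left unset, errors follow the
    reported qualities exactly (a perfectly calibrated instrument).
    """

    seed: int
    genome_length: int = 300_000
    chromosome: str = "chr1"
    n_transcripts: int = 40
    min_exons: int = 1
    max_exons: int = 10
    exon_length_range: Tuple[int, int] = (80, 300)
    intron_length_range: Tuple[int, int] = (60, 400)
    intergenic_gap_range: Tuple[int, int] = (200, 800)
    heterozygosity_rate: float = 0.001
    hom_alt_fraction: float = 1.0 / 3.0
    read_length: int = 33
    n_lanes: int = 7
    reads_per_lane: int = 20_000
    expression_sigma: float = 1.0  # lognormal spread of expression weights; 0 = even
    quality_5prime: int = 34
    quality_3prime: int = 20
    true_error_5prime: Optional[float] = None
    true_error_3prime: Optional[float] = None
    true_error_shape: float = 1.0  # 1 = linear ramp; >1 concentrates errors at the 3' end
    pcr_duplicate_rate: float = 0.0
    n_individuals: int = 1

    def __post_init__(self) -> None:
        for name in ("heterozygosity_rate", "hom_alt_fraction", "pcr_duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        if self.heterozygosity_rate >= 0.1:
            raise ValueError("heterozygosity_rate above 0.1 is not a credible sample")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def quality_profile(self) -> np.ndarray:
        """Reported Phred quality per sequencing cycle (linear 5'->3' ramp)."""
        return np.rint(
            np.linspace(self.quality_5prime, self.quality_3prime, self.read_length)
        ).astype(np.int16)

    def error_profile(self) -> np.ndarray:
        """True injected error probability per cycle."""
        if self.true_error_5prime is None and self.true_error_3prime is None:
            return 10.0 ** (-self.quality_profile().astype(float) / 10.0)
        e5 = self.true_error_5prime
        e3 = self.true_error_3prime
        if e5 is None or e3 is None:
            raise ValueError("set both true_error_5prime and true_error_3prime or neither")
        # de-phasing error accumulates sharply toward the 3' end; shape > 1
        # keeps early cycles clean and concentrates errors in the final cycles
        t = np.linspace(0.0, 1.0, self.read_length) ** self.true_error_shape
        return e5 + (e3 - e5) * t


@dataclass
class TruthSet:
    """Planted genotypes per simulated individual, keyed (chromosome, 0-based pos)."""

    genotypes: Dict[int, Dict[Tuple[str, int], Genotype]]

    def individual(self, index: int = 0) -> Dict[Tuple[str, int], Genotype]:
        return self.genotypes[index]

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)


@dataclass
class SampledReads:
    """One individual's simulated reads with their true alignments."""

    transcript_reads: List[AlignedRead]  # transcript-space coordinates
    genomic_reads: List[AlignedRead]  # same reads lifted to the genome
    origins: Dict[str, Tuple[str, int, int, int]]  # read -> (transcript, t_start, haplotype, n_errors)


def simulate_genome_and_transcripts(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Dict[str, str], List[TranscriptModel]]:
    """Random genome plus non-overlapping multi-exon genes on both strands."""
    rng = rng or np.random.default_rng(config.seed)
    genome = "".join(rng.choice(_BASES, size=config.genome_length))
    models: List[TranscriptModel] = []
    cursor = 0
    for t in range(config.n_transcripts):
        cursor += int(rng.integers(*config.intergenic_gap_range))
        n_exons = int(rng.integers(config.min_exons, config.max_exons + 1))
        exons = []
        pos = cursor
        for k in range(n_exons):
            if k > 0:
                pos += int(rng.integers(*config.intron_length_range))
            length = int(rng.integers(*config.exon_length_range))
            exons.append((pos, pos + length))
            pos += length
        if pos > config.genome_length:
            raise ValueError(
                f"could only place {len(models)} of {config.n_transcripts} "
                f"transcripts in {config.genome_length} bp; increase genome_length"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            TranscriptModel(
                transcript_id=f"T{t + 1:03d}",
                gene_id=f"G{t + 1:03d}",
                chromosome=config.chromosome,
                strand=strand,
                exons=tuple(exons),
            )
        )
        cursor = pos
    return ({config.chromosome: genome}, models)


def exonic_positions(models: Iterable[TranscriptModel]) -> Dict[str, np.ndarray]:
    """Sorted union of exonic genomic positions per chromosome."""
    per_chrom: Dict[str, set] = {}
    for m in models:
        bucket = per_chrom.setdefault(m.chromosome, set())
        for s, e in m.exons:
            bucket.update(range(s, e))
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in per_chrom.items()}


def plant_variants(
    genome: Mapping[str, str],
    models: Sequence[TranscriptModel],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> TruthSet:
    """Plant variants in exonic sequence, independently per individual.

    Each exonic site becomes a variant with probability
    ``heterozygosity_rate``; a ``hom_alt_fraction`` of these are homozygous
    non-reference instead of heterozygous.  Planted genotypes never equal
    homozygous reference.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    positions = exonic_positions(models)
    truth: Dict[int, Dict[Tuple[str, int], Genotype]] = {}
    for individual in range(config.n_individuals):
        table: Dict[Tuple[str, int], Genotype] = {}
        for chrom, pos in positions.items():
            hit = rng.random(len(pos)) < config.heterozygosity_rate
            for p in pos[hit]:
                ref = genome[chrom][p]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                if rng.random() < config.hom_alt_fraction:
                    table[(chrom, int(p))] = Genotype(alt, alt)
                else:
                    table[(chrom, int(p))] = Genotype(ref, alt)
        truth[individual] = table
    return TruthSet(genotypes=truth)


def _haplotype_sequences(
    genome: ReferenceGenome,
    model: TranscriptModel,
    truth: Mapping[Tuple[str, int], Genotype],
) -> Tuple[np.ndarray, np.ndarray]:
    """The two haplotype mRNA sequences of one transcript as char arrays.

    Heterozygous alleles are phased arbitrarily: haplotype 0 carries the
    lexicographically smaller allele.  Alleles are recorded on the genome
    strand, so minus-strand transcripts substitute the complement.
    """
    ref = model.spliced_sequence(genome)
    hap = [np.array(list(ref)), np.array(list(ref))]
    for s, e in model.exons:
        for g in range(s, e):
            genotype = truth.get((model.chromosome, g))
            if genotype is None:
                continue
            t = model.transcript_position(g)
            for h, allele in enumerate(genotype.alleles):
                hap[h][t] = allele if model.strand == "+" else _COMPLEMENT[allele]
    return hap[0], hap[1]


def draw_expression_weights(
    models: Sequence[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Relative expression per transcript (lognormal; zero for unsampleable ones)."""
    if config.expression_sigma > 0:
        weights = rng.lognormal(0.0, config.expression_sigma, len(models))
    else:
        weights = np.ones(len(models))
    for i, m in enumerate(models):
        if m.length < config.read_length:
            weights[i] = 0.0
    if weights.sum() == 0:
        raise ValueError("no transcript is long enough to sample reads from")
    return weights / weights.sum()


def sample_reads(
    genome: Mapping[str, str],
    models: Sequence[TranscriptModel],
    truth: TruthSet,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    individual: int = 0,
) -> SampledReads:
    """Sample error-injected reads from transcripts for one individual.

    Reads are drawn from transcripts proportionally to expression weights;
    each read's haplotype is a fair coin; a sequencing error at a cycle
    replaces the base with one of the other three uniformly.  PCR duplicates
    are exact copies (same errors, same qualities) of their template.
    """
    rng = rng or np.random.default_rng(config.seed + 100 + individual)
    reference = ReferenceGenome(genome)
    table = truth.individual(individual)
    weights = draw_expression_weights(models, config, rng)
    haplotypes = [_haplotype_sequences(reference, m, table) for m in models]
    qualities = config.quality_profile()
    errors = config.error_profile()
    rl = config.read_length

    transcript_reads: List[AlignedRead] = []
    genomic_reads: List[AlignedRead] = []
    origins: Dict[str, Tuple[str, int, int, int]] = {}
    for lane_no in range(config.n_lanes):
        lane = f"L{lane_no + 1}"
        tids = rng.choice(len(models), size=config.reads_per_lane, p=weights)
        haps = rng.integers(0, 2, size=config.reads_per_lane)
        for k in range(config.reads_per_lane):
            model = models[tids[k]]
            start = int(rng.integers(0, model.length - rl + 1))
            seq = haplotypes[tids[k]][haps[k]][start: start + rl].copy()
            err = rng.random(rl) < errors
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err)
                codes = np.array(["ACGT".index(b) for b in seq[err]])
                seq[err] = _BASES[(codes + shift) % 4]
            read_id = f"i{individual}_{lane}_r{k}"
            t_read = AlignedRead(
                read_id=read_id,
                lane_id=lane,
                reference_name=model.transcript_id,
                strand="+",
                blocks=((start, start + rl),),
                bases="".join(seq),
                qualities=qualities.copy(),
            )
            origins[read_id] = (model.transcript_id, start, int(haps[k]), n_err)
            copies = [t_read]
            if config.pcr_duplicate_rate and rng.random() < config.pcr_duplicate_rate:
                dup = replace(
                    t_read,
                    read_id=read_id + "_dup",
                    qualities=t_read.qualities.copy(),
                    mask=t_read.mask.copy(),
                )
                origins[dup.read_id] = origins[read_id]
                copies.append(dup)
            for copy in copies:
                transcript_reads.append(copy)
                genomic_reads.append(transfer_to_genome(copy, model))
    return SampledReads(
        transcript_reads=transcript_reads,
        genomic_reads=sort_reads(genomic_reads),
        origins=origins,
    )


@dataclass
class PooledSample:
    """Reads pooled from several individuals plus the union truth table."""

    reads: List[AlignedRead]
    truth: Dict[Tuple[str, int], Dict[int, Genotype]]


def pool_individuals(
    read_sets: Sequence[Sequence[AlignedRead]],
    truths: Sequence[Mapping[Tuple[str, int], Genotype]],
) -> PooledSample:
    """Concatenate read sets from individuals sharing one reference.

    Reads keep their individual-of-origin tag (embedded in the read id by the
    simulator); the union truth records every individual's genotype per locus.
    """
    if len(read_sets) != len(truths):
        raise ValueError("one truth table per read set required")
    chrom_sets = [
        {r.reference_name for r in reads if r.is_mapped} for reads in read_sets
    ]
    nonempty = [cs for cs in chrom_sets if cs]
    for cs in nonempty[1:]:
        if cs != nonempty[0]:
            raise ValueError("read sets come from different references")
    merged: List[AlignedRead] = []
    for reads in read_sets:
        merged.extend(reads)
    union: Dict[Tuple[str, int], Dict[int, Genotype]] = {}
    for individual, truth in enumerate(truths):
        for locus, genotype in truth.items():
            union.setdefault(locus, {})[individual] = genotype
    return PooledSample(reads=sort_reads(merged), truth=union)


# ---------------------------------------------------------------------------
# Deterministic decision-table fixture for the merge module
# ---------------------------------------------------------------------------


def merge_decision_fixture() -> Tuple[
    List[AlignedRead], List[AlignedRead], List[TranscriptModel], Dict[str, str]
]:
    """Ten reads, one per row of the alignment-merging decision table.

    Returns (genome-side reads, transcript-side reads, annotation, expected
    category per read id).  Hard merging keeps exactly r01, r04 and r08; soft
    merging additionally keeps r03 and r05.
    """
    t1 = TranscriptModel("T1", "G1", "chr1", "+", ((100, 150), (200, 250)))
    t2 = TranscriptModel("T2", "G2", "chr1", "+", ((1000, 1100),))
    models = [t1, t2]
    q = np.full(10, 30)

    def g_read(rid: str, start: int) -> AlignedRead:
        return AlignedRead(rid, "L1", "chr1", "+", ((start, start + 10),), "ACGTACGTAC", q.copy())

    def t_read(rid: str, tid: str, start: int) -> AlignedRead:
        return AlignedRead(rid, "L1", tid, "+", ((start, start + 10),), "ACGTACGTAC", q.copy())

    def unmapped(rid: str) -> AlignedRead:
        return AlignedRead(rid, "L1", "*", "+", (), "ACGTACGTAC", q.copy(), mapping_status="unmapped")

    genome_side = [
        g_read("r01", 110),  # agrees with T1 transcript hit at t=10
        g_read("r02", 1000),  # disagrees with its transcript hit
        g_read("r03", 110),
        g_read("r04", 110),
        g_read("r05", 110), g_read("r05", 1000),  # two hits: multiple
        g_read("r06", 110), g_read("r06", 1000),
        g_read("r07", 110), g_read("r07", 1000),
        unmapped("r08"),
        unmapped("r09"),
        unmapped("r10"),
    ]
    transcript_side = [
        t_read("r01", "T1", 10),  # lifts to chr1:[110,120)
        t_read("r02", "T1", 10),
        t_read("r03", "T1", 10), t_read("r03", "T2", 0),  # two genomic locations
        unmapped("r04"),
        t_read("r05", "T1", 10),
        t_read("r06", "T1", 10), t_read("r06", "T2", 0),
        unmapped("r07"),
        t_read("r08", "T1", 45),  # spans the splice junction
        t_read("r09", "T1", 10), t_read("r09", "T2", 0),
        unmapped("r10"),
    ]
    expected = {
        "r01": "unique/unique/agree",
        "r02": "unique/unique/disagree",
        "r03": "unique/multiple",
        "r04": "unique/unmapped",
        "r05": "multiple/unique",
        "r06": "multiple/multiple",
        "r07": "multiple/unmapped",
        "r08": "unmapped/unique",
        "r09": "unmapped/multiple",
        "r10": "unmapped/unmapped",
    }
    return (genome_side, transcript_side, models, expected)


def random_merge_inputs(
    n_reads: int, rng: np.random.Generator
) -> Tuple[List[AlignedRead], List[AlignedRead], List[TranscriptModel]]:
    """Random dual-mapping inputs hitting arbitrary decision-table rows.

    Every read is assigned a uniformly random mapping category on each side
    (with random agreement when dual-unique), yielding inputs over which the
    hard-kept-is-a-subset-of-soft-kept property can be exercised.
    """
    genome_fixture, transcript_fixture, models, _ = merge_decision_fixture()
    t1 = models[0]
    q = np.full(10, 30)
    genome_side: List[AlignedRead] = []
    transcript_side: List[AlignedRead] = []
    for k in range(n_reads):
        rid = f"x{k:04d}"
        g_cat = ["unique", "multiple", "unmapped"][rng.integers(3)]
        t_cat = ["unique", "multiple", "unmapped"][rng.integers(3)]
        agree = bool(rng.integers(2))
        if t_cat == "unique":
            t_start = int(rng.integers(0, t1.length - 10))
            transcript_side.append(
                AlignedRead(rid, "L1", "T1", "+", ((t_start, t_start + 10),), "ACGTACGTAC", q.copy())
            )
            lifted_start = t1.genomic_blocks(t_start, t_start + 10)[0][0]
        elif t_cat == "multiple":
            transcript_side.append(
                AlignedRead(rid, "L1", "T1", "+", ((0, 10),), "ACGTACGTAC", q.copy())
            )
            transcript_side.append(
                AlignedRead(rid, "L1", "T2", "+", ((0, 10),), "ACGTACGTAC", q.copy())
            )
            lifted_start = None
        else:
            transcript_side.append(
                AlignedRead(rid, "L1", "*", "+", (), "ACGTACGTAC", q.copy(), mapping_status="unmapped")
            )
            lifted_start = None
        if g_cat == "unique":
            if t_cat == "unique" and agree and lifted_start is not None:
                start = lifted_start
            else:
                start = int(rng.integers(2000, 3000))
            genome_side.append(
                AlignedRead(rid, "L1", "chr1", "+", ((start, start + 10),), "ACGTACGTAC", q.copy())
            )
        elif g_cat == "multiple":
            for start in (2000, 3000):
                genome_side.append(
                    AlignedRead(rid, "L1", "chr1", "+", ((start, start + 10),), "ACGTACGTAC", q.copy())
                )
        else:
            genome_side.append(
                AlignedRead(rid, "L1", "*", "+", (), "ACGTACGTAC", q.copy(), mapping_status="unmapped")
            )
    return (genome_side, transcript_side, models)
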