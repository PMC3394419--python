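"""Determinism, error model and structural guarantees of the data generator."""

import numpy as np
import pytest
from scipy import stats

from rnasnv.filters import start_locus_filter
from rnasnv.formats_io import ReferenceGenome
from rnasnv.genotyper import Genotype
from rnasnv.simulate import (
    SimulationConfig,
    _haplotype_sequences,
    exonic_positions,
    plant_variants,
    pool_individuals,
    sample_reads,
    simulate_genome_and_transcripts,
)


def _config(**kwargs):
    base = dict(
        seed=42, genome_length=60_000, n_transcripts=8,
        heterozygosity_rate=0.01, reads_per_lane=1000, n_lanes=2,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestGenomeAndTranscripts:
    def test_deterministic_under_fixed_seed(self):
        g1, m1 = simulate_genome_and_transcripts(_config())
        g2, m2 = simulate_genome_and_transcripts(_config())
        assert g1 == g2
        assert [(m.transcript_id, m.strand, m.exons) for m in m1] == [
            (m.transcript_id, m.strand, m.exons) for m in m2]

    def test_single_exon_mode(self):
        _, models = simulate_genome_and_transcripts(_config(max_exons=1))
        assert all(len(m.exons) == 1 for m in models)

    def test_exons_fit_in_genome(self):
        config = _config()
        genome, models = simulate_genome_and_transcripts(config)
        total_exonic = sum(e - s for m in models for s, e in m.exons)
        assert total_exonic <= config.genome_length
        assert all(m.end <= config.genome_length for m in models)

    def test_genes_do_not_overlap(self):
        _, models = simulate_genome_and_transcripts(_config())
        spans = sorted((m.start, m.end) for m in models)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_infeasible_packing_reports_helpfully(self):
        with pytest.raises(ValueError, match="genome_length"):
            simulate_genome_and_transcripts(_config(genome_length=2_000, n_transcripts=50))


class TestPlantVariants:
    def test_zero_rate_empty_truth(self):
        config = _config(heterozygosity_rate=0.0)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        assert truth.individual(0) == {}

    def test_count_matches_binomial_expectation(self):
        config = _config(heterozygosity_rate=0.02)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        n_sites = sum(len(p) for p in exonic_positions(models).values())
        expected = n_sites * 0.02
        sigma = np.sqrt(n_sites * 0.02 * 0.98)
        assert abs(len(truth.individual(0)) - expected) < 4 * sigma

    def test_never_homozygous_reference(self):
        config = _config(heterozygosity_rate=0.05)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        assert truth.individual(0)
        for (chrom, pos), genotype in truth.individual(0).items():
            ref = genome[chrom][pos]
            assert genotype != Genotype(ref, ref)

    def test_variants_are_exonic(self):
        config = _config(heterozygosity_rate=0.05)
        genome, models = simulate_genome_and_transcripts(config)
        positions = {
            (c, int(p)) for c, arr in exonic_positions(models).items() for p in arr}
        truth = plant_variants(genome, models, config)
        assert set(truth.individual(0)) <= positions

    def test_individuals_draw_independently(self):
        config = _config(heterozygosity_rate=0.02, n_individuals=2)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        assert truth.individual(0) != truth.individual(1)


class TestSampleReads:
    def test_deterministic(self):
        config = _config()
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        a = sample_reads(genome, models, truth, config)
        b = sample_reads(genome, models, truth, config)
        assert [(r.read_id, r.bases, r.blocks) for r in a.genomic_reads] == [
            (r.read_id, r.bases, r.blocks) for r in b.genomic_reads]

    def test_zero_error_reads_match_haplotype(self):
        config = _config(true_error_5prime=0.0, true_error_3prime=0.0)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        sample = sample_reads(genome, models, truth, config)
        reference = ReferenceGenome(genome)
        haplotypes = {
            m.transcript_id: _haplotype_sequences(reference, m, truth.individual(0))
            for m in models
        }
        for read in sample.transcript_reads:
            tid, start, hap, n_err = sample.origins[read.read_id]
            assert n_err == 0
            expected = "".join(haplotypes[tid][hap][start: start + len(read.bases)])
            assert read.bases == expected

    def test_error_rate_matches_quality_claim(self):
        # constant q=20 and calibrated errors: mismatch rate vs the true
        # haplotype should be ~1% within binomial noise
        config = _config(quality_5prime=20, quality_3prime=20,
                         heterozygosity_rate=0.0, reads_per_lane=2000)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        sample = sample_reads(genome, models, truth, config)
        n_errors = sum(sample.origins[r.read_id][3] for r in sample.transcript_reads)
        n_bases = sum(r.read_length for r in sample.transcript_reads)
        p = 0.01
        sigma = np.sqrt(n_bases * p * (1 - p))
        assert abs(n_errors - n_bases * p) < 4 * sigma

    def test_expression_weights_recovered(self):
        config = _config(reads_per_lane=25_000, n_lanes=2, expression_sigma=1.0)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        rng = np.random.default_rng(config.seed + 100)
        from rnasnv.simulate import draw_expression_weights

        weights = draw_expression_weights(models, config, rng)
        sample = sample_reads(genome, models, truth, config)
        counts = np.zeros(len(models))
        index = {m.transcript_id: i for i, m in enumerate(models)}
        for read in sample.transcript_reads:
            if read.read_id.endswith("_dup"):
                continue
            counts[index[sample.origins[read.read_id][0]]] += 1
        expected = weights * counts.sum()
        keep = expected > 5
        _, p_value = stats.chisquare(counts[keep], expected[keep] * counts[keep].sum()
                                     / expected[keep].sum())
        assert p_value > 0.001

    def test_duplicates_removed_by_start_locus_cap(self):
        config = _config(pcr_duplicate_rate=0.5)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        sample = sample_reads(genome, models, truth, config)
        n_dups = sum(r.read_id.endswith("_dup") for r in sample.genomic_reads)
        assert n_dups > 0
        kept = start_locus_filter(sample.genomic_reads, 1)
        keys = [(r.reference_name, r.start, r.strand) for r in kept]
        assert len(keys) == len(set(keys))
        # every duplicate's key collides with its template, so the cap removes
        # at least the duplicate excess
        assert len(kept) <= len(sample.genomic_reads) - n_dups

    def test_spliced_reads_exercise_junctions(self):
        config = _config()
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        sample = sample_reads(genome, models, truth, config)
        if any(len(m.exons) > 1 for m in models):
            assert any(len(r.blocks) > 1 for r in sample.genomic_reads)


class TestPoolIndividuals:
    def _samples(self, k):
        config = _config(n_individuals=k, heterozygosity_rate=0.02, reads_per_lane=300)
        genome, models = simulate_genome_and_transcripts(config)
        truth = plant_variants(genome, models, config)
        samples = [
            sample_reads(genome, models, truth, config, individual=i) for i in range(k)
        ]
        return config, truth, samples

    def test_single_individual_identity(self):
        _, truth, samples = self._samples(1)
        pooled = pool_individuals([samples[0].genomic_reads], [truth.individual(0)])
        assert len(pooled.reads) == len(samples[0].genomic_reads)
        assert set(pooled.truth) == set(truth.individual(0))

    def test_union_truth_set_algebra(self):
        _, truth, samples = self._samples(3)
        tables = [truth.individual(i) for i in range(3)]
        pooled = pool_individuals([s.genomic_reads for s in samples], tables)
        union = set(tables[0]) | set(tables[1]) | set(tables[2])
        assert set(pooled.truth) == union
        total = sum(len(t) for t in tables)
        shared = total - len(union)
        assert len(pooled.truth) == total - shared

    def test_deterministic(self):
        _, truth, samples = self._samples(2)
        tables = [truth.individual(i) for i in range(2)]
        a = pool_individuals([s.genomic_reads for s in samples], tables)
        b = pool_individuals([s.genomic_reads for s in samples], tables)
        assert [r.read_id for r in a.reads] == [r.read_id for r in b.reads]

    def test_mismatched_reference_rejected(self):
        _, truth, samples = self._samples(1)
        import dataclasses

        alien = [dataclasses.replace(r, reference_name="chrZ",
                                     qualities=r.qualities.copy(), mask=r.mask.copy())
                 for r in samples[0].genomic_reads[:5]]
        with pytest.raises(ValueError):
            pool_individuals(
                [samples[0].genomic_reads, alien],
                [truth.individual(0), {}],
            )
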