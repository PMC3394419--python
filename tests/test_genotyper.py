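"""The Bayesian ten-genotype model: likelihoods, priors, posteriors, calls."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnasnv.formats_io import (
    BaseObservation,
    ObservationStore,
    PileupColumn,
    ReferenceGenome,
)
from rnasnv.genotyper import (
    EPSILON_MAX,
    GENOTYPES,
    Genotype,
    PriorConfig,
    call_genotype,
    call_variants_from_store,
    genotype_all,
    genotype_posteriors,
    genotype_priors,
    phred_to_error_prob,
    read_likelihood,
)


def brute_force_posterior(column, h):
    """Independent direct-probability oracle: prior x product, then normalise."""
    posterior = {}
    for a, b in itertools.combinations_with_replacement("ACGT", 2):
        p = (1.0 - h) / 4.0 if a == b else h / 6.0
        for obs in column.observations:
            eps = min(10.0 ** (-obs.quality / 10.0), EPSILON_MAX)
            if a == b:
                p *= (1.0 - eps) if obs.base == a else eps / 3.0
            elif obs.base in (a, b):
                p *= 0.5 - eps / 3.0
            else:
                p *= eps / 3.0
        posterior[Genotype(a, b)] = p
    total = sum(posterior.values())
    return {g: p / total for g, p in posterior.items()}, total


def random_column(rng, max_obs=10):
    n = int(rng.integers(0, max_obs + 1))
    obs = [
        BaseObservation("ACGT"[rng.integers(4)], int(rng.integers(2, 41)), "L1", 0, 0)
        for _ in range(n)
    ]
    return PileupColumn("chr1", 100, "A", obs)


class TestGenotypeType:
    def test_ten_distinct_genotypes(self):
        assert len(GENOTYPES) == len(set(GENOTYPES)) == 10

    def test_unordered_pair(self):
        assert Genotype("C", "A") == Genotype("A", "C")
        assert str(Genotype("C", "A")) == "AC"

    def test_invalid_allele_rejected(self):
        with pytest.raises(ValueError):
            Genotype("A", "N")


class TestPhred:
    @pytest.mark.parametrize("q,expected", [(10, 0.1), (20, 0.01), (30, 0.001)])
    def test_phred_formula(self, q, expected):
        assert phred_to_error_prob(q) == pytest.approx(expected)

    def test_zero_quality_capped(self):
        assert phred_to_error_prob(0) == EPSILON_MAX < 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phred_to_error_prob(-1)


class TestReadLikelihood:
    @pytest.mark.parametrize(
        "genotype,base,eps,expected",
        [
            (Genotype("A", "A"), "A", 0.01, 0.99),
            (Genotype("A", "A"), "C", 0.01, 0.01 / 3),
            (Genotype("A", "C"), "A", 0.01, 0.5 - 0.01 / 3),
            (Genotype("A", "C"), "A", 0.0, 0.5),
            (Genotype("A", "C"), "G", 0.01, 0.01 / 3),
        ],
    )
    def test_model_cases(self, genotype, base, eps, expected):
        assert read_likelihood(base, eps, genotype) == pytest.approx(expected)

    def test_allele_order_symmetry(self):
        for base in "ACGT":
            assert read_likelihood(base, 0.02, Genotype("A", "C")) == read_likelihood(
                base, 0.02, Genotype("C", "A")
            )

    @given(st.floats(min_value=1e-4, max_value=0.74))
    @settings(deadline=None, derandomize=True)
    def test_sums_to_one_over_bases(self, eps):
        for genotype in GENOTYPES:
            total = sum(read_likelihood(base, eps, genotype) for base in "ACGT")
            assert abs(total - 1.0) < 1e-12


class TestPriors:
    def test_reference_values(self):
        priors = genotype_priors(PriorConfig(0.001))
        assert priors[Genotype("A", "A")] == pytest.approx(0.24975)
        assert priors[Genotype("A", "C")] == pytest.approx(0.001 / 6)

    @pytest.mark.parametrize("h", [1e-5, 0.001, 0.05, 0.5])
    def test_normalised_for_any_h(self, h):
        assert sum(genotype_priors(PriorConfig(h)).values()) == pytest.approx(1.0, abs=1e-15)

    def test_invalid_h_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(0.0)


class TestPosteriors:
    def test_zero_observations_returns_prior(self):
        post = genotype_posteriors(PileupColumn("chr1", 0, "A"), PriorConfig(0.001))
        priors = genotype_priors(PriorConfig(0.001))
        for g in GENOTYPES:
            assert post.probabilities[g] == pytest.approx(priors[g], rel=1e-12)

    def test_single_observation_worked_example(self):
        col = PileupColumn("chr1", 0, "A", [BaseObservation("A", 20, "L1", 0, 0)])
        post = genotype_posteriors(col, PriorConfig(0.001))
        assert post.probabilities[Genotype("A", "A")] == pytest.approx(0.98901, abs=5e-6)

    def test_single_observation_unnormalised_mass_quarter(self):
        # prior symmetry over bases + per-genotype likelihood normalisation
        rng = np.random.default_rng(3)
        for _ in range(20):
            base = "ACGT"[rng.integers(4)]
            q = int(rng.integers(2, 41))
            col = PileupColumn("chr1", 0, "A", [BaseObservation(base, q, "L1", 0, 0)])
            _, total = brute_force_posterior(col, 0.001)
            assert total == pytest.approx(0.25, rel=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            col = random_column(rng)
            expected, _ = brute_force_posterior(col, 0.001)
            post = genotype_posteriors(col, PriorConfig(0.001))
            for g in GENOTYPES:
                assert post.probabilities[g] == pytest.approx(expected[g], rel=1e-9)

    def test_posterior_normalised(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            post = genotype_posteriors(random_column(rng), PriorConfig(0.001))
            assert sum(post.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_base_relabelling_permutes_posteriors(self):
        mapping = str.maketrans("ACGT", "GTAC")
        col = PileupColumn("chr1", 0, "A", [
            BaseObservation("A", 25, "L1", 0, 0),
            BaseObservation("C", 17, "L1", 0, 0),
            BaseObservation("A", 31, "L1", 0, 0),
        ])
        relabelled = PileupColumn("chr1", 0, "G", [
            BaseObservation(o.base.translate(mapping), o.quality, o.lane_id, 0, 0)
            for o in col.observations
        ])
        post = genotype_posteriors(col, PriorConfig(0.001))
        post2 = genotype_posteriors(relabelled, PriorConfig(0.001))
        for g in GENOTYPES:
            g2 = Genotype(*(a.translate(mapping) for a in g.alleles))
            assert post2.probabilities[g2] == pytest.approx(post.probabilities[g], rel=1e-12)

    def test_posterior_of_truth_grows_with_coverage(self):
        config = PriorConfig(0.001)
        last = 0.0
        for n in [1, 2, 5, 10, 20, 50]:
            col = PileupColumn("chr1", 0, "A",
                               [BaseObservation("C", 30, "L1", 0, 0)] * n)
            p = genotype_posteriors(col, config).probabilities[Genotype("C", "C")]
            assert p > last
            last = p
        assert last > 0.9999


class TestCallGenotype:
    def test_worked_example_variant_posterior(self):
        col = PileupColumn("chr1", 0, "A", [BaseObservation("A", 20, "L1", 0, 0)])
        call = call_genotype(genotype_posteriors(col, PriorConfig(0.001)), "A")
        assert not call.is_variant
        assert call.variant_posterior == pytest.approx(0.01099, abs=5e-6)

    def test_zero_coverage_tie_resolves_to_reference(self):
        post = genotype_posteriors(PileupColumn("chr1", 0, "T"), PriorConfig(0.001))
        call = call_genotype(post, "T")
        assert call.genotype == Genotype("T", "T")
        assert not call.is_variant

    def test_strong_alt_evidence_called_variant(self):
        col = PileupColumn("chr1", 0, "A",
                           [BaseObservation("C", 30, "L1", 0, 0)] * 20)
        call = call_genotype(genotype_posteriors(col, PriorConfig(0.001)), "A")
        assert call.genotype == Genotype("C", "C")
        assert call.is_variant
        assert call.variant_posterior > 0.999999

    def test_n_reference_yields_no_call(self):
        post = genotype_posteriors(PileupColumn("chr1", 0, "N"), PriorConfig(0.001))
        assert call_genotype(post, "N") is None


class TestGenotypeAll:
    def _columns(self):
        return [
            PileupColumn("chr1", 5, "A", [BaseObservation("A", 30, "L1", 0, 0)] * 3),
            PileupColumn("chr1", 9, "A", [BaseObservation("C", 30, "L1", 0, 0)] * 6),
            PileupColumn("chr2", 2, "G", [BaseObservation("G", 30, "L1", 0, 0)] * 3),
        ]

    def test_ordered_calls_with_reference_emission(self):
        calls = list(genotype_all(self._columns(), emit_reference_calls=True))
        assert [(c.chromosome, c.position) for c in calls] == [
            ("chr1", 5), ("chr1", 9), ("chr2", 2)]

    def test_variant_only_by_default(self):
        calls = list(genotype_all(self._columns()))
        assert [(c.position, str(c.genotype)) for c in calls] == [(9, "CC")]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            list(genotype_all(self._columns()[::-1]))

    def test_deterministic(self):
        a = list(genotype_all(self._columns(), emit_reference_calls=True))
        b = list(genotype_all(self._columns(), emit_reference_calls=True))
        assert [(c.position, c.posterior) for c in a] == [(c.position, c.posterior) for c in b]


class TestVectorisedPath:
    def test_matches_per_column_reference_implementation(self, tiny_dataset):
        reads = tiny_dataset["sample"].genomic_reads[:4000]
        reference = tiny_dataset["reference"]
        store = ObservationStore.from_reads(reads)
        fast = {
            (c.chromosome, c.position): c
            for c in call_variants_from_store(
                store, reference, PriorConfig(0.001), emit_reference_calls=True)
        }
        n_checked = 0
        for column in store.columns(reference):
            if column.reference_base == "N":
                continue
            slow = call_genotype(
                genotype_posteriors(column, PriorConfig(0.001)),
                column.reference_base,
                chromosome=column.chromosome,
                position=column.position,
                coverage=column.coverage,
            )
            fast_call = fast[(column.chromosome, column.position)]
            assert fast_call.genotype == slow.genotype
            assert fast_call.posterior == pytest.approx(slow.posterior, rel=1e-9)
            assert fast_call.variant_posterior == pytest.approx(
                slow.variant_posterior, rel=1e-9, abs=1e-12)
            assert fast_call.coverage == slow.coverage
            n_checked += 1
        assert n_checked > 1000
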