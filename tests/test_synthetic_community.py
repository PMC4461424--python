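"""Mock-community generator: references, variants, designs, reads, truth."""

import edlib
import numpy as np
import pytest
from scipy import stats as sps

from mockotu import synthetic_community as sc
from mockotu.otu_cluster import DivergenceConvention, pair_divergence

INT = DivergenceConvention.INTERNAL_GAPS_ONLY


def _template(seed=3, length=460):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return sc.ReferenceTemplate("spX", "Copepoda", seq, "fixture species")


class TestReferenceSet:
    def test_pairwise_divergence_within_requested_range(self):
        templates = sc.generate_reference_set(6, (0.05, 0.15), seed=1)
        assert len(templates) == 6
        assert len({t.species_id for t in templates}) == 6
        for i, a in enumerate(templates):
            for b in templates[i + 1 :]:
                d = pair_divergence(a.sequence, b.sequence, INT)
                assert 0.05 <= d <= 0.15

    def test_deterministic_under_seed(self):
        a = sc.generate_reference_set(4, (0.05, 0.20), seed=7)
        b = sc.generate_reference_set(4, (0.05, 0.20), seed=7)
        assert [t.sequence for t in a] == [t.sequence for t in b]

    def test_infeasible_range_fails_explicitly(self):
        with pytest.raises(RuntimeError, match="pairwise_divergence_range"):
            sc.generate_reference_set(
                3, (0.001, 0.002), seed=1, max_tries=5
            )


class TestIntragenomicVariants:
    def test_single_variant_is_the_template(self):
        t = _template()
        (v,) = sc.generate_intragenomic_variants(t, 1)
        assert v.sequence == t.sequence
        assert v.copy_frequency == 1.0
        assert v.mutation_record == ()

    def test_36nt_deletion_shortens_by_36(self):
        t = _template()
        for seed in range(10):  # either indel direction may be drawn
            vs = sc.generate_intragenomic_variants(
                t, 2, substitutions_per_variant=0,
                indel_length_choices=(36,), frequency_weights=(0.5, 0.5),
                seed=seed,
            )
            assert abs(len(vs[1].sequence) - len(t.sequence)) == 36

    def test_seven_subs_four_indels_edit_distance(self):
        # 7 substitutions + indels of 1/2/3/6 nt -> edit distance 19,
        # checked with edlib as an independent edit-distance oracle
        t = _template()
        vs = sc.generate_intragenomic_variants(
            t, 2, substitutions_per_variant=7,
            indel_length_choices=(1, 2, 3, 6), seed=5,
        )
        d = edlib.align(vs[0].sequence, vs[1].sequence, task="distance")
        assert d["editDistance"] == 19

    @pytest.mark.parametrize("seed", range(6))
    def test_mutation_record_replays_to_sequence(self, seed):
        t = _template(seed)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        vs = sc.generate_intragenomic_variants(
            t, n, substitutions_per_variant=int(rng.integers(0, 6)),
            indel_length_choices=tuple(
                int(x) for x in rng.integers(1, 15, size=rng.integers(0, 3))
            ),
            seed=seed,
        )
        assert abs(sum(v.copy_frequency for v in vs) - 1.0) < 1e-9
        for v in vs:
            assert sc.apply_mutations(t.sequence, v.mutation_record) == v.sequence

    def test_oversized_edits_rejected(self):
        t = sc.ReferenceTemplate("spY", "Rotifera", "ACGT" * 7, "tiny")
        with pytest.raises(ValueError):
            sc.generate_intragenomic_variants(
                t, 2, substitutions_per_variant=0, indel_length_choices=(36,)
            )


class TestCommunityAssembly:
    def test_tagged_individuals_one_sample_per_species(self):
        templates = sc.generate_reference_set(5, (0.05, 0.25), seed=2)
        design = sc.assemble_individuals_community(templates, True, seed=2)
        assert len(design.samples) == 5
        mids = [s.mid_tag for s in design.samples]
        assert len(set(mids)) == 5 and all(len(m) == 10 for m in mids)
        for a_i, a in enumerate(mids):
            for b in mids[a_i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_untagged_individuals_single_pool(self):
        rng = np.random.default_rng(0)
        templates = [
            sc.ReferenceTemplate(
                f"sp{k:02d}", "Cladocera",
                "".join(rng.choice(list("ACGT"), size=440)), f"species {k}",
            )
            for k in range(61)
        ]
        design = sc.assemble_individuals_community(templates, False, seed=1)
        assert len(design.samples) == 1
        assert design.samples[0].mid_tag is None
        assert len(design.samples[0].members) == 61

    def test_population_sizes_and_weights(self):
        templates = sc.generate_reference_set(2, (0.05, 0.25), seed=3)
        design = sc.assemble_populations_community(
            templates, [("sp01", 5), ("sp01", 10), ("sp01", 30)], True, seed=3
        )
        assert [len(s.members) for s in design.samples] == [5, 10, 30]
        # per-individual equal weight: a 10-individual population carries
        # twice the weight of a 5-individual one
        assert design.samples[1].total_weight == 2 * design.samples[0].total_weight

    def test_size_one_populations_reduce_to_individuals(self):
        templates = sc.generate_reference_set(3, (0.05, 0.25), seed=4)
        design = sc.assemble_populations_community(
            templates, [(t.species_id, 1) for t in templates], True, seed=4
        )
        assert all(len(s.members) == 1 for s in design.samples)

    def test_24_populations_over_13_species(self):
        from mockotu.pipeline import DEFAULT_POPULATION_SIZES

        templates = sc.generate_reference_set(13, (0.10, 0.30), seed=5)
        design = sc.assemble_populations_community(
            templates, list(DEFAULT_POPULATION_SIZES), True, seed=5
        )
        assert len(design.samples) == 24
        assert len({s for s, _n in DEFAULT_POPULATION_SIZES}) == 13


def _noise_free(seed=9, reads=30):
    return sc.SimulationConfig(
        seed=seed, reads_per_sample=reads,
        pcr_substitution_rate=0.0, seq_substitution_rate=0.0,
        homopolymer_indel_rate=0.0, chimera_fraction=0.0,
    )


def _small_setup(n_species=3, seed=13):
    templates = sc.generate_reference_set(n_species, (0.08, 0.30), seed=seed)
    variants = {
        t.species_id: sc.generate_intragenomic_variants(t, 1, seed=seed)
        for t in templates
    }
    design = sc.assemble_individuals_community(templates, True, seed=seed)
    genomes = sc.default_genomes(design, variants)
    return templates, variants, design, genomes


class TestSimulateReads:
    def test_noise_free_reads_are_template_prefixes(self):
        _t, _v, design, genomes = _small_setup()
        reads, truth = sc.simulate_reads(design, genomes, _noise_free())
        assert len(reads) == len(truth) == 30 * len(design.samples)
        by_sample = {s.sample_id: s for s in design.samples}
        for read, rec in zip(reads, truth):
            sample = by_sample[rec.sample_id]
            header = len(sample.mid_tag) + len(sample.forward_primer)
            insert = read.sequence[header:]
            variant_seq = genomes[rec.individual_id].variant_sequences[
                rec.variant_id
            ]
            assert variant_seq.startswith(insert)
            assert read.sequence.startswith(sample.mid_tag)

    def test_identical_seed_identical_output(self):
        _t, _v, design, genomes = _small_setup()
        r1, t1 = sc.simulate_reads(design, genomes, _noise_free())
        r2, t2 = sc.simulate_reads(design, genomes, _noise_free())
        assert r1 == r2 and t1 == t2

    def test_chimera_fraction_flags_reads(self):
        _t, _v, design, genomes = _small_setup()
        config = sc.SimulationConfig(
            seed=4, reads_per_sample=300, chimera_fraction=0.1,
            pcr_substitution_rate=0.0, seq_substitution_rate=0.0,
            homopolymer_indel_rate=0.0,
        )
        _reads, truth = sc.simulate_reads(design, genomes, config)
        n_chim = sum(t.is_chimera for t in truth)
        n = len(truth)
        # binomial(n, 0.1) within 5 sigma
        assert abs(n_chim - 0.1 * n) < 5 * (n * 0.1 * 0.9) ** 0.5
        assert all(
            t.chimera_parents is not None for t in truth if t.is_chimera
        )

    def test_empty_design_rejected(self):
        with pytest.raises(Exception):
            sc.simulate_reads(
                sc.CommunityDesign(samples=()), {}, _noise_free()
            )

    def test_variant_frequency_law(self):
        # with zero error rates, per-variant read fractions follow
        # copy frequencies (chi-square goodness of fit at alpha = 0.01)
        t = _template(seed=17)
        variants = sc.generate_intragenomic_variants(
            t, 3, substitutions_per_variant=3,
            frequency_weights=(0.6, 0.3, 0.1), seed=17,
        )
        design = sc.assemble_individuals_community([t], True, seed=17)
        genomes = sc.default_genomes(design, {"spX": variants})
        _reads, truth = sc.simulate_reads(
            design, genomes, _noise_free(seed=17, reads=10000)
        )
        counts = {v.variant_id: 0 for v in variants}
        for rec in truth:
            counts[rec.variant_id] += 1
        observed = [counts[v.variant_id] for v in variants]
        expected = [v.copy_frequency * 10000 for v in variants]
        assert sps.chisquare(observed, expected).pvalue > 0.01


class TestFixtureIO:
    def test_round_trip(self, tmp_path):
        from mockotu.demux_filter import read_fastq, read_tagmap

        templates, variants, design, genomes = _small_setup()
        reads, truth = sc.simulate_reads(design, genomes, _noise_free())
        sc.write_fixture(tmp_path, design, templates, variants, reads, truth)
        back = read_fastq(tmp_path / "reads.fastq")
        assert back == reads
        tagmap = read_tagmap(tmp_path / "tagmap.tsv")
        assert [s for s, _m, _p in tagmap] == [
            s.sample_id for s in design.samples
        ]
        truth_back = sc.read_truth(tmp_path / "truth.tsv")
        assert truth_back == truth
        refs = (tmp_path / "refs.fasta").read_text().count(">")
        assert refs == len(templates)
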