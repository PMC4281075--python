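"""Read simulation: sampling, clone construction, mutation model, output."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairbin.errors import ConfigurationError, InputError
from pairbin.fixtures import TOY_SPECIES
from pairbin.simulator import (
    Genome,
    SimConfig,
    make_long_clones,
    make_roche_set,
    make_short_clones,
    mutate,
    random_genomes,
    revcomp,
    sample_fragments,
    simulate_all,
    write_dataset,
)


@pytest.fixture(scope="module")
def genomes():
    return random_genomes(4, 12_000, seed=11, organism_taxon_ids=TOY_SPECIES)


@pytest.fixture(scope="module")
def genome_lookup(genomes):
    return {g.genome_id: g for g in genomes}


class TestMutate:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate("ACGTN" * 20, 0.0, rng) == "ACGTN" * 20

    def test_rate_one_changes_every_non_n_position(self):
        rng = np.random.default_rng(0)
        seq = "ACGTN" * 100
        out = mutate(seq, 1.0, rng)
        assert len(out) == len(seq)
        for a, b in zip(seq, out):
            if a == "N":
                assert b == "N"
            else:
                assert b != a and b in "ACGT"

    def test_observed_rate_within_three_sigma_of_binomial(self):
        n, rate = 1_000_000, 0.01
        rng = np.random.default_rng(42)
        seq = "ACGT" * (n // 4)
        out = mutate(seq, rate, rng)
        mism = sum(a != b for a, b in zip(seq, out))
        sigma = (n * rate * (1 - rate)) ** 0.5
        assert abs(mism - n * rate) <= 3 * sigma

    def test_invalid_characters_rejected(self):
        with pytest.raises(InputError):
            mutate("ACGU", 0.1, np.random.default_rng(0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", max_size=200), st.floats(0, 1))
    def test_length_and_alphabet_preserved(self, seq, rate):
        out = mutate(seq, rate, np.random.default_rng(1))
        assert len(out) == len(seq)
        assert set(out) <= set("ACGTN")
        # N positions never touched
        assert all(b == "N" for a, b in zip(seq, out) if a == "N")


class TestSampleFragments:
    def test_equal_proportions_exact_division(self, genomes):
        config = SimConfig(n_fragments=40, seed=1)
        reads = sample_fragments(genomes, config)
        assert len(reads) == 40
        per = {g.genome_id: 0 for g in genomes}
        for r in reads:
            per[r.genome_id] += 1
        assert set(per.values()) == {10}

    def test_remainder_goes_to_first_genomes_in_order(self, genomes):
        config = SimConfig(n_fragments=10, seed=1)
        per = {}
        for r in sample_fragments(genomes, config):
            per[r.genome_id] = per.get(r.genome_id, 0) + 1
        counts = [per.get(g.genome_id, 0) for g in genomes]
        assert counts == [3, 3, 2, 2]

    def test_zero_fragments(self, genomes):
        assert sample_fragments(genomes, SimConfig(n_fragments=0, seed=1)) == []

    def test_deterministic_under_seed(self, genomes):
        config = SimConfig(n_fragments=25, seed=9)
        assert sample_fragments(genomes, config) == sample_fragments(genomes, config)

    def test_truth_slices_match_for_unmutated_fragments(self, genomes, genome_lookup):
        for r in sample_fragments(genomes, SimConfig(n_fragments=30, seed=2)):
            src = genome_lookup[r.genome_id].sequence
            assert r.sequence == src[r.start : r.end]
            assert r.end - r.start == len(r.sequence) == 400

    def test_short_genome_rejected(self):
        tiny = [Genome("tiny", TOY_SPECIES[0], "ACGT" * 20)]
        with pytest.raises(ConfigurationError, match="tiny"):
            sample_fragments(tiny, SimConfig(n_fragments=1, seed=0))


class TestRocheSet:
    def test_lengths_and_count(self, genomes):
        reads = make_roche_set(genomes, SimConfig(n_fragments=50, seed=3))
        assert len(reads) == 50
        assert {len(r.sequence) for r in reads} == {400}

    def test_rate_zero_reads_are_exact_genome_substrings(self, genomes, genome_lookup):
        config = SimConfig(n_fragments=20, mutation_rate=0.0, seed=4)
        for r in make_roche_set(genomes, config):
            src = genome_lookup[r.genome_id].sequence
            assert r.sequence == src[r.start : r.end]


class TestShortClones:
    def test_coordinates_and_orientation(self, genomes, genome_lookup):
        config = SimConfig(n_fragments=20, mutation_rate=0.0, seed=5)
        fragments = sample_fragments(genomes, config)
        pairs = make_short_clones(fragments, config)
        assert len(pairs) == 20
        for pair, parent in zip(pairs, fragments):
            m1, m2 = pair.mate1, pair.mate2
            assert (m1.start, m1.end) == (parent.start, parent.start + 150)
            assert (m2.start, m2.end) == (parent.end - 150, parent.end)
            assert (m1.strand, m2.strand) == ("+", "-")
            src = genome_lookup[parent.genome_id].sequence
            assert m1.sequence == src[m1.start : m1.end]
            assert revcomp(m2.sequence) == src[m2.start : m2.end]
            assert m1.genome_id == m2.genome_id
            assert m1.organism_taxon_id == m2.organism_taxon_id

    def test_too_short_parent_rejected(self, genomes):
        config = SimConfig(n_fragments=1, seed=0)
        fragment = sample_fragments(genomes, config)[0]
        stub = type(fragment)(
            fragment.read_id, fragment.sequence[:200], fragment.organism_taxon_id,
            fragment.genome_id, fragment.start, fragment.start + 200, "+",
        )
        with pytest.raises(ConfigurationError):
            make_short_clones([stub], config)


class TestLongClones:
    def test_spans_within_bounds(self, genomes):
        config = SimConfig(n_fragments=200, seed=6)
        fragments = sample_fragments(genomes, config)
        pairs = make_long_clones(genomes, fragments, config)
        assert pairs
        assert all(2000 <= p.insert_span <= 5000 for p in pairs)

    def test_degenerate_interval_fixes_span(self, genomes):
        config = SimConfig(n_fragments=50, seed=6,
                           long_insert_min=3000, long_insert_max=3000)
        fragments = sample_fragments(genomes, config)
        pairs = make_long_clones(genomes, fragments, config)
        assert all(p.insert_span == 3000 for p in pairs)

    def test_mean_span_near_uniform_expectation(self, genomes):
        config = SimConfig(n_fragments=2000, seed=8)
        fragments = sample_fragments(genomes, config)
        spans = [p.insert_span for p in make_long_clones(genomes, fragments, config)]
        # Uniform[2000, 5000]: mean 3500, sd ~866; allow 4 standard errors.
        se = 866 / len(spans) ** 0.5
        assert abs(np.mean(spans) - 3500) < 4 * se

    def test_rate_zero_mates_match_genome(self, genomes, genome_lookup):
        config = SimConfig(n_fragments=50, mutation_rate=0.0, seed=9)
        fragments = sample_fragments(genomes, config)
        for p in make_long_clones(genomes, fragments, config):
            src = genome_lookup[p.mate1.genome_id].sequence
            assert p.mate1.sequence == src[p.mate1.start : p.mate1.end]
            assert revcomp(p.mate2.sequence) == src[p.mate2.start : p.mate2.end]


class TestSimulateAll:
    def test_three_sets_share_truth_provenance(self, genomes):
        config = SimConfig(n_fragments=30, seed=10)
        ds = simulate_all(genomes, config)
        assert len(ds["roche"]) == len(ds["short"]) == 30
        for roche, pair in zip(ds["roche"], ds["short"]):
            assert pair.mate1.genome_id == roche.genome_id
            assert pair.mate1.start == roche.start

    def test_byte_identical_under_same_config(self, genomes):
        config = SimConfig(n_fragments=15, seed=12)
        assert simulate_all(genomes, config) == simulate_all(genomes, config)


class TestWriteDataset:
    def test_pair_files_and_truth_rows(self, genomes, tmp_path):
        config = SimConfig(n_fragments=10, seed=13)
        pairs = make_short_clones(sample_fragments(genomes, config), config)
        paths = write_dataset(pairs, tmp_path / "ds", fmt="fastq")
        r1, r2, truth = paths
        from Bio import SeqIO

        rec1 = list(SeqIO.parse(str(r1), "fastq"))
        rec2 = list(SeqIO.parse(str(r2), "fastq"))
        assert len(rec1) == len(rec2) == 10
        assert rec1[0].id.endswith("/1") and rec2[0].id.endswith("/2")
        lines = (tmp_path / "ds_truth.tsv").read_text().splitlines()
        assert len(lines) == 1 + 20  # header + two rows per pair

    def test_sequence_round_trip(self, genomes, tmp_path):
        config = SimConfig(n_fragments=8, seed=14)
        reads = make_roche_set(genomes, config)
        (fasta, _) = write_dataset(reads, tmp_path / "frags", fmt="fasta")
        from Bio import SeqIO

        back = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        assert back == {r.read_id: r.sequence for r in reads}

    def test_empty_set_is_valid(self, tmp_path):
        fasta, truth = write_dataset([], tmp_path / "empty", fmt="fasta")
        assert fasta.read_text() == ""
        assert truth.read_text().startswith("read_id\t")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mutation_rate": 1.5},
            {"long_insert_min": 10, "long_insert_max": 5},
            {"fragment_length": 200, "mate_length": 150},
            {"length_jitter": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)
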