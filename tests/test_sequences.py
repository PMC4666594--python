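"""Sequence I/O, mutation mechanics, synthetic generation, splitting."""

import numpy as np
import pytest

from genomogram.sequences import (
    DnaSequence,
    MutationRecord,
    SequenceError,
    apply_mutation,
    default_class_counts,
    read_fasta,
    read_mutation_table,
    simulate_dataset,
    split_dataset,
    write_fasta,
    write_mutation_table,
)
from conftest import small_config


class TestFastaIO:
    def test_reads_and_uppercases(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">g1\nacgt\n")
        seqs = read_fasta(p)
        assert len(seqs) == 1
        assert seqs[0].id == "g1"
        assert seqs[0].bases == "ACGT"
        assert seqs[0].n == 4

    def test_preserves_record_order(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">g1\nACGT\nACGT\n>g2\nTTTT\n")
        seqs = read_fasta(p)
        assert [s.id for s in seqs] == ["g1", "g2"]
        assert seqs[0].bases == "ACGTACGT"  # wrapped lines joined

    def test_invalid_character_names_record_and_offset(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">g1\nACGX\n")
        with pytest.raises(SequenceError, match=r"g1.*offset 4"):
            read_fasta(p)

    def test_ambiguity_codes_rejected(self, tmp_path):
        p = tmp_path / "n.fa"
        p.write_text(">g1\nACGN\n")
        with pytest.raises(SequenceError):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "absent.fa")

    def test_round_trip(self, tmp_path, rng):
        seqs = [
            DnaSequence(f"s{i}", "".join(rng.choice(list("ACGT"), size=80)))
            for i in range(3)
        ]
        p = tmp_path / "rt.fa"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.id, s.bases) for s in back] == [
            (s.id, s.bases) for s in seqs
        ]


class TestMutationTableIO:
    def test_round_trip(self, tmp_path):
        recs = [
            MutationRecord("g1", "substitution", 3, ref="G", alt="T"),
            MutationRecord("g2", "deletion", 2, del_length=5),
        ]
        p = tmp_path / "m.tsv"
        write_mutation_table(recs, p)
        assert read_mutation_table(p) == recs


class TestApplyMutation:
    def test_substitution(self):
        seq = DnaSequence("s", "ACGTA")
        m = MutationRecord("s", "substitution", 3, ref="G", alt="T")
        out = apply_mutation(seq, m)
        assert out.bases == "ACTTA"
        assert "3G>T" in out.id

    def test_deletion(self):
        seq = DnaSequence("s", "ACGTA")
        out = apply_mutation(seq, MutationRecord("s", "deletion", 2, del_length=2))
        assert out.bases == "ATA"

    def test_ref_mismatch(self):
        seq = DnaSequence("s", "ACGTA")
        m = MutationRecord("s", "substitution", 3, ref="A", alt="T")
        with pytest.raises(SequenceError, match="ref mismatch"):
            apply_mutation(seq, m)

    def test_position_out_of_range(self):
        seq = DnaSequence("s", "ACGTA")
        with pytest.raises(SequenceError, match="out of range"):
            apply_mutation(seq, MutationRecord("s", "substitution", 6, ref="A", alt="T"))

    def test_deletion_overrun(self):
        seq = DnaSequence("s", "ACGTA")
        with pytest.raises(SequenceError, match="overruns"):
            apply_mutation(seq, MutationRecord("s", "deletion", 4, del_length=3))

    @pytest.mark.parametrize("pos,length", [(1, 1), (2, 3), (5, 1)])
    def test_deletion_length_arithmetic(self, pos, length):
        seq = DnaSequence("s", "ACGTACGTA")
        out = apply_mutation(seq, MutationRecord("s", "deletion", pos, del_length=length))
        assert out.n == seq.n - length

    def test_record_invariants(self):
        with pytest.raises(SequenceError):
            MutationRecord("g", "substitution", 1, ref="A", alt="A")
        with pytest.raises(SequenceError):
            MutationRecord("g", "deletion", 1, alt="T")
        with pytest.raises(SequenceError):
            MutationRecord("g", "inversion", 1, ref="A", alt="T")


class TestSimulateDataset:
    def test_deterministic(self):
        cfg = small_config()
        a = simulate_dataset(cfg, seed=7)
        b = simulate_dataset(cfg, seed=7)
        assert [(s.id, s.bases, s.label) for s in a.samples] == [
            (s.id, s.bases, s.label) for s in b.samples
        ]

    def test_seed_changes_data(self):
        cfg = small_config()
        a = simulate_dataset(cfg, seed=7)
        b = simulate_dataset(cfg, seed=8)
        assert [s.bases for s in a.samples] != [s.bases for s in b.samples]

    def test_default_config_totals(self):
        ds = simulate_dataset(seed=7)
        assert len(ds) == 534
        assert len(ds.class_names) == 14
        assert ds.counts == default_class_counts()

    def test_class_counts_match_config(self, small_dataset):
        assert small_dataset.counts == small_config().class_counts

    def test_substitution_samples_at_hamming_distance_one(self, small_dataset):
        refs = {
            s.id.split("|")[0]: s
            for s in small_dataset.samples
            if s.label == "Normal"
        }
        subs = [s for s in small_dataset.samples if s.label.endswith("Substitution")]
        assert subs
        for s in subs:
            ref = refs[s.id.split("|")[0]]
            assert len(s.bases) == len(ref.bases)
            hamming = sum(a != b for a, b in zip(s.bases, ref.bases))
            assert hamming == 1

    def test_deletion_samples_shorter_than_reference(self, small_dataset):
        refs = {
            s.id.split("|")[0]: s
            for s in small_dataset.samples
            if s.label == "Normal"
        }
        dels = [s for s in small_dataset.samples if s.label.endswith("Deletion")]
        assert dels
        for s in dels:
            ref = refs[s.id.split("|")[0]]
            assert 1 <= len(ref.bases) - len(s.bases) <= 10

    def test_bad_configs_rejected(self):
        from genomogram.sequences import GeneProfile, SimulationConfig

        genes = [GeneProfile("g", 100, (0.25, 0.25, 0.25, 0.25))]
        with pytest.raises(ValueError, match="unknown gene"):
            SimulationConfig(genes=genes, class_counts={"other Substitution": 3},
                             deletion_length_range=(1, 5))
        with pytest.raises(ValueError, match="count"):
            SimulationConfig(genes=genes, class_counts={"g Substitution": 0},
                             deletion_length_range=(1, 5))
        with pytest.raises(ValueError, match="deletion range"):
            SimulationConfig(genes=genes, class_counts={"g Deletion": 3},
                             deletion_length_range=(1, 200))


class TestSplitDataset:
    def test_flooring_rule_small_class(self):
        from genomogram.sequences import DnaSequence, LabeledDataset

        samples = [DnaSequence(f"s{i}", "ACGTACGT", label="only") for i in range(10)]
        ds = LabeledDataset(samples, ["only"])
        train, val, test = split_dataset(ds, seed=0)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_default_dataset_partition_sizes(self):
        ds = simulate_dataset(seed=3)
        train, val, test = split_dataset(ds, seed=3)
        assert len(train) + len(val) + len(test) == 534
        assert len(val) + len(test) <= 160
        assert len(train) >= 374

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_partitions_disjoint_and_exhaustive(self, small_dataset, seed):
        train, val, test = split_dataset(small_dataset, seed=seed)
        ids = [s.id for part in (train, val, test) for s in part.samples]
        assert sorted(ids) == sorted(s.id for s in small_dataset.samples)
        assert len(set(ids)) == len(ids)

    def test_stratified_per_class(self, small_dataset):
        train, val, test = split_dataset(small_dataset, seed=5)
        for cls, n in small_dataset.counts.items():
            n_val = int(np.floor(0.15 * n))
            assert val.counts[cls] == n_val
            assert test.counts[cls] == n_val
            assert train.counts[cls] == n - 2 * n_val

    def test_same_seed_same_partition(self, small_dataset):
        a = split_dataset(small_dataset, seed=9)
        b = split_dataset(small_dataset, seed=9)
        for pa, pb in zip(a, b):
            assert [s.id for s in pa.samples] == [s.id for s in pb.samples]

    def test_tiny_class_warns(self):
        from genomogram.sequences import DnaSequence, LabeledDataset

        samples = [DnaSequence(f"s{i}", "ACGT", label="tiny") for i in range(3)]
        ds = LabeledDataset(samples, ["tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            split_dataset(ds, seed=0)
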