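import numpy as np
import pytest
from scipy import stats

from greybind.dataset import (
    BINDING,
    NON_BINDING,
    FastaParseError,
    LabeledDataset,
    ProteinRecord,
    attach_labels,
    default_profiles,
    filter_min_length,
    filter_x_runs,
    generate_synthetic,
    greedy_identity_filter,
    pairwise_identity,
    read_fasta,
    read_labels,
    write_fasta,
    write_labels,
)
from greybind.encoding import STANDARD_RESIDUES


class TestRecords:
    def test_record_validation(self):
        with pytest.raises(ValueError, match="id"):
            ProteinRecord(id="", sequence="ACD")
        with pytest.raises(ValueError, match="empty sequence"):
            ProteinRecord(id="p", sequence="")
        with pytest.raises(ValueError, match="label"):
            ProteinRecord(id="p", sequence="ACD", label="maybe")

    def test_dataset_counts_and_duplicates(self):
        records = (
            ProteinRecord("a", "ACDY", BINDING),
            ProteinRecord("b", "ACDY", NON_BINDING),
            ProteinRecord("c", "ACDY", BINDING),
        )
        data = LabeledDataset(records)
        assert data.class_counts == {BINDING: 2, NON_BINDING: 1}
        with pytest.raises(ValueError, match="duplicate"):
            LabeledDataset(records + (ProteinRecord("a", "WWWW", BINDING),))

    def test_dataset_rejects_unlabeled(self):
        with pytest.raises(ValueError, match="unlabeled"):
            LabeledDataset((ProteinRecord("a", "ACDY"),))


class TestFastaIO:
    def test_read_two_records_in_order(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">p1 some description\nACDE\nFGHI\n>p2\nWYWY\n")
        records = read_fasta(path)
        assert [r.id for r in records] == ["p1", "p2"]
        assert records[0].sequence == "ACDEFGHI"
        assert records[1].sequence == "WYWY"

    def test_roundtrip_424_synthetic_records(self, tmp_path):
        data = generate_synthetic(212, length_range=(50, 90), seed=3)
        path = tmp_path / "bench.fasta"
        write_fasta(data.records, path)
        back = read_fasta(path)
        assert len(back) == 424
        assert [r.id for r in back] == [r.id for r in data.records]
        assert [r.sequence for r in back] == [r.sequence for r in data.records]
        assert [r.label for r in back] == [r.label for r in data.records]

    def test_duplicate_id_names_offender(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">p1\nACDE\n>p1\nWYWY\n")
        with pytest.raises(FastaParseError, match="p1"):
            read_fasta(path)

    def test_sequence_less_header_has_line_number(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">p1\n>p2\nACDE\n")
        with pytest.raises(FastaParseError, match=":1:"):
            read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(FastaParseError, match="no FASTA"):
            read_fasta(path)

    def test_data_before_header_rejected(self, tmp_path):
        path = tmp_path / "stray.fasta"
        path.write_text("ACDE\n>p1\nACDE\n")
        with pytest.raises(FastaParseError, match=":1:"):
            read_fasta(path)

    def test_label_tokens_roundtrip(self, tmp_path):
        path = tmp_path / "labeled.fasta"
        write_fasta([ProteinRecord("p1", "ACDE", BINDING)], path)
        assert ">p1|1" in path.read_text()
        assert read_fasta(path)[0].label == BINDING

    def test_label_sidecar_roundtrip(self, tmp_path):
        records = [ProteinRecord("a", "ACDE", BINDING), ProteinRecord("b", "ACDE", NON_BINDING)]
        path = tmp_path / "labels.tsv"
        write_labels(records, path)
        labels = read_labels(path)
        assert labels == {"a": BINDING, "b": NON_BINDING}
        data = attach_labels([ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACDE")], labels)
        assert data.class_counts == {BINDING: 1, NON_BINDING: 1}


class TestScreeningFilters:
    def test_min_length_boundary(self):
        short = ProteinRecord("short", "A" * 49)
        exact = ProteinRecord("exact", "A" * 50)
        kept, removed = filter_min_length([short, exact])
        assert kept == [exact]
        assert removed == [short]

    def test_min_length_empty_input(self):
        assert filter_min_length([]) == ([], [])

    def test_x_run_boundary(self):
        eleven = ProteinRecord("r11", "A" * 20 + "X" * 11 + "A" * 20)
        ten = ProteinRecord("r10", "A" * 20 + "X" * 10 + "A" * 20)
        scattered = ProteinRecord("scat", ("AX" * 11) + "A" * 30)
        kept, removed = filter_x_runs([eleven, ten, scattered])
        assert [r.id for r in kept] == ["r10", "scat"]
        assert [r.id for r in removed] == ["r11"]

    def test_identity_filter_removes_duplicate(self):
        a = ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY" * 3)
        b = ProteinRecord("b", "ACDEFGHIKLMNPQRSTVWY" * 3)
        assert [r.id for r in greedy_identity_filter([a, b])] == ["a"]

    def test_identity_filter_keeps_disjoint(self):
        a = ProteinRecord("a", "ACDEFGHIKL" * 5)
        b = ProteinRecord("b", "MNPQRSTVWY" * 5)
        assert pairwise_identity(a.sequence, b.sequence) <= 0.25
        assert len(greedy_identity_filter([a, b])) == 2

    def test_identity_filter_single_record(self):
        a = ProteinRecord("a", "ACDEFGHIKL")
        assert greedy_identity_filter([a]) == [a]

    def test_identity_of_identical_sequences_is_one(self):
        assert pairwise_identity("ACDEFG", "ACDEFG") == pytest.approx(1.0)

    def test_filter_composition_idempotent(self):
        data = generate_synthetic(10, length_range=(50, 80), seed=8)
        records = list(data.records)
        once, _ = filter_min_length(records)
        once, _ = filter_x_runs(once)
        once = greedy_identity_filter(once)
        twice, _ = filter_min_length(once)
        twice, _ = filter_x_runs(twice)
        twice = greedy_identity_filter(twice)
        assert twice == once


class TestSyntheticGenerator:
    def test_deterministic_for_fixed_seed(self):
        a = generate_synthetic(5, seed=42)
        b = generate_synthetic(5, seed=42)
        assert a.records == b.records
        assert a.records != generate_synthetic(5, seed=43).records

    def test_benchmark_shape(self):
        data = generate_synthetic(212, length_range=(50, 60), seed=0)
        assert len(data) == 424
        assert data.class_counts == {BINDING: 212, NON_BINDING: 212}

    def test_positive_class_enriched_in_k_and_r(self):
        data = generate_synthetic(40, length_range=(80, 120), seed=2)
        def kr_fraction(label):
            seqs = "".join(r.sequence for r in data if r.label == label)
            return (seqs.count("K") + seqs.count("R")) / len(seqs)
        assert kr_fraction(BINDING) > 2.5 * kr_fraction(NON_BINDING)

    def test_equal_profiles_give_matching_compositions(self):
        profiles = {BINDING: np.full(20, 0.05), NON_BINDING: np.full(20, 0.05)}
        data = generate_synthetic(60, length_range=(80, 120), bias=profiles, seed=5)
        for label in (BINDING, NON_BINDING):
            seqs = "".join(r.sequence for r in data if r.label == label)
            n = len(seqs)
            lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.05)
            for residue in STANDARD_RESIDUES:
                assert lo <= seqs.count(residue) <= hi, residue

    def test_invalid_profile_rejected(self):
        bad = {BINDING: np.full(20, 0.04), NON_BINDING: np.full(20, 0.05)}
        with pytest.raises(ValueError, match="distribution"):
            generate_synthetic(5, bias=bad, seed=0)

    def test_length_floor_enforced(self):
        with pytest.raises(ValueError, match="50"):
            generate_synthetic(5, length_range=(40, 60), seed=0)

    def test_lengths_within_range(self):
        data = generate_synthetic(30, length_range=(50, 55), seed=9)
        assert all(50 <= len(r) <= 55 for r in data)

    def test_default_profiles_are_distributions(self):
        for profile in default_profiles().values():
            assert profile.shape == (20,)
            assert profile.sum() == pytest.approx(1.0)
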