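import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncsubloc.exceptions import DataError
from lncsubloc.io import (
    FoldChangeTable,
    TranscriptRecord,
    normalize_sequence,
    read_annotation,
    read_fasta,
    read_foldchange_table,
    read_pwm,
    read_pwm_collection,
    write_fasta,
    write_pwm,
)
from lncsubloc.motifs import PWM


class TestReadFasta:
    def test_multiline_sequence_is_concatenated(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">tx1\nACGT\nACGT\n")
        assert read_fasta(p) == [("tx1", "ACGTACGT")]

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fasta")

    def test_sequence_before_header_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("ACGT\n>tx1\nACGT\n")
        with pytest.raises(DataError, match="before any FASTA header"):
            read_fasta(p)

    def test_duplicate_ids_rejected_with_offsets(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">tx1\nACGT\n>tx2\nGGGG\n>tx1\nTTTT\n")
        with pytest.raises(DataError, match="offsets 0 and 2"):
            read_fasta(p)

    def test_empty_record_rejected(self, tmp_path):
        p = tmp_path / "er.fasta"
        p.write_text(">tx1\n>tx2\nACGT\n")
        with pytest.raises(DataError, match="empty"):
            read_fasta(p)

    def test_roundtrip_100_random_records(self, tmp_path, rng):
        records = [
            (f"tx{i}", "".join(rng.choice(list("ACGTN"), size=rng.integers(10, 300))))
            for i in range(100)
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(records, p)
        assert read_fasta(p) == records


class TestNormalizeSequence:
    @pytest.mark.parametrize(
        "raw,expected",
        [("acgu", "ACGT"), ("ACGRN", "ACGNN"), ("uuu", "TTT"), ("AcGtN", "ACGTN")],
    )
    def test_examples(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_empty_raises(self):
        with pytest.raises(DataError):
            normalize_sequence("")

    def test_all_n_warns(self):
        with pytest.warns(UserWarning, match="all-N"):
            assert normalize_sequence("RYSW") == "NNNN"

    @given(st.text(alphabet="ACGTUNRYSWKMBDHVacgtun", min_size=1, max_size=80))
    def test_idempotent_with_canonical_alphabet(self, raw):
        once = normalize_sequence(raw)
        assert normalize_sequence(once) == once
        assert set(once) <= set("ACGTN")


class TestAnnotation:
    def test_parse_and_chromosome_normalization(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "transcript_id\tbiotype\tchromosome\n"
            "tx1\tantisense\tchr7\n"
            "tx2\tlincRNA\tX\n"
            "tx3\tsense_intronic\tchrM\n"
        )
        ann = read_annotation(p)
        assert ann["tx1"] == ("antisense", "7")
        assert ann["tx2"] == ("lincRNA", "X")
        assert ann["tx3"] == ("sense_intronic", "MT")

    def test_unknown_biotype_falls_back_with_warning(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("transcript_id\tbiotype\tchromosome\ntx1\tTEC\t1\n")
        with pytest.warns(UserWarning, match="unknown biotype"):
            ann = read_annotation(p)
        assert ann["tx1"] == ("other", "1")

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("transcript_id\tbiotype\ntx1\tantisense\n")
        with pytest.raises(DataError, match="chromosome"):
            read_annotation(p)

    def test_conflicting_duplicate_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "transcript_id\tbiotype\tchromosome\ntx1\tantisense\t1\ntx1\tlincRNA\t2\n"
        )
        with pytest.raises(DataError, match="conflicting"):
            read_annotation(p)

    def test_fixture_file_equals_hand_built_map(self, tmp_path, rng):
        biotypes = ["lincRNA", "antisense", "sense_intronic", "sense_overlapping"]
        chroms = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
        rows, expected = [], {}
        for i in range(50):
            b = biotypes[rng.integers(len(biotypes))]
            c = chroms[rng.integers(len(chroms))]
            rows.append(f"tx{i}\t{b}\tchr{c}")
            expected[f"tx{i}"] = (b, c)
        p = tmp_path / "ann.tsv"
        p.write_text("transcript_id\tbiotype\tchromosome\n" + "\n".join(rows) + "\n")
        assert read_annotation(p) == expected


class TestPWMIO:
    def test_consensus_parse(self, tmp_path):
        p = tmp_path / "m1.txt"
        p.write_text("Pos\tA\tC\tG\tU\n1\t1\t0\t0\t0\n2\t0\t1\t0\t0\n3\t0\t0\t1\t0\n")
        pwm = read_pwm(p)
        assert pwm.motif_id == "m1"
        assert pwm.width == 3
        np.testing.assert_allclose(pwm.probs, np.eye(4)[:3])

    def test_unnormalized_row_renormalized_with_warning(self, tmp_path):
        p = tmp_path / "m2.txt"
        p.write_text("Pos A C G U\n1 0.3 0.3 0.3 0.3\n")
        with pytest.warns(UserWarning, match="renormalized"):
            pwm = read_pwm(p)
        np.testing.assert_allclose(pwm.probs[0], [0.25] * 4)

    def test_negative_entry_rejected(self, tmp_path):
        p = tmp_path / "m3.txt"
        p.write_text("Pos A C G U\n1 -0.1 0.4 0.4 0.3\n")
        with pytest.raises(DataError, match="negative"):
            read_pwm(p)

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "m4.txt"
        p.write_text("Pos A C G U\n1 0.25 0.25 0.5\n")
        with pytest.raises(DataError, match="5 columns"):
            read_pwm(p)

    def test_empty_matrix_rejected(self, tmp_path):
        p = tmp_path / "m5.txt"
        p.write_text("Pos A C G U\n")
        with pytest.raises(DataError, match="no positions"):
            read_pwm(p)

    def test_roundtrip_random_pwms(self, tmp_path, rng):
        for i in range(10):
            probs = rng.dirichlet(np.ones(4), size=rng.integers(3, 9))
            pwm = PWM(motif_id=f"r{i}", probs=probs)
            path = tmp_path / f"r{i}.txt"
            write_pwm(pwm, path)
            back = read_pwm(path)
            np.testing.assert_allclose(back.probs, probs, atol=1e-9)

    def test_collection_reads_directory_sorted(self, tmp_path):
        for name in ("b", "a"):
            (tmp_path / f"{name}.txt").write_text("Pos A C G U\n1 1 0 0 0\n")
        pwms = read_pwm_collection(tmp_path)
        assert [p.motif_id for p in pwms] == ["a", "b"]


class TestFoldChange:
    def test_parse_and_nonfinite_dropped(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("transcript_id\tl2fc\ntx1\t2.5\ntx2\tnan\ntx3\t-1.0\n")
        with pytest.warns(UserWarning, match="non-finite"):
            table = read_foldchange_table(p, "K562", 4)
        assert table.entries == {"tx1": 2.5, "tx3": -1.0}
        assert table.n_samples == 4

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("transcript_id\tvalue\ntx1\t2.5\n")
        with pytest.raises(DataError, match="l2fc"):
            read_foldchange_table(p, "K562", 4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(Exception, match="n_samples"):
            FoldChangeTable(cell_type="K562", entries={"tx1": 1.0}, n_samples=1)

    def test_roundtrip(self, tmp_path, rng):
        entries = {f"tx{i}": float(rng.normal()) for i in range(30)}
        p = tmp_path / "fc.tsv"
        p.write_text(
            "transcript_id\tl2fc\n"
            + "\n".join(f"{t}\t{v!r}" for t, v in entries.items())
            + "\n"
        )
        table = read_foldchange_table(p, "HepG2", 3)
        assert table.entries == pytest.approx(entries)


class TestTranscriptRecord:
    def test_invariants_enforced(self):
        with pytest.raises(Exception):
            TranscriptRecord(transcript_id="", sequence="ACGT")
        with pytest.raises(Exception):
            TranscriptRecord(transcript_id="t", sequence="")
        with pytest.raises(Exception):
            TranscriptRecord(transcript_id="t", sequence="acgt")
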