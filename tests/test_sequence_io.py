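"""Readers, label derivation and the matrix store."""

import numpy as np
import pytest

import edkernel as ek
from edkernel.errors import ConfigurationError, FormatError, ParameterError, RecordError
from edkernel.sequence_io import (
    EventTableDialect,
    derive_bp_label,
    read_event_table,
    read_labels,
    read_matrix,
    read_peptide_table,
    write_event_table,
    write_labels,
    write_matrix,
)

# The single-subject event-stream fixture: eight coded events across five
# visit dates, including a diabetes diagnosis (C10..00) and a blood-pressure
# examination code (246..00).
PATIENT_ROWS = """patient_id,event_date,read_code
p1,19951024,C10..00
p1,19951024,137..00
p1,19951030,136..00
p1,19951114,229..00
p1,19951114,22A..00
p1,19951202,246..00
p1,19951202,115..00
p1,19951202,1225.11
"""

EXPECTED_CODES = ("C10..00", "137..00", "136..00", "229..00", "22A..00",
                  "246..00", "115..00", "1225.11")


class TestEventTable:
    def test_single_patient_date_ordering(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text(PATIENT_ROWS)
        ds = read_event_table(p)
        assert len(ds) == 1
        assert ds[0].symbols == EXPECTED_CODES
        assert ds[0].label is None

    def test_row_order_permutation_invariance(self, tmp_path):
        """Shuffling rows with distinct dates leaves the output unchanged;
        equal-date ties keep file order (stable sort)."""
        lines = PATIENT_ROWS.strip().splitlines()
        header, rows = lines[0], lines[1:]
        # rotate blocks of distinct dates while keeping equal-date order
        shuffled = rows[5:] + rows[2:5] + rows[:2]
        p = tmp_path / "shuffled.csv"
        p.write_text("\n".join([header] + shuffled) + "\n")
        ds = read_event_table(p)
        assert ds[0].symbols == EXPECTED_CODES

    def test_single_row_file(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("patient_id,event_date,read_code\np9,20200101,ABC\n")
        ds = read_event_table(p)
        assert len(ds) == 1 and len(ds[0]) == 1

    def test_two_interleaved_subjects(self, tmp_path):
        p = tmp_path / "two.csv"
        p.write_text(
            "patient_id,event_date,read_code\n"
            "a,20200103,A3\nb,20200101,B1\na,20200101,A1\n"
            "b,20200103,B2\na,20200102,A2\nb,20200105,B3\n"
        )
        ds = read_event_table(p)
        assert len(ds) == 2
        assert ds.get("a").symbols == ("A1", "A2", "A3")
        assert ds.get("b").symbols == ("B1", "B2", "B3")

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("pid,event_date,read_code\np1,20200101,A\n")
        with pytest.raises(ConfigurationError, match="patient_id"):
            read_event_table(p)

    def test_unparseable_date_fails_with_row_number(self, tmp_path):
        p = tmp_path / "baddate.csv"
        p.write_text("patient_id,event_date,read_code\np1,20200101,A\np1,notadate,B\n")
        with pytest.raises(RecordError, match="row 3"):
            read_event_table(p)
        ds = read_event_table(p, skip_bad_dates=True)
        assert ds[0].symbols == ("A",)

    def test_writer_reader_round_trip(self, small_ds, tmp_path):
        p = tmp_path / "synth.csv"
        write_event_table(small_ds, p)
        back = read_event_table(
            p, EventTableDialect(date_format="index", label_col="label")
        )
        assert back.ids == tuple(sorted(small_ds.ids))
        for seq in small_ds:
            got = back.get(seq.id)
            assert got.symbols == seq.symbols
            assert got.label == seq.label


def _bp_reader_from(readings):
    """readings: {(seq_id, event_index): (sbp, dbp)}"""
    def reader(seq, i):
        return readings.get((seq.id, i))
    return reader


class TestDeriveBPLabel:
    def _ds(self, codes, timestamps=None):
        seqs = [
            ek.SymbolSequence(sid, tuple(c), timestamps=None if timestamps is None else tuple(timestamps[sid]))
            for sid, c in codes.items()
        ]
        return ek.LabeledDataset(tuple(seqs))

    def test_elevated_bp_before_diagnosis_is_positive(self):
        ds = self._ds({"p": ["246..00", "C10..00"]}, {"p": [1, 2]})
        out = derive_bp_label(ds, bp_reader=_bp_reader_from({("p", 0): (135, 85)}))
        assert out.get("p").label == 1

    def test_elevated_bp_after_diagnosis_is_negative(self):
        ds = self._ds({"p": ["C10..00", "246..00"]}, {"p": [1, 2]})
        out = derive_bp_label(ds, bp_reader=_bp_reader_from({("p", 1): (160, 95)}))
        assert out.get("p").label == -1

    def test_threshold_inclusive_at_130_80(self):
        ds = self._ds({"p": ["246..00", "C10..00"]}, {"p": [1, 2]})
        out = derive_bp_label(ds, bp_reader=_bp_reader_from({("p", 0): (130, 80)}))
        assert out.get("p").label == 1

    def test_one_sided_elevation_is_negative(self):
        ds = self._ds({"p": ["246..00", "C10..00"]}, {"p": [1, 2]})
        out = derive_bp_label(ds, bp_reader=_bp_reader_from({("p", 0): (140, 75)}))
        assert out.get("p").label == -1

    def test_missing_numerics_skipped_and_no_code_dropped(self):
        ds = self._ds(
            {"p": ["246..00", "C10..00"], "q": ["137..00"]},
            {"p": [1, 2], "q": [1]},
        )
        out = derive_bp_label(ds, bp_reader=_bp_reader_from({("p", 0): (None, None)}))
        assert out.ids == ("p",)
        assert out.get("p").label == -1

    def test_raising_thresholds_is_monotone(self):
        readings = {("p", 0): (135, 85)}
        ds = self._ds({"p": ["246..00", "C10..00"]}, {"p": [1, 2]})
        lo = derive_bp_label(ds, sbp_threshold=130, dbp_threshold=80,
                             bp_reader=_bp_reader_from(readings))
        hi = derive_bp_label(ds, sbp_threshold=140, dbp_threshold=90,
                             bp_reader=_bp_reader_from(readings))
        assert lo.get("p").label == 1 and hi.get("p").label == -1


PEPTIDES = """sequence,class
AAWKWAWAKKWAKAKKWAKAA,mod. active
ACDEF,inactive - virtual
FFGHIK,inactive-exp
GLLWK,very active
MMKKW,inactive-virtual
"""


class TestPeptideTable:
    def test_character_tokenization_and_one_vs_all(self, tmp_path):
        p = tmp_path / "pep.csv"
        p.write_text(PEPTIDES)
        ds = read_peptide_table(p)
        assert len(ds[0]) == 21 and ds[0].label == -1
        assert ds[1].symbols == tuple("ACDEF") and ds[1].label == 1
        assert [s.label for s in ds] == [-1, 1, -1, -1, 1]

    def test_class_count_conservation(self, tmp_path):
        p = tmp_path / "pep.csv"
        p.write_text(PEPTIDES)
        ds = read_peptide_table(p)
        y = ds.labels()
        assert int(np.sum(y == 1)) + int(np.sum(y == -1)) == 5

    def test_balanced_subsample(self, tmp_path):
        p = tmp_path / "pep.csv"
        p.write_text(PEPTIDES)
        ds = read_peptide_table(p, balanced=True, seed=0)
        y = ds.labels()
        assert int(np.sum(y == 1)) == int(np.sum(y == -1)) == 2

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "pep.csv"
        p.write_text("sequence,class\n,mod. active\n")
        with pytest.raises(RecordError):
            read_peptide_table(p)

    def test_unknown_class_lists_known(self, tmp_path):
        p = tmp_path / "pep.csv"
        p.write_text("sequence,class\nACDEF,hyperactive\n")
        with pytest.raises(RecordError, match="inactive-virtual"):
            read_peptide_table(p)


class TestMatrixStore:
    def test_kernel_round_trip_exact(self, tmp_path, rng):
        V = rng.normal(size=(3, 3))
        V = V + V.T
        K = ek.KernelMatrix(V, ("a", "b", "c"),
                            {"distance_variant": "k_ed3", "zero_vector_id": "p121",
                             "postprocessing": ["raw", "clip"]})
        path = tmp_path / "k.mat"
        write_matrix(K, path)
        back = read_matrix(path)
        assert isinstance(back, ek.KernelMatrix)
        assert np.array_equal(back.values, K.values)  # bit-exact round trip
        assert back.ids == K.ids
        assert back.provenance["distance_variant"] == "k_ed3"
        assert back.provenance["zero_vector_id"] == "p121"

    def test_distance_round_trip(self, small_ds, tmp_path):
        D = ek.pairwise_distances(small_ds, "k_ed4")
        path = tmp_path / "d.mat"
        write_matrix(D, path)
        back = read_matrix(path)
        assert isinstance(back, ek.DistanceMatrix)
        assert np.array_equal(back.values, D.values)
        assert back.variant == "k_ed4" and back.costs == D.costs

    def test_non_square_payload_rejected(self, tmp_path):
        path = tmp_path / "bad.mat"
        path.write_text('#edkernel-matrix {"kind": "kernel", "ids": ["a", "b"]}\n1.0\t0.0\n')
        with pytest.raises(FormatError):
            read_matrix(path)

    def test_label_file_round_trip(self, small_ds, tmp_path):
        path = tmp_path / "labels.csv"
        write_labels(small_ds, path)
        labs = read_labels(path)
        assert np.array_equal(labs.reindex(list(small_ds.ids)).to_numpy(), small_ds.labels())
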