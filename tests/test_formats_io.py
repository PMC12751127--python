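import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adtcount import (
    CellWhitelist,
    CountMatrix,
    OligoReference,
    PairedFastqStream,
    ReadLayout,
    load_oligo_reference,
    load_whitelist,
    read_dense_csv,
    read_mtx_triplet,
    write_dense_csv,
    write_mtx_triplet,
)
from adtcount.formats_io import FEATURE_TYPE

from conftest import write_fastq


CELL_READ = "AAAACCCCGGGGTTTT" + "ACGTACGTACGT"  # 16 bc + 12 umi
TAG_READ = "AAAATTTTCCCCGGGG"


class TestReadLayout:
    def test_defaults_give_16_12_16_windows(self):
        lay = ReadLayout()
        assert (lay.barcode_len, lay.umi_len, lay.tag_len) == (16, 12, 16)
        assert lay.cellid_read_min_len == 28
        assert lay.oligo_read_min_len == 16

    @pytest.mark.parametrize("kwargs", [{"barcode_start": -1}, {"umi_len": 0}, {"tag_len": 0}])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ReadLayout(**kwargs)


class TestPairedFastq:
    def test_three_pairs_pass_through_in_order(self, tmp_path):
        c = write_fastq(tmp_path / "c.fq", [(f"r{i}", CELL_READ) for i in range(3)])
        o = write_fastq(tmp_path / "o.fq", [(f"r{i}", TAG_READ) for i in range(3)])
        stream = PairedFastqStream([c], [o])
        recs = list(stream)
        assert [r.read_id for r in recs] == ["r0", "r1", "r2"]
        assert recs[0].cell_seq == CELL_READ[:16]
        assert recs[0].umi_seq == CELL_READ[16:28]
        assert recs[0].tag_seq == TAG_READ
        assert stream.n_pairs == 3 and stream.n_skipped_short == 0

    def test_short_cell_read_skipped_and_tallied(self, tmp_path):
        c = write_fastq(tmp_path / "c.fq", [("r0", CELL_READ[:20]), ("r1", CELL_READ)])
        o = write_fastq(tmp_path / "o.fq", [("r0", TAG_READ), ("r1", TAG_READ)])
        stream = PairedFastqStream([c], [o])
        recs = list(stream)
        assert len(recs) == 1 and recs[0].read_id == "r1"
        assert stream.n_skipped_short == 1
        assert stream.n_pairs == 2

    def test_two_lanes_concatenate_in_order(self, tmp_path):
        c1 = write_fastq(tmp_path / "c1.fq", [("a0", CELL_READ), ("a1", CELL_READ)], gzipped=False)
        o1 = write_fastq(tmp_path / "o1.fq", [("a0", TAG_READ), ("a1", TAG_READ)])
        c2 = write_fastq(tmp_path / "c2.fq.gz", [("b0", CELL_READ), ("b1", CELL_READ)], gzipped=True)
        o2 = write_fastq(tmp_path / "o2.fq.gz", [("b0", TAG_READ), ("b1", TAG_READ)], gzipped=True)
        recs = list(PairedFastqStream([c1, c2], [o1, o2]))
        assert [r.read_id for r in recs] == ["a0", "a1", "b0", "b1"]

    def test_unequal_record_counts_error_names_lane(self, tmp_path):
        c = write_fastq(tmp_path / "c.fq", [("r0", CELL_READ), ("r1", CELL_READ)])
        o = write_fastq(tmp_path / "o.fq", [("r0", TAG_READ)])
        with pytest.raises(ValueError, match="lane 0"):
            list(PairedFastqStream([c], [o]))

    def test_mismatched_lane_lists_rejected(self, tmp_path):
        c = write_fastq(tmp_path / "c.fq", [("r0", CELL_READ)])
        with pytest.raises(ValueError, match="pair"):
            PairedFastqStream([c, c], [c])

    def test_empty_input_is_an_error(self, tmp_path):
        c = tmp_path / "c.fq"
        o = tmp_path / "o.fq"
        c.write_text("")
        o.write_text("")
        with pytest.raises(ValueError, match="empty"):
            list(PairedFastqStream([c], [o]))


class TestOligoReference:
    def test_file_order_preserved_with_header(self, tmp_path):
        p = tmp_path / "ref.csv"
        p.write_text("marker,sequence\nCD4,AAAATTTTCCCCGGGG\nCD8,CGCGCGCGATATATAT\n")
        ref = load_oligo_reference(p)
        assert ref.names == ("CD4", "CD8")
        assert ref.sequences[0] == "AAAATTTTCCCCGGGG"

    def test_tab_delimited_without_header(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("CD4\tAAAATTTTCCCCGGGG\nCD8\tCGCGCGCGATATATAT\n")
        assert load_oligo_reference(p).names == ("CD4", "CD8")

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "ref.csv"
        p.write_text("CD4,AAAATTTTCCCCGGGG\nCD4,CGCGCGCGATATATAT\n")
        with pytest.raises(ValueError, match="CD4"):
            load_oligo_reference(p)

    def test_ragged_lengths_rejected(self, tmp_path):
        p = tmp_path / "ref.csv"
        p.write_text("CD4,AAAATTTTCCCCGGGG\nCD8,CGCGCGCGATATATA\n")
        with pytest.raises(ValueError, match="ragged"):
            load_oligo_reference(p)

    def test_non_acgt_rejected(self, tmp_path):
        p = tmp_path / "ref.csv"
        p.write_text("CD4,AAAATTTTCCCCGGGX\n")
        with pytest.raises(ValueError, match="non-ACGT"):
            load_oligo_reference(p)


class TestWhitelist:
    def test_dash_suffix_stripped(self, tmp_path):
        p = tmp_path / "wl.txt"
        p.write_text("AAAACCCCGGGGTTTT-1\nACGTACGTACGTACGT-1\n")
        wl = load_whitelist(p)
        assert wl.barcodes == ("AAAACCCCGGGGTTTT", "ACGTACGTACGTACGT")

    def test_gzipped_whitelist(self, tmp_path):
        p = tmp_path / "wl.txt.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("AAAACCCCGGGGTTTT\n")
        assert len(load_whitelist(p)) == 1

    def test_duplicate_after_stripping_rejected(self, tmp_path):
        p = tmp_path / "wl.txt"
        p.write_text("AAAACCCCGGGGTTTT-1\nAAAACCCCGGGGTTTT-2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_whitelist(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "wl.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_whitelist(p)

    def test_mixed_lengths_rejected(self, tmp_path):
        p = tmp_path / "wl.txt"
        p.write_text("AAAACCCCGGGGTTTT\nAAAACCCCGGGGTTT\n")
        with pytest.raises(ValueError, match="ragged"):
            load_whitelist(p)


def _matrix(counts, rows, cols) -> CountMatrix:
    return CountMatrix(counts=np.array(counts), row_names=tuple(rows), col_names=tuple(cols))


class TestMtxTriplet:
    def test_single_entry_body_line(self, tmp_path):
        m = _matrix([[0, 5], [0, 0]], ["CD4", "CD8"], ["AAAA", "CCCC"])
        mtx_path, _, _ = write_mtx_triplet(m, tmp_path)
        lines = [
            ln for ln in gzip.open(mtx_path, "rt").read().splitlines() if not ln.startswith("%")
        ]
        assert lines[0].split() == ["2", "2", "1"]
        assert lines[1].split() == ["1", "2", "5"]

    def test_all_zero_matrix_has_no_body(self, tmp_path):
        m = _matrix(np.zeros((3, 4), dtype=int), list("abc"), list("wxyz"))
        mtx_path, _, _ = write_mtx_triplet(m, tmp_path)
        lines = [
            ln for ln in gzip.open(mtx_path, "rt").read().splitlines() if not ln.startswith("%")
        ]
        assert lines == ["3 4 0"]
        assert read_mtx_triplet(tmp_path) == m

    def test_features_file_declares_antibody_capture(self, tmp_path):
        m = _matrix([[1]], ["CD4"], ["AAAA"])
        _, _, ft = write_mtx_triplet(m, tmp_path)
        line = gzip.open(ft, "rt").read().splitlines()[0]
        assert line.split("\t") == ["CD4", "CD4", FEATURE_TYPE]
        assert FEATURE_TYPE == "Antibody Capture"

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        data=st.data(),
        n_rows=st.integers(1, 6),
        n_cols=st.integers(1, 6),
    )
    def test_roundtrip_identity_on_random_matrices(self, tmp_path_factory, data, n_rows, n_cols):
        counts = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 50), min_size=n_cols, max_size=n_cols),
                    min_size=n_rows,
                    max_size=n_rows,
                )
            )
        )
        m = _matrix(counts, [f"f{i}" for i in range(n_rows)], [f"B{j}" for j in range(n_cols)])
        out = tmp_path_factory.mktemp("mtx")
        write_mtx_triplet(m, out)
        assert read_mtx_triplet(out) == m


class TestDenseCsv:
    def test_single_cell_single_marker(self, tmp_path):
        m = _matrix([[7]], ["CD4"], ["AAAACCCCGGGGTTTT"])
        path = write_dense_csv(m, tmp_path / "m.csv")
        lines = path.read_text().splitlines()
        assert lines[0] == "marker,AAAACCCCGGGGTTTT"
        assert lines[1] == "CD4,7"

    def test_roundtrip_and_zero_matrix_keeps_dimensions(self, tmp_path):
        m = _matrix(np.zeros((2, 3), dtype=int), ["CD4", "CD8"], ["A", "C", "G"])
        path = write_dense_csv(m, tmp_path / "m.csv")
        back = read_dense_csv(path)
        assert back == m
        assert back.counts.shape == (2, 3)
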