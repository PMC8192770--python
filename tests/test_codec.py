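"""Progressive-JPEG segmentation, codebook, strand encode/decode, reassembly."""

import io
import random
import warnings

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from dnapreview import fixtures as fx
from dnapreview import preview_codec as pc
from dnapreview.thermo import hamming_distance, reverse_complement

SITES = {
    0: ("ACGTTGCAACGGTCATGCAT", "TGCATCATGGTCAACGTTGC"),
}
FLANK_F = "GATTACAGATTACAGATTAC"
FLANK_R = "CCATGATTACGGATTCACGT"


def _partition_from_bytes(raw: bytes, tier: int = 0) -> pc.Partition:
    part = pc.Partition(
        ordinal=1, scan_indices=[], raw=raw, hd_tier=tier, copy_multiplier=1
    )
    part.fwd_site, part.rev_site = SITES[0]
    return part


class TestScanScript:
    def test_forty_two_scans_dc_first(self):
        script = pc.build_scan_script()
        assert len(script) == 42
        assert script[0] == pc.ScanSpec("Y", 0, 0)
        assert script[1] == pc.ScanSpec("Cr", 0, 0)
        assert script[2] == pc.ScanSpec("Cb", 0, 0)
        assert script[-1] == pc.ScanSpec("Cr", 61, 63)
        assert all(s.lo == s.hi == 0 for s in script[:3])
        assert all(s.lo > 0 for s in script[3:])

    def test_every_coefficient_covered_once_per_band(self):
        script = pc.build_scan_script()
        for band in ("Y", "Cb", "Cr"):
            covered = []
            for s in script:
                if s.band == band:
                    covered.extend(range(s.lo, s.hi + 1))
            assert sorted(covered) == list(range(64))


class TestSegmentation:
    def test_segment_count_matches_sos_marker_scan(self, small_jpeg):
        header, segments = pc.segment_progressive_jpeg(small_jpeg)
        # independent oracle: count SOS markers in the raw byte stream
        assert len(segments) == small_jpeg.count(b"\xff\xda")
        assert all(s.startswith(b"\xff\xda") for s in segments)

    def test_split_is_lossless(self, small_jpeg):
        header, segments = pc.segment_progressive_jpeg(small_jpeg)
        assert header + b"".join(segments) + b"\xff\xd9" == small_jpeg

    def test_baseline_jpeg_rejected(self):
        img = Image.fromarray(
            np.random.default_rng(0).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        )
        buf = io.BytesIO()
        img.save(buf, "JPEG", quality=75)  # sequential baseline
        with pytest.raises(pc.JpegFormatError, match="baseline"):
            pc.segment_progressive_jpeg(buf.getvalue())

    def test_truncated_stream_rejected(self, small_jpeg):
        with pytest.raises(pc.JpegFormatError):
            pc.segment_progressive_jpeg(small_jpeg[: len(small_jpeg) // 2])

    def test_non_jpeg_rejected(self):
        with pytest.raises(pc.JpegFormatError):
            pc.segment_progressive_jpeg(b"not a jpeg at all")


class TestPartitioning:
    def _fake_segments(self, n=42):
        return [bytes([0xFF, 0xDA, i]) for i in range(n)]

    def test_three_way_split_bookkeeping(self):
        header = b"HDR"
        segs = self._fake_segments()
        parts = pc.partition_scans(header, segs, [3, 18, 21])
        assert [p.n_scans for p in parts] == [3, 18, 21]
        assert parts[0].raw.startswith(b"HDR")
        assert parts[1].raw == b"".join(segs[3:21])
        tiers = [p.hd_tier for p in parts]
        assert tiers == sorted(tiers) and len(set(tiers)) == 3

    def test_default_tier_and_copy_schedule(self):
        parts = pc.partition_scans(b"", self._fake_segments(), [3, 18, 21])
        assert [p.hd_tier for p in parts] == [0, 4, 6]
        assert [p.copy_multiplier for p in parts] == [1, 100, 1000]
        four = pc.partition_scans(b"", self._fake_segments(), [3, 15, 12, 12])
        assert [p.hd_tier for p in four] == [0, 2, 4, 6]
        assert [p.copy_multiplier for p in four] == [1, 10, 100, 1000]

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            pc.partition_scans(b"", self._fake_segments(), [0, 21, 21])

    def test_uncovered_scans_rejected(self):
        with pytest.raises(ValueError):
            pc.partition_scans(b"", self._fake_segments(), [3, 18])


class TestCodebook:
    def test_greedy_book_constraints_brute_force(self, books):
        primary, alternate = books
        for book in (primary, alternate):
            assert len(set(book.codewords)) == 256
            assert all(len(w) == 8 for w in book.codewords)
            assert all(
                sum(1 for b in w if b in "GC") == 4 for w in book.codewords
            )
        combined = primary.codewords + alternate.codewords
        assert len(set(combined)) == 512  # books are disjoint
        min_ed = min(
            edlib.align(a, b, task="distance")["editDistance"]
            for i, a in enumerate(primary.codewords)
            for b in primary.codewords[i + 1 :]
        )
        assert min_ed >= 2

    def test_bijective_byte_map(self, books):
        book = books[0]
        inv = book.inverse
        assert all(inv[book.encode_byte(v)] == v for v in range(256))


class TestEncodePartition:
    def test_one_block_yields_255_strands_of_200nt(self, books):
        part = _partition_from_bytes(bytes(range(256)) * 6 + bytes(129))
        assert len(part.raw) == 1665
        strands = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)
        assert len(strands) == 255
        assert all(len(s.seq) == 200 for s in strands)
        assert len({s.index for s in strands}) == 255

    def test_single_byte_is_zero_padded_to_a_block(self, books):
        part = _partition_from_bytes(b"\x42")
        strands = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)
        assert len(strands) == 255

    def test_strand_count_formula(self, books):
        for nbytes in (1, 1665, 1666, 3330, 4000):
            part = _partition_from_bytes(bytes(nbytes))
            strands = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)
            assert len(strands) == -(-nbytes // 1665) * 255

    def test_payload_rederivation_matches_row(self, books):
        rng = random.Random(5)
        part = _partition_from_bytes(bytes(rng.randrange(256) for _ in range(400)))
        strands = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)
        for s in strands[::17]:
            row = pc.strand_to_row(s.seq, books=books)
            assert row is not None
            index, data = row
            assert index == s.index
        # layout: flank + site + payload + rc(site) + rc(flank)
        s0 = strands[0]
        assert s0.seq.startswith(FLANK_F + SITES[0][0])
        assert s0.seq.endswith(
            reverse_complement(SITES[0][1]) + reverse_complement(FLANK_R)
        )

    def test_restriction_site_at_payload_midpoint(self, books):
        part = _partition_from_bytes(bytes(100))
        strands = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)
        assert strands[0].seq[96:104] == pc.RESTRICTION_SITES[0]

    def test_empty_partition_rejected(self, books):
        with pytest.raises(ValueError):
            pc.encode_partition(
                _partition_from_bytes(b""), FLANK_F, FLANK_R, books=books
            )

    def test_guard_escapes_primer_like_payload(self, books):
        """A payload window close to a partition primer is re-synthesised
        through the alternate codebook and still decodes."""
        part = _partition_from_bytes(bytes(range(200)))
        guards = [SITES[0][0], SITES[0][1]]
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no unresolved guard violations
            strands = pc.encode_partition(
                part, FLANK_F, FLANK_R, books=books,
                guard_primers=guards, guard_min_hd=6,
            )
        for s in strands:
            row = pc.strand_to_row(s.seq, books=books)
            assert row is not None and row[0] == s.index


@pytest.fixture(scope="module")
def block(books):
    rng = random.Random(11)
    raw = bytes(rng.randrange(256) for _ in range(1665))
    part = _partition_from_bytes(raw)
    strands = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)
    rows = [pc.strand_to_row(s.seq, books=books) for s in strands]
    return raw, rows


class TestDecodeStrands:

    def test_lossless_round_trip(self, block):
        raw, rows = block
        data, statuses = pc.decode_strands(rows, partition_length=1665)
        assert data == raw
        assert all(s.ok for s in statuses)

    def test_recovers_from_70_missing_rows(self, block):
        raw, rows = block
        rng = random.Random(0)
        keep = rng.sample(range(255), 255 - 70)
        data, statuses = pc.decode_strands(
            [rows[i] for i in keep], partition_length=1665
        )
        assert data == raw and statuses[0].ok

    def test_71_missing_rows_flagged_failed(self, block):
        raw, rows = block
        rng = random.Random(1)
        keep = rng.sample(range(255), 255 - 71)
        data, statuses = pc.decode_strands(
            [rows[i] for i in keep], partition_length=1665
        )
        assert not statuses[0].ok

    def test_duplicate_rows_resolved_by_majority(self, block):
        raw, rows = block
        corrupted = list(rows) + [(rows[0][0], b"\x00" * 9)]
        data, statuses = pc.decode_strands(
            corrupted + [rows[0]], partition_length=1665
        )
        assert data == raw and statuses[0].ok

    def test_single_corrupt_codeword_corrected_by_inner_code(self, books):
        part = _partition_from_bytes(bytes(50))
        strand = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)[7]
        seq = list(strand.seq)
        seq[60:68] = "AAAAAAAA"  # clobber one payload codeword
        row = pc.strand_to_row("".join(seq), books=books)
        assert row is not None and row[0] == strand.index


class TestReassembly:
    def test_full_reassembly_is_byte_identical(self, small_jpeg):
        header, segments = pc.segment_progressive_jpeg(small_jpeg)
        parts = pc.partition_scans(header, segments, [1, 5, 4])
        out = pc.reassemble_jpeg([p.raw for p in parts], [True, True, True])
        assert out == small_jpeg

    def test_partition_one_alone_is_a_readable_jpeg(self, small_jpeg):
        header, segments = pc.segment_progressive_jpeg(small_jpeg)
        parts = pc.partition_scans(header, segments, [1, 5, 4])
        preview = pc.reassemble_jpeg([parts[0].raw], [True])
        img = Image.open(io.BytesIO(preview))
        img.load()
        assert img.size == (64, 64)

    def test_everything_after_first_failure_dropped(self, small_jpeg):
        header, segments = pc.segment_progressive_jpeg(small_jpeg)
        parts = pc.partition_scans(header, segments, [1, 5, 4])
        out = pc.reassemble_jpeg(
            [parts[0].raw, None, parts[2].raw], [True, False, True]
        )
        assert out == parts[0].raw + b"\xff\xd9"

    def test_missing_partition_one_is_unreadable(self):
        with pytest.raises(pc.UnreadableImageError):
            pc.reassemble_jpeg([None, b"x"], [False, True])


class TestRoundTripProperty:
    @settings(max_examples=100, deadline=None)
    @given(st.binary(min_size=1, max_size=4000))
    def test_encode_decode_identity_on_arbitrary_bytes(self, payload):
        books = pc.build_codebook(with_alternate=True)
        part = _partition_from_bytes(payload)
        strands = pc.encode_partition(part, FLANK_F, FLANK_R, books=books)
        rows = [pc.strand_to_row(s.seq, books=books) for s in strands]
        assert all(r is not None for r in rows)
        data, statuses = pc.decode_strands(rows, partition_length=len(payload))
        assert all(s.ok for s in statuses)
        assert data == payload


class TestPreviewShare:
    def test_default_fixture_partitioning_previews_about_5_percent(self):
        """Partition 1 of a realistically sized file holds ~5% of strands."""
        jpeg = fx.make_progressive_jpeg(
            fx.SyntheticImageSpec(224, 224, "noise", 88, 7)
        )
        header, segments = pc.segment_progressive_jpeg(jpeg)
        spec = pc.auto_partition_spec(segments)
        parts = pc.partition_scans(header, segments, spec)
        blocks = [-(-len(p.raw) // 1665) for p in parts]
        share = blocks[0] / sum(blocks)
        assert 0.03 <= share <= 0.08
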