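"""Progressive-JPEG to DNA codec with Hamming-distance-tiered File Preview layout.

A progressive JPEG delivers its image content in scans — entropy-coded passes
that each carry a band of DCT coefficients for one color component. Because
early scans (DC coefficients, low AC frequencies of luminance) already render
a recognizable low-resolution image, the file can be split into ordered
partitions of scans, and each partition bound to its own primer binding sites.
The File Preview layout gives partition 1 perfectly matching (0 HD) binding
sites and later partitions sites at increasing Hamming distance from the same
primers, so a single primer pair retrieves progressively more of the file as
PCR conditions are made more promiscuous.

Pipeline per partition: raw bytes -> zero-padded 1665-byte blocks -> 185x9
byte matrix -> column-wise outer Reed-Solomon [255,185,71] -> per row a 2-byte
index plus 9 data bytes protected by an inner Reed-Solomon [14,11,4] -> 14
bytes mapped through a GC-balanced codebook (8 nt per byte) -> 112 nt payload
with an 8-nt restriction site at its midpoint, partition primers, and common
flanking primers, for a 200 nt strand.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rs import INNER_CODE, OUTER_CODE, ReedSolomonError, RSCode
from .thermo import reverse_complement

__all__ = [
    "ScanSpec",
    "build_scan_script",
    "JpegFormatError",
    "segment_progressive_jpeg",
    "Partition",
    "partition_scans",
    "DEFAULT_TIERS",
    "COPY_SCHEDULE",
    "RESTRICTION_SITES",
    "CodeParameters",
    "Codebook",
    "build_codebook",
    "EncodedStrand",
    "encode_partition",
    "strand_to_row",
    "decode_strands",
    "BlockStatus",
    "reassemble_jpeg",
]


# ---------------------------------------------------------------------------
# Scan script
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanSpec:
    """One progressive scan: a color band and an inclusive coefficient range."""

    band: str  # "Y", "Cb" or "Cr"
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.band not in ("Y", "Cb", "Cr"):
            raise ValueError(f"unknown band {self.band!r}")
        if not 0 <= self.lo <= self.hi <= 63:
            raise ValueError("coefficient range must satisfy 0 <= lo <= hi <= 63")


def build_scan_script() -> list[ScanSpec]:
    """The canonical 42-scan progressive script used for Preview encoding.

    Three DC scans (Y, Cr, Cb) are followed by the luminance AC coefficients
    in groups of five (final group 61:63), then the chrominance AC groups
    interleaved Cb/Cr. Every coefficient 0-63 of every band is covered exactly
    once.
    """
    scans = [ScanSpec("Y", 0, 0), ScanSpec("Cr", 0, 0), ScanSpec("Cb", 0, 0)]
    groups = [(lo, min(lo + 4, 63)) for lo in range(1, 64, 5)]
    scans.extend(ScanSpec("Y", lo, hi) for lo, hi in groups)
    for lo, hi in groups:
        scans.append(ScanSpec("Cb", lo, hi))
        scans.append(ScanSpec("Cr", lo, hi))
    return scans


# ---------------------------------------------------------------------------
# JPEG segmentation (byte/marker level)
# ---------------------------------------------------------------------------

class JpegFormatError(ValueError):
    """Input is not a parseable progressive JPEG."""


_SOF_MARKERS = {0xC0, 0xC1, 0xC2, 0xC3, 0xC5, 0xC6, 0xC7, 0xC9, 0xCA, 0xCB,
                0xCD, 0xCE, 0xCF}
_STANDALONE = set(range(0xD0, 0xD8)) | {0x01}


def segment_progressive_jpeg(data: bytes) -> tuple[bytes, list[bytes]]:
    """Split a progressive JPEG into header bytes and per-scan segments.

    The header is everything before the first SOS marker. Segment *i* runs
    from scan *i*'s SOS marker up to (but excluding) the next SOS marker, or
    the trailing EOI for the last scan; stuffed ``FF00`` bytes and restart
    markers inside entropy-coded data do not terminate a segment. The
    concatenation ``header + b"".join(segments) + b"\\xff\\xd9"`` reproduces
    the input byte-for-byte.
    """
    if len(data) < 4 or data[0:2] != b"\xff\xd8":
        raise JpegFormatError("missing SOI marker; not a JPEG stream")
    sos_offsets: list[int] = []
    sof_marker: int | None = None
    eoi_offset: int | None = None
    i = 2
    n = len(data)
    while i < n:
        if data[i] != 0xFF:
            raise JpegFormatError(f"expected marker at offset {i}")
        if i + 1 >= n:
            raise JpegFormatError("truncated stream at marker prefix")
        marker = data[i + 1]
        if marker == 0xD9:
            eoi_offset = i
            break
        if marker in _STANDALONE:
            i += 2
            continue
        if i + 4 > n:
            raise JpegFormatError("truncated marker segment header")
        seg_len = int.from_bytes(data[i + 2 : i + 4], "big")
        if seg_len < 2 or i + 2 + seg_len > n:
            raise JpegFormatError("truncated or corrupt marker segment")
        if marker in _SOF_MARKERS and sof_marker is None:
            sof_marker = marker
        if marker == 0xDA:
            sos_offsets.append(i)
            i += 2 + seg_len
            # Skip entropy-coded data: 0xFF is only a marker prefix when not
            # followed by 0x00 (byte stuffing) or a restart marker.
            while i < n:
                if data[i] == 0xFF and i + 1 < n:
                    nxt = data[i + 1]
                    if nxt != 0x00 and not (0xD0 <= nxt <= 0xD7):
                        break
                    i += 2
                else:
                    i += 1
            if i >= n:
                raise JpegFormatError("entropy-coded data ran past end of stream")
        else:
            i += 2 + seg_len
    if sof_marker is None:
        raise JpegFormatError("no SOF marker found")
    if sof_marker == 0xC0 or sof_marker == 0xC1:
        raise JpegFormatError(
            "baseline JPEG (sequential DCT) is unsupported; re-encode as progressive"
        )
    if sof_marker != 0xC2:
        raise JpegFormatError(
            f"unsupported SOF marker 0xFF{sof_marker:02X}; progressive (SOF2) required"
        )
    if eoi_offset is None:
        raise JpegFormatError("missing EOI marker")
    if not sos_offsets:
        raise JpegFormatError("no scans found")
    header = data[: sos_offsets[0]]
    bounds = sos_offsets + [eoi_offset]
    segments = [data[bounds[j] : bounds[j + 1]] for j in range(len(sos_offsets))]
    return header, segments


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

#: Default Hamming-distance tier assignment by number of partitions.
DEFAULT_TIERS: dict[int, tuple[int, ...]] = {3: (0, 4, 6), 4: (0, 2, 4, 6)}

#: Stored physical copy multiplier per Hamming-distance tier: higher-HD
#: strands amplify less efficiently and are stored with extra copies.
COPY_SCHEDULE: dict[int, int] = {0: 1, 2: 10, 4: 100, 6: 1000}

#: Synthetic per-tier restriction sites (8-cutter recognition sequences),
#: inserted at the payload midpoint so each tier can be cut and quantified.
RESTRICTION_SITES: dict[int, str] = {
    0: "GCGGCCGC",  # NotI-like
    2: "GGCGCGCC",  # AscI-like
    4: "TTAATTAA",  # PacI-like
    6: "CCTGCAGG",  # SbfI-like
}


@dataclass
class Partition:
    """A contiguous group of scans bound to one HD tier and one primer pair."""

    ordinal: int
    scan_indices: list[int]
    raw: bytes
    hd_tier: int
    copy_multiplier: int
    fwd_site: str | None = None
    rev_site: str | None = None

    @property
    def n_scans(self) -> int:
        return len(self.scan_indices)


def partition_scans(
    header: bytes,
    segments: list[bytes],
    partition_spec: list[int],
    tiers: tuple[int, ...] | None = None,
) -> list[Partition]:
    """Group scan segments into partitions with tier and copy assignments.

    ``partition_spec`` lists the number of scans per partition and must cover
    every segment. Partition 1 additionally carries the JPEG header. Tiers
    default to the schedule for the partition count and must be strictly
    increasing; copy multipliers follow :data:`COPY_SCHEDULE`.
    """
    if any(c <= 0 for c in partition_spec):
        raise ValueError("every partition must contain at least one scan")
    if sum(partition_spec) != len(segments):
        raise ValueError(
            f"partition spec {partition_spec} does not cover {len(segments)} scans"
        )
    if tiers is None:
        try:
            tiers = DEFAULT_TIERS[len(partition_spec)]
        except KeyError:
            raise ValueError(
                f"no default tier schedule for {len(partition_spec)} partitions; "
                "pass tiers explicitly"
            ) from None
    if len(tiers) != len(partition_spec):
        raise ValueError("one tier per partition required")
    if list(tiers) != sorted(set(tiers)):
        raise ValueError("tiers must be strictly increasing with partition ordinal")
    partitions = []
    start = 0
    for ordinal, (count, tier) in enumerate(zip(partition_spec, tiers), start=1):
        idx = list(range(start, start + count))
        raw = b"".join(segments[j] for j in idx)
        if ordinal == 1:
            raw = header + raw
        partitions.append(
            Partition(
                ordinal=ordinal,
                scan_indices=idx,
                raw=raw,
                hd_tier=tier,
                copy_multiplier=COPY_SCHEDULE.get(tier, 1),
            )
        )
        start += count
    return partitions


# ---------------------------------------------------------------------------
# Code parameters and codebook
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeParameters:
    outer_n: int = 255
    outer_k: int = 185
    inner_n: int = 14
    inner_k: int = 11
    block_rows: int = 185
    block_cols: int = 9
    index_bytes: int = 2
    codeword_nt: int = 8
    strand_nt: int = 200
    primer_nt: int = 20

    def __post_init__(self) -> None:
        if self.block_rows * self.block_cols != self.block_bytes:
            raise AssertionError("inconsistent block geometry")
        if self.index_bytes + self.block_cols + (self.inner_n - self.inner_k) != self.inner_n:
            raise ValueError("inner code must cover index + data + parity exactly")
        if self.outer_k != self.block_rows:
            raise ValueError("outer code dimension must equal block rows")

    @property
    def block_bytes(self) -> int:
        return 1665 if (self.block_rows, self.block_cols) == (185, 9) else self.block_rows * self.block_cols

    @property
    def outer_distance(self) -> int:
        return self.outer_n - self.outer_k + 1

    @property
    def inner_distance(self) -> int:
        return self.inner_n - self.inner_k + 1

    @property
    def payload_nt(self) -> int:
        return self.inner_n * self.codeword_nt


@dataclass(frozen=True)
class Codebook:
    """Bijective byte -> 8-nt codeword map, GC-balanced with pairwise edit distance >= 2."""

    codewords: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codewords) != 256:
            raise ValueError("a codebook holds exactly 256 codewords")

    def encode_byte(self, value: int) -> str:
        return self.codewords[value]

    def encode(self, payload: bytes) -> str:
        return "".join(self.codewords[b] for b in payload)

    @property
    def inverse(self) -> dict[str, int]:
        return {cw: i for i, cw in enumerate(self.codewords)}

    @property
    def identity_hash(self) -> str:
        return hashlib.sha256("".join(self.codewords).encode()).hexdigest()[:16]


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _greedy_codewords(n_needed: int, length: int = 8) -> list[str]:
    """Greedy scan of all ``4**length`` candidates in lexicographic order.

    Accepts GC-balanced candidates (exactly half G/C) whose edit distance to
    every previously accepted codeword is at least two. For equal-length
    sequences an edit distance of one is only achievable by a single
    substitution, so the constraint reduces to Hamming distance >= 2, checked
    vectorised.
    """
    half = length // 2
    accepted = np.empty((n_needed, length), dtype=np.uint8)
    count = 0
    for cand in itertools.product("ACGT", repeat=length):
        gc = sum(1 for b in cand if b in "GC")
        if gc != half:
            continue
        vec = np.fromiter((_BASE_IDX[b] for b in cand), dtype=np.uint8, count=length)
        if count:
            if int((accepted[:count] != vec).sum(axis=1).min()) < 2:
                continue
        accepted[count] = vec
        count += 1
        if count == n_needed:
            break
    if count < n_needed:
        raise RuntimeError(
            f"greedy codeword search exhausted candidates at {count}/{n_needed}"
        )
    return ["".join("ACGT"[i] for i in row) for row in accepted]


_CODEBOOK_CACHE: dict[int, tuple[Codebook, Codebook]] = {}


def build_codebook(with_alternate: bool = False) -> Codebook | tuple[Codebook, Codebook]:
    """Build the default greedy codebook (and optionally the alternate book).

    The alternate book holds the next 256 codewords from the same greedy scan;
    it is disjoint from the primary book and used to re-synthesise rows whose
    assembled strand would otherwise contain a window too close to a partition
    primer.
    """
    if 512 not in _CODEBOOK_CACHE:
        words = _greedy_codewords(512)
        _CODEBOOK_CACHE[512] = (
            Codebook(tuple(words[:256])),
            Codebook(tuple(words[256:])),
        )
    primary, alternate = _CODEBOOK_CACHE[512]
    return (primary, alternate) if with_alternate else primary


# ---------------------------------------------------------------------------
# Strand encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodedStrand:
    """One 200-nt record: flanks, partition primers, indexed RS-protected payload."""

    seq: str
    index: int
    partition: int
    block: int
    row: int
    copies: int

    @property
    def record_id(self) -> str:
        return (
            f"partition={self.partition}|block={self.block + 1}|row={self.row + 1}"
            f"|index={self.index}|copies={self.copies}"
        )


def _window_min_hd(
    seqs: list[str],
    primers: list[str],
    primer_nt: int,
    exclude_starts: tuple[int, ...] = (),
) -> int:
    """Minimum Hamming distance of any length-20 window over ``seqs`` to any primer.

    ``exclude_starts`` removes the designated binding-site windows themselves:
    a strand's own (possibly low-HD) address sites are the access mechanism,
    not payload accidents.
    """
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    wins = np.lib.stride_tricks.sliding_window_view(arr, primer_nt, axis=1)
    keep = np.array(
        [j for j in range(wins.shape[1]) if j not in exclude_starts], dtype=int
    )
    pr = np.frombuffer("".join(primers).encode(), dtype=np.uint8).reshape(
        len(primers), primer_nt
    )
    # (strands, windows, primers)
    hd = (wins[:, keep][:, :, None, :] != pr[None, None, :, :]).sum(axis=-1)
    return int(hd.min())


def _assemble(
    payload14: bytes,
    book: Codebook,
    site: str,
    flank_fwd: str,
    flank_rev: str,
    fwd_site: str,
    rev_site: str,
) -> str:
    dna = book.encode(payload14)
    half = len(dna) // 2
    return (
        flank_fwd
        + fwd_site
        + dna[:half]
        + site
        + dna[half:]
        + reverse_complement(rev_site)
        + reverse_complement(flank_rev)
    )


def encode_partition(
    partition: Partition,
    flank_fwd: str,
    flank_rev: str,
    code: CodeParameters | None = None,
    books: tuple[Codebook, Codebook] | None = None,
    guard_primers: list[str] | None = None,
    guard_min_hd: int = 6,
) -> list[EncodedStrand]:
    """Encode one partition's bytes into 200-nt strands.

    The partition's bytes are zero-padded to whole 1665-byte blocks; each
    block becomes a 185x9 matrix extended column-wise to 255 rows by the outer
    code, and every row is emitted as ``index(2) + data(9)`` protected by the
    inner code, converted to DNA through the codebook, and framed by the
    restriction site, partition binding sites and flanking primers.

    ``guard_primers`` (typically all partition binding sites of the file)
    triggers the payload-vs-primer guard: any strand with a 20-nt window
    closer than ``guard_min_hd`` to a guard primer (or its reverse complement)
    is re-synthesised through the alternate codebook.
    """
    code = code or CodeParameters()
    if books is None:
        books = build_codebook(with_alternate=True)
    primary, alternate = books
    if partition.fwd_site is None or partition.rev_site is None:
        raise ValueError("partition has no primer binding sites assigned")
    if not partition.raw:
        raise ValueError("cannot encode an empty partition")
    outer = OUTER_CODE if (code.outer_n, code.outer_k) == (255, 185) else RSCode(
        code.outer_n - code.outer_k
    )
    inner = INNER_CODE if (code.inner_n, code.inner_k) == (14, 11) else RSCode(
        code.inner_n - code.inner_k
    )
    site = RESTRICTION_SITES.get(partition.hd_tier, RESTRICTION_SITES[0])
    data = partition.raw
    n_blocks = -(-len(data) // code.block_bytes)
    if n_blocks * code.outer_n > 2 ** (8 * code.index_bytes):
        raise ValueError(
            f"partition of {len(data)} bytes exceeds the "
            f"{code.index_bytes}-byte index capacity"
        )
    data = data.ljust(n_blocks * code.block_bytes, b"\x00")
    guards: list[str] = []
    for g in guard_primers or []:
        guards.extend((g, reverse_complement(g)))
    # Window positions of the designated forward site and reverse-site
    # complement within the assembled strand.
    site_starts = (code.primer_nt, code.strand_nt - 2 * code.primer_nt)
    strands: list[EncodedStrand] = []
    for b in range(n_blocks):
        block = data[b * code.block_bytes : (b + 1) * code.block_bytes]
        matrix = np.frombuffer(block, dtype=np.uint8).reshape(
            code.block_rows, code.block_cols
        )
        extended = np.empty((code.outer_n, code.block_cols), dtype=np.uint8)
        for col in range(code.block_cols):
            extended[:, col] = np.frombuffer(
                outer.encode(bytes(matrix[:, col])), dtype=np.uint8
            )
        for row in range(code.outer_n):
            index = b * code.outer_n + row
            message = index.to_bytes(code.index_bytes, "big") + bytes(
                extended[row]
            )
            payload14 = inner.encode(message)
            seq = _assemble(
                payload14, primary, site, flank_fwd, flank_rev,
                partition.fwd_site, partition.rev_site,
            )
            if guards and _window_min_hd(
                [seq], guards, code.primer_nt, exclude_starts=site_starts
            ) < guard_min_hd:
                alt_seq = _assemble(
                    payload14, alternate, site, flank_fwd, flank_rev,
                    partition.fwd_site, partition.rev_site,
                )
                if _window_min_hd(
                    [alt_seq], guards, code.primer_nt, exclude_starts=site_starts
                ) >= guard_min_hd:
                    seq = alt_seq
                else:
                    warnings.warn(
                        f"strand index {index} of partition {partition.ordinal} "
                        "violates the payload-primer guard under both codebooks",
                        stacklevel=2,
                    )
            strands.append(
                EncodedStrand(
                    seq=seq,
                    index=index,
                    partition=partition.ordinal,
                    block=b,
                    row=row,
                    copies=partition.copy_multiplier,
                )
            )
    return strands


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def strand_to_row(
    seq: str,
    code: CodeParameters | None = None,
    books: tuple[Codebook, Codebook] | None = None,
) -> tuple[int, bytes] | None:
    """Recover ``(index, 11 message bytes)`` from a 200-nt strand sequence.

    Codewords are looked up exactly; unknown 8-mers become erasures for the
    inner code. The primary codebook is tried first, then the alternate book
    (used for guard-escaped strands). Returns ``None`` when the inner code
    cannot correct the row.
    """
    code = code or CodeParameters()
    if books is None:
        books = build_codebook(with_alternate=True)
    if len(seq) != code.strand_nt:
        return None
    half = (code.inner_n // 2) * code.codeword_nt
    start = 2 * code.primer_nt
    site_nt = code.codeword_nt
    payload = (
        seq[start : start + half]
        + seq[start + half + site_nt : start + 2 * half + site_nt]
    )
    words = [
        payload[i * code.codeword_nt : (i + 1) * code.codeword_nt]
        for i in range(code.inner_n)
    ]
    inner = INNER_CODE if (code.inner_n, code.inner_k) == (14, 11) else RSCode(
        code.inner_n - code.inner_k
    )
    for book in books:
        inv = book.inverse
        symbols = [inv.get(w) for w in words]
        erasures = [i for i, s in enumerate(symbols) if s is None]
        if len(erasures) > inner.nsym:
            continue
        cw = bytes(s if s is not None else 0 for s in symbols)
        try:
            message = inner.decode(cw, erase_pos=erasures)
        except ReedSolomonError:
            continue
        index = int.from_bytes(message[: code.index_bytes], "big")
        return index, message[code.index_bytes :]
    return None


@dataclass
class BlockStatus:
    block: int
    ok: bool
    n_missing: int
    detail: str = ""


def decode_strands(
    rows: list[tuple[int, bytes]],
    partition_length: int | None = None,
    code: CodeParameters | None = None,
) -> tuple[bytes, list[BlockStatus]]:
    """Reconstruct one partition's bytes from recovered ``(index, data)`` rows.

    Duplicate indices are resolved by majority vote. Absent rows are erasures
    for the column-wise outer code; a block with more than ``d - 1`` missing
    rows is flagged failed rather than raising. ``partition_length`` strips
    the zero padding; if omitted, trailing zero bytes are stripped.
    """
    code = code or CodeParameters()
    outer = OUTER_CODE if (code.outer_n, code.outer_k) == (255, 185) else RSCode(
        code.outer_n - code.outer_k
    )
    by_index: dict[int, dict[bytes, int]] = {}
    for index, payload in rows:
        if len(payload) != code.block_cols:
            continue
        by_index.setdefault(index, {})
        by_index[index][bytes(payload)] = by_index[index].get(bytes(payload), 0) + 1
    if not by_index:
        return b"", [BlockStatus(block=0, ok=False, n_missing=code.outer_n,
                                 detail="no rows recovered")]
    resolved = {
        idx: max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        for idx, votes in by_index.items()
    }
    n_blocks = max(resolved) // code.outer_n + 1
    if partition_length is not None:
        n_blocks = max(n_blocks, -(-partition_length // code.block_bytes))
    out = bytearray()
    statuses: list[BlockStatus] = []
    for b in range(n_blocks):
        matrix = np.zeros((code.outer_n, code.block_cols), dtype=np.uint8)
        missing = []
        for row in range(code.outer_n):
            data = resolved.get(b * code.outer_n + row)
            if data is None:
                missing.append(row)
            else:
                matrix[row] = np.frombuffer(data, dtype=np.uint8)
        if len(missing) > outer.nsym:
            statuses.append(
                BlockStatus(b, False, len(missing),
                            f"{len(missing)} missing rows exceed erasure capacity "
                            f"{outer.nsym}")
            )
            out.extend(b"\x00" * code.block_bytes)
            continue
        try:
            cols = [
                outer.decode(bytes(matrix[:, col]), erase_pos=missing)
                for col in range(code.block_cols)
            ]
        except ReedSolomonError as exc:
            statuses.append(BlockStatus(b, False, len(missing), str(exc)))
            out.extend(b"\x00" * code.block_bytes)
            continue
        decoded = np.stack(
            [np.frombuffer(c, dtype=np.uint8) for c in cols], axis=1
        )
        out.extend(decoded.tobytes())
        statuses.append(BlockStatus(b, True, len(missing)))
    data = bytes(out)
    if partition_length is not None:
        data = data[:partition_length]
    else:
        data = data.rstrip(b"\x00")
    return data, statuses


class UnreadableImageError(RuntimeError):
    """Partition 1 (header + first scans) failed; no image can be rendered."""


def reassemble_jpeg(
    partitions: list[bytes | None],
    statuses: list[bool],
) -> bytes:
    """Concatenate the successful prefix of partitions and close with EOI.

    Everything at and after the first failed partition is dropped: later
    partitions only refine the image, so their loss reduces quality rather
    than readability. A failed or missing first partition makes the image
    unreadable.
    """
    if not partitions or not statuses:
        raise ValueError("no partitions supplied")
    if not statuses[0] or partitions[0] is None:
        raise UnreadableImageError(
            "partition 1 (JPEG header and first scans) is missing or undecodable"
        )
    keep: list[bytes] = []
    for part, ok in zip(partitions, statuses):
        if not ok or part is None:
            break
        keep.append(part)
    return b"".join(keep) + b"\xff\xd9"


# ---------------------------------------------------------------------------
# File-level orchestration
# ---------------------------------------------------------------------------

def auto_partition_spec(segments: list[bytes], n_partitions: int = 3) -> list[int]:
    """Choose scan cut points: partition 1 takes the DC-leading scans, the
    rest of the file is split by byte mass (~70/30 between later partitions
    for three partitions)."""
    if n_partitions < 2 or n_partitions > len(segments):
        raise ValueError("n_partitions must be in [2, n_scans]")
    spec = [1]
    remaining = len(segments) - 1
    sizes = [len(s) for s in segments[1:]]
    total = sum(sizes)
    targets = [0.7, 0.3] if n_partitions == 3 else [1.0 / (n_partitions - 1)] * (
        n_partitions - 1
    )
    acc = 0
    counts = []
    cum_target = 0.0
    for t in targets[:-1]:
        cum_target += t
        # take scans until cumulative bytes reach the target share
        run = 0
        while acc < cum_target * total and len(counts) + run < remaining - (
            len(targets) - len(counts) - 1
        ):
            acc += sizes[sum(counts) + run]
            run += 1
        counts.append(max(run, 1))
    counts.append(remaining - sum(counts))
    if counts[-1] < 1:
        raise ValueError("auto partitioning failed; pass an explicit spec")
    return spec + counts


def encode_file(
    jpeg: bytes,
    address_set,
    flank_fwd: str,
    flank_rev: str,
    partition_spec: list[int] | None = None,
    tiers: tuple[int, ...] | None = None,
    code: CodeParameters | None = None,
    books: tuple[Codebook, Codebook] | None = None,
    guard_min_hd: int = 6,
    seed: int | None = None,
):
    """Encode a progressive JPEG into a tiered strand library.

    Returns ``(strands, manifest, partitions)``. Partition ``k`` uses the
    address set's primary site pair at its HD tier; all partition sites guard
    the payload of every strand.
    """
    from .io_utils import Manifest

    code = code or CodeParameters()
    if books is None:
        books = build_codebook(with_alternate=True)
    header, segments = segment_progressive_jpeg(jpeg)
    if partition_spec is None:
        partition_spec = auto_partition_spec(segments)
    partitions = partition_scans(header, segments, partition_spec, tiers=tiers)
    for part in partitions:
        if part.hd_tier not in address_set.variants:
            raise ValueError(
                f"address set has no sites at Hamming distance {part.hd_tier}"
            )
        part.fwd_site, part.rev_site = address_set.primary_pair(part.hd_tier)
    guards = [s for part in partitions for s in (part.fwd_site, part.rev_site)]
    strands = []
    for part in partitions:
        strands.extend(
            encode_partition(
                part,
                flank_fwd,
                flank_rev,
                code=code,
                books=books,
                guard_primers=guards,
                guard_min_hd=guard_min_hd,
            )
        )
    manifest = Manifest(
        codebook_hash=books[0].identity_hash,
        flank_fwd=flank_fwd,
        flank_rev=flank_rev,
        partition_spec=list(partition_spec),
        partition_lengths=[len(p.raw) for p in partitions],
        tiers=[p.hd_tier for p in partitions],
        copies=[p.copy_multiplier for p in partitions],
        sites=[[p.fwd_site, p.rev_site] for p in partitions],
        base_fwd=address_set.base_forward.seq,
        base_rev=address_set.base_reverse.seq,
        scan_script=[[s.band, s.lo, s.hi] for s in build_scan_script()],
        seed=seed,
    )
    return strands, manifest, partitions


def decode_from_counts(
    references: dict[str, str],
    counts: dict[str, int],
    manifest,
    code: CodeParameters | None = None,
    books: tuple[Codebook, Codebook] | None = None,
    min_count: int = 1,
):
    """Decode a library from per-reference read counts (clustering output).

    ``references`` maps codec record ids (``partition=k|...``) to strand
    sequences; a reference with fewer than ``min_count`` attributed reads is
    treated as missing. Returns ``(jpeg_bytes, partition_bytes, statuses)``
    where ``statuses[k]`` is True when every block of partition ``k+1``
    decoded.
    """
    code = code or CodeParameters()
    if books is None:
        books = build_codebook(with_alternate=True)
    manifest.check_codebook(books[0].identity_hash)
    n_parts = len(manifest.partition_lengths)
    rows_by_part: dict[int, list[tuple[int, bytes]]] = {k: [] for k in range(1, n_parts + 1)}
    for rid, seq in references.items():
        if counts.get(rid, 0) < min_count:
            continue
        part = None
        for token in rid.split("|"):
            if token.startswith("partition="):
                part = int(token.split("=", 1)[1])
        if part is None or part not in rows_by_part:
            continue
        row = strand_to_row(seq, code=code, books=books)
        if row is not None:
            rows_by_part[part].append(row)
    partition_bytes: list[bytes | None] = []
    statuses: list[bool] = []
    for k in range(1, n_parts + 1):
        length = manifest.partition_lengths[k - 1]
        if not rows_by_part[k]:
            partition_bytes.append(None)
            statuses.append(False)
            continue
        data, block_status = decode_strands(
            rows_by_part[k], partition_length=length, code=code
        )
        ok = bool(block_status) and all(s.ok for s in block_status)
        partition_bytes.append(data if ok else None)
        statuses.append(ok)
    jpeg = None
    if statuses and statuses[0]:
        jpeg = reassemble_jpeg(partition_bytes, statuses)
    return jpeg, partition_bytes, statuses
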