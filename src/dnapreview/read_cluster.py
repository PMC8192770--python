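"""Seeded Levenshtein clustering of sequencing reads against a strand library.

Decoding starts from noisy reads rather than clean strands. Reads are
clustered by greedy message passing: sequences are processed in descending
multiplicity, and a sequence's reads are attributed to an existing centroid
when the centroid is within the Levenshtein cap (default 8 edits) and holds
at least ``cluster_ratio`` (default 5) times the sequence's count. Every
reference strand is pre-seeded with ``seed_copies`` (default 20) synthetic
copies so it is guaranteed to form a centroid; its reported read count is the
final cluster size minus the seeds. Centroids that match no reference are
reported separately — sequencing artifacts and background strands land there
without contaminating the decode.

Candidate search is exact for substitution-only neighbors (vectorised Hamming
distance, a Levenshtein upper bound at equal length) and uses a pigeonhole
seed index for indel-containing reads: with nine centroid chunks and at most
eight edits, at least one chunk appears exactly in the read within the indel
offset bound, so chunk lookup plus banded edlib verification finds every
centroid within the cap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "ClusterConfig",
    "ReadCluster",
    "ClusterResult",
    "cluster_reads",
]

_N_CHUNKS = 9


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering parameters: distance cap, message-passing ratio, seeding."""

    max_levenshtein: int = 8
    cluster_ratio: int = 5
    seed_copies: int = 20
    min_read_length: int = 150
    max_read_length: int = 250

    def __post_init__(self) -> None:
        for name in ("max_levenshtein", "cluster_ratio", "seed_copies"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReadCluster:
    """One centroid with its accumulated read mass."""

    centroid: str
    is_reference: bool
    raw_size: int
    adjusted_count: int
    members: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    reference_counts: dict[str, int]  # reference id -> adjusted count
    reference_clusters: dict[str, ReadCluster]
    unassigned: list[ReadCluster]
    n_reads: int  # reads surviving the length filter
    n_length_filtered: int

    @property
    def total_unassigned_reads(self) -> int:
        return sum(c.raw_size for c in self.unassigned)


class _SeedIndex:
    """Pigeonhole chunk index: exact chunk hit -> candidate centroid ids."""

    def __init__(self, max_edits: int):
        self.max_edits = max_edits
        self.table: dict[str, set[int]] = {}
        self.meta: dict[int, list[tuple[int, str]]] = {}

    def add(self, cid: int, seq: str) -> None:
        size = max(1, len(seq) // _N_CHUNKS)
        chunks = []
        for j in range(_N_CHUNKS):
            start = j * size
            if start >= len(seq):
                break
            chunk = seq[start : start + size]
            chunks.append((start, chunk))
            self.table.setdefault(chunk, set()).add(cid)
        self.meta[cid] = chunks

    def candidates(self, read: str) -> set[int]:
        out: set[int] = set()
        probed: set[str] = set()
        size_guess = max(1, len(read) // _N_CHUNKS)
        for j in range(_N_CHUNKS + 1):
            base = j * size_guess
            for off in range(-self.max_edits, self.max_edits + 1):
                start = base + off
                if start < 0 or start + size_guess > len(read):
                    continue
                sub = read[start : start + size_guess]
                if sub in probed:
                    continue
                probed.add(sub)
                out |= self.table.get(sub, set())
        return out


def _encode_200(seq: str, width: int) -> np.ndarray | None:
    if len(seq) != width:
        return None
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def cluster_reads(
    reads: list[str],
    references: dict[str, str] | list[str],
    config: ClusterConfig | None = None,
) -> ClusterResult:
    """Assign reads to reference strands by seeded message-passing clustering.

    ``references`` maps record ids to strand sequences (a plain list gets
    positional ids). Returns per-reference adjusted counts (cluster size minus
    the synthetic seeds), the full reference clusters, and all non-reference
    centroids. Ties between eligible centroids go to the larger cluster, then
    lexicographically smaller centroid sequence. Order of the input reads
    never matters: sequences are aggregated to multiplicities first.
    """
    config = config or ClusterConfig()
    if isinstance(references, list):
        references = {f"ref{i}": s for i, s in enumerate(references)}
    if not references:
        raise ValueError("references must be non-empty")
    ref_by_seq: dict[str, str] = {}
    for rid, seq in references.items():
        if seq in ref_by_seq:
            raise ValueError(f"duplicate reference sequence for {rid}")
        ref_by_seq[seq] = rid

    kept: Counter[str] = Counter()
    n_filtered = 0
    for r in reads:
        if config.min_read_length <= len(r) <= config.max_read_length:
            kept[r] += 1
        else:
            n_filtered += 1
    n_reads = sum(kept.values())

    counts: Counter[str] = Counter(kept)
    for seq in references.values():
        counts[seq] += config.seed_copies

    ref_width = len(next(iter(references.values())))

    # Centroid state.
    cent_seqs: list[str] = []
    cent_counts: list[int] = []
    cent_members: list[list[tuple[str, int]]] = []
    exact: dict[str, int] = {}
    seed_index = _SeedIndex(config.max_levenshtein)
    cap = 1024
    matrix = np.zeros((cap, ref_width), dtype=np.uint8)
    mat_rows: list[int] = []  # centroid id per matrix row
    row_of: dict[int, int] = {}

    def add_centroid(seq: str, count: int) -> None:
        nonlocal cap, matrix
        cid = len(cent_seqs)
        cent_seqs.append(seq)
        cent_counts.append(count)
        cent_members.append([(seq, count)])
        exact[seq] = cid
        seed_index.add(cid, seq)
        vec = _encode_200(seq, ref_width)
        if vec is not None:
            if len(mat_rows) == cap:
                cap *= 2
                bigger = np.zeros((cap, ref_width), dtype=np.uint8)
                bigger[: len(mat_rows)] = matrix[: len(mat_rows)]
                matrix = bigger
            matrix[len(mat_rows)] = vec
            row_of[cid] = len(mat_rows)
            mat_rows.append(cid)

    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ref_seq_set = set(ref_by_seq)

    for seq, cnt in ordered:
        if seq in ref_seq_set:
            # References are seeded precisely so that they always form their
            # own centroid; never absorb them into another cluster.
            add_centroid(seq, cnt)
            continue
        best: tuple[int, str, int] | None = None  # (-count, seq, cid)
        if cent_seqs:
            cand_ids: set[int] = set()
            vec = _encode_200(seq, ref_width)
            if vec is not None and mat_rows:
                counts_np = np.asarray(cent_counts, dtype=np.int64)
                rows = np.asarray(mat_rows)
                eligible = counts_np[rows] >= config.cluster_ratio * cnt
                if eligible.any():
                    sub = matrix[: len(mat_rows)][eligible]
                    hd = (sub != vec).sum(axis=1)
                    hits = np.nonzero(hd <= config.max_levenshtein)[0]
                    cand_ids |= {int(rows[eligible.nonzero()[0][h]]) for h in hits}
            # Pigeonhole search catches indel-containing matches (and any
            # equal-length neighbor whose Hamming distance exceeds the cap).
            for cid in seed_index.candidates(seq):
                if cent_counts[cid] < config.cluster_ratio * cnt:
                    continue
                if cid in cand_ids:
                    continue
                res = edlib.align(
                    seq, cent_seqs[cid], task="distance", k=config.max_levenshtein
                )
                if 0 <= res["editDistance"] <= config.max_levenshtein:
                    cand_ids.add(cid)
            if cand_ids:
                best = min(
                    (-cent_counts[cid], cent_seqs[cid], cid) for cid in cand_ids
                )
        if best is None:
            add_centroid(seq, cnt)
        else:
            cid = best[2]
            cent_counts[cid] += cnt
            cent_members[cid].append((seq, cnt))

    reference_counts: dict[str, int] = {}
    reference_clusters: dict[str, ReadCluster] = {}
    unassigned: list[ReadCluster] = []
    for cid, seq in enumerate(cent_seqs):
        rid = ref_by_seq.get(seq)
        if rid is not None:
            adjusted = cent_counts[cid] - config.seed_copies
            cluster = ReadCluster(
                centroid=seq,
                is_reference=True,
                raw_size=cent_counts[cid],
                adjusted_count=adjusted,
                members=[s for s, _ in cent_members[cid]],
            )
            reference_counts[rid] = adjusted
            reference_clusters[rid] = cluster
        else:
            unassigned.append(
                ReadCluster(
                    centroid=seq,
                    is_reference=False,
                    raw_size=cent_counts[cid],
                    adjusted_count=cent_counts[cid],
                    members=[s for s, _ in cent_members[cid]],
                )
            )
    return ClusterResult(
        reference_counts=reference_counts,
        reference_clusters=reference_clusters,
        unassigned=unassigned,
        n_reads=n_reads,
        n_length_filtered=n_filtered,
    )
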