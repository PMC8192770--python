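"""Shared I/O: FASTA/FASTQ round trips, the library manifest, logging."""

from __future__ import annotations

import gzip
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "Manifest",
    "ManifestMismatchError",
    "setup_logging",
]

_VALID = set("ACGTN")


class FormatError(ValueError):
    """Malformed sequence file."""


def _open(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _validate(records: list, path, with_quality: bool):
    out = []
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            raise FormatError(
                f"{path}: record {i + 1} ({rec.id}) contains invalid symbols "
                f"{sorted(bad)}; only ACGTN are allowed"
            )
        if with_quality:
            qual = rec.letter_annotations.get("phred_quality")
            out.append((rec.id, seq, qual))
        else:
            out.append((rec.id, seq))
    return out


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA (optionally gzipped) as ``(id, SEQUENCE)`` tuples."""
    try:
        with _open(path, "r") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return _validate(records, path, with_quality=False)


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with _open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ (optionally gzipped) as ``(id, SEQUENCE, qualities)``."""
    try:
        with _open(path, "r") as fh:
            records = list(SeqIO.parse(fh, "fastq"))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return _validate(records, path, with_quality=True)


def write_fastq(
    path: str | Path, records: list[tuple[str, str]] | list[tuple[str, str, list[int]]]
) -> None:
    recs = []
    for item in records:
        rid, seq = item[0], item[1]
        qual = item[2] if len(item) > 2 and item[2] is not None else [40] * len(seq)
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = qual
        recs.append(rec)
    with _open(path, "w") as fh:
        SeqIO.write(recs, fh, "fastq")


class ManifestMismatchError(RuntimeError):
    """Decoder manifest does not match the encoder's library."""


@dataclass
class Manifest:
    """Everything a decoder needs to invert an encoded library."""

    codebook_hash: str
    flank_fwd: str
    flank_rev: str
    partition_spec: list[int] = field(default_factory=list)
    partition_lengths: list[int] = field(default_factory=list)
    tiers: list[int] = field(default_factory=list)
    copies: list[int] = field(default_factory=list)
    sites: list[list[str]] = field(default_factory=list)  # [fwd, rev] per partition
    base_fwd: str = ""
    base_rev: str = ""
    scan_script: list[list] = field(default_factory=list)
    seed: int | None = None
    version: str = "1"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        return cls.from_json(Path(path).read_text())

    def check_codebook(self, expected_hash: str) -> None:
        if self.codebook_hash != expected_hash:
            raise ManifestMismatchError(
                f"manifest codebook hash {self.codebook_hash} does not match "
                f"the decoder's codebook {expected_hash}"
            )


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
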