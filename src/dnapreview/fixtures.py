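"""Synthetic inputs for every pipeline stage: images, libraries, reads.

Nothing here is downloaded: progressive JPEGs are rendered from procedural
pixel content (gradient, checkerboard, noise), strand libraries come from the
codec, and sequencing reads are sampled from simulated post-PCR abundances
with a configurable per-base error rate. All generators are deterministic
under a seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SyntheticImageSpec",
    "make_progressive_jpeg",
    "ReadSimulationError",
    "make_noisy_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Procedural test image: content style, size, JPEG quality, seed."""

    width: int = 64
    height: int = 64
    content: str = "gradient"
    quality: int = 75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.width <= 512 and 1 <= self.height <= 512):
            raise ValueError("image dimensions must be within 512x512")
        if self.content not in ("gradient", "checkerboard", "noise"):
            raise ValueError("content must be gradient, checkerboard or noise")


def _pixels(spec: SyntheticImageSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.rng_seed)
    if spec.content == "gradient":
        y, x = np.mgrid[0:h, 0:w]
        r = (255 * x / max(w - 1, 1)).astype(np.uint8)
        g = (255 * y / max(h - 1, 1)).astype(np.uint8)
        b = ((r.astype(int) + g.astype(int)) // 2).astype(np.uint8)
        return np.dstack([r, g, b])
    if spec.content == "checkerboard":
        y, x = np.mgrid[0:h, 0:w]
        cell = ((x // 8 + y // 8) % 2).astype(np.uint8) * 255
        tint = rng.integers(0, 64, size=3, dtype=np.uint8)
        return np.dstack([np.clip(cell + t, 0, 255).astype(np.uint8) for t in tint])
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


def make_progressive_jpeg(spec: SyntheticImageSpec | None = None) -> bytes:
    """Render the spec's pixels as a progressive JPEG byte stream."""
    from PIL import Image  # imaging library used for fixtures only

    spec = spec or SyntheticImageSpec()
    img = Image.fromarray(_pixels(spec), mode="RGB")
    buf = io.BytesIO()
    img.save(buf, format="JPEG", quality=spec.quality, progressive=True)
    return buf.getvalue()


class ReadSimulationError(ValueError):
    pass


def make_noisy_reads(
    pool: dict[str, float] | list[tuple[str, float]],
    per_base_error: float = 0.01,
    depth: float = 30.0,
    indel_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Sample sequencing reads from a strand pool with abundances.

    ``pool`` maps strand sequences to (relative) abundances. The total read
    budget is ``depth * len(pool)``; each strand's read count is Poisson with
    mean proportional to its abundance share. Errors hit each base
    independently at ``per_base_error``; a fraction ``indel_fraction`` of
    errors are single-base insertions or deletions instead of substitutions.
    Returns ``(read_id, sequence)`` pairs, deterministic under the seed.
    """
    if isinstance(pool, dict):
        pool = list(pool.items())
    if not pool:
        return []
    if not 0.0 <= per_base_error <= 0.2:
        raise ReadSimulationError("per-base error rate must be in [0, 0.2]")
    if not 0.0 <= indel_fraction <= 1.0:
        raise ReadSimulationError("indel fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    abundances = np.array([max(a, 0.0) for _, a in pool], dtype=float)
    total = abundances.sum()
    if total <= 0:
        return []
    budget = depth * len(pool)
    lam = budget * abundances / total
    n_reads = rng.poisson(lam)
    reads: list[tuple[str, str]] = []
    for (seq, _), n in zip(pool, n_reads):
        if n == 0:
            continue
        base = np.frombuffer(seq.encode(), dtype=np.uint8)
        for k in range(int(n)):
            read = base.copy()
            err_mask = rng.random(read.size) < per_base_error
            err_pos = np.nonzero(err_mask)[0]
            if err_pos.size:
                out = read.copy()
                indels: list[tuple[int, str]] = []
                for p in err_pos:
                    if rng.random() < indel_fraction:
                        indels.append(
                            (int(p), "ins" if rng.random() < 0.5 else "del")
                        )
                    else:
                        cur = out[p]
                        choices = _BASES[_BASES != cur]
                        out[p] = choices[rng.integers(0, len(choices))]
                if indels:
                    lst = list(out)
                    for p, kind in sorted(indels, reverse=True):
                        if kind == "del":
                            del lst[p]
                        else:
                            lst.insert(p, int(_BASES[rng.integers(0, 4)]))
                    out = np.array(lst, dtype=np.uint8)
                read = out
            reads.append((f"read|{len(reads)}", read.tobytes().decode()))
    return reads
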