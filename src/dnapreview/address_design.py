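"""Tiered file-address design: one primer pair, many Hamming-distance variants.

A File Preview address system uses a single base primer pair per file plus
variant binding sites at chosen Hamming distances from those primers. Strands
carrying 0 HD sites amplify under any condition; strands carrying higher-HD
sites require progressively more promiscuous PCR. This module generates such
address sets (with edit-distance and cross-tier guards) and computes the
amplification-tunability statistic used to rank primer/condition pairs:

    tunability = ([nonspecific]/[specific])_promiscuous
               - ([nonspecific]/[specific])_stringent

Positive values mean the condition swing moves nonspecific amplification in
the expected direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _product

import numpy as np

from .thermo import (
    PrimerSequence,
    design_random_primer,
    edit_distance,
    hamming_distance,
    mutate_to_hd,
)

__all__ = [
    "AddressSet",
    "AddressGenerationError",
    "generate_address_set",
    "TunabilityMeasurement",
    "amplification_tunability",
]


class AddressGenerationError(RuntimeError):
    """No constraint-satisfying variant set could be generated."""


@dataclass
class AddressSet:
    """A base primer pair and variant binding sites grouped by HD level."""

    base_forward: PrimerSequence
    base_reverse: PrimerSequence
    variants: dict[int, list[tuple[str, str]]] = field(default_factory=dict)

    def sites_for_level(self, level: int) -> list[tuple[str, str]]:
        return self.variants[level]

    def primary_pair(self, level: int) -> tuple[str, str]:
        """The first (seed-order) forward/reverse site pair at ``level``."""
        return self.variants[level][0]

    @property
    def all_sites(self) -> list[str]:
        return [s for pairs in self.variants.values() for pair in pairs for s in pair]


def _passes_edit_screen(base: str, variant: str, hd: int, margin: int) -> bool:
    if hd == 0:
        return True
    return edit_distance(base, variant) > min(hd - margin, hd // 2)


def _generate_level_sites(
    base: PrimerSequence,
    level: int,
    count: int,
    gc_range: tuple[float, float],
    edit_screen_margin: int,
    accepted_by_level: dict[int, list[str]],
    rng: np.random.Generator,
    max_attempts: int,
) -> list[str]:
    sites: list[str] = []
    lo_gc, hi_gc = gc_range
    for _ in range(max_attempts):
        if len(sites) == count:
            return sites
        cand = mutate_to_hd(base, level, rng=rng)
        gc = (cand.count("G") + cand.count("C")) / len(cand)
        if not lo_gc <= gc <= hi_gc:
            continue
        if not _passes_edit_screen(base.seq, cand, level, edit_screen_margin):
            continue
        if cand in sites:
            continue
        # Cross-level guard: keep tiers cleanly separated. A candidate at
        # level h must sit strictly farther from every accepted variant of any
        # other non-zero level than the tiers' design separation |h - h'|, so
        # that no variant doubles as a near-address of another tier. Distance
        # to the base site (level 0) is exactly h by construction and needs
        # no check.
        conflict = False
        for other_level, other_sites in accepted_by_level.items():
            if other_level in (level, 0):
                continue
            floor = abs(level - other_level) + 1
            if any(hamming_distance(cand, s) < floor for s in other_sites):
                conflict = True
                break
        if conflict:
            continue
        sites.append(cand)
    if len(sites) < count:
        raise AddressGenerationError(
            f"could only generate {len(sites)}/{count} binding sites at "
            f"Hamming distance {level} within {max_attempts} attempts"
        )
    return sites


def generate_address_set(
    base_pair: tuple[PrimerSequence, PrimerSequence] | None = None,
    hd_levels: list[int] = (0, 4, 6),
    count_per_level: int = 1,
    gc_range: tuple[float, float] = (0.30, 0.70),
    edit_screen_margin: int = 3,
    pairing: str = "zip",
    rng: np.random.Generator | None = None,
    max_attempts_per_level: int = 5000,
) -> AddressSet:
    """Generate variant binding-site pairs at each requested Hamming distance.

    Forward and reverse variants are generated independently by the
    mutate-to-HD walk and combined positionally (``pairing="zip"``) or as the
    full cross of forward and reverse candidates (``pairing="product"``,
    mirroring an all-pairs experimental screen). Level 0 always contains
    exactly the base pair's own binding sites. Deterministic under a fixed
    ``rng`` seed.

    GC bounds on variants default looser than primer-design bounds: a variant
    site inherits most of its base's composition, and the walk may shift GC by
    up to ``level`` positions.
    """
    if pairing not in ("zip", "product"):
        raise ValueError("pairing must be 'zip' or 'product'")
    rng = np.random.default_rng(rng)
    if base_pair is None:
        base_pair = (design_random_primer(rng=rng), design_random_primer(rng=rng))
    base_f, base_r = base_pair
    levels = sorted(set(int(h) for h in hd_levels))
    for h in levels:
        if not 0 <= h <= base_f.length:
            raise ValueError(
                f"Hamming-distance level {h} outside [0, {base_f.length}]"
            )
    if count_per_level < 1:
        raise ValueError("count_per_level must be >= 1")
    variants: dict[int, list[tuple[str, str]]] = {}
    accepted_f: dict[int, list[str]] = {0: [base_f.seq]}
    accepted_r: dict[int, list[str]] = {0: [base_r.seq]}
    for level in levels:
        if level == 0:
            variants[0] = [(base_f.seq, base_r.seq)]
            continue
        try:
            fwd_sites = _generate_level_sites(
                base_f, level, count_per_level, gc_range, edit_screen_margin,
                accepted_f, rng, max_attempts_per_level,
            )
            rev_sites = _generate_level_sites(
                base_r, level, count_per_level, gc_range, edit_screen_margin,
                accepted_r, rng, max_attempts_per_level,
            )
        except AddressGenerationError as exc:
            raise AddressGenerationError(f"level {level}: {exc}") from exc
        accepted_f[level] = fwd_sites
        accepted_r[level] = rev_sites
        if pairing == "zip":
            variants[level] = list(zip(fwd_sites, rev_sites))
        else:
            variants[level] = list(_product(fwd_sites, rev_sites))
    return AddressSet(base_forward=base_f, base_reverse=base_r, variants=variants)


@dataclass(frozen=True)
class TunabilityMeasurement:
    """Product concentrations (any common unit) under two PCR conditions."""

    ns_promiscuous: float
    s_promiscuous: float
    ns_stringent: float
    s_stringent: float

    @property
    def tunability(self) -> float:
        return amplification_tunability(self)


def amplification_tunability(m: TunabilityMeasurement) -> float:
    """Change in the nonspecific:specific product ratio, promiscuous minus stringent."""
    if m.s_promiscuous <= 0 or m.s_stringent <= 0:
        raise ValueError(
            "specific-strand concentrations must be strictly positive"
        )
    return m.ns_promiscuous / m.s_promiscuous - m.ns_stringent / m.s_stringent
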