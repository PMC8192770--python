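"""Nearest-neighbor duplex thermodynamics and the hybridization-vs-Hamming-distance model.

This module provides the thermodynamic foundation for tiered file addressing in
PCR-based DNA storage: a two-state nearest-neighbor model of duplex free energy
(Watson-Crick stack parameters with a flat destabilization penalty for
mismatched stacks, plus a monovalent/divalent salt correction), primer design
under the field's usual constraints (GC balance, melting temperature, no long
homopolymers), a repeat-until random-mutation walk that produces binding-site
variants at an exact Hamming distance, and a Monte-Carlo estimate of the
likelihood that a primer still hybridizes to a variant binding site as a
function of Hamming distance.

The central empirical picture this reproduces: hybridization likelihood decays
with Hamming distance and flattens into a plateau well before the full primer
length, which is why conventional address designs that demand >=10 mismatches
between any two addresses waste most of the usable address space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "BASES",
    "COMPLEMENT",
    "reverse_complement",
    "hamming_distance",
    "edit_distance",
    "duplex_dG",
    "melting_temperature",
    "PrimerSequence",
    "PrimerDesignError",
    "design_random_primer",
    "mutate_to_hd",
    "HybridizationTrial",
    "HybridizationModelConfig",
    "HybridizationCurve",
    "hybridization_curve",
]

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987e-3
#: Gas constant in cal/(mol*K), used with entropy sums.
R_CAL = 1.98720425

# Unified Watson-Crick nearest-neighbor parameters at 1 M NaCl:
# stack (5'->3' on the top strand) -> (dH kcal/mol, dS cal/(mol*K)).
# The ten unique stacks; the remaining six follow by strand symmetry.
NN_STACKS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# Strand-symmetric equivalents (e.g. TT/AA is the AA/TT stack read off the
# complementary strand).
for _stack, _params in list(NN_STACKS.items()):
    _rc = COMPLEMENT[_stack[1]] + COMPLEMENT[_stack[0]]
    NN_STACKS.setdefault(_rc, _params)

#: Duplex initiation terms keyed by terminal base pair class.
NN_INIT_GC = (0.1, -2.8)
NN_INIT_AT = (2.3, 4.1)

#: Flat free-energy penalty, kcal/mol, for a stack containing at least one
#: mismatched base pair (replaces the Watson-Crick stack contribution).
MISMATCH_STACK_PENALTY = 1.8


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(
            f"Hamming distance requires equal lengths (got {len(a)} and {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions, deletions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _salt_na_equivalent_molar(monovalent_mM: float, divalent_mM: float) -> float:
    """Monovalent-equivalent cation concentration (mol/L).

    Divalent cations are folded in with the square-root rule
    [Na+]eq = [mono] + 120*sqrt([Mg2+]) (concentrations in mM).
    """
    na_eq_mM = monovalent_mM + 120.0 * math.sqrt(max(divalent_mM, 0.0))
    if na_eq_mM <= 0:
        raise ValueError("total cation concentration must be positive")
    return na_eq_mM / 1000.0


def _duplex_sums(a: str, t: str) -> tuple[float, float, int, int]:
    """Sum NN contributions for strand ``a`` paired position-wise with target ``t``.

    ``t`` is the reverse complement of the partner strand, so position i of
    ``a`` pairs with position i of ``t``; equality means a Watson-Crick pair.
    Returns (dH kcal, dS cal, n_wc_stacks, n_mismatch_stacks).
    """
    dH = 0.0
    dS = 0.0
    n_wc = 0
    n_mm = 0
    wc = [x == y for x, y in zip(a, t)]
    for i in range(len(a) - 1):
        if wc[i] and wc[i + 1]:
            h, s = NN_STACKS[a[i : i + 2]]
            dH += h
            dS += s
            n_wc += 1
        else:
            n_mm += 1
    for end, is_wc in ((0, wc[0]), (len(a) - 1, wc[-1])):
        if is_wc and a[end] in "GC":
            h, s = NN_INIT_GC
        else:
            # A/T terminus, or a frayed (mismatched) terminus treated as A/T-like.
            h, s = NN_INIT_AT
        dH += h
        dS += s
    return dH, dS, n_wc, n_mm


def duplex_dG(
    a: str,
    b: str,
    temperature: float = 37.0,
    monovalent_mM: float = 50.0,
    divalent_mM: float = 0.0,
    mismatch_penalty: float = MISMATCH_STACK_PENALTY,
) -> float:
    """Two-state free energy (kcal/mol) of the a:b duplex at ``temperature`` (degC).

    Strands are aligned antiparallel: ``a[i]`` pairs with ``b[len-1-i]``, so a
    perfect duplex has ``b == reverse_complement(a)``. Watson-Crick stacks use
    the unified nearest-neighbor table; any stack touching a mismatched pair
    contributes a flat ``mismatch_penalty`` instead. The salt correction
    adjusts the entropy of Watson-Crick stacks only.
    """
    for name, seq in (("a", a), ("b", b)):
        if len(seq) < 2:
            raise ValueError(f"sequence {name!r} must be at least 2 nt")
    if len(a) != len(b):
        raise ValueError("duplex model requires equal-length strands")
    t = reverse_complement(b)
    dH, dS, n_wc, n_mm = _duplex_sums(a, t)
    na_eq = _salt_na_equivalent_molar(monovalent_mM, divalent_mM)
    dS_corr = dS + 0.368 * n_wc * math.log(na_eq)
    T = temperature + 273.15
    return dH - T * dS_corr / 1000.0 + mismatch_penalty * n_mm


def melting_temperature(
    seq: str,
    monovalent_mM: float = 50.0,
    divalent_mM: float = 0.0,
    primer_conc_nM: float = 250.0,
) -> float:
    """Two-state melting temperature (degC) of ``seq`` against its perfect complement."""
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 nt")
    dH, dS, n_wc, _ = _duplex_sums(seq, seq)
    na_eq = _salt_na_equivalent_molar(monovalent_mM, divalent_mM)
    dS_corr = dS + 0.368 * n_wc * math.log(na_eq)
    c_total = primer_conc_nM * 1e-9
    tm_K = 1000.0 * dH / (dS_corr + R_CAL * math.log(c_total / 4.0))
    return tm_K - 273.15


class PrimerDesignError(RuntimeError):
    """Raised when no primer satisfying the constraints is found."""


@dataclass(frozen=True)
class PrimerSequence:
    """A primer (or primer binding site) with its design summary statistics."""

    seq: str
    tm: float

    def __post_init__(self) -> None:
        if set(self.seq) - set(BASES):
            raise ValueError(f"primer alphabet must be ACGT, got {self.seq!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best


def design_random_primer(
    length: int = 20,
    gc_range: tuple[float, float] = (0.40, 0.60),
    tm_range: tuple[float, float] = (50.0, 55.0),
    max_homopolymer: int = 4,
    rng: np.random.Generator | None = None,
    monovalent_mM: float = 50.0,
    primer_conc_nM: float = 250.0,
    max_attempts: int = 20000,
) -> PrimerSequence:
    """Rejection-sample a random primer meeting GC, Tm and homopolymer constraints.

    Deterministic for a fixed ``rng`` state. Raises :class:`PrimerDesignError`
    if the constraints are not met within ``max_attempts`` draws.
    """
    rng = np.random.default_rng(rng)
    lo_gc, hi_gc = gc_range
    lo_tm, hi_tm = tm_range
    for _ in range(max_attempts):
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        gc = (seq.count("G") + seq.count("C")) / length
        if not (lo_gc <= gc <= hi_gc):
            continue
        if _max_homopolymer(seq) > max_homopolymer:
            continue
        tm = melting_temperature(
            seq, monovalent_mM=monovalent_mM, primer_conc_nM=primer_conc_nM
        )
        if not (lo_tm <= tm <= hi_tm):
            continue
        return PrimerSequence(seq=seq, tm=tm)
    raise PrimerDesignError(
        f"no primer satisfying gc in {gc_range}, Tm in {tm_range} degC and "
        f"homopolymer <= {max_homopolymer} found in {max_attempts} attempts"
    )


def mutate_to_hd(
    primer: PrimerSequence | str,
    target_hd: int,
    rng: np.random.Generator | None = None,
    max_steps: int = 200000,
) -> str:
    """Random-mutation walk until the mutant is exactly ``target_hd`` from ``primer``.

    Each step picks a uniform random position and replaces its base with one of
    the other three, equiprobably; the walk repeats until the Hamming distance
    to the original equals ``target_hd``. Reversions are allowed, matching the
    repeat-until procedure, so the walk terminates with probability one.
    """
    seq = primer.seq if isinstance(primer, PrimerSequence) else primer
    n = len(seq)
    if not 0 <= target_hd <= n:
        raise ValueError(f"target_hd must be in [0, {n}], got {target_hd}")
    rng = np.random.default_rng(rng)
    current = list(seq)
    hd = 0
    for _ in range(max_steps):
        if hd == target_hd:
            return "".join(current)
        pos = int(rng.integers(0, n))
        alternatives = [b for b in BASES if b != current[pos]]
        new_base = alternatives[int(rng.integers(0, 3))]
        was_mutant = current[pos] != seq[pos]
        current[pos] = new_base
        is_mutant = new_base != seq[pos]
        hd += int(is_mutant) - int(was_mutant)
    raise RuntimeError(
        f"mutation walk did not reach Hamming distance {target_hd} in {max_steps} steps"
    )


@dataclass(frozen=True)
class HybridizationTrial:
    """One Monte-Carlo trial: a primer, its mutant, and the binding verdict."""

    original: str
    mutant: str
    hd: int
    edit_dist: int
    dG: float
    binds: bool


@dataclass(frozen=True)
class HybridizationModelConfig:
    """Parameters of the Monte-Carlo hybridization model.

    ``dG_threshold`` is the free-energy cutoff (kcal/mol): duplexes more
    negative than the threshold count as bound. The edit-distance screen
    discards trials whose edit distance is at most
    ``min(hd - edit_screen_margin, hd // 2)`` — shift-like mutants that keep a
    low edit distance despite a high Hamming distance would otherwise bind and
    skew the curve. The ``hd // 2`` cap matters at large Hamming distances,
    where even unrelated random sequences sit at roughly half-length edit
    distance and a fixed margin would discard essentially every trial.
    """

    n_trials: int = 10000
    dG_threshold: float = -10.0
    eval_temperature: float = 37.0
    monovalent_mM: float = 50.0
    divalent_mM: float = 0.0
    edit_screen_margin: int = 3
    primer_length: int = 20
    gc_range: tuple[float, float] = (0.40, 0.60)
    tm_range: tuple[float, float] = (50.0, 55.0)
    max_homopolymer: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.dG_threshold >= 0:
            raise ValueError("dG_threshold must be negative")


@dataclass
class HybridizationCurve:
    """Per-Hamming-distance fraction of mutants that still hybridize."""

    fraction_bound: dict[int, float]
    n_kept: dict[int, int] = field(default_factory=dict)
    n_bound: dict[int, int] = field(default_factory=dict)
    config: HybridizationModelConfig = field(default_factory=HybridizationModelConfig)

    def standard_error(self, hd: int) -> float:
        """Binomial standard error of the bound fraction at ``hd``."""
        n = self.n_kept[hd]
        p = self.fraction_bound[hd]
        return math.sqrt(p * (1.0 - p) / n) if n else float("nan")


def hybridization_curve(
    hd_values: list[int] | range,
    config: HybridizationModelConfig | None = None,
) -> HybridizationCurve:
    """Monte-Carlo hybridization likelihood as a function of Hamming distance.

    For every requested Hamming distance, each trial designs a fresh
    constraint-satisfying primer, mutates it to the exact distance, screens
    out shift-like mutants by edit distance, evaluates the free energy of the
    primer against the reverse complement of the mutant's binding site, and
    classifies binding by the threshold. Distances at which every trial was
    screened out are reported as missing entries with a warning.
    """
    config = config or HybridizationModelConfig()
    fraction: dict[int, float] = {}
    kept_counts: dict[int, int] = {}
    bound_counts: dict[int, int] = {}
    for hd in hd_values:
        if not 0 <= hd <= config.primer_length:
            raise ValueError(
                f"Hamming distance {hd} outside [0, {config.primer_length}]"
            )
        rng = np.random.default_rng([config.rng_seed, hd])
        kept = 0
        bound = 0
        for _ in range(config.n_trials):
            primer = design_random_primer(
                length=config.primer_length,
                gc_range=config.gc_range,
                tm_range=config.tm_range,
                max_homopolymer=config.max_homopolymer,
                rng=rng,
                monovalent_mM=config.monovalent_mM,
            )
            mutant = mutate_to_hd(primer, hd, rng=rng)
            ed = edit_distance(primer.seq, mutant)
            if ed <= min(hd - config.edit_screen_margin, hd // 2):
                continue
            # The data strand carries the reverse complement of the mutant, so
            # the primer is evaluated against that binding site; position-wise
            # this pits the primer directly against the mutant sequence.
            dG = duplex_dG(
                primer.seq,
                reverse_complement(mutant),
                temperature=config.eval_temperature,
                monovalent_mM=config.monovalent_mM,
                divalent_mM=config.divalent_mM,
            )
            kept += 1
            bound += int(dG < config.dG_threshold)
        if kept == 0:
            warnings.warn(
                f"all {config.n_trials} trials at Hamming distance {hd} were "
                "screened out by the edit-distance filter; entry omitted",
                stacklevel=2,
            )
            continue
        fraction[hd] = bound / kept
        kept_counts[hd] = kept
        bound_counts[hd] = bound
    return HybridizationCurve(
        fraction_bound=fraction,
        n_kept=kept_counts,
        n_bound=bound_counts,
        config=config,
    )
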