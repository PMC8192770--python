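"""Competitive PCR access simulation: stringent through promiscuous conditions.

The stringency of a PCR reaction toward mismatched primer binding sites is
governed by the equilibrium fraction of sites bound by primer,

    theta = c*K / (1 + c*K),    K = exp(-dG / (R*T)),

with c the free primer concentration, dG the duplex free energy of primer and
binding site at the annealing temperature, R the gas constant and T the
annealing temperature. Mismatched sites carry a per-mismatch free-energy
penalty, so lowering the annealing temperature or raising primer
concentration turns amplification of higher-Hamming-distance strands on.

The cycle-by-cycle simulation is deterministic expectation propagation: each
species grows per cycle by ``1 + eff * theta_fwd * theta_rev`` and every new
strand consumes one forward and one reverse primer from shared, finite pools
(amplification stalls when primers exhaust). Stochastic per-strand sampling
is used only for the error-prone background generator.

Salt handling: MgCl2 enters the duplex model mechanistically through the
monovalent-equivalent salt correction (more Mg -> more binding -> more
promiscuous). KCl is a signed phenomenological stringency modifier — it
scales the per-mismatch penalty upward and, beyond 150 mM, inhibits the
reaction entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .address_design import TunabilityMeasurement, amplification_tunability
from .thermo import R_KCAL, duplex_dG, reverse_complement

__all__ = [
    "AVOGADRO",
    "PCRCondition",
    "PREVIEW_CONDITION",
    "INTERMEDIATE_CONDITION",
    "FULL_ACCESS_CONDITION",
    "DEFAULT_MISMATCH_PENALTY",
    "DEFAULT_READOUT_THRESHOLD",
    "TemplateSpecies",
    "BindingEquilibrium",
    "binding_theta",
    "site_dG",
    "AmplificationResult",
    "simulate_competitive_pcr",
    "AccessResult",
    "simulate_access",
    "screen_primers_for_tunability",
    "ErrorProneProfile",
    "error_prone_background",
    "BackgroundAccounting",
    "background_gb",
]

AVOGADRO = 6.02214076e23

#: Free-energy penalty per mismatched primer-site position, kcal/mol,
#: applied on top of the perfect-match duplex energy. Calibrated so the
#: 0/2/4/6 HD access thresholds fall inside the screened 40-60 degC PCR
#: window at 125-500 nM primer.
DEFAULT_MISMATCH_PENALTY = 1.5

#: A species is "accessed" when it makes up at least this fraction of the
#: final molecule pool (sequencing/electrophoresis visibility proxy).
DEFAULT_READOUT_THRESHOLD = 1e-3

#: Polymerase extension efficiency per primer-site mismatch. Unlike the
#: annealing equilibrium, this penalty persists under promiscuous conditions:
#: a primer bound across mismatches still extends less efficiently every
#: cycle. Calibrated jointly with the stored-copy schedule (100x for 4 HD,
#: 1000x for 6 HD) so that full-access amplification yields roughly even
#: molecule shares across tiers.
MISMATCH_EXTENSION_EFFICIENCY = 0.96

#: Phenomenological KCl stringency: extra kcal/mol per mismatch per 100 mM
#: KCl above the 50 mM baseline.
KCL_STRINGENCY_PER_100MM = 0.5

#: KCl concentration beyond which amplification is fully inhibited (mM).
KCL_INHIBITION_MM = 150.0


@dataclass(frozen=True)
class PCRCondition:
    """One PCR environment: temperature, primer and salt concentrations."""

    annealing_temperature: float  # degC
    primer_concentration: float  # nM per primer
    mgcl2: float = 2.0  # mM
    kcl: float = 50.0  # mM
    cycles: int = 35
    polymerase_efficiency: float = 0.95
    volume_uL: float = 6.0

    def __post_init__(self) -> None:
        if not 30.0 <= self.annealing_temperature <= 75.0:
            raise ValueError("annealing temperature must be within [30, 75] degC")
        for name in ("primer_concentration", "mgcl2", "kcl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.polymerase_efficiency <= 1:
            raise ValueError("polymerase efficiency must be in (0, 1]")

    @property
    def temperature_K(self) -> float:
        return self.annealing_temperature + 273.15

    @property
    def primer_pool_copies(self) -> float:
        """Initial copies of each primer in the reaction volume."""
        return self.primer_concentration * 1e-9 * AVOGADRO * self.volume_uL * 1e-6

    @property
    def inhibited(self) -> bool:
        return self.kcl > KCL_INHIBITION_MM


#: Default access conditions (250 nM primer; temperature is the main dial):
#: 60 degC accesses only the 0-HD preview tier, 46 degC adds the 4-HD tier,
#: 41 degC amplifies all tiers including 6 HD.
PREVIEW_CONDITION = PCRCondition(60.0, 250.0)
INTERMEDIATE_CONDITION = PCRCondition(46.0, 250.0)
FULL_ACCESS_CONDITION = PCRCondition(41.0, 250.0)


def binding_theta(dG: float, T: float, primer_conc_nM: float) -> float:
    """Equilibrium fraction of binding sites occupied by primer.

    ``T`` in kelvin; primer-excess approximation ``theta = cK/(1+cK)`` with
    ``c`` the free primer concentration in mol/L.
    """
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if primer_conc_nM < 0:
        raise ValueError("primer concentration must be non-negative")
    if primer_conc_nM == 0:
        return 0.0
    c = primer_conc_nM * 1e-9
    log_cK = math.log(c) - dG / (R_KCAL * T)
    if log_cK > 700:
        return 1.0
    cK = math.exp(log_cK)
    return cK / (1.0 + cK)


@dataclass
class BindingEquilibrium:
    """The dG/R/T bundle governing one primer-site association."""

    dG: float
    T: float  # kelvin
    primer_conc_nM: float
    R: float = R_KCAL

    @property
    def K_eq(self) -> float:
        return math.exp(-self.dG / (self.R * self.T))

    @property
    def theta(self) -> float:
        return binding_theta(self.dG, self.T, self.primer_conc_nM)


def site_dG(
    primer_seq: str,
    hd: int,
    condition: PCRCondition,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
) -> float:
    """Free energy of a primer bound to a binding site ``hd`` mismatches away.

    The perfect-match energy comes from the nearest-neighbor model at the
    annealing temperature with Mg2+ folded into the salt correction; each
    mismatch then adds ``mismatch_penalty`` plus the KCl stringency term.
    The 50 mM monovalent baseline is fixed — KCl acts only through the
    phenomenological mismatch term, matching its observed direct relationship
    with specificity.
    """
    dG_pm = duplex_dG(
        primer_seq,
        reverse_complement(primer_seq),
        temperature=condition.annealing_temperature,
        monovalent_mM=50.0,
        divalent_mM=condition.mgcl2,
    )
    per_mm = mismatch_penalty + KCL_STRINGENCY_PER_100MM * max(
        0.0, condition.kcl - 50.0
    ) / 100.0
    return dG_pm + hd * per_mm


@dataclass
class TemplateSpecies:
    """One template population competing for the shared primer pair."""

    label: str
    hd_fwd: int
    hd_rev: int
    length: int  # bp
    copies: float
    dG_fwd: float | None = None
    dG_rev: float | None = None

    def with_condition(
        self,
        condition: PCRCondition,
        primer_fwd: str,
        primer_rev: str,
        mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
    ) -> "TemplateSpecies":
        """Recompute the duplex energies for a new condition."""
        return replace(
            self,
            dG_fwd=site_dG(primer_fwd, self.hd_fwd, condition, mismatch_penalty),
            dG_rev=site_dG(primer_rev, self.hd_rev, condition, mismatch_penalty),
        )


@dataclass
class AmplificationResult:
    """Cycle-by-cycle abundances and primer bookkeeping for one reaction."""

    labels: list[str]
    trajectory: np.ndarray  # (cycles + 1, n_species)
    primers_consumed_fwd: np.ndarray  # per cycle
    primers_consumed_rev: np.ndarray
    new_strands: np.ndarray  # per cycle, total across species
    condition: PCRCondition

    @property
    def final_abundances(self) -> dict[str, float]:
        return dict(zip(self.labels, self.trajectory[-1]))

    def final_fractions(self) -> dict[str, float]:
        total = float(self.trajectory[-1].sum())
        if total == 0:
            return {lab: 0.0 for lab in self.labels}
        return {lab: float(v) / total for lab, v in zip(self.labels, self.trajectory[-1])}

    def accessed(self, threshold: float = DEFAULT_READOUT_THRESHOLD) -> set[str]:
        return {lab for lab, f in self.final_fractions().items() if f >= threshold}


def simulate_competitive_pcr(
    species: list[TemplateSpecies],
    condition: PCRCondition,
    primer_fwd: str | None = None,
    primer_rev: str | None = None,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
    extension_efficiency: float = MISMATCH_EXTENSION_EFFICIENCY,
) -> AmplificationResult:
    """Deterministic competitive amplification of template species.

    Each cycle, species ``i`` gains
    ``N_i * eff * theta_fwd_i * theta_rev_i * eta**(hd_fwd_i + hd_rev_i)``
    copies, where the thetas use the free primer concentration at the start of
    the cycle and ``eta`` is the per-mismatch extension efficiency. Every new
    strand consumes one primer from each of the shared forward/reverse pools;
    when a pool cannot cover demand, all species are scaled back
    proportionally (mass balance holds exactly).
    """
    if not species:
        raise ValueError("at least one template species is required")
    sp = list(species)
    if primer_fwd is not None and primer_rev is not None:
        sp = [
            s.with_condition(condition, primer_fwd, primer_rev, mismatch_penalty)
            for s in sp
        ]
    if any(s.dG_fwd is None or s.dG_rev is None for s in sp):
        raise ValueError(
            "species need dG_fwd/dG_rev, or pass primer sequences to compute them"
        )
    n = len(sp)
    N = np.array([float(s.copies) for s in sp])
    traj = np.empty((condition.cycles + 1, n))
    traj[0] = N
    pool_scale = AVOGADRO * condition.volume_uL * 1e-6  # copies per (mol/L)
    p_fwd = condition.primer_pool_copies
    p_rev = condition.primer_pool_copies
    used_f = np.zeros(condition.cycles)
    used_r = np.zeros(condition.cycles)
    new_tot = np.zeros(condition.cycles)
    eff = 0.0 if condition.inhibited else condition.polymerase_efficiency
    T = condition.temperature_K
    dg_f = np.array([s.dG_fwd for s in sp])
    dg_r = np.array([s.dG_rev for s in sp])
    ext = np.array(
        [extension_efficiency ** (s.hd_fwd + s.hd_rev) for s in sp]
    )
    for c in range(condition.cycles):
        cf_nM = p_fwd / pool_scale * 1e9
        cr_nM = p_rev / pool_scale * 1e9
        th_f = np.array([binding_theta(g, T, cf_nM) for g in dg_f])
        th_r = np.array([binding_theta(g, T, cr_nM) for g in dg_r])
        delta = N * eff * th_f * th_r * ext
        demand = delta.sum()
        if demand > 0:
            scale = min(1.0, p_fwd / demand, p_rev / demand)
            delta *= scale
            demand *= scale
        N = N + delta
        p_fwd = max(p_fwd - demand, 0.0)
        p_rev = max(p_rev - demand, 0.0)
        used_f[c] = demand
        used_r[c] = demand
        new_tot[c] = demand
        traj[c + 1] = N
    return AmplificationResult(
        labels=[s.label for s in sp],
        trajectory=traj,
        primers_consumed_fwd=used_f,
        primers_consumed_rev=used_r,
        new_strands=new_tot,
        condition=condition,
    )


@dataclass
class AccessResult:
    """Outcome of amplifying a tiered strand library under one condition."""

    accessed_tiers: set[int]
    tier_fractions: dict[int, float]
    strand_abundance: dict[str, float]  # record id -> expected final copies
    amplification: AmplificationResult


def simulate_access(
    strands,
    tier_of_partition: dict[int, int],
    condition: PCRCondition,
    primer_fwd: str,
    primer_rev: str,
    readout_threshold: float = DEFAULT_READOUT_THRESHOLD,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
) -> AccessResult:
    """Tier-level competitive amplification of an encoded strand library.

    ``strands`` are codec records with ``partition``, ``copies`` and
    ``record_id``; all strands of one HD tier share the tier's binding-site
    energies, so amplification is simulated per tier and the tier's final
    abundance is apportioned to strands by their stored copy numbers.
    """
    strands = list(strands)
    if not strands:
        raise ValueError("empty strand library")
    tier_copies: dict[int, float] = {}
    for s in strands:
        tier = tier_of_partition[s.partition]
        tier_copies[tier] = tier_copies.get(tier, 0.0) + s.copies
    species = [
        TemplateSpecies(
            label=str(tier), hd_fwd=tier, hd_rev=tier, length=200, copies=total
        )
        for tier, total in sorted(tier_copies.items())
    ]
    result = simulate_competitive_pcr(
        species, condition, primer_fwd, primer_rev, mismatch_penalty
    )
    fractions = result.final_fractions()
    finals = result.final_abundances
    tier_fractions = {int(lab): f for lab, f in fractions.items()}
    accessed = {int(lab) for lab in result.accessed(readout_threshold)}
    abundance: dict[str, float] = {}
    for s in strands:
        tier = tier_of_partition[s.partition]
        abundance[s.record_id] = finals[str(tier)] * s.copies / tier_copies[tier]
    return AccessResult(
        accessed_tiers=accessed,
        tier_fractions=tier_fractions,
        strand_abundance=abundance,
        amplification=result,
    )


def screen_primers_for_tunability(
    candidates: list,
    stringent: PCRCondition,
    promiscuous: PCRCondition,
    hd: int = 2,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
) -> list[tuple[float, object]]:
    """Rank candidate primers by simulated amplification tunability.

    Mirrors the experimental screen: each candidate is evaluated in a
    competitive reaction of a perfect-match 200 bp template against a
    ``hd``-mismatch 60 bp template under the stringent and promiscuous
    conditions, and scored by the tunability statistic. Returns
    ``(tunability, candidate)`` pairs, best first (ties broken by seed order).
    """
    scored = []
    for cand in candidates:
        seq = cand.seq if hasattr(cand, "seq") else cand
        species = [
            TemplateSpecies("s", 0, 0, 200, 1e6),
            TemplateSpecies("ns", hd, hd, 60, 1e6),
        ]
        res_p = simulate_competitive_pcr(
            species, promiscuous, seq, seq, mismatch_penalty
        ).final_abundances
        res_s = simulate_competitive_pcr(
            species, stringent, seq, seq, mismatch_penalty
        ).final_abundances
        tun = amplification_tunability(
            TunabilityMeasurement(
                ns_promiscuous=res_p["ns"],
                s_promiscuous=res_p["s"],
                ns_stringent=res_s["ns"],
                s_stringent=res_s["s"],
            )
        )
        scored.append((tun, cand))
    scored.sort(key=lambda t: -t[0])
    return scored


# ---------------------------------------------------------------------------
# Error-prone PCR background
# ---------------------------------------------------------------------------

_BASE_TO_I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProneProfile:
    """Per-cycle 4x4 substitution matrix (rows: from-base A,C,G,T)."""

    matrix: tuple[tuple[float, ...], ...]
    cycles: int = 35

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("substitution matrix rows must sum to 1")
        if (np.diag(m)[:, None] < m).any():
            raise ValueError("diagonal must dominate each row")

    @classmethod
    def transition_biased(
        cls, rate: float = 2e-3, cycles: int = 35, transition_fold: float = 10.0
    ) -> "ErrorProneProfile":
        """Mutagenic-dNTP-style profile: transitions elevated over transversions.

        ``rate`` is the total substitution probability per base per cycle; the
        single transition (A<->G, C<->T) carries ``transition_fold`` times the
        weight of each of the two transversions.
        """
        ts = rate * transition_fold / (transition_fold + 2.0)
        tv = rate / (transition_fold + 2.0)
        m = np.full((4, 4), tv)
        np.fill_diagonal(m, 1.0 - rate)
        # transitions: A<->G (0,2), C<->T (1,3)
        m[0, 2] = m[2, 0] = ts
        m[1, 3] = m[3, 1] = ts
        return cls(matrix=tuple(map(tuple, m)), cycles=cycles)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix)

    def expected_divergence(self, template: str) -> float:
        """Exact expected number of positions differing from the template
        after ``cycles`` rounds (accounts for back-mutation)."""
        m_c = np.linalg.matrix_power(self.as_array(), self.cycles)
        stay = np.diag(m_c)
        return float(sum(1.0 - stay[_BASE_TO_I[b]] for b in template))


def error_prone_background(
    template: str,
    n_unique: int,
    profile: ErrorProneProfile | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Generate ``n_unique`` independently mutagenized copies of ``template``.

    Each copy passes through ``profile.cycles`` rounds of per-base
    substitution sampling; deterministic under a fixed seed.
    """
    if n_unique < 1:
        raise ValueError("n_unique must be >= 1")
    profile = profile or ErrorProneProfile.transition_biased()
    rng = np.random.default_rng(rng)
    m = profile.as_array()
    cum = np.cumsum(m, axis=1)
    base = np.array([_BASE_TO_I[b] for b in template], dtype=np.int64)
    pool = np.tile(base, (n_unique, 1))
    for _ in range(profile.cycles):
        u = rng.random(pool.shape)
        pool = (u[..., None] > cum[pool]).sum(axis=-1)
    seqs = _I_TO_BASE[pool]
    return [s.tobytes().decode() for s in seqs]


# ---------------------------------------------------------------------------
# Background data-quantity accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundAccounting:
    """Strand layout used to express a physical strand count as gigabytes."""

    strand_nt: int = 200
    primer_nt: int = 20  # per primer, two primers per strand
    index_nt: int = 16
    checksum_nt: int = 8
    nt_per_byte: int = 8
    redundancy: int = 10

    @property
    def bytes_per_strand(self) -> int:
        payload = self.strand_nt - 2 * self.primer_nt - self.index_nt - self.checksum_nt
        if payload % self.nt_per_byte:
            raise ValueError("layout does not divide into whole codewords")
        return payload // self.nt_per_byte


def background_gb(
    n_physical_strands: float, acct: BackgroundAccounting | None = None
) -> float:
    """Data quantity (GB) represented by ``n_physical_strands`` background strands."""
    if n_physical_strands < 0:
        raise ValueError("strand count must be non-negative")
    acct = acct or BackgroundAccounting()
    return n_physical_strands * acct.bytes_per_strand / acct.redundancy / 1e9
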