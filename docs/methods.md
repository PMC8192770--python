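# Methods

This note documents the models implemented in `dnapreview`, the parameters
that matter, how the defaults were chosen, and what the simulations do and do
not capture.

## Duplex thermodynamics

Primer–site association is modeled as a two-state equilibrium. The free
energy of a duplex is the sum of unified Watson–Crick nearest-neighbor stack
parameters (ΔH in kcal/mol, ΔS in cal/mol·K at 1 M NaCl) plus initiation
terms per terminal base pair. Monovalent salt corrects the entropy by
`0.368·N_stacks·ln[Na+]`; divalent cations are folded in as a monovalent
equivalent `[Na+]eq = [mono] + 120·√[Mg2+]` (mM). Any stack that touches a
mismatched pair contributes a flat destabilization of **+1.8 kcal/mol**
instead of its table value; an isolated internal mismatch therefore costs
roughly +5 to +7 kcal/mol once the two lost Watson–Crick stacks are counted.
This is deliberately coarser than a full mismatch-resolved parameter set:
the quantities this package relies on are curve *shapes* and binding
*classifications* against a −10 kcal/mol threshold, not absolute free
energies, and the flat penalty keeps the model auditable by hand summation
(the unit tests verify perfect-duplex energies against an independent
literal-table summation to 1e−9).

Melting temperatures use the same sums:
`Tm = ΔH / (ΔS_salt + R·ln(C/4))` with a 250 nM default primer
concentration.

## Primer design and the hybridization curve

Primers are rejection-sampled uniformly over ACGT: 20 nt, GC fraction in
[0.40, 0.60], Tm in [50, 55] °C at 50 mM monovalent salt, homopolymer runs
≤ 4. Variant binding sites at an exact Hamming distance h are produced by
the repeat-until mutation walk: pick a uniform position, substitute a
uniform different base, repeat until the distance to the original is exactly
h (reversions allowed; terminates with probability one).

The hybridization-likelihood curve runs, per Hamming distance, fresh trials
of (design primer → mutate to h → screen → evaluate ΔG of the primer
against the reverse complement of the mutant's binding site → classify
bound if ΔG < −10 kcal/mol). The default evaluation temperature is 37 °C at
50 mM monovalent salt. The screen discards mutants whose edit distance is
≤ `min(h − 3, h // 2)`: substitution-only walks essentially never produce
such sequences (they are shift-like artifacts that would bind despite a high
Hamming distance), and the half-distance cap keeps the screen from
swallowing entire high-HD bins, where even unrelated random 20-mers sit at
edit distance ~10–14. With 1000 trials per distance the curve is 1.0 at
HD 0 (a perfect 20-mer duplex is far below threshold at 37 °C), decays
through HD 1–4, and plateaus near zero well before HD 10.

## Address sets

An address set is a screened base primer pair plus variant site pairs at the
requested HD levels (defaults 0/4/6). Variants must pass the edit screen,
a loose GC bound ([0.30, 0.70] — a variant inherits most of its base's
composition), and a cross-tier guard: a candidate at level h is rejected if
it comes within `|h − h'|` of any accepted variant at another non-zero level
h', so no site doubles as a near-address of a different tier. Distance to
the base site is exactly h by construction. Forward and reverse variants are
generated independently and paired positionally (`zip`); the all-pairs
`product` pairing used in experimental screens is available as an option.

Base primers are ranked by *simulated amplification tunability*: each
candidate runs a competitive two-template reaction (perfect-match 200-mer vs
2-HD 60-mer) under a stringent and a promiscuous condition, and is scored by
the change in the nonspecific:specific product ratio. This mirrors how
primers were screened experimentally and selects primers whose perfect-match
ΔG places the tier thresholds inside the usable condition window.

## Competitive PCR model

Each template species carries forward/reverse site energies
`ΔG_site = ΔG_perfect(T, Mg) + h·p`, with the per-mismatch penalty
**p = 1.5 kcal/mol** by default. Per cycle, species i grows by

    ΔN_i = N_i · ε · θ_fwd,i · θ_rev,i · η^(h_fwd,i + h_rev,i)

where `θ = cK/(1+cK)` uses the free primer concentration at the start of the
cycle, `ε = 0.95` is the polymerase efficiency, and **η = 0.96** is the
per-mismatch extension efficiency. Every new strand consumes one primer from
each of the finite forward/reverse pools (250 nM in 6 µL by default ≈ 9×10¹⁴
copies); when demand exceeds the pool all species are scaled back
proportionally, so mass balance is exact and amplification stalls on primer
exhaustion.

The two penalty channels play different roles. The equilibrium term `h·p`
is the stringency *switch*: it moves the temperature/concentration threshold
at which a tier turns on. The extension term `η^h` is a persistent per-cycle
*efficiency deficit* that does not saturate away under promiscuous
conditions; it is what the stored-copy schedule (1×/100×/1000× for tiers
0/4/6) compensates, so that a full-access reaction yields comparable
molecule counts per tier. Without it, an equilibrium-only model drives every
accessed tier to θ ≈ 1 and the copy multipliers would bury the preview tier
below 0.1% of molecules — contradicting the design goal the multipliers
serve.

Calibration (done once, against the screened condition window of
40–60 °C and 62.5–1000 nM): p = 1.5 puts the 2-HD on/off boundary between
(125 nM, 55 °C) and (500 nM, 55 °C) and between 60 °C and 45 °C at 250 nM
for most constraint-satisfying primers, with the 4-HD and 6-HD boundaries
near 49 °C and 43 °C; η = 0.96 makes 100× copies offset the 4-HD efficiency
deficit over a ~30-cycle effective exponential phase. The default named
conditions are **preview = 60 °C**, **intermediate = 46 °C**,
**full access = 41 °C**, all at 250 nM.

Salt effects: MgCl₂ enters mechanistically through the salt correction
(more Mg²⁺ → more negative ΔG → more promiscuous). KCl is phenomenological —
it scales the per-mismatch penalty (+0.5 kcal/mol per mismatch per 100 mM
above 50 mM, reflecting its observed direct relationship with specificity)
and fully inhibits the reaction above 150 mM. A species is *accessed* when
its final share of molecules is ≥ 0.1% (readout threshold; configurable).
The 0.1% default, rather than a stricter 1%, keeps the preview tier
detectable under full access, where its equilibrium share sits near 1%
by design of the copy schedule.

The simulation is deterministic expectation propagation at the species/tier
level; no per-molecule stochasticity. Consequences: exact reproducibility,
exact conservation of the equal-ΔG invariant (equal-energy species preserve
their initial copy ratios), but no amplification jackpots or dropout noise.

## Codec

Scan script: 42 scans — DC of Y, Cr, Cb, then luminance AC in groups of five
coefficients (final group 61:63), then chrominance AC interleaved Cb/Cr.
Actual JPEG handling is at the byte/marker level: a progressive (SOF2)
stream is split into its header and per-SOS segments, and partitions are
formed from contiguous scan runs (partition 1 also carries the header).
Fixture JPEGs produced by the imaging library use its own progressive
script (~10 scans); the codec is agnostic to the scan count. Baseline
(SOF0) streams are rejected.

Per partition: bytes are zero-padded to 1665-byte blocks; each block is a
185×9 matrix; the outer RS [255, 185, 71] extends each column to 255 rows;
each row is emitted as 2 index bytes + 9 data bytes + 3 inner-RS parity
bytes = 14 bytes = 14 codewords of 8 nt; an 8-nt tier-specific restriction
site (synthetic 8-cutter recognition sequences) splits the payload at its
midpoint; partition binding sites and common flanking primers complete the
200-nt strand. Row indices are unique within a partition
(index = block·255 + row); partition identity is carried by the primer
sites. The codebook is built by a greedy lexicographic scan over all 4⁸
8-mers, accepting GC-balanced words at edit distance ≥ 2 from all previous
acceptances; the first 256 words form the primary book and the next 256 the
disjoint alternate book.

Payload-vs-primer guard: after assembly, every 20-nt window of the strand
(except the two designated binding-site windows, which are low-HD by design)
must be ≥ 6 HD from every partition site and site complement. A violating
strand is re-synthesized through the alternate codebook; the decoder tries
the primary book first and falls back to the alternate when the inner code
fails, which is unambiguous because the books share no codewords. The guard
threshold of 6 (rather than the conventional 8) keeps encoding feasible at
fixture scale while still excluding accidental sub-tier binding sites.

Decoding inverts each stage: exact codeword lookup (unknown 8-mers become
inner-code erasures), inner RS correction (1 error or up to 3 erasures per
row), majority vote over duplicate indices, column-wise outer erasure/error
decoding (≤ 70 missing rows per block), padding strip, and reassembly of the
successful partition prefix closed by an EOI marker. A failed partition 1
makes the image unreadable; any other failure only truncates quality.

## Read clustering

Sequences are aggregated to multiplicities and processed in descending
count. A sequence joins an existing centroid if the centroid's accumulated
count is ≥ 5× its own and the Levenshtein distance is ≤ 8; ties prefer the
larger, then lexicographically smaller centroid. Reference strands are
seeded with 20 synthetic copies and always form their own centroids (that
is what the seeding is for); their reported counts are cluster size minus
seeds. Reads outside [150, 250] nt are filtered first. Candidate search is
exact Hamming distance (vectorized) for equal-length sequences — a
Levenshtein upper bound — plus a nine-chunk pigeonhole index with banded
edlib verification for indel-containing reads; with ≤ 8 edits at least one
chunk survives intact within the offset bound, so no within-cap centroid is
missed by the indel path. Corner-case divergence from other message-passing
implementations (e.g., an equal-length pair whose Levenshtein distance is
under the cap only via compensating indels while its Hamming distance is
over) is possible but was never observed on simulated data.

## Error-prone background

Background pools are independent mutagenized copies of a template run
through 35 rounds of per-base substitution with a transition-biased matrix
(A↔G, C↔T at 10× each transversion; total rate 2×10⁻³ per base per cycle —
the mutagenic-dNTP chemistry motivates the bias, the absolute rate is a
chosen default). The expected divergence from the template is computed
exactly as a matrix power (back-mutations included) and the generator is
validated against it. Data-quantity accounting uses the single-primer-pair
layout: (200 − 40 − 16 − 8)/8 = 17 bytes per strand, divided by a 10-copy
physical redundancy; 1.5 GB therefore corresponds to ≈ 8.8×10⁸ physical
strands.

## Economics

Storage density: `D(f, c) = f + (1−f)·c` stored copies per unique strand
relative to single-copy encoding (an alternative `(1−f)·c` accounting is
exposed as `density_model="fullonly"`). Cost to find one file among n, in
full-file sequencing units: preview all n files and sequence the target
fully, `n·f + 1` vs `n` (an expected-position variant uses `(n+1)/2`).
A per-full-access overhead multiplier (default 1.0) is exposed for
calibrating to empirically uneven read distributions. The model excludes
read-depth oversampling and monetary conversion.

## Simulation scales and what passing tests show

The end-to-end test encodes a 64×64 synthetic progressive JPEG (three
partitions of one block each, 765 strands), simulates the three access
conditions, samples reads at 1% per-base error (10% of errors as single-base
indels) and mean depth 30, mixes 10,000 error-prone background strands into
the full-access read set, clusters, and decodes. The hybridization curve
acceptance runs 1,000 Monte-Carlo trials per Hamming distance; the library
intended for production-like use defaults to 10,000. These sizes were chosen
as the smallest at which the phenomena of interest (erasure-capacity
boundaries, tier separation, background rejection) are deterministic under
seeded randomness.

The synthetic data emulate: progressive-JPEG structure, tiered competitive
amplification, substitution/indel sequencing noise, and a mutagenized
off-target background. They do not emulate: synthesis errors or strand
dropout before amplification, polymerase chimera formation, sequencing
quality-score structure, real secondary structure of payloads, or
condition-dependent per-molecule stochasticity. Passing tests therefore
demonstrate internal consistency of the codec and the directional behavior
of the thermodynamic access model — not wet-lab performance.

## Known limitations

- The flat mismatch-stack penalty ignores mismatch identity and position;
  terminal mismatches are treated as A/T-like initiations.
- KCl and the extension-efficiency factor are phenomenological, calibrated
  to reproduce directional behavior, not fitted to measurements.
- Absolute ΔG values are not comparable to partition-function calculators;
  only threshold classifications and curve shapes are used.
- The readout threshold is a proxy for gel/NGS detectability; with
  fraction-based readout, extremely promiscuous conditions can dilute the
  preview tier below any fixed threshold.
- Scan-aware previewing applies to progressive JPEGs only; other byte
  streams encode and decode but partition arbitrarily.
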