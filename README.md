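# dnapreview

Thermodynamically tiered DNA data storage with a **File Preview** operation:
encode a progressive JPEG into a synthetic DNA strand library whose
partitions answer to *one* PCR primer pair at different stringencies, so that
a stringent reaction retrieves only a low-resolution preview of the image
while progressively promiscuous reactions retrieve the full file.

## Who this is for

Researchers working on PCR-based random access in DNA storage who want a
desk-scale, fully simulated version of the tiered-address workflow: primer
thermodynamics, address design, encoding, access simulation, noisy-read
decoding, and the storage/cost economics — without wet-lab data.

## The idea

File addresses in DNA storage are ~20-nt primer binding sites. Primer–site
hybridization is governed by two-state thermodynamics: the fraction of sites
bound is

    theta = c·K / (1 + c·K),   K = exp(−ΔG / RT),

with `c` the primer concentration and `ΔG` the duplex free energy at the
annealing temperature `T` (nearest-neighbor model with salt correction).
Mismatched sites have a less favorable `ΔG`, so annealing temperature and
primer concentration act as stringency dials: sites at Hamming distance (HD)
2, 4 or 6 from the primer can be switched on or off by the PCR condition.

A file is split into partitions of progressive-JPEG scans. Partition 1
(headers + DC scans — a recognizable grayscale preview) gets perfectly
matching (0 HD) binding sites; later partitions get 4 HD and 6 HD variant
sites of the *same* primer pair, stored at 100× and 1000× copy number to
compensate for their lower amplification efficiency. Each partition is
protected by two Reed–Solomon codes over GF(256): an outer `[255, 185, 71]`
code across the 255 strands of each 1665-byte block (any 70 lost strands are
recoverable erasures) and an inner `[14, 11, 4]` code within each strand over
its 2-byte index plus 9 data bytes. Bytes become DNA through a 256-word
codebook of GC-balanced 8-mers with pairwise edit distance ≥ 2.

Decoding starts from sequencing reads: reads are clustered onto reference
strands by seeded message passing (Levenshtein cap 8, cluster ratio 5, 20
seed copies per reference), surviving rows feed the inner then outer RS
decoders, and successfully decoded partitions are reassembled in order — a
lost suffix partition only lowers image resolution.

## Worked example

```
$ dnapreview encode --in img.jpg --cuts 1,5,4 --seed 1 --out lib
765 strands -> lib/library.fasta

$ dnapreview simulate-access --library lib/library.fasta \
      --manifest lib/manifest.json --temp 60 --out access.csv
accessed tiers [0] -> access.csv

$ dnapreview decode --library lib/library.fasta \
      --manifest lib/manifest.json --out out.jpg
decoded partitions [1, 2, 3] -> out.jpg

$ cmp img.jpg out.jpg && echo identical
identical
```

The 64×64 test image encodes into 765 strands of 200 nt (three partitions of
one 1665-byte block each, at HD tiers 0/4/6 with 1×/100×/1000× stored
copies). At a stringent 60 °C annealing temperature only tier 0 — the
preview partition — is amplified; at 46 °C tiers {0, 4} and at 41 °C all
three tiers come up, and decoding the clean library reproduces the input
byte-for-byte.

The economics of previewing a 15-file library with 5% preview strands:

```
$ dnapreview economics --f 0.05 --c 100
{
  "density_ratio": 95.05,
  "cost_preview": 1.75,
  "cost_normal": 15.0,
  "savings": 0.8833333333333333
}
```

Storing full-file strands at a 1:100 copy ratio costs 95× the physical space
of normal encoding (4.8× at a 1:5 ratio), while finding and fully sequencing
one of 15 files costs 1.75 full-file units instead of 15 — an ~88% saving
that grows as the preview fraction shrinks.

The hybridization model behind the address tiers:

```
$ dnapreview hyb-curve --hd-list 0,2,4,6,8,10 --trials 1000 --seed 1 --out curve.csv
```

writes the Monte-Carlo fraction of variant binding sites that still
hybridize at each Hamming distance (1.0 at HD 0, decaying to a plateau near
zero before HD 10).

## Layout

| module | role |
| --- | --- |
| `dnapreview.thermo` | nearest-neighbor duplex ΔG/Tm, primer design, mutate-to-HD walk, hybridization-vs-HD Monte Carlo |
| `dnapreview.address_design` | tiered binding-site generation, amplification tunability |
| `dnapreview.rs` | GF(256) Reed–Solomon with errors-and-erasures decoding |
| `dnapreview.preview_codec` | scan segmentation, partitioning, codebook, strand encode/decode, JPEG reassembly |
| `dnapreview.access_sim` | equilibrium binding, competitive PCR cycles, error-prone background, GB accounting |
| `dnapreview.read_cluster` | seeded Levenshtein message-passing clustering |
| `dnapreview.economics` | density ratio and cost-to-find models |
| `dnapreview.fixtures` | synthetic progressive JPEGs and noisy read sets |
| `dnapreview.cli` | `dnapreview` command-line interface |

See `docs/methods.md` for the model details, calibrated defaults, and known
limitations.
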