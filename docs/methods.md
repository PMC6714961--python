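# Methods

## Background and model

Repeat-Induced Point mutation (RIP) is a genome-defense pathway of
ascomycete fungi that acts during sexual reproduction: it recognizes
repeated or duplicated DNA and introduces C→T transition mutations into
both copies, preferentially at CpA dinucleotides (equivalently TpG on the
complementary strand). A region that has been through RIP is therefore
depleted of the pathway's substrate dinucleotides (CpA, TpG), enriched for
its product dinucleotide (TpA), and — after enough rounds — strongly
AT-rich.

`ripscan` quantifies this footprint with three classical dinucleotide
indices computed over a region:

- product index = TpA / ApT
- substrate index = (CpA + TpG) / (ApC + GpT)
- composite index = product − substrate

together with GC content (G + C)/(A + C + G + T). ApT and (ApC + GpT)
serve as composition-matched internal controls: under an i.i.d. base model
with any GC content the expectation of both ratios is 1, so deviations
signal dinucleotide-level structure rather than mere base composition.
All four quantities are strand-symmetric: each numerator/denominator term
maps onto a term of the same index under reverse complement (TpA and ApT
are self-complementary; CpA↔TpG; ApC↔GpT), a property the test suite
checks exhaustively.

A **RIP-positive window** requires all three indices to signal RIP
simultaneously:

- product ≥ `product_min` (default 1.1),
- substrate ≤ `substrate_max` (default 0.75),
- composite > `composite_min` (default 0).

The product and substrate bounds are inclusive; composite is strictly
greater-than. Any window with an undefined index (see below) is negative.
The default cut-offs are the stringent setting selected by the
random-sequence calibration below: at substrate ≤ 0.75 essentially no
long false-positive structure survives in random sequence, while known
RIP-affected fungal sequences remain clearly positive.

## Sliding-window scan

Windows of `window` bp (default 1,000) advance in `step` bp increments
(default 500) along each sequence independently; contigs are never
concatenated. A start `s` is emitted iff `s + step ≤ length`, so a
sequence of length L yields exactly `floor(L / step)` windows; the final
window may be truncated at the sequence end. Coordinates are 0-based and
end-exclusive throughout, including all output tables.

Counting uses prefix sums over base- and dinucleotide-indicator arrays, so
a scan is O(L) in sequence length, independent of window overlap; a 41 Mbp
assembly scans in a few seconds. A scalar per-region API
(`region_indices`) implements the same definitions independently, and a
test cross-checks the two routes window by window.

Ambiguity handling: residues outside {A, C, G, T} (after uppercasing and
U→T mapping) stay in the sequence so coordinates are preserved, but are
excluded from every count; an overlapping pair touching an ambiguous base
is tallied as skipped. Windows are never broken or shrunk by ambiguity. A
zero denominator (e.g. an AT-free, GC-free or all-N window) makes the
affected index undefined — `None` in the scalar API, NaN in tables — and
an undefined index is never RIP-positive. Indices are stored at full
floating precision; rounding to 2 decimals happens only in the reporting
layer (disable with `--full-precision`).

## Large RIP Affected Regions (LRARs)

An LRAR is a maximal run ("index chain") of consecutive RIP-positive
windows — consecutive meaning adjacent window ordinals; one negative
window breaks the chain — that satisfies both
`lrar_min_windows` ≥ 7 and span ≥ `lrar_min_span` = 4,000 bp (defaults).
The reported interval runs from the first window's start to the last
window's nominal end (start + window), clipped at the sequence end, so an
interior chain of n windows spans exactly (n − 1)·step + window bp; with
defaults, 7 windows ⇒ 4,000 bp. Per-LRAR statistics (mean product,
substrate, composite, GC) are unweighted means over member windows — all
windows are equal-sized except possibly the last, so bp-weighting would
change nothing material while complicating the definition.

The detector is linear-time run detection; the test suite proves it
equivalent to an exhaustive check of every candidate window range on
10,000 random positivity vectors.

## RIP profile

The genome profile counts windows: percent RIP = 100 · positive windows /
windows investigated (window-based, not bp-based). Genome GC is a single
pooled ratio over all unambiguous bases of all records, not a mean of
window GCs. LRAR-level averages (size, GC, indices) are unweighted means
of per-LRAR values. Per-sequence summaries report the same quantities per
contig/chromosome.

## False-positive calibration by simulation

To measure how often random sequence is mistaken for RIP, the simulator
draws i.i.d. sequences with P(G) = P(C) = gc/2, P(A) = P(T) = (1 − gc)/2
at nine GC levels (10%…90%), scans each replicate once with the default
window geometry, and applies a full 4 × 4 grid of cut-offs
(product ∈ {1.1, 1.15, 1.2, 1.25} × substrate ∈ {0.75, 0.8, 0.85, 0.9})
to the same window metrics — mirroring a design in which one simulated
data set is analysed at every stringency level. Per cell it reports the
number of flagged replicates (≥ 1 positive window), the mean percentage
of positive windows, and the total LRAR count.

The defaults follow the full study design (100 replicates of 1 Mbp per GC
level). The bundled tests and the acceptance script run the package's
desk-scale preset of 10 replicates per level (~11 s on one CPU), which is
ample for the qualitative conclusions: at substrate ≤ 0.75 **zero LRARs**
arise anywhere on the grid; flagged counts and affected percentages are
monotone non-decreasing in the substrate cut-off and non-increasing in the
product cut-off (deterministically, since each replicate is reused across
cells); and false positives concentrate at high GC under lax substrate
cut-offs. Note that with 2,000 windows per 1 Mbp replicate, the
*sequence-level* flag (≥ 1 positive window) saturates even at stringent
cut-offs — single-window false positives are common in random sequence;
it is long consecutive structure (LRARs) that stringent cut-offs eliminate
entirely. Conclusions about real genomes should therefore rest on LRARs
and on the affected *percentage*, not on the presence of isolated positive
windows.

The i.i.d. model is the simplest one consistent with "random sequence of a
given average GC content"; it deliberately lacks the dinucleotide
correlations, isochore structure and repeats of real genomes, so passing
calibration bounds the composition-driven false-positive rate only.

## Synthetic fixtures with planted RIP-like blocks

The fixture generator produces multi-contig genomes with known ground
truth. Background is i.i.d. at GC 0.5 (product ≈ substrate ≈ 1, so flanks
stay negative). Inside each planted block the RIP process itself is
emulated: in one pass, the C of every CpA and the G of every TpG are
replaced (by T and A respectively) independently with probability 0.9 —
a heavily mutated region, as seen in long-RIPped fungal repeats. This
drives the product index to ≈ 1.8 and the substrate index to ≈ 0.1 in
expectation while depressing GC, comfortably clearing the default
cut-offs. Because detection is window-quantized, recovered LRAR
boundaries are only guaranteed to within one window (±1,000 bp by
default) of the planted interval; tests and the acceptance script assert
exactly that resolution.

## Numerical and design choices

- Window-emission rule (`s + step ≤ length`) was chosen because it is the
  unique simple rule consistent with the published per-genome window total
  for a ~41.1 Mbp assembly at 500 bp steps (total = floor(size/step)).
- Boundary semantics: product/substrate cut-offs inclusive, composite
  strict; all user-tunable. On real data, boundary equality is
  measure-zero.
- RNG: `numpy.random.default_rng` seeded from a single user seed;
  identical (seed, spec) pairs reproduce sequences, sweeps and fixtures
  bit-exactly. Sub-seeds are derived with `SeedSequence`.
- Undefined-value policy trades a little API friction (`Optional[float]`)
  for never raising on degenerate windows.
- Equal-seeming alternatives not taken: merging LRARs across short gaps,
  bp-weighted LRAR means, HMM/wavelet segmentation, and sub-window
  boundary refinement are out of scope; the window grid is the resolution
  limit.

## Known limitations

- Index values for short regions (≪ window) are noisy; the fine-scale
  preset (100 bp windows, 50 bp steps) trades variance for resolution.
- LRAR boundaries inherit window quantization (± one window).
- The scanner measures dinucleotide skew only; it does not align repeats,
  infer the dominant mutation form, or reconstruct pre-RIP ancestors.
- Low-quality assemblies that collapse or omit AT-rich repeats will
  understate genome-wide RIP, whatever the scanner does.
- Validation against published per-assembly statistics requires the
  corresponding public genome assemblies; the test
  `tests/test_acceptance.py::test_neurospora_crassa_reference_genome_statistics`
  runs only when a local copy is placed under `data/` (see README) and
  fails otherwise.
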