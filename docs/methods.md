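# Methods

## Simulation model

`artfastq` simulates paired-end short-read sequencing of a known reference,
with no variants and no chimeras: reads are copied from the reference (mate 2
reverse-complemented), so the only differences between a read and its origin
interval are simulated base-call errors. This is deliberate — the tool's
purpose is to provide sequencing data whose truth set is the reference
itself, so that anything a downstream pipeline calls is attributable to the
pipeline, not the data.

The generator streams each FASTA record left to right under a sliding window
of `engine.nucleobaseBufferSize` bases (default 10 000). Within the window it
makes repeated passes over candidate template start positions, scanning left
to right. A candidate is accepted when (a) the pending template fits inside
the window and (b) every base either mate would cover is below its target
coverage. Accepted templates immediately increment the per-base achieved
counters for the two mate intervals only — the unsequenced template interior
does not count as coverage, matching the definition of coverage as the number
of reads a base appears in. A pass that accepts nothing is the saturation
signal, and the window slides right by half its size. Half-window overlap
guarantees that every base spends time in the left half of some window, i.e.
gets the chance to start left-end reads after earlier windows could only
cover it near their right edge. At the reference end the window shrinks with
the remaining tail and then reports itself exhausted.

### Template lengths and the pending-draw rule

Template lengths are `round(Normal(template.mean, template.sd))` (defaults
400 ± 25 bp), redrawn while shorter than twice the read length so the two
mates never overhang the template; redrawing rather than truncating keeps
the distribution's shape (at the defaults the floor of 200 bp sits 8 sd below
the mean, so rejection is vanishingly rare).

One length is drawn at a time and stays *pending* until some start position
can host it; only placement consumes the draw. The obvious alternative —
drawing a fresh length per candidate and discarding it on rejection — lets
the coverage constraint select on length: a longer template lands its second
mate further right, in territory the left-to-right fill has not yet
saturated, so long draws are accepted preferentially. Measured on a 100 kb
run (~11 000 pairs) this shifted the emitted mean template length several
base pairs above the configured value, many standard errors away. With the
pending rule every placed length is an unconditioned draw from the
configured normal, and the recovered moments agree with
(`template.mean`, `template.sd`) to within sampling error. The cost is that a
pending length may skip a hole it does not fit, leaving that hole for a later
window or unfilled; the effect on achieved coverage is negligible at the
defaults.

### Target coverage

Each base's target is sampled exactly once, in genomic order, when its record
is opened, and cached for the run:

- regional GC fraction `g` over a `coverage.gcRegionSize`-base region
  (default 150 bp) centred on the base and truncated at the record ends,
  counting G+C over A+C+G+T (N excluded from both counts; an all-N region has
  undefined GC and is treated as sitting at the profile peak);
- mean `m(g) = peak · exp(−(g − g₀)²/(2w²))` with defaults
  `coverage.peakMean = 30`, `coverage.gcAtPeak = 0.45`,
  `coverage.decayWidth = 0.18`; with `coverage.gcBiasEnabled = false` the
  mean is flat at `peak`;
- one draw from `Normal(m, coverage.sdMultiple · m)` (default multiple 0.1),
  rounded to the nearest integer and clamped at zero.

The default bell (peak 30× at GC 0.45, width 0.18) reproduces the familiar
capture-experiment shape — depth greatest at intermediate GC and decaying
toward both extremes — and is fully user-assignable rather than learned from
resequencing data, so arbitrary bias profiles can be dialled in.

Note a structural consequence of the placement rule: because a mate is
admissible only when *all* ~`reads.length` bases it covers are under target,
achieved coverage tracks the running minimum of targets over roughly a read
length. With `sdMultiple = 0.1` this sits a few reads below the local mean
target (≈22× achieved for a 30× peak at the defaults); with `sdMultiple = 0`
interior bases saturate to ~95 % of the uniform cap. The cap itself is never
exceeded — that is an invariant, audited in tests by a brute-force recount
from the emitted index.

### Qualities and errors

Uniform mode assigns every base Phred 40 (`I`). FASTQ mode serves quality
strings from user-supplied files in record order, recycling from the start
when the pool runs out — recycling (rather than failing mid-genome) makes
the pool size independent of the genome size. With two files, mate 1 and
mate 2 draw from separate pools; with one file both mates share a single
pool and cursor. Length mismatches are fixed by duplicating or removing
*leading* scores only, preserving the end-of-read degradation pattern that
makes recycled qualities worth using.

Error simulation treats the quality score as the sole parameter: base `i` is
substituted with probability `10^(−Q_i/10)`, the wrong call drawn uniformly
from the three alternatives (no transition/transversion or motif bias —
nothing in the quality string justifies one). Substitutions only; no
simulated indels. N bases are never mutated, always emit quality 2 (`#`),
and with `reads.filterN` enabled any pair whose mates contain an N is
dropped *without* consuming target coverage (its bases were never emitted).

## Outputs

`<prefix>.1.fastq` / `<prefix>.2.fastq` (4-line Sanger FASTQ, record *k* of
file 2 mated to record *k* of file 1, headers `@<record>_<pairId>/1|2`),
`<prefix>.index.tsv` (refName, readId, mate, start, end; 1-based closed
coordinates, declared in the header comment), `<prefix>.log`
(configuration echo including the seed, total reads/base calls, simulated
errors and their percentage to 2 d.p., and min/max/mean achieved coverage
per `stats.regionSize` = 10 000-base block and overall) and
`<prefix>.stats.json` (the same, machine-readable). Coverage means count
A/C/G/T reference positions only; N positions are excluded.

## Determinism

All randomness flows from `engine.seed` through one `numpy` PCG64 stream per
FASTA record (spawned via `SeedSequence`), so runs are reproducible byte for
byte and records could be simulated in separate processes and merged without
changing any record's output.

## Synthetic references

`artfastq make-ref` (and `artfastq.fixtures`) builds references as
concatenated blocks with exact GC base counts shuffled uniformly, optionally
with embedded N runs. Realised block GC therefore matches the request to
rounding error. These fixtures emulate composition, not genome structure:
there are no repeats, no soft-masked regions, and no long-range correlation,
so tests passing on them demonstrate the generator's own contracts
(fidelity, caps, calibration, determinism) — not alignability or
variant-calling difficulty on real genomes, which depend on repeat structure
the fixtures do not model.

## Problem sizes and test design

The test suite and the reproduction script run on synthetic references of
5–100 kb, sizes at which every headline property is measurable with
comfortable statistical margins: ground-truth fidelity and template-moment
recovery on a 100 kb run (~11 000 pairs, >2 × 10⁶ emitted bases), coverage-cap
audits on five 10 kb runs, error calibration at ≥10⁵ base calls per quality
score (binomial 4-SE bands), and GC-bias recovery on a 3 × 10 kb block
fixture. The bias-off indistinguishability check subsamples per-base coverage
at a 500 bp lag — beyond the longest plausible template — because adjacent
bases share reads and naive per-base tests would be invalid under that
autocorrelation.

## Known limitations

- Substitution errors only; no indel, PCR-duplicate, optical-duplicate or
  chimera simulation; no variant spiking.
- Single-end GC model (regional GC around each base), not a fragment-level
  two-end model; the bias is parametric, not learned from data.
- Sanger (+33) quality encoding only.
- FR (forward/reverse) libraries only; mate-pair (RF) layouts are not
  modelled.
- Achieved coverage sits below the configured peak mean in proportion to
  `sdMultiple` (see the running-minimum effect above); set `sdMultiple = 0`
  if exact uniform depth near the cap is wanted.
- Uncompressed FASTA input only; each record must fit in memory (the sliding
  window bounds the engine's working set, not the parser's).
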