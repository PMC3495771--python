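# artfastq

Artificial paired-end FASTQ reads simulated directly from a reference genome.

NGS analysis pipelines — aligner, realignment, duplicate marking,
recalibration, variant caller — vary widely in fidelity, and evaluating one
requires data whose truth is known. `artfastq` takes a reference genome
(FASTA) and emits paired-end FASTQ files whose reads are copied verbatim from
that reference, together with a ground-truth index recording each read's true
origin interval. Every variant a pipeline then calls on these reads is by
construction a false positive, and every misplaced alignment is detectable
against the index, so the output is a gold standard for benchmarking
read alignment and variant calling. The simulation is configurable in the
ways that matter for such benchmarks: template/read lengths, GC-dependent
coverage, real or idealised base qualities, and quality-driven sequencing
errors.

## Model

- **Read placement.** A window of `nucleobaseBufferSize` bases slides
  rightward over the reference. Within the window, repeated left-to-right
  passes propose paired-end templates; a template is accepted only if every
  base covered by either mate is still below its *target coverage* — the cap
  on how many reads that base may appear in. When a pass accepts nothing, the
  window slides right by half its size, so memory stays bounded and every
  base eventually gets left-end read opportunities.
- **Template lengths** are drawn from `Normal(μ_t, σ_t)` (defaults 400, 25 bp);
  mate 1 is the leftmost `L` bases of the template (default `L` = 100), mate 2
  the reverse complement of the rightmost `L` bases (Illumina FR orientation).
- **GC-biased coverage.** For each base, the GC fraction *g* of the
  `gcRegionSize`-base region centred on it is computed, and its target
  coverage is drawn from `Normal(m(g), s·m(g))`, rounded and clamped at 0,
  where the mean is a Gaussian (bell-shaped) function of GC:

      m(g) = peak · exp( −(g − g₀)² / (2w²) )

  with peak height `peak` (default 30), peak position `g₀` (0.45) and width
  `w` (0.18). A switch disables the bias, making `m(g) = peak` everywhere.
- **Qualities and errors.** Phred scores are Sanger-encoded
  (`char = ASCII(Q+33)`). Default is uniform Q40 (`I`); alternatively quality
  strings are recycled from real FASTQ files, length-adjusted by editing only
  the *start* of the string so end-of-read degradation is preserved. Error
  simulation substitutes each base independently with its Phred error
  probability `P = 10^(−Q/10)`; N bases are never mutated, always carry Q2,
  and read pairs containing N can optionally be filtered out.

## Worked example

```bash
artfastq make-ref --out ref.fa --length 20000 --gc 0.2 --gc 0.45 --gc 0.8 --seed 7
artfastq generate --fasta ref.fa --out sim --seed 1 --buffer-size 2000
```

```
reads: 2260
base calls: 226000
simulated errors: 0
mean coverage (A/C/G/T bases): 11.30
outputs: sim.1.fastq, sim.2.fastq, sim.index.tsv, sim.log, sim.stats.json
```

The fixture is three 6.7 kb blocks at GC 0.2 / 0.45 / 0.8. Mean achieved
coverage is 11.3× rather than the 30× peak because only the middle block sits
at the peak of the GC bell; the AT- and GC-rich flanks are sampled at the
bell's tails (the per-block means are in `sim.log` under
`[regional coverage]`). Errors are off by default, so every emitted base
matches the reference, e.g. the first index line

```
refName	readId	mate	start	end
synthetic	synthetic_1	1	1	100
synthetic	synthetic_1	2	291	390
```

records that pair 1 came from a 390 bp template: mate 1 is reference bases
1–100 and mate 2 the reverse complement of bases 291–390 (1-based, closed).
Re-running with the same seed reproduces all five files byte for byte.

Library use mirrors the CLI:

```python
from artfastq import RunConfiguration, run
stats = run(RunConfiguration(fasta="ref.fa", out_prefix="sim", seed=1,
                             buffer_size=2000))
print(stats.total_reads, stats.overall_mean_coverage)
```

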