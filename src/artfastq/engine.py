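"""Paired-end read generation under per-base target-coverage caps.

The engine walks a sliding window over each reference record.  Within the
current window it makes repeated left-to-right passes over candidate template
start positions; at each candidate it draws a template length from a normal
distribution, and accepts the placement only if every base that either mate
would cover is still below its sampled target coverage.  When a full pass
accepts no novel pair the window slides right by half its size, so bases that
could previously only be reached as right-end (mate 2) positions get their
chance to start left-end (mate 1) reads.  Generation for a record ends when
the window has passed the reference end.

Accepted templates are emitted in Illumina FR orientation: mate 1 is the
leftmost ``read_length`` bases of the template read forward, mate 2 the
reverse complement of the rightmost ``read_length`` bases.  With error
simulation off, every emitted base therefore matches the reference at the
coordinates recorded in the ground-truth index — the property that makes the
output usable as a gold standard for aligner and variant-caller benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .coverage import CoverageParameters, sample_targets
from .quality import QualitySource, apply_errors, filter_n_reads, mask_n_quality
from .reference import ReferenceSequence, open_window, slide_window

__all__ = [
    "GenerationParameters",
    "CoverageLedger",
    "ReadPair",
    "sample_template_length",
    "reverse_complement",
    "can_place_pair",
    "pass_over_window",
    "generate_pairs",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenerationParameters:
    """Knobs of the placement engine.

    ``template_mean``/``template_sd`` parameterise the normal template-length
    distribution (the gap between mates is template length minus twice the
    read length).  ``buffer_size`` is the sliding-window capacity
    (``nucleobaseBufferSize``); it must comfortably exceed the longest
    plausible template so a template proposed in a window always fits in it.
    """

    read_length: int = 100
    template_mean: float = 400.0
    template_sd: float = 25.0
    buffer_size: int = 10000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError(f"reads.length must be >= 1, got {self.read_length}")
        if self.template_sd < 0:
            raise ValueError(f"template.sd must be >= 0, got {self.template_sd}")
        if self.template_mean < 2 * self.read_length:
            raise ValueError(
                f"template.mean ({self.template_mean}) must be >= twice "
                f"reads.length ({self.read_length}): mates may not overhang the template"
            )
        if self.buffer_size < self.template_mean + 6 * self.template_sd:
            raise ValueError(
                f"engine.nucleobaseBufferSize ({self.buffer_size}) must be >= "
                f"template.mean + 6*template.sd "
                f"({self.template_mean + 6 * self.template_sd:.0f})"
            )


class CoverageLedger:
    """Per-base achieved and target coverage for one reference record.

    Targets are sampled once per base (in genomic order) and cached; achieved
    counters only ever increase and, by construction of the placement check,
    never exceed the target.
    """

    def __init__(self, targets: np.ndarray):
        self.targets = targets
        self.achieved = np.zeros(targets.size, dtype=np.int64)
        # remaining capacity, kept in sync for fast placement checks
        self._remaining = targets.astype(np.int64).copy()

    @property
    def length(self) -> int:
        return self.targets.size

    def target(self, pos: int) -> int:
        """Target coverage of the 1-based position ``pos``."""
        return int(self.targets[pos - 1])

    def coverage(self, pos: int) -> int:
        """Achieved coverage of the 1-based position ``pos``."""
        return int(self.achieved[pos - 1])

    def can_cover(self, start: int, end: int) -> bool:
        """True iff every base in the 1-based closed interval has spare capacity."""
        seg = self._remaining[start - 1 : end]
        return bool(seg.min(initial=1) > 0)

    def add_read(self, start: int, end: int) -> None:
        self.achieved[start - 1 : end] += 1
        self._remaining[start - 1 : end] -= 1
        assert self._remaining[start - 1 : end].min(initial=0) >= 0


@dataclass(frozen=True)
class ReadPair:
    """One accepted template and its two oriented reads.

    Coordinates are 1-based closed reference intervals.  ``mate1`` runs
    forward from ``template_start``; ``mate2`` is the reverse complement of
    the template's last ``read_length`` bases, so ``mate2_start`` /
    ``mate2_end`` describe the forward-strand interval it was copied from.
    """

    pair_id: int
    ref_name: str
    template_start: int
    template_end: int
    read_length: int
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str
    errors_mate1: int = 0
    errors_mate2: int = 0

    @property
    def template_length(self) -> int:
        return self.template_end - self.template_start + 1

    @property
    def mate1_start(self) -> int:
        return self.template_start

    @property
    def mate1_end(self) -> int:
        return self.template_start + self.read_length - 1

    @property
    def mate2_start(self) -> int:
        return self.template_end - self.read_length + 1

    @property
    def mate2_end(self) -> int:
        return self.template_end

    @property
    def read_id(self) -> str:
        return f"{self.ref_name}_{self.pair_id}"


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def sample_template_length(
    params: GenerationParameters, rng: np.random.Generator
) -> int:
    """Draw one template length: rounded normal, redrawn while shorter than
    two read lengths (the mates must fit in the template without overhanging)."""
    floor = 2 * params.read_length
    while True:
        draw = int(round(rng.normal(params.template_mean, params.template_sd)))
        if draw >= floor:
            return draw


def can_place_pair(
    ledger: CoverageLedger, template_start: int, template_len: int, read_length: int
) -> bool:
    """True iff both mate intervals fit the reference and every base they cover
    is below its target.  Only the two sequenced mates consume coverage; the
    unsequenced template interior does not."""
    template_end = template_start + template_len - 1
    if template_start < 1 or template_end > ledger.length:
        return False
    return ledger.can_cover(
        template_start, template_start + read_length - 1
    ) and ledger.can_cover(template_end - read_length + 1, template_end)


def _build_pair(
    ref: ReferenceSequence,
    pair_id: int,
    template_start: int,
    template_end: int,
    params: GenerationParameters,
    quality1: QualitySource,
    quality2: QualitySource,
    errors_enabled: bool,
    filter_n: bool,
    ledger: CoverageLedger,
    err_rng: np.random.Generator,
) -> Optional[ReadPair]:
    rl = params.read_length
    m1 = ref.fetch(template_start, template_start + rl - 1)
    m2 = reverse_complement(ref.fetch(template_end - rl + 1, template_end))
    if not filter_n_reads(m1, m2, filter_n):
        return None  # dropped pairs never consume target coverage
    q1 = quality1.next_quality_string(rl)
    q2 = quality2.next_quality_string(rl)
    e1 = e2 = 0
    if errors_enabled:
        m1, q1, e1, _ = apply_errors(m1, q1, err_rng)
        m2, q2, e2, _ = apply_errors(m2, q2, err_rng)
    else:
        q1 = mask_n_quality(m1, q1)
        q2 = mask_n_quality(m2, q2)
    ledger.add_read(template_start, template_start + rl - 1)
    ledger.add_read(template_end - rl + 1, template_end)
    return ReadPair(
        pair_id=pair_id,
        ref_name=ref.name,
        template_start=template_start,
        template_end=template_end,
        read_length=rl,
        mate1_seq=m1,
        mate1_qual=q1,
        mate2_seq=m2,
        mate2_qual=q2,
        errors_mate1=e1,
        errors_mate2=e2,
    )


def pass_over_window(
    window,
    ref: ReferenceSequence,
    ledger: CoverageLedger,
    params: GenerationParameters,
    quality1: QualitySource,
    quality2: QualitySource,
    errors_enabled: bool,
    filter_n: bool,
    rng: np.random.Generator,
    err_rng: np.random.Generator,
    next_pair_id: int,
    out: list,
    pending_length: Optional[int] = None,
) -> tuple[int, int, int]:
    """One left-to-right pass over the window's candidate template starts.

    A template length is drawn once and stays *pending* until a start
    position can host it; only a placed length consumes the draw, whereupon
    a fresh one is drawn.  Discarding draws at infeasible placements instead
    would let the coverage constraint select on length (long templates reach
    into fresher territory) and visibly skew the emitted template-length
    distribution away from the configured normal.

    Accepted pairs are appended to ``out``.  Returns ``(accepted count,
    next pair id, pending length)``; zero accepted is the caller's signal
    to slide.
    """
    if pending_length is None:
        pending_length = sample_template_length(params, rng)
    window_end = window.end
    accepted = 0
    for start in range(window.offset, window_end + 1):
        end = start + pending_length - 1
        if end > window_end:
            continue  # pending template does not fit here; retry after slide
        if not can_place_pair(ledger, start, pending_length, params.read_length):
            continue
        pair = _build_pair(
            ref, next_pair_id, start, end, params, quality1, quality2,
            errors_enabled, filter_n, ledger, err_rng,
        )
        pending_length = sample_template_length(params, rng)
        if pair is None:
            continue  # N-filtered: not novel, no coverage consumed
        out.append(pair)
        next_pair_id += 1
        accepted += 1
    return accepted, next_pair_id, pending_length


def generate_pairs(
    ref: ReferenceSequence,
    params: GenerationParameters,
    coverage_params: CoverageParameters,
    quality1: QualitySource,
    quality2: QualitySource,
    rng: np.random.Generator,
    errors_enabled: bool = False,
    filter_n: bool = False,
    ledger_out: Optional[list] = None,
    first_pair_id: int = 1,
) -> Iterator[ReadPair]:
    """Generate all read pairs for one reference record.

    Deterministic given the generator states.  Per-base targets are sampled
    up front (once per base, in genomic order); the window then slides over
    the record, each position saturating to its target before the window
    moves past it.  A record shorter than one template yields no reads.

    If ``ledger_out`` is a list, the record's :class:`CoverageLedger` is
    appended to it so callers can compute summary statistics.
    """
    targets = sample_targets(ref.seq, coverage_params, rng)
    ledger = CoverageLedger(targets)
    if ledger_out is not None:
        ledger_out.append(ledger)
    if ref.length < 2 * params.read_length:
        return
    window = open_window(ref, params.buffer_size)
    pair_id = first_pair_id
    pending: Optional[int] = None
    while not window.exhausted:
        while True:
            batch: list[ReadPair] = []
            accepted, pair_id, pending = pass_over_window(
                window, ref, ledger, params, quality1, quality2,
                errors_enabled, filter_n, rng, rng, pair_id, batch,
                pending_length=pending,
            )
            yield from batch
            if accepted == 0:
                break
        window = slide_window(window, ref)
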