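"""Reference-genome access: validated FASTA records and a rightward sliding window.

Read generation never needs random access to the genome: the engine works on a
bounded window that only moves right, so a multi-gigabase reference can be
processed with memory proportional to the window size, not the genome.  The
window abstraction here is what enforces that contract; :class:`ReferenceSequence`
keeps the record text it was built from but all engine code goes through
:class:`ReferenceWindow` slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "ReferenceSequence",
    "ReferenceWindow",
    "read_fasta",
    "open_window",
    "slide_window",
]

VALID_BASES = frozenset("ACGTN")


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


@dataclass(frozen=True)
class ReferenceSequence:
    """One FASTA record: identifier plus validated, uppercased sequence.

    The alphabet is restricted to ``A/C/G/T/N``; soft-masked (lowercase) bases
    are uppercased and treated as ordinary bases, anything else is rejected at
    parse time.
    """

    name: str
    seq: str
    source: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Return bases in the 1-based closed interval [start, end]."""
        if start < 1 or end > self.length or start > end:
            raise IndexError(
                f"interval [{start}, {end}] outside reference {self.name!r} "
                f"of length {self.length}"
            )
        return self.seq[start - 1 : end]


@dataclass
class ReferenceWindow:
    """A bounded view of the reference that only ever moves right.

    ``offset`` is the 1-based genomic position of the first buffered base.
    Once the window has served the reference tail, sliding it again flips
    ``exhausted`` instead of raising.
    """

    bases: str
    offset: int
    buffer_size: int
    exhausted: bool = False
    peak_resident: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.peak_resident = max(self.peak_resident, len(self.bases))

    @property
    def end(self) -> int:
        """1-based genomic position of the last buffered base."""
        return self.offset + len(self.bases) - 1


def read_fasta(path) -> list[ReferenceSequence]:
    """Parse a (multi-record) FASTA file into validated records, in file order.

    Raises
    ------
    FastaError
        On an empty file, a record with no sequence, or a character outside
        ``A/C/G/T/N`` (reported with record name and 1-based position).
    """
    records: list[ReferenceSequence] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"record {rec.id!r} in {path} has an empty sequence")
        for pos, base in enumerate(seq, start=1):
            if base not in VALID_BASES:
                raise FastaError(
                    f"illegal character {base!r} at position {pos} of record "
                    f"{rec.id!r} in {path} (allowed: A, C, G, T, N)"
                )
        records.append(ReferenceSequence(name=rec.id, seq=seq, source=f"{path}#{idx}"))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def open_window(ref: ReferenceSequence, buffer_size: int) -> ReferenceWindow:
    """Open a window on the first ``buffer_size`` bases of ``ref``."""
    if buffer_size < 1:
        raise ValueError(f"buffer_size must be positive, got {buffer_size}")
    end = min(buffer_size, ref.length)
    return ReferenceWindow(bases=ref.fetch(1, end), offset=1, buffer_size=buffer_size)


def slide_window(window: ReferenceWindow, ref: ReferenceSequence) -> ReferenceWindow:
    """Slide the window right by half its capacity.

    The half-buffer slide means every reference base spends time in the left
    half of some window, which is what lets left-end reads be generated for
    bases that earlier windows could only reach as right-end mates.  At the
    reference end the window shrinks to the remaining tail; once the tail has
    been served, the next slide returns an exhausted sentinel.
    """
    if window.exhausted:
        return window
    slide = max(1, window.buffer_size // 2)
    new_offset = window.offset + slide
    if new_offset > ref.length:
        return ReferenceWindow(
            bases="",
            offset=ref.length + 1,
            buffer_size=window.buffer_size,
            exhausted=True,
            peak_resident=window.peak_resident,
        )
    new_end = min(new_offset + window.buffer_size - 1, ref.length)
    return ReferenceWindow(
        bases=ref.fetch(new_offset, new_end),
        offset=new_offset,
        buffer_size=window.buffer_size,
        peak_resident=window.peak_resident,
    )
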