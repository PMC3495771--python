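"""Phred quality strings and quality-driven sequencing-error simulation.

Qualities come from one of two sources: a uniform high score (Q40, the Sanger
character ``I``) for idealised reads, or real quality strings recycled from
user-supplied FASTQ files so simulated reads carry empirically realistic
quality profiles.  When recycled strings do not match the configured read
length they are adjusted at the *start* of the string only — duplicating or
dropping leading scores — so the characteristic deterioration of quality
toward the end of a read survives the adjustment.

Error simulation uses the quality score as its sole parameter: each base is
substituted independently with the Phred error probability P = 10^(-Q/10).
Unknown reference bases (N) are never mutated and always carry quality 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "SANGER_OFFSET",
    "decode_phred",
    "encode_phred",
    "error_probability",
    "adjust_quality_length",
    "QualitySource",
    "apply_errors",
    "mask_n_quality",
    "pair_contains_n",
]

SANGER_OFFSET = 33
MAX_PHRED = 93
N_BASE_QUALITY = 2  # Ns are always reported at this very low Phred score

_N_QUAL_CHAR = chr(N_BASE_QUALITY + SANGER_OFFSET)
_BASE_ALTERNATIVES = {b: tuple(a for a in "ACGT" if a != b) for b in "ACGT"}


def decode_phred(c: str) -> int:
    """Decode one Sanger-encoded quality character to its Phred score."""
    if len(c) != 1:
        raise ValueError(f"expected a single character, got {c!r}")
    code = ord(c)
    if not SANGER_OFFSET <= code <= SANGER_OFFSET + MAX_PHRED:
        raise ValueError(
            f"character {c!r} (ASCII {code}) outside the Sanger quality range "
            f"[{SANGER_OFFSET}, {SANGER_OFFSET + MAX_PHRED}]"
        )
    return code - SANGER_OFFSET


def encode_phred(q: int) -> str:
    """Encode a Phred score as its Sanger quality character (ASCII q + 33)."""
    if not 0 <= q <= MAX_PHRED:
        raise ValueError(f"Phred score must be in [0, {MAX_PHRED}], got {q}")
    return chr(q + SANGER_OFFSET)


def error_probability(q: int) -> float:
    """Estimated probability of a base-call error at Phred score ``q``: 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def adjust_quality_length(qual: str, target_len: int) -> str:
    """Fit a quality string to ``target_len`` by editing only its start.

    Shortening drops leading scores; lengthening duplicates the first score.
    The tail — where real reads degrade — is preserved verbatim.
    """
    if target_len < 1:
        raise ValueError(f"target length must be >= 1, got {target_len}")
    if not qual:
        raise ValueError("quality string must be non-empty")
    if len(qual) > target_len:
        return qual[len(qual) - target_len :]
    return qual[0] * (target_len - len(qual)) + qual


@dataclass
class QualitySource:
    """Supplies one quality string per read.

    ``uniform`` mode emits a homogeneous string at ``uniform_q``.  ``fromFastq``
    mode serves quality strings from a real FASTQ file in record order,
    recycling from the first record when the pool is exhausted, each string
    length-adjusted via :func:`adjust_quality_length`.
    """

    mode: str = "uniform"
    uniform_q: int = 40
    pool: list[str] = field(default_factory=list)
    cursor: int = 0

    @classmethod
    def uniform(cls, q: int = 40) -> "QualitySource":
        encode_phred(q)  # range check
        return cls(mode="uniform", uniform_q=q)

    @classmethod
    def from_fastq(cls, path) -> "QualitySource":
        pool: list[str] = []
        for rec in SeqIO.parse(str(path), "fastq"):
            scores = rec.letter_annotations["phred_quality"]
            pool.append("".join(encode_phred(q) for q in scores))
        if not pool:
            raise ValueError(f"quality FASTQ {path} contains no records")
        return cls(mode="fromFastq", pool=pool)

    def next_quality_string(self, read_len: int) -> str:
        if read_len < 1:
            raise ValueError(f"read length must be >= 1, got {read_len}")
        if self.mode == "uniform":
            return encode_phred(self.uniform_q) * read_len
        qual = self.pool[self.cursor]
        self.cursor = (self.cursor + 1) % len(self.pool)
        return adjust_quality_length(qual, read_len)


def mask_n_quality(seq: str, qual: str) -> str:
    """Overwrite the quality of every N base with the Sanger character for Q2."""
    if len(seq) != len(qual):
        raise ValueError(f"sequence length {len(seq)} != quality length {len(qual)}")
    if "N" not in seq:
        return qual
    return "".join(_N_QUAL_CHAR if b == "N" else q for b, q in zip(seq, qual))


def apply_errors(
    seq: str, qual: str, rng: np.random.Generator
) -> tuple[str, str, int, np.ndarray]:
    """Simulate base-call errors on one read.

    Each non-N base is independently substituted with probability
    ``error_probability(decode_phred(qual[i]))``; the wrong call is uniform
    over the three alternative bases.  N bases are never mutated and their
    quality is overwritten to Q2.

    Returns ``(mutated sequence, adjusted quality, error count, per-base flags)``.
    """
    if len(seq) != len(qual):
        raise ValueError(f"sequence length {len(seq)} != quality length {len(qual)}")
    codes = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
    if codes.size and (codes.min() < SANGER_OFFSET or codes.max() > SANGER_OFFSET + MAX_PHRED):
        bad = chr(codes[(codes < SANGER_OFFSET) | (codes > SANGER_OFFSET + MAX_PHRED)][0])
        raise ValueError(f"quality character {bad!r} outside the Sanger range")
    p_err = 10.0 ** (-(codes - SANGER_OFFSET) / 10.0)
    is_n = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("N")
    flags = (rng.random(len(seq)) < p_err) & ~is_n
    n_err = int(flags.sum())
    if n_err:
        bases = list(seq)
        choices = rng.integers(0, 3, size=n_err)
        for pos, alt in zip(np.flatnonzero(flags), choices):
            bases[pos] = _BASE_ALTERNATIVES[bases[pos]][alt]
        seq = "".join(bases)
    return seq, mask_n_quality(seq, qual), n_err, flags


def pair_contains_n(mate1_seq: str, mate2_seq: str) -> bool:
    return "N" in mate1_seq or "N" in mate2_seq


def filter_n_reads(mate1_seq: str, mate2_seq: str, filter_enabled: bool) -> bool:
    """Keep/drop decision for a read pair: drop when filtering is on and either
    mate contains at least one N."""
    if not filter_enabled:
        return True
    return not pair_contains_n(mate1_seq, mate2_seq)


__all__.append("filter_n_reads")
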