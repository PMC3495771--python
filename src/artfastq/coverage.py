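"""GC-biased target-coverage model.

Sequencing depth on Illumina instruments is not uniform along the genome: it
depends strongly on local GC content, typically peaking at intermediate GC and
falling off toward AT- or GC-rich extremes.  This module models that bias
parametrically.  For each reference nucleobase the GC fraction of a small
region centred on it is computed, the *mean* target coverage is a Gaussian
(bell-shaped) function of that GC fraction, and the base's target coverage —
the cap on how many reads the base may appear in — is a single draw from a
normal distribution around that mean.  Switching the bias off makes the mean
uniform, so coverage depends on GC only through sampling noise.

The bias is deliberately parametric rather than learned from resequencing
data: the user sets the peak height, peak position, and decay width directly,
so arbitrary profiles can be simulated without a training BAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoverageParameters",
    "gc_content",
    "mean_coverage",
    "sample_target_coverage",
    "gc_profile",
    "sample_targets",
]

_GC = frozenset("GC")
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CoverageParameters:
    """Parameters of the Gaussian GC-bias profile.

    Attributes
    ----------
    peak_mean:
        Mean target coverage at the peak of the bell (reads per base).
    gc_at_peak:
        GC fraction in [0, 1] at which mean coverage peaks.
    decay_width:
        Width of the bell on the GC-fraction axis; smaller values make mean
        coverage fall off faster away from ``gc_at_peak``.
    sd_multiple:
        Standard deviation of the per-base target draw, as a multiple of the
        (GC-dependent) mean.
    gc_region_size:
        Number of bases, centred on the nucleobase, over which GC content is
        computed.
    gc_bias_enabled:
        When False the mean is ``peak_mean`` for every base regardless of GC.
    """

    peak_mean: float = 30.0
    gc_at_peak: float = 0.45
    decay_width: float = 0.18
    sd_multiple: float = 0.1
    gc_region_size: int = 150
    gc_bias_enabled: bool = True

    def __post_init__(self) -> None:
        if self.peak_mean <= 0:
            raise ValueError(f"coverage.peakMean must be > 0, got {self.peak_mean}")
        if not 0.0 <= self.gc_at_peak <= 1.0:
            raise ValueError(f"coverage.gcAtPeak must be in [0, 1], got {self.gc_at_peak}")
        if self.decay_width <= 0:
            raise ValueError(f"coverage.decayWidth must be > 0, got {self.decay_width}")
        if self.sd_multiple < 0:
            raise ValueError(f"coverage.sdMultiple must be >= 0, got {self.sd_multiple}")
        if self.gc_region_size < 1:
            raise ValueError(f"coverage.gcRegionSize must be >= 1, got {self.gc_region_size}")


def gc_content(region: str) -> float:
    """GC fraction of ``region``: (#G + #C) / (#A + #C + #G + #T).

    N bases are excluded from numerator and denominator.  An all-N region has
    no defined GC content and returns NaN; callers treat that sentinel as GC
    equal to the profile peak, so fully ambiguous regions get the peak mean
    rather than an arbitrary extreme.
    """
    if not region:
        raise ValueError("cannot compute GC content of an empty region")
    region = region.upper()
    gc = sum(1 for b in region if b in _GC)
    acgt = sum(1 for b in region if b in _ACGT)
    if acgt == 0:
        return math.nan
    return gc / acgt


def mean_coverage(gc: float, params: CoverageParameters) -> float:
    """Mean target coverage for a region of GC fraction ``gc``.

    A Gaussian of GC: ``peak_mean * exp(-(gc - gc_at_peak)^2 / (2 * decay_width^2))``.
    With the bias disabled, ``peak_mean`` regardless of GC.  A NaN ``gc``
    (all-N region) is treated as ``gc_at_peak``.
    """
    if not params.gc_bias_enabled:
        return params.peak_mean
    if math.isnan(gc):
        return params.peak_mean
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction must be in [0, 1], got {gc}")
    z = (gc - params.gc_at_peak) / params.decay_width
    return params.peak_mean * math.exp(-0.5 * z * z)


def sample_target_coverage(
    gc: float, params: CoverageParameters, rng: np.random.Generator
) -> int:
    """Draw one nucleobase's target coverage.

    Normal around :func:`mean_coverage` with sd ``sd_multiple * mean``,
    rounded to the nearest integer and clamped at zero (targets count reads).
    """
    mean = mean_coverage(gc, params)
    draw = rng.normal(mean, params.sd_multiple * mean)
    return max(0, int(round(draw)))


def gc_profile(seq: str, region_size: int) -> np.ndarray:
    """Per-base GC fraction of the ``region_size``-base region centred on each base.

    Regions are truncated at the sequence ends.  Positions whose region is
    entirely N get NaN.  Vectorised with prefix sums so whole records are
    profiled in O(n).
    """
    if region_size < 1:
        raise ValueError(f"region_size must be >= 1, got {region_size}")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = arr.size
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = arr != ord("N")
    gc_cum = np.concatenate(([0], np.cumsum(is_gc)))
    acgt_cum = np.concatenate(([0], np.cumsum(is_acgt)))
    idx = np.arange(n)
    # closed region [i - (rs-1)//2, i + rs//2], clipped to the sequence
    lo = np.maximum(idx - (region_size - 1) // 2, 0)
    hi = np.minimum(idx + region_size // 2, n - 1)
    gc = gc_cum[hi + 1] - gc_cum[lo]
    acgt = acgt_cum[hi + 1] - acgt_cum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(acgt > 0, gc / np.maximum(acgt, 1), np.nan)
    return out


def sample_targets(
    seq: str, params: CoverageParameters, rng: np.random.Generator
) -> np.ndarray:
    """Sample every base's target coverage for a whole record, in genomic order.

    Each base is sampled exactly once; the engine caches the result for the
    run.  Returns an int64 array of length ``len(seq)``.
    """
    gc = gc_profile(seq, params.gc_region_size)
    if params.gc_bias_enabled:
        z = (np.nan_to_num(gc, nan=params.gc_at_peak) - params.gc_at_peak) / params.decay_width
        means = params.peak_mean * np.exp(-0.5 * z * z)
    else:
        means = np.full(len(seq), float(params.peak_mean))
    draws = rng.normal(means, params.sd_multiple * means)
    return np.maximum(0, np.rint(draws)).astype(np.int64)
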