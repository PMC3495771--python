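"""Run configuration: every simulator parameter, with cross-field validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .coverage import CoverageParameters
from .engine import GenerationParameters


class ConfigError(ValueError):
    """A configuration invariant was violated; the message names the keys."""


@dataclass
class RunConfiguration:
    """Everything one simulation run needs, in one validated object.

    Dotted key names (``reads.length``, ``coverage.peakMean``, ...) are the
    canonical vocabulary used in error messages and the run log.
    """

    fasta: str = ""
    out_prefix: str = ""
    seed: int = 1
    read_length: int = 100
    template_mean: float = 400.0
    template_sd: float = 25.0
    buffer_size: int = 10000
    quality_mode: str = "uniform"  # uniform | fastq
    uniform_q: int = 40
    quality_fastq1: Optional[str] = None
    quality_fastq2: Optional[str] = None
    errors_enabled: bool = False
    filter_n: bool = False
    gc_bias_enabled: bool = True
    peak_mean: float = 30.0
    gc_at_peak: float = 0.45
    decay_width: float = 0.18
    sd_multiple: float = 0.1
    gc_region_size: int = 150
    stats_region_size: int = 10000
    _problems: list = field(default_factory=list, repr=False)

    def validate(self) -> "RunConfiguration":
        problems: list[str] = []
        if not self.fasta:
            problems.append("input.fasta: a reference FASTA path is required")
        if not self.out_prefix:
            problems.append("output.prefix: an output prefix is required")
        if self.read_length < 1:
            problems.append(f"reads.length: must be >= 1, got {self.read_length}")
        if self.template_sd < 0:
            problems.append(f"template.sd: must be >= 0, got {self.template_sd}")
        if self.read_length >= 1 and self.read_length > self.template_mean / 2:
            problems.append(
                f"reads.length ({self.read_length}) and template.mean "
                f"({self.template_mean}): reads.length must be <= template.mean / 2"
            )
        if self.buffer_size < self.template_mean + 6 * self.template_sd:
            problems.append(
                f"engine.nucleobaseBufferSize ({self.buffer_size}), template.mean "
                f"({self.template_mean}) and template.sd ({self.template_sd}): "
                "buffer must be >= template.mean + 6 * template.sd"
            )
        if self.quality_mode not in ("uniform", "fastq"):
            problems.append(f"quality.mode: must be 'uniform' or 'fastq', got {self.quality_mode!r}")
        if self.quality_mode == "fastq" and not self.quality_fastq1:
            problems.append("quality.mode=fastq requires quality.fastq1 (and optionally quality.fastq2)")
        if not 0 <= self.uniform_q <= 93:
            problems.append(f"quality.uniformQ: must be in [0, 93], got {self.uniform_q}")
        try:
            self.coverage_parameters()
        except ValueError as exc:
            problems.append(str(exc))
        if problems:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
        return self

    def coverage_parameters(self) -> CoverageParameters:
        return CoverageParameters(
            peak_mean=self.peak_mean,
            gc_at_peak=self.gc_at_peak,
            decay_width=self.decay_width,
            sd_multiple=self.sd_multiple,
            gc_region_size=self.gc_region_size,
            gc_bias_enabled=self.gc_bias_enabled,
        )

    def generation_parameters(self) -> GenerationParameters:
        return GenerationParameters(
            read_length=self.read_length,
            template_mean=self.template_mean,
            template_sd=self.template_sd,
            buffer_size=self.buffer_size,
            seed=self.seed,
        )

    def as_log_dict(self) -> dict:
        """Flat dotted-key view of the configuration, echoed into the run log."""
        return {
            "input.fasta": self.fasta,
            "output.prefix": self.out_prefix,
            "engine.seed": self.seed,
            "engine.nucleobaseBufferSize": self.buffer_size,
            "reads.length": self.read_length,
            "reads.filterN": self.filter_n,
            "template.mean": self.template_mean,
            "template.sd": self.template_sd,
            "quality.mode": self.quality_mode,
            "quality.uniformQ": self.uniform_q,
            "quality.fastq1": self.quality_fastq1 or "",
            "quality.fastq2": self.quality_fastq2 or "",
            "error.enabled": self.errors_enabled,
            "coverage.peakMean": self.peak_mean,
            "coverage.gcAtPeak": self.gc_at_peak,
            "coverage.decayWidth": self.decay_width,
            "coverage.sdMultiple": self.sd_multiple,
            "coverage.gcRegionSize": self.gc_region_size,
            "coverage.gcBiasEnabled": self.gc_bias_enabled,
            "stats.regionSize": self.stats_region_size,
        }
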