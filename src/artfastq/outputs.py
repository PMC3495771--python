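"""Writers for FASTQ pairs, the ground-truth read index, and run statistics.

Five artifacts per run prefix: ``<prefix>.1.fastq`` / ``<prefix>.2.fastq``
(Sanger-encoded paired FASTQ, record *k* of file 2 is the mate of record *k*
of file 1), ``<prefix>.index.tsv`` (the truth set: each read's true origin
interval on the reference, 1-based closed coordinates), ``<prefix>.log``
(human-readable ``key = value`` run report) and ``<prefix>.stats.json`` (the
same statistics, machine-readable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .engine import CoverageLedger, ReadPair

__all__ = [
    "ReadIndexEntry",
    "RegionStats",
    "SummaryStatistics",
    "write_fastq_pair",
    "index_entries",
    "write_read_index",
    "read_index",
    "compute_summary",
    "write_log",
]

INDEX_HEADER = "# coordinates: 1-based, fully closed intervals"
INDEX_COLUMNS = ("refName", "readId", "mate", "start", "end")


@dataclass(frozen=True)
class ReadIndexEntry:
    """True origin of one read: reference record, mate number, closed interval."""

    ref_name: str
    read_id: str
    mate: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} for {self.read_id}")
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")


@dataclass(frozen=True)
class RegionStats:
    ref_name: str
    start: int
    end: int
    min_coverage: int
    max_coverage: int
    mean_coverage: float


@dataclass
class SummaryStatistics:
    """Overall error counters plus regional and overall achieved coverage.

    Coverage means are over A/C/G/T reference positions only; N positions are
    excluded (a region that is entirely N reports NaN for its mean).
    """

    total_reads: int = 0
    total_base_calls: int = 0
    simulated_errors: int = 0
    regional: list[RegionStats] = field(default_factory=list)
    overall_mean_coverage: float = 0.0
    overall_min_coverage: int = 0
    overall_max_coverage: int = 0

    @property
    def error_rate(self) -> float:
        if self.total_base_calls == 0:
            return 0.0
        return self.simulated_errors / self.total_base_calls


def write_fastq_pair(pairs: Iterable[ReadPair], path1, path2) -> int:
    """Write standard 4-line FASTQ records, one file per mate; returns pair count."""
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.read_id}/1\n{pair.mate1_seq}\n+\n{pair.mate1_qual}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.mate2_seq}\n+\n{pair.mate2_qual}\n")
            n += 1
    return n


def index_entries(pair: ReadPair) -> tuple[ReadIndexEntry, ReadIndexEntry]:
    return (
        ReadIndexEntry(pair.ref_name, pair.read_id, 1, pair.mate1_start, pair.mate1_end),
        ReadIndexEntry(pair.ref_name, pair.read_id, 2, pair.mate2_start, pair.mate2_end),
    )


def write_read_index(entries: Iterable[ReadIndexEntry], path) -> int:
    """Write the ground-truth index as TSV, in emission order; returns entry count."""
    n = 0
    with open(path, "w") as fh:
        fh.write(INDEX_HEADER + "\n")
        fh.write("\t".join(INDEX_COLUMNS) + "\n")
        for e in entries:
            fh.write(f"{e.ref_name}\t{e.read_id}\t{e.mate}\t{e.start}\t{e.end}\n")
            n += 1
    return n


def read_index(path) -> list[ReadIndexEntry]:
    """Parse an index file written by :func:`write_read_index`."""
    out: list[ReadIndexEntry] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("refName"):
                continue
            ref_name, read_id, mate, start, end = line.rstrip("\n").split("\t")
            out.append(ReadIndexEntry(ref_name, read_id, int(mate), int(start), int(end)))
    return out


def compute_summary(
    ledgers: Sequence[tuple[str, str, CoverageLedger]],
    total_reads: int,
    total_base_calls: int,
    simulated_errors: int,
    region_size: int = 10000,
) -> SummaryStatistics:
    """Summarise achieved coverage per consecutive ``region_size``-base block
    and overall, plus the run's error counters.

    ``ledgers`` holds ``(record name, record sequence, ledger)`` triples; the
    sequence is needed to exclude N positions from coverage means.
    """
    if region_size < 1:
        raise ValueError(f"region_size must be >= 1, got {region_size}")
    regional: list[RegionStats] = []
    cov_sum = 0
    acgt_total = 0
    overall_min: int | None = None
    overall_max: int | None = None
    for name, seq, ledger in ledgers:
        cov = ledger.achieved
        is_n = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("N")
        for block_start in range(0, ledger.length, region_size):
            block_end = min(block_start + region_size, ledger.length)
            block = cov[block_start:block_end]
            block_n = is_n[block_start:block_end]
            acgt = block[~block_n]
            regional.append(
                RegionStats(
                    ref_name=name,
                    start=block_start + 1,
                    end=block_end,
                    min_coverage=int(block.min()),
                    max_coverage=int(block.max()),
                    mean_coverage=float(acgt.mean()) if acgt.size else float("nan"),
                )
            )
        acgt_cov = cov[~is_n]
        if acgt_cov.size:
            cov_sum += int(acgt_cov.sum())
            acgt_total += acgt_cov.size
            lo, hi = int(acgt_cov.min()), int(acgt_cov.max())
            overall_min = lo if overall_min is None else min(overall_min, lo)
            overall_max = hi if overall_max is None else max(overall_max, hi)
    return SummaryStatistics(
        total_reads=total_reads,
        total_base_calls=total_base_calls,
        simulated_errors=simulated_errors,
        regional=regional,
        overall_mean_coverage=cov_sum / acgt_total if acgt_total else float("nan"),
        overall_min_coverage=overall_min if overall_min is not None else 0,
        overall_max_coverage=overall_max if overall_max is not None else 0,
    )


def write_log(stats: SummaryStatistics, config: dict, path, json_path=None) -> None:
    """Write the run log (``key = value`` text) and its JSON twin.

    The log echoes the full configuration including the seed, then all
    summary counters; the simulated error rate is reported as a percentage
    to two decimal places.
    """
    lines = ["[configuration]"]
    for key in sorted(config):
        lines.append(f"{key} = {config[key]}")
    lines.append("")
    lines.append("[summary]")
    lines.append(f"totalReads = {stats.total_reads}")
    lines.append(f"totalBaseCalls = {stats.total_base_calls}")
    lines.append(f"simulatedErrors = {stats.simulated_errors}")
    lines.append(f"simulatedErrorRate = {100.0 * stats.error_rate:.2f}%")
    lines.append(f"overallMeanCoverage = {stats.overall_mean_coverage:.4f}")
    lines.append(f"overallMinCoverage = {stats.overall_min_coverage}")
    lines.append(f"overallMaxCoverage = {stats.overall_max_coverage}")
    lines.append("")
    lines.append("[regional coverage]")
    lines.append("refName\tstart\tend\tmin\tmax\tmean")
    for r in stats.regional:
        lines.append(
            f"{r.ref_name}\t{r.start}\t{r.end}\t{r.min_coverage}\t"
            f"{r.max_coverage}\t{r.mean_coverage:.4f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if json_path is not None:
        payload = {
            "configuration": {k: config[k] for k in sorted(config)},
            "summary": {
                "totalReads": stats.total_reads,
                "totalBaseCalls": stats.total_base_calls,
                "simulatedErrors": stats.simulated_errors,
                "simulatedErrorRate": stats.error_rate,
                "overallMeanCoverage": stats.overall_mean_coverage,
                "overallMinCoverage": stats.overall_min_coverage,
                "overallMaxCoverage": stats.overall_max_coverage,
            },
            "regionalCoverage": [
                {
                    "refName": r.ref_name,
                    "start": r.start,
                    "end": r.end,
                    "min": r.min_coverage,
                    "max": r.max_coverage,
                    "mean": r.mean_coverage,
                }
                for r in stats.regional
            ],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
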