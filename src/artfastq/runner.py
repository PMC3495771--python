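"""Run orchestration: reference in, five output artifacts out.

Each FASTA record is simulated independently with its own RNG stream spawned
from the run seed, so per-record output is reproducible even if records are
later simulated in separate processes and merged.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfiguration
from .engine import generate_pairs
from .outputs import compute_summary, index_entries, write_log
from .quality import QualitySource
from .reference import read_fasta

logger = logging.getLogger(__name__)

__all__ = ["run", "output_paths"]


def output_paths(prefix: str) -> dict:
    return {
        "fastq1": f"{prefix}.1.fastq",
        "fastq2": f"{prefix}.2.fastq",
        "index": f"{prefix}.index.tsv",
        "log": f"{prefix}.log",
        "stats": f"{prefix}.stats.json",
    }


def _quality_sources(config: RunConfiguration) -> tuple[QualitySource, QualitySource]:
    if config.quality_mode == "uniform":
        q1 = QualitySource.uniform(config.uniform_q)
        q2 = QualitySource.uniform(config.uniform_q)
        return q1, q2
    q1 = QualitySource.from_fastq(config.quality_fastq1)
    if config.quality_fastq2:
        return q1, QualitySource.from_fastq(config.quality_fastq2)
    return q1, q1  # one pool shared by both mates


def run(config: RunConfiguration):
    """Execute one simulation run; returns the computed SummaryStatistics."""
    config.validate()
    refs = read_fasta(config.fasta)
    gen_params = config.generation_parameters()
    cov_params = config.coverage_parameters()
    paths = output_paths(config.out_prefix)

    seeds = np.random.SeedSequence(config.seed).spawn(len(refs))
    total_reads = 0
    simulated_errors = 0
    ledgers = []
    pair_id = 1
    with open(paths["fastq1"], "w") as f1, open(paths["fastq2"], "w") as f2, open(
        paths["index"], "w"
    ) as fidx:
        fidx.write("# coordinates: 1-based, fully closed intervals\n")
        fidx.write("refName\treadId\tmate\tstart\tend\n")
        for ref, seed_seq in zip(refs, seeds):
            rng = np.random.default_rng(seed_seq)
            quality1, quality2 = _quality_sources(config)
            record_ledgers: list = []
            n_pairs = 0
            for pair in generate_pairs(
                ref,
                gen_params,
                cov_params,
                quality1,
                quality2,
                rng,
                errors_enabled=config.errors_enabled,
                filter_n=config.filter_n,
                ledger_out=record_ledgers,
                first_pair_id=pair_id,
            ):
                f1.write(f"@{pair.read_id}/1\n{pair.mate1_seq}\n+\n{pair.mate1_qual}\n")
                f2.write(f"@{pair.read_id}/2\n{pair.mate2_seq}\n+\n{pair.mate2_qual}\n")
                for e in index_entries(pair):
                    fidx.write(f"{e.ref_name}\t{e.read_id}\t{e.mate}\t{e.start}\t{e.end}\n")
                simulated_errors += pair.errors_mate1 + pair.errors_mate2
                n_pairs += 1
            pair_id += n_pairs
            total_reads += 2 * n_pairs
            ledgers.append((ref.name, ref.seq, record_ledgers[0]))
            if n_pairs == 0:
                logger.warning("record %s produced no reads", ref.name)
            else:
                logger.info("record %s: %d pairs", ref.name, n_pairs)

    stats = compute_summary(
        ledgers,
        total_reads=total_reads,
        total_base_calls=total_reads * config.read_length,
        simulated_errors=simulated_errors,
        region_size=config.stats_region_size,
    )
    write_log(stats, config.as_log_dict(), paths["log"], json_path=paths["stats"])
    return stats
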