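import pytest

from artfastq.config import RunConfiguration
from artfastq.fixtures import write_synthetic_reference
from artfastq.runner import output_paths, run


@pytest.fixture
def fasta_factory(tmp_path):
    """Write a synthetic reference FASTA into the test's tmp dir."""

    def make(length, gc_targets=(0.5,), n_runs=(), seed=1, name="synthetic"):
        path = tmp_path / f"ref_{length}_{seed}.fa"
        seq = write_synthetic_reference(path, length, gc_targets, n_runs, seed, name)
        return path, seq

    return make


@pytest.fixture(scope="session")
def uniform_run(tmp_path_factory):
    """One shared default-parameter run on a 100 kb uniform-GC reference.

    Errors off and uniform Q40 qualities, so the outputs double as a
    ground-truth oracle: every emitted base must match the reference.
    """
    d = tmp_path_factory.mktemp("uniform_run")
    ref_path = d / "ref.fa"
    seq = write_synthetic_reference(ref_path, 100_000, (0.41,), seed=20, name="chrS")
    config = RunConfiguration(fasta=str(ref_path), out_prefix=str(d / "out"), seed=1)
    stats = run(config)
    return {
        "seq": seq,
        "stats": stats,
        "paths": output_paths(str(d / "out")),
        "config": config,
    }
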