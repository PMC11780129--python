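import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phagenick import SimulationSpec, make_genome, simulate_reads
from phagenick.sequence_io import Genome, StrandCoverage
from phagenick.synthetic_data import reads_to_coverage

settings.register_profile(
    "det", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def random_genome(rng, length, gc=0.5, gid="g"):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=length, p=probs)
    return Genome(id=gid, seq="".join(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation: genome, truth, native and control
    strand coverage (45,228 bp, 13 minus-strand nicks, ~50x per strand)."""
    spec = SimulationSpec(seed=7)
    genome, truth = make_genome(spec)
    native, control = simulate_reads(genome, truth, spec)
    nf, nr = reads_to_coverage(native, genome.length)
    cf, cr = reads_to_coverage(control, genome.length)
    return {
        "spec": spec, "genome": genome, "truth": truth,
        "native_reads": native, "control_reads": control,
        "native": StrandCoverage(genome.id, nf, nr, "native"),
        "control": StrandCoverage(genome.id, cf, cr, "wga"),
    }
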