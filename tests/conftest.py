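import pytest

from stress5p import (
    AnnotatedTranscript,
    GenomeBundle,
    SimulationConfig,
    build_toy_genome,
    make_binding_truth,
)
from stress5p.truth import StressModel


@pytest.fixture(scope="session")
def small_bundle() -> GenomeBundle:
    return build_toy_genome(n_study=8, n_spike=2, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return make_binding_truth(small_bundle, {"fivep_share": 0.9}, StressModel(), seed=11)


@pytest.fixture()
def config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_reads=2_000)


@pytest.fixture(scope="session")
def hand_bundle() -> GenomeBundle:
    """A fully hand-specified two-transcript genome for boundary tests.

    TPLUS: plus strand, 5'UTR 20 nt, CDS 300 nt, 3'UTR 30 nt (span 10..360).
    TMINUS: minus strand with the same structure laid out in reverse
    (3'UTR at low coordinates), span 400..750.
    """
    import numpy as np

    rng = np.random.default_rng(123)
    bases = "ACGT"
    seq = "".join(bases[i] for i in rng.integers(0, 4, size=800))
    tplus = AnnotatedTranscript(
        id="TPLUS", species="study", chrom="chr1", strand="+",
        utr5=(10, 30), cds=(30, 330), utr3=(330, 360),
    )
    tminus = AnnotatedTranscript(
        id="TMINUS", species="study", chrom="chr1", strand="-",
        utr3=(400, 430), cds=(430, 730), utr5=(730, 750),
    )
    return GenomeBundle(chromosomes={"chr1": seq}, transcripts=[tplus, tminus])
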