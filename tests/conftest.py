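import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from domaingrn.ish import DomainPair
from domaingrn.peaks import GeneModel, GeneModelSet, Peak, PeakSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix():
    """Hand-built binary matrix: 2 markers + 3 genes over 3+3+1 regions."""
    regions = ["a1", "a2", "a3", "b1", "b2", "b3", "o1"]
    data = {
        "mA": [1, 1, 1, 0, 0, 0, 0],
        "mB": [0, 0, 0, 1, 1, 1, 0],
        "gA": [1, 1, 0, 0, 0, 0, 1],
        "gB": [0, 0, 0, 1, 1, 0, 0],
        "gNone": [0, 0, 0, 0, 0, 0, 0],
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=regions)


@pytest.fixture
def small_domains(small_matrix):
    return DomainPair(
        domain_a=("a1", "a2", "a3"),
        domain_b=("b1", "b2", "b3"),
        marker_a="mA",
        marker_b="mB",
        unassigned=("o1",),
    )


@pytest.fixture
def toy_genes():
    """Two genes, one per strand, with exon/CDS structure."""
    return GeneModelSet(
        [
            GeneModel(
                "plus", "chr1", "+", 100_000, 120_000,
                exons=((100_000, 101_000), (110_000, 120_000)),
                cds=(100_500, 115_000),
            ),
            GeneModel(
                "minus", "chr1", "-", 300_000, 320_000,
                exons=((300_000, 310_000), (319_000, 320_000)),
                cds=(305_000, 319_500),
            ),
        ]
    )


def make_peak(chrom, summit, name="p1"):
    return Peak(name, chrom, summit - 50, summit + 51, summit)


@pytest.fixture
def peak_factory():
    return make_peak


@pytest.fixture
def single_peak_set():
    def factory(chrom, summit):
        return PeakSet([make_peak(chrom, summit)])

    return factory
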