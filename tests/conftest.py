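import pytest

from peakrepro.intervals_io import GenomicInterval, PeakSet
from peakrepro.consensus import build_consensus
from peakrepro.synthetic_data import default_scenarios, generate


def gi(chrom, start, end, pvalue=None, score=None):
    return GenomicInterval(chrom, start, end, pvalue=pvalue, score=score)


@pytest.fixture
def toy_replicates():
    """Two replicates on a 1 kb toy genome; three consensus regions:
    chr1:100-250 (support 2), chr1:300-400 (s=1), chr1:500-600 (s=1)."""
    r1 = PeakSet("R1", [gi("chr1", 100, 200, pvalue=1e-6),
                        gi("chr1", 300, 400, pvalue=1e-5)])
    r2 = PeakSet("R2", [gi("chr1", 150, 250, pvalue=1e-6),
                        gi("chr1", 500, 600, pvalue=0.5)])
    return [r1, r2]


@pytest.fixture
def toy_consensus(toy_replicates):
    return build_consensus(toy_replicates)


@pytest.fixture
def toy_tracks():
    """pG4/oG4 tracks making chr1:100-250 the lone high-confidence region."""
    pg4 = [gi("chr1", 100, 260), gi("chr1", 300, 400)]
    og4 = [gi("chr1", 120, 240)]
    return pg4, og4


@pytest.fixture(scope="session")
def rep6_bundle():
    return generate(default_scenarios()["rep6"])
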