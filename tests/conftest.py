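import numpy as np
import pytest
from hypothesis import settings

from transductomics import call_patterns
from transductomics.simulate import make_fixture

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lambda_fixture():
    """One contig with an induced prophage and rare two-sided specialized flanks."""
    pairs, truths, frags = make_fixture("lambda_like", seed=11, return_fragments=True)
    return pairs[0], truths[0], frags[pairs[0].contig_id]


@pytest.fixture(scope="session")
def p22_fixture():
    pairs, truths = make_fixture("p22_like", seed=11)
    return pairs[0], truths[0]


@pytest.fixture(scope="session")
def pbsx_fixture():
    pairs, truths = make_fixture("pbsx_like", seed=11)
    return pairs[0], truths[0]


@pytest.fixture(scope="session")
def p1_fixture():
    pairs, truths = make_fixture("p1_like", seed=11)
    return pairs[0], truths[0]


@pytest.fixture(scope="session")
def faecalis_fixture():
    pairs, truths = make_fixture("faecalis_like", seed=11)
    return pairs[0], truths[0]


@pytest.fixture(scope="session")
def community():
    pairs, truths = make_fixture("community_like", seed=11)
    return pairs, truths


@pytest.fixture(scope="session")
def community_calls(community):
    pairs, truths = community
    return [call_patterns(p) for p in pairs]


def make_track(depths, bin_size=100, total_mapped=1e6, contig_id="ctg", source="vlp",
               contig_length=None):
    """Small helper: a CoverageTrack from literal bin depths."""
    from transductomics import CoverageTrack

    depths = np.asarray(depths, dtype=float)
    if contig_length is None:
        contig_length = depths.size * bin_size
    return CoverageTrack(
        contig_id=contig_id, contig_length=contig_length, bin_size=bin_size,
        depths=depths, total_mapped=total_mapped, source=source,
    )
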