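import numpy as np
import pytest

from pdupack.genome import (
    FACTOR_ISCEI,
    FACTOR_LACI,
    OperatorSite,
    Replicon,
    SampleModel,
    Segment,
    build_design,
)


@pytest.fixture(scope="session")
def lacO8_model():
    return build_design("lacO8", 5000, seed=1)


@pytest.fixture(scope="session")
def lacO5_model():
    return build_design("lacO5", 5000, seed=1)


@pytest.fixture(scope="session")
def lexA_model():
    return build_design("lexA", 5000, seed=1)


def make_simple_model(
    n_sites: int = 1,
    spacing: int = 40,
    site_len: int = 21,
    plasmid_length: int = 5000,
    chromosome_length: int = 10_000,
    copy_number: float = 1.0,
    first_site: int = 2000,
    with_sequence: bool = False,
) -> SampleModel:
    """A chromosome plus one plasmid carrying `n_sites` LacI sites."""
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))

    def seq(n):
        return "".join(bases[rng.integers(0, 4, n)]) if with_sequence else None

    sites = []
    pos = first_site
    for i in range(n_sites):
        sites.append(OperatorSite("plasmid", pos, pos + site_len, FACTOR_LACI, f"s{i}"))
        pos += site_len + spacing
    seg_start = max(0, first_site - 50)
    return SampleModel(
        replicons=[
            Replicon("chrom", chromosome_length, 1.0, seq(chromosome_length), is_chromosome=True),
            Replicon("plasmid", plasmid_length, copy_number, seq(plasmid_length)),
        ],
        sites=sites,
        segment=Segment("plasmid", seg_start, seg_start + 600),
    )
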