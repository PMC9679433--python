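import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import haplostock as hs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_dataset():
    """Two estuaries + hatchery broodstock, hand-built, 10 samples, L=8."""
    import pandas as pd

    ids = [f"s{i}" for i in range(8)] + ["b0", "b1"]
    seqs = hs.AlignedSeqSet.from_strings(ids, [
        "ACGTACGT",  # s0 North
        "ACGTACGT",  # s1 North  (shares with s0)
        "ACGTACGA",  # s2 North
        "ACGAACGT",  # s3 North
        "ACGTACCT",  # s4 South
        "ACCTACGT",  # s5 South
        "AGGTACGT",  # s6 South
        "ACGTTCGT",  # s7 South
        "ACGTACGT",  # b0 broodstock (matches s0/s1)
        "TTTTACGT",  # b1 broodstock
    ])
    meta = pd.DataFrame({
        "sample_id": ids,
        "site": ["North"] * 4 + ["South"] * 4 + ["Hatchery"] * 2,
        "collection_date": ["2014-10-01"] * 2 + ["2015-03-01"] * 2
        + ["2014-10-01"] * 4 + ["2015-11-01"] * 2,
        "role": ["estuary"] * 8 + ["broodstock"] * 2,
    })
    calendar = pd.DataFrame({
        "site": ["North", "South"],
        "release_date": pd.to_datetime(["2014-12-15", "2014-12-15"]),
        "count": [1000, 0],
    })
    frame = hs.build_sample_frame(meta, calendar)
    return hs.bind(seqs, frame, calendar)


@pytest.fixture(scope="session")
def default_sim():
    """The full default synthetic study (871 samples), shared across tests."""
    return hs.simulate_estuary_timeseries(hs.default_scenario(seed=1))


def random_seqset(rng, n, length, alphabet="ACGT"):
    letters = np.array(list(alphabet))
    matrix = letters[rng.integers(0, len(letters), size=(n, length))]
    return hs.AlignedSeqSet(ids=[f"r{i}" for i in range(n)], matrix=matrix)
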