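import numpy as np
import pandas as pd
import pytest

from arisakit.io import (
    OTUTable,
    PeakRecord,
    PeakTable,
    READ_COUNT,
    RELATIVE_INTENSITY,
    SampleMetadata,
)


@pytest.fixture
def peak_tsv(tmp_path):
    """Three well-formed peaks in canonical TSV layout."""
    p = tmp_path / "peaks.tsv"
    p.write_text(
        "sample_id\treplicate_id\tsize_bp\tintensity_rfu\n"
        "S1\trep1\t250.4\t500\n"
        "S1\trep1\t699.9\t50\n"
        "S2\trep1\t1001.0\t120.5\n"
    )
    return p


@pytest.fixture
def count_table():
    data = pd.DataFrame(
        [[0, 3, 0, 7], [5, 0, 2, 1], [1, 1, 1, 1]],
        index=["S1", "S2", "S3"],
        columns=["O1", "O2", "O3", "O4"],
    )
    return OTUTable(data, READ_COUNT)


@pytest.fixture
def four_group_meta():
    groups = {}
    sizes = {"g1": 6, "g2": 5, "g3": 5, "g4": 5}
    for g, n in sizes.items():
        for i in range(n):
            groups[f"{g}s{i + 1:02d}"] = g
    return SampleMetadata(groups)


def random_peaks(rng, n=1000, sample="S1", rep="rep1"):
    """Random peak table spanning beyond the detection window."""
    sizes = rng.uniform(100.0, 1300.0, size=n)
    inten = rng.exponential(200.0, size=n) + rng.uniform(0, 15, size=n)
    return PeakTable(
        [PeakRecord(sample, rep, float(s), float(i)) for s, i in zip(sizes, inten)]
    )
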