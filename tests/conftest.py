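import numpy as np
import pytest

import tetradscape as ts


@pytest.fixture(scope="session")
def genome():
    return ts.default_genome()


@pytest.fixture(scope="session")
def dense_markers(genome):
    """Default-density marker map (~61k markers at ~196 bp spacing)."""
    return ts.place_markers(genome, 196, seed=11)


@pytest.fixture(scope="session")
def params():
    return ts.SimParams()


@pytest.fixture(scope="session")
def long_genome():
    """Two 10-Mb chromosomes: a low-truncation regime for interference fits."""
    return ts.GenomeModel(
        chromosomes=(("c1", 10_000_000), ("c2", 10_000_000)),
        centromeres={"c1": 5_000_000, "c2": 5_000_000},
    )


@pytest.fixture(scope="session")
def sparse_long_markers(long_genome):
    return ts.place_markers(long_genome, 5_000, seed=0)


def truth_co_points(truth_sets):
    """(tetrad, chrom, point) frame from truth CO events of several tetrads."""
    import pandas as pd

    rows = []
    for name, truth in truth_sets:
        for e in truth.select("CO"):
            rows.append({"tetrad": name, "chrom": e.chrom, "point": e.point})
    return pd.DataFrame(rows)
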