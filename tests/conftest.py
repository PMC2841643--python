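import numpy as np
import pytest

from metaprof.io import PathwayDB, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_db():
    """Two partially overlapping pathways plus an exact duplicate variant.

    R1 is private to P1; RS is shared by the otherwise-disjoint P1 and P2;
    P2dup duplicates P2 exactly.
    """
    pathways = {
        "P1": ["R1", "R2", "R3", "R4", "RS"],
        "P2": ["R5", "R6", "R7", "R8", "RS"],
        "P2dup": ["R5", "R6", "R7", "R8", "RS"],
    }
    rxns = sorted({r for v in pathways.values() for r in v})
    proteins = {r: {f"{r}.p0", f"{r}.p1"} for r in rxns}
    ec = {r: (f"1.1.1.{i}", False) for i, r in enumerate(rxns, 1)}
    return PathwayDB(pathways, proteins, ec)


def random_pathway_dict(rng, n_pathways=8, pool=30, size_range=(2, 8)):
    """A random pathway -> reaction-list mapping for oracle comparisons."""
    pool_ids = [f"R{i:02d}" for i in range(pool)]
    out = {}
    for p in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        rxns = rng.choice(pool_ids, size=size, replace=False)
        out[f"P{p:02d}"] = list(rxns)
    return out


def record(seq, id="s1"):
    return SequenceRecord(id=id, seq=seq)
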