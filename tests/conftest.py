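import numpy as np
import pytest

from metaguide.assembly import assemble_sample
from metaguide.refdb import ReferenceDatabase
from metaguide.simdata import SimParams, simulate_community, simulate_reads


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def community():
    """Three-species community (60 kb genomes, equal abundance, 20x reads)."""
    truth, genomes, markers = simulate_community(
        3, lengths=(60_000, 60_000, 60_000), weights=[1.0, 1.0, 1.0], seed=5)
    db = ReferenceDatabase({g.accession: g for g in genomes},
                           {m.marker_id: m for m in markers})
    reads, origins = simulate_reads(truth, SimParams(depth=20, seed=5))
    return truth, db, reads


@pytest.fixture(scope="session")
def assembled(community):
    truth, db, reads = community
    return assemble_sample(reads, db)
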