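import os
import tempfile

import pytest

from svhotspot import genome_forge as gf
from svhotspot import pair_io


@pytest.fixture(scope="session")
def small_genome():
    return gf.make_reference(1, [400_000], 0.41, seed=11, chrom_names=["chr17"])


@pytest.fixture(scope="session")
def library():
    return gf.LibraryModel(read_len=50, error_rate=0.0)


def simulate_and_ingest(genome, haplotypes, model, coverage, seed, sample="S"):
    """Simulate a library and round-trip it through SAM ingest."""
    pairs = gf.simulate_mate_pairs(haplotypes, model, coverage, seed=seed, sample=sample)
    with tempfile.TemporaryDirectory() as d:
        sam = os.path.join(d, "pairs.sam")
        pair_io.write_sam(pairs, genome, sam, sample=sample)
        aligned, stats = pair_io.read_pairs_sam(sam, sample=sample)
    return pairs, aligned, stats
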