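import numpy as np
import pandas as pd
import pytest

from epidiff.dmr import SmoothedTrack
from epidiff.simulate import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def tiny_genome():
    """A 2 x 100 kb genome small enough for per-test pipeline runs."""
    spec = GenomeSpec(
        n_chroms=2, chrom_length=100_000, n_pcgs=40, n_tes=40, seed=7
    )
    return make_genome(spec)


def make_track(genotype, context, pos, meth, unmeth, chrom="chr1"):
    return SmoothedTrack(
        genotype, chrom, context,
        np.asarray(pos), np.asarray(meth, float), np.asarray(unmeth, float),
    )


def make_cytosine_frame(rows):
    """rows: (chrom, pos, strand, context, meth, unmeth)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"]
    )
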