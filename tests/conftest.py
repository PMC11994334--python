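import numpy as np
import pandas as pd
import pytest

import secmdecon as sd


@pytest.fixture(scope="session")
def genome():
    return sd.Genome.scaled_hg19()


@pytest.fixture(scope="session")
def bins(genome):
    return sd.make_bins(genome)


@pytest.fixture(scope="session")
def signatures():
    return sd.builtin_signatures()


def make_readset(rows, genome=None, sample_id="test"):
    """Build a SampleReadSet from (read_id, chrom, start, end, n_cpg, n_meth
    [, n_unmeth_ch]) tuples."""
    cols = ["read_id", "chrom", "start", "end", "n_cpg", "n_meth", "n_unmeth_ch"]
    rows = [tuple(r) + (0,) * (7 - len(r)) for r in rows]
    df = pd.DataFrame(rows, columns=cols)
    if genome is None:
        genome = sd.Genome.from_intervals(df["chrom"], df["end"], name="tiny")
    return sd.SampleReadSet(sample_id=sample_id, records=df, genome=genome)


@pytest.fixture
def tiny_reads():
    return make_readset([
        ("r1", "chr1", 100, 200, 4, 2),
        ("r2", "chr1", 50, 150, 3, 0),
        ("r3", "chr2", 10, 110, 0, 0),
        ("r4", "chr2", 500, 600, 2, 2),
    ])


@pytest.fixture(scope="session")
def blastocyst_100k(genome, signatures):
    return sd.generate_reads(signatures["blastocyst"], sd.Karyotype.euploid("XX"),
                             100_000, genome, seed=11)


@pytest.fixture(scope="session")
def cumulus_100k(genome, signatures):
    return sd.generate_reads(signatures["cumulus"], sd.Karyotype.euploid("XX"),
                             100_000, genome, seed=13)
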