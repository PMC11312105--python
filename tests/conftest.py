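import numpy as np
import pandas as pd
import pytest

from nitroprofile.catalog import load_catalog
from nitroprofile.io import DepthTable, Sample
from nitroprofile.simulate import SimConfig, simulate_community


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_depth_table(lengths, counts_per_sample, read_length=150):
    """Build a DepthTable from explicit read counts.

    lengths: {contig_id: bp}; counts_per_sample: {sample_id: {contig_id: n}}.
    """
    ids = sorted(lengths)
    length_series = pd.Series({c: lengths[c] for c in ids}, name="length_bp")
    length_series.index.name = "contig_id"
    counts = pd.DataFrame(
        {s: [counts_per_sample[s].get(c, 0) for c in ids]
         for s in sorted(counts_per_sample)},
        index=pd.Index(ids, name="contig_id"),
    )
    depths = counts.mul(read_length).div(length_series, axis=0)
    return DepthTable(lengths=length_series, depths=depths, read_counts=counts)


def make_sample(sample_id="S1", total_mapped_reads=1_000_000,
                lake="AQK", month="April"):
    return Sample(sample_id, lake, month,
                  raw_reads_size=total_mapped_reads / 1e6,
                  total_mapped_reads=total_mapped_reads)


@pytest.fixture(scope="session")
def small_truth():
    """A small but fully featured simulated community (shared, read-only)."""
    cfg = SimConfig(n_genomes=8, n_samples=4, genome_size_bp=100_000,
                    contig_length=10_000, seed=11, n_species_pairs=2)
    return simulate_community(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240709)
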