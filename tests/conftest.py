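import numpy as np
import pandas as pd
import pytest

from methinfo.methylome_io import MethylomeSample, build_matrix


@pytest.fixture
def generic_table(tmp_path):
    """Small generic-dialect count table on disk (unsorted on purpose)."""
    path = tmp_path / "sample.tsv"
    path.write_text(
        "chrom\tpos\tstrand\tcontext\tn_meth\tn_total\n"
        "chr1\t10\t+\tCG\t5\t10\n"
        "chr1\t25\t+\tCHH\t0\t8\n"
        "chr1\t12\t+\tCG\t10\t10\n"
    )
    return path


@pytest.fixture
def sample_a():
    return MethylomeSample(
        "a",
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "pos": [10, 20, 30],
                "strand": ["+", "+", "-"],
                "context": ["CG", "CHG", "CHH"],
                "n_meth": [5, 0, 3],
                "n_total": [10, 8, 3],
            }
        ),
    )


@pytest.fixture
def sample_b():
    return MethylomeSample(
        "b",
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "pos": [40, 5],
                "strand": ["+", "+"],
                "context": ["CG", "CG"],
                "n_meth": [1, 2],
                "n_total": [4, 2],
            }
        ),
    )


@pytest.fixture
def pair_matrix(sample_a):
    """Two-sample matrix over identical keys with differing levels."""
    other = MethylomeSample(
        "c",
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "pos": [10, 20, 30],
                "strand": ["+", "+", "-"],
                "context": ["CG", "CHG", "CHH"],
                "n_meth": [10, 4, 0],
                "n_total": [10, 8, 4],
            }
        ),
    )
    return build_matrix([sample_a, other])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
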