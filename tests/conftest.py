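import numpy as np
import pandas as pd
import pytest

from snpsens.genotyper import CallerParams
from snpsens.regions_io import make_panel, make_regions
from snpsens.simulate import DepthProfile


@pytest.fixture
def caller() -> CallerParams:
    return CallerParams()  # eps=0.01, uniform prior


@pytest.fixture
def small_regions() -> pd.DataFrame:
    return make_regions(chrom=["chr1", "chr1", "chr2"],
                        start=[100, 1000, 50],
                        end=[350, 1100, 250],
                        gc=[0.45, 0.70, 0.40],
                        repeat=[False, True, False],
                        alignability=[0.95, 0.40, 0.99])


@pytest.fixture
def small_panel() -> pd.DataFrame:
    return make_panel(chrom=["chr1", "chr1", "chr1", "chr2"],
                      pos=[150, 200, 1050, 100],
                      ref=["A", "C", "G", "T"],
                      alt=["G", "T", "A", "C"],
                      maf=[0.2, 0.005, 0.3, 0.08])


def constant_profile(regions: pd.DataFrame, depth: int) -> DepthProfile:
    from snpsens.simulate import targeted_positions
    sites = targeted_positions(regions)
    sites["depth"] = depth
    return DepthProfile(sites)


@pytest.fixture
def make_constant_profile():
    return constant_profile


def make_reads(n: int, depth: int, alt_counts) -> pd.DataFrame:
    """SiteReads table on chr1 positions 1..n with given depth and alt counts."""
    alt = np.asarray(alt_counts)
    return pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1),
                         "ref": "A", "alt": "G",
                         "ref_count": depth - alt, "alt_count": alt})
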