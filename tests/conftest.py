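import numpy as np
import pytest

from prfkit import polyprotein as pp
from prfkit import sortseq as ss
from prfkit import variants as va


@pytest.fixture(scope="session")
def fixture_record():
    record, regions, slip, bp = pp.make_polyprotein_fixture(seed=1)
    return record, regions, slip, bp


@pytest.fixture(scope="session")
def small_sortseq():
    """A small seeded sort-seq dataset with known truth (2000 variants)."""
    ids = [va.WT_ID] + [f"v{i}" for i in range(1999)]
    truth = ss.make_truth(ids, seed=3, sigma_cell=0.25)
    ab = np.full(len(ids), 0.98 / (len(ids) - 1))
    ab[0] = 0.02
    cal, assign = ss.simulate_sort(truth, n_cells=60_000, seed=4, abundances=ab)
    counts = ss.sequence_bins(assign, depth_per_bin=20_000, seed=5)
    return truth, cal, assign, counts
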