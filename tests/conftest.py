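import numpy as np
import pandas as pd
import pytest

from ionnet import BaitDesign, IntensityMatrix


def make_design(n_baits=3, n_reps=4, families=None, igg=2):
    baits = [f"b{i + 1}" for i in range(n_baits)]
    rep_map = {b: [f"{b}_r{r + 1}" for r in range(n_reps)] for b in baits}
    fam = families or {b: b for b in baits}
    return BaitDesign(baits, rep_map, fam, [f"IgG_r{r + 1}" for r in range(igg)])


def make_matrix(design, values=None, n_proteins=10, seed=0):
    """Raw-scale matrix over the design's samples (bait pulldowns + IgG)."""
    cols = design.pulldown_samples + design.igg_samples
    rng = np.random.default_rng(seed)
    if values is None:
        values = np.exp2(rng.normal(20, 1, (n_proteins, len(cols))))
    proteins = [f"P{i + 1}" for i in range(values.shape[0])]
    return IntensityMatrix(pd.DataFrame(values, index=proteins, columns=cols))


@pytest.fixture
def small_design():
    return make_design()


@pytest.fixture
def small_matrix(small_design):
    return make_matrix(small_design)
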