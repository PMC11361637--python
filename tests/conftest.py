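"""Shared fixtures: the default synthetic study datasets, computed once.

The heavy objects (2000-cell paired datasets, fitted pseudotime, delta
profiles) are session-scoped so trajectory, fate-bias and acceptance tests
reuse one computation.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from mgregen import preprocess as pp
from mgregen import synthetic_data as sd
from mgregen import trajectory as tj

DEFAULT_SEED = 1


def _processed(ds: sd.SyntheticDataset) -> SimpleNamespace:
    filtered = pp.qc_filter(ds.counts)
    norm = pp.normalize_log(filtered)
    keep = np.isin(ds.counts.cell_ids, filtered.cell_ids)
    return SimpleNamespace(
        ds=ds,
        counts=filtered,
        norm=norm,
        state=ds.state_label[keep],
        cond=ds.condition_label[keep],
        t_true=ds.true_pseudotime[keep],
    )


@pytest.fixture(scope="session")
def abl_pair() -> SimpleNamespace:
    """Default control + ablated wild-type dataset (2000 cells), processed."""
    cfg = sd.SimulationConfig(seed=DEFAULT_SEED)
    return _processed(sd.simulate_ablation_pair(cfg))


@pytest.fixture(scope="session")
def abl_pt(abl_pair) -> tj.PseudotimeAssignment:
    return tj.fit_pseudotime(abl_pair.norm, abl_pair.state,
                             tj.TrajectoryParams(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def ko_pair() -> SimpleNamespace:
    """Default ablated wild-type + knockout dataset sharing one network."""
    cfg = sd.SimulationConfig(seed=DEFAULT_SEED)
    ds, ko_tf = sd.simulate_ko_pair(cfg)
    out = _processed(ds)
    out.ko_tf = ko_tf
    return out


@pytest.fixture(scope="session")
def ko_delta(ko_pair):
    pt = tj.fit_pseudotime(ko_pair.norm, ko_pair.state,
                           tj.TrajectoryParams(seed=DEFAULT_SEED))
    binned, delta = tj.bin_and_delta(
        ko_pair.norm, pt, ko_pair.cond,
        tj.TrajectoryParams(seed=DEFAULT_SEED),
        cond_a="ablated_wildtype", cond_b="ablated_knockout",
    )
    return SimpleNamespace(pt=pt, binned=binned, delta=delta)
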