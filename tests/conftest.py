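import pytest

import stride_prev as sp
from stride_prev.config import default_cutoffs, default_item_maps


@pytest.fixture(scope="session")
def item_maps():
    return default_item_maps()


@pytest.fixture(scope="session")
def cutoffs():
    return default_cutoffs()


@pytest.fixture(scope="session")
def indo_results():
    """Fitted large-cohort scenario (2216 recruited, 106 planted non-evaluable)."""
    model = sp.DementiaPrevalenceModel.from_simulation(
        sp.indonesia_like(), n_boot=200
    )
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def sa_results():
    """Fitted small-cohort scenario (490 recruited, 82 planted non-evaluable)."""
    model = sp.DementiaPrevalenceModel.from_simulation(
        sp.southafrica_like(), n_boot=200
    )
    return model.fit(seed=1)


def make_complete_record(item_maps, fill=0):
    """A record answering every item of every instrument with `fill`
    (clipped to each item's allowed codes)."""
    rec = {}
    for imap in item_maps.values():
        for item in imap.items:
            allowed = sorted(item.contributions)
            rec[item.item_id] = min(max(fill, allowed[0]), allowed[-1])
    return rec
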