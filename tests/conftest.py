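import copy
import dataclasses

import pytest

import ciris


def reduce_scan(
    scenario,
    *,
    wn_step=10.0,
    cycles=2,
    stochastic=False,
    baseline=0.0,
    source_rate=None,
    dt=None,
    fluence_scale=None,
):
    """A desk-scale copy of a preset scenario for fast scan simulations."""
    sc = copy.deepcopy(scenario)
    scan_kw = {"wn_step": wn_step}
    if fluence_scale is not None:
        scan_kw["fluence_scale"] = fluence_scale
    sc.scan = dataclasses.replace(sc.scan, **scan_kw)
    sc.trap = dataclasses.replace(sc.trap, cycles_per_wavenumber=cycles)
    sc.stochastic = stochastic
    sc.baseline = baseline
    if source_rate is not None:
        sc.source_rate = source_rate
    if dt is not None:
        sc.dt = dt
    return sc


@pytest.fixture(scope="session")
def leu_enk():
    return ciris.make_preset("leu_enk")


@pytest.fixture(scope="session")
def mixture():
    return ciris.make_preset("trisaccharide_mixture")


@pytest.fixture(scope="session")
def sliced():
    return ciris.make_preset("melezitose_sliced")


@pytest.fixture
def calibration():
    return ciris.DEFAULT_CALIBRATION


@pytest.fixture
def fresh(request):
    """Deep copy of a session-scoped preset so tests can mutate freely."""

    def _fresh(scenario):
        return copy.deepcopy(scenario)

    return _fresh
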