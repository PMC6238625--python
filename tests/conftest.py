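"""Shared fixtures.  Expensive objects are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from clockloops.clamping import ClampAnalysis, core_loop_catalog
from clockloops.config import RhythmCriterion, SimConfig
from clockloops.network import default_topology, parameter_bounds
from clockloops.synth import FIXTURE_FAMILIES, ground_truth_fixture


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture(scope="session")
def bounds(topo):
    return parameter_bounds(topo)


@pytest.fixture(scope="session")
def fast_sim():
    """Cheap but still multi-cycle simulation settings for tests."""
    return SimConfig(duration=240.0, step=0.1, transient=144.0)


@pytest.fixture(scope="session")
def fast_criterion():
    return RhythmCriterion(transient=144.0, window=96.0)


@pytest.fixture(scope="session")
def catalog(topo):
    return core_loop_catalog(topo)


@pytest.fixture(scope="session")
def fixtures(fast_sim):
    """The three verified ground-truth fixtures (noiseless)."""
    return {
        fam: ground_truth_fixture(fam, seed=1, noise=0.0, sim=fast_sim)
        for fam in FIXTURE_FAMILIES
    }


@pytest.fixture(scope="session")
def analyses(fixtures, topo, fast_sim, fast_criterion):
    """Clamping analyses of the three fixtures (cached single-edge verdicts)."""
    return {
        fam: ClampAnalysis(fx.params, topo, sim=fast_sim, criterion=fast_criterion)
        for fam, fx in fixtures.items()
    }


@pytest.fixture(scope="session")
def reports(analyses, catalog):
    return {
        fam: an.report(catalog, fit_id=f"{fam}-truth") for fam, an in analyses.items()
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261002)


@pytest.fixture(scope="session")
def antiphase_vfo_result(topo, bounds):
    """VFO solution for a profile whose Bmal1 targets all peak in antiphase.

    Computed once per session (about 1.5 min): 30 quasi-Newton starts on a
    strict antiphase profile, where gradient matching must place the Bmal1
    regulator delay high in its [0, 6] h range.
    """
    from clockloops.config import VfoConfig
    from clockloops.network import GENES
    from clockloops.scoring import ExpressionProfile
    from clockloops.vfo import run_vfo

    t = np.arange(0.0, 48.0, 2.0)
    phases = (0.0, 12.0, 12.0, 12.0, 12.0)
    amps = (0.5, 0.6, 0.6, 0.5, 0.7)
    vals = np.empty((5, len(t)))
    for i in range(5):
        vals[i] = 1.0 + amps[i] * np.cos(2 * np.pi * (t - phases[i]) / 24.0)
    prof = ExpressionProfile(genes=GENES, times=t, values=vals)
    return run_vfo(prof, bounds, VfoConfig(n_starts=30, maxiter=200),
                   seed=0, topo=topo)
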