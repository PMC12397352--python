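"""Shared fixtures: small grids and the reduced-scale coupled trend study.

The trend study (one coarse 16-cilium strip, one recorded beat cycle of
flow, five dissolution/transport episodes across drugs and attachment
strengths) is expensive, so it is computed once per session and shared by
the acceptance and metrics tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mucosim.cilia import MarkerField, build_lattice
from mucosim.dissolution import DRUGS
from mucosim.flow import FlowSolver
from mucosim.grid import GridSpec
from mucosim.rheology import GiesekusParams
from mucosim.transport import TransportSolver

#: Reduced-scale study conditions: a 16-cilium strip on a coarse grid
#: (dx ~ 1.4 um), spun up for two beat cycles with the third recorded.
#: kappa values are chosen so the per-episode attachment removal is O(10%)
#: and O(50%) of the injected mass, bracketing the competitive regime.
TREND_GRID = dict(nx=24, ny=4, nz=12)
TREND_CILIA = 16
TREND_KAPPAS = (0.0, 0.02, 0.08)
#: Interface area fed by the single 5-um particle: the full 100 x 100
#: lattice footprint (100 cilia x 0.4 um spacing per side).
FULL_TOP_AREA = (100 * 0.4e-6) ** 2


@pytest.fixture(scope="session")
def trend_setup():
    """Grid, markers and one recorded flow cycle of the reduced strip."""
    grid = GridSpec(**TREND_GRID)
    lattice = build_lattice(count=TREND_CILIA, spacing=grid.lx / TREND_CILIA)
    with pytest.warns(UserWarning):  # coarse grid under-resolves the surface
        markers = MarkerField(lattice, grid.dx, y_center=grid.ly / 2)
    solver = FlowSolver(grid, giesekus=GiesekusParams.hbe_mucus(),
                        markers=markers, dt=(1.0 / 15.0) / 900,
                        n_force_iter=4)
    replay = solver.run_cycles(solver.initial_state(), 3.0, record=24)
    return {"grid": grid, "markers": markers, "replay": replay,
            "lattice": lattice}


def _episode(setup, drug_name: str, kappa: float):
    replay = setup["replay"]
    solver = TransportSolver(
        setup["grid"], DRUGS[drug_name], flow=replay,
        markers=setup["markers"], kappa_att=kappa, top_area=FULL_TOP_AREA,
        umax_hint=float(np.abs(replay.u).max()))
    return solver.run(diameter=5e-6)


@pytest.fixture(scope="session")
def trend_runs(trend_setup):
    """Coupled episodes: TIO across kappa values, all drugs at fixed kappa."""
    runs = {}
    for kappa in TREND_KAPPAS:
        runs[("TIO", kappa)] = _episode(trend_setup, "TIO", kappa)
    for drug in ("RIF", "SAL"):
        runs[(drug, TREND_KAPPAS[1])] = _episode(trend_setup, drug,
                                                 TREND_KAPPAS[1])
    return runs
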