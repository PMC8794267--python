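"""Shared fixtures.

The heavy simulations (single-cell relaxation/drift, the doublet adhesion
scan, the 1-to-4-cell program and the coarse full program) are
session-scoped so unit and acceptance tests share one computation.
All fixtures are deterministic: the simulator core contains no randomness.
"""

from __future__ import annotations

import numpy as np
import pytest

import embryophase as ep
from embryophase.attraction import zero_matrix
from embryophase.division import Lineage
from embryophase.dynamics import _advance, build_sigma


def make_unit_grid(dims=(40, 40, 40)) -> ep.GridSpec:
    return ep.GridSpec(dims, dl=1.0)


def tanh_sphere(grid, center, radius, k=np.sqrt(0.5)):
    """Analytic tanh sphere of nominal radius (voxels), not volume-corrected."""
    x, y, z = grid.meshgrid()
    r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    return ep.PhaseField(0.5 * (1.0 + np.tanh(k * (radius - r))), grid)


@pytest.fixture(scope="session")
def single_cell_relaxation():
    """A well-resolved cell (r ~ 12 voxels) relaxing inside a roomy shell.

    Returns a dict with the state after 2000 steps (shape metrics) and the
    volume drift after a further 10000 steps.
    """
    grid = make_unit_grid()
    volume = 4.0 / 3.0 * np.pi * 12.0**3
    shell_spec = ep.EggshellSpec(
        semi_axis_x=17.0, semi_axis_z=16.0, y_half_width=16.0, compressed=False
    )
    shell = ep.make_compressed_eggshell_field(grid, shell_spec)
    f = ep.init_cell_sphere(grid, (19.5, 19.5, 19.5), volume)
    cell = ep.CellState("P0", f, volume)
    embryo = ep.EmbryoState([cell], shell, grid)
    p = ep.ForceParams()
    d = ep.DynamicsParams()
    sigma = zero_matrix(["P0"])
    _advance(embryo, p, d, sigma, 2000)
    relaxed = cell.field.copy()
    alpha = ep.deformation_alpha(cell)
    area = ep.surface_area(cell)
    _advance(embryo, p, d, sigma, 10000)
    drift = cell.field.volume_um3() / volume - 1.0
    return {
        "grid": grid,
        "volume": volume,
        "shell": shell,
        "relaxed_field": relaxed,
        "alpha_after_2000": alpha,
        "area_after_2000": area,
        "drift_after_12000": drift,
        "embryo": embryo,
        "params": p,
        "dynamics": d,
    }


@pytest.fixture(scope="session")
def doublet_scan():
    """Equilibrium contact area of a two-cell doublet across the sigma grid."""
    grid = ep.GridSpec((48, 32, 32), dl=1.0)
    shell_spec = ep.EggshellSpec(
        semi_axis_x=20.0, semi_axis_z=13.0, y_half_width=13.0, compressed=False
    )
    shell = ep.make_compressed_eggshell_field(grid, shell_spec)
    v0 = 2 * 2145.0
    p = ep.ForceParams()
    d = ep.DynamicsParams(sample_stride=20)

    def make_doublet():
        f = ep.init_cell_sphere(grid, (23.5, 15.5, 15.5), v0)
        embryo = ep.EmbryoState([ep.CellState("P0", f, v0)], shell, grid)
        _advance(embryo, p, d, build_sigma("zero", ["P0"], Lineage()), 300)
        return ep.bisect_cell(
            embryo, ep.DivisionSpec("P0", ("AB", "P1"), (1.0, 0.0, 0.0), (1.0, 1.0))
        )

    areas = {}
    embryos = {}
    for s in (0.0, 0.3, 0.6, 0.9, 1.2, 1.5):
        embryo = make_doublet()
        mode = f"uniform:{s}" if s > 0 else "zero"
        _advance(embryo, p, d, build_sigma(mode, embryo.names, Lineage()), 2500)
        areas[s] = ep.contact_area(embryo.cell("AB"), embryo.cell("P1"))
        embryos[s] = embryo
    return {"areas": areas, "embryos": embryos, "grid": grid}


@pytest.fixture(scope="session")
def fourcell_run():
    """1-to-4-cell program with the fitted 4-cell attraction matrix, quarter
    resolution, relaxed to mechanical equilibrium."""
    cfg = ep.builtin("fourcell_emsp2_scan", grid_divisor=4).variants[1]  # EMS-P2 = 0.2
    result = cfg.run()
    return {"config": cfg, "result": result, "embryo": result.embryo}


@pytest.fixture(scope="session")
def tiny_wt_runs():
    """Full 7-stage coarse runs, with and without the ABpl-E motif.

    Qualitative only: at 1/8 of the reference pitch the smallest 8-cell
    blastomeres are a few voxels across.
    """
    from embryophase.scenarios import wt_tiny_config

    with_motif = wt_tiny_config().run()
    without_motif = wt_tiny_config(eightcell_motifs=()).run()
    return {"with_motif": with_motif, "without_motif": without_motif}
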