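"""Shared fixtures: solved point-source fields (analytic oracle target), an
analytically sampled field solution, and a small 2-subject synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from dbscompare.cohort import CohortSpec, generate_cohort
from dbscompare.evaluate import EvalOptions, run_cohort
from dbscompare.fields import (
    ConductivityMap,
    FieldSolution,
    Grid,
    LeadVoxels,
    SolverOptions,
    VolumeConductor,
    point_source_potential,
)


def make_sphere_conductor(h: float, half: float = 12.0, sigma: float = 0.2):
    """Homogeneous medium with a single metal voxel at the center: the
    numerical analog of a point current source."""
    n = int(round(2 * half / h)) + 1
    grid = Grid(origin=(-half, -half, -half), spacing=h, shape=(n, n, n))
    sig = np.full(grid.shape, sigma)
    center = np.ravel_multi_index((n // 2, n // 2, n // 2), grid.shape)
    lv = LeadVoxels(
        contact_voxels={0: np.array([center])},
        body=np.zeros(grid.shape, bool),
        surface_distance=np.full(grid.shape, np.inf),
    )
    sig.reshape(-1)[center] = 1e3
    cond = ConductivityMap(grid, sig, "df_homogeneous_scar", sigma, lv)
    return VolumeConductor(cond, SolverOptions(spacing=h))


def solve_sphere(h: float, half: float = 12.0, sigma: float = 0.2) -> FieldSolution:
    vc = make_sphere_conductor(h, half, sigma)
    phi = vc.unit_solution(0)
    return FieldSolution(
        grid=vc.grid,
        potential=phi,
        conductivity=vc.cond,
        contact_currents_mA={0: 1.0},
    )


@pytest.fixture(scope="session")
def sphere_solution_05() -> FieldSolution:
    return solve_sphere(0.5)


@pytest.fixture(scope="session")
def sphere_solution_025() -> FieldSolution:
    return solve_sphere(0.25)


def analytic_point_solution(
    current_mA: float = 1.0, sigma: float = 0.2, h: float = 0.1, half: float = 3.0
) -> FieldSolution:
    """Field solution whose potential is the exact closed form (no solver):
    the independent oracle for predictor-level tests."""
    n = int(round(2 * half / h)) + 1
    grid = Grid(origin=(-half, -half, -half), spacing=h, shape=(n, n, n))
    r = np.linalg.norm(grid.voxel_centers(), axis=-1)
    r = np.maximum(r, h / 2.0)
    phi = point_source_potential(current_mA, sigma, r)
    center = np.ravel_multi_index((n // 2, n // 2, n // 2), grid.shape)
    lv = LeadVoxels(
        contact_voxels={0: np.array([center])},
        body=np.zeros(grid.shape, bool),
        surface_distance=np.full(grid.shape, np.inf),
    )
    cond = ConductivityMap(grid, np.full(grid.shape, sigma), "df_homogeneous_scar", sigma, lv)
    return FieldSolution(grid=grid, potential=phi, conductivity=cond,
                         contact_currents_mA={0: current_mA})


@pytest.fixture(scope="session")
def analytic_solution() -> FieldSolution:
    return analytic_point_solution()


COARSE_EVAL = EvalOptions(vta_solver=SolverOptions(spacing=1.0, padding=7.0))


@pytest.fixture(scope="session")
def fixture_cohort():
    spec = CohortSpec(n_subjects=2, seed=5, fibers_per_bundle=30)
    subjects = generate_cohort(spec, eval_options=COARSE_EVAL)
    return spec, subjects, COARSE_EVAL


@pytest.fixture(scope="session")
def fixture_activations(fixture_cohort):
    _, subjects, options = fixture_cohort
    return run_cohort(subjects, options=options)
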