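"""VTA construction, overlap metrics, streamline intersection, and the
driving-force threshold predictor."""

import math

import numpy as np
import pytest

from conftest import analytic_point_solution

from dbscompare.fields import FieldSolution
from dbscompare.predictors import (
    ExcitationParams,
    FiberThresholds,
    activating_function,
    build_vta,
    driving_force_profile,
    fiber_threshold,
    fibers_through_vta,
    internodal_length_mm,
    percent_fibers_activated,
    points_to_voxels,
    structure_overlap_vertices,
    structure_overlap_voxels,
)
from dbscompare.leads import StimSetting

VTA_TH = 0.2  # V/mm
R_CLOSED_FORM = math.sqrt(1.0 / (4 * math.pi * 0.2 * VTA_TH))  # 1.4105 mm at 1 mA


def _mask_radius(vta) -> float:
    return (3.0 * vta.volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


class TestVTA:
    def test_point_source_vta_radius_matches_closed_form(self, analytic_solution):
        vta = build_vta(analytic_solution, VTA_TH)
        assert abs(_mask_radius(vta) - R_CLOSED_FORM) < analytic_solution.grid.spacing

    def test_threshold_above_max_gives_empty_mask(self, analytic_solution):
        vta = build_vta(analytic_solution, 1e9)
        assert vta.empty and vta.volume_mm3 == 0.0

    def test_volume_monotone_in_amplitude(self, analytic_solution):
        sols = [analytic_point_solution(current_mA=a) for a in (1.0, 2.0, 4.0)]
        vols = [build_vta(s, VTA_TH).volume_mm3 for s in sols]
        assert vols[0] < vols[1] < vols[2]

    def test_disconnected_suprathreshold_island_dropped(self, analytic_solution):
        sol = analytic_solution
        e = sol.efield_magnitude.copy()
        e[0:3, 0:3, 0:3] = 10.0  # far corner island, not connected to the contact
        hacked = FieldSolution(
            grid=sol.grid, potential=sol.potential, conductivity=sol.conductivity,
            contact_currents_mA=sol.contact_currents_mA, _efield=e,
        )
        vta = build_vta(hacked, VTA_TH)
        assert not vta.mask[0, 0, 0]


class TestOverlapMetrics:
    def test_structure_subset_and_disjoint(self, analytic_solution):
        vta = build_vta(analytic_solution, VTA_TH)
        inside = np.zeros(vta.grid.shape, bool)
        c = vta.grid.shape[0] // 2
        inside[c - 2 : c + 3, c - 2 : c + 3, c - 2 : c + 3] = True  # 0.5 mm box at center
        assert structure_overlap_voxels(vta, inside & vta.mask) == 100.0
        outside = np.zeros_like(inside)
        outside[:4, :4, :4] = True
        assert structure_overlap_voxels(vta, outside) == 0.0

    def test_counting_toy_structure(self, analytic_solution):
        vta = build_vta(analytic_solution, VTA_TH)
        flat_in = np.flatnonzero(vta.mask.reshape(-1))[:4]
        flat_out = np.flatnonzero(~vta.mask.reshape(-1))[:4]
        st = np.zeros(vta.grid.n_voxels, bool)
        st[flat_in] = st[flat_out] = True
        assert structure_overlap_voxels(vta, st.reshape(vta.grid.shape)) == 50.0

    def test_empty_structure_rejected(self, analytic_solution):
        vta = build_vta(analytic_solution, VTA_TH)
        with pytest.raises(ValueError):
            structure_overlap_voxels(vta, np.zeros(vta.grid.shape, bool))

    def test_vertices_inside_and_halfspace(self, analytic_solution):
        vta = build_vta(analytic_solution, VTA_TH)
        verts = np.array([[0.0, 0.0, 0.3], [0.3, 0.0, 0.0], [0.0, 0.2, 0.1]])
        assert structure_overlap_vertices(vta, verts) == 100.0
        half = np.array([[0.0, 0.0, 0.2], [0.0, 0.0, 2.9]])  # one in, one out
        assert structure_overlap_vertices(vta, half) == 50.0

    def test_boundary_vertex_floor_convention(self):
        from dbscompare.fields import Grid

        grid = Grid(origin=(0.0, 0.0, 0.0), spacing=0.5, shape=(8, 8, 8))
        # the face between voxels 0 and 1 is at 0.25: assigned to voxel 1
        p = np.array([[0.25, 0.0, 0.0]])
        assert points_to_voxels(p, grid)[0, 0] == 1

    def test_empty_mesh_rejected(self, analytic_solution):
        vta = build_vta(analytic_solution, VTA_TH)
        with pytest.raises(ValueError):
            structure_overlap_vertices(vta, np.empty((0, 3)))


def _line(p0, direction, length=12.0, n=25):
    direction = np.asarray(direction, float)
    direction /= np.linalg.norm(direction)
    t = np.linspace(-length / 2, length / 2, n)[:, None]
    return np.asarray(p0, float) + t * direction


class TestFibersThroughVTA:
    def test_counting(self, analytic_solution):
        vta = build_vta(analytic_solution, VTA_TH)  # radius ~1.4 mm sphere
        fibers = [
            _line((0.5, 0, 0), (0, 0, 1)),  # crosses
            _line((0, 1.0, 0), (1, 0, 0)),  # crosses
            _line((0, 2.8, 0), (1, 0, 0)),  # tangent outside
            _line((2.9, 0, 0), (0, 1, 1)),  # outside
        ]
        assert fibers_through_vta(vta, fibers) == 50.0

    def test_empty_mask_and_empty_pathway(self, analytic_solution):
        empty = build_vta(analytic_solution, 1e9)
        assert fibers_through_vta(empty, [_line((0, 0, 0), (0, 0, 1))]) == 0.0
        vta = build_vta(analytic_solution, VTA_TH)
        with pytest.raises(ValueError):
            fibers_through_vta(vta, [])

    def test_tangent_line_beyond_radius_not_counted(self, analytic_solution):
        # 2 mm-radius spherical mask, line at 3 mm: brute-force point checks agree
        vta = build_vta(analytic_solution, VTA_TH)
        r = np.linalg.norm(vta.grid.voxel_centers(), axis=-1)
        vta.mask = r <= 2.0
        line = _line((3.0, 0, 0), (0, 1, 0), length=20.0, n=101)
        assert fibers_through_vta(vta, [line]) == 0.0

    def test_matches_brute_force_oracle(self, analytic_solution):
        """Any-point inclusion equals exhaustive point-in-mask testing at 10x
        finer resampling on a 20-fiber instance."""
        vta = build_vta(analytic_solution, VTA_TH)
        rng = np.random.default_rng(11)
        fibers = [
            _line(rng.uniform(-2.5, 2.5, 3), rng.normal(size=3), length=10.0, n=40)
            for _ in range(20)
        ]
        got = fibers_through_vta(vta, fibers)
        # independent oracle: dense points, floor-convention voxel lookup
        h = vta.grid.spacing / 10.0
        hits = 0
        for f in fibers:
            seg = np.diff(f, axis=0)
            inside = False
            for p0, d in zip(f[:-1], seg):
                L = np.linalg.norm(d)
                for t in np.arange(0.0, L + h, h):
                    p = p0 + d * min(t / L, 1.0)
                    ijk = [
                        math.floor((p[k] - vta.grid.origin[k]) / vta.grid.spacing + 0.5)
                        for k in range(3)
                    ]
                    if all(0 <= ijk[k] < vta.grid.shape[k] for k in range(3)) and vta.mask[
                        tuple(ijk)
                    ]:
                        inside = True
                        break
                if inside:
                    break
            hits += inside
        assert got == pytest.approx(100.0 * hits / len(fibers))


class TestDrivingForce:
    def test_second_difference_annihilates_affine(self):
        v = 3.0 + 0.7 * np.arange(10)
        assert np.allclose(activating_function(v), 0.0, atol=1e-12)

    def test_hand_check_on_closed_form_potentials(self):
        # cathodic point source, node at 1 mm with neighbors at +-1 mm along the fiber
        v = -np.array([0.28145, 0.39789, 0.28145])
        f = activating_function(v)
        assert f[0] == pytest.approx(0.2329, abs=1e-3)
        assert f[0] > 0  # depolarizing at the nearest node

    def test_profile_on_sampled_field_matches_hand_value(self):
        sol = analytic_point_solution(current_mA=-1.0, sigma=0.2, h=0.05, half=2.5)
        fiber = _line((1.0, 0, 0), (0, 1, 0), length=4.0, n=81)
        prof = driving_force_profile(sol, fiber, diameter_um=10.0, phase=2.0)  # L = 1 mm
        assert prof.max() == pytest.approx(0.2329, abs=0.01)

    def test_linear_potential_along_straight_fiber_gives_zero(self, analytic_solution):
        grad = FieldSolution(
            grid=analytic_solution.grid,
            potential=analytic_solution.grid.voxel_centers()[..., 0] * 0.1,
            conductivity=analytic_solution.conductivity,
            contact_currents_mA={0: 1.0},
        )
        fiber = _line((0, 0, 0), (1, 1, 0), length=4.0)
        prof = driving_force_profile(grad, fiber, diameter_um=5.0)
        assert np.allclose(prof, 0.0, atol=1e-9)

    def test_short_fiber_flagged_unevaluable(self, analytic_solution):
        stub = _line((1, 0, 0), (0, 1, 0), length=1.0, n=12)
        with pytest.raises(ValueError, match="unevaluable"):
            driving_force_profile(analytic_solution, stub, diameter_um=12.0)
        assert fiber_threshold(analytic_solution, stub, 12.0, 60.0) == np.inf

    def test_wider_spacing_increases_drive_near_point_source(self):
        sol = analytic_point_solution(current_mA=-1.0, h=0.05, half=2.5)
        fiber = _line((1.0, 0, 0), (0, 1, 0), length=4.5, n=91)
        ex = ExcitationParams(n_phases=16)
        th_thin = fiber_threshold(sol, fiber, 5.0, 60.0, ex)
        th_thick = fiber_threshold(sol, fiber, 10.0, 60.0, ex)
        assert th_thick < th_thin

    def test_threshold_reciprocal_in_peak_drive(self):
        solA = analytic_point_solution(current_mA=-2.0, h=0.1, half=2.5)
        solB = analytic_point_solution(current_mA=-1.0, h=0.1, half=2.5)
        fiber = _line((1.0, 0, 0), (0, 1, 0), length=4.0)
        a = fiber_threshold(solA, fiber, 8.0, 60.0)
        b = fiber_threshold(solB, fiber, 8.0, 60.0)
        assert a == pytest.approx(b / 2.0, rel=1e-9)

    def test_df_linearity_scaling_potentials_scales_thresholds(self):
        sol = analytic_point_solution(current_mA=-1.0, h=0.1, half=2.5)
        scaled = FieldSolution(
            grid=sol.grid, potential=3.0 * sol.potential,
            conductivity=sol.conductivity, contact_currents_mA=sol.contact_currents_mA,
        )
        fiber = _line((0.8, 0, 0), (0, 1, 0), length=4.0)
        assert fiber_threshold(scaled, fiber, 6.0, 60.0) == pytest.approx(
            fiber_threshold(sol, fiber, 6.0, 60.0) / 3.0, rel=1e-9
        )

    def test_threshold_nonincreasing_in_pulse_width(self):
        sol = analytic_point_solution(current_mA=-1.0, h=0.1, half=2.5)
        fiber = _line((1.0, 0, 0), (0, 1, 0), length=4.0)
        ths = [fiber_threshold(sol, fiber, 6.0, pw) for pw in (30.0, 60.0, 120.0)]
        assert ths == sorted(ths, reverse=True)

    def test_internodal_convention(self):
        assert internodal_length_mm(4.0) == pytest.approx(0.4)
        assert internodal_length_mm(12.0) == pytest.approx(1.2)


class TestPercentActivated:
    def _th(self, values):
        return FiberThresholds("p", np.asarray(values, float), 4.0, 60.0)

    def test_counting(self):
        s = StimSetting(cathodes=(0,), anodes=(), amplitude_mA=2.0)
        assert percent_fibers_activated(self._th([0.5, 1.5, 2.5, 3.5]), s) == 50.0

    def test_all_below_and_all_above(self):
        low = StimSetting(cathodes=(0,), anodes=(), amplitude_mA=0.1)
        hi = StimSetting(cathodes=(0,), anodes=(), amplitude_mA=10.0)
        th = self._th([0.5, 1.5, 2.5])
        assert percent_fibers_activated(th, low) == 0.0
        assert percent_fibers_activated(th, hi) == 100.0

    def test_infinite_thresholds_never_activate(self):
        s = StimSetting(cathodes=(0,), anodes=(), amplitude_mA=5.0)
        assert percent_fibers_activated(self._th([np.inf, 1.0]), s) == 50.0
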