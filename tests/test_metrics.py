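"""Morphometrics against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import embryophase as ep
from embryophase.errors import FitError
from embryophase.metrics import (
    CONSERVED_CONTACT,
    CONSERVED_NON_CONTACT,
    UNCONSERVED,
    ContactMap,
    classify_conserved,
    surface_area_isosurface,
)

from conftest import make_unit_grid, tanh_sphere


def ellipsoid_field(grid, center, semi_axes, k=np.sqrt(0.5)):
    """Level-set tanh field of an axis-aligned ellipsoid."""
    x, y, z = grid.meshgrid()
    a, b, c = semi_axes
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2)
    gn = np.sqrt((dx / a**2) ** 2 + (dy / b**2) ** 2 + (dz / c**2) ** 2)
    d = np.where(gn > 0, (rho - 1.0) * rho / np.maximum(gn, 1e-300), -min(a, b, c))
    return ep.PhaseField(0.5 * (1.0 + np.tanh(k * (-d))), grid)


def ellipsoid_alpha_quadrature(semi_axes, n_theta=400, n_phi=800):
    """Dense parametric surface quadrature of the deformation integral."""
    a, b, c = semi_axes
    V = 4.0 / 3.0 * np.pi * a * b * c
    rbar = (3.0 * V / (4 * np.pi)) ** (1 / 3)
    th = np.linspace(0, np.pi, n_theta)
    phv = np.linspace(0, 2 * np.pi, n_phi)
    T, P = np.meshgrid(th, phv, indexing="ij")
    X, Y, Z = a * np.sin(T) * np.cos(P), b * np.sin(T) * np.sin(P), c * np.cos(T)
    Xt, Yt, Zt = a * np.cos(T) * np.cos(P), b * np.cos(T) * np.sin(P), -c * np.sin(T)
    Xp, Yp = -a * np.sin(T) * np.sin(P), b * np.sin(T) * np.cos(P)
    cr = np.stack([Yt * 0 - Zt * Yp, Zt * Xp - Xt * 0, Xt * Yp - Yt * Xp])
    dS = np.linalg.norm(cr, axis=0)
    R = np.sqrt(X**2 + Y**2 + Z**2)
    integ = (R - rbar) ** 2 / (rbar**2 * R**2) * dS
    return float(np.trapezoid(np.trapezoid(integ, phv, axis=1), th))


class TestDeformationAlpha:
    def test_sphere_is_nearly_undeformed(self):
        grid = make_unit_grid()
        f = tanh_sphere(grid, (19.5, 19.5, 19.5), 12.0)
        cell = ep.CellState("c", f, f.volume_um3())
        assert ep.deformation_alpha(cell) < 1e-2

    def test_scale_invariance(self):
        alpha = {}
        for radius, dims in [(8.0, (40, 40, 40)), (16.0, (80, 80, 80))]:
            grid = ep.GridSpec(dims, dl=1.0)
            c = ((dims[0] - 1) / 2.0,) * 3
            f = ellipsoid_field(grid, c, (1.6 * radius, radius, radius))
            cell = ep.CellState("c", f, f.volume_um3())
            alpha[radius] = ep.deformation_alpha(cell)
        assert alpha[8.0] == pytest.approx(alpha[16.0], rel=0.15)

    def test_ellipsoid_matches_quadrature_oracle(self):
        grid = ep.GridSpec((64, 48, 48), dl=1.0)
        a = 10.0
        f = ellipsoid_field(grid, (31.5, 23.5, 23.5), (2 * a, a, a))
        cell = ep.CellState("c", f, f.volume_um3())
        oracle = ellipsoid_alpha_quadrature((2 * a, a, a))
        assert ep.deformation_alpha(cell) == pytest.approx(oracle, rel=0.05)


class TestSurfaceArea:
    def test_tanh_sphere_within_three_percent(self):
        grid = make_unit_grid()
        for r in (10.0, 12.0):
            f = tanh_sphere(grid, (19.5, 19.5, 19.5), r)
            cell = ep.CellState("c", f, f.volume_um3())
            assert ep.surface_area(cell) == pytest.approx(4 * np.pi * r**2, rel=0.03)

    def test_quadratic_scaling(self):
        g1 = ep.GridSpec((40, 40, 40), dl=1.0)
        g2 = ep.GridSpec((80, 80, 80), dl=1.0)
        f1 = tanh_sphere(g1, (19.5, 19.5, 19.5), 8.0)
        f2 = tanh_sphere(g2, (39.5, 39.5, 39.5), 16.0)
        a1 = ep.surface_area(ep.CellState("a", f1, 1.0))
        a2 = ep.surface_area(ep.CellState("b", f2, 1.0))
        assert a2 == pytest.approx(4 * a1, rel=0.03)

    def test_zero_field(self):
        grid = ep.GridSpec((10, 10, 10), dl=1.0)
        assert ep.surface_area(ep.CellState("c", ep.PhaseField(np.zeros((10,) * 3), grid), 1.0)) == 0.0

    def test_gradient_and_isosurface_estimators_agree(self):
        grid = make_unit_grid()
        f = tanh_sphere(grid, (19.5, 19.5, 19.5), 11.0)
        cell = ep.CellState("c", f, f.volume_um3())
        assert ep.surface_area(cell) == pytest.approx(
            surface_area_isosurface(cell), rel=0.05
        )


class TestPositionalVariation:
    def test_identical_zero(self):
        pts = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6])]
        assert ep.positional_variation_eta(pts, pts) == 0.0

    def test_single_offset_example(self):
        sim = [np.zeros(3), np.zeros(3), np.zeros(3)]
        exp = [np.array([3.0, 0, 0]), np.zeros(3), np.zeros(3)]
        assert ep.positional_variation_eta(sim, exp) == pytest.approx(3.0)

    def test_matches_brute_force_and_scales_quadratically(self):
        rng = np.random.default_rng(11)
        sim = rng.normal(size=(5, 3))
        exp = rng.normal(size=(5, 3))
        brute = sum(((s - e) ** 2).sum() for s, e in zip(sim, exp)) / 5
        eta = ep.positional_variation_eta(sim, exp)
        assert eta == pytest.approx(brute)
        assert ep.positional_variation_eta(3 * sim, 3 * exp) == pytest.approx(9 * eta)


class TestRelativeError:
    def test_basic_values(self):
        assert ep.relative_error_delta(5.0, 5.0) == 0.0
        assert ep.relative_error_delta(10.0, 5.0) == 1.0
        # an overshoot to ~2x the measured value reads as delta > 0.91
        assert ep.relative_error_delta(1.95, 1.0) > 0.91

    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, s0, s, scale):
        d1 = ep.relative_error_delta(s0, s)
        d2 = ep.relative_error_delta(scale * s0, scale * s)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestContacts:
    def test_half_space_slabs_full_cross_section(self):
        grid = ep.GridSpec((16, 64, 64), dl=1.0)
        a = np.zeros(grid.dims)
        b = np.zeros(grid.dims)
        a[:8] = 1.0
        b[8:] = 1.0
        ca = ep.CellState("a", ep.PhaseField(a, grid), 1.0)
        cb = ep.CellState("b", ep.PhaseField(b, grid), 1.0)
        assert ep.contact_area(ca, cb) == 4096.0

    def test_disjoint_cells_absent(self):
        grid = make_unit_grid()
        a = tanh_sphere(grid, (10.5, 19.5, 19.5), 5.0)
        b = tanh_sphere(grid, (29.5, 19.5, 19.5), 5.0)
        ca = ep.CellState("a", a, 1.0)
        cb = ep.CellState("b", b, 1.0)
        assert ep.contact_area(ca, cb) == 0.0
        shell = ep.PhaseField(np.zeros(grid.dims), grid)
        cmap = ep.contact_map(ep.EmbryoState([ca, cb], shell, grid))
        assert not cmap.pairs

    def test_doublet_contact_vs_isosurface_oracle(self, doublet_scan):
        """Voxel-face contact area within 10% of a triangulated-interface
        oracle on the relaxed doublet."""
        from scipy.ndimage import map_coordinates
        from skimage.measure import marching_cubes

        embryo = doublet_scan["embryos"][0.9]
        a = embryo.cell("AB").field
        b = embryo.cell("P1").field
        area = ep.contact_area(embryo.cell("AB"), embryo.cell("P1"))
        # oracle: triangulated midsurface phi_a = phi_b, clipped to the
        # overlap band where the two cells together dominate the exterior
        verts, faces, _, _ = marching_cubes(a.values - b.values, level=0.0)
        tri = verts[faces]
        centroids = tri.mean(axis=1)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        tri_areas = 0.5 * np.linalg.norm(cross, axis=1)
        total = map_coordinates(a.values + b.values, centroids.T, order=1)
        oracle = float(tri_areas[total > 0.6].sum()) * a.grid.dl**2
        assert area == pytest.approx(oracle, rel=0.10)

    def test_contact_map_symmetric_and_deterministic(self, doublet_scan):
        embryo = doublet_scan["embryos"][0.9]
        m1 = ep.contact_map(embryo)
        m2 = ep.contact_map(embryo)
        assert m1.pairs == m2.pairs
        assert m1.area("AB", "P1") == m1.area("P1", "AB")

    def test_no_leakage_outside_eggshell(self, doublet_scan):
        """Labelled cell volume never exceeds the shell interior volume."""
        from embryophase.metrics import label_volume

        embryo = doublet_scan["embryos"][1.5]
        labels = label_volume(embryo)
        cell_voxels = int((labels > 0).sum())
        interior_voxels = int((embryo.eggshell.values < 0.5).sum())
        assert cell_voxels <= interior_voxels


class TestConservedClassification:
    def make_maps(self, presence):
        """presence: list per sample of bool for pair (a, b)."""
        maps = []
        for has in presence:
            pairs = {frozenset(("a", "b"))} if has else set()
            maps.append(ContactMap(pairs, {}, 0.0, ("a", "b")))
        return maps

    def test_ternary_rule(self):
        cls = classify_conserved(self.make_maps([True] * 4))
        assert cls.of("a", "b") == CONSERVED_CONTACT
        cls = classify_conserved(self.make_maps([False] * 4))
        assert cls.of("a", "b") == CONSERVED_NON_CONTACT
        cls = classify_conserved(self.make_maps([True, True, False, False]))
        assert cls.of("a", "b") == UNCONSERVED

    @given(st.permutations([True, True, False, True]))
    @settings(max_examples=24, deadline=None)
    def test_permutation_invariance(self, order):
        cls = classify_conserved(self.make_maps(list(order)))
        assert cls.of("a", "b") == UNCONSERVED
        assert cls.n_contact[frozenset(("a", "b"))] == 3


class TestPathSignature:
    def test_constant_map_collapses(self):
        m = ContactMap({frozenset(("a", "b"))}, {}, 0.0, ("a", "b"))
        assert len(ep.path_signature([m, m, m])) == 1

    def test_single_change_two_states(self):
        m1 = ContactMap({frozenset(("a", "b"))}, {}, 0.0, ("a", "b"))
        m2 = ContactMap(set(), {}, 0.0, ("a", "b"))
        sig = ep.path_signature([m1, m1, m2, m2])
        assert len(sig) == 2
        assert sig[0] == frozenset({frozenset(("a", "b"))})


class TestEmbryoWidth:
    def test_examples(self):
        assert ep.embryo_width([np.array([0.0, 5.0, 0.0])]) == 0.0
        pts = [np.array([0, 1.0, 0]), np.array([0, 4.0, 0]), np.array([0, 6.0, 0])]
        assert ep.embryo_width(pts) == 5.0

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        brute = max(abs(p[1] - q[1]) for p in pts for q in pts)
        assert ep.embryo_width(pts) == pytest.approx(brute)


class TestTimescale:
    def test_noiseless_fit_exact(self):
        k = 16000.0
        exp = np.array([4.0, 6.5, 10.0])
        sim = k * (exp - 2.2784)
        fit = ep.fit_timescale(sim, exp)
        assert fit.k == pytest.approx(k, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_within_ten_percent(self):
        rng = np.random.default_rng(123)
        k = 16000.0
        exp = np.array([3.5, 5.0, 8.0, 12.0])
        sim = k * (exp - 2.2784) * (1 + rng.normal(0, 0.05, exp.size))
        fit = ep.fit_timescale(sim, exp)
        assert fit.k == pytest.approx(k, rel=0.10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            ep.fit_timescale([100.0], [5.0])
        with pytest.raises(FitError):
            ep.fit_timescale([1.0, 2.0], [5.0, 5.0])

    def test_steps_to_minutes_identities(self):
        fit = ep.TimescaleFit(k=1.6735e4, r_squared=1.0, delta_t0=2.2784)
        assert ep.steps_to_minutes(0, fit) == 0.0
        assert ep.steps_to_minutes(fit.k, fit) == pytest.approx(1.0)
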