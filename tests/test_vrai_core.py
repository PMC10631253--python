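"""The 2D reduction, mode orientation, stream width, and Gaussian partition."""

import numpy as np
import pytest
from scipy.stats import norm

from dynaselect.errors import DegenerateInputError, ValidationError
from dynaselect.io_qc import Geometry, NormalModeSet, StationaryPoint
from dynaselect.vrai_core import (
    BondCoordinateSet,
    ProjectedPES2D,
    StreamWidth,
    orient_imaginary_mode,
    predict_multi_product_ratio,
    predict_two_product_ratio,
    project_to_2d,
    select_bond_coordinates,
    stream_width,
)
from dynaselect.vrai_core import _two_product_analysis


def geom4(r_co=1.4, r_cc=1.5):
    """Four heavy atoms; pair (0,1) is C-O, pair (2,3) is C-C, far apart."""
    return Geometry(
        ["C", "O", "C", "C"],
        np.array(
            [
                [0.0, 0.0, 0.0],
                [r_co, 0.0, 0.0],
                [0.0, 50.0, 0.0],
                [0.0, 50.0, r_cc],
            ]
        ),
    )


class TestBondSelection:
    def test_selects_exactly_the_changing_pairs(self):
        p1 = geom4(1.4, 1.5)
        p2 = geom4(2.8, 2.6)
        ts = geom4(1.6, 1.7)
        coords = select_bond_coordinates(geom4(1.8, 1.9), [p1, p2], ts, threshold=0.3)
        assert sorted(coords.atom_pairs) == [(0, 1), (2, 3)]

    def test_identical_products_are_degenerate(self):
        g = geom4()
        with pytest.raises(DegenerateInputError):
            select_bond_coordinates(g, [g, g], g, threshold=0.3)

    def test_threshold_halving_recovers_small_changes(self):
        # differences of 0.02 A need three halvings of the 0.1 A threshold
        p1 = geom4(1.40, 1.50)
        p2 = geom4(1.42, 1.52)
        coords = select_bond_coordinates(geom4(), [p1, p2], geom4(), threshold=0.1)
        assert sorted(coords.atom_pairs) == [(0, 1), (2, 3)]
        assert coords.selection_threshold < 0.1

    def test_embedded_fixture_recovers_ground_truth_pairs(self, symmetric_fixture):
        net = symmetric_fixture.network
        coords = select_bond_coordinates(
            net.points["INT2"].geometry,
            [net.points["P1"].geometry, net.points["P2"].geometry],
            net.points["TS1"].geometry,
        )
        assert sorted(coords.atom_pairs) == sorted(symmetric_fixture.reactive_pairs)


class TestProjection:
    def _plane(self, fixture):
        net = fixture.network
        coords = select_bond_coordinates(
            net.points["INT2"].geometry,
            [net.points["P1"].geometry, net.points["P2"].geometry],
            net.points["TS1"].geometry,
        )
        plane = project_to_2d(
            net.points["TS1"], net.points["INT2"],
            [net.points["P1"], net.points["P2"]], coords,
        )
        return net, coords, plane

    def test_intermediate_is_origin_and_g_vec_definition(self, symmetric_fixture):
        _, _, plane = self._plane(symmetric_fixture)
        assert np.allclose(plane.origin, 0.0)
        assert np.allclose(plane.g_vec, -plane.ts_position)

    def test_basis_is_orthonormal(self, tilted_fixture):
        _, _, plane = self._plane(tilted_fixture)
        assert np.allclose(plane.basis @ plane.basis.T, np.eye(2), atol=1e-10)

    def test_projection_is_a_contraction(self, tilted_fixture):
        net, coords, plane = self._plane(tilted_fixture)
        geoms = [p.geometry for p in net.points.values()]
        for a in geoms:
            for b in geoms:
                full = coords.distances(a) - coords.distances(b)
                assert np.linalg.norm(plane.project(full)) <= np.linalg.norm(full) + 1e-12

    def test_parallel_product_directions_are_degenerate(self):
        ts, int_g = geom4(1.6, 1.7), geom4(1.8, 1.9)
        p1 = geom4(2.4, 1.9)  # both products move only along the C-O coordinate
        p2 = geom4(1.2, 1.9)
        coords = BondCoordinateSet([(0, 1), (2, 3)], 0.3)
        sp = lambda lbl, g: StationaryPoint(lbl, "product", g, 0.0)
        with pytest.raises(DegenerateInputError, match="parallel"):
            project_to_2d(ts, int_g, [sp("P1", p1), sp("P2", p2)], coords)


class TestImaginaryModeOrientation:
    def test_sign_fixed_toward_intermediate(self, tilted_fixture):
        net = tilted_fixture.network
        ts = net.points["TS1"]
        coords = select_bond_coordinates(
            net.points["INT2"].geometry,
            [net.points["P1"].geometry, net.points["P2"].geometry],
            ts.geometry,
        )
        plane = project_to_2d(ts, net.points["INT2"],
                              [net.points["P1"], net.points["P2"]], coords)
        a = orient_imaginary_mode(ts, plane, coords)
        assert float(np.dot(a, plane.g_vec)) >= 0
        # flipping the stored eigenvector must not change the oriented result
        flipped = StationaryPoint(
            ts.label, ts.role, ts.geometry, ts.gibbs_free_energy,
            modes=NormalModeSet(
                ts.modes.frequencies, -ts.modes.displacements, ts.modes.convention_tag
            ),
        )
        a2 = orient_imaginary_mode(flipped, plane, coords)
        assert np.allclose(a, a2, atol=1e-12)

    def test_mode_orthogonal_to_plane_is_degenerate(self, symmetric_fixture):
        net = symmetric_fixture.network
        ts = net.points["TS1"]
        coords = select_bond_coordinates(
            net.points["INT2"].geometry,
            [net.points["P1"].geometry, net.points["P2"].geometry],
            ts.geometry,
        )
        plane = project_to_2d(ts, net.points["INT2"],
                              [net.points["P1"], net.points["P2"]], coords)
        # displace atoms 0 and 1 rigidly: no bond-distance rate on any pair
        disp = np.zeros((2, 4, 3))
        disp[0, 0] = disp[0, 1] = [0.0, 1.0, 0.0]
        disp[1, 2, 0] = 1.0  # real mode, perpendicular to both bonds
        bad = StationaryPoint(
            ts.label, ts.role, ts.geometry, ts.gibbs_free_energy,
            modes=NormalModeSet(np.array([-500.0, 400.0]), disp, "cartesian_normalized"),
        )
        with pytest.raises(DegenerateInputError, match="orthogonal"):
            orient_imaginary_mode(bad, plane, coords)


class TestStreamWidth:
    @pytest.mark.parametrize(
        "wavenumber,expected_A",
        [(3000.0, 0.0750), (1000.0, 0.130)],
    )
    def test_zero_point_width_closed_form(self, wavenumber, expected_A):
        from dynaselect.constants import harmonic_sigma_zero_point

        assert harmonic_sigma_zero_point(wavenumber, 1.0) == pytest.approx(
            expected_A, abs=5e-4
        )

    def test_doubling_frequency_shrinks_width_by_sqrt2(self):
        from dynaselect.constants import harmonic_sigma_zero_point

        s1 = harmonic_sigma_zero_point(700.0, 1.0)
        s2 = harmonic_sigma_zero_point(1400.0, 1.0)
        assert s1 / s2 == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_contributions_sum_to_sigma_squared(self, tilted_fixture):
        net = tilted_fixture.network
        ts = net.points["TS1"]
        coords = select_bond_coordinates(
            net.points["INT2"].geometry,
            [net.points["P1"].geometry, net.points["P2"].geometry],
            ts.geometry,
        )
        plane = project_to_2d(ts, net.points["INT2"],
                              [net.points["P1"], net.points["P2"]], coords)
        orient_imaginary_mode(ts, plane, coords)
        width = stream_width(ts, plane, coords)
        total = sum(c for _, c in width.per_mode_contributions)
        assert width.sigma**2 == pytest.approx(total, rel=1e-12)
        assert width.sigma > 0


def synthetic_plane(p1=(1.0, -1.0), p2=(-1.0, -1.0), ts=(0.0, 1.0)):
    return ProjectedPES2D(
        origin=np.zeros(2),
        ts_position=np.array(ts, dtype=float),
        product_positions={"P1": np.array(p1, float), "P2": np.array(p2, float)},
        g_vec=-np.array(ts, dtype=float),
        basis=np.eye(2),
    )


class TestGaussianPartition:
    def test_center_on_ridge_splits_evenly(self):
        plane = synthetic_plane()
        a = np.array([0.0, -1.0])
        width = StreamWidth(0.2, [(500.0, 0.04)])
        res = predict_two_product_ratio(plane, a, width)
        assert res.fractions["P1"] == pytest.approx(0.5)

    @pytest.mark.parametrize("n_sigma,expected", [(1.0, norm.cdf(1.0)), (3.0, norm.cdf(3.0))])
    def test_offset_in_sigma_units_follows_normal_cdf(self, n_sigma, expected):
        sigma = 0.2
        delta = n_sigma * sigma
        a = np.array([delta, -np.sqrt(1.0 - delta**2)])
        plane = synthetic_plane()
        res = predict_two_product_ratio(plane, a, StreamWidth(sigma, [(500.0, sigma**2)]))
        assert res.diagnostics["delta_A"] == pytest.approx(delta, rel=1e-9)
        assert res.fractions["P1"] == pytest.approx(expected, abs=1e-9)
        if n_sigma >= 3:
            assert res.fractions["P1"] >= 0.998

    def test_product_at_intermediate_is_degenerate(self):
        plane = synthetic_plane(p1=(0.0, 0.0))
        with pytest.raises(DegenerateInputError):
            predict_two_product_ratio(
                plane, np.array([0.0, -1.0]), StreamWidth(0.2, [(500.0, 0.04)])
            )


class TestMultiProduct:
    def test_two_products_reduce_to_pairwise_analysis(self, tilted_fixture):
        net = tilted_fixture.network
        args = (net.points["TS1"], net.points["INT2"])
        prods = [net.points["P1"], net.points["P2"]]
        a = predict_multi_product_ratio(*args, prods)
        b = _two_product_analysis(*args, prods[0], prods[1], 298.15, "zero_point", 0.3)
        assert a.fractions == b.fractions

    def test_symmetric_trifurcation_gives_equal_flanker_fractions(self):
        from dynaselect.model_surfaces import embed_as_molecule, make_surface

        fix = embed_as_molecule(make_surface(n_wells=3))
        net = fix.network
        res = predict_multi_product_ratio(
            net.points["TS1"], net.points["INT2"],
            [net.points[k] for k in ("P1", "P2", "P3")],
        )
        assert res.fractions["P1"] == pytest.approx(res.fractions["P2"], abs=1e-9)
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_single_product(self, symmetric_fixture):
        net = symmetric_fixture.network
        with pytest.raises(ValidationError):
            predict_multi_product_ratio(
                net.points["TS1"], net.points["INT2"], [net.points["P1"]]
            )
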