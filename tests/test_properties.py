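"""Randomized property tests for the package-wide invariants.

Each invariant runs under hypothesis with at least 200 derandomized cases:
fraction normalization, rigid-motion invariance, atom-relabeling invariance,
Sankey flow conservation, the coverage prefix property, and the
energy-check branching rule.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynaselect.io_qc import Geometry, StationaryPoint
from dynaselect.pipeline import RunSettings, run_selectivity_pipeline
from dynaselect.thermo import boltzmann_weights, energy_check, select_top_coverage
from dynaselect.vrai_core import (
    ProjectedPES2D,
    StreamWidth,
    predict_two_product_ratio,
    _two_product_analysis,
)

from .conftest import build_network, toy_point

COMMON = dict(max_examples=200, deadline=None, derandomize=True)


def rotation_matrix(angles):
    ax, ay, az = angles
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def transform_point(sp, rot, shift):
    geom = Geometry(
        sp.geometry.atom_symbols,
        sp.geometry.coordinates @ rot.T + shift,
        sp.geometry.masses,
    )
    modes = sp.modes
    if modes is not None:
        from dynaselect.io_qc import NormalModeSet

        modes = NormalModeSet(
            modes.frequencies, modes.displacements @ rot.T, modes.convention_tag
        )
    return StationaryPoint(sp.label, sp.role, geom, sp.gibbs_free_energy, modes,
                           sp.stereochem)


def permute_point(sp, perm):
    geom = Geometry(
        [sp.geometry.atom_symbols[i] for i in perm],
        sp.geometry.coordinates[perm],
        sp.geometry.masses[perm],
    )
    modes = sp.modes
    if modes is not None:
        from dynaselect.io_qc import NormalModeSet

        modes = NormalModeSet(
            modes.frequencies, modes.displacements[:, perm, :], modes.convention_tag
        )
    return StationaryPoint(sp.label, sp.role, geom, sp.gibbs_free_energy, modes,
                           sp.stereochem)


class TestFractionNormalization:
    @given(
        offset=st.floats(-3, 3),
        sigma=st.floats(0.01, 1.0),
        spread=st.floats(0.2, 2.0),
        tilt_deg=st.floats(-60, 60),
    )
    @settings(**COMMON)
    def test_partition_fractions_always_normalized(self, offset, sigma, spread, tilt_deg):
        ang = np.deg2rad(tilt_deg)
        plane = ProjectedPES2D(
            origin=np.zeros(2),
            ts_position=np.array([0.0, 1.0]),
            product_positions={
                "P1": np.array([spread, -1.0]),
                "P2": np.array([-spread * np.cos(ang) - 0.0, -1.0 + np.sin(ang)]),
            },
            g_vec=np.array([0.0, -1.0]),
            basis=np.eye(2),
        )
        a = np.array([np.sin(np.arctan(offset)), -np.cos(np.arctan(offset))])
        res = predict_two_product_ratio(plane, a, StreamWidth(sigma, [(500.0, sigma**2)]))
        vals = np.array(list(res.fractions.values()))
        assert np.all(vals >= 0)
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)


class TestGeometricInvariance:
    @given(
        angles=st.tuples(*[st.floats(0, 2 * np.pi)] * 3),
        shift=st.tuples(*[st.floats(-30, 30)] * 3),
    )
    @settings(**COMMON)
    def test_rigid_motion_leaves_fractions_unchanged(self, tilted_fixture, angles, shift):
        net = tilted_fixture.network
        rot, t = rotation_matrix(angles), np.array(shift)
        base = _two_product_analysis(
            net.points["TS1"], net.points["INT2"], net.points["P1"], net.points["P2"],
            298.15, "zero_point", 0.3,
        )
        moved = {k: transform_point(p, rot, t) for k, p in net.points.items()}
        res = _two_product_analysis(
            moved["TS1"], moved["INT2"], moved["P1"], moved["P2"],
            298.15, "zero_point", 0.3,
        )
        for k in base.fractions:
            assert res.fractions[k] == pytest.approx(base.fractions[k], abs=1e-9)

    @given(perm_seed=st.integers(0, 10_000))
    @settings(**COMMON)
    def test_consistent_atom_relabeling_leaves_fractions_unchanged(
        self, tilted_fixture, perm_seed
    ):
        net = tilted_fixture.network
        perm = np.random.default_rng(perm_seed).permutation(4)
        base = _two_product_analysis(
            net.points["TS1"], net.points["INT2"], net.points["P1"], net.points["P2"],
            298.15, "zero_point", 0.3,
        )
        moved = {k: permute_point(p, perm) for k, p in net.points.items()}
        res = _two_product_analysis(
            moved["TS1"], moved["INT2"], moved["P1"], moved["P2"],
            298.15, "zero_point", 0.3,
        )
        for k in base.fractions:
            assert res.fractions[k] == pytest.approx(base.fractions[k], abs=1e-9)

    def test_swapping_product_labels_swaps_fractions(self, tilted_fixture):
        net = tilted_fixture.network
        fwd = _two_product_analysis(
            net.points["TS1"], net.points["INT2"], net.points["P1"], net.points["P2"],
            298.15, "zero_point", 0.3,
        )
        rev = _two_product_analysis(
            net.points["TS1"], net.points["INT2"], net.points["P2"], net.points["P1"],
            298.15, "zero_point", 0.3,
        )
        assert fwd.fractions["P1"] == pytest.approx(rev.fractions["P1"], abs=1e-12)
        assert fwd.fractions["P2"] == pytest.approx(rev.fractions["P2"], abs=1e-12)

    def test_continuity_under_tiny_ts_perturbation(self, tilted_fixture):
        net = tilted_fixture.network
        ts = net.points["TS1"]
        base = _two_product_analysis(
            ts, net.points["INT2"], net.points["P1"], net.points["P2"],
            298.15, "zero_point", 0.3,
        )
        rng = np.random.default_rng(11)
        for _ in range(10):
            bumped = StationaryPoint(
                ts.label, ts.role,
                Geometry(
                    ts.geometry.atom_symbols,
                    ts.geometry.coordinates + rng.uniform(-1e-4, 1e-4, (4, 3)),
                    ts.geometry.masses,
                ),
                ts.gibbs_free_energy, ts.modes,
            )
            res = _two_product_analysis(
                bumped, net.points["INT2"], net.points["P1"], net.points["P2"],
                298.15, "zero_point", 0.3,
            )
            for k in base.fractions:
                assert abs(res.fractions[k] - base.fractions[k]) <= 1e-2


class TestFlowConservation:
    @given(
        e_ts1=st.lists(st.floats(0, 4), min_size=1, max_size=4),
        e_ts2=st.lists(st.floats(0, 3), min_size=2, max_size=4),
        coverage=st.floats(0.5, 1.0),
    )
    @settings(**COMMON)
    def test_sankey_flow_conserved_on_random_networks(self, e_ts1, e_ts2, coverage):
        pts, edges = [], []
        catalog = {}
        for i, e1 in enumerate(e_ts1):
            ts1, intm = f"TS1-{i}", f"INT-{i}"
            pts += [toy_point(ts1, "TS1", e1), toy_point(intm, "INT2", -10.0)]
            edges.append((ts1, intm))
            for j, e2 in enumerate(e_ts2):
                t2, prod = f"TS2-{i}-{j}", f"P{j}"
                pts.append(toy_point(t2, "TS2", e2 - 8.0))
                edges += [(intm, t2), (t2, prod)]
                catalog[prod] = (f"species{j}", None)
        for lbl in catalog:
            pts.append(toy_point(lbl, "product", -30.0))
        # deduplicate product points
        seen, unique = set(), []
        for p in pts:
            if p.label not in seen:
                seen.add(p.label)
                unique.append(p)
        net = build_network(unique, edges, catalog)
        dist = run_selectivity_pipeline(
            net, RunSettings(mode="tst_only", coverage_fraction=coverage)
        )
        edges_out = dist.sankey_edges()
        nodes = {n for e in edges_out for n in e[:2]}
        for node in nodes - {"TS1 ensemble"}:
            inflow = sum(f for s, t, f in edges_out if t == node)
            outflow = sum(f for s, t, f in edges_out if s == node)
            if outflow:
                assert inflow == pytest.approx(outflow, abs=1e-9)
        assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=1e-9)


class TestCoveragePrefix:
    @given(
        energies=st.lists(st.floats(0, 8), min_size=1, max_size=10),
        coverage=st.floats(0.05, 1.0),
    )
    @settings(**COMMON)
    def test_selection_is_a_minimal_renormalized_prefix(self, energies, coverage):
        ens = boltzmann_weights(energies, 298.15)
        top = select_top_coverage(ens, coverage)
        k = len(top.weights)
        assert top.labels == ens.labels[:k]
        assert np.isclose(top.weights.sum(), 1.0, atol=1e-12)
        # the smallest prefix reaching the coverage...
        min_k = min(
            int(np.searchsorted(np.cumsum(ens.weights), coverage - 1e-12)) + 1,
            len(ens.weights),
        )
        assert k >= min_k
        # ...extended only by members tied in energy with the boundary member
        for i in range(min_k, k):
            assert np.isclose(
                ens.rel_energies[i], ens.rel_energies[min_k - 1], atol=1e-12
            )
        # and nothing tied with the boundary is left out
        if k < len(ens.weights):
            assert not np.isclose(
                ens.rel_energies[k], ens.rel_energies[k - 1], atol=1e-12
            )


class TestEnergyCheckBranching:
    @given(
        ts1_e=st.floats(-5, 15),
        ts2_es=st.lists(st.floats(-5, 15), min_size=0, max_size=5),
    )
    @settings(**COMMON)
    def test_vrai_iff_every_downstream_ts_strictly_below(self, ts1_e, ts2_es):
        ts1 = toy_point("TS1", "TS1", ts1_e)
        ts2s = [toy_point(f"TS2-{i}", "TS2", e) for i, e in enumerate(ts2_es)]
        decision = energy_check(ts1, ts2s)
        should_be_vrai = all(e < ts1_e for e in ts2_es)
        assert (decision.method == "VRAI") == should_be_vrai
        if decision.method == "TST_fallback":
            offenders = [t.label for t in ts2s if t.gibbs_free_energy >= ts1_e]
            assert all(lbl in decision.reason for lbl in offenders)
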