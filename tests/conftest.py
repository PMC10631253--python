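"""Shared fixtures: model surfaces, embedded bundles, and toy networks."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from dynaselect.io_qc import Geometry, ReactionNetwork, StationaryPoint
from dynaselect.model_surfaces import embed_as_molecule, make_surface


@pytest.fixture(scope="session")
def symmetric_surface():
    return make_surface()


@pytest.fixture(scope="session")
def symmetric_fixture(symmetric_surface):
    return embed_as_molecule(symmetric_surface)


@pytest.fixture(scope="session")
def tilted_surface():
    return make_surface(tilt=0.05)


@pytest.fixture(scope="session")
def tilted_fixture(tilted_surface):
    return embed_as_molecule(tilted_surface)


def toy_point(
    label: str,
    role: str,
    energy: float,
    stereochem: str | None = None,
    shift: float = 0.0,
) -> StationaryPoint:
    """Minimal stationary point for graph/thermo tests (no modes needed)."""
    geom = Geometry(["C", "O"], np.array([[0.0, 0.0, 0.0], [1.2 + shift, 0.0, 0.0]]))
    return StationaryPoint(label, role, geom, energy, modes=None, stereochem=stereochem)


def build_network(points, edges, catalog, kinds=None, experimental=None, stage0=None):
    """Assemble a ReactionNetwork from toy points."""
    graph = nx.DiGraph()
    graph.add_nodes_from(p.label for p in points)
    graph.add_edges_from(edges)
    return ReactionNetwork(
        points={p.label: p for p in points},
        graph=graph,
        channel_kind=kinds or {},
        product_catalog=catalog,
        experimental_percentages=experimental,
        stage0=stage0,
    )


@pytest.fixture()
def two_stage_network():
    """Two TS1 conformers, each with Boltzmann-competing TS2 channels."""
    pts = [
        toy_point("TS1-a", "TS1", 10.0),
        toy_point("TS1-b", "TS1", 11.0),
        toy_point("INT-a", "INT2", 2.0),
        toy_point("INT-b", "INT2", 2.5),
        toy_point("TS2-a1", "TS2", 5.0),
        toy_point("TS2-a2", "TS2", 5.0),
        toy_point("TS2-b1", "TS2", 6.0),
        toy_point("PA", "product", -20.0),
        toy_point("PB", "product", -18.0),
    ]
    edges = [
        ("TS1-a", "INT-a"), ("INT-a", "TS2-a1"), ("INT-a", "TS2-a2"),
        ("TS2-a1", "PA"), ("TS2-a2", "PB"),
        ("TS1-b", "INT-b"), ("INT-b", "TS2-b1"), ("TS2-b1", "PB"),
    ]
    catalog = {"PA": ("A", None), "PB": ("B", None)}
    return build_network(pts, edges, catalog)
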