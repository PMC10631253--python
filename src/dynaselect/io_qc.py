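"""Stationary-point I/O: XYZ geometries, harmonic normal modes, reaction networks.

A *stationary point* bundles one optimized structure (geometry, Gibbs free
energy on a common kcal/mol reference, and — for transition states and
intermediates — its harmonic normal modes).  A *reaction network* wires
stationary points into the directed pathway graph used by the selectivity
pipeline: first transition states (TS1 conformers) lead through a shared
intermediate to second transition states (TS2) and on to labelled products,
or directly to a product when the post-TS1 channel is barrierless.

Normal modes are accepted from Gaussian-16-style log files (frequency blocks
are parsed, nothing is ever run) or from a portable JSON sidecar::

    {"frequencies_cm1": [...],
     "displacements": [[[dx,dy,dz], ...], ...],
     "convention": "cartesian_normalized" | "mass_weighted"}

Imaginary frequencies are stored as negative wavenumbers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .constants import HARTREE_TO_KCAL, atomic_mass
from .errors import ParseError, ValidationError

TS_ROLES = frozenset({"TS0", "TS1", "TS2", "TS3"})
MINIMUM_ROLES = frozenset({"INT1", "INT2", "INT3", "product"})
ROLES = TS_ROLES | MINIMUM_ROLES

#: Wavenumber magnitude (cm^-1) below which an eigenvalue is treated as a
#: translational/rotational null mode rather than a genuine vibration.
NULL_MODE_CUTOFF_CM1 = 1.0


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class Geometry:
    """Cartesian structure: element symbols, N x 3 coordinates (angstrom), masses (amu)."""

    atom_symbols: list[str]
    coordinates: np.ndarray
    masses: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError("coordinates must be an N x 3 array")
        if len(self.atom_symbols) != self.coordinates.shape[0]:
            raise ValidationError(
                f"{len(self.atom_symbols)} atom symbols but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        if self.masses is None:
            self.masses = np.array(
                [_mass_for(sym, line=None) for sym in self.atom_symbols]
            )
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.atom_symbols),):
                raise ValidationError("masses must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValidationError("all atomic masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    def distance(self, i: int, j: int) -> float:
        """Interatomic distance between atoms *i* and *j* (0-based indices)."""
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))


def _mass_for(symbol: str, line: int | None) -> float:
    try:
        return atomic_mass(symbol)
    except Exception:
        where = f" (line {line})" if line is not None else ""
        raise ValidationError(f"unknown element symbol {symbol!r}{where}") from None


def read_xyz(path: str | Path) -> Geometry:
    """Read a standard XYZ file (count line, comment line, atom lines)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: malformed count line {lines[0]!r}") from None
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ParseError(f"{path}: count line says {n} atoms but only {len(body)} listed")
    symbols: list[str] = []
    coords = np.empty((n, 3))
    for k, raw in enumerate(body):
        parts = raw.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed atom line {k + 3}: {raw!r}")
        symbols.append(parts[0])
        try:
            coords[k] = [float(x) for x in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: non-numeric coordinate on line {k + 3}") from None
    masses = np.array([_mass_for(s, line=k + 3) for k, s in enumerate(symbols)])
    return Geometry(symbols, coords, masses)


def write_xyz(geometry: Geometry, path: str | Path, comment: str = "") -> None:
    """Write a Geometry as a standard XYZ file (6 decimal places)."""
    out = [str(geometry.n_atoms), comment.replace("\n", " ")]
    for sym, (x, y, z) in zip(geometry.atom_symbols, geometry.coordinates):
        out.append(f"{sym:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Normal modes
# ---------------------------------------------------------------------------

@dataclass
class NormalModeSet:
    """Harmonic modes: wavenumbers (cm^-1, negative = imaginary) + displacement patterns.

    ``convention_tag`` records whether ``displacements`` are Gaussian-style
    Cartesian-normalized patterns or orthonormal mass-weighted eigenvectors.
    """

    frequencies: np.ndarray
    displacements: np.ndarray  # (n_modes, n_atoms, 3)
    convention_tag: str = "cartesian_normalized"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 3:
            raise ValidationError("displacements must be (n_modes, n_atoms, 3)")
        if len(self.frequencies) != self.displacements.shape[0]:
            raise ValidationError(
                f"{len(self.frequencies)} frequencies but "
                f"{self.displacements.shape[0]} displacement patterns"
            )
        if self.convention_tag not in ("cartesian_normalized", "mass_weighted"):
            raise ValidationError(f"unknown convention tag {self.convention_tag!r}")

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.frequencies < 0))

    @property
    def imaginary_index(self) -> int:
        """Index of the single imaginary mode; raises if there is not exactly one."""
        idx = np.flatnonzero(self.frequencies < 0)
        if len(idx) != 1:
            raise ValidationError(f"expected exactly one imaginary mode, found {len(idx)}")
        return int(idx[0])

    def canonical_cartesian(self, masses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (unit-norm Cartesian patterns, reduced masses in amu).

        The Cartesian pattern c of a mode is its physical displacement
        direction; the reduced mass mu = sum_a m_a |c_a|^2 relates the
        harmonic normal-coordinate amplitude to a Cartesian amplitude, so a
        quantum/thermal spread sigma(mu, omega) applied along c gives the
        physical position distribution of the mode.
        """
        masses = np.asarray(masses, dtype=float)
        disp = self.displacements
        if self.convention_tag == "mass_weighted":
            disp = disp / np.sqrt(masses)[None, :, None]
        norms = np.linalg.norm(disp.reshape(self.n_modes, -1), axis=1)
        if np.any(norms == 0):
            raise ValidationError("zero-norm mode displacement")
        cart = disp / norms[:, None, None]
        mu = np.einsum("a,kai->k", masses, cart**2)
        return cart, mu


def read_frequency_data(path: str | Path, dialect: str) -> NormalModeSet:
    """Read harmonic modes from a Gaussian-style log or a JSON sidecar file."""
    if dialect == "sidecar_json":
        return _read_sidecar(path)
    if dialect == "gaussian_log":
        return _read_gaussian_log(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_sidecar(path: str | Path) -> NormalModeSet:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from None
    for key in ("frequencies_cm1", "displacements", "convention"):
        if key not in data:
            raise ParseError(f"{path}: sidecar missing key {key!r}")
    return NormalModeSet(
        np.asarray(data["frequencies_cm1"], dtype=float),
        np.asarray(data["displacements"], dtype=float),
        data["convention"],
    )


def write_sidecar(modes: NormalModeSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "frequencies_cm1": modes.frequencies.tolist(),
                "displacements": modes.displacements.tolist(),
                "convention": modes.convention_tag,
            },
            indent=1,
        )
    )


_FREQ_STD_RE = re.compile(r"^\s*Frequencies\s*--(?!-)\s*(.*)$")
_FREQ_HP_RE = re.compile(r"^\s*Frequencies\s*---+\s*(.*)$")
_ATOM_ROW_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s+((?:\s*-?\d+\.\d+){3,})\s*$")
_COORD_ROW_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s+(\d+)\s+((?:\s*-?\d+\.\d+)+)\s*$")


def _parse_standard_blocks(lines, path):
    freqs: list[float] = []
    disps: list[list[list[float]]] = []  # per mode: list of [dx,dy,dz]
    i = 0
    while i < len(lines):
        m = _FREQ_STD_RE.match(lines[i])
        if not m:
            i += 1
            continue
        block_freqs = [float(x) for x in m.group(1).split()]
        ncols = len(block_freqs)
        # skip ancillary rows (Red. masses, Frc consts, IR Inten, header row)
        j = i + 1
        rows: list[list[float]] = []
        while j < len(lines):
            am = _ATOM_ROW_RE.match(lines[j])
            if am:
                vals = [float(x) for x in am.group(3).split()]
                if len(vals) != 3 * ncols:
                    raise ParseError(
                        f"{path}: line {j + 1}: expected {3 * ncols} displacement "
                        f"values, found {len(vals)}"
                    )
                rows.append(vals)
            elif rows or _FREQ_STD_RE.match(lines[j]):
                break  # end of the atom table for this block
            j += 1
        if not rows:
            raise ParseError(f"{path}: frequency block near line {i + 1} has no atom rows")
        for c in range(ncols):
            freqs.append(block_freqs[c])
            disps.append([row[3 * c : 3 * c + 3] for row in rows])
        i = j
    return freqs, disps


def _parse_hp_blocks(lines, path):
    """High-precision (HPModes-style) blocks: one row per Cartesian coordinate."""
    freqs: list[float] = []
    columns: list[dict[int, float]] = []  # per mode: coord index -> value
    i = 0
    while i < len(lines):
        m = _FREQ_HP_RE.match(lines[i])
        if not m:
            i += 1
            continue
        block_freqs = [float(x) for x in m.group(1).split()]
        ncols = len(block_freqs)
        j = i + 1
        block_cols: list[dict[int, float]] = [dict() for _ in range(ncols)]
        seen = False
        while j < len(lines):
            cm = _COORD_ROW_RE.match(lines[j])
            if cm:
                vals = [float(x) for x in cm.group(4).split()]
                if len(vals) != ncols:
                    raise ParseError(
                        f"{path}: line {j + 1}: expected {ncols} high-precision "
                        f"values, found {len(vals)}"
                    )
                coord = 3 * (int(cm.group(2)) - 1) + (int(cm.group(1)) - 1)
                for c in range(ncols):
                    block_cols[c][coord] = vals[c]
                seen = True
            elif seen:
                break
            j += 1
        if not seen:
            raise ParseError(f"{path}: high-precision block near line {i + 1} has no rows")
        freqs.extend(block_freqs)
        columns.extend(block_cols)
        i = j
    return freqs, columns


def _read_gaussian_log(path: str | Path) -> NormalModeSet:
    """Parse the harmonic-frequency section of a Gaussian-16-style log file.

    The high-precision (HPModes-style) block is preferred when present —
    displacement precision limits the projection accuracy downstream — with
    the standard three-column block as the fallback.
    """
    lines = Path(path).read_text().splitlines()
    hp_freqs, hp_cols = _parse_hp_blocks(lines, path)
    if hp_freqs:
        n_coords = max(max(c) for c in hp_cols) + 1
        if n_coords % 3:
            raise ParseError(f"{path}: high-precision rows do not cover whole atoms")
        # rows are indexed coord = 3*(atom-1) + (xyz-1)
        disp = np.zeros((len(hp_freqs), n_coords // 3, 3))
        for k, col in enumerate(hp_cols):
            for coord, val in col.items():
                disp[k, coord // 3, coord % 3] = val
        return NormalModeSet(np.asarray(hp_freqs), disp, "cartesian_normalized")
    freqs, disps = _parse_standard_blocks(lines, path)
    if not freqs:
        raise ParseError(f"{path}: no frequency block found")
    n_atoms = len(disps[0])
    if any(len(d) != n_atoms for d in disps):
        raise ParseError(f"{path}: inconsistent atom count across frequency blocks")
    return NormalModeSet(np.asarray(freqs), np.asarray(disps), "cartesian_normalized")


# ---------------------------------------------------------------------------
# Stationary points
# ---------------------------------------------------------------------------

@dataclass
class StationaryPoint:
    """One optimized structure with its Gibbs free energy and (optional) modes.

    ``gibbs_free_energy`` is in kcal/mol on the network's common reference.
    Products may omit modes: downstream analysis only needs their geometry.
    """

    label: str
    role: str
    geometry: Geometry
    gibbs_free_energy: float
    modes: NormalModeSet | None = None
    stereochem: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"{self.label}: unknown role {self.role!r}")
        if not np.isfinite(self.gibbs_free_energy):
            raise ValidationError(f"{self.label}: Gibbs free energy is not finite")
        if self.modes is not None:
            if self.modes.displacements.shape[1] != self.geometry.n_atoms:
                raise ValidationError(
                    f"{self.label}: modes describe {self.modes.displacements.shape[1]} "
                    f"atoms but geometry has {self.geometry.n_atoms}"
                )
            n_imag = self.modes.n_imaginary
            if self.is_ts and n_imag != 1:
                raise ValidationError(
                    f"{self.label}: transition state must carry exactly one "
                    f"imaginary mode, found {n_imag}"
                )
            if not self.is_ts and n_imag != 0:
                raise ValidationError(
                    f"{self.label}: minimum must have no imaginary modes, found {n_imag}"
                )

    @property
    def is_ts(self) -> bool:
        return self.role in TS_ROLES


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------

@dataclass
class ReactionNetwork:
    """Directed pathway graph from TS1 conformers to labelled products.

    ``channel_kind`` tags each TS1 outgoing edge as ``via_TS2`` (through the
    shared intermediate and a second transition state) or
    ``barrierless_direct`` (straight to a product).  ``product_catalog`` maps
    each product label to its (species, stereochem) identity used in reports.
    ``stage0``, when present, describes a dynamic complexation stage: a TS0
    whose VRAI analysis partitions flow among intermediate stereochemistry
    channels before TS1-level resolution.
    """

    points: dict[str, StationaryPoint]
    graph: nx.DiGraph
    channel_kind: dict[tuple[str, str], str] = field(default_factory=dict)
    product_catalog: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    experimental_percentages: dict[str, float] | None = None
    stage0: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ------------------------------------------------------------

    def by_role(self, role: str) -> list[StationaryPoint]:
        return [p for p in self.points.values() if p.role == role]

    def successors(self, label: str) -> list[StationaryPoint]:
        return [self.points[s] for s in self.graph.successors(label)]

    def intermediate_of(self, ts1_label: str) -> StationaryPoint | None:
        """The single downstream intermediate of a TS1, or None if all-barrierless."""
        ints = [p for p in self.successors(ts1_label) if p.role.startswith("INT")]
        if not ints:
            return None
        if len(ints) > 1:
            raise ValidationError(f"{ts1_label}: more than one downstream intermediate")
        return ints[0]

    def ts2s_of(self, ts1_label: str) -> list[StationaryPoint]:
        """All TS-role descendants of a TS1 (TS2s, and TS3s beyond a stable INT3)."""
        return [
            self.points[d]
            for d in nx.descendants(self.graph, ts1_label)
            if self.points[d].is_ts
        ]

    def products_of(self, label: str) -> list[StationaryPoint]:
        """All product-role descendants of a node, ordered by label."""
        prods = [
            self.points[d]
            for d in nx.descendants(self.graph, label)
            if self.points[d].role == "product"
        ]
        return sorted(prods, key=lambda p: p.label)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for u, v in self.graph.edges:
            for lbl in (u, v):
                if lbl not in self.points:
                    raise ValidationError(f"edge references unknown point {lbl!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValidationError("reaction network must be acyclic")
        for p in self.points.values():
            if p.role == "product" and p.label not in self.product_catalog:
                raise ValidationError(f"product {p.label!r} missing from product_catalog")
        for label in self.product_catalog:
            if label not in self.points:
                raise ValidationError(f"product_catalog entry {label!r} has no point")
        for ts1 in self.by_role("TS1"):
            succs = list(self.graph.successors(ts1.label))
            if not succs:
                raise ValidationError(f"TS1 {ts1.label!r} has no outgoing channels")
            kinds = {
                self.channel_kind.get((ts1.label, s), "via_TS2") for s in succs
            }
            ints = [s for s in succs if self.points[s].role.startswith("INT")]
            if not ints and kinds != {"barrierless_direct"}:
                raise ValidationError(
                    f"TS1 {ts1.label!r} has no downstream intermediate and "
                    f"non-barrierless channels"
                )
        # the projection math assumes one common atom mapping across the network
        seqs = {tuple(p.geometry.atom_symbols) for p in self.points.values()}
        if len(seqs) > 1:
            raise ValidationError(
                "stationary points do not share a common atom-symbol sequence"
            )
        if self.experimental_percentages is not None:
            for label in self.experimental_percentages:
                if label not in self.product_catalog:
                    raise ValidationError(
                        f"experimental percentage for unknown product {label!r}"
                    )


def load_network(config_path: str | Path) -> ReactionNetwork:
    """Load a reaction network from its YAML description.

    Schema::

        points:
          - {label, role, xyz, energy, energy_unit: kcal/mol|hartree,
             modes: <sidecar or log path>, modes_dialect: sidecar_json|gaussian_log,
             stereochem}
        edges:
          - [from, to]                      # via_TS2 by default
          - {from: ..., to: ..., kind: barrierless_direct}
        products:
          - {label, species, stereochem}
        experimental_percentages: {label: percent}
        stage0: {ts0, intermediate, channels: {stereochem: INT2-label}}

    File paths are resolved relative to the YAML file.  Hartree energies are
    converted with 627.5095 kcal/mol per Hartree and shifted to a common zero
    at the lowest-energy point.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    base = config_path.parent
    if not isinstance(cfg, dict) or "points" not in cfg:
        raise ParseError(f"{config_path}: network YAML must define 'points'")

    points: dict[str, StationaryPoint] = {}
    energies: dict[str, float] = {}
    units: set[str] = set()
    raw: list[dict] = []
    for entry in cfg["points"]:
        label = entry.get("label")
        if label is None:
            raise ValidationError("point without a label")
        if label in points:
            raise ValidationError(f"duplicate point label {label!r}")
        unit = str(entry.get("energy_unit", "kcal/mol")).lower()
        if unit not in ("kcal/mol", "hartree"):
            raise ValidationError(f"{label}: unknown energy unit {unit!r}")
        units.add(unit)
        raw.append(entry)
        points[label] = None  # type: ignore[assignment]  # reserve for dup check
        energies[label] = float(entry["energy"]) * (
            HARTREE_TO_KCAL if unit == "hartree" else 1.0
        )
    if len(units) > 1:
        raise ValidationError(
            "mixed energy units across points; declare one unit (or convert) explicitly"
        )
    if units == {"hartree"}:
        zero = min(energies.values())
        energies = {k: v - zero for k, v in energies.items()}

    for entry in raw:
        label = entry["label"]
        geom = read_xyz(base / entry["xyz"])
        modes = None
        if entry.get("modes"):
            modes = read_frequency_data(
                base / entry["modes"], entry.get("modes_dialect", "sidecar_json")
            )
        points[label] = StationaryPoint(
            label=label,
            role=entry["role"],
            geometry=geom,
            gibbs_free_energy=energies[label],
            modes=modes,
            stereochem=entry.get("stereochem"),
        )

    graph = nx.DiGraph()
    graph.add_nodes_from(points)
    channel_kind: dict[tuple[str, str], str] = {}
    for edge in cfg.get("edges", []):
        if isinstance(edge, dict):
            u, v, kind = edge["from"], edge["to"], edge.get("kind", "via_TS2")
        else:
            (u, v), kind = edge, "via_TS2"
        if kind not in ("via_TS2", "barrierless_direct"):
            raise ValidationError(f"edge {u}->{v}: unknown channel kind {kind!r}")
        for lbl in (u, v):
            if lbl not in points:
                raise ValidationError(f"edge {u}->{v} references unknown point {lbl!r}")
        graph.add_edge(u, v)
        channel_kind[(u, v)] = kind

    catalog = {
        p["label"]: (p["species"], p.get("stereochem"))
        for p in cfg.get("products", [])
    }
    exp = cfg.get("experimental_percentages")
    exp = {str(k): float(v) for k, v in exp.items()} if exp else None

    return ReactionNetwork(
        points=points,
        graph=graph,
        channel_kind=channel_kind,
        product_catalog=catalog,
        experimental_percentages=exp,
        stage0=cfg.get("stage0"),
    )
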