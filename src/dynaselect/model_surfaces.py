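"""Analytic bifurcating model surfaces, molecular embeddings, and a trajectory oracle.

The model potential is a two-dimensional valley-ridge-inflection surface:

    V(x, y) = -h*phi(t) + (1 - s(t))*k0*x^2/2 + s(t)*U(x)
              + h*x*(tilt*t + asym*t^2),         t = -y / L

with ``phi(t) = s(t) = 2 t^2 - t^4``.  A first-order saddle sits exactly at
the origin with its unstable direction along -y.  Downstream (t -> 1) the
transverse potential morphs from a harmonic valley (force constant k0) into
``U(x)``, a double well (or triple well) whose minima are the product
basins; the valley becomes a ridge at the VRI where the on-axis transverse
curvature changes sign.  ``tilt`` rotates the imaginary eigenvector of the
saddle; ``asym`` pushes the downstream valley and ridge sideways; both are
zero for an exactly mirror-symmetric surface.

``embed_as_molecule`` maps (x, y) onto two interatomic distances of a
four-atom toy molecule, producing XYZ geometries, analytic-Hessian normal
modes and a network description — a complete download-free input bundle for
the full selectivity pipeline.  ``trajectory_oracle`` integrates classical
trajectories on the 2D surface itself (independent of the projection
machinery under test) and defines reference product ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.constants as _sc
from numba import njit


from .constants import ACC_CONV, DEFAULT_TEMPERATURE_K, R_KCAL_MOL_K
from .errors import ValidationError
from .io_qc import (
    Geometry,
    NormalModeSet,
    ReactionNetwork,
    StationaryPoint,
    write_sidecar,
    write_xyz,
)

#: rad/fs -> cm^-1
_WAVENUMBER_PER_RADFS = 1e15 / (2.0 * np.pi * _sc.c * 1e2)

#: hbar in (kcal/mol) * fs  (so that <q^2> = hbar_kcalfs/(2 m omega) / ACC ... )
# We work with sigma in angstrom directly via the SI helpers in constants.


def _sigma_q(omega_radfs: float, mass_amu: float, temperature: float, model: str) -> float:
    """Harmonic position spread (angstrom) of a mode at angular frequency omega."""
    omega_si = omega_radfs * 1e15
    m_si = mass_amu * _sc.atomic_mass
    if model == "zero_point":
        return float(np.sqrt(_sc.hbar / (2.0 * m_si * omega_si)) * 1e10)
    if model == "thermal":
        return float(np.sqrt(_sc.k * temperature / (m_si * omega_si**2)) * 1e10)
    raise ValidationError(f"unknown width model {model!r}")


def _sigma_v(omega_radfs: float, mass_amu: float, temperature: float, model: str) -> float:
    """Harmonic velocity spread (angstrom/fs) of the same mode (Wigner / classical)."""
    if model == "zero_point":
        return _sigma_q(omega_radfs, mass_amu, temperature, model) * omega_radfs
    return float(np.sqrt(R_KCAL_MOL_K * temperature * ACC_CONV / mass_amu))


# ---------------------------------------------------------------------------
# Surface
# ---------------------------------------------------------------------------

@dataclass
class SurfaceParams:
    """Parameters of the bifurcating model potential.

    barrier_height   well depth below the saddle, kcal/mol
    well_separation  distance between the two outer wells, angstrom
    ridge_height     height of the inter-well ridge above the wells, kcal/mol
    asymmetry        dimensionless sideways push on the downstream region
    tilt             dimensionless rotation of the saddle's imaginary mode
    vri_position     distance (angstrom) from saddle to the on-axis VRI
    path_length      distance (angstrom) from saddle to the well row
    n_wells          2 (bifurcation) or 3 (trifurcation)
    mass_amu         effective 2D mass; 1.008/2 matches the reduced mass of
                     the H-H distance pairs used by the molecular embedding
    """

    barrier_height: float = 10.0
    well_separation: float = 2.0
    ridge_height: float = 2.0
    asymmetry: float = 0.0
    tilt: float = 0.0
    vri_position: float = 0.5
    path_length: float = 1.0
    n_wells: int = 2
    mass_amu: float = 1.008 / 2.0


class BifurcatingSurface:
    """Analytic 2D bifurcating potential with cached stationary points."""

    def __init__(self, params: SurfaceParams):
        p = params
        if p.barrier_height <= 0:
            raise ValidationError("barrier_height must be positive")
        if p.well_separation <= 0 or p.ridge_height <= 0:
            raise ValidationError(
                "no bifurcation: well_separation and ridge_height must be positive "
                "(a single-well surface has no competing basins)"
            )
        if p.ridge_height >= p.barrier_height:
            raise ValidationError("ridge_height must be below barrier_height")
        if not 0 < p.vri_position < p.path_length:
            raise ValidationError("vri_position must lie between saddle and wells")
        if p.n_wells not in (2, 3):
            raise ValidationError("n_wells must be 2 or 3")
        self.params = p
        self.h = p.barrier_height
        self.L = p.path_length
        self.w = p.well_separation / 2.0
        self.rh = p.ridge_height
        self.kappa = 4.0 * p.ridge_height / self.w**2
        t_star = p.vri_position / p.path_length
        s_star = 2 * t_star**2 - t_star**4
        self.k0 = self.kappa * s_star / (1.0 - s_star)
        if p.n_wells == 3:
            # U(x) = A x^2 (x^2 - w^2)^2: wells at 0, +/-w; ridges at +/-w/sqrt(3)
            self._A3 = 27.0 * self.rh / (4.0 * self.w**6)
        self._stationary: dict | None = None

    # -- potential ----------------------------------------------------------

    @staticmethod
    def _phi(t):
        return 2.0 * t**2 - t**4

    def _U(self, x):
        if self.params.n_wells == 2:
            return self.kappa * (x**2 - self.w**2) ** 2 / (4.0 * self.w**2)
        return self._A3 * x**2 * (x**2 - self.w**2) ** 2

    def _dU(self, x):
        if self.params.n_wells == 2:
            return self.kappa * x * (x**2 - self.w**2) / self.w**2
        return self._A3 * (6.0 * x**5 - 8.0 * self.w**2 * x**3 + 2.0 * self.w**4 * x)

    def _d2U(self, x):
        if self.params.n_wells == 2:
            return self.kappa * (3.0 * x**2 - self.w**2) / self.w**2
        return self._A3 * (30.0 * x**4 - 24.0 * self.w**2 * x**2 + 2.0 * self.w**4)

    def potential(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        t = -y / self.L
        s = self._phi(t)
        p = self.params
        return (
            -self.h * s
            + (1.0 - s) * self.k0 * x**2 / 2.0
            + s * self._U(x)
            + self.h * x * (p.tilt * t + p.asymmetry * t**2)
        )

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        t = -y / self.L
        s = self._phi(t)
        ds = 4.0 * t - 4.0 * t**3
        p = self.params
        vx = (
            (1.0 - s) * self.k0 * x
            + s * self._dU(x)
            + self.h * (p.tilt * t + p.asymmetry * t**2)
        )
        vt = (
            -self.h * ds
            + ds * (self._U(x) - self.k0 * x**2 / 2.0)
            + self.h * x * (p.tilt + 2.0 * p.asymmetry * t)
        )
        return np.stack([vx, -vt / self.L], axis=-1)

    def hessian(self, xy: np.ndarray) -> np.ndarray:
        x, y = float(xy[0]), float(xy[1])
        t = -y / self.L
        s = self._phi(t)
        ds = 4.0 * t - 4.0 * t**3
        d2s = 4.0 - 12.0 * t**2
        p = self.params
        vxx = (1.0 - s) * self.k0 + s * self._d2U(x)
        vxt = ds * (self._dU(x) - self.k0 * x) + self.h * (p.tilt + 2.0 * p.asymmetry * t)
        vtt = (
            -self.h * d2s
            + d2s * (self._U(x) - self.k0 * x**2 / 2.0)
            + 2.0 * self.h * x * p.asymmetry
        )
        return np.array(
            [[vxx, -vxt / self.L], [-vxt / self.L, vtt / self.L**2]]
        )

    # -- stationary points ----------------------------------------------------

    def _root(self, guess: np.ndarray) -> np.ndarray:
        # Plain 2x2 Newton with a closed-form solve.  Deliberately not a
        # library root-finder: the arithmetic mirrors bit-exactly under
        # (x, tilt, asym) -> (-x, -tilt, -asym), which the oracle's
        # mirror-symmetry contract depends on.
        xy = np.asarray(guess, dtype=float).copy()
        for _ in range(200):
            g = self.gradient(xy)
            if g[0] * g[0] + g[1] * g[1] < 1e-28:
                break
            hxx, hxy = self.hessian(xy)[0]
            hyy = self.hessian(xy)[1, 1]
            det = hxx * hyy - hxy * hxy
            if det == 0.0:
                raise ValidationError(f"singular Hessian during search from {guess}")
            xy[0] -= (hyy * g[0] - hxy * g[1]) / det
            xy[1] -= (hxx * g[1] - hxy * g[0]) / det
        if np.linalg.norm(self.gradient(xy)) > 1e-8:
            raise ValidationError(f"stationary-point search failed from {guess}")
        if self.params.tilt == 0.0 and self.params.asymmetry == 0.0 and abs(xy[0]) < 1e-9:
            xy[0] = 0.0  # snap to the exact mirror symmetry of the surface
        return xy

    def stationary_points(self) -> dict:
        """Saddle, wells and ridge saddle(s), root-found and cached.

        Outer wells are labelled ``P1`` (x > 0) and ``P2`` (x < 0); a central
        well (n_wells = 3) is ``P3``.
        """
        if self._stationary is not None:
            return self._stationary
        pts: dict[str, np.ndarray] = {"saddle": self._root([0.0, 0.0])}
        L, w = self.L, self.w
        pts["P1"] = self._root([w, -L])
        pts["P2"] = self._root([-w, -L])
        if self.params.n_wells == 3:
            pts["P3"] = self._root([0.0, -L])
            pts["ridge+"] = self._root([w / np.sqrt(3.0), -L])
            pts["ridge-"] = self._root([-w / np.sqrt(3.0), -L])
        else:
            pts["ridge"] = self._root([0.0, -L])
        # sanity: saddle has exactly one negative Hessian eigenvalue, wells none
        for name in ("P1", "P2") + (("P3",) if self.params.n_wells == 3 else ()):
            if np.any(np.linalg.eigvalsh(self.hessian(pts[name])) <= 0):
                raise ValidationError(f"well {name} is not a local minimum")
        ev = np.linalg.eigvalsh(self.hessian(pts["saddle"]))
        if not (ev[0] < 0 < ev[1]):
            raise ValidationError("saddle is not first-order")
        self._stationary = pts
        return pts

    def shoulder_point(self, t: float | None = None) -> np.ndarray:
        """On-axis shoulder (the 'intermediate'): valley-floor point at fixed y.

        Found by root-finding dV/dx = 0 at y = -t*L.  Defaults to the point
        three quarters of the way to the well row, past the VRI, where the
        trajectory stream detaches from the valley floor.
        """
        if t is None:
            t = 0.75
        y = -t * self.L
        # Newton from the axis: converges to the on-axis crest/floor, never to
        # the flanking product valleys (which also satisfy dV/dx = 0 past the VRI)
        x0 = 0.0
        for _ in range(100):
            g = float(self.gradient(np.array([x0, y]))[0])
            if abs(g) < 1e-13:
                break
            h = float(self.hessian(np.array([x0, y]))[0, 0])
            if h == 0.0:
                raise ValidationError("flat transverse curvature at the shoulder")
            x0 -= g / h
        if abs(x0) > self.w:
            raise ValidationError("shoulder search left the inter-well region")
        if self.params.tilt == 0.0 and self.params.asymmetry == 0.0 and abs(x0) < 1e-9:
            x0 = 0.0
        return np.array([x0, y])

    def well_labels(self) -> list[str]:
        return ["P1", "P2"] + (["P3"] if self.params.n_wells == 3 else [])

    def saddle_modes(self) -> tuple[np.ndarray, np.ndarray]:
        """(wavenumbers cm^-1, eigenvectors as columns) of the saddle, mass mass_amu."""
        pts = self.stationary_points()
        hess = self.hessian(pts["saddle"]) / self.params.mass_amu
        lam_lo, lam_hi, v_lo, v_hi = _eig2x2_symmetric(
            hess[0, 0], hess[0, 1], hess[1, 1]
        )
        lam = np.array([lam_lo, lam_hi])
        omega = np.sign(lam) * np.sqrt(np.abs(lam) * ACC_CONV)  # rad/fs, signed
        return omega * _WAVENUMBER_PER_RADFS, np.column_stack([v_lo, v_hi])


def make_surface(params: SurfaceParams | None = None, **kwargs) -> BifurcatingSurface:
    """Build a bifurcating model surface (see :class:`SurfaceParams`)."""
    if params is None:
        params = SurfaceParams(**kwargs)
    elif kwargs:
        raise ValueError("pass either a SurfaceParams or keyword overrides, not both")
    return BifurcatingSurface(params)


# ---------------------------------------------------------------------------
# Molecular embedding
# ---------------------------------------------------------------------------

#: Embedding geometry constants: base bond lengths and the spacer distance.
_R1_0, _R2_0, _SPACER = 2.5, 3.0, 10.0
#: Ground-truth reactive atom pairs of the embedding (0-based).
REACTIVE_PAIRS = [(0, 1), (2, 3)]


@dataclass
class EmbeddedFixture:
    """A complete pipeline input bundle generated from a model surface."""

    network: ReactionNetwork
    surface: BifurcatingSurface
    reactive_pairs: list[tuple[int, int]]
    network_yaml: Path | None = None
    labels_2d: dict[str, np.ndarray] = field(default_factory=dict)


def _embed_geometry(xy: np.ndarray) -> Geometry:
    """Map 2D surface coordinates onto the r(0,1) and r(2,3) distances.

    Atoms 0-1 form one H-H pair along the x axis (r01 = R1_0 + x) and atoms
    2-3 a second pair along z, displaced by a long spacer so that every
    non-designated interatomic distance varies by less than the default bond
    selection threshold over the surface's working range.
    """
    x, y = float(xy[0]), float(xy[1])
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [_R1_0 + x, 0.0, 0.0],
            [_R1_0, _SPACER, 0.0],
            [_R1_0, _SPACER, _R2_0 + y],
        ]
    )
    return Geometry(["H", "H", "H", "H"], coords)


def _embed_jacobian() -> np.ndarray:
    """d(x, y)/d(cartesian) for the embedding; constant because the designated
    bonds stay axis-aligned (the remaining coordinates are frozen)."""
    jac = np.zeros((2, 12))
    jac[0, 0] = -1.0  # x = r01 - R1_0, bond along +x
    jac[0, 3] = 1.0
    jac[1, 8] = -1.0  # y = r23 - R2_0, bond along +z
    jac[1, 11] = 1.0
    return jac


def _embedded_modes(surface: BifurcatingSurface, xy: np.ndarray) -> NormalModeSet:
    """Normal modes of the embedded point from the analytic 2D Hessian.

    The Cartesian Hessian is J^T H_2d J (exact at stationary points, where
    the gradient term vanishes); after mass-weighting with the H masses its
    two non-null modes are returned.
    """
    jac = _embed_jacobian()
    h2 = surface.hessian(xy)
    h_cart = jac.T @ h2 @ jac
    mass = np.repeat(1.008, 12)
    hmw = h_cart / np.sqrt(np.outer(mass, mass))
    lam, vec = np.linalg.eigh(hmw)
    keep = np.abs(lam) > 1e-10
    lam, vec = lam[keep], vec[:, keep]
    omega = np.sign(lam) * np.sqrt(np.abs(lam) * ACC_CONV)
    freqs = omega * _WAVENUMBER_PER_RADFS
    order = np.argsort(freqs)
    disp = vec[:, order].T.reshape(-1, 4, 3)  # mass-weighted == cartesian here
    return NormalModeSet(freqs[order], disp, "mass_weighted")


def embed_as_molecule(
    surface: BifurcatingSurface,
    out_dir: str | Path | None = None,
    shoulder_t: float | None = None,
) -> EmbeddedFixture:
    """Emit the surface's stationary points as a toy-molecule reaction network.

    The saddle becomes TS1, the on-axis shoulder becomes the intermediate
    INT2, and the wells become products; Gibbs free energies equal the
    potential values.  With ``out_dir`` set, XYZ files, a TS normal-mode
    sidecar and a network YAML are written there as well.
    """
    pts2d = surface.stationary_points()
    shoulder = surface.shoulder_point(shoulder_t)
    labels_2d = {"TS1": pts2d["saddle"], "INT2": shoulder}
    for lbl in surface.well_labels():
        labels_2d[lbl] = pts2d[lbl]

    points: dict[str, StationaryPoint] = {}
    for lbl, xy in labels_2d.items():
        role = {"TS1": "TS1", "INT2": "INT2"}.get(lbl, "product")
        modes = _embedded_modes(surface, xy) if role == "TS1" else None
        points[lbl] = StationaryPoint(
            label=lbl,
            role=role,
            geometry=_embed_geometry(xy),
            gibbs_free_energy=float(surface.potential(xy)),
            modes=modes,
            stereochem=None,
        )

    graph = nx.DiGraph()
    graph.add_nodes_from(points)
    graph.add_edge("TS1", "INT2")
    for lbl in surface.well_labels():
        graph.add_edge("INT2", lbl)
    catalog = {lbl: (lbl, None) for lbl in surface.well_labels()}
    network = ReactionNetwork(
        points=points,
        graph=graph,
        channel_kind={("TS1", "INT2"): "via_TS2"},
        product_catalog=catalog,
    )

    yaml_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for lbl, sp in points.items():
            stem = lbl.lower()
            write_xyz(sp.geometry, out_dir / f"{stem}.xyz", comment=f"embedded {lbl}")
            entry = {
                "label": lbl,
                "role": sp.role,
                "xyz": f"{stem}.xyz",
                "energy": sp.gibbs_free_energy,
                "energy_unit": "kcal/mol",
            }
            if sp.modes is not None:
                write_sidecar(sp.modes, out_dir / f"{stem}.modes.json")
                entry["modes"] = f"{stem}.modes.json"
                entry["modes_dialect"] = "sidecar_json"
            entries.append(entry)
        cfg = {
            "points": entries,
            "edges": [["TS1", "INT2"]] + [["INT2", lbl] for lbl in surface.well_labels()],
            "products": [{"label": lbl, "species": lbl} for lbl in surface.well_labels()],
        }
        import yaml as _yaml

        yaml_path = out_dir / "network.yaml"
        yaml_path.write_text(_yaml.safe_dump(cfg, sort_keys=False))

    return EmbeddedFixture(
        network=network,
        surface=surface,
        reactive_pairs=list(REACTIVE_PAIRS),
        network_yaml=yaml_path,
        labels_2d=labels_2d,
    )


def write_synthetic_gaussian_log(
    modes: NormalModeSet, masses: np.ndarray, path: str | Path, hp: bool = False
) -> None:
    """Write a synthetic Gaussian-16-style frequency block for parser tests.

    This is a fixture writer, not a Gaussian output: it reproduces the layout
    of the harmonic-frequency section — the standard three-column block with
    per-atom displacement rows, or (``hp=True``) the high-precision layout
    with one row per Cartesian coordinate.
    """
    cart, _ = modes.canonical_cartesian(np.asarray(masses))
    freqs = modes.frequencies
    n_atoms = cart.shape[1]
    lines = [" Harmonic frequencies (cm**-1), synthetic fixture", ""]
    for start in range(0, len(freqs), 3):
        group = range(start, min(start + 3, len(freqs)))
        lines.append("                    " + "".join(f"{k + 1:>23d}" for k in group))
        dashes = "---" if hp else "--"
        lines.append(
            f" Frequencies {dashes}" + "".join(f"{freqs[k]:>23.4f}" for k in group)
        )
        lines.append(
            f" Red. masses {dashes}" + "".join(f"{1.0:>23.4f}" for _ in group)
        )
        if hp:
            lines.append(" Coord Atom Element:")
            for a in range(n_atoms):
                for i in range(3):
                    row = f"{i + 1:>4d}{a + 1:>6d}{1:>6d}"
                    row += "".join(f"{cart[k, a, i]:>12.8f}" for k in group)
                    lines.append(row)
        else:
            lines.append("  Atom  AN" + "       X         Y         Z " * len(group))
            for a in range(n_atoms):
                row = f"{a + 1:>6d}{1:>4d}"
                for k in group:
                    row += "".join(f"{cart[k, a, i]:>10.6f}" for i in range(3))
                lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectory oracle
# ---------------------------------------------------------------------------

def _eig2x2_symmetric(a: float, b: float, c: float):
    """Closed-form eigendecomposition of [[a, b], [b, c]].

    Returns (lam_lo, lam_hi, v_lo, v_hi) with unit eigenvectors.  Written in
    terms of b**2 wherever possible so that negating b mirrors the
    eigenvectors bit-exactly (x -> -x), which the oracle's mirror-symmetry
    contract relies on.
    """
    half_tr = 0.5 * (a + c)
    half_diff = 0.5 * (a - c)
    r = np.sqrt(half_diff * half_diff + b * b)
    lam_lo, lam_hi = half_tr - r, half_tr + r
    if b == 0.0:
        v_lo = np.array([1.0, 0.0]) if a <= c else np.array([0.0, 1.0])
        v_hi = np.array([0.0, 1.0]) if a <= c else np.array([1.0, 0.0])
        return lam_lo, lam_hi, v_lo, v_hi
    v_hi = np.array([b, lam_hi - a])
    v_hi /= np.sqrt(b * b + (lam_hi - a) ** 2)
    v_lo = np.array([-v_hi[1], v_hi[0]])
    return lam_lo, lam_hi, v_lo, v_hi


@njit(cache=False)
def _integrate_ensemble(
    pos0, vel0, wells, h, L, w, kappa, k0, A3, tilt, asym, n_wells,
    acc_over_m, dt, max_steps, capture_r2, e0,
):  # pragma: no cover - exercised through trajectory_oracle
    n = pos0.shape[0]
    basin = -np.ones(n, dtype=np.int64)
    drift = np.zeros(n)
    for i in range(n):
        x, y = pos0[i, 0], pos0[i, 1]
        vx, vy = vel0[i, 0], vel0[i, 1]
        # one force evaluation per step (velocity Verlet)
        fx, fy = _force(x, y, h, L, w, kappa, k0, A3, tilt, asym, n_wells)
        for _ in range(max_steps):
            vx += 0.5 * dt * fx * acc_over_m
            vy += 0.5 * dt * fy * acc_over_m
            x += dt * vx
            y += dt * vy
            fx, fy = _force(x, y, h, L, w, kappa, k0, A3, tilt, asym, n_wells)
            vx += 0.5 * dt * fx * acc_over_m
            vy += 0.5 * dt * fy * acc_over_m
            for kw in range(wells.shape[0]):
                dx = x - wells[kw, 0]
                dy = y - wells[kw, 1]
                if dx * dx + dy * dy <= capture_r2:
                    basin[i] = kw
                    break
            if basin[i] >= 0:
                v_here = _potential(x, y, h, L, w, kappa, k0, A3, tilt, asym, n_wells)
                ke = 0.5 * (vx * vx + vy * vy) / acc_over_m
                e_now = v_here + ke
                denom = abs(e0[i])
                if denom < 1e-30:
                    denom = 1e-30
                drift[i] = abs(e_now - e0[i]) / denom
                break
    return basin, drift


@njit(cache=False, inline="always")
def _potential(x, y, h, L, w, kappa, k0, A3, tilt, asym, n_wells):  # pragma: no cover
    t = -y / L
    t2 = t * t
    s = 2.0 * t2 - t2 * t2
    if n_wells == 2:
        d = x * x - w * w
        u = kappa * d * d / (4.0 * w * w)
    else:
        d = x * x - w * w
        u = A3 * x * x * d * d
    return -h * s + (1.0 - s) * 0.5 * k0 * x * x + s * u + h * x * (tilt * t + asym * t2)


@njit(cache=False, inline="always")
def _force(x, y, h, L, w, kappa, k0, A3, tilt, asym, n_wells):  # pragma: no cover
    t = -y / L
    t2 = t * t
    s = 2.0 * t2 - t2 * t2
    ds = 4.0 * t - 4.0 * t * t2
    if n_wells == 2:
        u = kappa * (x * x - w * w) ** 2 / (4.0 * w * w)
        du = kappa * x * (x * x - w * w) / (w * w)
    else:
        u = A3 * x * x * (x * x - w * w) ** 2
        du = A3 * (6.0 * x**5 - 8.0 * w * w * x**3 + 2.0 * w**4 * x)
    vx = (1.0 - s) * k0 * x + s * du + h * (tilt * t + asym * t2)
    vt = -h * ds + ds * (u - 0.5 * k0 * x * x) + h * x * (tilt + 2.0 * asym * t)
    return -vx, vt / L

@dataclass
class TrajectoryEnsembleResult:
    """Basin statistics of a quasi-classical ensemble on the model surface."""

    n_trajectories: int
    seed: int
    basin_counts: dict[str, int]
    fractions: dict[str, float]
    undecided_count: int
    max_energy_drift: float
    step_cap_warning: bool

    def __post_init__(self) -> None:
        if sum(self.basin_counts.values()) + self.undecided_count != self.n_trajectories:
            raise ValidationError("basin counts do not sum to the ensemble size")


def trajectory_oracle(
    surface: BifurcatingSurface,
    n: int,
    seed: int,
    temperature: float = DEFAULT_TEMPERATURE_K,
    width_model: str = "zero_point",
    dt_fs: float = 0.001,
    max_steps: int = 1000000,
    capture_radius: float | None = None,
    forward_energy_kcal: float | None = None,
    reflect: bool = False,
    antithetic: bool = True,
) -> TrajectoryEnsembleResult:
    """Classical trajectory ensemble from the saddle; basins decided by first entry.

    Initial transverse position and velocity are drawn from the saddle's
    harmonic distribution along its stable eigenvector (ground-state Wigner
    for ``zero_point``, classical Boltzmann for ``thermal``), with a fixed
    forward kick of ``forward_energy_kcal`` (default R*T/2) along the
    downhill imaginary eigenvector.  Trajectories are integrated by velocity
    Verlet at a fixed step and assigned to the basin whose capture disc they
    enter first; on a conservative surface this committor-style criterion is
    the well-defined replacement for energy-based capture.  Random draws are
    keyed by (seed, trajectory index), so results do not depend on execution
    order.  ``reflect`` negates the transverse draws, which maps the ensemble
    onto the mirror ensemble exactly.
    """
    if n < 1:
        raise ValidationError("need at least one trajectory")
    p = surface.params
    m = p.mass_amu
    pts = surface.stationary_points()
    saddle = pts["saddle"]
    labels = surface.well_labels()
    centers = np.array([pts[lbl] for lbl in labels])
    if capture_radius is None:
        capture_radius = 0.5 * surface.w
    if forward_energy_kcal is None:
        # flux-weighted mean translational energy through the dividing surface
        forward_energy_kcal = R_KCAL_MOL_K * temperature

    freqs_cm1, vecs = surface.saddle_modes()
    i_unstable = int(np.argmin(freqs_cm1))
    i_stable = 1 - i_unstable
    if freqs_cm1[i_unstable] >= 0:
        raise ValidationError("saddle has no unstable direction")
    e_u = vecs[:, i_unstable]
    if e_u[1] > 0:  # orient downhill (toward the wells at negative y)
        e_u = -e_u
    e_s = vecs[:, i_stable]
    # sign convention chosen so that reflecting the surface mirrors e_s exactly
    if e_s[0] < 0 or (e_s[0] == 0 and e_s[1] < 0):
        e_s = -e_s
    omega_s = freqs_cm1[i_stable] / _WAVENUMBER_PER_RADFS  # rad/fs

    sq = _sigma_q(omega_s, m, temperature, width_model)
    sv = _sigma_v(omega_s, m, temperature, width_model)
    v_fwd = float(np.sqrt(2.0 * forward_energy_kcal * ACC_CONV / m))

    # draws keyed by (seed, index): independent of execution order; with
    # antithetic pairing, trajectory 2k+1 negates the draws of trajectory 2k
    # (variance reduction; the paired ensemble is exactly mirror-symmetric)
    if antithetic:
        children = np.random.SeedSequence(seed).spawn((n + 1) // 2)
        draws = np.empty((n, 2))
        for i, child in enumerate(children):
            d = np.random.default_rng(child).standard_normal(2)
            draws[2 * i] = d
            if 2 * i + 1 < n:
                draws[2 * i + 1] = -d
    else:
        children = np.random.SeedSequence(seed).spawn(n)
        draws = np.empty((n, 2))
        for i, child in enumerate(children):
            draws[i] = np.random.default_rng(child).standard_normal(2)
    if reflect:
        draws = -draws

    pos = saddle[None, :] + (draws[:, 0] * sq)[:, None] * e_s[None, :]
    vel = v_fwd * e_u[None, :] + (draws[:, 1] * sv)[:, None] * e_s[None, :]
    e0 = surface.potential(pos) + 0.5 * m * np.einsum("ij,ij->i", vel, vel) / ACC_CONV

    basin, drift = _integrate_ensemble(
        pos, vel, centers,
        surface.h, surface.L, surface.w, surface.kappa, surface.k0,
        getattr(surface, "_A3", 0.0), p.tilt, p.asymmetry, p.n_wells,
        ACC_CONV / m, dt_fs, max_steps, capture_radius**2, e0,
    )

    counts = {lbl: int(np.sum(basin == k)) for k, lbl in enumerate(labels)}
    undecided = int(np.sum(basin < 0))
    decided = n - undecided
    fractions = {
        lbl: (c / decided if decided else float("nan")) for lbl, c in counts.items()
    }
    return TrajectoryEnsembleResult(
        n_trajectories=n,
        seed=seed,
        basin_counts=counts,
        fractions=fractions,
        undecided_count=undecided,
        max_energy_drift=float(drift.max()) if decided else float("nan"),
        step_cap_warning=undecided > 0.2 * n,
    )


#: Canonical asymmetry sweep for validating the stream partition against the
#: trajectory oracle: mode-rotation (tilt) settings at two magnitudes and both
#: signs, sideways-shift (asym) settings, and moderate mixed settings.  The
#: magnitudes keep both product basins intact and span predicted major-product
#: fractions of roughly 50-84%; simultaneous strong tilt and shift is outside
#: the moderate-asymmetry regime the stream partition targets (see the
#: methods note) and is not part of the canonical sweep.
CANONICAL_SWEEP: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.05, 0.0),
    (0.10, 0.0),
    (-0.05, 0.0),
    (-0.10, 0.0),
    (0.0, 0.10),
    (0.0, 0.20),
    (0.05, 0.05),
    (-0.05, 0.10),
)


def compare_vrai_with_oracle(
    tilt: float,
    asymmetry: float,
    n_trajectories: int = 2000,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    width_model: str = "zero_point",
) -> dict:
    """Predicted vs trajectory-ensemble P1 fraction on one model surface.

    Runs the full pipeline (embedding -> network -> stream partition) on one
    side and the 2D trajectory oracle on the other; both see the same surface
    and the same width model.
    """
    from .pipeline import RunSettings, run_selectivity_pipeline  # avoid cycle

    surface = make_surface(tilt=tilt, asymmetry=asymmetry)
    fixture = embed_as_molecule(surface)
    dist = run_selectivity_pipeline(
        fixture.network,
        RunSettings(temperature_K=temperature, width_model=width_model),
    )
    oracle = trajectory_oracle(
        surface, n_trajectories, seed, temperature=temperature, width_model=width_model
    )
    return {
        "tilt": tilt,
        "asymmetry": asymmetry,
        "vrai_percent_P1": dist.label_percentages["P1"],
        "oracle_percent_P1": 100.0 * oracle.fractions["P1"],
        "oracle_undecided": oracle.undecided_count,
        "n_trajectories": n_trajectories,
    }


def oracle_result_json(result: TrajectoryEnsembleResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_trajectories": result.n_trajectories,
                "seed": result.seed,
                "basin_counts": result.basin_counts,
                "fractions": result.fractions,
                "undecided_count": result.undecided_count,
                "max_energy_drift": result.max_energy_drift,
                "step_cap_warning": result.step_cap_warning,
            },
            indent=1,
        )
    )
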