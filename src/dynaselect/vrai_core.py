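"""Dynamic-selectivity core: trajectory-stream partition on a reduced 2D surface.

The post-transition-state region of a bifurcating reaction is reduced to two
dimensions built from the interatomic distances that actually change between
the competing products (the forming/breaking bonds).  In that plane:

* ``ā``  — the imaginary eigenvector of the first transition state (TS^I),
  oriented to point from TS^I toward the intermediate;
* ``ḡ``  — the separation vector from TS^I to the intermediate (INT);
* the *ridge* — the line through INT bisecting the two INT→product
  directions, separating the product basins;
* the *trajectory stream* — the bundle of classical trajectories leaving
  TS^I, modelled as a Gaussian whose center is TS^I displaced along ā by
  ``|ḡ|`` and whose width σ comes from the harmonic real modes of the TS.

The fraction of the stream on each side of the ridge is the predicted
product ratio: fraction(P1) = Φ(δ/σ) with δ the signed perpendicular
distance from the stream center to the ridge and Φ the standard normal CDF.
With more than two products sharing one TS^I and intermediate, pairwise
partitions against a fixed reference product are combined by odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .constants import (
    DEFAULT_TEMPERATURE_K,
    harmonic_sigma_thermal,
    harmonic_sigma_zero_point,
)
from .errors import DegenerateInputError, ValidationError
from .io_qc import Geometry, StationaryPoint

DEFAULT_BOND_THRESHOLD_A = 0.3


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class BondCoordinateSet:
    """The interatomic distances spanning the reduced reaction space."""

    atom_pairs: list[tuple[int, int]]
    selection_threshold: float
    source: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.atom_pairs:
            if i == j:
                raise ValidationError(f"bond pair ({i}, {j}) pairs an atom with itself")
            if (i, j) in seen:
                raise ValidationError(f"duplicate bond pair ({i}, {j})")
            seen.add((i, j))
        if len(self.atom_pairs) < 2:
            raise ValidationError("need at least 2 bond coordinates")

    def distances(self, geom: Geometry) -> np.ndarray:
        """Vector of selected interatomic distances for one structure."""
        xyz = geom.coordinates
        return np.array([np.linalg.norm(xyz[j] - xyz[i]) for i, j in self.atom_pairs])

    def rates(self, cart_disp: np.ndarray, ref_geom: Geometry) -> np.ndarray:
        """Bond-distance rates of a Cartesian displacement pattern.

        For pair (i, j) this is the component of the relative displacement of
        the two atoms along the unit bond vector evaluated at *ref_geom*.
        """
        xyz = ref_geom.coordinates
        out = np.empty(len(self.atom_pairs))
        for k, (i, j) in enumerate(self.atom_pairs):
            b = xyz[j] - xyz[i]
            nb = np.linalg.norm(b)
            if nb == 0:
                raise DegenerateInputError(f"atoms {i} and {j} coincide in reference geometry")
            out[k] = float(np.dot(cart_disp[j] - cart_disp[i], b / nb))
        return out


@dataclass
class ProjectedPES2D:
    """Reduced 2D picture with INT at the origin.

    ``basis`` holds two orthonormal directions in bond-distance space;
    2D positions are components along them, relative to the intermediate.
    """

    origin: np.ndarray
    ts_position: np.ndarray
    product_positions: dict[str, np.ndarray]
    g_vec: np.ndarray
    basis: np.ndarray  # (2, n_pairs)
    a_vec: np.ndarray | None = None

    def project(self, bond_disp: np.ndarray) -> np.ndarray:
        """Project a bond-space displacement into the plane."""
        return self.basis @ bond_disp


@dataclass
class StreamWidth:
    """Gaussian stream width σ (angstrom) and its per-mode decomposition."""

    sigma: float
    per_mode_contributions: list[tuple[float, float]]  # (wavenumber cm^-1, A^2)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DegenerateInputError("stream width must be positive")
        total = sum(c for _, c in self.per_mode_contributions)
        if abs(total - self.sigma**2) > 1e-10 * max(1.0, self.sigma**2):
            raise ValidationError("per-mode contributions do not sum to sigma^2")


@dataclass
class SelectivityResult:
    """Per-product fractions from one stream partition (or its TST fallback)."""

    fractions: dict[str, float]
    method: str  # "VRAI" | "TST_fallback"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.array(list(self.fractions.values()))
        if np.any(vals < -1e-12):
            raise ValidationError("negative product fraction")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {vals.sum()}, not 1")


# ---------------------------------------------------------------------------
# Bond-coordinate selection
# ---------------------------------------------------------------------------

def select_bond_coordinates(
    int_geom: Geometry,
    product_geoms: list[Geometry],
    ts_geom: Geometry,
    threshold: float = DEFAULT_BOND_THRESHOLD_A,
) -> BondCoordinateSet:
    """Atom pairs whose distance differs by > *threshold* across the branching.

    A pair qualifies if its interatomic distance differs by more than the
    threshold between any two product geometries, or between any product and
    the TS geometry.  If fewer than two pairs qualify the threshold is halved
    (up to six times) — geometrically similar structures still need a plane.
    """
    geoms = [ts_geom] + list(product_geoms)
    n = ts_geom.n_atoms
    for g in geoms + [int_geom]:
        if g.n_atoms != n:
            raise ValidationError("all structures must share the atom count")
    coords = np.stack([g.coordinates for g in geoms])  # (S, N, 3)
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dists = np.linalg.norm(diff, axis=-1)  # (S, N, N)
    # spread between products, and product-vs-TS (index 0 is the TS)
    prod = dists[1:]
    spread_pp = prod.max(axis=0) - prod.min(axis=0)
    spread_pt = np.abs(prod - dists[0][None]).max(axis=0)
    spread = np.maximum(spread_pp, spread_pt)
    iu, ju = np.triu_indices(n, k=1)

    thr = float(threshold)
    for _ in range(7):  # initial threshold + up to 6 halvings
        mask = spread[iu, ju] > thr
        if mask.sum() >= 2:
            pairs = [(int(i), int(j)) for i, j in zip(iu[mask], ju[mask])]
            return BondCoordinateSet(pairs, thr, source="product/TS bond differences")
        thr /= 2.0
    raise DegenerateInputError(
        "structures are geometrically identical: no bond pair exceeds the "
        "selection threshold even after six halvings"
    )


# ---------------------------------------------------------------------------
# 2D projection
# ---------------------------------------------------------------------------

def project_to_2d(
    ts: StationaryPoint | Geometry,
    intermediate: StationaryPoint | Geometry,
    products: list[StationaryPoint],
    coords: BondCoordinateSet,
) -> ProjectedPES2D:
    """Project TS^I, INT and two products into the bifurcation plane.

    The plane is the Gram–Schmidt orthonormalization of the INT→P1 and
    INT→P2 displacement vectors in bond-distance space, with INT at the
    origin.  ``g_vec`` is the in-plane vector from the TS projection to INT.
    """
    if len(products) != 2:
        raise ValidationError("project_to_2d requires exactly two products")
    ts_geom = ts.geometry if isinstance(ts, StationaryPoint) else ts
    int_geom = (
        intermediate.geometry if isinstance(intermediate, StationaryPoint) else intermediate
    )
    d_int = coords.distances(int_geom)
    w = [coords.distances(p.geometry) - d_int for p in products]
    n1, n2 = np.linalg.norm(w[0]), np.linalg.norm(w[1])
    if n1 < 1e-10 or n2 < 1e-10:
        raise DegenerateInputError("a product coincides with the intermediate in bond space")
    cosang = abs(float(np.dot(w[0], w[1])) / (n1 * n2))
    if cosang > np.cos(np.deg2rad(1.0)):
        raise DegenerateInputError(
            "INT->product displacement vectors are parallel within 1 degree: "
            "no resolvable bifurcation plane"
        )
    e1 = w[0] / n1
    e2 = w[1] - np.dot(w[1], e1) * e1
    e2 /= np.linalg.norm(e2)
    basis = np.vstack([e1, e2])

    ts_pos = basis @ (coords.distances(ts_geom) - d_int)
    prod_pos = {p.label: basis @ wk for p, wk in zip(products, w)}
    return ProjectedPES2D(
        origin=np.zeros(2),
        ts_position=ts_pos,
        product_positions=prod_pos,
        g_vec=-ts_pos,
        basis=basis,
    )


def orient_imaginary_mode(
    ts: StationaryPoint, plane: ProjectedPES2D, coords: BondCoordinateSet
) -> np.ndarray:
    """Project the imaginary eigenvector into the plane, oriented toward INT.

    The Cartesian displacement pattern of the single imaginary mode is
    converted to bond-distance rates, projected into the plane, normalized,
    and sign-fixed so that ā·ḡ ≥ 0 (initial motion toward the intermediate
    side of the surface).  The oriented vector is stored on the plane.
    """
    if ts.modes is None:
        raise ValidationError(f"{ts.label}: no normal modes available")
    cart, _ = ts.modes.canonical_cartesian(ts.geometry.masses)
    imag = cart[ts.modes.imaginary_index]
    rate = coords.rates(imag, ts.geometry)
    full_norm = np.linalg.norm(rate)
    a2 = plane.project(rate)
    if full_norm < 1e-12 or np.linalg.norm(a2) < 1e-8 * max(full_norm, 1e-12):
        raise DegenerateInputError(
            f"{ts.label}: imaginary mode is orthogonal to the bifurcation plane"
        )
    a2 = a2 / np.linalg.norm(a2)
    if float(np.dot(a2, plane.g_vec)) < 0:
        a2 = -a2
    plane.a_vec = a2
    return a2


def stream_width(
    ts: StationaryPoint,
    plane: ProjectedPES2D,
    coords: BondCoordinateSet,
    temperature: float = DEFAULT_TEMPERATURE_K,
    width_model: str = "zero_point",
) -> StreamWidth:
    """Harmonic trajectory-stream width perpendicular to ā, in angstrom.

    Each real mode k contributes its 1D harmonic spread σ_k — zero-point
    sqrt(ħ/2μ_k ω_k) or classical-thermal sqrt(k_B T/μ_k ω_k²) — times the
    component of its bond-rate projection along the in-plane direction
    perpendicular to ā; contributions add in quadrature.
    """
    if plane.a_vec is None:
        raise ValidationError("orient the imaginary mode before computing the width")
    if width_model not in ("zero_point", "thermal"):
        raise ValidationError(f"unknown width model {width_model!r}")
    if ts.modes is None:
        raise ValidationError(f"{ts.label}: no normal modes available")
    cart, mu = ts.modes.canonical_cartesian(ts.geometry.masses)
    perp = np.array([-plane.a_vec[1], plane.a_vec[0]])
    contributions: list[tuple[float, float]] = []
    total = 0.0
    for k, nu in enumerate(ts.modes.frequencies):
        if nu <= 0:
            continue
        if width_model == "zero_point":
            sig_k = harmonic_sigma_zero_point(float(nu), float(mu[k]))
        else:
            sig_k = harmonic_sigma_thermal(float(nu), float(mu[k]), temperature)
        comp = float(np.dot(plane.project(coords.rates(cart[k], ts.geometry)), perp))
        c = (sig_k * comp) ** 2
        contributions.append((float(nu), c))
        total += c
    if not contributions:
        raise ValidationError(f"{ts.label}: transition state has no real modes")
    if total <= 1e-24:
        raise DegenerateInputError(
            f"{ts.label}: every real mode is orthogonal to the in-plane direction "
            "perpendicular to the imaginary mode (zero stream width)"
        )
    return StreamWidth(sigma=float(np.sqrt(total)), per_mode_contributions=contributions)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

def predict_two_product_ratio(
    plane: ProjectedPES2D, a_vec: np.ndarray, width: StreamWidth
) -> SelectivityResult:
    """Partition the Gaussian stream between the two products in the plane.

    The ridge runs through INT along the bisector of the two INT→product
    directions (degenerating to the valley axis −ḡ when the products sit on
    exactly opposite sides).  The stream center is TS^I displaced along ā by
    |ḡ|; its signed perpendicular offset δ from the ridge (positive toward
    P1) gives fraction(P1) = Φ(δ/σ).
    """
    labels = list(plane.product_positions)
    if len(labels) != 2:
        raise ValidationError("two-product partition needs exactly two products")
    p1, p2 = labels
    u = {}
    for lbl in labels:
        pos = plane.product_positions[lbl]
        n = np.linalg.norm(pos)
        if n < 1e-10:
            raise DegenerateInputError(f"product {lbl!r} sits at the intermediate")
        u[lbl] = pos / n
    bis = u[p1] + u[p2]
    if np.linalg.norm(bis) < 1e-8:
        # products exactly opposite: the basin boundary approaches INT along
        # the valley axis, so the ridge line runs along g
        gn = np.linalg.norm(plane.g_vec)
        if gn < 1e-12:
            raise DegenerateInputError("TS and INT coincide: ridge direction undefined")
        ridge = plane.g_vec / gn
    else:
        ridge = bis / np.linalg.norm(bis)
    normal = np.array([-ridge[1], ridge[0]])
    if float(np.dot(normal, u[p1])) < 0:
        normal = -normal
    center = plane.ts_position + a_vec * np.linalg.norm(plane.g_vec)
    delta = float(np.dot(center, normal))
    if delta == 0.0:
        f1 = 0.5
    else:
        f1 = float(norm.cdf(delta / width.sigma))
    angles = {
        lbl: float(np.degrees(np.arccos(np.clip(np.dot(a_vec, u[lbl]), -1, 1))))
        for lbl in labels
    }
    return SelectivityResult(
        fractions={p1: f1, p2: 1.0 - f1},
        method="VRAI",
        diagnostics={
            "delta_A": delta,
            "sigma_A": width.sigma,
            "per_mode_contributions_A2": width.per_mode_contributions,
            "a_vec": a_vec.tolist(),
            "g_vec": plane.g_vec.tolist(),
            "ts_position": plane.ts_position.tolist(),
            "product_positions": {k: v.tolist() for k, v in plane.product_positions.items()},
            "product_angles_deg": angles,
        },
    )


def _two_product_analysis(
    ts: StationaryPoint,
    intermediate: StationaryPoint,
    p1: StationaryPoint,
    p2: StationaryPoint,
    temperature: float,
    width_model: str,
    bond_threshold: float,
) -> SelectivityResult:
    coords = select_bond_coordinates(
        intermediate.geometry, [p1.geometry, p2.geometry], ts.geometry, bond_threshold
    )
    plane = project_to_2d(ts, intermediate, [p1, p2], coords)
    a_vec = orient_imaginary_mode(ts, plane, coords)
    width = stream_width(ts, plane, coords, temperature, width_model)
    result = predict_two_product_ratio(plane, a_vec, width)
    result.diagnostics["bond_pairs"] = coords.atom_pairs
    result.diagnostics["bond_threshold_A"] = coords.selection_threshold
    return result


def predict_multi_product_ratio(
    ts: StationaryPoint,
    intermediate: StationaryPoint,
    products: list[StationaryPoint],
    temperature: float = DEFAULT_TEMPERATURE_K,
    width_model: str = "zero_point",
    bond_threshold: float = DEFAULT_BOND_THRESHOLD_A,
) -> SelectivityResult:
    """Stream partition among two or more products sharing one TS^I and INT.

    For two products this is exactly the pairwise analysis.  For more, a
    reference product r is fixed — the one whose INT→product direction in
    bond-distance space is most anti-parallel to ḡ (ties broken by label) —
    and each other product p is partitioned against r in the (p, r) plane.
    The pairwise odds o_p = fraction(p)/fraction(r) are combined with
    f_r ∝ 1, f_p ∝ o_p and normalized.  A geometrically degenerate pair
    falls back to Boltzmann weighting of the two product energies, recorded
    in the diagnostics.
    """
    if len(products) < 2:
        raise ValidationError("need at least two products")
    if len(products) == 2:
        return _two_product_analysis(
            ts, intermediate, products[0], products[1],
            temperature, width_model, bond_threshold,
        )

    coords_all = select_bond_coordinates(
        intermediate.geometry, [p.geometry for p in products], ts.geometry, bond_threshold
    )
    d_int = coords_all.distances(intermediate.geometry)
    g_full = d_int - coords_all.distances(ts.geometry)
    gn = np.linalg.norm(g_full)
    if gn < 1e-12:
        raise DegenerateInputError("TS and INT coincide in bond space")
    g_hat = g_full / gn

    def anti_score(p: StationaryPoint) -> float:
        w = coords_all.distances(p.geometry) - d_int
        n = np.linalg.norm(w)
        if n < 1e-10:
            raise DegenerateInputError(f"product {p.label!r} coincides with INT")
        return float(np.dot(w / n, g_hat))

    ref = min(products, key=lambda p: (anti_score(p), p.label))
    others = sorted((p for p in products if p.label != ref.label), key=lambda p: p.label)

    from .thermo import boltzmann_weights  # local: avoid import cycle at module load

    odds: dict[str, float] = {}
    pairwise: dict[str, dict] = {}
    fallbacks: list[str] = []
    for p in others:
        try:
            res = _two_product_analysis(
                ts, intermediate, p, ref, temperature, width_model, bond_threshold
            )
            f_p, f_r = res.fractions[p.label], res.fractions[ref.label]
            odds[p.label] = f_p / max(f_r, 1e-300)
            pairwise[p.label] = res.diagnostics
        except DegenerateInputError as exc:
            ens = boltzmann_weights(
                [p.gibbs_free_energy, ref.gibbs_free_energy],
                temperature,
                labels=[p.label, ref.label],
            )
            w = dict(zip(ens.labels, ens.weights))
            odds[p.label] = w[p.label] / max(w[ref.label], 1e-300)
            fallbacks.append(p.label)
            pairwise[p.label] = {"tst_pair_fallback": str(exc)}

    raw = {ref.label: 1.0, **odds}
    total = sum(raw.values())
    fractions = {k: v / total for k, v in raw.items()}
    return SelectivityResult(
        fractions=fractions,
        method="VRAI",
        diagnostics={
            "reference_product": ref.label,
            "pairwise": pairwise,
            "tst_pair_fallbacks": fallbacks,
        },
    )
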