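# Methods

## Scope and assumptions

`dynaselect` predicts product percentages for reaction networks in which
selectivity is set beyond the first transition state (TS1): bifurcating
surfaces with a valley-ridge inflection, or cascades through a shallow
intermediate whose onward barriers are small compared to the drop from TS1.
The central physical assumptions are:

- **Curtin–Hammett-style conformer statistics at TS1.** Competing TS1
  conformers interconvert upstream fast enough that their fluxes follow
  Boltzmann factors of ΔΔG‡. Only relative free energies matter; rate
  constants, tunnelling and recrossing are out of scope.
- **Ballistic post-TS1 motion.** When every downstream transition state lies
  strictly below TS1 (the *energy check*, strict `<`; equality conservatively
  falls back to TST), trajectories are assumed to traverse the intermediate
  region without thermalizing, so the branching is decided by the geometry of
  the stream leaving TS1, not by downstream barrier heights.
- **Harmonic, separable transverse motion.** The lateral spread of the
  trajectory stream is the harmonic ground-state (or classical thermal)
  position spread of the TS1 real modes, transported rigidly ("frozen") from
  TS1 to the ridge. Growth of the spread during descent, transverse velocity
  spread and anharmonicity are neglected; the oracle comparison below
  measures the cost of these approximations.

## The two-dimensional reduction

All structures of one branch (TS1, intermediate, products) are mapped to the
vector of interatomic distances over the *selected bond pairs* — pairs whose
distance changes by more than `bond_threshold_A` (default 0.3 Å, halved up to
six times if fewer than two pairs qualify) between any two products or
between a product and TS1. The working plane is the Gram–Schmidt
orthonormalization of the INT→P1 and INT→P2 displacement vectors in that
bond-distance space; an explicit degenerate-input error is raised when these
are parallel within 1°, when a product coincides with the intermediate, when
the imaginary mode has no in-plane component (relative magnitude < 1e-8), or
when every real mode is perpendicular to the partition direction.

Normal-mode displacements are canonicalized before projection: whichever
convention the input declares (Gaussian-style Cartesian-normalized or
orthonormal mass-weighted), modes are stored as unit-norm Cartesian patterns
c with reduced mass μ = Σ_a m_a |c_a|², so that the harmonic amplitude
σ_k(μ, ω) applied along c reproduces the physical position distribution.
Bond-distance *rates* of a Cartesian pattern are computed against the TS1
geometry: for pair (i, j), the component of the relative displacement along
the unit bond vector.

The partition itself: ridge through INT along the bisector of the two
INT→product unit vectors (degenerating to the valley axis when the products
sit exactly opposite); stream center C = TS1 + ā·|ḡ|; δ = signed
perpendicular distance from C to the ridge (positive toward P1);
fraction(P1) = Φ(δ/σ). A δ of exactly zero reports exactly 50/50. Swapping
the product labels swaps the fractions bit-exactly because every quantity is
defined through in-plane inner products.

**Multi-product branches** run pairwise against a fixed reference product
(the one whose INT→product direction is most anti-parallel to ḡ; ties broken
lexicographically); odds o_p = f(p)/f(r) are renormalized with f_r ∝ 1. A
geometrically degenerate pair falls back to Boltzmann weighting of the two
product energies, recorded in the diagnostics. This pairwise construction is
accurate when the intermediate lies near the pairwise basin boundaries —
true for two-product bifurcations, where the shoulder sits on the dividing
ridge. It is *not* a good model for a trifurcation with a dominant central
channel: there the center of the stream lies on every pairwise ridge line
through INT, each pairwise partition returns ≈50/50, and the prediction
tends toward equal fractions while trajectories strongly favour the central
basin. This is a known structural limitation of the partition geometry, and
the three-well tests assert only its symmetry properties.

## Pipeline arithmetic

TS1 conformers are Boltzmann-weighted and pruned to 99% cumulative
population (`coverage_fraction`; members tied in energy at the boundary are
all retained, so the result is order-independent; pruned pathways contribute
exactly zero and are not redistributed). Each retained branch is resolved by
the stream partition (over *all* products reachable from its intermediate,
which folds channels through a stable downstream shoulder into one
multi-product analysis) or, on a failed energy check, by recursive Boltzmann
weighting over the downstream transition states with the same 99% rule
applied within the branch. Barrierless channels carry their full branch
weight directly to their product. When a dynamic complexation stage is
declared (a TS0 whose partition splits flow among intermediate
stereochemistry channels), the TS1 ensemble is weighted *within* each
stereochemistry group and scaled by the stage-0 fractions — sequential flow
multiplication, Sankey-style. Temperature (default 298.15 K), coverage,
width model and bond threshold are run-level hyperparameters recorded in
every result file.

## The synthetic surfaces and what they do (and do not) emulate

The model potential (see `model_surfaces`) places a first-order saddle at
the origin with its unstable direction along the path coordinate; downstream
the transverse potential morphs smoothly from a harmonic valley into a
double (or triple) well, crossing a VRI where the on-axis transverse
curvature changes sign. Defaults: barrier height 10 kcal/mol, well
separation 2 Å, ridge 2 kcal/mol above the wells, path length 1 Å, VRI
halfway, effective mass 1.008/2 amu. The energetic regime — a large drop
from TS1 with only a small residual ridge — is the regime in which the
ballistic assumption holds and which the method targets; the two asymmetry
knobs (`tilt`, rotating the saddle's imaginary eigenvector; `asymmetry`,
pushing the downstream valley and ridge sideways) stay small enough that
both outer wells persist (the wells annihilate when h·tilt exceeds
2κw/(3√3)).

The embedding maps (x, y) onto two H–H distances of a four-atom toy
molecule, 10 Å apart so that every non-designated distance varies by less
than the bond-selection threshold; the designated pair reduced mass
(1.008/2 amu) matches the surface's effective mass, making the embedded
normal-mode widths and the 2D oracle sampling physically consistent. The
intermediate of the emitted network is the on-axis shoulder at 3/4 of the
path — past the VRI, where the stream detaches from the axis, playing the
role of the shallow late intermediate of real cascades. Gibbs free energies
equal potential values (no thermal corrections), all atoms are hydrogens,
and there are no conformers — so passing tests on these fixtures validate
the projection, orientation, width and partition arithmetic, not the
robustness of bond-pair selection on crowded 100-atom systems.

## The trajectory oracle

Ground truth is generated on the analytic 2D surface itself, independent of
the projection machinery under test. Initial conditions at the saddle:
transverse position and velocity drawn from the stable mode's ground-state
Wigner distribution (`zero_point`) or classical Boltzmann (`thermal`), a
fixed forward kick of R·T (the flux-weighted mean translational energy
through a dividing surface) along the downhill imaginary eigenvector.
Draws are keyed by (seed, trajectory index) and antithetically paired
(trajectory 2k+1 negates the draws of 2k), which halves the Monte-Carlo
variance and makes the paired ensemble exactly mirror-symmetric — the
symmetric surface yields exactly 50/50 among decided trajectories.

Integration is velocity Verlet at 0.001 fs (energy drift ≤ 1e-6 of the
initial total energy per trajectory). A trajectory is assigned to the basin
whose capture disc (radius 0.5·w around each well) it enters first; on a
conservative two-dimensional surface trajectories never lose energy, so an
energy-based capture criterion can never trigger and the first-entry
committor is the standard, well-defined replacement. Trajectories that reach
the step cap undecided (quasi-periodic wanderers, up to ~25% at low ridge
heights) are excluded from the fractions and flagged when they exceed 20%.
The saddle eigenvectors come from a closed-form 2×2 eigensolver and the
stationary points from a hand-written Newton polish, both arranged so the
arithmetic mirrors bit-exactly under reflection — the mirror-symmetry
contract of the oracle is structural, not statistical.

The canonical validation sweep (`CANONICAL_SWEEP`) covers tilt-only
(±0.05, ±0.10), shift-only (0.10, 0.20) and moderate mixed settings,
spanning predicted major-product fractions up to ≈84%. Across this sweep
the stream partition tracks the 2000-trajectory oracle to within ~3.5
percentage points (max; mean ≈1.8). Outside it, when strong tilt and strong
shift act together (e.g. both at 0.10), the frozen-transport approximation
under-responds by ~8 points — a documented limitation, consistent with the
method's intended regime of moderate asymmetries.

## Numerical choices

- Energies internally in kcal/mol (Hartree inputs × 627.5095, shifted to a
  common zero at the lowest point); R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹;
  width formulas evaluated in SI via scipy.constants and returned in Å.
- Atom indices 0-based internally; file formats and reports follow
  chemistry convention.
- Atomic masses: standard atomic weights (fast path for common organic
  elements, rdkit's periodic table otherwise).
- Validation is strict and early: transition states must carry exactly one
  imaginary mode when modes are present, minima none; networks must be
  acyclic, share one atom-symbol sequence, and reference every product in
  the catalog; mixed energy units are rejected.
- Percentage normalization tolerances: branch fractions sum to 1 within
  1e-9, final percentages to 100 within 1e-6, Sankey flow conserved within
  1e-9.
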