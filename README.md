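# dynaselect

Dynamics-aware prediction of chemo- and stereoselectivity for reactions whose
outcome is decided *after* the first transition state — on bifurcating
potential energy surfaces with a valley-ridge inflection (VRI), where a single
transition state leads to more than one product basin and transition state
theory (TST) alone gets the product ratio wrong.

The package is aimed at computational organic chemists who already have
quantum-chemistry stationary-point data (geometries, Gibbs free energies,
harmonic frequencies from e.g. Gaussian 16) for the competing transition-state
conformers, intermediates and products of a reaction network — for example
chiral oxazaborolidinium-ion (COBI) catalysed carbonyl/diazo chemistry, where
ketone, aldehyde and epoxide channels share the same first transition state —
and want product percentages without running quasi-classical molecular
dynamics.

## The model

Two ingredients are combined along every pathway:

**1. Boltzmann/TST populations of competing transition states.** Conformers
of the first transition state (TS1) are populated as
w_i ∝ exp(−ΔΔG‡_i / RT), with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹; only the
low-energy conformers jointly carrying 99% of the population are kept
(renormalized). The same weighting resolves second-transition-state (TS2)
competition when TST is used for a branch.

**2. A trajectory-stream partition of the post-TS1 flow.** The surface beyond
TS1 is reduced to two dimensions built from the interatomic distances that
change between the competing products. In that plane, with the intermediate
INT at the origin:

- **ā** — the imaginary eigenvector of TS1, converted to bond-distance rates,
  projected, normalized, and oriented so that ā·ḡ ≥ 0;
- **ḡ** — the separation vector from TS1 to INT;
- the *ridge* — the line through INT bisecting the two INT→product directions;
- the stream width **σ** — each real TS mode contributes its harmonic spread
  σ_k = √(ħ/2μ_k ω_k) (zero-point, default) or √(k_B T/μ_k ω_k²) (thermal)
  times its bond-rate component perpendicular to ā, in quadrature.

The stream center is TS1 displaced along ā by |ḡ|; its signed perpendicular
offset δ from the ridge gives the branch ratio **fraction(P1) = Φ(δ/σ)**.
With more than two products sharing one TS1 and intermediate, pairwise
partitions against a fixed reference product are combined by odds.

A branch only receives the dynamic treatment after an *energy check*: every
downstream TS must lie strictly below TS1 in Gibbs free energy (the
post-TS1 region is then traversed ballistically); otherwise the branch falls
back to TST. Final percentages are Σ over pathways of (TS1 population ×
branch fraction), and a mean absolute error (MAE, percentage points) against
experimental percentages is reported when those are provided.

The package also ships a first-class synthetic-data module: analytic 2D
bifurcating surfaces with tunable mode tilt and sideways asymmetry, embedded
into a four-atom toy molecule (XYZ + normal-mode sidecars + network YAML),
plus a velocity-Verlet quasi-classical trajectory oracle that defines
reference product ratios on the same surfaces.

## Worked example

Generate a tilted model-surface fixture bundle and run both modes:

```bash
dynaselect fixtures --tilt 0.05 --out demo
dynaselect run --network demo/network.yaml --mode with_vrai --out demo/vrai.json
dynaselect run --network demo/network.yaml --mode tst_only  --out demo/tst.json
```

The result files contain (abridged):

```
with_vrai:  {"P1": 39.18, "P2": 60.82}   method: VRAI
            ("all downstream TSs below TS1 in Gibbs free energy")
tst_only:   {"P1": 15.62, "P2": 84.38}
```

The tilt rotates the imaginary eigenvector of the saddle so that the
trajectory stream favours the P2 basin — but only moderately: the stream
partition predicts 39/61. TST instead sees only the 1 kcal/mol free-energy
gap between the product wells and predicts 16/84. A 2000-trajectory
quasi-classical ensemble on the same surface
(`dynaselect oracle --tilt 0.05 --n 2000 --seed 1 --out demo/oracle.json`)
gives 35.9/64.1 — the dynamic prediction is within ~3 percentage points,
TST is ~20 points off.

Every result JSON embeds the resolved run configuration (temperature,
coverage, width model, bond threshold, mode) and SHA-256 checksums of its
inputs, so runs are reproducible from the result file alone. The diagnostics
(selected bond pairs, 2D coordinates, ā, ḡ, δ, σ, per-mode width
contributions, Sankey edge list) are sufficient to re-plot the reduced-PES
and flow diagrams.

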