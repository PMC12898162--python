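# Methods

## Model

The generator is an **overdamped Langevin (Brownian-dynamics) electrolyte**,
a statistical stand-in for coarse-grained membrane MD. Each particle obeys

    x(t+Δt) = x(t) + (D / k_BT) · F · Δt + sqrt(2 D Δt) · ξ,   ξ ~ N(0, 1)

with D the species diffusion coefficient and F the sum of:

- the applied uniform field force q·E_z ẑ (default E_z = 0.2 V/nm);
- optionally (interacting mode) minimum-image, hard-cutoff Coulomb pair
  forces scaled by 1/ε_r, with pair distances clamped at 0.3 nm (soft core
  standing in for the finite ion/bead size);
- optionally the exact periodic-capacitor field of antisymmetric surface
  charges on the membrane faces (`wall_sigma`, used only by the double-layer
  validation fixture).

The membrane is an impermeable slab [z_lower, z_upper]; mobile particles
reflect specularly off its faces. All three axes are periodic; positions are
wrapped into [0, L). A species with D = 0 is frozen (used for planted water
chains). There is no inertia, no explicit solvent, no lipid degrees of
freedom, and no pore *formation* dynamics — pores enter only as planted
fixtures. What the generator does reproduce, and what the analysis needs, is
the statistical structure: electrophoretic drift at the Einstein velocity
D·q·E/(k_BT), accumulation of counter-drifting ion clouds at the membrane
faces, exact charge neutrality, and (interacting mode) Debye-type screening.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| box | 18.1 × 18.1 × 12.6 | nm | reference membrane-electrolyte system size |
| membrane thickness | 4.3 | nm | bilayer slab, centered in z |
| applied_field_Ez | 0.2 | V/nm | electroporating-strength transmembrane field |
| temperature | 310 | K | physiological |
| timestep | 1e-3 | ns | keeps rms step (~0.07 nm) ≪ slab thickness and cutoff |
| coulomb_cutoff | 1.4 | nm | typical real-space electrostatics distance in coarse-grained membrane simulation; set ∞ for all-pairs |
| epsilon_r | 78 | — | implicit aqueous solvent screening of pair forces |
| D (Na⁺/Cl⁻/Mg²⁺) | 1.33 / 2.03 / 0.706 | nm²/ns | infinite-dilution literature values near 310 K |
| D (water bead) | 2.3 | nm²/ns | coarse-grained 4-water bead, 72 amu |

Ion counts for a molarity are placed in the solvent-accessible volume
(box minus slab): N_cation = round(c·N_A·V_solvent), anions fixed by
electroneutrality, which `SyntheticConfig` enforces as an invariant.

Units: nm, ns, e, eV, V. Constants: k_B = 8.617333262×10⁻⁵ eV/K,
1/(4πε₀) = 1.43996 eV·nm/e², so ε₀ = 0.0552635 e/(V·nm) and a Poisson solve
over e/nm³ yields volts directly.

## Charge gridding

Nearest-grid-point (NGP) and cloud-in-cell (CIC, trilinear over the 8
surrounding nodes) assignment onto a node-centered fully periodic grid;
charges are divided by the voxel volume so grid values are densities
(e/nm³). Both schemes conserve total charge to machine precision by
construction (partition of unity). **CIC is the default**: it removes the
voxel-quantization noise of NGP at the same cost and is the standard
particle-mesh choice. Grids come from `GridSpec.from_box`, which picks even
voxel counts so that dims × spacing reproduces the box exactly
(FFT-friendly, spacing within ~1% of the 0.1 nm target). Time averaging
accumulates on a single grid (streaming), which is mathematically identical
to averaging per-frame grids.

## Poisson solve and the inner potential

∇²φ = −ρ/ε₀ is solved spectrally: φ̂(k) = ρ̂(k)/(ε₀ ε_r |k|²) with the
continuum symbol, using scipy.fft rfftn/irfftn (≈4× faster than numpy.fft
here; mathematically identical). Under full periodic boundaries the k = 0
mode is arbitrary; we fix the **zero-mean gauge** φ̂(0) = 0 and report only
potential differences. A net-charged source makes the periodic problem
ill-posed and is rejected with an explicit error. The residual identity
(spectral Laplacian of φ returns −ρ/ε₀) holds to ~1e-14 relative; an
independent dense DFT-matrix reference (no FFT code path) agrees to ~1e-14 V.

The **inner potential** is the potential of the solution ions alone — the
applied uniform field never enters ρ, so it is excluded by construction.
The scalar summary is the mean of φ over a 1 nm-thick bulk reference slab
starting 1 nm above the upper membrane face, minus the same below the lower
face. Width and offset 1 nm place the windows outside the accumulated
surface layers yet away from the periodic boundary; both are recorded in
every report so the convention is auditable.

**Sign convention / direction of accumulation.** Under a +z field with 3D
periodic boundaries and an impermeable slab, cations drift upward, wrap
through the box top, and pile against the *lower* membrane face; anions
collect at the upper face. The signed inner potential (upper − lower) is
therefore negative at these conditions; concentration- and valence-trend
statements use |Δφ|.

## Pore detection

A frame bears a pore when a connected chain of water beads — contacts at
minimum-image distance ≤ 0.55 nm — links a water at or below the lower
leaflet plane to one at or above the upper plane. Operational details:

- **Neighbourhood restriction.** At bulk density the entire solvent is one
  contact component that percolates through the periodic z boundary, so
  "component touches both planes" alone would always fire. The graph is
  restricted to waters within one cutoff of the slab
  ([z_lower − c, z_upper + c]), periodic in x/y but *open* in z, forcing any
  spanning path through the slab interior.
- **Cutoff 0.55 nm**: first-shell contact distance for ~0.47 nm
  coarse-grained water beads, below the second shell. The contact query uses
  a 1e-9 relative guard so a distance exactly equal to the cutoff is
  included despite float rounding.
- **Persistence 2**: the electroporation time is the first frame starting
  ≥ 2 consecutive chain-bearing frames, rejecting single-frame flickers
  while keeping "first distinct chain" timing. Trajectories that never pore
  yield a **censored** event whose time (trajectory end) is a lower bound;
  censored runs are counted, never averaged as finite times.
- The returned chain is the breadth-first shortest path with lowest-id
  tie-breaking, so detection is deterministic.

## Kinematics

Unwrapping accumulates per-step minimum-image displacements and refuses
(with particle and frame named) if any stored-frame jump reaches L/2, where
the image becomes ambiguous. Drift velocity is the ensemble-mean unwrapped
z-displacement per unit time. The **charge concentration** covariate is the
sum over cation species of molarity × valence (NaCl at c → c; MgCl₂ at
c → 2c); it collapses the monovalent and divalent inner-potential curves
onto a single ordering.

## Validation oracles

- **Capacitor**: ±σ parallel sheets, Δφ = σd(1 − d/L_z)/ε₀, cross-checked by
  direct 1D integration of the periodic field; solver agrees within 0.8% at
  0.1 nm spacing (discretization of the sheet, first-order in spacing).
- **Cosine eigenmode**: ρ = A cos(kz) gives φ = A cos(kz)/(ε₀k²) exactly on
  the spectral grid; agreement to machine precision.
- **Dense reference**: explicit per-axis DFT matrices (einsum, no FFT)
  inverting the same continuum symbol.
- **Einstein drift**: v = D·q·E/(k_BT); with the endpoint estimator
  mean Δz(T)/T the standard error over N ions is sqrt(2DT)/(T·sqrt(N)).
- **Debye screening**: charged-wall fixture (antisymmetric ±8 e faces on a
  7×7 nm wall, 0.05 mol/L 1:1 electrolyte, ε_r = 78, all-pairs Coulomb). The
  face-antisymmetrized charge excess decays exponentially; the fitted decay
  length sits within ~5–8% of λ_D = sqrt(ε_rε₀k_BT/Σnᵢqᵢ²), the small
  positive bias being the finite-concentration (nonlinear Gouy–Chapman)
  correction to the linearized Debye form.

## Resolved modelling choices

- **Charge assignment default**: CIC (see above); NGP retained for
  cross-checks and conservation tests.
- **Inner-potential scalar**: bulk-slab Δφ with width 1 nm, offset 1 nm
  (see above), rather than e.g. peak-to-peak of the axial profile, which is
  dominated by the contact layers.
- **Charge concentration**: molarity × valence, a stated convention.
- **Pore rule**: connectivity with 2-frame persistence and censoring
  (see above).
- **Diffusion coefficients**: infinite-dilution literature values; the
  generator does not model concentration-dependent mobility.

## Limitations

- The generator is not MD: no lipid dynamics, no pore nucleation, no
  electrostriction; pore events appear only via planted fixtures, so
  electroporation *times* from the generator are bookkeeping, not physics.
- Interacting mode is O(N²) per step; practical up to a few thousand
  particles.
- Slab reflection resolves single-step face crossings; a step long enough to
  jump the entire slab would pass through undetected, so the timestep must
  keep typical steps well below the slab thickness (the defaults do, by two
  orders of magnitude). Non-finite coordinates abort with the particle and
  step named.
- The spectral solve uses the continuum −|k|² symbol, so "exact" statements
  are exact for the finite Fourier spectrum of the grid, not for point
  charges; the capacitor error (~0.8% at 0.1 nm) is the corresponding
  discretization error of a sheet source.
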