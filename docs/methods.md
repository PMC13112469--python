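# Methods

`pgalbind` computes the implicit-solvent binding energetics of poly(gallic
acid) (PGAL) with L-histidine, and the statistics of the accompanying
in-vitro assays.  This note records the models, the numerical choices, and
what the synthetic inputs do and do not represent.

## Binding free-energy model

For a rigid receptor–ligand pose the binding free energy is decomposed as

    ΔG_b = ΔG_solv + ΔG_coul + ΔG_non-elec

* **ΔG_solv** — change in electrostatic solvation free energy on binding:
  G_solv(complex) − G_solv(receptor) − G_solv(ligand), each from a
  two-dielectric Poisson calculation (solvent ε = 78, solute ε = 3.0 — a
  value in the polyimide/polypropylene range appropriate for a dense
  polyphenolic solute).  Positive for charged contact pairs (desolvation
  penalty).
* **ΔG_coul** — Coulombic contribution, the inter-molecular pair sum
  Σ k_e q_i q_j / (ε_solute r_ij).  Under rigid binding the intra-molecular
  sums cancel exactly, so only cross-species pairs enter.  The uniform
  dielectric for this term is the solute value (3.0), following the standard
  Poisson–Boltzmann binding-energy protocol; it is a config switch.
* **ΔG_non-elec** — hydrophobic term γ·ΔSASA with γ = 5 cal·mol⁻¹·Å⁻²
  (converted to kJ/mol) and ΔSASA = SASA(complex) − SASA(receptor) −
  SASA(ligand), probe radius 1.4 Å.  ΔSASA ≤ 0 for any contacting pose, so
  the term is always favorable and small.

Poses are ranked ascending in ΔG_b (most favorable first; ties broken by
replicate then pose index), and the best pose gets an interaction report
with a hydrogen-bond map.

## Poisson solver

The equation ∇·(ε∇φ) = −4π k_e ρ is discretized on a regular grid
(7-point stencil).  Choices:

* **Dielectric boundary** — abrupt atom-sphere (van der Waals) boundary:
  nodes inside any atom sphere get ε_solute, others ε_out; edge
  dielectrics are harmonic means of the adjacent nodes.  No probe-traced
  molecular surface; the scheme is the simplest that converges to the Born
  closed form under grid refinement.
* **Charges** — trilinear spreading to the 8 surrounding nodes; the energy
  ½Σ q_i φ(r_i) is evaluated by trilinear interpolation at atom centers.
* **Boundary conditions** — analytic Coulomb (or Debye–Hückel when an ionic
  strength is set; default 0 M, plain Poisson) superposition in ε_out on the
  box faces.  Optional two-level focusing: a coarse, heavily padded solve
  provides Dirichlet data for the fine box.
* **Linear solver** — the interior system is symmetric positive definite and
  is solved with Jacobi-preconditioned conjugate gradients started from the
  analytic superposition field; convergence at relative residual ≤ 1e-6
  (cap 20 000 iterations).  A non-converged solve is flagged and the pose is
  dropped from ranking rather than imputed.
* **Self-energy** — removed strictly by same-grid differencing: solvation is
  G(ε_out = ε_solvent) − G(ε_out = ε_solute) on the identical grid, never by
  analytic subtraction.  The homogeneous reference run also cancels most of
  the discretization error of the point-charge self-term.
* **Grids** — minimum 33 nodes per axis, padding ≥ 5 Å beyond the atom
  spheres.  Accuracy protocol: 0.25 Å focused spacing reproduces the Born
  ion (q = 1 e, a = 2 Å, 1→78) within ~2% of −342.9 kJ/mol.  Screening
  protocol (pose scoring): one shared study grid per receptor/ligand system
  at 1.4 Å spacing covering the whole contact shell, so the receptor
  solvation is computed once and every pose is differenced on the same grid.

## Surface areas

Shrake–Rupley quadrature on probe-expanded spheres with a deterministic
golden-spiral point set (default 960 points/atom; neighbor culling at
r_i + r_j + 2·probe).  Coordinates are first expressed in a canonical
molecular frame (principal axes with third-moment sign fixing), which makes
SASA bit-reproducible and invariant under rigid motion of the molecule.  The
price is that ΔSASA of well-separated species vanishes only to quadrature
tolerance (~0.1% of the total area at 960 points), not exactly; molecules
with degenerate principal moments have no unique frame and are only
approximately invariant.  Hydrogens: templates carry polar hydrogens only;
nonpolar hydrogens are folded into heavy-atom radii.

## Synthetic structures

The study's structural inputs (a quantum-chemically optimized PGAL nonamer
and docked complexes) are not deposited, so the package generates idealized
stand-ins:

* **Gallic unit / oligomer** — a planar idealized gallic-acid unit (benzene
  ring, carboxyl, three ring hydroxyls; 16 atoms with explicit polar
  hydrogens) stacked on a helix with rise 3.5 Å and twist 40°/unit,
  reflecting the polymer's helical architecture.  Default nonamer, net
  charge 0 (fully protonated).
* **Histidine** — idealized geometry; zwitterion (NH3+/COO−, neutral ring,
  net 0) and imidazolium-protonated form (net +1) share one heavy-atom
  skeleton and differ by one ring proton.
* **Partial charges** — the bundled table holds Gasteiger-like template
  values normalized so each residue sums exactly to its formal charge
  (GAL 0, zwitterion 0, protonated +1).  No published charge set exists for
  these species, so the table is explicitly swappable input, and every
  validated quantity depends only on the formal-charge invariants and
  closed-form oracles, not on specific template values.
* **Poses** — docking is replaced by a seeded rigid-body sampler: uniform
  random orientations (normalized 4-normal versors) and surface-biased
  translations sliding the ligand along a random ray until the closest
  atom-center approach lies in [2.2, 4.5] Å (clash floor, contact shell).
  Default campaign: 50 poses × 3 replicates per protonation state,
  replicate r seeded with seed + r.  Ranking uses the package's own ΔG_b,
  the same criterion the original docking campaign used for best-pose
  selection.  Bounded attempts (10 000/pose) guard impossible constraints.

**What passing tests show** — the algorithms are validated against
closed-form oracles (Born ion, Coulomb constants, sphere/lens areas) and
arithmetic identities, and the full pipeline is deterministic and respects
the sign structure of the decomposition (desolvation penalty positive,
buried-area term negative).  The synthetic geometry does *not* reproduce the
published per-complex energies (−55 and −88 kJ/mol), which depend on the
unpublished optimized structures and poses; those numbers are validated only
through the decomposition identity, which is exact.  Synthetic best-pose
energies are a few kJ/mol — idealized random contact poses lack the
optimized complementary charge contacts of docked structures — so the
published ordering between the two protonation states is a soft expectation,
logged but not asserted.

## Assay statistics

* **Probit IC50** — response = Φ(β0 + β1·log10 c).  With replicate counts:
  binomial maximum likelihood (GLM, probit link; logit optional).  Without:
  least squares on the fractions.  IC50 = 10^(−β0/β1); SE by the delta
  method from the coefficient covariance.  An IC50 outside the dosed range
  is flagged as an extrapolation.  Scale equivariance (concentration units
  cancel) holds to machine precision.  The synthetic generator uses a true
  IC50 of 0.165 mg/mL (the DPPH value for the unmodified polymer) and probit
  slope 2.2 over 8 log-spaced doses (0.02–1.5 mg/mL), with optional binomial
  noise at 4 replicates/dose matching the quadruplicate assay design.
* **Calibration** — ordinary least squares on standards (Trolox 0–500 µM,
  TNBSA/L-histidine), inverse prediction for quantification; zero slope is a
  quantification error.
* **ROS inhibition** — 100 × (control − treated)/control on percent-positive
  cells, reported rounded to integers (full precision retained), with a
  > 70% flag column.  The bundled table carries the THP-1 flow-cytometry
  percentages at 24 h and 48 h.

## Degenerate inputs and tie-breaks

Empty molecules assign trivially but refuse energy/surface computation;
atoms closer than 0.7 Å fail validation; coincident charged atoms raise a
singularity error; flat dose-response data and zero calibration slopes are
fit errors; ranking ties break deterministically by (replicate, pose_id).

## Known limitations

Idealized geometry (no torsional flexibility, no QM-optimized helix);
template charges are plausible but not fitted; abrupt dielectric boundary
(no probe-traced cavity) biases absolute solvation magnitudes at coarse
spacing; the distance-only hydrogen-bond criterion (heavy-atom cutoff
3.35 Å, no angle term) overcounts relative to angular criteria; linearized
salt screening only.
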