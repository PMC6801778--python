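# Methods

This note documents the models and estimators implemented in `memanchor`,
the defaults chosen where several conventions are in use, and what the
synthetic-data generators do and do not emulate.

## Coordinate conventions and trajectory model

All quantities are computed in nm/ns/amu on orthorhombic boxes with the
bilayer normal fixed to +z (planar membranes built in the x,y-plane; no
normal estimation, no triclinic or curved-membrane support). File readers
and writers (MDAnalysis underneath) convert Angstrom/ps formats at the
boundary. DCD headers often carry meaningless timestamps, so
`load_trajectory` accepts a `time_step` override and otherwise falls back
to frame indices when stored times are not strictly increasing.

Leaflets are assigned per frame by a median-z split of the phosphorus
atoms (one per phospholipid). The median split is invariant under common
z-translation, so slow membrane drift cannot flip labels; cholesterol,
which has no phosphate, can be assigned by passing its hydroxyl oxygen
instead. Whether upstream trajectories were wrapped or whole-molecule
imaged does not matter for these analyses: displacements are always
reduced to their minimum image first, with the tie at exactly +L/2 kept
positive (documented boundary convention of `wrap_displacement`).

## Membrane observables

**Thickness** is the difference of mean phosphorus z between leaflets — a
phosphate-plane separation, not an electron-density thickness. **Area per
lipid** is lateral box area over lipids per leaflet, counting every lipid
molecule (cholesterol included) in the denominator; Voronoi per-lipid areas
are out of scope.

**Order parameters.** `S_CD = ⟨(3cos²θ_CH − 1)/2⟩` per chain carbon
(C2–C15 of the saturated sn-1 palmitoyl chain), averaged over both C–H
bonds, all selected lipids and all frames. The reported chain average is
the mean of |S_CD| over carbons so that the rigid planar limit maps to
+0.5, matching the sign convention of deuterium-NMR tables. Magnitudes are
taken only after ensemble averaging — |P2| of a single methylene snapshot
is upward-biased noise, not an order parameter. With explicit hydrogens
(all-atom force fields) the C–H vectors are used directly; for H-less
topologies a geometric reconstruction from the carbon skeleton
(tetrahedral methylene hydrogens perpendicular to the C(i−1)→C(i+1) axis,
in the Douliez spirit) is available via `reconstruct=True`; the two routes
agree within 0.01 on chains whose hydrogens are placed tetrahedrally
(terminal carbons, lacking both neighbours, are skipped by the rebuild).

**Local order maps** bin each lipid's signed instantaneous chain-average
P2 by the grid cell (default 0.2 nm spacing) of its wrapped lateral chain
centroid, time-average per cell, take magnitudes, and subtract the global
average. Cells never visited are flagged and excluded. The scalar
anchor-proximal deviation averages lipids whose centroid lies within the
cutoff (default 0.5 nm, minimum-image) of the per-frame anchor lateral
centroid. The map assumes a common S_CD sign across the membrane (negative
for fluid acyl chains), which holds for every system in scope.

**Uncertainties** for thickness/APL/order are standard deviations over 5
contiguous time blocks; the estimator behind published ± values is
generally unstated, and block averaging is the conservative default for
correlated trajectory data.

## Lateral diffusion

Tracks are unwrapped by replacing each consecutive-frame lateral
displacement with its minimum image before cumulative summation; steps
reaching box/2 are counted and reported as undersampling warnings. For 2D
Brownian motion the squared jump over lag Δt is exponentially distributed
with mean 4DΔt, so the jump-distance mixture is fitted by
expectation-maximisation on squared jumps — maximum likelihood on the raw
displacements, with closed-form M-steps and no histogram binning
sensitivity. The fit is deterministic given the seed (fixed multi-start
schedule: quantile split, geometric bracket, one seeded perturbation).
Components with fraction < 0.01 are pruned with a warning and the rest
refitted; the dominant component is never pruned.

Defaults: lag 1 ns with overlapping time origins (both choices exposed;
overlapping origins maximise statistics at the cost of correlated jumps,
which the block uncertainties absorb). Model order is chosen between one
and two components by BIC, with a margin of 10 required before the
two-component model is reported — species tables conventionally carry one
coefficient. Uncertainties are sds over 5 contiguous track segments,
refitted independently. The MSD cross-check fits a line to the ensemble-
and origin-averaged MSD(t) and reports slope/4, flagging negative slopes
rather than clamping. No anomalous exponents or finite-size
(Saffman–Delbrück) corrections are applied.

Unit note: coefficients are computed in nm²/ns and reported in
10⁻⁷ cm² s⁻¹ (multiply nm²/ns by 100). Mobility ratios are rounded to two
significant figures, with first-order error propagation
(σ_r = r·√((σ_a/a)² + (σ_b/b)²)) in cross-system tables.

## Anchoring geometry

**Insertion depth** = (mean z of same-leaflet phosphorus atoms within
1.0 nm lateral distance of the anchor-carbon centroid) − (minimum z over
anchor carbons). Positive means inserted below the phosphate plane; values
are never clamped so desorption excursions remain visible. The 1.0 nm
neighbour cutoff operationalises "surrounding headgroups" and is
configurable; with fewer than three neighbours the whole-leaflet mean is
used with a warning. Depth-distribution modality compares 1- vs
2-component Gaussian mixtures by BIC (scikit-learn, deterministic
initialisation); histograms default to 0.05 nm bins.

**Per-residue membrane distances** use the mass-weighted residue COM z
minus the proximal (upper) leaflet mean phosphorus z — the mean plane, not
local phosphates, since residues far from the anchor have no natural local
neighbourhood.

**RMSF** superposes the fit selection of every frame onto frame 1
(mass-weighted Kabsch with reflection guard; collinear sets are rejected)
and reports per-atom fluctuations about the fitted-trajectory mean, so
rigid tumbling contributes nothing. The result depends on the reference
frame only at the sub-2% level on jittered fixtures.

**Orientation.** With A the anchor-carbon centroid, G the G-domain
(residues 15–185) mass-weighted COM, S the switch-region COM (switch I
50–60, switch II 75–92) and M = A − ẑ: θ is the angle between G − A and
+z, and ω the dihedral M–A–G–S in [0, 360). The atom-level definition
behind the published θ/ω descriptors is not fully specified anywhere
accessible, so this A/G/S/M construction is a documented, self-consistent
stand-in that preserves the stated constraints — θ = 90° is a
membrane-parallel domain, and ω separates the torsional populations,
labelled `exo` within ±45° of 80° and `endo` within ±45° of 190° (the
reported population centres), `intermediate` otherwise. θ of exactly
0°/180° leaves ω undefined (reported as NaN). The quantity is called ω
throughout; a source that names the same torsion φ is describing the same
descriptor.

## Synthetic data: what is emulated

Generators plant ground truth for every observable and are bit-for-bit
reproducible given their spec (seed included).

* **Bilayers** place pseudo-lipids on a lattice with phosphate planes at
  ±thickness/2 (Gaussian z-jitter, default sd 0.05 nm, redrawn per frame),
  a lateral box satisfying Lx·Ly = n·APL exactly, and chain C–H vectors
  drawn from an equatorial-band orientation distribution (uniform in solid
  angle within half-angle w of the membrane plane). The band gives
  |⟨P2⟩| = cos²w/2, calibrated to the target order by bisection against
  numerical quadrature; the closed form and a Monte-Carlo estimate serve as
  independent cross-checks in the tests. An optional "disorder disk"
  reduces the planted order inside a lateral disk to emulate
  anchor-induced local disordering. Default spec values describe the
  six-component early-endosome-like membrane (thickness 4.54 nm, APL
  0.466 nm², order 0.305, with a plausible endosomal species mix — the mix
  only labels residues).
* **Brownian tracks** draw per-axis Gaussian steps of variance 2DΔt and
  wrap them into the periodic box, returning both the wrapped trajectory
  and the unwrapped truth. Positions are quantized to 2⁻²⁰ nm so that,
  with a dyadic box length, all wrap/minimum-image arithmetic is exact in
  double precision and the unwrap round trip is bit-exact. Steps larger
  than box/4 are rejected as un-unwrappable.
* **Anchored proteins** pose a coarse pseudo-protein (one Cα bead per
  residue 1–215 plus 20-carbon anchor chains at residues 212/213) so that
  per-frame planted depth/θ/ω hold exactly: the deepest anchor carbon sits
  at the local phosphate-plane mean minus the drawn depth (same neighbour
  rule as the analysis), the G-domain COM at the planted pivot angle, and
  the switch blob at the planted torsion via an explicit dihedral
  construction. Optional per-residue jitter feeds RMSF fixtures.

These pseudo-systems are geometric stand-ins: no force-field energetics,
no chain conformational statistics, no real dynamics beyond Brownian
steps, no protein secondary structure. Passing recovery tests therefore
demonstrates correctness of the estimators and their conventions, not the
physics of any particular membrane; applied to real trajectories the same
code paths run unchanged, but statistical issues absent from the fixtures
(correlation times, finite-size effects, force-field bias) re-enter.

## Numerical choices and degenerate inputs

Bisection tolerance for the cone calibration is 1e-6 on the order value.
EM stops at a relative log-likelihood change of 1e-8 (600-iteration cap,
non-convergence is an error, not a silent result). Leaflet assignment
falls back to a rank split when the median value is attained by multiple
atoms. `wrap_displacement` keeps +L/2 at the tie. Superposition rejects
collinear point sets; mixture fractions are renormalised after pruning so
they sum to 1 exactly. Problem sizes in the test suite and acceptance
script (tens of lipids, hundreds to 2000 frames, ≤ a few hundred tracks)
were chosen as the smallest ensembles at which the planted-recovery
tolerances are comfortably met.

## Known limitations

Single planar bilayer, +z normal, orthorhombic boxes only; APL is a box
quotient (no per-lipid tessellation); JDA assumes free 2D Brownian motion
within each subpopulation; the θ/ω construction is a stand-in as noted
above; the Gaussian-mixture modality test can prefer two components for
heavy-tailed unimodal data at very large n.
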