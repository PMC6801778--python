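# memanchor

Post-processing toolkit for molecular-dynamics trajectories of
lipid-anchored peripheral membrane proteins — the Rab5 GTPase with its
C-terminal geranylgeranyl (GG) anchors is the motivating system. The
package computes, from a topology + trajectory (PDB/GRO + DCD/XTC):

* **membrane structure** — phosphate-plane bilayer thickness, area per
  lipid (APL), per-carbon acyl-chain order parameters
  `S_CD = ⟨(3 cos²θ_CH − 1)/2⟩` for the saturated sn-1 palmitoyl chain
  (C2–C15), headgroup P→N tilt angles, and lateral maps of the local order
  deviation around a membrane anchor (default 0.5 nm cutoff);
* **lateral diffusion** — single-particle tracks unwrapped through periodic
  boundaries, jump-distance analysis (JDA) with maximum-likelihood mixture
  fitting of the 2D Brownian jump density
  `p(r) = Σᵢ fᵢ · r/(2DᵢΔt) · exp(−r²/(4DᵢΔt))`, an MSD cross-check
  (`D = slope/4`), and mobility ratios between systems;
* **anchoring geometry** — GG-anchor insertion depth below the local
  phosphate plane, depth-distribution modality (1- vs 2-component Gaussian
  mixture by BIC), per-residue protein–membrane z-distances, radius of
  gyration, superposition-based Cα RMSF (Kabsch), and the G-domain
  orientation descriptors: pivot angle θ (θ = 90° ⇔ domain parallel to the
  bilayer) and internal torsion ω separating `endo` (≈190°) from `exo`
  (≈80°) switch-region conformations.

Because bilayer MD trajectories are rarely deposited, the package also
ships first-class **synthetic-data generators** (`memanchor.synthetic_data`)
that produce pseudo-bilayers, Brownian track sets and anchored-protein
poses with planted ground truth for every observable; every analysis stage
is validated by recovering those planted values.

## Worked example

```bash
memanchor run --config demo.yml
```

with

```yaml
seed: 7
outdir: demo_out
systems:
  - name: six_component
    bilayer: {n_lipids_per_leaflet: 36, thickness: 4.54, area_per_lipid: 0.466,
              target_order: 0.305, jitter_sd: 0.05, n_frames: 10}
    tracks: {populations: [{species: POPC, d: 0.74, fraction: 0.5},
                           {species: CHOL, d: 0.59, fraction: 0.5}],
             n_particles: 120, n_steps: 600}
    protein: {depth_means: [1.74], depth_sds: [0.15], depth_weights: [1.0],
              theta: 90.0, omega: 190.0, n_frames: 400}
```

writes `demo_out/report.json` plus CSV tables; the recovered values are

```
thickness 4.538 +- 0.008 nm
APL       0.466 nm^2
order     0.304 +- 0.001
D(CHOL) 0.594 +- 0.005 e-7 cm2/s
D(POPC) 0.737 +- 0.013 e-7 cm2/s
depth 1.739 +- 0.148 nm, modality 1
theta 90.0 deg, omega 190.0 deg, labels {'endo': 1.0, ...}
```

i.e. the analysis recovers the planted early-endosome-like membrane
(4.54 nm thick, APL 0.466 nm², order 0.305), the two planted diffusion
populations (0.74 and 0.59 ×10⁻⁷ cm² s⁻¹ — POPC faster than cholesterol),
a unimodal anchor depth of 1.74 nm, and a membrane-parallel G domain in the
`endo` torsion. Uncertainties are standard deviations over five contiguous
trajectory blocks.

The same analyses are importable as functions
(`memanchor.membrane_props.bilayer_thickness`,
`memanchor.diffusion.fit_jda`,
`memanchor.protein_geometry.anchor_insertion_depth`, ...) for use on loaded
trajectories:

```python
from memanchor import traj_core as core, membrane_props as mem

traj = core.load_trajectory("system.pdb", "system.dcd", time_step=1.0)  # ns/frame
phosphorus = core.select(traj.topology, "element P and name P")
print(mem.bilayer_thickness(traj.frames[0], phosphorus))
```

## Selection mini-grammar

`select(topology, expr)` supports the keywords `name`, `resname`,
`element`, `segid` (each followed by one or more values), `resid` with
1-based inclusive ranges (`resid 15:185`), and `and` / `or` / `not` with
parentheses. Examples: `element P and resname POPC`,
`name CA and resid 50:60 or name CA and resid 75:92`. An empty match is a
valid (logged) empty selection; malformed input raises `SelectionError`.

## Units

nm, ns and amu internally; diffusion coefficients are reported in
10⁻⁷ cm² s⁻¹ (1 nm²/ns = 100 ×10⁻⁷ cm² s⁻¹). Angstrom-based file formats
are converted at the I/O boundary. The bilayer normal is +z.

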