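"""Synthetic trajectories with planted ground truth.

Generators for (a) planar two-leaflet bilayers of pseudo-lipids with planted
phosphate-plane separation, area per lipid and acyl C-H orientation
statistics, (b) 2D Brownian particle tracks at planted diffusion
coefficients wrapped into a periodic box, and (c) anchored pseudo-protein
configurations with planted anchor insertion depths and orientation angles.

The pseudo-molecules are geometric stand-ins, not chemically valid
structures: atom naming mimics the CHARMM-style conventions (P, N, C2..C15,
H2A/H2B, ...) only as far as selections and the analysis operations need.
Every generator is bit-for-bit reproducible given its spec (which includes
the seed).

C-H orientation model
---------------------
Planted order parameters use unit vectors distributed uniformly (in solid
angle) over an equatorial band: polar angle within ``halfangle`` of 90 deg.
At band half-width w the second-Legendre average is (sin^2 w - 1)/2, so
|<P2>| runs from 0.5 (w=0, all bonds in-plane: the rigid planar limit) to 0
(w=90 deg, the isotropic sphere). The calibration routine inverts this
relation numerically (bisection against quadrature) rather than using the
closed form, so it can serve as an independent oracle for the analysis side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .traj_core import (
    ELEMENT_MASSES,
    Frame,
    Topology,
    Trajectory,
    wrap_into_box,
)
from .diffusion import TrackSet

__all__ = [
    "BilayerSpec",
    "TrackSpec",
    "AnchorSpec",
    "cone_halfangle_for_order",
    "sample_ch_vectors",
    "make_bilayer",
    "make_brownian_tracks",
    "make_anchored_protein",
]

CHAIN_CARBONS = tuple(range(2, 16))
CH_BOND = 0.109          # nm
CC_SPACING = 0.127       # nm, vertical rise per chain carbon


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class BilayerSpec:
    """Planted bilayer parameters.

    Defaults emulate the six-component early-endosome model membrane:
    thickness 4.54 nm, area per lipid 0.466 nm^2, chain order 0.305, with a
    plausible endosomal composition (the mixture ratios only steer residue
    labels on the pseudo-lipids).
    """

    n_lipids_per_leaflet: int = 64
    thickness: float = 4.54          # nm, phosphate plane separation
    area_per_lipid: float = 0.466    # nm^2
    target_order: float = 0.305      # chain-averaged |S_CD| in (0, 0.5]
    species_fractions: dict = field(default_factory=lambda: {
        "POPC": 0.37, "CHOL": 0.25, "PSM": 0.13,
        "POPE": 0.10, "POPS": 0.10, "PI3P": 0.05,
    })
    jitter_sd: float = 0.05          # nm, P-plane roughness
    n_frames: int = 5
    seed: int = 0
    # optional planted local perturbation: lipids whose lateral site lies
    # within disk_radius of disk_center get order target_order - disk_delta
    disk_center: tuple | None = None
    disk_radius: float = 0.5
    disk_delta: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_lipids_per_leaflet, self.thickness, self.area_per_lipid,
               self.target_order, self.n_frames) <= 0:
            raise ValueError("all bilayer spec quantities must be positive")
        if not 0 < self.target_order <= 0.5:
            raise ValueError("target_order must lie in (0, 0.5]")
        total = sum(self.species_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("species fractions must sum to 1")


@dataclass
class TrackSpec:
    """Planted Brownian-track parameters; D in 1e-7 cm^2 s^-1."""

    populations: list = field(default_factory=lambda: [("POPC", 1.36, 1.0)])
    n_particles: int = 100
    n_steps: int = 500
    dt: float = 1.0      # ns
    box: float = 15.0    # nm
    seed: int = 0

    def __post_init__(self) -> None:
        fr = sum(p[2] for p in self.populations)
        if abs(fr - 1.0) > 1e-6:
            raise ValueError("population fractions must sum to 1")
        if any(p[1] < 0 for p in self.populations):
            raise ValueError("diffusion coefficients must be non-negative")


@dataclass
class AnchorSpec:
    """Planted anchored-protein parameters.

    Depth distribution is a Gaussian mixture (means/sds/weights, nm);
    defaults plant the doubly anchored protein in the endosomal membrane
    (unimodal depth 1.74 nm, domain parallel to the surface, switch regions
    in the membrane-facing 'endo' torsion).
    """

    depth_means: tuple = (1.74,)
    depth_sds: tuple = (0.15,)
    depth_weights: tuple = (1.0,)
    theta: float = 90.0      # degrees
    theta_sd: float = 0.0
    omega: float = 190.0     # degrees
    omega_sd: float = 0.0
    n_anchors: int = 2
    n_frames: int = 200
    domain_distance: float = 2.5   # nm, anchor centroid to G-domain COM
    blob_jitter_sd: float = 0.0    # nm, per-frame positional noise on residues
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.depth_weights) - 1.0) > 1e-6:
            raise ValueError("depth weights must sum to 1")
        if not (len(self.depth_means) == len(self.depth_sds) == len(self.depth_weights)):
            raise ValueError("depth mixture arrays must have equal length")
        if self.n_anchors not in (1, 2):
            raise ValueError("n_anchors must be 1 or 2")


# ---------------------------------------------------------------------------
# Orientation-distribution calibration
# ---------------------------------------------------------------------------

def _band_p2_mean(halfangle: float) -> float:
    """<P2(cos theta)> for unit vectors uniform over the equatorial band,
    computed by numerical quadrature over cos(theta)."""
    s = np.sin(halfangle)
    if s <= 0:
        return -0.5
    val, _ = quad(lambda c: 1.5 * c * c - 0.5, -s, s)
    return val / (2.0 * s)


def cone_halfangle_for_order(target_s: float, tol: float = 1e-6) -> float:
    """Band half-angle (radians) whose |<P2>| equals ``target_s``.

    |<P2>| decreases monotonically from 0.5 at half-angle 0 (planar limit)
    to 0 at pi/2 (isotropy); the root is found by bisection against the
    quadrature evaluation. Targets outside (0, 0.5] are unattainable.
    """
    if not 0 < target_s <= 0.5:
        raise ValueError("target order must lie in (0, 0.5]")
    lo, hi = 0.0, np.pi / 2
    if abs(_band_p2_mean(lo)) < target_s - tol:
        raise ValueError("target order unattainable")
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if abs(_band_p2_mean(mid)) > target_s:
            lo = mid
        else:
            hi = mid
        if abs(abs(_band_p2_mean(mid)) - target_s) < tol:
            return mid
    return 0.5 * (lo + hi)


def sample_ch_vectors(rng: np.random.Generator, n: int, halfangle: float) -> np.ndarray:
    """Unit vectors uniform in solid angle over the equatorial band."""
    s = np.sin(halfangle)
    c = rng.uniform(-s, s, size=n)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    sin_t = np.sqrt(1.0 - c**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), c])


# ---------------------------------------------------------------------------
# Bilayer generator
# ---------------------------------------------------------------------------

_PHOSPHO_SPECIES = {"POPC", "PSM", "POPE", "POPS", "PI3P"}
_HAS_NITROGEN = {"POPC", "PSM", "POPE", "POPS"}


def _lipid_atom_plan(species: str):
    """(names, elements) for one pseudo-lipid of the given species."""
    names, elements = [], []
    if species in _PHOSPHO_SPECIES:
        names.append("P")
        elements.append("P")
        if species in _HAS_NITROGEN:
            names.append("N")
            elements.append("N")
        for k in CHAIN_CARBONS:
            names.append(f"C{k}")
            elements.append("C")
            for suffix in ("A", "B"):
                names.append(f"H{k}{suffix}")
                elements.append("H")
    else:  # cholesterol-like: hydroxyl oxygen + short H-less carbon body
        names.append("O3")
        elements.append("O")
        for k in range(2, 9):
            names.append(f"C{k}")
            elements.append("C")
    return names, elements


def make_bilayer(spec: BilayerSpec) -> Trajectory:
    """Build a two-leaflet pseudo-bilayer trajectory with planted observables.

    Phosphate planes sit at +-thickness/2 (plus Gaussian jitter of sd
    ``jitter_sd``, redrawn each frame); the lateral box satisfies
    Lx*Ly = n_lipids_per_leaflet * area_per_lipid exactly; every chain C-H
    vector is drawn from the equatorial-band distribution calibrated to
    ``target_order`` (or ``target_order - disk_delta`` inside the optional
    planted disk).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lipids_per_leaflet
    L = float(np.sqrt(n * spec.area_per_lipid))
    Lz = spec.thickness + 3.0
    half = spec.thickness / 2.0
    z_center = Lz / 2.0

    halfangle = cone_halfangle_for_order(spec.target_order)
    halfangle_disk = None
    if spec.disk_center is not None and spec.disk_delta > 0:
        halfangle_disk = cone_halfangle_for_order(spec.target_order - spec.disk_delta)

    # species assignment: deterministic counts from fractions, shuffled
    species_list = []
    items = sorted(spec.species_fractions.items())
    counts = {s: int(round(f * 2 * n)) for s, f in items}
    while sum(counts.values()) < 2 * n:
        counts[items[0][0]] += 1
    while sum(counts.values()) > 2 * n:
        for s in counts:
            if counts[s] > 0 and sum(counts.values()) > 2 * n:
                counts[s] -= 1
    for s, c in counts.items():
        species_list += [s] * c
    rng.shuffle(species_list)

    # lateral lattice (same sites every frame; jitter is vertical only)
    grid = int(np.ceil(np.sqrt(n)))
    pitch = L / grid
    sites = [((i + 0.5) * pitch, (j + 0.5) * pitch)
             for i in range(grid) for j in range(grid)][:n]

    names, elements, resnames, resids, segids = [], [], [], [], []
    lipid_meta = []  # (species, leaflet_sign, site_xy, first_atom_index)
    for leaflet, sign in (("UPPR", +1.0), ("LOWR", -1.0)):
        for li in range(n):
            species = species_list[len(lipid_meta)]
            a_names, a_elems = _lipid_atom_plan(species)
            first = len(names)
            names += a_names
            elements += a_elems
            resnames += [species] * len(a_names)
            resids += [len(lipid_meta) + 1] * len(a_names)
            segids += [leaflet] * len(a_names)
            lipid_meta.append((species, sign, sites[li], first))

    names = np.array(names, dtype=object)
    elements = np.array(elements, dtype=object)
    masses = np.array([ELEMENT_MASSES[e] for e in elements])
    resnames = np.array(resnames, dtype=object)
    resids = np.array(resids, dtype=int)
    segids = np.array(segids, dtype=object)
    molecule_ids = resids - 1
    molecule_labels = {i: lipid_meta[i][0] for i in range(len(lipid_meta))}
    top = Topology(names, elements, masses, resnames, resids, segids,
                   molecule_ids, molecule_labels)

    frames = []
    for t in range(spec.n_frames):
        coords = np.zeros((top.n_atoms, 3))
        for species, sign, (x, y), first in lipid_meta:
            z_p = z_center + sign * half
            if spec.jitter_sd > 0:
                z_p += rng.normal(0.0, spec.jitter_sd)
            i = first
            in_disk = False
            if halfangle_disk is not None:
                cx, cy = spec.disk_center
                in_disk = np.hypot(x - cx, y - cy) <= spec.disk_radius
            ha = halfangle_disk if in_disk else halfangle
            if species in _PHOSPHO_SPECIES:
                coords[i] = (x, y, z_p)
                i += 1
                if species in _HAS_NITROGEN:
                    phi = rng.uniform(0, 2 * np.pi)
                    coords[i] = (x + 0.08 * np.cos(phi), y + 0.08 * np.sin(phi),
                                 z_p + 0.05 * sign)
                    i += 1
                n_ch = 2 * len(CHAIN_CARBONS)
                ch = sample_ch_vectors(rng, n_ch, ha)
                ci = 0
                for k in CHAIN_CARBONS:
                    zig = 0.04 if k % 2 == 0 else -0.04
                    c_pos = np.array([x + zig, y, z_p - sign * (0.2 + (k - 2) * CC_SPACING)])
                    coords[i] = c_pos
                    i += 1
                    for _ in range(2):
                        coords[i] = c_pos + CH_BOND * ch[ci]
                        ci += 1
                        i += 1
            else:
                coords[i] = (x, y, z_p - sign * 0.3)
                i += 1
                for k in range(2, 9):
                    zig = 0.04 if k % 2 == 0 else -0.04
                    coords[i] = (x + zig, y, z_p - sign * (0.4 + (k - 2) * CC_SPACING))
                    i += 1
        frames.append(Frame(coords, np.array([L, L, Lz]), float(t)))
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# Brownian tracks
# ---------------------------------------------------------------------------

def make_brownian_tracks(spec: TrackSpec) -> tuple[Trajectory, TrackSet]:
    """2D Brownian tracks in a periodic box plus the unwrapped ground truth.

    Per-axis step variance is 2 D dt (D converted from 1e-7 cm^2 s^-1 to
    nm^2/ns). The returned trajectory holds the wrapped coordinates (one
    pseudo-atom per particle), exactly what a PBC trajectory file would
    contain; the TrackSet holds the unwrapped truth.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_particles
    counts = [int(round(f * n)) for _, _, f in spec.populations]
    while sum(counts) < n:
        counts[0] += 1
    while sum(counts) > n:
        for i in range(len(counts)):
            if counts[i] > 0 and sum(counts) > n:
                counts[i] -= 1
    labels, ds = [], []
    for (species, d, _), c in zip(spec.populations, counts):
        labels += [species] * c
        ds += [d / 100.0] * c          # 1e-7 cm^2/s -> nm^2/ns
    ds = np.array(ds)

    sd = np.sqrt(2.0 * ds * spec.dt)
    if np.any(sd > spec.box / 4.0):
        raise ValueError("step sd exceeds box/4; unwrapping would be ambiguous")

    # Positions are quantized to multiples of 2^-20 nm (~1e-6 nm, far below
    # any physical scale). With a dyadic box length this makes every wrap /
    # minimum-image operation exact in double precision, so the documented
    # unwrap round-trip invariant holds bit-for-bit, not just approximately.
    quantum = 2.0**-20
    start = np.round(rng.uniform(0.0, spec.box, size=(n, 2)) / quantum) * quantum
    steps = rng.normal(0.0, 1.0, size=(n, spec.n_steps, 2)) * sd[:, None, None]
    steps = np.round(steps / quantum) * quantum
    truth = np.concatenate([start[:, None, :],
                            start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    wrapped = wrap_into_box(truth, spec.box)

    n_frames = spec.n_steps + 1
    names = np.array(["P"] * n, dtype=object)
    elements = np.array(["P"] * n, dtype=object)
    masses = np.full(n, ELEMENT_MASSES["P"])
    resnames = np.array([lbl[:4] for lbl in labels], dtype=object)
    resids = np.arange(1, n + 1)
    segids = np.array(["TRK"] * n, dtype=object)
    molecule_ids = np.arange(n)
    molecule_labels = {i: labels[i] for i in range(n)}
    top = Topology(names, elements, masses, resnames, resids, segids,
                   molecule_ids, molecule_labels)
    box = np.array([spec.box, spec.box, 2.0])
    frames = []
    for t in range(n_frames):
        coords = np.zeros((n, 3))
        coords[:, :2] = wrapped[:, t, :]
        coords[:, 2] = 1.0
        frames.append(Frame(coords, box, t * spec.dt))
    return Trajectory(top, frames), TrackSet(truth, spec.dt, labels)


# ---------------------------------------------------------------------------
# Anchored protein
# ---------------------------------------------------------------------------

_N_RESIDUES = 215
_G_DOMAIN = range(15, 186)
_SWITCH = set(range(50, 61)) | set(range(75, 93))


def _sphere_points(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    pts = radius * np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)])
    return pts - pts.mean(axis=0)  # exactly zero-mean so blob COMs are exact


def _local_p_plane(frame: Frame, top: Topology, anchor_xy: np.ndarray,
                   cutoff: float = 1.0) -> float:
    """Mean z of upper-leaflet P atoms near the anchor (generator-side
    bookkeeping mirroring the documented insertion-depth definition)."""
    p_idx = np.flatnonzero((np.asarray(top.names, dtype=object) == "P")
                           & (np.asarray(top.elements, dtype=object) == "P"))
    z = frame.coordinates[p_idx, 2]
    upper = p_idx[z > np.median(z)]
    lat = frame.coordinates[upper, :2] - anchor_xy
    for a in range(2):
        Lb = frame.box[a]
        lat[:, a] = lat[:, a] - Lb * np.ceil(lat[:, a] / Lb - 0.5)
    near = np.hypot(lat[:, 0], lat[:, 1]) <= cutoff
    if near.sum() >= 3:
        return float(frame.coordinates[upper[near], 2].mean())
    return float(frame.coordinates[upper, 2].mean())


def make_anchored_protein(spec: AnchorSpec, bilayer: Trajectory) -> Trajectory:
    """Combine a bilayer with a posed pseudo-protein, frame by frame.

    The pseudo-protein has one C-alpha bead per residue 1..215 plus 20
    anchor carbons (atom names CG01..CG20, resname GGA) per geranylgeranyl
    chain at residues 212/213. Each output frame draws an insertion depth
    from the planted mixture and pivot/torsion angles from the planted
    normals, then poses anchor, G-domain blob (residues 15-185), switch
    blob (50-60, 75-92) and linker chains accordingly. Bilayer frames are
    cycled when ``n_frames`` exceeds the bilayer length.
    """
    rng = np.random.default_rng(spec.seed)
    btop = bilayer.topology

    thickness_est = None
    max_depth_mean = max(spec.depth_means)

    # protein topology ------------------------------------------------------
    names, elements, resnames, resids, segids = [], [], [], [], []
    for r in range(1, _N_RESIDUES + 1):
        names.append("CA")
        elements.append("C")
        resnames.append("GLY")
        resids.append(r)
        segids.append("PROT")
    anchor_resids = (212, 213)[: spec.n_anchors]
    for ar in anchor_resids:
        for k in range(1, 21):
            names.append(f"CG{k:02d}")
            elements.append("C")
            resnames.append("GGA")
            resids.append(ar)
            segids.append("ANCH")
    names = np.array(names, dtype=object)
    elements = np.array(elements, dtype=object)
    masses = np.array([ELEMENT_MASSES[e] for e in elements])
    resnames = np.array(resnames, dtype=object)
    resids_arr = np.array(resids, dtype=int)
    segids = np.array(segids, dtype=object)

    combined_names = np.concatenate([np.asarray(btop.names, dtype=object), names])
    combined_elements = np.concatenate([np.asarray(btop.elements, dtype=object), elements])
    combined_masses = np.concatenate([btop.masses, masses])
    combined_resnames = np.concatenate([np.asarray(btop.resnames, dtype=object), resnames])
    combined_resids = np.concatenate([btop.resids, resids_arr])
    combined_segids = np.concatenate([np.asarray(btop.segids, dtype=object), segids])
    prot_mol = int(btop.molecule_ids.max()) + 1
    combined_mol = np.concatenate([btop.molecule_ids,
                                   np.full(len(names), prot_mol, dtype=int)])
    labels = dict(btop.molecule_labels)
    labels[prot_mol] = "protein"
    top = Topology(combined_names, combined_elements, combined_masses,
                   combined_resnames, combined_resids, combined_segids,
                   combined_mol, labels)

    n_bilayer_atoms = btop.n_atoms
    ca_offset = n_bilayer_atoms
    anchor_offset = n_bilayer_atoms + _N_RESIDUES

    g_res = [r for r in _G_DOMAIN]
    sw_res = sorted(_SWITCH)
    rest_res = [r for r in g_res if r not in _SWITCH]
    n_g, n_sw, n_rest = len(g_res), len(sw_res), len(rest_res)
    sw_cloud = _sphere_points(n_sw, 0.3)
    rest_cloud = _sphere_points(n_rest, 0.8)

    frames = []
    mix_k = rng.choice(len(spec.depth_weights), size=spec.n_frames,
                       p=np.array(spec.depth_weights))
    for t in range(spec.n_frames):
        bframe = bilayer.frames[t % bilayer.n_frames]
        box = bframe.box
        anchor_xy = np.array([box[0] / 2.0, box[1] / 2.0])
        p_plane = _local_p_plane(bframe, btop, anchor_xy)
        if thickness_est is None:
            z_all = bframe.coordinates[
                np.flatnonzero(np.asarray(btop.elements, dtype=object) == "P"), 2]
            thickness_est = float(z_all.max() - z_all.min()) or box[2]
            if max_depth_mean > thickness_est:
                raise ValueError(
                    f"planted depth {max_depth_mean} nm exceeds the leaflet "
                    f"depth of this bilayer (~{thickness_est:.2f} nm)")

        k = mix_k[t]
        depth = rng.normal(spec.depth_means[k], spec.depth_sds[k])
        theta = np.deg2rad(rng.normal(spec.theta, spec.theta_sd)) \
            if spec.theta_sd > 0 else np.deg2rad(spec.theta)
        omega = (rng.normal(spec.omega, spec.omega_sd) if spec.omega_sd > 0
                 else spec.omega) % 360.0

        coords = np.zeros((top.n_atoms, 3))
        coords[:n_bilayer_atoms] = bframe.coordinates

        # anchors: vertical 20-carbon chains, deepest carbon at p_plane-depth
        anchor_pos = []
        offsets = [(-0.25, 0.0), (0.25, 0.0)][: spec.n_anchors]
        ai = anchor_offset
        for ox, oy in offsets:
            for j in range(20):
                zig = 0.04 if j % 2 == 0 else -0.04
                coords[ai] = (anchor_xy[0] + ox + zig, anchor_xy[1] + oy,
                              p_plane - depth + j * 0.12)
                anchor_pos.append(coords[ai].copy())
                ai += 1
        A = np.mean(anchor_pos, axis=0)

        # G-domain COM at planted pivot angle (azimuth fixed: theta/omega are
        # invariant under rotations about z)
        G = A + spec.domain_distance * np.array(
            [np.sin(theta), 0.0, np.cos(theta)])

        # switch-region COM from the planted dihedral M-A-G-S, M = A - z_hat
        b1 = np.array([0.0, 0.0, 1.0])      # A - M
        u = (G - A) / np.linalg.norm(G - A)
        v = b1 - (b1 @ u) * u
        vn = np.linalg.norm(v)
        if vn < 1e-9:
            raise ValueError("theta of 0/180 deg leaves the torsion undefined")
        v /= vn
        w = np.cross(u, v)
        # the dihedral's reference half-plane is on the membrane (-z) side, so
        # the in-plane rotation is offset by 180 deg from the target torsion
        S = None
        for delta in (np.deg2rad(omega - 180.0), np.deg2rad(180.0 - omega)):
            cand = G + 0.5 * u + 0.8 * (np.cos(delta) * v + np.sin(delta) * w)
            from .protein_geometry import dihedral
            got = dihedral(A - b1, A, G, cand)
            if abs((got - omega + 180.0) % 360.0 - 180.0) < 1e-6:
                S = cand
                break
        if S is None:  # pragma: no cover - construction covers both signs
            raise RuntimeError("torsion construction failed")

        # residue placement: switch blob around S, remaining G-domain blob
        # positioned so the full-domain COM lands exactly on G
        G_rest = (n_g * G - n_sw * S) / n_rest
        jit = (rng.normal(0.0, spec.blob_jitter_sd, size=(_N_RESIDUES, 3))
               if spec.blob_jitter_sd > 0 else np.zeros((_N_RESIDUES, 3)))
        for i, r in enumerate(sw_res):
            coords[ca_offset + r - 1] = S + sw_cloud[i] + jit[r - 1]
        for i, r in enumerate(rest_res):
            coords[ca_offset + r - 1] = G_rest + rest_cloud[i] + jit[r - 1]
        # N-terminal tail 1-14 and C-terminal linker 186-215: simple chains
        top_of_anchor = A + np.array([0.0, 0.0, 1.2])
        for i, r in enumerate(range(1, 15)):
            coords[ca_offset + r - 1] = G + np.array([0.0, 0.3, 0.9 + 0.1 * i]) + jit[r - 1]
        start = G
        for i, r in enumerate(range(186, 216)):
            frac = (i + 1) / 31.0
            coords[ca_offset + r - 1] = (1 - frac) * start + frac * top_of_anchor \
                + np.array([0.0, 0.25, 0.0]) + jit[r - 1]

        frames.append(Frame(coords, box.copy(), float(t)))
    return Trajectory(top, frames)
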