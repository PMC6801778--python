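"""Anchoring geometry of a peripheral membrane protein.

Covers the insertion depth of the lipid anchor below the phosphate plane,
per-residue z-distances between protein and membrane surface, radius of
gyration, superposition-based RMSF, and the two orientation descriptors of
the folded domain at the membrane:

* the pivot angle theta between the anchor-to-domain vector and the bilayer
  normal (+z); theta = 90 deg means the domain lies parallel to the surface;
* the internal dihedral omega describing the torsion of the switch regions
  about the anchor-domain axis, which separates an 'endo' conformation
  (switch regions facing the membrane, population near 190 deg) from an
  'exo' conformation (solvent-exposed, near 80 deg).

The exact atom groups behind theta/omega are configurable; defaults follow
the Rab5 numbering used throughout the package (G domain residues 15-185,
switch I 50-60, switch II 75-92).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .traj_core import AtomSet, Frame, Trajectory, assign_leaflets, wrap_displacement

logger = logging.getLogger(__name__)

__all__ = [
    "DepthSeries",
    "ResidueDistanceMap",
    "OrientationSeries",
    "anchor_insertion_depth",
    "depth_distribution",
    "residue_membrane_distances",
    "radius_of_gyration",
    "superpose",
    "rmsf",
    "dihedral",
    "orientation_angles",
    "orientation_series",
    "classify_omega",
]

G_DOMAIN_RANGE = (15, 185)
SWITCH_I_RANGE = (50, 60)
SWITCH_II_RANGE = (75, 92)


@dataclass
class DepthSeries:
    """Per-frame anchor insertion depths with distribution summary."""

    depths: np.ndarray
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    modality: int                 # Gaussian-mixture components preferred by BIC
    component_means: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.sum() != len(self.depths):
            raise ValueError("histogram counts must sum to the number of frames")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class ResidueDistanceMap:
    """(residue x frame) matrix of residue-COM z-distances to the P plane."""

    resids: np.ndarray
    times: np.ndarray
    distances: np.ndarray  # (n_residues, n_frames), nm

    def __post_init__(self) -> None:
        if self.distances.shape != (len(self.resids), len(self.times)):
            raise ValueError("distance matrix shape mismatch")


@dataclass
class OrientationSeries:
    """Per-frame (theta, omega) in degrees plus a conformation label."""

    times: np.ndarray
    theta: np.ndarray   # [0, 180]
    omega: np.ndarray   # [0, 360)
    labels: list        # 'endo' | 'exo' | 'intermediate'

    def __post_init__(self) -> None:
        if np.any((self.theta < 0) | (self.theta > 180)):
            raise ValueError("theta out of [0, 180]")
        if np.any((self.omega < 0) | (self.omega >= 360)):
            raise ValueError("omega out of [0, 360)")


# ---------------------------------------------------------------------------
# Insertion depth
# ---------------------------------------------------------------------------

def anchor_insertion_depth(frame: Frame, gg_carbons: AtomSet, phosphorus: AtomSet,
                           neighbor_cutoff: float = 1.0) -> float:
    """Depth of the deepest anchor carbon below the local phosphate plane.

    depth = (mean z of same-leaflet P atoms within ``neighbor_cutoff``
    lateral distance of the anchor centroid) - (min z over anchor carbons).
    Positive when inserted; negative values (anchor above the plane, e.g.
    during desorption) are reported unclamped. The anchor is assumed to
    insert into the upper leaflet (protein on the +z side). With fewer than
    3 lateral neighbours the whole-leaflet mean is used, with a warning.
    """
    if len(gg_carbons) == 0:
        raise ValueError("anchor carbon selection is empty")
    labels = assign_leaflets(frame, phosphorus)
    p_idx = phosphorus.indices[labels == "upper"]
    if len(p_idx) == 0:
        raise ValueError("no upper-leaflet phosphorus atoms")
    anchor_xy = frame.coordinates[gg_carbons.indices, :2].mean(axis=0)
    lat = frame.coordinates[p_idx, :2] - anchor_xy
    lat[:, 0] = wrap_displacement(lat[:, 0], frame.box[0])
    lat[:, 1] = wrap_displacement(lat[:, 1], frame.box[1])
    near = np.hypot(lat[:, 0], lat[:, 1]) <= neighbor_cutoff
    if near.sum() >= 3:
        p_plane = frame.coordinates[p_idx[near], 2].mean()
    else:
        warnings.warn(
            "anchor_insertion_depth: fewer than 3 neighbouring P atoms within "
            f"{neighbor_cutoff} nm; using whole-leaflet mean", stacklevel=2)
        p_plane = frame.coordinates[p_idx, 2].mean()
    deepest = frame.coordinates[gg_carbons.indices, 2].min()
    return float(p_plane - deepest)


def depth_distribution(depths: np.ndarray, bin_width: float = 0.05,
                       seed: int = 0) -> DepthSeries:
    """Histogram + mean/sd + modality of an insertion-depth series.

    Modality is decided by comparing 1- vs 2-component Gaussian mixtures by
    BIC (scikit-learn, deterministic initialisation).
    """
    depths = np.asarray(depths, dtype=float)
    if len(depths) < 100:
        raise ValueError("depth distribution needs at least 100 frames")
    lo = np.floor(depths.min() / bin_width) * bin_width
    hi = np.ceil(depths.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(depths, bins=n_bins, range=(lo, lo + n_bins * bin_width))

    from sklearn.mixture import GaussianMixture

    X = depths.reshape(-1, 1)
    bics, means = [], []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed,
                             covariance_type="full")
        gm.fit(X)
        bics.append(gm.bic(X))
        means.append(np.sort(gm.means_.ravel()))
    modality = 1 if bics[0] <= bics[1] else 2
    return DepthSeries(
        depths=depths,
        mean=float(depths.mean()),
        sd=float(depths.std(ddof=0)),
        bin_edges=edges,
        counts=counts,
        modality=modality,
        component_means=means[modality - 1],
    )


# ---------------------------------------------------------------------------
# Residue-membrane distances
# ---------------------------------------------------------------------------

def residue_membrane_distances(traj: Trajectory, protein: AtomSet,
                               phosphorus: AtomSet) -> ResidueDistanceMap:
    """Per residue and frame: residue COM z minus upper-leaflet P mean z."""
    top = traj.topology
    groups = top.residue_groups(protein.indices)
    resids = np.array([resid for (_, resid) in groups.keys()])
    atom_lists = list(groups.values())
    masses = [top.masses[ids] for ids in atom_lists]
    for (seg, resid), ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"residue {seg}:{resid} has no atoms")
    dist = np.empty((len(resids), traj.n_frames))
    for t, frame in enumerate(traj.frames):
        labels = assign_leaflets(frame, phosphorus)
        p_plane = frame.coordinates[phosphorus.indices[labels == "upper"], 2].mean()
        for j, (ids, m) in enumerate(zip(atom_lists, masses)):
            com_z = np.average(frame.coordinates[ids, 2], weights=m)
            dist[j, t] = com_z - p_plane
    return ResidueDistanceMap(resids, traj.times, dist)


# ---------------------------------------------------------------------------
# Compactness, superposition, fluctuations
# ---------------------------------------------------------------------------

def radius_of_gyration(frame: Frame, topology, protein: AtomSet) -> float:
    """Mass-weighted RMS distance of atoms from their centre of mass (nm)."""
    idx = protein.indices
    if len(idx) < 2:
        raise ValueError("radius of gyration needs at least two atoms")
    coords = frame.coordinates[idx]
    masses = np.asarray(topology.masses[idx], dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None):
    """Least-squares rigid superposition (Kabsch, reflection-guarded).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    weighted least-squares sense.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise ValueError("superpose needs two equal (n>=3, 3) coordinate sets")
    n = mobile.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    mob_c = np.average(mobile, axis=0, weights=w)
    ref_c = np.average(reference, axis=0, weights=w)
    A = mobile - mob_c
    B = reference - ref_c
    # degenerate (collinear) sets have a rank-deficient covariance
    H = (A * w[:, None]).T @ B
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear) point set; superposition undefined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    fitted = A @ R.T + ref_c
    rmsd = float(np.sqrt(np.average(np.sum((fitted - B - ref_c) ** 2, axis=1), weights=w)))
    return R, t, rmsd


def rmsf(traj: Trajectory, ca_atoms: AtomSet, fit_atoms: AtomSet) -> np.ndarray:
    """Per-atom RMSF after superposing ``fit_atoms`` onto the first frame.

    Each frame is rigid-body fitted (mass-weighted) on ``fit_atoms``; the
    fluctuation of each ``ca_atoms`` position about its fitted-trajectory
    mean is then reported, so rigid tumbling contributes nothing.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    top = traj.topology
    fit_idx = fit_atoms.indices
    ca_idx = ca_atoms.indices
    w = top.masses[fit_idx]
    ref = traj.frames[0].coordinates[fit_idx]
    fitted = np.empty((traj.n_frames, len(ca_idx), 3))
    for t, frame in enumerate(traj.frames):
        R, tvec, _ = superpose(frame.coordinates[fit_idx], ref, w)
        fitted[t] = frame.coordinates[ca_idx] @ R.T + tvec
    mean_pos = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Orientation descriptors
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral p0-p1-p2-p3 in degrees, mapped to [0, 360)."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral geometry")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / b2n)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang % 360.0)


def classify_omega(omega: float, exo_center: float = 80.0,
                   endo_center: float = 190.0, half_width: float = 45.0) -> str:
    """'exo'/'endo'/'intermediate' by circular distance to the population centres."""
    def circ_dist(a, b):
        d = abs(a - b) % 360.0
        return min(d, 360.0 - d)
    if circ_dist(omega, exo_center) <= half_width:
        return "exo"
    if circ_dist(omega, endo_center) <= half_width:
        return "endo"
    return "intermediate"


def orientation_angles(frame: Frame, topology, g_domain: AtomSet,
                       switch_regions: AtomSet, anchor: AtomSet):
    """Pivot angle theta and internal dihedral omega for one frame.

    With A the anchor-carbon centroid, G the mass-weighted G-domain COM,
    S the switch-region COM and M = A - z_hat (a point displaced into the
    membrane along the inward normal): theta is the angle between (G - A)
    and +z, and omega the dihedral M-A-G-S in [0, 360).
    """
    for name, s in (("g_domain", g_domain), ("switch_regions", switch_regions),
                    ("anchor", anchor)):
        if len(s) == 0:
            raise ValueError(f"{name} selection is empty")
    coords = frame.coordinates
    masses = topology.masses
    A = coords[anchor.indices].mean(axis=0)
    G = np.average(coords[g_domain.indices], axis=0,
                   weights=masses[g_domain.indices])
    S = np.average(coords[switch_regions.indices], axis=0,
                   weights=masses[switch_regions.indices])
    M = A - np.array([0.0, 0.0, 1.0])
    vG = G - A
    nG = np.linalg.norm(vG)
    if nG < 1e-12:
        raise ValueError("anchor centroid and G-domain COM coincide")
    theta = float(np.degrees(np.arccos(np.clip(vG[2] / nG, -1.0, 1.0))))
    if np.linalg.norm(S - G) < 1e-12:
        raise ValueError("switch-region COM coincides with G-domain COM")
    try:
        omega = dihedral(M, A, G, S)
    except ValueError:
        # theta of 0/180 deg (or S on the A-G axis) leaves the torsion undefined
        omega = float("nan")
    return theta, omega


def orientation_series(traj: Trajectory, g_domain: AtomSet,
                       switch_regions: AtomSet, anchor: AtomSet) -> OrientationSeries:
    """Per-frame (theta, omega) with endo/exo labels over a trajectory."""
    thetas, omegas, labels = [], [], []
    for frame in traj.frames:
        th, om = orientation_angles(frame, traj.topology, g_domain,
                                    switch_regions, anchor)
        thetas.append(th)
        omegas.append(om)
        labels.append(classify_omega(om))
    return OrientationSeries(traj.times, np.array(thetas), np.array(omegas), labels)
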