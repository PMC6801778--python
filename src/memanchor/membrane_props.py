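"""Membrane structural observables.

Global descriptors — phosphate-plane thickness, area per lipid, and the
chain-averaged acyl order parameter S_CD — plus local order-deviation maps
around a membrane anchor and headgroup P–N tilt angles.

The order parameter of an acyl C–H bond is

    S_CD = <(3 cos^2 theta_CH - 1) / 2>,

with theta_CH the angle between the C–H vector and the bilayer normal (+z).
S_CD lies in [-0.5, 1]: -0.5 when every C–H bond is in the membrane plane,
0 for isotropic orientations. Chain averages are reported as the mean of
|S_CD| over carbons C2..C15 of the saturated sn-1 chain, so the planar limit
maps to +0.5 and fluid-bilayer values are positive, matching the deuterium
NMR convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .traj_core import AtomSet, Frame, Trajectory, assign_leaflets, wrap_displacement

logger = logging.getLogger(__name__)

__all__ = [
    "OrderProfile",
    "MembraneSummary",
    "LocalOrderMap",
    "bilayer_thickness",
    "area_per_lipid",
    "acyl_order_parameters",
    "order_profile_from_ch_vectors",
    "local_order_map",
    "headgroup_pn_angle",
    "membrane_summary",
]

CHAIN_CARBONS = tuple(range(2, 16))  # C2..C15, the saturated sn-1 palmitoyl chain


@dataclass
class OrderProfile:
    """Per-carbon S_CD values plus the chain-averaged scalar."""

    carbons: tuple          # carbon positions, e.g. (2, ..., 15)
    s_cd: np.ndarray        # signed per-carbon S_CD
    chain_average: float    # mean of |S_CD| over carbons
    uncertainty: float      # sd of chain_average over time blocks (nan if <2 blocks)

    def __post_init__(self) -> None:
        s = np.asarray(self.s_cd, dtype=float)
        if np.any(s < -0.5 - 1e-9) or np.any(s > 1.0 + 1e-9):
            raise ValueError("S_CD values must lie in [-0.5, 1]")


@dataclass
class MembraneSummary:
    thickness: float
    thickness_sd: float
    area_per_lipid: float
    area_per_lipid_sd: float
    order: float
    order_sd: float


@dataclass
class LocalOrderMap:
    """Lateral grid of (local chain-average order - global chain-average order).

    Cells never visited by a lipid centroid are NaN and excluded from all
    averages. ``anchor_deviation`` is the time-averaged order of lipids whose
    chain centroid lies within ``cutoff`` (lateral, minimum-image) of the
    anchor's lateral position, minus the global average.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    deviation: np.ndarray       # (nx, ny), NaN where no data
    grid_spacing: float
    cutoff: float
    anchor_deviation: float
    global_order: float


# ---------------------------------------------------------------------------
# Global descriptors
# ---------------------------------------------------------------------------

def bilayer_thickness(frame: Frame, phosphorus: AtomSet) -> float:
    """Phosphate-plane separation: mean upper-leaflet P z minus mean lower."""
    labels = assign_leaflets(frame, phosphorus)
    z = frame.coordinates[phosphorus.indices, 2]
    upper = z[labels == "upper"]
    lower = z[labels == "lower"]
    if len(upper) < 2 or len(lower) < 2:
        raise ValueError("bilayer thickness needs >=2 phosphorus atoms per leaflet")
    return float(upper.mean() - lower.mean())


def area_per_lipid(frame: Frame, lipids_per_leaflet: int) -> float:
    """Lateral box area divided by the number of lipids in one leaflet."""
    if lipids_per_leaflet <= 0:
        raise ValueError("lipids_per_leaflet must be positive")
    return float(frame.box[0] * frame.box[1] / lipids_per_leaflet)


# ---------------------------------------------------------------------------
# Acyl order parameters
# ---------------------------------------------------------------------------

_CARBON_RE = re.compile(r"^C(\d+)$")
_HYDROGEN_RE = re.compile(r"^H(\d+)[A-Z]?$")


def _p2_of_vectors(vectors: np.ndarray) -> np.ndarray:
    """Second Legendre polynomial of cos(theta) w.r.t. +z, per vector."""
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms == 0):
        raise ValueError("zero-length C-H vector")
    cosz = v[..., 2] / norms
    return 1.5 * cosz**2 - 0.5


def order_profile_from_ch_vectors(vectors_by_carbon: dict[int, np.ndarray],
                                  block_averages: np.ndarray | None = None) -> OrderProfile:
    """Build an OrderProfile from raw C–H vector samples grouped by carbon."""
    carbons = tuple(sorted(vectors_by_carbon))
    s = np.array([_p2_of_vectors(vectors_by_carbon[c]).mean() for c in carbons])
    chain_avg = float(np.abs(s).mean())
    unc = float(np.std(block_averages, ddof=1)) if block_averages is not None \
        and len(block_averages) > 1 else float("nan")
    return OrderProfile(carbons, s, chain_avg, unc)


def _ch_pairs(topology, carbons: AtomSet, reconstruct: bool):
    """Return (carbon_idx, hydrogen_idx, carbon_number, lipid_ordinal) arrays.

    Hydrogens are matched within the same residue by carbon number (C5 pairs
    with H5A/H5B/H5R/...). With ``reconstruct`` and no hydrogens on a carbon,
    a skeleton entry (hydrogen index -1) is emitted for geometric rebuild.
    """
    groups = topology.residue_groups(carbons.indices)
    c_idx, h_idx, c_num, lipid_ord = [], [], [], []
    skeleton = []  # (carbon_idx, prev_idx, next_idx, number, lipid)
    for lipid, (key, atom_ids) in enumerate(groups.items()):
        seg, resid = key
        res_mask = (topology.segids == seg) & (topology.resids == resid)
        res_atoms = np.flatnonzero(res_mask)
        hydrogens: dict[int, list[int]] = {}
        for i in res_atoms:
            m = _HYDROGEN_RE.match(str(topology.names[i]))
            if m and topology.elements[i] == "H":
                hydrogens.setdefault(int(m.group(1)), []).append(int(i))
        by_number = {}
        for i in atom_ids:
            m = _CARBON_RE.match(str(topology.names[i]))
            if not m:
                raise ValueError(f"selected atom {topology.names[i]!r} is not a chain carbon")
            by_number[int(m.group(1))] = int(i)
        for num, ci in sorted(by_number.items()):
            hs = hydrogens.get(num, [])
            if hs:
                for hi in hs:
                    c_idx.append(ci)
                    h_idx.append(hi)
                    c_num.append(num)
                    lipid_ord.append(lipid)
            elif reconstruct:
                prev_i = by_number.get(num - 1)
                next_i = by_number.get(num + 1)
                if prev_i is None or next_i is None:
                    continue  # terminal carbons cannot be rebuilt from neighbours
                skeleton.append((ci, prev_i, next_i, num, lipid))
            else:
                raise ValueError(
                    f"carbon C{num} in residue {seg}:{resid} has no hydrogens; "
                    "enable reconstruction or provide explicit hydrogens"
                )
    return (np.array(c_idx, dtype=int), np.array(h_idx, dtype=int),
            np.array(c_num, dtype=int), np.array(lipid_ord, dtype=int),
            skeleton, len(groups))


def _reconstructed_ch_vectors(coords: np.ndarray, skeleton) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rebuild methylene C–H directions from the carbon skeleton.

    For carbon Ci with neighbours C(i-1), C(i+1): the two H's lie in the
    plane perpendicular to the C(i-1)->C(i+1) axis, along the outward
    bisector tilted by +-half the H-C-H angle (tetrahedral geometry).
    """
    half_hch = np.deg2rad(109.47 / 2.0)
    vecs, nums, lipids = [], [], []
    for ci, pi, ni, num, lipid in skeleton:
        u = coords[ni] - coords[pi]
        u /= np.linalg.norm(u)
        mid = 0.5 * (coords[ni] + coords[pi])
        w = coords[ci] - mid
        w = w - (w @ u) * u
        wn = np.linalg.norm(w)
        if wn < 1e-9:
            continue  # collinear skeleton: bisector undefined
        w /= wn
        n = np.cross(u, w)
        for sign in (+1.0, -1.0):
            vecs.append(np.cos(half_hch) * w + sign * np.sin(half_hch) * n)
            nums.append(num)
            lipids.append(lipid)
    return np.asarray(vecs), np.asarray(nums, dtype=int), np.asarray(lipids, dtype=int)


def acyl_order_parameters(traj: Trajectory, chain_carbons: AtomSet,
                          reconstruct: bool = False, n_blocks: int = 5) -> OrderProfile:
    """Per-carbon S_CD averaged over lipids and frames, plus chain average.

    Uses explicit hydrogens when present; with ``reconstruct=True`` missing
    methylene hydrogens are rebuilt geometrically from the carbon skeleton
    (Douliez-style), which permits order parameters on H-less topologies.
    Uncertainty is the sd of the chain average over ``n_blocks`` contiguous
    time blocks.
    """
    c_idx, h_idx, c_num, _, skeleton, n_lipids = _ch_pairs(
        traj.topology, chain_carbons, reconstruct)
    if len(c_idx) == 0 and not skeleton:
        raise ValueError("no C-H pairs found in the chain selection")

    carbons = sorted(set(c_num.tolist()) | {s[3] for s in skeleton})
    sums = {c: 0.0 for c in carbons}
    counts = {c: 0 for c in carbons}
    block_chain_avgs = []
    blocks = np.array_split(np.arange(traj.n_frames), min(n_blocks, traj.n_frames))

    for block in blocks:
        if len(block) == 0:
            continue
        bsums = {c: 0.0 for c in carbons}
        bcounts = {c: 0 for c in carbons}
        for fi in block:
            coords = traj.frames[fi].coordinates
            if len(c_idx):
                p2 = _p2_of_vectors(coords[h_idx] - coords[c_idx])
                for c in np.unique(c_num):
                    sel = c_num == c
                    bsums[int(c)] += p2[sel].sum()
                    bcounts[int(c)] += int(sel.sum())
            if skeleton:
                vecs, nums, _ = _reconstructed_ch_vectors(coords, skeleton)
                if len(vecs):
                    p2r = _p2_of_vectors(vecs)
                    for c in np.unique(nums):
                        sel = nums == c
                        bsums[int(c)] += p2r[sel].sum()
                        bcounts[int(c)] += int(sel.sum())
        for c in carbons:
            sums[c] += bsums[c]
            counts[c] += bcounts[c]
        per_c = np.array([bsums[c] / bcounts[c] for c in carbons if bcounts[c] > 0])
        if len(per_c):
            block_chain_avgs.append(np.abs(per_c).mean())

    s = np.array([sums[c] / counts[c] for c in carbons if counts[c] > 0])
    carbons = tuple(c for c in carbons if counts[c] > 0)
    chain_avg = float(np.abs(s).mean())
    block_chain_avgs = np.asarray(block_chain_avgs)
    unc = float(np.std(block_chain_avgs, ddof=1)) if len(block_chain_avgs) > 1 else float("nan")
    return OrderProfile(carbons, s, chain_avg, unc)


# ---------------------------------------------------------------------------
# Local order-deviation map
# ---------------------------------------------------------------------------

def _per_lipid_order_and_centroid(traj, chain_carbons, reconstruct):
    """Per-frame arrays of (signed lipid chain-average P2, lateral centroid).

    Values stay signed here: S_CD is an ensemble average, so magnitudes are
    taken only after averaging (the instantaneous two-vector |P2| of a
    single methylene is upward-biased noise, not an order parameter).
    """
    c_idx, h_idx, c_num, lipid_ord, skeleton, n_lipids = _ch_pairs(
        traj.topology, chain_carbons, reconstruct)
    groups = traj.topology.residue_groups(chain_carbons.indices)
    lipid_atom_ids = list(groups.values())
    per_frame = []
    for frame in traj.frames:
        coords = frame.coordinates
        order_sum = np.zeros(n_lipids)
        order_cnt = np.zeros(n_lipids)
        if len(c_idx):
            p2 = _p2_of_vectors(coords[h_idx] - coords[c_idx])
            np.add.at(order_sum, lipid_ord, p2)
            np.add.at(order_cnt, lipid_ord, 1.0)
        if skeleton:
            vecs, _, lipids = _reconstructed_ch_vectors(coords, skeleton)
            if len(vecs):
                p2r = _p2_of_vectors(vecs)
                np.add.at(order_sum, lipids, p2r)
                np.add.at(order_cnt, lipids, 1.0)
        with np.errstate(invalid="ignore"):
            order = order_sum / order_cnt
        centroids = np.array([coords[ids, :2].mean(axis=0) for ids in lipid_atom_ids])
        per_frame.append((order, centroids, frame.box))
    return per_frame


def local_order_map(traj: Trajectory, anchor: AtomSet, chain_carbons: AtomSet,
                    cutoff: float = 0.5, grid_spacing: float = 0.2,
                    reconstruct: bool = False) -> LocalOrderMap:
    """Map of local chain-average order minus the global average.

    Per frame, each lipid contributes its instantaneous chain-average |S_CD|
    to the grid cell containing its (wrapped) lateral chain centroid; the map
    reports time-averaged cell values minus the global time-average. Lipids
    within ``cutoff`` of the anchor's lateral centroid (minimum image)
    additionally feed the scalar ``anchor_deviation``.
    """
    if len(anchor) == 0:
        raise ValueError("anchor selection is empty")
    per_frame = _per_lipid_order_and_centroid(traj, chain_carbons, reconstruct)
    box = traj.frames[0].box
    nx = max(1, int(round(box[0] / grid_spacing)))
    ny = max(1, int(round(box[1] / grid_spacing)))
    dx, dy = box[0] / nx, box[1] / ny
    grid_sum = np.zeros((nx, ny))
    grid_cnt = np.zeros((nx, ny))
    total_sum = 0.0
    total_cnt = 0
    prox_sum = 0.0
    prox_cnt = 0

    for frame, (order, centroids, fbox) in zip(traj.frames, per_frame):
        valid = np.isfinite(order)
        anchor_xy = frame.coordinates[anchor.indices, :2].mean(axis=0)
        cx = (centroids[:, 0] - box[0] * np.floor(centroids[:, 0] / box[0]))
        cy = (centroids[:, 1] - box[1] * np.floor(centroids[:, 1] / box[1]))
        ix = np.minimum((cx / dx).astype(int), nx - 1)
        iy = np.minimum((cy / dy).astype(int), ny - 1)
        np.add.at(grid_sum, (ix[valid], iy[valid]), order[valid])
        np.add.at(grid_cnt, (ix[valid], iy[valid]), 1.0)
        total_sum += order[valid].sum()
        total_cnt += int(valid.sum())
        lat = centroids - anchor_xy
        lat[:, 0] = wrap_displacement(lat[:, 0], fbox[0])
        lat[:, 1] = wrap_displacement(lat[:, 1], fbox[1])
        near = valid & (np.hypot(lat[:, 0], lat[:, 1]) <= cutoff)
        prox_sum += order[near].sum()
        prox_cnt += int(near.sum())

    if total_cnt == 0:
        raise ValueError("no lipid order data in trajectory")
    # signed averages first, magnitudes last (acyl S_CD is negative; the
    # reported chain-average order is its magnitude)
    global_order = abs(total_sum / total_cnt)
    with np.errstate(invalid="ignore"):
        deviation = np.abs(grid_sum / grid_cnt) - global_order
    deviation[grid_cnt == 0] = np.nan
    n_empty = int((grid_cnt == 0).sum())
    if n_empty:
        logger.info("local order map: %d/%d empty cells excluded", n_empty, nx * ny)
    anchor_dev = (abs(prox_sum / prox_cnt) - global_order) if prox_cnt else float("nan")
    return LocalOrderMap(
        x_centers=(np.arange(nx) + 0.5) * dx,
        y_centers=(np.arange(ny) + 0.5) * dy,
        deviation=deviation,
        grid_spacing=grid_spacing,
        cutoff=cutoff,
        anchor_deviation=float(anchor_dev),
        global_order=float(global_order),
    )


# ---------------------------------------------------------------------------
# Headgroup tilt
# ---------------------------------------------------------------------------

def headgroup_pn_angle(frame: Frame, p_atom: int, n_atom: int) -> float:
    """Angle (degrees, [0, 180]) between +z and the P->N headgroup vector."""
    v = frame.coordinates[n_atom] - frame.coordinates[p_atom]
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("P and N atoms are coincident")
    return float(np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def membrane_summary(traj: Trajectory, phosphorus: AtomSet, chain_carbons: AtomSet,
                     lipids_per_leaflet: int, reconstruct: bool = False,
                     n_blocks: int = 5) -> MembraneSummary:
    """Time-averaged thickness, APL and chain order with block-average sds."""
    th = np.array([bilayer_thickness(f, phosphorus) for f in traj.frames])
    apl = np.array([area_per_lipid(f, lipids_per_leaflet) for f in traj.frames])
    profile = acyl_order_parameters(traj, chain_carbons, reconstruct, n_blocks)

    def _block_sd(series):
        blocks = np.array_split(series, min(n_blocks, len(series)))
        means = np.array([b.mean() for b in blocks if len(b)])
        return float(np.std(means, ddof=1)) if len(means) > 1 else float("nan")

    return MembraneSummary(
        thickness=float(th.mean()), thickness_sd=_block_sd(th),
        area_per_lipid=float(apl.mean()), area_per_lipid_sd=_block_sd(apl),
        order=profile.chain_average, order_sd=profile.uncertainty,
    )
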