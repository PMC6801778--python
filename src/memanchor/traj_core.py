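"""Trajectory data model, atom selection, leaflet assignment, and PBC utilities.

Internal units are nm (lengths), ns (times) and amu (masses) throughout the
package; conversions from the native units of on-disk formats (e.g. the
Angstrom/ps convention of DCD/XTC readers) happen once, at load time.

The bilayer normal is fixed to +z: membranes are assumed to be built in the
x,y-plane of an orthorhombic box, which is the standard setup for planar
bilayer simulations. Curved membranes and triclinic boxes are out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "AtomSet",
    "FormatError",
    "ConsistencyError",
    "SelectionError",
    "load_trajectory",
    "write_trajectory",
    "select",
    "assign_leaflets",
    "wrap_displacement",
    "wrap_into_box",
]

#: element -> atomic mass (amu)
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
}


class FormatError(ValueError):
    """An input file could not be parsed as the expected format."""


class ConsistencyError(ValueError):
    """Topology and trajectory disagree (e.g. atom counts)."""


class SelectionError(ValueError):
    """A selection expression could not be parsed."""


def guess_element(name: str) -> str:
    """Guess the element from an atom name (first letter, digits ignored).

    Follows the convention of biomolecular force-field atom names where the
    leading letter is the element ("CA" is an alpha carbon, not calcium).
    """
    stripped = re.sub(r"[0-9']", "", name).strip()
    if not stripped:
        raise ValueError(f"cannot guess element for atom name {name!r}")
    return stripped[0].upper()


@dataclass
class Topology:
    """Per-atom static attributes plus a molecule table.

    Molecules coincide with residues for lipids (one residue per lipid);
    protein residues all map to a single molecule labelled ``"protein"``.
    """

    names: np.ndarray          # str, shape (n_atoms,)
    elements: np.ndarray       # str
    masses: np.ndarray         # float, amu
    resnames: np.ndarray       # str
    resids: np.ndarray         # int (1-based, unique within a segment)
    segids: np.ndarray         # str
    molecule_ids: np.ndarray   # int, one molecule per atom
    molecule_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "masses", "resnames", "resids", "segids", "molecule_ids"):
            if len(getattr(self, attr)) != n:
                raise ConsistencyError(f"topology attribute {attr} has wrong length")
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_groups(self, atom_indices: np.ndarray) -> dict[tuple[str, int], np.ndarray]:
        """Group the given atom indices by (segid, resid), insertion-ordered."""
        groups: dict[tuple[str, int], list[int]] = {}
        for i in np.asarray(atom_indices, dtype=int):
            key = (str(self.segids[i]), int(self.resids[i]))
            groups.setdefault(key, []).append(i)
        return {k: np.array(v, dtype=int) for k, v in groups.items()}


@dataclass
class Frame:
    """One snapshot: coordinates (nm), orthorhombic box (nm), time (ns)."""

    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray          # (Lx, Ly, Lz) nm
    time: float              # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")


@dataclass
class Trajectory:
    """An ordered sequence of frames over a fixed topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ConsistencyError(
                    f"frame has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = np.array([f.time for f in self.frames])
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class AtomSet:
    """An ordered, duplicate-free list of atom indices into a Topology."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("atom indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


# ---------------------------------------------------------------------------
# File I/O (delegated to MDAnalysis; units converted at this boundary)
# ---------------------------------------------------------------------------

def _times_from_reader(universe) -> np.ndarray:
    times_ps = []
    for ts in universe.trajectory:
        times_ps.append(float(ts.time))
    times = np.asarray(times_ps) / 1000.0  # ps -> ns
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        # Readers without real timestamps report zeros; fall back to frame index.
        times = np.arange(len(times), dtype=float)
    return times


def load_trajectory(topology_path, trajectory_path=None, time_step: float | None = None) -> Trajectory:
    """Read a topology (PDB/GRO) plus optional coordinate file (DCD/XTC).

    Parameters
    ----------
    time_step
        Optional frame spacing in ns, overriding whatever timestamps the
        coordinate file carries (DCD headers often store meaningless times).

    Returns a :class:`Trajectory` in nm/ns regardless of the source format's
    native units.
    """
    import MDAnalysis as mda

    try:
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(trajectory_path))
    except ValueError as exc:
        raise ConsistencyError(str(exc)) from exc
    except Exception as exc:
        raise FormatError(f"cannot read input files: {exc}") from exc

    names = np.array([a.name for a in u.atoms], dtype=object)
    try:
        elements = np.array([str(e).capitalize() for e in u.atoms.elements], dtype=object)
        if any(not e for e in elements):
            raise AttributeError
    except Exception:
        elements = np.array([guess_element(n) for n in names], dtype=object)
    masses = np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements])
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    resids = np.array([a.resid for a in u.atoms], dtype=int)
    try:
        segids = np.array([str(a.segid) for a in u.atoms], dtype=object)
    except Exception:
        segids = np.array(["SYS"] * len(names), dtype=object)

    molecule_ids, molecule_labels = _molecules_from_residues(resnames, resids, segids)
    top = Topology(names, elements, masses, resnames, resids, segids,
                   molecule_ids, molecule_labels)

    times = _times_from_reader(u)
    if time_step is not None:
        times = np.arange(len(times), dtype=float) * time_step
    frames = []
    for i, ts in enumerate(u.trajectory):
        coords = ts.positions / 10.0  # A -> nm
        box = np.asarray(ts.dimensions[:3], dtype=float) / 10.0
        frames.append(Frame(coords, box, float(times[i])))
    return Trajectory(top, frames)


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _molecules_from_residues(resnames, resids, segids):
    """One molecule per lipid residue; all protein-like residues form one molecule."""
    molecule_ids = np.zeros(len(resnames), dtype=int)
    labels: dict[int, str] = {}
    next_id = 0
    protein_id = None
    seen: dict[tuple, int] = {}
    for i, (rn, ri, sg) in enumerate(zip(resnames, resids, segids)):
        if rn in _AMINO_ACIDS or sg in ("PROT", "PRO"):
            if protein_id is None:
                protein_id = next_id
                labels[protein_id] = "protein"
                next_id += 1
            molecule_ids[i] = protein_id
        else:
            key = (sg, ri)
            if key not in seen:
                seen[key] = next_id
                labels[next_id] = str(rn)
                next_id += 1
            molecule_ids[i] = seen[key]
    return molecule_ids, labels


def write_trajectory(traj: Trajectory, topology_path, trajectory_path=None) -> None:
    """Write PDB/GRO topology and optionally a DCD/XTC coordinate file.

    Provided for building fixtures and exporting synthetic systems so that
    analyses can exercise the full file round trip.
    """
    import MDAnalysis as mda

    top = traj.topology
    n_res_keys = []
    resindex = np.zeros(top.n_atoms, dtype=int)
    seen: dict[tuple, int] = {}
    for i in range(top.n_atoms):
        key = (str(top.segids[i]), int(top.resids[i]))
        if key not in seen:
            seen[key] = len(n_res_keys)
            n_res_keys.append(key)
        resindex[i] = seen[key]
    n_residues = len(n_res_keys)
    res_resids = np.zeros(n_residues, dtype=int)
    res_resnames = np.empty(n_residues, dtype=object)
    res_seg = np.zeros(n_residues, dtype=int)
    seg_keys = sorted({k[0] for k in n_res_keys})
    seg_index = {s: j for j, s in enumerate(seg_keys)}
    for i in range(top.n_atoms):
        j = resindex[i]
        res_resids[j] = top.resids[i]
        res_resnames[j] = top.resnames[i]
        res_seg[j] = seg_index[str(top.segids[i])]

    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=n_residues,
        n_segments=len(seg_keys),
        atom_resindex=resindex,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in top.names])
    u.add_TopologyAttr("elements", [str(e) for e in top.elements])
    u.add_TopologyAttr("masses", top.masses)
    u.add_TopologyAttr("resnames", [str(r) for r in res_resnames])
    u.add_TopologyAttr("resids", res_resids)
    u.add_TopologyAttr("segids", seg_keys)

    f0 = traj.frames[0]
    u.atoms.positions = f0.coordinates * 10.0
    u.dimensions = [f0.box[0] * 10, f0.box[1] * 10, f0.box[2] * 10, 90, 90, 90]
    u.atoms.write(str(topology_path))

    if trajectory_path is not None:
        with mda.Writer(str(trajectory_path), n_atoms=top.n_atoms) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coordinates * 10.0
                u.dimensions = [fr.box[0] * 10, fr.box[1] * 10, fr.box[2] * 10, 90, 90, 90]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------
#
#   expr     := or_expr
#   or_expr  := and_expr ("or" and_expr)*
#   and_expr := not_expr ("and" not_expr)*
#   not_expr := "not" not_expr | "(" expr ")" | primary
#   primary  := key value+
#   key      := "name" | "resname" | "element" | "segid" | "resid"
#   value    := bare token; for "resid" also "a:b" (1-based, inclusive)

_KEYWORDS = {"name", "resname", "element", "segid", "resid"}
_OPERATORS = {"and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    expression = expression.replace("(", " ( ").replace(")", " ) ")
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], top: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = top

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens starting at {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() == "and":
            self.take()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.not_expr()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        key = self.take()
        if key not in _KEYWORDS:
            raise SelectionError(f"unknown selection keyword {key!r}")
        values = []
        while self.peek() is not None and self.peek() not in _OPERATORS \
                and self.peek() not in _KEYWORDS:
            values.append(self.take())
        if not values:
            raise SelectionError(f"keyword {key!r} needs at least one value")
        top = self.top
        n = top.n_atoms
        mask = np.zeros(n, dtype=bool)
        if key == "resid":
            resids = top.resids
            for v in values:
                if ":" in v:
                    lo_s, hi_s = v.split(":", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid range {v!r}") from exc
                    mask |= (resids >= lo) & (resids <= hi)
                else:
                    try:
                        mask |= resids == int(v)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid {v!r}") from exc
        else:
            attr = {"name": top.names, "resname": top.resnames,
                    "element": top.elements, "segid": top.segids}[key]
            attr = np.asarray(attr, dtype=object)
            for v in values:
                mask |= attr == v
        return mask


def select(topology: Topology, expression: str) -> AtomSet:
    """Evaluate a selection expression, returning an index-ordered AtomSet.

    The grammar supports ``name``/``resname``/``element``/``segid`` value
    lists, 1-based inclusive ``resid a:b`` ranges, and ``and``/``or``/``not``
    with parentheses. An empty result is legal (and logged), a malformed
    expression raises :class:`SelectionError`.
    """
    mask = _Parser(_tokenize(expression), topology).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        logger.info("selection %r matched no atoms", expression)
    return AtomSet(indices)


# ---------------------------------------------------------------------------
# Leaflets and periodic boundaries
# ---------------------------------------------------------------------------

def assign_leaflets(frame: Frame, reference_atoms: AtomSet) -> np.ndarray:
    """Label each reference atom 'upper' or 'lower' by a median-z split.

    The reference atoms are typically the phosphorus atoms of the
    phospholipids (one per lipid); cholesterol, which has no phosphate, can
    be assigned by passing its hydroxyl oxygen instead. The median split is
    invariant under any common z-translation, so membrane drift along the
    normal does not flip labels.
    """
    idx = reference_atoms.indices
    if len(idx) < 2:
        raise ValueError("leaflet assignment needs at least two reference atoms")
    z = frame.coordinates[idx, 2]
    median = np.median(z)
    labels = np.where(z > median, "upper", "lower")
    # A strict >-median split can starve one leaflet when the median value is
    # attained; fall back to a rank split in that (degenerate) case.
    if (labels == "upper").sum() == 0 or (labels == "lower").sum() == 0:
        order = np.argsort(z, kind="stable")
        labels = np.empty(len(idx), dtype=object)
        half = len(idx) // 2
        labels[order[:half]] = "lower"
        labels[order[half:]] = "upper"
    logger.debug("leaflet counts: upper=%d lower=%d",
                 (labels == "upper").sum(), (labels == "lower").sum())
    return np.asarray(labels, dtype=object)


def wrap_displacement(dx, box_length):
    """Minimum-image displacement in (-L/2, +L/2]; +L/2 kept at the tie."""
    dx = np.asarray(dx, dtype=float)
    L = np.asarray(box_length, dtype=float)
    if np.any(L <= 0):
        raise ValueError("box length must be positive")
    out = dx - L * np.ceil(dx / L - 0.5)
    if out.ndim == 0:
        return float(out)
    return out


def wrap_into_box(x, box_length):
    """Wrap absolute coordinates into [0, L)."""
    x = np.asarray(x, dtype=float)
    L = np.asarray(box_length, dtype=float)
    return x - L * np.floor(x / L)
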