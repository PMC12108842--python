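"""Topology and trajectory data model with periodic geometry.

Internal units are angstrom (coordinates, box edges) and picosecond (times)
throughout the package; unit conversion happens only inside the MDAnalysis
readers/writers used at the I/O boundary.  Only orthorhombic boxes are
supported: triclinic inputs are rejected rather than silently wrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .exceptions import (
    EmptyTrajectoryError,
    FormatMismatchError,
    UnsupportedBoxError,
)

#: Residue names recognised as water (rigid 3-site and 4/5-site models).
WATER_RESNAMES = frozenset(
    {"SOL", "WAT", "HOH", "TIP3", "TIP4", "TIP5", "SPC", "SPCE", "T3P", "T4P"}
)

#: Standard amino-acid residue names, including common protonation variants.
PROTEIN_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "CYM", "ASH", "GLH",
        "LYN", "ACE", "NME", "NHE",
    }
)

_ION_RESNAMES = frozenset(
    {"NA", "NA+", "SOD", "CL", "CL-", "CLA", "K", "K+", "POT", "MG", "MG2",
     "ZN", "CAL"}
)

#: Atom-name prefixes that mark massless virtual sites (TIP4P/TIP5P style).
_VIRTUAL_PREFIXES = ("MW", "EP", "LP", "DUM")


def guess_element(name: str, resname: str) -> str:
    """Guess the chemical element from an atom name.

    Returns ``""`` for virtual sites (e.g. the TIP4P M site).  Ion residues
    are resolved from the residue name so that a calcium ion is not confused
    with a C-alpha atom.
    """
    n = name.strip().upper()
    base = n.rstrip("0123456789+-")
    if base.startswith(_VIRTUAL_PREFIXES) or base == "M":
        return ""
    if resname.strip().upper() in _ION_RESNAMES:
        two = {"NA": "Na", "SOD": "Na", "CL": "Cl", "CLA": "Cl", "K": "K",
               "POT": "K", "MG": "Mg", "MG2": "Mg", "ZN": "Zn", "CAL": "Ca"}
        return two.get(base, base.capitalize())
    for ch in n:
        if ch.isalpha():
            return ch.upper()
    raise FormatMismatchError(f"cannot guess element for atom name {name!r}")


@dataclass(frozen=True)
class WaterSites:
    """Atom indices of the real sites of one water molecule."""

    oxygen: int
    hydrogens: tuple[int, int]
    virtual: tuple[int, ...] = ()


@dataclass
class Topology:
    """Static description of the system: atoms, residues, water site map.

    ``atom_resindices`` are 0-based internal residue indices; reports render
    them 1-based to follow PDB numbering.
    """

    atom_names: np.ndarray
    atom_elements: np.ndarray
    atom_resindices: np.ndarray
    residue_names: np.ndarray
    segment_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.atom_elements = np.asarray(self.atom_elements, dtype=object)
        self.atom_resindices = np.asarray(self.atom_resindices, dtype=np.intp)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        if self.segment_ids is None:
            self.segment_ids = np.asarray(["SYS"] * self.n_atoms, dtype=object)
        if not (
            len(self.atom_names)
            == len(self.atom_elements)
            == len(self.atom_resindices)
            == len(self.segment_ids)
        ):
            raise FormatMismatchError("atom attribute arrays differ in length")
        if self.atom_resindices.min(initial=0) < 0 or (
            self.n_atoms and self.atom_resindices.max() >= self.n_residues
        ):
            raise FormatMismatchError("atom residue index out of range")
        # Validate the water site map eagerly: every water must have exactly
        # one oxygen and two hydrogens.
        _ = self.water_sites

    # -- basic sizes -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    # -- residue-level flags ----------------------------------------------
    @cached_property
    def is_water(self) -> np.ndarray:
        return np.asarray(
            [str(r).upper() in WATER_RESNAMES for r in self.residue_names]
        )

    @cached_property
    def is_protein(self) -> np.ndarray:
        return np.asarray(
            [str(r).upper() in PROTEIN_RESNAMES for r in self.residue_names]
        )

    @cached_property
    def water_residues(self) -> np.ndarray:
        return np.flatnonzero(self.is_water)

    @cached_property
    def protein_residues(self) -> np.ndarray:
        return np.flatnonzero(self.is_protein)

    # -- atom-level selections --------------------------------------------
    @cached_property
    def residue_atoms(self) -> list[np.ndarray]:
        """Atom indices of each residue, in residue order."""
        order = np.argsort(self.atom_resindices, kind="stable")
        bounds = np.searchsorted(
            self.atom_resindices[order], np.arange(self.n_residues + 1)
        )
        return [order[bounds[i]: bounds[i + 1]] for i in range(self.n_residues)]

    @cached_property
    def heavy_atom_mask(self) -> np.ndarray:
        """Real atoms that are not hydrogen (virtual sites excluded)."""
        return np.asarray(
            [e not in ("H", "") for e in self.atom_elements], dtype=bool
        )

    @cached_property
    def protein_atom_mask(self) -> np.ndarray:
        return self.is_protein[self.atom_resindices]

    @cached_property
    def protein_heavy_mask(self) -> np.ndarray:
        return self.protein_atom_mask & self.heavy_atom_mask

    @cached_property
    def protein_carbons(self) -> np.ndarray:
        """Indices of protein carbon atoms (the hydration-shell reference)."""
        mask = self.protein_atom_mask & (self.atom_elements == "C")
        return np.flatnonzero(mask)

    @cached_property
    def water_sites(self) -> dict[int, WaterSites]:
        """Per-water map of oxygen / hydrogen / virtual-site atom indices."""
        sites: dict[int, WaterSites] = {}
        for res in np.flatnonzero(self.is_water):
            atoms = self.residue_atoms[int(res)]
            elems = [self.atom_elements[a] for a in atoms]
            oxy = [int(a) for a, e in zip(atoms, elems) if e == "O"]
            hyd = [int(a) for a, e in zip(atoms, elems) if e == "H"]
            virt = tuple(int(a) for a, e in zip(atoms, elems) if e == "")
            if len(oxy) != 1 or len(hyd) != 2:
                raise FormatMismatchError(
                    f"water residue {res} has {len(oxy)} oxygen(s) and "
                    f"{len(hyd)} hydrogen(s); expected 1 and 2"
                )
            sites[int(res)] = WaterSites(oxy[0], (hyd[0], hyd[1]), virt)
        return sites


@dataclass
class Frame:
    """One trajectory frame: coordinates (A), orthorhombic box (A), time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise UnsupportedBoxError(
                f"box must be three positive edge lengths, got {self.box}"
            )
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise FormatMismatchError("coordinates must have shape (n_atoms, 3)")


_DT_TOL = 1e-6  # ps; tolerance on uniform frame spacing


@dataclass
class FrameSet:
    """A topology plus ordered, uniformly spaced periodic frames."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3) in A
    boxes: np.ndarray  # (n_frames, 3) in A
    times: np.ndarray  # (n_frames,) in ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.boxes = np.asarray(self.boxes, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatMismatchError("coordinates must be (n_frames, n_atoms, 3)")
        if len(self.coordinates) == 0:
            raise EmptyTrajectoryError("trajectory contains zero frames")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise FormatMismatchError(
                f"trajectory has {self.coordinates.shape[1]} atoms/frame but "
                f"topology has {self.topology.n_atoms}"
            )
        if np.any(self.boxes <= 0):
            raise UnsupportedBoxError("all box edges must be positive")
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise FormatMismatchError("frame times must strictly increase")
            if np.ptp(dts) > _DT_TOL:
                raise FormatMismatchError(
                    "frame spacing is not uniform within 1e-6 ps"
                )

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def n_frames(self) -> int:
        return len(self.coordinates)

    @property
    def dt(self) -> float:
        """Frame spacing in ps (0.0 for a single-frame set)."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def slice_time(self, start: float | None, end: float | None) -> "FrameSet":
        """Restrict to frames with start <= time < end (None = unbounded)."""
        mask = np.ones(self.n_frames, dtype=bool)
        if start is not None:
            mask &= self.times >= start - _DT_TOL
        if end is not None:
            mask &= self.times < end - _DT_TOL
        if not mask.any():
            raise EmptyTrajectoryError("analysis window selects zero frames")
        return FrameSet(
            self.topology, self.coordinates[mask], self.boxes[mask],
            self.times[mask],
        )


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary image of an orthorhombic box.

    Works on any array whose last axis has length 3; ``box`` broadcasts.
    """
    d = np.asarray(d, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    return d - box * np.round(d / box)


def minimum_image_distance(p, q, box) -> np.ndarray | float:
    """Minimum-image distance between points ``p`` and ``q`` (angstrom).

    ``p`` and ``q`` may be single 3-vectors or broadcastable arrays of them.

    Raises
    ------
    UnsupportedBoxError
        If any box edge is non-positive.
    """
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise UnsupportedBoxError("box edges must be positive")
    d = minimum_image_displacement(np.asarray(p, dtype=np.float64) - q, box)
    r = np.sqrt(np.einsum("...i,...i->...", d, d))
    return float(r) if np.ndim(r) == 0 else r


def pairwise_min_image_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances."""
    d = minimum_image_displacement(a[:, None, :] - b[None, :, :], box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# ---------------------------------------------------------------------------
# I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None or np.all(dimensions[:3] == 0):
        raise UnsupportedBoxError("trajectory frame carries no box vectors")
    angles = np.asarray(dimensions[3:6], dtype=float)
    if np.any(np.abs(angles - 90.0) > 1e-3):
        raise UnsupportedBoxError(
            f"only orthorhombic boxes are supported (angles {angles})"
        )
    return np.asarray(dimensions[:3], dtype=np.float64)


def topology_from_universe(u) -> Topology:
    """Build a :class:`Topology` from an MDAnalysis Universe."""
    names = [str(n) for n in u.atoms.names]
    resnames_atom = [str(r) for r in u.atoms.resnames]
    elements = [guess_element(n, r) for n, r in zip(names, resnames_atom)]
    try:
        segids = [str(s) for s in u.atoms.segids]
    except Exception:  # pragma: no cover - segids always present in practice
        segids = ["SYS"] * len(names)
    return Topology(
        atom_names=np.asarray(names, dtype=object),
        atom_elements=np.asarray(elements, dtype=object),
        atom_resindices=np.asarray(u.atoms.resindices, dtype=np.intp),
        residue_names=np.asarray([str(r) for r in u.residues.resnames],
                                 dtype=object),
        segment_ids=np.asarray(segids, dtype=object),
    )


def load_system(topology_path, trajectory_path=None) -> FrameSet:
    """Read a topology (PDB/GRO) plus trajectory (XTC/TRR/DCD) into a FrameSet.

    MDAnalysis performs all unit conversion; coordinates arrive in angstrom
    and times in picoseconds.  Water residues are auto-detected by residue
    name (SOL, WAT, HOH, TIP4, ...).
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(Path(trajectory_path)))
    except (ValueError, IOError, OSError) as exc:
        raise FormatMismatchError(
            f"could not combine {topology_path} with {trajectory_path}: {exc}"
        ) from exc

    topology = topology_from_universe(u)
    coords, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.n_atoms != topology.n_atoms:
                raise FormatMismatchError(
                    f"frame has {ts.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            boxes.append(_check_orthorhombic(ts.dimensions))
            coords.append(np.array(ts.positions, dtype=np.float64))
            times.append(float(ts.time))
    if not coords:
        raise EmptyTrajectoryError(f"{trajectory_path} contains zero frames")
    return FrameSet(topology, np.stack(coords), np.stack(boxes),
                    _regularize_times(np.asarray(times)))


def _regularize_times(times: np.ndarray) -> np.ndarray:
    """Snap file times to an exact uniform grid.

    Trajectory formats store times in single precision, so a nominally
    constant spacing drifts by a few float32 ulps over long runs.  Times
    within that rounding of a uniform grid are replaced by the exact grid;
    genuinely non-uniform spacing is left untouched (and rejected by the
    FrameSet invariant)."""
    if len(times) < 3:
        return times
    dt = float(times[-1] - times[0]) / (len(times) - 1)
    if dt <= 0:
        return times
    grid = times[0] + dt * np.arange(len(times))
    tol = max(1e-5, 8.0 * np.abs(times).max() * np.finfo(np.float32).eps)
    if np.abs(times - grid).max() <= tol:
        return grid
    return times


def _universe_from_frameset(fs: FrameSet):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    top = fs.topology
    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=top.n_residues,
        atom_resindex=top.atom_resindices,
        residue_segindex=np.zeros(top.n_residues, dtype=int),
        trajectory=False,
    )
    u.add_TopologyAttr("names", [str(n) for n in top.atom_names])
    u.add_TopologyAttr("resnames", [str(r) for r in top.residue_names])
    u.add_TopologyAttr("resids", np.arange(1, top.n_residues + 1))
    u.add_TopologyAttr("segids", ["SYS"])
    dims = np.zeros((fs.n_frames, 6), dtype=np.float64)
    dims[:, :3] = fs.boxes
    dims[:, 3:] = 90.0
    u.load_new(
        fs.coordinates.astype(np.float32),
        format=MemoryReader,
        dimensions=dims,
        dt=fs.dt if fs.n_frames > 1 else 1.0,
    )
    return u


def write_system(fs: FrameSet, topology_path, trajectory_path=None) -> None:
    """Write a FrameSet as GRO (first frame) plus optional TRR trajectory.

    Used to persist synthetic fixtures in standard formats; MDAnalysis
    converts to the nm-based GRO/TRR units on output.
    """
    import MDAnalysis as mda

    u = _universe_from_frameset(fs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.trajectory[0]
        u.atoms.write(str(topology_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n_atoms=fs.topology.n_atoms) as w:
                for ts in u.trajectory:
                    w.write(u.atoms)
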