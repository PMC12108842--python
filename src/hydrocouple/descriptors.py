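"""Per-residue structural descriptors: RMSF, SASA, RMSD series, chemistry.

RMSF and the per-residue RMSD series are computed after a global
least-squares (Kabsch) superposition of every frame onto a reference frame
using the protein heavy atoms, so rigid-body motion never contributes to
the reported fluctuations.  SASA uses the Shrake-Rupley construction with a
deterministic golden-spiral point set and Bondi van der Waals radii, so
results are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ClassificationError, ConfigurationError
from .series import GappedSeries
from .trajectory import Frame, FrameSet, Topology

#: Bondi van der Waals radii (A).
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "Na": 2.27,
    "K": 2.75,
    "Mg": 1.73,
    "Zn": 1.39,
    "Ca": 2.31,
}

DEFAULT_PROBE_RADIUS = 1.4  # A
DEFAULT_SASA_POINTS = 960

NONPOLAR = frozenset({"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"})
POLAR = frozenset({"SER", "THR", "CYS", "TYR", "ASN", "GLN"})
CHARGED = frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"})
_HIS_VARIANTS = frozenset({"HIS", "HID", "HIE", "HIP", "HSD", "HSE", "HSP"})


def residue_class(resname: str, histidine: str = "charged") -> str:
    """Chemical class of a standard amino acid.

    Glycine, lacking a side chain, is ``"excluded"`` from class statistics.
    Histidine is titratable and defaults to ``"charged"``; pass
    ``histidine="polar"`` to move it.
    """
    name = str(resname).strip().upper()
    if name == "GLY":
        return "excluded"
    if name in _HIS_VARIANTS:
        if histidine not in ("charged", "polar"):
            raise ClassificationError(f"invalid histidine class {histidine!r}")
        return histidine
    if name in NONPOLAR:
        return "non-polar"
    if name in POLAR:
        return "polar"
    if name in CHARGED:
        return "charged"
    raise ClassificationError(f"unknown residue name {resname!r}")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix R with (mobile - cm) @ R ~ (reference - cr)."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def superpose_frames(
    fs: FrameSet,
    fit_mask: np.ndarray | None = None,
    reference_index: int = 0,
) -> np.ndarray:
    """Least-squares superpose every frame onto a reference frame.

    Returns a new (n_frames, n_atoms, 3) coordinate array; the fit uses the
    atoms selected by ``fit_mask`` (default: protein heavy atoms) and the
    resulting rigid transform is applied to all atoms.
    """
    if fit_mask is None:
        fit_mask = fs.topology.protein_heavy_mask
    fit_idx = np.flatnonzero(fit_mask)
    if len(fit_idx) == 0:
        raise ConfigurationError("superposition fit selection is empty")
    ref = fs.coordinates[reference_index, fit_idx]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(fs.coordinates)
    for i in range(fs.n_frames):
        mob = fs.coordinates[i, fit_idx]
        cm = mob.mean(axis=0)
        rot = kabsch_rotation(mob - cm, ref_c)
        out[i] = (fs.coordinates[i] - cm) @ rot + ref.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _selection_mask(topology: Topology, selection: str) -> np.ndarray:
    if selection == "heavy":
        return topology.protein_heavy_mask
    if selection == "all":
        return topology.protein_atom_mask & np.asarray(
            [e != "" for e in topology.atom_elements]
        )
    raise ConfigurationError(f"unknown RMSF selection {selection!r}")


def rmsf(
    fs: FrameSet,
    selection: str = "heavy",
    reference_index: int = 0,
    superpose: bool = True,
) -> pd.Series:
    """Per-residue RMSF (A): sqrt of the mean squared deviation of each
    atom from its time-averaged position, averaged over the residue's
    selected atoms, after global superposition.

    ``superpose=False`` skips the fit for trajectories that are already
    aligned."""
    if fs.n_frames < 2:
        raise ConfigurationError("RMSF requires at least 2 frames")
    mask = _selection_mask(fs.topology, selection)
    if not mask.any():
        raise ConfigurationError("RMSF atom selection is empty")
    if superpose:
        coords = superpose_frames(fs, fs.topology.protein_heavy_mask,
                                  reference_index)
    else:
        coords = fs.coordinates
    sel = np.flatnonzero(mask)
    x = coords[:, sel, :]
    mean_pos = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean_pos) ** 2, axis=2), axis=0))
    res_of = fs.topology.atom_resindices[sel]
    out = pd.Series(per_atom).groupby(res_of).mean()
    out.index.name = "residue"
    out.name = "rmsf"
    return out.reindex(fs.topology.protein_residues)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley, golden-spiral quadrature)
# ---------------------------------------------------------------------------

def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_frame(
    frame: Frame,
    topology: Topology,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    radii: dict[str, float] | None = None,
    atom_indices: np.ndarray | None = None,
) -> pd.Series:
    """Per-residue solvent-accessible surface area (A^2) of one frame.

    Each atom's expanded sphere (vdW radius + probe) is sampled with
    ``n_points`` quasi-uniform points; points falling inside any other
    atom's expanded sphere are buried.  The per-residue value is the sum
    over the residue's atoms.
    """
    table = BONDI_RADII if radii is None else radii
    if atom_indices is None:
        atom_indices = np.flatnonzero(
            topology.protein_atom_mask
            & np.asarray([e != "" for e in topology.atom_elements])
        )
    atom_indices = np.asarray(atom_indices, dtype=np.intp)
    if len(atom_indices) == 0:
        raise ConfigurationError("SASA selection is empty")
    elems = [topology.atom_elements[a] for a in atom_indices]
    missing = sorted({e for e in elems if e not in table})
    if missing:
        raise ConfigurationError(f"no vdW radius for element(s) {missing}")
    r_exp = np.asarray([table[e] for e in elems]) + probe
    xyz = frame.coordinates[atom_indices]
    sphere = _golden_spiral_points(n_points)

    # Neighbor lists from the pairwise upper bound r_i + r_j.
    diff = xyz[:, None, :] - xyz[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    cut2 = (r_exp[:, None] + r_exp[None, :]) ** 2
    np.fill_diagonal(d2, np.inf)
    nbrs = [np.flatnonzero(d2[i] < cut2[i]) for i in range(len(atom_indices))]

    areas = np.empty(len(atom_indices))
    for i in range(len(atom_indices)):
        pts = xyz[i] + r_exp[i] * sphere
        if len(nbrs[i]) == 0:
            frac = 1.0
        else:
            nd = pts[:, None, :] - xyz[nbrs[i]][None, :, :]
            d2 = np.einsum("pjk,pjk->pj", nd, nd)
            r2 = r_exp[nbrs[i]] ** 2
            tol = 1e-9 * r2
            # Points exactly on another expanded sphere (degenerate overlap,
            # e.g. coincident atoms) are buried only against a lower atom
            # index, so a shared surface is counted exactly once.
            inside = d2 < r2 - tol
            inside |= (np.abs(d2 - r2) <= tol) & (nbrs[i] < i)
            frac = 1.0 - inside.any(axis=1).mean()
        areas[i] = frac * 4.0 * np.pi * r_exp[i] ** 2

    res_of = topology.atom_resindices[atom_indices]
    out = pd.Series(areas).groupby(res_of).sum()
    out.index.name = "residue"
    out.name = "sasa"
    return out.reindex(topology.protein_residues, fill_value=0.0)


def sasa(
    fs: FrameSet,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    stride: int = 1,
    radii: dict[str, float] | None = None,
) -> pd.Series:
    """Time-mean per-residue SASA over every ``stride``-th frame."""
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    frames = range(0, fs.n_frames, stride)
    acc = None
    count = 0
    for i in frames:
        s = sasa_frame(fs.frame(i), fs.topology, probe, n_points, radii)
        acc = s if acc is None else acc + s
        count += 1
    return acc / count


# ---------------------------------------------------------------------------
# Per-residue RMSD series
# ---------------------------------------------------------------------------

def residue_rmsd_series(
    fs: FrameSet,
    reference_index: int = 0,
    fit_selection: str = "heavy",
    superpose: bool = True,
) -> dict[int, GappedSeries]:
    """Gap-free per-residue RMSD (A) versus a reference frame.

    Every frame is globally superposed onto the reference using the protein
    heavy atoms; the per-residue value is then the RMSD of that residue's
    heavy atoms relative to the reference."""
    if superpose:
        fit_mask = _selection_mask(fs.topology, fit_selection)
        coords = superpose_frames(fs, fit_mask, reference_index)
    else:
        coords = fs.coordinates
    topo = fs.topology
    dt = fs.dt if fs.n_frames > 1 else 1.0
    out: dict[int, GappedSeries] = {}
    for r in topo.protein_residues:
        atoms = topo.residue_atoms[int(r)]
        atoms = atoms[topo.heavy_atom_mask[atoms]]
        if len(atoms) == 0:
            continue
        dx = coords[:, atoms, :] - coords[reference_index, atoms, :]
        vals = np.sqrt(np.mean(np.sum(dx**2, axis=2), axis=1))
        out[int(r)] = GappedSeries(int(r), vals, dt, "rmsd")
    return out


def descriptor_table(
    fs: FrameSet,
    rmsf_selection: str = "heavy",
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    sasa_stride: int = 1,
    histidine: str = "charged",
) -> pd.DataFrame:
    """Residue table: name, class, RMSF (A), time-mean SASA (A^2)."""
    topo = fs.topology
    prot = topo.protein_residues
    names = [str(topo.residue_names[int(r)]) for r in prot]
    classes = [residue_class(n, histidine) for n in names]
    table = pd.DataFrame(
        {
            "residue": prot,
            "name": names,
            "class": classes,
        }
    ).set_index("residue")
    table["rmsf"] = rmsf(fs, rmsf_selection)
    table["sasa"] = sasa(fs, probe, n_points, sasa_stride)
    return table
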