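"""Hydration-shell identification and water-to-residue contact assignment.

A water belongs to the hydration shell of a frame when any of its real atoms
(O, H, H) lies within a cutoff (default 5 A) of any protein carbon atom,
using minimum-image distances.  Each shell water is then assigned to the
protein residue whose surface it sits on: the residue minimising the
distance from the water oxygen to any heavy atom of the residue, with ties
broken by the lowest residue index for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .trajectory import Frame, FrameSet, Topology, pairwise_min_image_distances

DEFAULT_SHELL_CUTOFF = 5.0  # A


@dataclass(frozen=True)
class ShellAssignment:
    """Per-frame shell membership and water->residue contact map."""

    frame_index: int
    shell_waters: frozenset[int]
    contact_map: dict[int, int]
    bulk_waters: frozenset[int]


def _water_real_atoms(topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (atom_index, owner_water_residue) for all real water atoms."""
    atoms, owners = [], []
    for res in topology.water_residues:
        sites = topology.water_sites[int(res)]
        for a in (sites.oxygen, *sites.hydrogens):
            atoms.append(a)
            owners.append(int(res))
    return np.asarray(atoms, dtype=np.intp), np.asarray(owners, dtype=np.intp)


def shell_waters(
    frame: Frame,
    topology: Topology,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
) -> frozenset[int]:
    """Water residues with any real atom within ``cutoff`` of a protein carbon."""
    carbons = topology.protein_carbons
    if len(carbons) == 0:
        raise ConfigurationError("topology contains no protein carbon atoms")
    if len(topology.water_residues) == 0:
        raise ConfigurationError("topology contains no water residues")
    atoms, owners = _water_real_atoms(topology)
    d = pairwise_min_image_distances(
        frame.coordinates[atoms], frame.coordinates[carbons], frame.box
    )
    hit = d.min(axis=1) < cutoff
    return frozenset(int(w) for w in np.unique(owners[hit]))


def contact_map(
    frame: Frame,
    topology: Topology,
    shell: frozenset[int] | set[int],
    water_site: str = "oxygen",
    residue_atoms: str = "heavy",
) -> dict[int, int]:
    """Assign every shell water to its nearest protein residue.

    Parameters
    ----------
    water_site:
        ``"oxygen"`` (default) measures from the water oxygen; ``"any"``
        uses the closest of the three real water atoms.
    residue_atoms:
        Which residue atoms define its surface: ``"heavy"`` (default),
        ``"carbon"`` or ``"any"``.
    """
    if not shell:
        return {}
    waters = sorted(int(w) for w in shell)
    bad = [w for w in waters if w not in topology.water_sites]
    if bad:
        raise ConfigurationError(f"shell contains non-water residues {bad}")

    if water_site == "oxygen":
        site_atoms = [[topology.water_sites[w].oxygen] for w in waters]
    elif water_site == "any":
        site_atoms = [
            [topology.water_sites[w].oxygen, *topology.water_sites[w].hydrogens]
            for w in waters
        ]
    else:
        raise ConfigurationError(f"unknown contact_water_site {water_site!r}")

    if residue_atoms == "heavy":
        atom_mask = topology.protein_heavy_mask
    elif residue_atoms == "carbon":
        atom_mask = topology.protein_atom_mask & (topology.atom_elements == "C")
    elif residue_atoms == "any":
        atom_mask = topology.protein_atom_mask & np.asarray(
            [e != "" for e in topology.atom_elements]
        )
    else:
        raise ConfigurationError(f"unknown contact_residue_atoms {residue_atoms!r}")

    prot_atoms = np.flatnonzero(atom_mask)
    if len(prot_atoms) == 0:
        raise ConfigurationError("no protein atoms selected for contact map")
    prot_res = topology.atom_resindices[prot_atoms]
    order = np.argsort(prot_res, kind="stable")
    prot_atoms = prot_atoms[order]
    prot_res = prot_res[order]
    res_ids, starts = np.unique(prot_res, return_index=True)

    flat_sites = np.asarray([a for group in site_atoms for a in group])
    site_owner = np.repeat(
        np.arange(len(waters)), [len(g) for g in site_atoms]
    )
    d = pairwise_min_image_distances(
        frame.coordinates[flat_sites], frame.coordinates[prot_atoms], frame.box
    )
    # Minimum distance per (water site row, residue); then per water.
    per_res = np.minimum.reduceat(d, starts, axis=1)
    result: dict[int, int] = {}
    for wi, w in enumerate(waters):
        rows = per_res[site_owner == wi]
        best = rows.min(axis=0)
        # argmin returns the first (= lowest residue index) on exact ties
        result[w] = int(res_ids[int(np.argmin(best))])
    return result


def assign_frame(
    frame: Frame,
    topology: Topology,
    frame_index: int = 0,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    water_site: str = "oxygen",
    residue_atoms: str = "heavy",
) -> ShellAssignment:
    shell = shell_waters(frame, topology, cutoff)
    cmap = contact_map(frame, topology, shell, water_site, residue_atoms)
    bulk = frozenset(int(w) for w in topology.water_residues) - shell
    return ShellAssignment(frame_index, shell, cmap, bulk)


def assign_all(
    fs: FrameSet,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    water_site: str = "oxygen",
    residue_atoms: str = "heavy",
) -> list[ShellAssignment]:
    """Shell assignment for every frame of a FrameSet."""
    return [
        assign_frame(fs.frame(i), fs.topology, i, cutoff, water_site,
                     residue_atoms)
        for i in range(fs.n_frames)
    ]
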