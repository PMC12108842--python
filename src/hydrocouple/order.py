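"""Per-water structural order parameters and per-residue order series.

Two complementary measures of local water structure are computed:

* the translational order parameter zeta = r_nhb - r_hb, the oxygen-oxygen
  distance to the nearest non-hydrogen-bonded water minus the distance to
  the farthest hydrogen-bonded water.  Large positive zeta means an intact,
  well-separated first coordination shell; zeta near zero or negative means
  a non-bonded molecule has penetrated the first shell (local disorder).
* the orientational tetrahedral order parameter
  q = 1 - 3/8 * sum over the six angle pairs of (cos(theta_ij) + 1/3)^2,
  evaluated on the four nearest water oxygens.  q = 1 for a perfect
  tetrahedron, ~0 for random arrangements, and can be negative for
  constrained geometries; low-coordination waters are deliberately not
  filtered out.

Two waters are hydrogen bonded when their O-O minimum-image distance is
below 3.5 A and at least one O-H...O arrangement (either molecule donating
either hydrogen) deviates from linearity by no more than 40 degrees.

zeta is *undefined* (NaN, never clamped) for waters with no hydrogen-bond
partner or no non-bonded water; undefined records are excluded from every
statistic and counted in the run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    EmptyTrajectoryError,
    InsufficientNeighborsError,
)
from .series import GappedSeries
from .shell import ShellAssignment
from .trajectory import (
    Frame,
    FrameSet,
    Topology,
    minimum_image_displacement,
)

HB_OO_CUTOFF = 3.5  # A
HB_ANGLE_DEVIATION_MAX = 40.0  # degrees from linearity
Q_NEIGHBOR_COUNT = 4


def _water_coords(frame: Frame, topology: Topology):
    """Oxygen (nw,3) and hydrogen (nw,2,3) coordinates in water-residue order."""
    waters = topology.water_residues
    o_idx = np.asarray([topology.water_sites[int(w)].oxygen for w in waters])
    h_idx = np.asarray([topology.water_sites[int(w)].hydrogens for w in waters])
    return frame.coordinates[o_idx], frame.coordinates[h_idx], waters


def oo_distance_matrix(frame: Frame, topology: Topology) -> np.ndarray:
    """Minimum-image O-O distance matrix over all waters (inf on diagonal)."""
    o, _, _ = _water_coords(frame, topology)
    d = minimum_image_displacement(o[:, None, :] - o[None, :, :], frame.box)
    m = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    np.fill_diagonal(m, np.inf)
    return m


def hbond_adjacency(
    frame: Frame,
    topology: Topology,
    oo_cutoff: float = HB_OO_CUTOFF,
    angle_deviation_max: float = HB_ANGLE_DEVIATION_MAX,
    oo: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric boolean water-water hydrogen-bond matrix."""
    o, h, _ = _water_coords(frame, topology)
    n = len(o)
    if oo is None:
        oo = oo_distance_matrix(frame, topology)
    adj = np.zeros((n, n), dtype=bool)
    ii, jj = np.nonzero(np.triu(oo < oo_cutoff, k=1))
    if len(ii) == 0:
        return adj
    cos_max = np.cos(np.deg2rad(180.0 - angle_deviation_max))
    bonded = np.zeros(len(ii), dtype=bool)
    # Four donor arrangements: donor in {i, j} x hydrogen in {0, 1}.
    for donor_is_i in (True, False):
        don_o = o[ii] if donor_is_i else o[jj]
        acc_o = o[jj] if donor_is_i else o[ii]
        don_h = h[ii] if donor_is_i else h[jj]
        for k in (0, 1):
            hk = don_h[:, k, :]
            a = minimum_image_displacement(don_o - hk, frame.box)
            b = minimum_image_displacement(acc_o - hk, frame.box)
            cos = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            # angle at H >= 140 deg  <=>  cos(angle) <= cos(140 deg)
            bonded |= cos <= cos_max
    adj[ii[bonded], jj[bonded]] = True
    adj |= adj.T
    return adj


def is_hydrogen_bonded(
    water_a: int,
    water_b: int,
    frame: Frame,
    topology: Topology,
    oo_cutoff: float = HB_OO_CUTOFF,
    angle_deviation_max: float = HB_ANGLE_DEVIATION_MAX,
) -> bool:
    """Hydrogen-bond criterion for one water pair (residue indices)."""
    if water_a == water_b:
        raise ConfigurationError("a water cannot hydrogen-bond to itself")
    waters = list(topology.water_residues)
    ia, ib = waters.index(water_a), waters.index(water_b)
    adj = hbond_adjacency(frame, topology, oo_cutoff, angle_deviation_max)
    return bool(adj[ia, ib])


@dataclass
class WaterOrderFrame:
    """Per-water order parameters for one frame (NaN where undefined)."""

    waters: np.ndarray  # water residue indices, fixed order
    zeta: np.ndarray
    r_nhb: np.ndarray
    r_hb: np.ndarray
    n_hbonds: np.ndarray
    q: np.ndarray | None = None

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.zeta).sum())


def zeta_frame(
    frame: Frame,
    topology: Topology,
    oo_cutoff: float = HB_OO_CUTOFF,
    angle_deviation_max: float = HB_ANGLE_DEVIATION_MAX,
    with_q: bool = False,
) -> WaterOrderFrame:
    """zeta (and optionally q) for every water of a frame."""
    oo = oo_distance_matrix(frame, topology)
    adj = hbond_adjacency(frame, topology, oo_cutoff, angle_deviation_max, oo=oo)
    n = len(oo)
    if n < 2:
        raise InsufficientNeighborsError("zeta requires at least 2 waters")

    n_hb = adj.sum(axis=1)
    oo_b = np.where(adj, oo, -np.inf)
    r_hb = oo_b.max(axis=1)
    nonb = ~adj
    np.fill_diagonal(nonb, False)
    oo_n = np.where(nonb, oo, np.inf)
    r_nhb = oo_n.min(axis=1)

    defined = (n_hb >= 1) & np.isfinite(r_nhb)
    zeta = np.full(n, np.nan)
    zeta[defined] = r_nhb[defined] - r_hb[defined]
    r_hb = np.where(n_hb >= 1, r_hb, np.nan)
    r_nhb = np.where(np.isfinite(r_nhb), r_nhb, np.nan)

    q = tetrahedral_q_frame(frame, topology, oo=oo) if with_q else None
    _, _, waters = _water_coords(frame, topology)
    return WaterOrderFrame(waters, zeta, r_nhb, r_hb, n_hb, q)


def zeta(
    water: int,
    frame: Frame,
    topology: Topology,
    **kwargs,
) -> float:
    """zeta of a single water residue; NaN when undefined."""
    rec = zeta_frame(frame, topology, **kwargs)
    (pos,) = np.nonzero(rec.waters == water)
    if len(pos) != 1:
        raise ConfigurationError(f"residue {water} is not a water")
    return float(rec.zeta[pos[0]])


def tetrahedral_q_frame(
    frame: Frame,
    topology: Topology,
    n_neighbors: int = Q_NEIGHBOR_COUNT,
    oo: np.ndarray | None = None,
) -> np.ndarray:
    """Tetrahedral order q for every water, from its 4 nearest water oxygens."""
    o, _, _ = _water_coords(frame, topology)
    n = len(o)
    if n - 1 < n_neighbors:
        raise InsufficientNeighborsError(
            f"q requires {n_neighbors} other waters, found {n - 1}"
        )
    if oo is None:
        oo = oo_distance_matrix(frame, topology)
    nbr = np.argpartition(oo, n_neighbors - 1, axis=1)[:, :n_neighbors]
    # Unit vectors from each central oxygen to its neighbors (min-image).
    vec = minimum_image_displacement(o[nbr] - o[:, None, :], frame.box)
    vec /= np.linalg.norm(vec, axis=2, keepdims=True)
    cos = np.einsum("nik,njk->nij", vec, vec)
    iu, ju = np.triu_indices(n_neighbors, k=1)
    pair_cos = cos[:, iu, ju]  # (n, 6)
    return 1.0 - 3.0 / 8.0 * np.sum((pair_cos + 1.0 / 3.0) ** 2, axis=1)


def tetrahedral_q(
    water: int,
    frame: Frame,
    topology: Topology,
    n_neighbors: int = Q_NEIGHBOR_COUNT,
) -> float:
    q = tetrahedral_q_frame(frame, topology, n_neighbors)
    _, _, waters = _water_coords(frame, topology)
    (pos,) = np.nonzero(waters == water)
    if len(pos) != 1:
        raise ConfigurationError(f"residue {water} is not a water")
    return float(q[pos[0]])


@dataclass
class ResidueZetaResult:
    """Per-residue zeta series plus bookkeeping counts for the run log."""

    series: dict[int, GappedSeries]
    n_undefined_records: int = 0
    n_frames_without_contact: dict[int, int] = field(default_factory=dict)


def residue_zeta_series(
    fs: FrameSet,
    assignments: list[ShellAssignment],
    oo_cutoff: float = HB_OO_CUTOFF,
    angle_deviation_max: float = HB_ANGLE_DEVIATION_MAX,
) -> ResidueZetaResult:
    """Average zeta over each residue's contact waters, frame by frame.

    The entry for a residue in a frame is the mean of the *defined* zeta
    values of its contact waters; it is NaN when the residue has no contact
    water with defined zeta in that frame.
    """
    if len(assignments) != fs.n_frames:
        raise ConfigurationError("need one shell assignment per frame")
    topo = fs.topology
    prot = topo.protein_residues
    res_pos = {int(r): k for k, r in enumerate(prot)}
    values = np.full((fs.n_frames, len(prot)), np.nan)
    n_undef = 0
    water_pos = {int(w): k for k, w in enumerate(topo.water_residues)}

    for i in range(fs.n_frames):
        rec = zeta_frame(fs.frame(i), topo, oo_cutoff, angle_deviation_max)
        n_undef += rec.n_undefined
        sums = np.zeros(len(prot))
        counts = np.zeros(len(prot), dtype=int)
        for w, r in assignments[i].contact_map.items():
            z = rec.zeta[water_pos[w]]
            if np.isfinite(z) and r in res_pos:
                sums[res_pos[r]] += z
                counts[res_pos[r]] += 1
        has = counts > 0
        values[i, has] = sums[has] / counts[has]

    dt = fs.dt if fs.n_frames > 1 else 1.0
    series = {
        int(r): GappedSeries(int(r), values[:, k], dt, "zeta")
        for k, r in enumerate(prot)
    }
    no_contact = {
        int(r): int(np.isnan(values[:, k]).sum()) for k, r in enumerate(prot)
    }
    return ResidueZetaResult(series, n_undef, no_contact)


def bulk_reference(
    fs: FrameSet,
    mode: str = "pure_system",
    assignments: list[ShellAssignment] | None = None,
    with_q: bool = True,
) -> tuple[float, float]:
    """Mean zeta (and mean q) of bulk water.

    ``mode="pure_system"`` averages over every water of a protein-free
    system; ``mode="non_shell"`` averages over the non-shell waters of a
    protein system (requires per-frame shell assignments).
    """
    topo = fs.topology
    if mode == "pure_system":
        if len(topo.protein_residues) > 0:
            raise ConfigurationError(
                "pure_system bulk reference requires a protein-free system"
            )
    elif mode == "non_shell":
        if assignments is None or len(assignments) != fs.n_frames:
            raise ConfigurationError(
                "non_shell bulk reference requires per-frame shell assignments"
            )
    else:
        raise ConfigurationError(f"unknown bulk reference mode {mode!r}")

    water_pos = {int(w): k for k, w in enumerate(topo.water_residues)}
    z_all, q_all = [], []
    for i in range(fs.n_frames):
        rec = zeta_frame(fs.frame(i), topo, with_q=with_q)
        if mode == "non_shell":
            sel = np.asarray(
                [water_pos[w] for w in sorted(assignments[i].bulk_waters)],
                dtype=np.intp,
            )
        else:
            sel = np.arange(len(rec.zeta))
        z = rec.zeta[sel]
        z_all.append(z[np.isfinite(z)])
        if with_q and rec.q is not None:
            q_all.append(rec.q[sel])
    z_flat = np.concatenate(z_all) if z_all else np.empty(0)
    if z_flat.size == 0:
        raise EmptyTrajectoryError("bulk selection contains no defined zeta")
    mean_q = float(np.mean(np.concatenate(q_all))) if q_all else np.nan
    return float(z_flat.mean()), mean_q
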