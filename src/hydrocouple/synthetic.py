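"""Synthetic systems with known ground truth for every pipeline stage.

Three generators cover the pipeline's inputs without running any MD:

* :func:`gen_water_box` - a single-frame water configuration, either a
  diamond-cubic (ice-like) oxygen lattice whose interior waters have a
  perfect tetrahedral environment (q = 1), or a random gas-like packing.
  Gaussian positional noise tunes the degree of disorder continuously.
* :func:`gen_ou_series` - a stationary Ornstein-Uhlenbeck series with
  exactly exponential autocorrelation exp(-tau/tau0), optionally
  interrupted by gaps; OU is chosen because the relaxation estimator's
  contract is defined on the ACF, giving the 0.9*tau0 closed form as an
  oracle.
* :func:`gen_toy_system` - a pseudo-protein ring of two-carbon residues
  with tethered water clusters in which the local hydrogen-bond geometry
  encodes a per-residue order-parameter series with known mean and
  relaxation time, and residue positions follow OU displacements with
  class-dependent amplitude and timescale.  Residue flexibility is
  negatively coupled to hydration-water order with a tunable strength, so
  the end-to-end pipeline has a planted sign structure to recover.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GenerationError
from .series import GappedSeries
from .trajectory import FrameSet, Topology

OH_BOND = 0.9572  # A, rigid water O-H length
HOH_ANGLE = 104.52  # degrees
_D_NN = 2.75  # A, nearest-neighbor O-O spacing of the ice-like lattice


# ---------------------------------------------------------------------------
# Topology helpers
# ---------------------------------------------------------------------------

def _water_topology(n_waters: int) -> Topology:
    names, elems, residx = [], [], []
    for w in range(n_waters):
        names += ["OW", "HW1", "HW2"]
        elems += ["O", "H", "H"]
        residx += [w, w, w]
    return Topology(
        atom_names=np.asarray(names, dtype=object),
        atom_elements=np.asarray(elems, dtype=object),
        atom_resindices=np.asarray(residx),
        residue_names=np.asarray(["SOL"] * n_waters, dtype=object),
    )


def _single_frame(topology, coords, box) -> FrameSet:
    return FrameSet(
        topology,
        coords[None, :, :],
        np.asarray(box, dtype=float)[None, :],
        np.asarray([0.0]),
    )


# ---------------------------------------------------------------------------
# Water boxes
# ---------------------------------------------------------------------------

_FCC = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
# Hydrogen directions obeying ice rules on the diamond lattice: sublattice 0
# donates along (1,1,1) and (1,-1,-1); sublattice 1 along (1,-1,1) and
# (1,1,-1).  Every nearest-neighbor bond then has exactly one donor, so
# each water donates two and accepts two hydrogen bonds.
_H_DIRS_0 = np.array([[1, 1, 1], [1, -1, -1]], dtype=float) / np.sqrt(3.0)
_H_DIRS_1 = np.array([[1, -1, 1], [1, 1, -1]], dtype=float) / np.sqrt(3.0)


def gen_water_box(
    kind: str,
    n_waters: int,
    box: float | None = None,
    perturbation: float = 0.0,
    seed: int = 0,
) -> FrameSet:
    """One-frame water configuration on an ice-like lattice or at random.

    ``lattice`` places oxygens on a diamond-cubic lattice (every interior
    water sees four tetrahedral neighbors) with hydrogens pointing along
    two of the four bond directions, then rigidly displaces each molecule
    by Gaussian noise of standard deviation ``perturbation`` (A).
    ``random`` packs molecules uniformly with random orientations and a
    minimum O-O separation of 2.4 A.
    """
    if n_waters < 5:
        raise GenerationError("need at least 5 waters")
    rng = np.random.default_rng(seed)

    if kind == "lattice":
        cells = max(1, int(np.ceil((n_waters / 8.0) ** (1.0 / 3.0))))
        a = (box / cells) if box is not None else 4.0 * _D_NN / np.sqrt(3.0)
        edge = cells * a
        d_nn = a * np.sqrt(3.0) / 4.0
        o_pos, sublat = [], []
        for cx in range(cells):
            for cy in range(cells):
                for cz in range(cells):
                    for f in _FCC:
                        base = (np.array([cx, cy, cz]) + f) * a
                        o_pos.append(base)
                        sublat.append(0)
                        o_pos.append(base + 0.25 * a)
                        sublat.append(1)
        o_pos = np.asarray(o_pos)[:n_waters]
        sublat = np.asarray(sublat)[:n_waters]
        h_dirs = np.where(
            sublat[:, None, None] == 0, _H_DIRS_0, _H_DIRS_1
        )
        noise = rng.normal(0.0, perturbation, (n_waters, 3))
        o = o_pos + noise
        h = o[:, None, :] + OH_BOND * h_dirs
        _ = d_nn  # lattice spacing retained for clarity
    elif kind == "random":
        edge = float(box) if box is not None else max(
            12.0, (n_waters * 30.0) ** (1.0 / 3.0)
        )
        min_sep = 2.4
        o = np.empty((n_waters, 3))
        placed = 0
        attempts = 0
        while placed < n_waters:
            attempts += 1
            if attempts > 2000 * n_waters:
                raise GenerationError(
                    f"could not pack {n_waters} waters into a {edge} A box"
                )
            cand = rng.uniform(0.0, edge, 3)
            if placed:
                d = o[:placed] - cand
                d -= edge * np.round(d / edge)
                if np.min(np.einsum("ij,ij->i", d, d)) < min_sep**2:
                    continue
            o[placed] = cand
            placed += 1
        half = np.deg2rad(HOH_ANGLE) / 2.0
        template = OH_BOND * np.array(
            [
                [np.sin(half), 0.0, np.cos(half)],
                [-np.sin(half), 0.0, np.cos(half)],
            ]
        )
        h = np.empty((n_waters, 2, 3))
        for i in range(n_waters):
            rot = _random_rotation(rng)
            h[i] = o[i] + template @ rot.T
    else:
        raise GenerationError(f"unknown water box kind {kind!r}")

    coords = np.empty((n_waters * 3, 3))
    coords[0::3] = o
    coords[1::3] = h[:, 0]
    coords[2::3] = h[:, 1]
    coords %= edge
    return _single_frame(_water_topology(n_waters), coords,
                         [edge, edge, edge])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion construction)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck series
# ---------------------------------------------------------------------------

def _ou_path(
    rng: np.random.Generator,
    tau0: float,
    sigma: float,
    dt: float,
    n: int,
    mean: float = 0.0,
) -> np.ndarray:
    """Exact-discretization stationary OU path with ACF exp(-tau/tau0)."""
    phi = np.exp(-dt / tau0)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    innov = rng.normal(0.0, 1.0, n - 1) * sigma * np.sqrt(1.0 - phi * phi)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i - 1]
    return x + mean


def gen_ou_series(
    tau0: float,
    sigma: float,
    dt: float,
    n: int,
    gap_fraction: float = 0.0,
    mean_gap_len: float = 5.0,
    seed: int = 0,
    residue: int = 0,
) -> tuple[GappedSeries, dict]:
    """OU series with known decay time, optionally interrupted by gaps.

    Gap runs have geometric length with the given mean; defined runs are
    sized so the expected undefined fraction equals ``gap_fraction``.
    Returns the series and a metadata dict carrying the ground truth.
    """
    if tau0 <= 0 or dt <= 0:
        raise GenerationError("tau0 and dt must be positive")
    if not 0.0 <= gap_fraction < 1.0:
        raise GenerationError("gap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    values = _ou_path(rng, tau0, sigma, dt, n)
    if gap_fraction > 0.0:
        mean_def = mean_gap_len * (1.0 - gap_fraction) / gap_fraction
        mask = np.zeros(n, dtype=bool)
        pos = 0
        defined = True
        while pos < n:
            mean_run = mean_def if defined else mean_gap_len
            run = int(rng.geometric(min(1.0, 1.0 / mean_run)))
            if defined:
                mask[pos: pos + run] = True
            pos += run
            defined = not defined
        values = np.where(mask, values, np.nan)
    meta = {
        "tau0": tau0,
        "sigma": sigma,
        "dt": dt,
        "n": n,
        "gap_fraction": gap_fraction,
        "seed": seed,
    }
    return GappedSeries(residue, values, dt, "zeta"), meta


# ---------------------------------------------------------------------------
# Toy protein-water system
# ---------------------------------------------------------------------------

#: Per-class stationary displacement amplitude (A per coordinate).
DEFAULT_AMPLITUDES = {"non-polar": 0.25, "polar": 0.45, "charged": 0.7}
#: Per-class hydration-order relaxation time (ps).
DEFAULT_TAU_SCALE = {"non-polar": 0.3, "polar": 0.45, "charged": 0.7}
#: Residue relaxation time as a multiple of the water order relaxation time.
RMSD_TAU_FACTOR = 12.0
#: Count of static shielding carbons per class (controls solvent exposure).
_BLOCKERS = {"non-polar": 4, "polar": 2, "charged": 0}
_CLASS_RESNAME = {"non-polar": "LEU", "polar": "SER", "charged": "LYS"}

_ZETA_BASE = 0.95  # A, planted order-parameter mean at zero coupling
_ZETA_COUPLING = 0.9  # A of zeta lost per A of residue amplitude
_ZETA_MIN = -0.35  # keeps the encoded r_nhb above the O-O contact limit
_R_HB = 2.8  # A, encoded bonded-partner distance
_SPACING = 16.0  # A, arc spacing between residues on the ring


@dataclass
class ToySystem:
    """A generated toy system plus its ground-truth table."""

    frames: FrameSet
    ground_truth: pd.DataFrame


def gen_toy_system(
    n_residues: int = 60,
    waters_per_residue: int = 3,
    coupling_strength: float = 1.0,
    tau_scale_map: dict[str, float] | None = None,
    amplitude_map: dict[str, float] | None = None,
    n_frames: int = 2000,
    dt: float = 0.1,
    seed: int = 0,
) -> ToySystem:
    """Pseudo-protein ring with per-residue water clusters and planted signs.

    Each residue contributes two carbon beads (CA, CB) on a large ring,
    plus a three-water cluster tethered outside it: a central water, one
    hydrogen-bonded partner at a fixed 2.8 A, and one non-bonded water
    whose distance encodes the instantaneous order parameter
    zeta(t) = r_nhb(t) - 2.8.  zeta(t) follows an OU process whose mean
    decreases with the residue's displacement amplitude in proportion to
    ``coupling_strength``, and whose relaxation time is class-dependent;
    residue displacements are OU with a proportionally longer timescale.
    Rigid residues are shielded by static carbon scaffolds (glycine
    residues, excluded from class statistics) so solvent exposure rises
    with flexibility.
    """
    if n_residues < 8:
        raise GenerationError("need at least 8 residues to populate classes")
    if waters_per_residue < 3:
        raise GenerationError("need at least 3 waters per residue")
    if not 0.0 <= coupling_strength <= 1.0:
        raise GenerationError("coupling_strength must lie in [0, 1]")
    taus = dict(DEFAULT_TAU_SCALE if tau_scale_map is None else tau_scale_map)
    amps = dict(DEFAULT_AMPLITUDES if amplitude_map is None else amplitude_map)
    rng = np.random.default_rng(seed)

    classes = [("non-polar", "polar", "charged")[i % 3]
               for i in range(n_residues)]
    n_extra = waters_per_residue - 3
    ring_r = n_residues * _SPACING / (2.0 * np.pi)
    edge = 2.0 * (ring_r + 30.0 + 3.0 * n_extra)
    center = np.full(3, edge / 2.0)

    # Per-residue ground truth.
    amp = np.array([amps[c] * rng.uniform(0.8, 1.2) for c in classes])
    tau_z = np.array([taus[c] * rng.uniform(0.9, 1.1) for c in classes])
    tau_r = RMSD_TAU_FACTOR * tau_z
    mu = _ZETA_BASE - coupling_strength * _ZETA_COUPLING * amp
    sigma_z = np.clip(0.05 + 0.2 * (1.0 - amp / 0.9), 0.03, None)

    # --- static geometry -------------------------------------------------
    atom_names: list[str] = []
    atom_elems: list[str] = []
    atom_res: list[int] = []
    res_names: list[str] = []
    base: list[np.ndarray] = []
    owner: list[int] = []  # moving-group residue, -1 = static
    wn_atom_rows: list[int] = []  # atoms carrying the zeta-encoding offset
    wn_res_of_row: list[int] = []
    t_hat_store = np.empty((n_residues, 3))

    def add_atom(name, elem, res, pos, own):
        atom_names.append(name)
        atom_elems.append(elem)
        atom_res.append(res)
        base.append(np.asarray(pos, dtype=float))
        owner.append(own)

    next_res = 0
    half = np.deg2rad(HOH_ANGLE) / 2.0
    protein_entries = []  # deferred so protein residues precede waters

    for i, cls in enumerate(classes):
        phi = 2.0 * np.pi * i / n_residues
        r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
        t_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        t_hat_store[i] = t_hat
        ca = center + ring_r * r_hat
        cb = ca + 1.5 * r_hat
        blockers = [
            ca - 3.4 * r_hat,
            ca - 2.4 * r_hat + 2.4 * t_hat,
            ca - 2.4 * r_hat - 2.4 * t_hat,
            ca - 2.4 * r_hat + 2.4 * z_hat,
        ][: _BLOCKERS[cls]]
        w0 = cb + 3.4 * r_hat
        hb_dir1 = np.cos(half) * r_hat + np.sin(half) * z_hat
        hb_dir2 = np.cos(half) * r_hat - np.sin(half) * z_hat
        ang = np.deg2rad(HOH_ANGLE)
        w0_h2_dir = np.cos(ang) * t_hat + np.sin(ang) * z_hat
        protein_entries.append(
            (i, cls, ca, cb, blockers, w0, t_hat, hb_dir1, hb_dir2, w0_h2_dir)
        )

    # Protein residues first: mains 0..n-1, then glycine scaffolds.
    for i, cls, ca, cb, blockers, *_ in protein_entries:
        res_names.append(_CLASS_RESNAME[cls])
        add_atom("CA", "C", next_res, ca, i)
        add_atom("CB", "C", next_res, cb, i)
        next_res += 1
    for i, cls, ca, cb, blockers, *_ in protein_entries:
        if blockers:
            res_names.append("GLY")
            for k, b in enumerate(blockers):
                add_atom(f"C{k + 1}", "C", next_res, b, -1)
            next_res += 1
    # Water clusters.
    for entry in protein_entries:
        i, cls, ca, cb, blockers, w0, t_hat, d1, d2, w0h2 = entry
        # central water W0: donates along +t toward its partner
        res_names.append("SOL")
        add_atom("OW", "O", next_res, w0, i)
        add_atom("HW1", "H", next_res, w0 + OH_BOND * t_hat, i)
        add_atom("HW2", "H", next_res, w0 + OH_BOND * w0h2, i)
        next_res += 1
        # bonded partner Wb at the encoded r_hb
        wb = w0 + _R_HB * t_hat
        res_names.append("SOL")
        add_atom("OW", "O", next_res, wb, i)
        add_atom("HW1", "H", next_res, wb + OH_BOND * d1, i)
        add_atom("HW2", "H", next_res, wb + OH_BOND * d2, i)
        next_res += 1
        # non-bonded water Wn; its tangential retreat is set per frame
        res_names.append("SOL")
        row0 = len(base)
        add_atom("OW", "O", next_res, w0, i)
        add_atom("HW1", "H", next_res, w0 + OH_BOND * d1, i)
        add_atom("HW2", "H", next_res, w0 + OH_BOND * d2, i)
        wn_atom_rows += [row0, row0 + 1, row0 + 2]
        wn_res_of_row += [i, i, i]
        next_res += 1
        # optional distant spectator waters (outside the shell)
        for j in range(n_extra):
            pos = cb + (12.0 + 3.0 * j) * (cb - center) / np.linalg.norm(
                cb - center
            )
            res_names.append("SOL")
            add_atom("OW", "O", next_res, pos, -1)
            add_atom("HW1", "H", next_res, pos + OH_BOND * d1, -1)
            add_atom("HW2", "H", next_res, pos + OH_BOND * d2, -1)
            next_res += 1

    topology = Topology(
        atom_names=np.asarray(atom_names, dtype=object),
        atom_elements=np.asarray(atom_elems, dtype=object),
        atom_resindices=np.asarray(atom_res),
        residue_names=np.asarray(res_names, dtype=object),
    )
    base_arr = np.asarray(base)
    owner_arr = np.asarray(owner)

    # --- dynamics ---------------------------------------------------------
    zeta_t = np.empty((n_frames, n_residues))
    disp = np.zeros((n_frames, n_residues + 1, 3))  # slot -1 stays zero
    for i in range(n_residues):
        zeta_t[:, i] = np.maximum(
            _ou_path(rng, tau_z[i], sigma_z[i], dt, n_frames, mean=mu[i]),
            _ZETA_MIN,
        )
        for k in range(3):
            disp[:, i, k] = _ou_path(rng, tau_r[i], amp[i], dt, n_frames)

    coords = base_arr[None, :, :] + disp[:, owner_arr, :]
    wn_rows = np.asarray(wn_atom_rows)
    wn_res = np.asarray(wn_res_of_row)
    retreat = (_R_HB + zeta_t[:, wn_res])[:, :, None] * t_hat_store[wn_res]
    coords[:, wn_rows, :] -= retreat

    frames = FrameSet(
        topology,
        coords,
        np.full((n_frames, 3), edge),
        dt * np.arange(n_frames, dtype=float),
    )
    truth = pd.DataFrame(
        {
            "residue": np.arange(n_residues),
            "name": [_CLASS_RESNAME[c] for c in classes],
            "class": classes,
            "amplitude": amp,
            "tau_zeta_true": tau_z,
            "tau_rmsd_true": tau_r,
            "sigma_zeta_true": sigma_z,
            "zeta_mean_true": mu,
            "contact_zeta_mean_true": mu + _R_HB / 2.0,
            "coupling_strength": coupling_strength,
        }
    ).set_index("residue")
    return ToySystem(frames, truth)
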