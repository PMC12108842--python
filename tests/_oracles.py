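"""Independent brute-force oracles and fixture builders for the test suite.

Everything here is deliberately written as plain Python loops (or textbook
closed forms) so that it shares no code path with the vectorized package
implementation it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from hydrocouple.trajectory import Frame, FrameSet, Topology

SHIFTS = [np.array(s, dtype=float) for s in product((-1, 0, 1), repeat=3)]


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def min_image_dist_scan(p, q, box):
    """Minimum distance over an explicit scan of the 27 neighbor images."""
    p, q, box = map(np.asarray, (p, q, box))
    return min(np.linalg.norm(p - (q + s * box)) for s in SHIFTS)


def wrap_scan(d, box):
    """Minimum-norm image of a displacement vector, by exhaustive scan."""
    d, box = np.asarray(d, float), np.asarray(box, float)
    cands = [d + s * box for s in SHIFTS]
    return cands[int(np.argmin([np.linalg.norm(c) for c in cands]))]


# ---------------------------------------------------------------------------
# System builders
# ---------------------------------------------------------------------------

def water_system(o_pos, h_pos, box):
    """(Topology, Frame) for explicit water O/H positions.

    o_pos: (n, 3); h_pos: (n, 2, 3); box: 3 edges or scalar.
    """
    o_pos = np.asarray(o_pos, float)
    h_pos = np.asarray(h_pos, float)
    n = len(o_pos)
    names, elems, residx = [], [], []
    for w in range(n):
        names += ["OW", "HW1", "HW2"]
        elems += ["O", "H", "H"]
        residx += [w, w, w]
    top = Topology(
        np.array(names, dtype=object),
        np.array(elems, dtype=object),
        np.array(residx),
        np.array(["SOL"] * n, dtype=object),
    )
    coords = np.empty((3 * n, 3))
    coords[0::3] = o_pos
    coords[1::3] = h_pos[:, 0]
    coords[2::3] = h_pos[:, 1]
    box = np.broadcast_to(np.asarray(box, float), (3,)).copy()
    return top, Frame(coords, box)


def mixed_system(protein_spec, o_pos, h_pos, box):
    """(Topology, Frame) with protein residues plus waters.

    protein_spec: list of (resname, [(atom_name, element, xyz), ...]).
    """
    names, elems, residx, resnames, coords = [], [], [], [], []
    res = 0
    for resname, atoms in protein_spec:
        resnames.append(resname)
        for nm, el, xyz in atoms:
            names.append(nm)
            elems.append(el)
            residx.append(res)
            coords.append(np.asarray(xyz, float))
        res += 1
    o_pos = np.asarray(o_pos, float)
    h_pos = np.asarray(h_pos, float)
    for w in range(len(o_pos)):
        resnames.append("SOL")
        for nm, el, xyz in (
            ("OW", "O", o_pos[w]),
            ("HW1", "H", h_pos[w, 0]),
            ("HW2", "H", h_pos[w, 1]),
        ):
            names.append(nm)
            elems.append(el)
            residx.append(res)
            coords.append(np.asarray(xyz, float))
        res += 1
    top = Topology(
        np.array(names, dtype=object),
        np.array(elems, dtype=object),
        np.array(residx),
        np.array(resnames, dtype=object),
    )
    box = np.broadcast_to(np.asarray(box, float), (3,)).copy()
    return top, Frame(np.asarray(coords), box)


def random_dense_waters(n, box, seed, min_sep=2.4):
    """Random water positions with random orientations (rejection packing)."""
    rng = np.random.default_rng(seed)
    o = []
    while len(o) < n:
        cand = rng.uniform(0, box, 3)
        if all(min_image_dist_scan(cand, p, [box] * 3) >= min_sep for p in o):
            o.append(cand)
    o = np.asarray(o)
    h = np.empty((n, 2, 3))
    half = np.deg2rad(104.52) / 2
    template = 0.9572 * np.array(
        [[np.sin(half), 0, np.cos(half)], [-np.sin(half), 0, np.cos(half)]]
    )
    for i in range(n):
        a = rng.normal(size=(3, 3))
        qm, _ = np.linalg.qr(a)
        if np.linalg.det(qm) < 0:
            qm[:, 0] *= -1
        h[i] = o[i] + template @ qm.T
    return o, h


# ---------------------------------------------------------------------------
# Hydrogen bonds, zeta, q (pure-python re-implementations)
# ---------------------------------------------------------------------------

def hbond_oracle(i, j, o, h, box, oo_cutoff=3.5, max_dev=40.0):
    if min_image_dist_scan(o[i], o[j], box) >= oo_cutoff:
        return False
    for don, acc in ((i, j), (j, i)):
        for k in (0, 1):
            a = wrap_scan(o[don] - h[don, k], box)
            b = wrap_scan(o[acc] - h[don, k], box)
            cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            if 180.0 - ang <= max_dev:
                return True
    return False


def zeta_oracle(o, h, box):
    """Per-water zeta by exhaustive pair scanning; NaN where undefined."""
    n = len(o)
    out = np.full(n, np.nan)
    for i in range(n):
        bonded, nonbonded = [], []
        for j in range(n):
            if j == i:
                continue
            d = min_image_dist_scan(o[i], o[j], box)
            if hbond_oracle(i, j, o, h, box):
                bonded.append(d)
            else:
                nonbonded.append(d)
        if bonded and nonbonded:
            out[i] = min(nonbonded) - max(bonded)
    return out


def q_oracle(o, box, n_neighbors=4):
    n = len(o)
    out = np.empty(n)
    for i in range(n):
        dists = []
        for j in range(n):
            if j != i:
                dists.append((min_image_dist_scan(o[i], o[j], box), j))
        dists.sort()
        vecs = []
        for _, j in dists[:n_neighbors]:
            v = wrap_scan(o[j] - o[i], box)
            vecs.append(v / np.linalg.norm(v))
        total = 0.0
        for a in range(n_neighbors):
            for b in range(a + 1, n_neighbors):
                total += (np.dot(vecs[a], vecs[b]) + 1.0 / 3.0) ** 2
        out[i] = 1.0 - 3.0 / 8.0 * total
    return out


def shell_oracle(frame, top, cutoff=5.0):
    carbons = [
        a
        for a in range(top.n_atoms)
        if top.atom_elements[a] == "C"
        and top.is_protein[top.atom_resindices[a]]
    ]
    result = set()
    for w, sites in top.water_sites.items():
        for a in (sites.oxygen, *sites.hydrogens):
            if any(
                min_image_dist_scan(
                    frame.coordinates[a], frame.coordinates[c], frame.box
                )
                < cutoff
                for c in carbons
            ):
                result.add(w)
                break
    return result


def contact_oracle(frame, top, shell):
    out = {}
    for w in sorted(shell):
        o = frame.coordinates[top.water_sites[w].oxygen]
        best, best_res = np.inf, None
        for r in top.protein_residues:
            for a in top.residue_atoms[int(r)]:
                if not top.heavy_atom_mask[a]:
                    continue
                d = min_image_dist_scan(o, frame.coordinates[a], frame.box)
                if d < best:
                    best, best_res = d, int(r)
        out[w] = best_res
    return out


# ---------------------------------------------------------------------------
# Superposition (Horn quaternion method) and ranks
# ---------------------------------------------------------------------------

def quaternion_superpose(mobile, reference):
    """Rigidly fit ``mobile`` onto ``reference`` via Horn's quaternion method.

    Returns the transformed mobile coordinates.
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    m = mob_c.T @ ref_c
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, np.argmax(vals)]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return mob_c @ rot.T + reference.mean(axis=0)


def midranks(x):
    """Average ranks with ties, 1-based, by explicit counting."""
    x = np.asarray(x)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        out[i] = less + (equal + 1) / 2.0
    return out


# ---------------------------------------------------------------------------
# Geometry helpers for exact H-bond angle constructions
# ---------------------------------------------------------------------------

def h_between(o_d, o_a, angle_deg):
    """Hydrogen position giving an exact O-H...O angle on the bisector."""
    o_d, o_a = np.asarray(o_d, float), np.asarray(o_a, float)
    d = np.linalg.norm(o_a - o_d)
    axis = (o_a - o_d) / d
    perp = np.array([-axis[1], axis[0], 0.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    cos_t = np.cos(np.deg2rad(angle_deg))
    if angle_deg == 180.0:
        y = 0.0
    else:
        y = (d / 2.0) * np.sqrt((1 + cos_t) / (1 - cos_t))
    return o_d + axis * d / 2.0 + perp * y


def h_away(o_d, o_a, length=0.9572):
    """Hydrogen on the far side of the donor (O-H...O angle ~ 0)."""
    o_d, o_a = np.asarray(o_d, float), np.asarray(o_a, float)
    axis = (o_a - o_d) / np.linalg.norm(o_a - o_d)
    return o_d - length * axis
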