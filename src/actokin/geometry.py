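"""Geometry metrics on coordinate models.

These are the structural readouts used to characterize conformational
states and allosteric pathways in motor domains: least-squares rigid
superposition (Cα RMSD), the three-point relay-helix angle, backbone φ/ψ
dihedrals, hydrogen-bond populations over trajectory frames, per-residue
contact profiles, interdomain rotation angles, and an inscribed-sphere
estimate of binding-pocket volume.

All metrics are invariant under global rigid motion of their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .pdbio import CoordinateTrajectory, StructureModel

__all__ = [
    "HBondCriteria",
    "Superposition",
    "superpose",
    "ca_angle",
    "dihedral",
    "backbone_dihedrals",
    "hbond_population",
    "Contact",
    "contact_profile",
    "domain_rotation",
    "pocket_sphere_volume",
]

#: elements that can donate or accept a hydrogen bond (heavy-atom criterion)
_HBOND_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class HBondCriteria:
    """Heavy-atom distance criterion, with an optional D-H...A angle term.

    Crystal structures usually lack hydrogens, so the default is a pure
    donor–acceptor distance cutoff of 3.5 Å.
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float | None = None  # degrees, requires H positions

    def __post_init__(self) -> None:
        if not (2.0 < self.distance_cutoff < 5.0):
            raise ValueError("distance cutoff must be in (2.0, 5.0) Å")


@dataclass(frozen=True)
class Superposition:
    rmsd: float
    rotation: np.ndarray     # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _paired_coords(
    mobile: StructureModel,
    target: StructureModel,
    selection: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    """1:1 atom mapping by (chain, residue number, atom name)."""
    ms = mobile.subset(selection)
    ts = target.subset(selection)
    mkeys = {k: i for i, k in enumerate(ms.atom_keys())}
    tkeys = {k: i for i, k in enumerate(ts.atom_keys())}
    common = [k for k in mkeys if k in tkeys]
    unmatched = sorted(
        {(k[0], int(k[1])) for k in mkeys.keys() ^ tkeys.keys()}
    )
    if unmatched:
        raise ValueError(
            f"selection does not map 1:1; unmatched residues: "
            f"{unmatched[:20]}{'...' if len(unmatched) > 20 else ''}"
        )
    if len(common) < 3:
        raise ValueError(f"need >= 3 mapped atoms, got {len(common)}")
    a = ms.coords[[mkeys[k] for k in common]]
    b = ts.coords[[tkeys[k] for k in common]]
    return a, b


def _fit_rotation(mobile_c: np.ndarray, target_c: np.ndarray) -> Rotation:
    """Optimal proper rotation (Kabsch) for centred coordinate sets."""
    rot, _ = Rotation.align_vectors(target_c, mobile_c)
    return rot


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    selection: str | None = None,
) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Atoms are paired by (chain, residue number, atom name) within the
    selection.  Returns the post-fit RMSD over the selection and the rigid
    transform (always a proper rotation).
    """
    a, b = _paired_coords(mobile, target, selection)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    if np.linalg.matrix_rank(ac, tol=1e-9) < 2:
        raise ValueError("selection atoms are collinear; fit is degenerate")
    rot = _fit_rotation(ac, bc)
    R = rot.as_matrix()
    fitted = ac @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - bc) ** 2, axis=1))))
    translation = cb - ca @ R.T
    return Superposition(rmsd=rmsd, rotation=R, translation=translation,
                         n_atoms=len(a))


def _ca_position(model: StructureModel, resnum: int,
                 chain: str | None) -> np.ndarray:
    m = (model.resnum == resnum) & (model.name == "CA")
    if chain is not None:
        m &= model.chain == chain
    idx = np.nonzero(m)[0]
    if len(idx) == 0:
        raise ValueError(f"no Cα atom for residue {resnum}"
                         f"{' chain ' + chain if chain else ''}")
    return model.coords[idx[0]]


def ca_angle(
    model: StructureModel,
    residues: tuple[int, int, int],
    chain: str | None = None,
) -> float:
    """Planar angle (degrees) at the middle residue's Cα, in [0, 180]."""
    p = [_ca_position(model, r, chain) for r in residues]
    v1 = p[0] - p[1]
    v2 = p[2] - p[1]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Torsion angle in degrees, IUPAC sign convention, range (−180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


_PEPTIDE_BOND_MAX = 2.0  # Å, C(i)–N(i+1) distance above which a break is called


def backbone_dihedrals(
    model: StructureModel, chain: str
) -> list[tuple[int, float | None, float | None]]:
    """Backbone φ/ψ per residue of one chain.

    Terminal residues have undefined φ (first) and ψ (last); dihedrals
    spanning a chain break (peptide C–N distance > 2.0 Å or missing
    backbone atoms) are ``None``.
    """
    m = (model.chain == chain) & ~model.het
    if not m.any():
        raise ValueError(f"no atoms in chain {chain!r}")
    resnums = sorted(dict.fromkeys(model.resnum[m]))
    bb: dict[int, dict[str, np.ndarray]] = {}
    for rn in resnums:
        rm = m & (model.resnum == rn)
        atoms = {}
        for nm in ("N", "CA", "C"):
            am = rm & (model.name == nm)
            if am.any():
                atoms[nm] = model.coords[np.argmax(am)]
        bb[rn] = atoms

    def bonded(rn_prev: int, rn: int) -> bool:
        a, b = bb.get(rn_prev, {}), bb.get(rn, {})
        if "C" not in a or "N" not in b:
            return False
        return float(np.linalg.norm(a["C"] - b["N"])) <= _PEPTIDE_BOND_MAX

    out: list[tuple[int, float | None, float | None]] = []
    for i, rn in enumerate(resnums):
        cur = bb[rn]
        phi = psi = None
        complete = all(k in cur for k in ("N", "CA", "C"))
        if complete and i > 0 and bonded(resnums[i - 1], rn):
            phi = dihedral(bb[resnums[i - 1]]["C"], cur["N"], cur["CA"],
                           cur["C"])
        if complete and i < len(resnums) - 1 and bonded(rn, resnums[i + 1]):
            psi = dihedral(cur["N"], cur["CA"], cur["C"],
                           bb[resnums[i + 1]]["N"])
        out.append((int(rn), phi, psi))
    return out


def hbond_population(
    traj: CoordinateTrajectory,
    donor_sel: str,
    acceptor_sel: str,
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[float, dict[tuple, float]]:
    """Fraction of frames with any donor–acceptor pair inside the cutoff.

    Returns ``(population, per_pair)`` where ``per_pair`` maps
    ((donor chain, resnum, name), (acceptor chain, resnum, name)) to that
    pair's own frame fraction.
    """
    d0 = traj[0].select(donor_sel)
    a0 = traj[0].select(acceptor_sel)
    if not d0.any():
        raise ValueError(f"empty donor selection {donor_sel!r}")
    if not a0.any():
        raise ValueError(f"empty acceptor selection {acceptor_sel!r}")

    dkeys = [k for k, on in zip(traj[0].atom_keys(), d0) if on]
    akeys = [k for k, on in zip(traj[0].atom_keys(), a0) if on]
    any_count = 0
    pair_counts = np.zeros((len(dkeys), len(akeys)), dtype=int)
    for frame in traj.frames:
        dxyz = frame.coords[d0]
        axyz = frame.coords[a0]
        dist = np.linalg.norm(dxyz[:, None, :] - axyz[None, :, :], axis=2)
        hit = dist <= criteria.distance_cutoff
        pair_counts += hit
        if hit.any():
            any_count += 1
    n = len(traj)
    per_pair = {
        (dkeys[i], akeys[j]): pair_counts[i, j] / n
        for i in range(len(dkeys)) for j in range(len(akeys))
        if pair_counts[i, j] > 0
    }
    return any_count / n, per_pair


@dataclass(frozen=True)
class Contact:
    own_atom: tuple          # (chain, resnum, name)
    partner_atom: tuple
    partner_resname: str
    distance: float
    kind: str                # "hbond" | "vdW"


def contact_profile(
    model: StructureModel,
    residue: tuple[str, int],
    cutoff: float = 4.0,
    hbond_cutoff: float = 3.5,
) -> list[Contact]:
    """All inter-residue atom contacts of one residue within ``cutoff`` Å.

    A contact is classed ``hbond`` when both heavy atoms are N or O and lie
    within ``hbond_cutoff``; everything else is ``vdW``.  Sorted by distance.
    """
    chain, resnum = residue
    own = (model.chain == chain) & (model.resnum == resnum)
    if not own.any():
        raise ValueError(f"residue {chain}:{resnum} absent from model")
    other = ~own
    oidx = np.nonzero(own)[0]
    pidx = np.nonzero(other)[0]
    tree = cKDTree(model.coords[other])
    contacts: list[Contact] = []
    for i in oidx:
        for jj in tree.query_ball_point(model.coords[i], cutoff):
            j = pidx[jj]
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            polar = (model.element[i] in _HBOND_ELEMENTS
                     and model.element[j] in _HBOND_ELEMENTS)
            kind = "hbond" if polar and d <= hbond_cutoff else "vdW"
            contacts.append(Contact(
                own_atom=(model.chain[i], int(model.resnum[i]), model.name[i]),
                partner_atom=(model.chain[j], int(model.resnum[j]),
                              model.name[j]),
                partner_resname=str(model.resname[j]),
                distance=d,
                kind=kind,
            ))
    return sorted(contacts, key=lambda c: c.distance)


def domain_rotation(
    frameA: StructureModel,
    frameB: StructureModel,
    core_sel: str,
    domain_sel: str,
) -> float:
    """Rotation angle (degrees) of a domain between two frames.

    Frames are first superposed on the core selection; the optimal rigid fit
    of the domain selection then yields the rotation, reported as the
    axis–angle magnitude in [0, 180].
    """
    sup = superpose(frameB, frameA, core_sel)
    a, b = _paired_coords(frameB, frameA, domain_sel)
    a = sup.apply(a)  # domain of B in A's core frame
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if np.linalg.matrix_rank(bc, tol=1e-9) < 2:
        raise ValueError("domain selection is collinear; rotation undefined")
    rot = _fit_rotation(ac, bc)
    return float(np.degrees(rot.magnitude()))


def pocket_sphere_volume(
    model: StructureModel,
    center_sel: str,
    probe: float = 0.0,
) -> tuple[float, float]:
    """Inscribed-sphere estimate of a pocket volume.

    The sphere is centred on the centroid of ``center_sel``; its radius is
    the distance to the nearest non-selected protein heavy atom minus the
    probe radius, floored at zero.  Returns ``(radius Å, volume Å³)``.
    """
    sel = model.select(center_sel)
    if not sel.any():
        raise ValueError(f"empty center selection {center_sel!r}")
    wall = ~sel & model.heavy() & ~model.het
    if not wall.any():
        raise ValueError("no non-selected protein heavy atoms around center")
    centroid = model.coords[sel].mean(axis=0)
    dmin = float(np.min(np.linalg.norm(model.coords[wall] - centroid, axis=1)))
    radius = max(dmin - probe, 0.0)
    return radius, 4.0 / 3.0 * math.pi * radius**3
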