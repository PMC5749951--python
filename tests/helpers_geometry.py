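"""Shared geometry test helpers: cloud models and the quaternion oracle."""

import numpy as np

from actokin.pdbio import StructureModel


def cloud_model(coords, chain="A", element="C", het=False):
    n = len(coords)
    return StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array([f"C{i}" for i in range(n)], dtype=object),
        resname=np.array(["GLY"] * n, dtype=object),
        resnum=np.arange(1, n + 1),
        chain=np.array([chain] * n, dtype=object),
        altloc=np.array([""] * n, dtype=object),
        coords=np.asarray(coords, float),
        occupancy=np.ones(n),
        bfactor=np.zeros(n),
        element=np.array([element] * n, dtype=object),
        het=np.full(n, het),
    )


def quaternion_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Independent closed-form superposition oracle (Horn's quaternion
    method): the optimal RMSD follows from the largest eigenvalue of the 4x4
    key matrix, with no explicit rotation fit."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    ssd = np.sum(a**2) + np.sum(b**2) - 2.0 * lam
    return float(np.sqrt(max(ssd, 0.0) / len(a)))
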