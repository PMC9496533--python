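"""Least-squares rigid superposition (Kabsch algorithm)."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class Superposition(NamedTuple):
    """Result of a rigid least-squares fit of ``mobile`` onto ``target``."""

    aligned: np.ndarray      # mobile after the fitted transform, (n, 3)
    rotation: np.ndarray     # proper rotation, (3, 3)
    translation: np.ndarray  # aligned = (mobile @ R.T) + t
    rmsd: float


def kabsch(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Superpose ``mobile`` onto ``target`` with a proper rotation.

    Both arrays must be (n, 3) with matching row order.  The returned
    rotation always has determinant +1; a mirror image is therefore fitted
    with nonzero residual rather than an improper transform.

    Raises
    ------
    ValueError
        If the point sets differ in shape, have fewer than 3 points, or are
        degenerate (all points collinear), in which case the rotation about
        the common axis is undetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"point sets must be matching (n, 3) arrays, got {mobile.shape} and {target.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("at least 3 points are required for a rigid superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    # collinearity: second singular value of either centered cloud vanishes
    for cloud, name in ((p, "mobile"), (q, "target")):
        s = np.linalg.svd(cloud, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError(f"{name} points are collinear; rotation is undetermined")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    aligned = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - target) ** 2, axis=1))))
    return Superposition(aligned=aligned, rotation=rot, translation=trans, rmsd=rmsd)
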