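"""Least-squares rigid-body superposition kernels.

All public geometry operations funnel through :func:`kabsch` (single pair,
full transform) or :func:`min_rmsd` (batched, RMSD only).  The batched kernel
uses the singular values of the cross-covariance matrix, so the minimal RMSD
is obtained without constructing rotation matrices; this is what makes
structural-alphabet encoding of long trajectories affordable.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ContractError

__all__ = ["kabsch", "apply_transform", "min_rmsd"]


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation/translation superposing ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (n, 3) arrays
        Matched coordinate sets, n >= 3 and not collinear.

    Returns
    -------
    rotation : (3, 3) proper rotation matrix
    translation : (3,) vector
    rmsd : float
        RMSD after applying ``x @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ContractError("superposition requires matched (n, 3) coordinate sets")
    if mobile.shape[0] < 3:
        raise ContractError("superposition requires at least 3 atoms")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    # collinearity check: centred coordinates must span >= 2 dimensions
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise ContractError("degenerate (collinear) fit set")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cr - rot @ cm
    fitted = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to (..., 3) coordinates."""
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


def min_rmsd(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimal RMSD after optimal superposition, batched.

    ``x`` and ``y`` are (..., n, 3) arrays broadcastable against each other in
    the leading dimensions.  Uses the identity

        n * rmsd^2 = Gx + Gy - 2 * (s1 + s2 + sign(det H) * s3)

    with H the cross-covariance of the centred sets and s_i its singular
    values (reflections excluded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[-2]
    xc = x - x.mean(axis=-2, keepdims=True)
    yc = y - y.mean(axis=-2, keepdims=True)
    gx = np.sum(xc * xc, axis=(-2, -1))
    gy = np.sum(yc * yc, axis=(-2, -1))
    h = np.swapaxes(xc, -2, -1) @ yc
    s = np.linalg.svd(h, compute_uv=False)
    sign = np.sign(np.linalg.det(h))
    sign = np.where(sign == 0, 1.0, sign)
    trace = s[..., 0] + s[..., 1] + sign * s[..., 2]
    sq = np.maximum(gx + gy - 2.0 * trace, 0.0) / n
    return np.sqrt(sq)
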