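"""Superposition-based trajectory descriptors.

RMSD/RMSF, bend angles, principal component analysis of Cα motions and
GROMOS-style conformational clustering.  All fits are unweighted least-squares
(Kabsch) superpositions; coordinates are in Å throughout.

The RMSF/PCA reference is the iteratively refitted average structure: frames
are fit to the running mean until the mean moves by less than ``tol`` (the
reference procedure is a package choice; only the use of an average-structure
reference is fixed by the analysis design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._superpose import apply_transform, kabsch, min_rmsd
from .exceptions import ContractError, SelectionError
from .trajectory_io import CALPHA, CoordinateEnsemble, Selection, select

__all__ = [
    "PCAResult",
    "AngleSeries",
    "superpose",
    "rmsf",
    "rmsd_series",
    "bend_angle",
    "pca",
    "cluster_conformations",
    "average_structure",
]


@dataclass
class PCAResult:
    """Eigen-decomposition of the fitted Cα coordinate covariance.

    eigenvalues are in Å² and sorted non-increasing; ``projections`` holds one
    (frames, modes) array per input ensemble, in Å.
    """

    mean_structure: np.ndarray          # (n_atoms, 3)
    eigenvectors: np.ndarray            # (modes, 3N), orthonormal rows
    eigenvalues: np.ndarray             # (modes,)
    variance_fractions: np.ndarray
    projections: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)


@dataclass
class AngleSeries:
    """Per-frame planar angle (degrees) at the middle residue of a triplet."""

    angles: np.ndarray
    residue_triplet: tuple


def superpose(mobile: np.ndarray, reference: np.ndarray, fit_indices=None):
    """Kabsch fit of one frame onto another.

    Returns ``(rotation, translation, rmsd)`` where the RMSD is evaluated over
    the fit atoms.  ``fit_indices`` restricts the fit to a subset of atoms;
    the transform still applies to the full frame.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is not None:
        return kabsch(mobile[fit_indices], reference[fit_indices])
    return kabsch(mobile, reference)


def _fit_frames(coords: np.ndarray, reference: np.ndarray, fit_idx=None) -> np.ndarray:
    """Superpose every frame of (F, A, 3) onto ``reference``."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        if fit_idx is not None:
            rot, trans, _ = kabsch(coords[f, fit_idx], reference[fit_idx])
        else:
            rot, trans, _ = kabsch(coords[f], reference)
        out[f] = apply_transform(coords[f], rot, trans)
    return out


def average_structure(coords: np.ndarray, fit_idx=None, tol: float = 1e-6,
                      max_iter: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively refitted average structure.

    Frames are fit to the running mean until the mean shifts by < ``tol`` Å
    (max ``max_iter`` iterations).  Returns ``(mean, fitted_coords)``.
    """
    fitted = _fit_frames(coords, coords[0], fit_idx)
    mean = fitted.mean(axis=0)
    for _ in range(max_iter):
        fitted = _fit_frames(coords, mean, fit_idx)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.max(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return mean, fitted


def rmsf(ensemble: CoordinateEnsemble, selection: Selection | None = None,
         fit: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the average structure.

    Each frame is least-squares fit to the iteratively computed average
    structure of the selected atoms; RMSF_i = sqrt(<|r_i - <r_i>|^2>).
    ``fit=False`` skips the superposition (frames already aligned).
    """
    if ensemble.n_frames < 2:
        raise ContractError("RMSF requires at least 2 frames")
    ens = select(ensemble, selection) if selection is not None else ensemble
    if fit:
        mean, fitted = average_structure(ens.coords)
    else:
        fitted = ens.coords
        mean = fitted.mean(axis=0)
    d2 = np.sum((fitted - mean) ** 2, axis=2)  # (F, A)
    return np.sqrt(d2.mean(axis=0))


def rmsd_series(ensemble: CoordinateEnsemble, reference_frame: int = 0,
                fit_selection: Selection | None = None,
                measure_selection: Selection | None = None) -> np.ndarray:
    """Per-frame RMSD from a reference frame after fitting.

    The fit uses ``fit_selection`` atoms (all atoms when None); the RMSD is
    measured over ``measure_selection`` atoms (fit atoms when None).
    """
    coords = ensemble.coords
    meta = ensemble.atom_meta
    fit_idx = np.flatnonzero(fit_selection.mask(meta)) if fit_selection is not None else np.arange(ensemble.n_atoms)
    meas_idx = np.flatnonzero(measure_selection.mask(meta)) if measure_selection is not None else fit_idx
    if fit_idx.size == 0 or meas_idx.size == 0:
        raise SelectionError("empty fit or measure selection")
    ref = coords[reference_frame]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        rot, trans, _ = kabsch(coords[f, fit_idx], ref[fit_idx])
        moved = apply_transform(coords[f, meas_idx], rot, trans)
        out[f] = np.sqrt(np.mean(np.sum((moved - ref[meas_idx]) ** 2, axis=1)))
    return out


def bend_angle(ensemble: CoordinateEnsemble, residue_triplet) -> AngleSeries:
    """Planar Cα angle (degrees) at the middle residue of a triplet.

    ``residue_triplet`` holds three distinct residue numbers (optionally
    (chain, residue_number) pairs).
    """
    if len(set(residue_triplet)) != 3:
        raise SelectionError("bend angle requires three distinct residues")
    meta = ensemble.atom_meta
    idx = []
    for item in residue_triplet:
        if isinstance(item, tuple):
            m = (meta["chain_id"] == item[0]) & (meta["residue_number"] == int(item[1])) & (meta["atom_name"] == "CA")
        else:
            m = (meta["residue_number"] == int(item)) & (meta["atom_name"] == "CA")
        where = np.flatnonzero(m.to_numpy())
        if where.size == 0:
            raise SelectionError(f"no Cα atom for residue {item!r}")
        idx.append(int(where[0]))
    a, b, c = (ensemble.coords[:, i, :] for i in idx)
    v1 = a - b
    v2 = c - b
    cosang = np.sum(v1 * v2, axis=1) / (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return AngleSeries(angles=ang, residue_triplet=tuple(residue_triplet))


def pca(ensembles: list[CoordinateEnsemble], selection: Selection | None = CALPHA,
        combine_window_ps: float | None = None, fit: bool = True) -> PCAResult:
    """Principal component analysis of (fitted) coordinates.

    All frames (or, with ``combine_window_ps``, only each ensemble's trailing
    window) enter an unweighted coordinate covariance which is then
    diagonalised.  Projections are returned for every frame of every input
    ensemble.  ``fit=False`` skips superposition (useful when frames are
    already in a common frame of reference).
    """
    if not ensembles:
        raise ContractError("pca requires at least one ensemble")
    sels = [select(e, selection) if selection is not None else e for e in ensembles]
    key = [tuple(zip(s.atom_meta["chain_id"], s.atom_meta["residue_number"], s.atom_meta["atom_name"]))
           for s in sels]
    if any(k != key[0] for k in key[1:]):
        from .exceptions import StructureError

        raise StructureError("selected atom sets differ across ensembles")

    def _window(e: CoordinateEnsemble) -> np.ndarray:
        if combine_window_ps is None:
            return e.coords
        n = int(round(combine_window_ps / e.frame_spacing_ps))
        n = max(1, min(n, e.n_frames))
        return e.coords[e.n_frames - n:]

    cov_frames = np.concatenate([_window(s) for s in sels], axis=0)
    if cov_frames.shape[0] < 2:
        raise ContractError("pca requires at least 2 frames")
    if fit:
        mean, fitted = average_structure(cov_frames)
    else:
        mean = cov_frames.mean(axis=0)
        fitted = cov_frames
    x = (fitted - mean).reshape(fitted.shape[0], -1)
    cov = (x.T @ x) / x.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order].T  # rows = modes
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    projections = []
    for s in sels:
        frames = _fit_frames(s.coords, mean) if fit else s.coords
        projections.append((frames - mean).reshape(s.n_frames, -1) @ evecs.T)
    return PCAResult(mean_structure=mean, eigenvectors=evecs, eigenvalues=evals,
                     variance_fractions=fractions, projections=projections,
                     labels=[s.label for s in sels])


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs minimal RMSD between frames of a (F, A, 3) array."""
    f = coords.shape[0]
    out = np.zeros((f, f))
    for i in range(f):
        if i + 1 < f:
            out[i, i + 1:] = min_rmsd(coords[i][None, :, :], coords[i + 1:])
            out[i + 1:, i] = out[i, i + 1:]
    return out


def cluster_conformations(ensemble: CoordinateEnsemble, cutoff: float):
    """GROMOS clustering on pairwise superposed RMSD.

    Iteratively takes the frame with the most neighbours within ``cutoff``
    (ties: lowest frame index) as a cluster representative, removes the
    cluster, and repeats.  Returns a list of dicts with ``representative``,
    ``members`` (frame indices) and ``population`` (fractions summing to 1).
    """
    if cutoff <= 0:
        raise ContractError("cutoff must be positive")
    if ensemble.n_frames < 1:
        raise ContractError("clustering requires at least one frame")
    d = pairwise_rmsd_matrix(ensemble.coords)
    neighbours = d < cutoff
    np.fill_diagonal(neighbours, True)
    remaining = np.ones(ensemble.n_frames, dtype=bool)
    clusters = []
    n_total = ensemble.n_frames
    while remaining.any():
        counts = (neighbours & remaining).sum(axis=1)
        counts[~remaining] = -1
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbours[rep] & remaining)
        clusters.append({
            "representative": rep,
            "members": members.tolist(),
            "population": members.size / n_total,
        })
        remaining[members] = False
    return clusters
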