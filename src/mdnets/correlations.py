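"""Correlation matrices: normalized mutual information, DCCM, consensus, deltas.

Local correlations between structural-alphabet letter sequences are scored as
normalized mutual information

    nMI(X, Y) = max(0, (I(X; Y) - eps) / H(X, Y))

where I is the plug-in mutual information of the joint letter histogram,
H(X, Y) the joint entropy (nats) and eps the Roulston finite-sampling bias
correction eps = (B_XY - B_X - B_Y + 1) / (2 N) with B the number of occupied
histogram bins.  Joint-entropy normalization keeps nMI in [0, 1] with
nMI(X, X) = 1 for non-constant sequences; the normalization is isolated in
:func:`nmi_from_counts` so an alternative convention can be swapped in.

Statistical significance of nMI values is assessed against a random
background of independently frame-permuted letter columns (destroying
inter-fragment correlation while preserving letter composition), with
Benjamini-Hochberg control over all fragment pairs.

Global correlations are scored as block-averaged dynamical cross-correlation
(DCC) matrices of Cα displacement vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._superpose import apply_transform, kabsch
from .alphabet import SAEncoding
from .exceptions import ContractError
from .trajectory_io import CALPHA, CoordinateEnsemble, Selection, select

__all__ = [
    "LabeledMatrix",
    "mutual_information_matrix",
    "significance_filter",
    "dccm",
    "consensus_matrix",
    "delta_matrix",
    "nmi_from_counts",
]


@dataclass
class LabeledMatrix:
    """Square symmetric matrix over fragments or residues with a kind tag."""

    values: np.ndarray
    labels: list
    kind: str  # nMI | DCCM | contact_freq | delta
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ContractError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ContractError("matrix must be symmetric")
        if self.kind in ("nMI", "contact_freq"):
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ContractError(f"{self.kind} entries must lie in [0, 1]")
        elif self.kind == "DCCM":
            if self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9:
                raise ContractError("DCCM entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "LabeledMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = []
        for v in df.index:
            try:
                labels.append(int(v))
            except (TypeError, ValueError):
                labels.append(str(v))
        return cls(values=df.to_numpy(dtype=float), labels=labels, kind=kind)


# ---------------------------------------------------------------------------
# normalized mutual information


def nmi_from_counts(joint: np.ndarray, bias_correction: bool = True) -> float:
    """nMI from a joint letter-count table (see module docstring)."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    if n <= 0:
        return 0.0
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def _h(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hx, hy = _h(px), _h(py)
    hxy = _h(p.ravel())
    if hxy <= 0:
        return 0.0
    i = hx + hy - hxy
    if bias_correction:
        bxy = int((joint > 0).sum())
        bx = int((px > 0).sum())
        by = int((py > 0).sum())
        i -= (bxy - bx - by + 1) / (2.0 * n)
    # the bias correction can be slightly negative; clamp into [0, 1]
    return min(1.0, max(0.0, i / hxy))


def _joint_counts(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(x.astype(np.int64) * k + y, minlength=k * k).reshape(k, k)


def mutual_information_matrix(encoding: SAEncoding, bias_correction: bool = True) -> LabeledMatrix:
    """Pairwise nMI between all fragment letter sequences.

    The diagonal is 1 for non-constant fragments.  A constant (zero-entropy)
    fragment has no defined correlation: its row/column and diagonal are 0 and
    it is recorded in the provenance.
    """
    if encoding.n_frames < 2:
        raise ContractError("mutual information requires at least 2 frames")
    codes = encoding.codes
    m = encoding.n_fragments
    k = int(codes.max()) + 1
    constant = [j for j in range(m) if np.all(codes[:, j] == codes[0, j])]
    const_set = set(constant)
    values = np.zeros((m, m))
    for i in range(m):
        if i not in const_set:
            values[i, i] = 1.0
        for j in range(i + 1, m):
            if i in const_set or j in const_set:
                continue
            joint = _joint_counts(codes[:, i], codes[:, j], k)
            v = nmi_from_counts(joint, bias_correction=bias_correction)
            values[i, j] = values[j, i] = v
    return LabeledMatrix(
        values=values,
        labels=list(encoding.fragment_ids),
        kind="nMI",
        provenance={
            "source": encoding.label,
            "n_frames": encoding.n_frames,
            "bias_correction": bias_correction,
            "constant_fragments": [encoding.fragment_ids[j] for j in constant],
        },
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        val = p[order[rank]] * m / (rank + 1)
        running = min(running, val)
        adj[order[rank]] = running
    return adj


def significance_filter(matrix: LabeledMatrix, encoding: SAEncoding,
                        n_samples: int = 1000, alpha: float = 0.01,
                        seed: int | np.random.Generator = 0,
                        per_pair: bool = False, null_model: str = "shift"):
    """Zero nMI entries that are not significant against a randomised null.

    The background is built by independently randomising each fragment's
    frame order, which destroys inter-fragment correlation while preserving
    letter composition.  Two null models are available:

    * ``"shift"`` (default): each column is circularly shifted by an
      independent random offset.  This additionally preserves each fragment's
      temporal autocorrelation, which full permutation destroys — letter
      sequences from trajectories are strongly autocorrelated, and a
      permutation null is anti-conservative on them (it understates the MI
      two independent but slowly-switching fragments reach by chance).
    * ``"permute"``: independent full permutations of each column (the
      classical exchangeable-frames null).

    By default the ``n_samples`` background nMI values are pooled across
    randomly chosen fragment pairs (one randomised pair per sample);
    ``per_pair=True`` instead draws ``n_samples`` randomisations for every
    pair (exact but quadratically more expensive).  The per-pair p-value is
    the fraction of background values >= observed; p-values are
    Benjamini-Hochberg adjusted across all pairs and entries with adjusted
    p >= alpha are zeroed.

    Returns ``(filtered_matrix, p_value_matrix)``.
    """
    if n_samples < 100:
        raise ContractError("n_samples must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ContractError("alpha must lie in (0, 1)")
    if matrix.kind != "nMI":
        raise ContractError("significance filtering applies to nMI matrices")
    if null_model not in ("shift", "permute"):
        raise ContractError(f"unknown null model {null_model!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = encoding.codes
    n_frames, m = codes.shape
    k = int(codes.max()) + 1
    bias = bool(matrix.provenance.get("bias_correction", True))
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]

    def _null_value(i, j):
        if null_model == "shift":
            xi = np.roll(codes[:, i], int(rng.integers(1, n_frames)))
            yj = np.roll(codes[:, j], int(rng.integers(1, n_frames)))
        else:
            xi = codes[rng.permutation(n_frames), i]
            yj = codes[rng.permutation(n_frames), j]
        return nmi_from_counts(_joint_counts(xi, yj, k), bias_correction=bias)

    observed = np.array([matrix.values[i, j] for i, j in pairs])
    if per_pair:
        pvals = np.empty(len(pairs))
        for idx, (i, j) in enumerate(pairs):
            bg = np.array([_null_value(i, j) for _ in range(n_samples)])
            pvals[idx] = float(np.mean(bg >= observed[idx]))
    else:
        choice = rng.integers(0, len(pairs), size=n_samples)
        bg = np.sort([_null_value(*pairs[c]) for c in choice])
        # p = fraction of pooled background >= observed
        pvals = 1.0 - np.searchsorted(bg, observed, side="left") / n_samples
    pvals[observed <= 0] = 1.0
    adj = _bh_adjust(pvals)

    filtered = matrix.values.copy()
    pmat = np.zeros((m, m))
    for idx, (i, j) in enumerate(pairs):
        pmat[i, j] = pmat[j, i] = pvals[idx]
        if adj[idx] >= alpha:
            filtered[i, j] = filtered[j, i] = 0.0
    prov = dict(matrix.provenance)
    prov.update({"n_samples": n_samples, "alpha": alpha,
                 "background": "per_pair" if per_pair else "pooled",
                 "adjustment": "benjamini-hochberg"})
    return (LabeledMatrix(values=filtered, labels=matrix.labels, kind="nMI", provenance=prov),
            LabeledMatrix(values=pmat, labels=matrix.labels, kind="delta",
                          provenance={"content": "p-values"}))


# ---------------------------------------------------------------------------
# dynamical cross-correlation


def _block_dccm(coords: np.ndarray, fit_idx) -> np.ndarray:
    """DCC matrix of one block: frames fit to the block mean."""
    if fit_idx is not None:
        mean = coords.mean(axis=0)
        for _ in range(3):
            fitted = np.empty_like(coords)
            for f in range(coords.shape[0]):
                rot, trans, _ = kabsch(coords[f, fit_idx], mean[fit_idx])
                fitted[f] = apply_transform(coords[f], rot, trans)
            new_mean = fitted.mean(axis=0)
            if np.allclose(new_mean, mean, atol=1e-9):
                mean = new_mean
                break
            mean = new_mean
        coords = fitted
    else:
        mean = coords.mean(axis=0)
    delta = coords - mean
    dots = np.einsum("fia,fja->ij", delta, delta) / coords.shape[0]
    var = np.diag(dots).copy()
    c = np.zeros_like(dots)
    nz = var > 1e-30
    denom = np.sqrt(np.outer(var, var))
    c[np.ix_(nz, nz)] = dots[np.ix_(nz, nz)] / denom[np.ix_(nz, nz)]
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def dccm(ensemble: CoordinateEnsemble, fit_selection: Selection | None = None,
         block_length_ps: float | None = None, calpha_only: bool = True) -> LabeledMatrix:
    """Block-averaged dynamical cross-correlation matrix on Cα atoms.

    The trajectory is split into consecutive blocks of ``block_length_ps``;
    within each block frames are fit to the block-mean structure (using
    ``fit_selection`` atoms; no fitting when None) and
    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) is computed.  The final
    matrix is the unweighted mean over full blocks (a trailing partial block
    is dropped).  ``block_length_ps=None`` uses a single block.
    """
    ens = select(ensemble, CALPHA) if calpha_only else ensemble
    f = ens.n_frames
    if block_length_ps is None:
        n_block = f
    else:
        n_block = int(round(block_length_ps / ens.frame_spacing_ps))
        if n_block < 2:
            raise ContractError("block length must cover at least 2 frames")
        if n_block > f:
            raise ContractError("block length exceeds trajectory duration")
    n_blocks = f // n_block
    fit_idx = np.flatnonzero(fit_selection.mask(ens.atom_meta)) if fit_selection is not None else None
    acc = np.zeros((ens.n_atoms, ens.n_atoms))
    for blk in range(n_blocks):
        acc += _block_dccm(ens.coords[blk * n_block:(blk + 1) * n_block], fit_idx)
    values = acc / n_blocks
    values = 0.5 * (values + values.T)
    labels = [rn if len({ch for ch, _ in ens.residue_ids()}) == 1 else f"{ch}:{rn}"
              for ch, rn in ens.residue_ids()]
    return LabeledMatrix(values=np.clip(values, -1, 1), labels=labels, kind="DCCM",
                         provenance={"source": ens.label, "n_blocks": n_blocks,
                                     "block_frames": n_block})


# ---------------------------------------------------------------------------
# consensus and difference matrices


def consensus_matrix(matrices: list[LabeledMatrix], min_support: int | None = None) -> LabeledMatrix:
    """Replica consensus: keep entries supported (nonzero) by enough replicas.

    Entry (i, j) is the mean over all input matrices when it is nonzero in at
    least ``min_support`` of them, else 0.  Default min_support is
    ceil(n/2) + 1 (3 of 4), clamped to the number of inputs.
    """
    if not matrices:
        raise ContractError("consensus requires at least one matrix")
    labels = matrices[0].labels
    kind = matrices[0].kind
    for m in matrices[1:]:
        if m.labels != labels:
            raise ContractError("consensus inputs must share labels")
        if m.kind != kind:
            raise ContractError("consensus inputs must share kind")
    n = len(matrices)
    if min_support is None:
        min_support = int(np.ceil(n / 2)) + 1
    if min_support > n:
        warnings.warn(f"min_support clamped from {min_support} to the number of replicas ({n})")
        min_support = n
    stack = np.stack([m.values for m in matrices])
    support = (np.abs(stack) > 0).sum(axis=0)
    mean = stack.mean(axis=0)
    values = np.where(support >= min_support, mean, 0.0)
    return LabeledMatrix(values=values, labels=labels, kind=kind,
                         provenance={"n_replicas": n, "min_support": min_support,
                                     "sources": [m.provenance.get("source") for m in matrices]})


def delta_matrix(bound: LabeledMatrix, apo: LabeledMatrix, threshold: float):
    """Signed difference bound - apo with a strict |delta| > threshold edge list.

    Returns ``(edges, delta)`` where edges is a list of (label_i, label_j,
    signed delta) for entries exceeding the threshold in absolute value.
    """
    if bound.labels != apo.labels:
        raise ContractError("delta inputs must share labels")
    if bound.kind != apo.kind:
        raise ContractError(f"kind mismatch: {bound.kind} vs {apo.kind}")
    diff = bound.values - apo.values
    n = len(bound.labels)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(diff[i, j]) > threshold:
                edges.append((bound.labels[i], bound.labels[j], float(diff[i, j])))
    lm = LabeledMatrix(values=diff, labels=bound.labels, kind="delta",
                       provenance={"threshold": threshold, "convention": "bound - apo",
                                   "input_kind": bound.kind})
    return edges, lm


def write_edge_list(edges, path) -> None:
    """Three-column edge list (id_i, id_j, value)."""
    with open(path, "w") as fh:
        for i, j, v in edges:
            fh.write(f"{i}\t{j}\t{v:.6g}\n")
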