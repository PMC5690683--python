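"""Residue-residue and ligand-residue contact analysis.

Two residues are in contact in a frame when the minimum distance over all
their non-hydrogen atom pairs is below the cutoff (default 4 Å); the contact
frequency is the fraction of frames in contact.  Sequence neighbours
(|i - j| <= 2 on the same chain) are excluded so trivially permanent backbone
contacts do not dominate the networks.

The bound-minus-apo contact-change network takes the absolute difference of
the two consensus contact matrices, keeps changes strictly larger than a
threshold (default 0.1), and is analysed with the shared strength-to-distance
transform and k-shortest-path machinery.

Threshold conventions: "at least" thresholds (stable contacts at 70%,
hydrophobic contacts at 50%) are inclusive (>=); "larger than" thresholds
(contact change 0.1) are strict (>).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .correlations import LabeledMatrix, consensus_matrix  # noqa: F401  (re-export for pipelines)
from .exceptions import ContractError
from .networks import PathSet, build_graph, k_shortest_paths
from .trajectory_io import CoordinateEnsemble

__all__ = [
    "ContactMatrix",
    "LigandFingerprint",
    "contact_frequency",
    "stable_contacts",
    "ligand_fingerprint",
    "hydrogen_bond_frequency",
    "contact_change_matrix",
    "contact_change_paths",
]

NONPOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class LigandFingerprint:
    """Per-residue ligand interaction frequencies."""

    contact_freq: dict              # residue id -> fraction of frames in contact
    hbond_freq: dict                # residue id -> H-bond frequency
    hydrophobic: dict               # residue id -> bool
    cutoff: float = 4.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\tcontact_freq\thbond_freq\thydrophobic\n")
            for rid, f in self.contact_freq.items():
                fh.write(f"{rid}\t{f:.6g}\t{self.hbond_freq.get(rid, 0.0):.6g}\t"
                         f"{int(self.hydrophobic.get(rid, False))}\n")


ContactMatrix = LabeledMatrix  # kind == "contact_freq"


def _residue_groups(ensemble: CoordinateEnsemble, heavy_only: bool = True):
    """Ordered residues with their atom indices; hydrogens dropped."""
    meta = ensemble.atom_meta
    is_h = meta["element"].astype(str).str.upper().eq("H").to_numpy()
    groups: dict = {}
    order: list = []
    for i, (ch, rn) in enumerate(zip(meta["chain_id"], meta["residue_number"])):
        key = (ch, int(rn))
        if key not in groups:
            groups[key] = []
            order.append(key)
        if not (heavy_only and is_h[i]):
            groups[key].append(i)
    return order, groups


def _labels(order) -> list:
    chains = {ch for ch, _ in order}
    if len(chains) == 1:
        return [rn for _, rn in order]
    return [f"{ch}:{rn}" for ch, rn in order]


def contact_frequency(ensemble: CoordinateEnsemble, cutoff: float = 4.0,
                      neighbour_exclusion: int = 2) -> LabeledMatrix:
    """Residue-residue contact-frequency matrix over non-hydrogen atoms.

    Pairs within ``neighbour_exclusion`` sequence positions on the same chain
    are fixed at 0.  Residues with no heavy atoms are flagged in provenance
    and their rows recorded as missing (0).
    """
    order, groups = _residue_groups(ensemble, heavy_only=True)
    n = len(order)
    missing = [key for key in order if not groups[key]]
    keep = [key for key in order if groups[key]]
    atom_idx = np.concatenate([groups[k] for k in keep]) if keep else np.array([], dtype=int)
    res_of_atom = np.concatenate([[order.index(k)] * len(groups[k]) for k in keep]) if keep else np.array([], dtype=int)
    member = np.zeros((atom_idx.size, n))
    member[np.arange(atom_idx.size), res_of_atom] = 1.0
    counts = np.zeros((n, n))
    for f in range(ensemble.n_frames):
        pts = ensemble.coords[f, atom_idx, :]
        close = (cdist(pts, pts) < cutoff).astype(float)
        res_contact = member.T @ close @ member
        counts += res_contact > 0
    freq = counts / max(ensemble.n_frames, 1)
    np.fill_diagonal(freq, 0.0)
    # sequence-neighbour exclusion within chains
    for i, (ci, ri) in enumerate(order):
        for j in range(i + 1, n):
            cj, rj = order[j]
            if ci == cj and abs(ri - rj) <= neighbour_exclusion:
                freq[i, j] = freq[j, i] = 0.0
    return LabeledMatrix(values=freq, labels=_labels(order), kind="contact_freq",
                         provenance={"source": ensemble.label, "cutoff": cutoff,
                                     "neighbour_exclusion": neighbour_exclusion,
                                     "missing_residues": [f"{c}:{r}" for c, r in missing]})


def stable_contacts(matrix: LabeledMatrix, min_freq: float = 0.7) -> list:
    """Residue pairs in contact for at least ``min_freq`` of the frames (>=)."""
    if matrix.kind != "contact_freq":
        raise ContractError("stable_contacts expects a contact-frequency matrix")
    edges = []
    n = matrix.n
    for i in range(n):
        for j in range(i + 1, n):
            f = matrix.values[i, j]
            if f >= min_freq and f > 0:
                edges.append((matrix.labels[i], matrix.labels[j], float(f)))
    return edges


def _min_dist_per_residue(protein: CoordinateEnsemble, ligand: CoordinateEnsemble,
                          atom_filter=None):
    """Per-frame minimum residue-to-ligand heavy-atom distances (F, R)."""
    order, groups = _residue_groups(protein, heavy_only=True)
    lig_meta = ligand.atom_meta
    lig_heavy = np.flatnonzero(~lig_meta["element"].astype(str).str.upper().eq("H").to_numpy())
    f = protein.n_frames
    out = np.full((f, len(order)), np.inf)
    for r, key in enumerate(order):
        idx = groups[key]
        if atom_filter is not None:
            idx = [i for i in idx if atom_filter(protein.atom_meta.iloc[i])]
        if not idx:
            continue
        for fr in range(f):
            d = cdist(protein.coords[fr, idx, :], ligand.coords[fr, lig_heavy, :])
            out[fr, r] = d.min()
    return order, out


def ligand_fingerprint(protein: CoordinateEnsemble, ligand: CoordinateEnsemble,
                       cutoff: float = 4.0, stable_freq: float = 0.5) -> LigandFingerprint:
    """Per-residue ligand contact fingerprint.

    Contact frequency = fraction of frames with min heavy-atom distance below
    ``cutoff``.  A residue is flagged hydrophobic when it is non-polar and its
    side-chain heavy atoms are within ``cutoff`` of the ligand for at least
    ``stable_freq`` of the frames (glycine, with no side chain beyond Cα, is
    never flagged).  H-bond frequencies use the geometric criterion of
    :func:`hydrogen_bond_frequency`.
    """
    if protein.n_frames != ligand.n_frames:
        raise ContractError("protein and ligand frame counts must match")
    order, dmin = _min_dist_per_residue(protein, ligand)
    labels = _labels(order)
    contact = {lab: float(np.mean(dmin[:, r] < cutoff)) for r, lab in enumerate(labels)}

    # side chain = non-backbone heavy atoms (CB included)
    _, dside = _min_dist_per_residue(protein, ligand,
                                     atom_filter=lambda row: row["atom_name"] not in BACKBONE_ATOMS)
    resname = {key: None for key in order}
    for i, (ch, rn) in enumerate(zip(protein.atom_meta["chain_id"], protein.atom_meta["residue_number"])):
        key = (ch, int(rn))
        if resname.get(key) is None:
            resname[key] = str(protein.atom_meta["residue_name"].iloc[i])
    hydrophobic = {}
    for r, key in enumerate(order):
        nonpolar = resname[key] in NONPOLAR_RESIDUES
        freq_side = float(np.mean(dside[:, r] < cutoff)) if np.isfinite(dside[:, r]).any() else 0.0
        hydrophobic[labels[r]] = bool(nonpolar and freq_side >= stable_freq)
    hbond = hydrogen_bond_frequency(protein, ligand)
    return LigandFingerprint(contact_freq=contact, hbond_freq=hbond,
                             hydrophobic=hydrophobic, cutoff=cutoff)


def _polar_atoms(meta) -> np.ndarray:
    el = meta["element"].astype(str).str.upper()
    return np.flatnonzero(el.isin(["N", "O", "S"]).to_numpy())


def _attached_hydrogens(ensemble: CoordinateEnsemble, frame: int, heavy_index: int) -> np.ndarray:
    """Indices of explicit hydrogens within bonding distance of a heavy atom."""
    meta = ensemble.atom_meta
    h_idx = np.flatnonzero(meta["element"].astype(str).str.upper().eq("H").to_numpy())
    if h_idx.size == 0:
        return h_idx
    d = np.linalg.norm(ensemble.coords[frame, h_idx, :] - ensemble.coords[frame, heavy_index, :], axis=1)
    return h_idx[d < 1.25]


def hydrogen_bond_frequency(protein: CoordinateEnsemble, ligand: CoordinateEnsemble,
                            dist_cutoff: float = 3.5, angle_cutoff: float = 120.0) -> dict:
    """Per-residue protein-ligand hydrogen-bond frequency.

    Geometric criterion: donor-acceptor heavy-atom (N/O/S) distance below
    ``dist_cutoff`` and, when an explicit hydrogen is attached to either
    candidate donor, a donor-H...acceptor angle above ``angle_cutoff``
    degrees.  When neither partner carries explicit hydrogens the distance
    criterion alone is applied (flagged implicitly by the absence of H atoms
    in the inputs).
    """
    if protein.n_frames != ligand.n_frames:
        raise ContractError("protein and ligand frame counts must match")
    prot_polar = _polar_atoms(protein.atom_meta)
    lig_polar = _polar_atoms(ligand.atom_meta)
    order, _ = _residue_groups(protein, heavy_only=True)
    labels = _labels(order)
    res_index = {key: r for r, key in enumerate(order)}
    counts = np.zeros(len(order))
    f = protein.n_frames
    for fr in range(f):
        bonded_residues = set()
        if prot_polar.size and lig_polar.size:
            d = cdist(protein.coords[fr, prot_polar, :], ligand.coords[fr, lig_polar, :])
            for a, b in zip(*np.nonzero(d < dist_cutoff)):
                pi, lj = prot_polar[a], lig_polar[b]
                if _hbond_geometry_ok(protein, ligand, fr, pi, lj, angle_cutoff):
                    meta = protein.atom_meta.iloc[pi]
                    bonded_residues.add(res_index[(meta["chain_id"], int(meta["residue_number"]))])
        for r in bonded_residues:
            counts[r] += 1
    return {labels[r]: counts[r] / f for r in range(len(order))}


def _hbond_geometry_ok(protein, ligand, frame, prot_atom, lig_atom, angle_cutoff) -> bool:
    p = protein.coords[frame, prot_atom]
    q = ligand.coords[frame, lig_atom]
    checked_any = False
    for ens, donor_pos, acceptor_pos, donor_idx in (
        (protein, p, q, prot_atom),
        (ligand, q, p, lig_atom),
    ):
        for h in _attached_hydrogens(ens, frame, donor_idx):
            checked_any = True
            hpos = ens.coords[frame, h]
            v1 = donor_pos - hpos
            v2 = acceptor_pos - hpos
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            ang = np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1, 1)))
            if ang > angle_cutoff:
                return True
    return not checked_any  # no explicit hydrogens anywhere: distance criterion only


def contact_change_matrix(bound_consensus: LabeledMatrix, apo_consensus: LabeledMatrix,
                          min_change: float = 0.1):
    """|bound - apo| contact-frequency change matrix, thresholded strictly.

    Entries with |Δf| <= min_change are zeroed.  Returns ``(change, signed)``
    where ``signed`` keeps the sign (positive = stabilised upon binding).
    """
    if bound_consensus.labels != apo_consensus.labels:
        raise ContractError("contact change requires matching residue labels")
    diff = bound_consensus.values - apo_consensus.values
    absd = np.abs(diff)
    absd[absd <= min_change] = 0.0
    signed = np.where(absd > 0, diff, 0.0)
    change = LabeledMatrix(values=absd, labels=bound_consensus.labels, kind="delta",
                           provenance={"min_change": min_change, "convention": "|bound - apo|"})
    signed_m = LabeledMatrix(values=signed, labels=bound_consensus.labels, kind="delta",
                             provenance={"min_change": min_change, "convention": "bound - apo"})
    return change, signed_m


def contact_change_paths(change_matrix: LabeledMatrix, source_residue,
                         target_residues, k: int = 5) -> PathSet:
    """Top-k paths per endpoint pair through the contact-change network.

    Edge strength is |Δf|; the shared w = 1 - s transform applies.  Sources or
    targets absent from the network are reported as unreachable.
    """
    if not np.any(change_matrix.values > 0):
        raise ContractError("contact-change matrix has no edges")
    graph = build_graph(change_matrix)
    merged = PathSet(pairs=[], paths=[], lengths=[])
    if source_residue not in graph:
        merged.unreachable = list(target_residues)
        return merged
    for target in target_residues:
        ps = k_shortest_paths(graph, source_residue, target, k=k)
        merged.pairs.extend(ps.pairs)
        merged.paths.extend(ps.paths)
        merged.lengths.extend(ps.lengths)
        merged.unreachable.extend(ps.unreachable)
    merged.recount()
    return merged
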