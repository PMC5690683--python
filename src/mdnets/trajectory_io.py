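"""Coordinate-ensemble container and trajectory file I/O.

The universal in-memory container is :class:`CoordinateEnsemble`: a
``(frames, atoms, 3)`` coordinate array in Å plus per-atom metadata carried as
a :class:`pandas.DataFrame`.  Residue numbering is preserved verbatim from the
source file (author numbering) and never re-indexed, because downstream
reports refer to residues by that numbering.

Multi-model PDB is the canonical text interchange format.  Binary formats
(XTC/DCD/TRR) are read through mdtraj behind a capability check.  Inputs are
assumed to be post-processed, whole-molecule trajectories: no periodic
boundary unwrapping is performed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CapabilityError, ContractError, ParseError, SelectionError, StructureError

__all__ = [
    "CoordinateEnsemble",
    "Selection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_binary_trajectory",
    "select",
]

ATOM_META_COLUMNS = ["residue_number", "residue_name", "atom_name", "chain_id", "element"]


@dataclass
class CoordinateEnsemble:
    """A trajectory: frames x atoms x 3 coordinates (Å) with atom metadata.

    ``atom_meta`` columns: residue_number (int, author numbering),
    residue_name, atom_name, chain_id, element.  ``frame_spacing_ps`` is the
    time between consecutive frames in picoseconds.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame
    frame_spacing_ps: float = 1.0
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ContractError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("coordinates must be finite")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise ContractError("atom_meta length must equal the atom dimension")
        missing = [c for c in ATOM_META_COLUMNS if c not in self.atom_meta.columns]
        if missing:
            raise ContractError(f"atom_meta missing columns: {missing}")
        self.atom_meta = self.atom_meta.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_ids(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for ch, rn in zip(self.atom_meta["chain_id"], self.atom_meta["residue_number"]):
            seen.setdefault((ch, int(rn)), None)
        return list(seen)

    def subset_atoms(self, indices: Sequence[int], label: str | None = None) -> "CoordinateEnsemble":
        indices = list(indices)
        return CoordinateEnsemble(
            coords=self.coords[:, indices, :].copy(),
            atom_meta=self.atom_meta.iloc[indices].reset_index(drop=True),
            frame_spacing_ps=self.frame_spacing_ps,
            label=label if label is not None else self.label,
        )

    def subset_frames(self, frame_indices: Sequence[int]) -> "CoordinateEnsemble":
        return replace(self, coords=self.coords[list(frame_indices)])


@dataclass
class Selection:
    """Predicate over atom metadata.

    Any combination of: a set of atom names, inclusive residue-number ranges,
    a chain set, and a residue exclusion list.  ``exclude_residues`` holds
    residue numbers (applied on every chain) or (chain_id, residue_number)
    pairs.
    """

    atom_names: set[str] | None = None
    residue_ranges: list[tuple[int, int]] | None = None
    chains: set[str] | None = None
    exclude_residues: set = field(default_factory=set)

    def mask(self, atom_meta: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(atom_meta), dtype=bool)
        if self.atom_names is not None:
            m &= atom_meta["atom_name"].isin(self.atom_names).to_numpy()
        if self.chains is not None:
            m &= atom_meta["chain_id"].isin(self.chains).to_numpy()
        if self.residue_ranges is not None:
            rn = atom_meta["residue_number"].to_numpy()
            rm = np.zeros(len(atom_meta), dtype=bool)
            for lo, hi in self.residue_ranges:
                rm |= (rn >= lo) & (rn <= hi)
            m &= rm
        if self.exclude_residues:
            rn = atom_meta["residue_number"].to_numpy()
            ch = atom_meta["chain_id"].to_numpy()
            excl = np.zeros(len(atom_meta), dtype=bool)
            for item in self.exclude_residues:
                if isinstance(item, tuple):
                    excl |= (ch == item[0]) & (rn == int(item[1]))
                else:
                    excl |= rn == int(item)
            m &= ~excl
        return m


CALPHA = Selection(atom_names={"CA"})


def select(ensemble: CoordinateEnsemble, selection: Selection, label: str | None = None) -> CoordinateEnsemble:
    """Restrict an ensemble to the atoms matching ``selection``.

    Raises :class:`SelectionError` if nothing matches.
    """
    mask = selection.mask(ensemble.atom_meta)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError("selection matched no atoms")
    return ensemble.subset_atoms(idx, label=label)


# ---------------------------------------------------------------------------
# multi-model PDB


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = name[:1]
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}") from exc
    return (name, resname, chain, resnum, element), (x, y, z)


def read_multimodel_pdb(path: str | os.PathLike) -> CoordinateEnsemble:
    """Read a (multi-model) PDB file into a :class:`CoordinateEnsemble`.

    One frame per MODEL record; a file without MODEL records yields a single
    frame.  Atom identity and order must be identical across models; a model
    that differs raises :class:`StructureError` naming the model.
    """
    frames: list[list[tuple[float, float, float]]] = []
    keys: list[list[tuple]] = []
    current_coords: list = []
    current_keys: list = []
    model_numbers: list[int] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model and current_coords:
                    frames.append(current_coords)
                    keys.append(current_keys)
                in_model = True
                current_coords, current_keys = [], []
                try:
                    model_numbers.append(int(line.split()[1]))
                except (IndexError, ValueError):
                    model_numbers.append(len(frames) + 1)
            elif rec == "ENDMDL":
                frames.append(current_coords)
                keys.append(current_keys)
                current_coords, current_keys = [], []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                key, xyz = _parse_atom_line(line, lineno)
                current_keys.append(key)
                current_coords.append(xyz)
    if current_coords:
        frames.append(current_coords)
        keys.append(current_keys)
        model_numbers.append(model_numbers[-1] + 1 if model_numbers else 1)
    if not frames:
        raise ParseError(f"no coordinates found in {path}")
    if not model_numbers:
        model_numbers = [1]
    ref = keys[0]
    for i, k in enumerate(keys[1:], start=1):
        model = model_numbers[i] if i < len(model_numbers) else i + 1
        if len(k) != len(ref):
            raise StructureError(
                f"model {model} has {len(k)} atoms, expected {len(ref)} (model 1)"
            )
        if k != ref:
            raise StructureError(f"model {model} atom records differ from model 1")
    meta = pd.DataFrame(
        [(rn, resname, name, chain, element) for (name, resname, chain, rn, element) in
         [(k[0], k[1], k[2], k[3], k[4]) for k in ref]],
        columns=["residue_number", "residue_name", "atom_name", "chain_id", "element"],
    )
    coords = np.array(frames, dtype=float)
    return CoordinateEnsemble(coords=coords, atom_meta=meta, label=str(path))


def write_multimodel_pdb(ensemble: CoordinateEnsemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame, 3 dp)."""
    meta = ensemble.atom_meta
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a in range(ensemble.n_atoms):
                row = meta.iloc[a]
                x, y, z = ensemble.coords[f, a]
                name = str(row["atom_name"])
                # PDB atom-name column convention: 1-letter elements start in col 14
                pname = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    "ATOM  {serial:5d} {name:4s} {res:<3s} {chain:1s}{resnum:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=a + 1,
                        name=pname,
                        res=str(row["residue_name"])[:3],
                        chain=str(row["chain_id"])[:1],
                        resnum=int(row["residue_number"]),
                        x=x, y=y, z=z, occ=1.0, b=0.0,
                        el=str(row["element"])[:2],
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


_BINARY_FORMATS = {".xtc", ".dcd", ".trr"}


def read_binary_trajectory(topology_path: str | os.PathLike, traj_path: str | os.PathLike,
                           stride: int = 1, label: str = "") -> CoordinateEnsemble:
    """Read an XTC/DCD/TRR trajectory (via mdtraj), subsampled by ``stride``.

    ``frame_spacing_ps`` is scaled by the stride.  Unsupported extensions
    raise :class:`CapabilityError` — never a silent fallback.
    """
    if stride < 1:
        raise ContractError("stride must be >= 1")
    ext = os.path.splitext(str(traj_path))[1].lower()
    if ext not in _BINARY_FORMATS:
        raise CapabilityError(f"unsupported trajectory format {ext!r}; supported: {sorted(_BINARY_FORMATS)}")
    import mdtraj

    traj = mdtraj.load(str(traj_path), top=str(topology_path), stride=stride)
    top = traj.topology
    rows = []
    for atom in top.atoms:
        rows.append(
            (atom.residue.resSeq, atom.residue.name, atom.name,
             atom.residue.chain.chain_id or "A",
             atom.element.symbol if atom.element is not None else atom.name[:1])
        )
    meta = pd.DataFrame(rows, columns=ATOM_META_COLUMNS)
    coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
    if traj.time is not None and len(traj.time) >= 2:
        spacing = float(traj.time[1] - traj.time[0])
    else:
        spacing = float(stride)
    return CoordinateEnsemble(coords=coords, atom_meta=meta, frame_spacing_ps=spacing,
                              label=label or str(traj_path))
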