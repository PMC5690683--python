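"""Structural-alphabet encoding of Cα trajectories.

A structural alphabet is a small library of prototypical 4-residue Cα
fragment conformations, each carrying a single-letter label.  Encoding a
trajectory replaces every overlapping 4-residue fragment in every frame by the
letter of the prototype with minimal RMSD after optimal superposition,
producing a symbolic trajectory on which letter-sequence statistics (mutual
information, transition counts) can be computed.

The default library name is "M32K25", the 25-letter alphabet used in the
original local-correlation analyses.  The published prototype coordinates are
not redistributed here: the packaged file ``data/m32k25_synthetic.txt`` is a
clearly-labelled synthetic stand-in with the same cardinality and format,
built on a grid of pseudo-bond-angle/pseudo-torsion values covering the
helical-to-extended range of protein Cα geometry (3.8 Å virtual bonds).  Any
library in the same plain-text format can be supplied instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from ._superpose import min_rmsd
from .exceptions import ConfigurationError, ParseError
from .trajectory_io import CALPHA, CoordinateEnsemble, select

__all__ = [
    "FragmentLibrary",
    "SAEncoding",
    "load_fragment_library",
    "encode",
    "fragment_from_internal",
]

FRAGMENT_LENGTH = 4
CA_VIRTUAL_BOND = 3.8  # Å, consecutive Cα distance (trans peptide)


def fragment_from_internal(theta1: float, theta2: float, tau: float,
                           bond: float = CA_VIRTUAL_BOND) -> np.ndarray:
    """Build a 4-point Cα fragment from internal coordinates.

    ``theta1``/``theta2`` are the pseudo bond angles at points 2 and 3 and
    ``tau`` the pseudo torsion 1-2-3-4, all in degrees.  Returns (4, 3)
    coordinates centred at the origin.
    """
    t1, t2, tau = np.radians([theta1, theta2, tau])
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([bond, 0.0, 0.0])
    p2 = p1 + bond * np.array([-np.cos(t1), np.sin(t1), 0.0])

    # natural-extension (NeRF) placement of the fourth point
    bc = p2 - p1
    bc /= np.linalg.norm(bc)
    n = np.cross(p1 - p0, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(t2), np.sin(t2) * np.cos(tau), -np.sin(t2) * np.sin(tau)])
    p3 = p2 + d[0] * bc + d[1] * m + d[2] * n
    frag = np.stack([p0, p1, p2, p3])
    return frag - frag.mean(axis=0)


@dataclass
class FragmentLibrary:
    """A structural alphabet: letters and their (L, 4, 3) prototype fragments."""

    letters: list[str]
    prototypes: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if len(self.letters) < 2:
            raise ConfigurationError("a fragment library needs at least 2 letters")
        if self.prototypes.shape != (len(self.letters), FRAGMENT_LENGTH, 3):
            raise ConfigurationError("prototypes must have shape (letters, 4, 3)")
        if len(set(self.letters)) != len(self.letters):
            raise ConfigurationError("duplicate letter labels in library")
        # all prototypes pairwise distinct under superposition
        l = len(self.letters)
        for i in range(l):
            r = min_rmsd(self.prototypes[i][None], self.prototypes[i + 1:])
            if i + 1 < l and np.any(r <= 1e-6):
                j = i + 1 + int(np.argmax(r <= 1e-6))
                raise ConfigurationError(
                    f"prototypes {self.letters[i]!r} and {self.letters[j]!r} are identical"
                )

    @property
    def n_letters(self) -> int:
        return len(self.letters)


def _parse_library_text(text: str, name: str) -> FragmentLibrary:
    letters: list[str] = []
    protos: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            letters.append(line[1:].strip())
            current = []
            protos.append(current)
        else:
            if current is None:
                raise ParseError(f"coordinate line before any letter header at line {lineno}")
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"expected 3 coordinates at line {lineno}: {raw!r}")
            try:
                current.append([float(v) for v in parts])
            except ValueError as exc:
                raise ParseError(f"non-numeric coordinate at line {lineno}: {raw!r}") from exc
    if not letters:
        raise ParseError("no fragment prototypes found")
    for letter, coords in zip(letters, protos):
        if len(coords) != FRAGMENT_LENGTH:
            raise ParseError(f"prototype {letter!r} has {len(coords)} points, expected {FRAGMENT_LENGTH}")
    return FragmentLibrary(letters=letters, prototypes=np.array(protos), name=name)


def load_fragment_library(source: str = "M32K25") -> FragmentLibrary:
    """Load a fragment library by built-in name or from a file path.

    ``"M32K25"`` resolves to the packaged 25-letter synthetic stand-in (see
    module docstring).  Any other string is treated as a path to a plain-text
    library file (``>letter`` headers followed by four ``x y z`` lines).
    """
    if source == "M32K25":
        text = importlib.resources.files("mdnets").joinpath("data/m32k25_synthetic.txt").read_text()
        return _parse_library_text(text, name="M32K25")
    try:
        with open(source) as fh:
            text = fh.read()
    except FileNotFoundError as exc:
        raise ConfigurationError(f"unknown library name or missing file: {source!r}") from exc
    return _parse_library_text(text, name=str(source))


@dataclass
class SAEncoding:
    """Symbolic trajectory: one letter per (frame, fragment).

    ``fragment_ids`` are the author residue numbers of each fragment's first
    residue (prefixed by chain id when the ensemble has several chains).
    ``codes`` holds the integer letter indices; ``letters_matrix`` the
    characters.
    """

    codes: np.ndarray               # (frames, fragments) int16
    fragment_ids: list
    library: FragmentLibrary
    frame_spacing_ps: float = 1.0
    label: str = ""

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.codes.shape[1]

    @property
    def letters_matrix(self) -> np.ndarray:
        lut = np.array(self.library.letters)
        return lut[self.codes]

    def to_text(self, path) -> None:
        """One row per frame; header line carries the fragment ids."""
        with open(path, "w") as fh:
            fh.write("# fragments\t" + "\t".join(str(i) for i in self.fragment_ids) + "\n")
            lut = self.library.letters
            for row in self.codes:
                fh.write("".join(lut[c] for c in row) + "\n")

    def to_fasta(self, path) -> None:
        """Per-fragment letter sequence across frames, FASTA-like."""
        with open(path, "w") as fh:
            lut = self.library.letters
            for j, fid in enumerate(self.fragment_ids):
                fh.write(f">{fid}\n")
                fh.write("".join(lut[c] for c in self.codes[:, j]) + "\n")


def _contiguous_segments(meta) -> list[list[int]]:
    """Indices of Cα atoms grouped into runs of consecutive residue numbers."""
    segments: list[list[int]] = []
    current: list[int] = []
    prev = None
    for i, (ch, rn) in enumerate(zip(meta["chain_id"], meta["residue_number"])):
        if prev is not None and (ch == prev[0] and int(rn) == prev[1] + 1):
            current.append(i)
        else:
            if current:
                segments.append(current)
            current = [i]
        prev = (ch, int(rn))
    if current:
        segments.append(current)
    return segments


def encode(ensemble: CoordinateEnsemble, library: FragmentLibrary,
           exclude_residues=None, chunk_frames: int = 256) -> SAEncoding:
    """Assign every 4-residue Cα fragment in every frame its closest letter.

    The chain is split into contiguous segments wherever the residue
    numbering jumps, the chain id changes, or an excluded residue (e.g. a
    modelled loop) interrupts it; fragments never span a break.  Each fragment
    gets the letter of the prototype with minimal superposed RMSD, ties broken
    by library order.  Segments shorter than 4 residues are skipped.
    """
    ca = select(ensemble, CALPHA)
    if exclude_residues:
        keep = ~ca.atom_meta["residue_number"].isin(set(int(r) for r in exclude_residues)).to_numpy()
        ca = ca.subset_atoms(np.flatnonzero(keep))
    meta = ca.atom_meta
    multi_chain = meta["chain_id"].nunique() > 1
    starts: list[int] = []
    fragment_ids: list = []
    for seg in _contiguous_segments(meta):
        if len(seg) < FRAGMENT_LENGTH:
            continue
        for k in range(len(seg) - FRAGMENT_LENGTH + 1):
            i0 = seg[k]
            starts.append(i0)
            rn = int(meta["residue_number"].iloc[i0])
            ch = meta["chain_id"].iloc[i0]
            fragment_ids.append(f"{ch}:{rn}" if multi_chain else rn)
    if not fragment_ids:
        raise ConfigurationError("no 4-residue fragment fits in any contiguous segment")
    starts_arr = np.array(starts)
    window = starts_arr[:, None] + np.arange(FRAGMENT_LENGTH)[None, :]
    protos = library.prototypes  # (L, 4, 3)
    n_frames = ca.n_frames
    codes = np.empty((n_frames, len(starts)), dtype=np.int16)
    for f0 in range(0, n_frames, chunk_frames):
        chunk = ca.coords[f0:f0 + chunk_frames]           # (f, A, 3)
        frags = chunk[:, window, :]                        # (f, M, 4, 3)
        r = min_rmsd(frags[:, :, None, :, :], protos[None, None, :, :, :])  # (f, M, L)
        codes[f0:f0 + chunk_frames] = np.argmin(r, axis=-1)
    return SAEncoding(codes=codes, fragment_ids=fragment_ids, library=library,
                      frame_spacing_ps=ensemble.frame_spacing_ps, label=ensemble.label)
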