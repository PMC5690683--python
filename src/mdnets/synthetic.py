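"""Synthetic two-condition trajectory generator with planted ground truth.

Emulates the study design of a comparative MD analysis — several replicas of
the same protein in two binding states ("apo" and "bound") — at toy scale,
so that every downstream stage (structural-alphabet encoding, mutual
information networks, ζ profiles, DCCM, contact-change networks) can be
validated against known, planted signal:

* the chain is built from rigid 4-residue blocks, each of which switches
  between two geometrically distinct local conformations ("kinked" vs
  "extended", internal RMSD ≈ 1.5 Å) as a two-state Markov chain — these
  blocks are the structural-alphabet fragments;
* a *coupled pair* of blocks with coupling c draws its states so that
  P(same state) = (1 + c)/2, planting a mutual-information edge;
* a *mobile domain* rotates rigidly about an axis through two hinge
  residues (Rodrigues rotation), with a per-frame angle drawn from a
  zero-mean normal distribution whose width differs between conditions;
* *rigidified pairs* are residue pairs whose contact (< 4 Å) is occupied
  much more often in the bound condition, planting a contact-frequency
  change;
* isotropic Gaussian noise of width ``noise_sd`` is added to every
  coordinate;
* a toy ligand occupies a pocket for a controllable fraction of frames.

Blocks are separated by a gap of one residue number, so encoding (which
never builds fragments across numbering breaks) yields exactly one fragment
per block and blocks are statistically independent unless coupled.  Replicas
differ only by their random stream; everything is deterministic given the
spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alphabet import fragment_from_internal
from .exceptions import ConfigurationError, ContractError
from .trajectory_io import CoordinateEnsemble

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_two_state_system",
    "generate_replica",
    "generate_ligand_fixture",
    "default_spec",
    "independent_spec",
]

BLOCK = 4                 # residues per rigid block (= fragment length)
NUMBERING_STRIDE = 5      # first residue of block k is 5k + 1 (gap of 1)
STATE_TEMPLATES = (
    fragment_from_internal(88.0, 88.0, -30.0),    # state 0: kinked / helical-like
    fragment_from_internal(116.0, 116.0, 35.0),   # state 1: more extended
)
CONTACT_ON_DISTANCE = 3.5   # Å, planted contact distance (< 4 Å cutoff)
CONTACT_OFF_DISTANCE = 8.0  # Å, planted no-contact distance (> 6 Å)
# planted contacts approach along +y+z, with the partner block pitched 60° out
# of the sheet plane: this keeps every *other* inter-block atom pair > 5.5 Å
# in all local-state combinations, so only the designated residue pair can
# cross the 4 Å contact cutoff
CONTACT_AXIS = np.array([0.0, np.sqrt(0.5), np.sqrt(0.5)])
_c60, _s60 = np.cos(np.radians(60.0)), np.sin(np.radians(60.0))
PARTNER_ROTATION = np.array([[_c60, 0.0, -_s60], [0.0, 1.0, 0.0], [_s60, 0.0, _c60]])


@dataclass
class SyntheticSpec:
    """Study design of a synthetic two-condition system.

    ``coupled_pairs`` (block indices, coupling c in [0, 1]) apply to both
    conditions; ``bound_extra_couplings`` only to the bound one.  Residue
    fields (``mobile_domain``, ``hinge_residues``, ``rigidify_pairs``,
    ``ligand_pocket_residues``) use residue numbers as they appear in the
    generated ensembles.
    """

    n_residues: int = 96
    n_replicas_per_condition: int = 4
    n_frames: int = 2000
    frame_spacing_ps: float = 1.0
    coupled_pairs: list = field(default_factory=list)
    bound_extra_couplings: list = field(default_factory=list)
    switch_prob: float = 0.1
    mobile_domain: tuple | None = None          # inclusive residue-number range
    hinge_residues: tuple | None = None
    hinge_amplitude_apo: float = 12.0           # degrees (sd of per-frame angle)
    hinge_amplitude_bound: float = 2.0
    rigidify_pairs: list = field(default_factory=list)
    rigidify_freq_apo: float = 0.4
    rigidify_freq_bound: float = 0.95
    noise_sd: float = 0.1                       # Å
    ligand_pocket_residues: list = field(default_factory=list)
    seed: int = 0
    blocks_per_row: int = 6                     # serpentine layout width

    @property
    def n_blocks(self) -> int:
        return self.n_residues // BLOCK

    def block_of_residue(self, resnum: int) -> int:
        b, pos = divmod(int(resnum) - 1, NUMBERING_STRIDE)
        if pos >= BLOCK or b < 0 or b >= self.n_blocks:
            raise ConfigurationError(f"residue number {resnum} does not exist in this system")
        return b

    def residue_numbers(self) -> np.ndarray:
        return np.array([NUMBERING_STRIDE * b + 1 + p
                         for b in range(self.n_blocks) for p in range(BLOCK)])

    def fragment_id(self, block: int) -> int:
        return NUMBERING_STRIDE * block + 1

    def validate(self) -> None:
        if self.n_blocks < 1 or self.n_residues % BLOCK != 0:
            raise ConfigurationError("n_residues must be a positive multiple of 4")
        if not 0.0 < self.switch_prob < 1.0:
            raise ConfigurationError("switch_prob must lie in (0, 1)")
        if self.hinge_amplitude_apo < 0 or self.hinge_amplitude_bound < 0:
            raise ConfigurationError("hinge amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        targets = set()
        for i, j, c in list(self.coupled_pairs) + list(self.bound_extra_couplings):
            if not (0.0 <= c <= 1.0):
                raise ConfigurationError(f"coupling c={c} outside [0, 1]")
            for b in (i, j):
                if not 0 <= b < self.n_blocks:
                    raise ConfigurationError(f"coupled pair block {b} out of range")
            if j in targets:
                raise ConfigurationError(f"block {j} is the target of more than one coupling")
            targets.add(j)
        mobile_blocks = set()
        if self.mobile_domain is not None:
            lo, hi = self.mobile_domain
            mobile_blocks = {self.block_of_residue(r)
                             for r in self.residue_numbers() if lo <= r <= hi}
            if self.hinge_residues is None:
                raise ConfigurationError("mobile_domain requires hinge_residues")
            for r in self.hinge_residues:
                if lo <= int(r) <= hi:
                    raise ConfigurationError(
                        f"hinge residue {r} lies inside the mobile domain {self.mobile_domain}")
        for ri, rj in self.rigidify_pairs:
            bi, bj = self.block_of_residue(ri), self.block_of_residue(rj)
            if bi in mobile_blocks or bj in mobile_blocks:
                raise ConfigurationError("rigidify pairs must lie outside the mobile domain")
            if bi == bj:
                raise ConfigurationError("rigidify pair within a single block")
        for r in self.ligand_pocket_residues:
            if self.block_of_residue(r) in mobile_blocks:
                raise ConfigurationError("ligand pocket must lie outside the mobile domain")


@dataclass
class GroundTruth:
    """Planted truth echoed from the spec, keyed by generated identifiers."""

    true_coupled_pairs: dict                 # condition -> [(frag_id_i, frag_id_j, c)]
    true_mobile_residues: list
    true_hinge_residues: list
    true_stabilised_contacts: list           # [(resnum_i, resnum_j)]
    replica_seeds: dict                      # condition -> [seed ints]
    fragment_ids: list
    states: dict = field(default_factory=dict, repr=False)  # condition -> [(F, B) arrays]

    def to_json(self, path) -> None:
        payload = {k: v for k, v in asdict(self).items() if k != "states"}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _layout(spec: SyntheticSpec):
    """Per-block base origin and orientation.

    Blocks lie on a serpentine grid; blocks that host the partner residue of
    a rigidify pair are lifted out of the sheet (pitched by
    ``PARTNER_ROTATION``) with their anchor residue at the OFF distance from
    the pair residue along ``CONTACT_AXIS``.
    """
    extent = max(np.ptp(t, axis=0).max() for t in STATE_TEMPLATES)
    pitch_x = extent + 7.0
    pitch_y = 13.0
    origins = np.zeros((spec.n_blocks, 3))
    rotations = np.tile(np.eye(3), (spec.n_blocks, 1, 1))
    for b in range(spec.n_blocks):
        row, col = divmod(b, spec.blocks_per_row)
        origins[b] = (col * pitch_x, row * pitch_y, 2.0 * (row % 2))
    for ri, rj in spec.rigidify_pairs:
        bi, bj = spec.block_of_residue(ri), spec.block_of_residue(rj)
        pi = (int(ri) - 1) % NUMBERING_STRIDE
        pj = (int(rj) - 1) % NUMBERING_STRIDE
        rotations[bj] = PARTNER_ROTATION
        base_i = origins[bi] + rotations[bi] @ STATE_TEMPLATES[0][pi]
        target_rj = base_i + CONTACT_OFF_DISTANCE * CONTACT_AXIS
        origins[bj] = target_rj - PARTNER_ROTATION @ STATE_TEMPLATES[0][pj]
    return origins, rotations


def _base_positions(spec: SyntheticSpec, origins: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    """Base (state-0 template) coordinates for every residue."""
    pos = np.empty((spec.n_blocks, BLOCK, 3))
    for b in range(spec.n_blocks):
        pos[b] = origins[b] + STATE_TEMPLATES[0] @ rotations[b].T
    return pos.reshape(-1, 3)


def _simulate_states(spec: SyntheticSpec, couplings: list, rng: np.random.Generator) -> np.ndarray:
    """Per-frame two-state sequences for every block (F, B)."""
    f, b = spec.n_frames, spec.n_blocks
    parents = {int(j): (int(i), float(c)) for i, j, c in couplings}
    states = np.empty((f, b), dtype=np.uint8)
    done = [False] * b
    # roots first (independent Markov chains), then children in waves
    for blk in range(b):
        if blk not in parents:
            s0 = rng.integers(0, 2, dtype=np.uint8)
            flips = (rng.random(f - 1) < spec.switch_prob).astype(np.uint8)
            seq = np.concatenate([[s0], flips])
            states[:, blk] = np.bitwise_xor.accumulate(seq)
            done[blk] = True
    remaining = [blk for blk in range(b) if not done[blk]]
    guard = 0
    while remaining:
        guard += 1
        if guard > b + 1:
            raise ConfigurationError("coupling definitions contain a cycle")
        still = []
        for blk in remaining:
            parent, c = parents[blk]
            if done[parent]:
                disagree = (rng.random(f) >= (1.0 + c) / 2.0).astype(np.uint8)
                states[:, blk] = states[:, parent] ^ disagree
                done[blk] = True
            else:
                still.append(blk)
        remaining = still
    return states


def _rodrigues(coords: np.ndarray, axis_point: np.ndarray, axis: np.ndarray,
               angles_rad: np.ndarray) -> np.ndarray:
    """Rotate (F, A, 3) coords about a fixed axis by per-frame angles."""
    k = axis / np.linalg.norm(axis)
    v = coords - axis_point
    cos = np.cos(angles_rad)[:, None, None]
    sin = np.sin(angles_rad)[:, None, None]
    kxv = np.cross(np.broadcast_to(k, v.shape), v)
    kdotv = np.sum(v * k, axis=-1, keepdims=True)
    rot = v * cos + kxv * sin + k * kdotv * (1.0 - cos)
    return rot + axis_point


def _build_replica(spec: SyntheticSpec, condition: str, replica: int):
    """Pre-noise coordinates, states and the replica's random stream."""
    spec.validate()
    if condition not in ("apo", "bound"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    cond_idx = 0 if condition == "apo" else 1
    ss = np.random.SeedSequence(spec.seed, spawn_key=(cond_idx, int(replica)))
    rng = np.random.default_rng(ss)

    couplings = list(spec.coupled_pairs)
    if condition == "bound":
        couplings += list(spec.bound_extra_couplings)
    states = _simulate_states(spec, couplings, rng)

    origins, rotations = _layout(spec)
    f, b = spec.n_frames, spec.n_blocks
    coords = np.empty((f, b * BLOCK, 3))
    for blk in range(b):
        sl = slice(blk * BLOCK, (blk + 1) * BLOCK)
        for s in (0, 1):
            m = states[:, blk] == s
            coords[m, sl, :] = origins[blk] + STATE_TEMPLATES[s] @ rotations[blk].T

    # planted contact changes: translate the partner block along the
    # pair axis so the residue-residue distance is ON or OFF exactly
    freq = spec.rigidify_freq_bound if condition == "bound" else spec.rigidify_freq_apo
    resnums = spec.residue_numbers()
    index_of = {int(r): i for i, r in enumerate(resnums)}
    for ri, rj in spec.rigidify_pairs:
        ai, aj = index_of[int(ri)], index_of[int(rj)]
        bj = spec.block_of_residue(rj)
        sl = slice(bj * BLOCK, (bj + 1) * BLOCK)
        on = rng.random(f) < freq
        target = np.where(on, CONTACT_ON_DISTANCE, CONTACT_OFF_DISTANCE)
        shift = (coords[:, ai, :] + target[:, None] * CONTACT_AXIS) - coords[:, aj, :]
        coords[:, sl, :] += shift[:, None, :]

    # hinge motion of the mobile domain
    if spec.mobile_domain is not None:
        lo, hi = spec.mobile_domain
        mobile_idx = np.array([i for i, r in enumerate(resnums) if lo <= r <= hi])
        amp = spec.hinge_amplitude_apo if condition == "apo" else spec.hinge_amplitude_bound
        angles = np.radians(rng.normal(0.0, amp, size=f)) if amp > 0 else np.zeros(f)
        base = _base_positions(spec, origins, rotations)
        p1 = base[index_of[int(spec.hinge_residues[0])]]
        p2 = base[index_of[int(spec.hinge_residues[1])]]
        coords[:, mobile_idx, :] = _rodrigues(coords[:, mobile_idx, :], p1, p2 - p1, angles)

    return coords, states, rng


def generate_replica(spec: SyntheticSpec, condition: str, replica: int):
    """One replica ensemble for one condition; returns (ensemble, states).

    Deterministic: the random stream is keyed on (spec.seed, condition,
    replica).  Conditions differ by their hinge amplitude, planted contact
    occupancy and (optionally) extra couplings; replicas only by the stream.
    """
    coords, states, rng = _build_replica(spec, condition, replica)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)

    resnums = spec.residue_numbers()
    meta = pd.DataFrame({
        "residue_number": resnums,
        "residue_name": "ALA",
        "atom_name": "CA",
        "chain_id": "A",
        "element": "C",
    })
    ens = CoordinateEnsemble(coords=coords, atom_meta=meta,
                             frame_spacing_ps=spec.frame_spacing_ps,
                             label=f"{condition}{replica + 1}")
    return ens, states


def generate_two_state_system(spec: SyntheticSpec):
    """All replicas of both conditions plus the planted ground truth."""
    spec.validate()
    ensembles: dict[str, list[CoordinateEnsemble]] = {}
    states: dict[str, list[np.ndarray]] = {}
    seeds: dict[str, list[int]] = {}
    for cond_idx, condition in enumerate(("apo", "bound")):
        ensembles[condition], states[condition], seeds[condition] = [], [], []
        for rep in range(spec.n_replicas_per_condition):
            ens, st = generate_replica(spec, condition, rep)
            ensembles[condition].append(ens)
            states[condition].append(st)
            seeds[condition].append(int(np.random.SeedSequence(
                spec.seed, spawn_key=(cond_idx, rep)).generate_state(1)[0]))
    fid = spec.fragment_id
    truth = GroundTruth(
        true_coupled_pairs={
            "apo": [(fid(i), fid(j), c) for i, j, c in spec.coupled_pairs],
            "bound": [(fid(i), fid(j), c) for i, j, c in
                      list(spec.coupled_pairs) + list(spec.bound_extra_couplings)],
        },
        true_mobile_residues=(
            [int(r) for r in spec.residue_numbers()
             if spec.mobile_domain and spec.mobile_domain[0] <= r <= spec.mobile_domain[1]]),
        true_hinge_residues=list(spec.hinge_residues) if spec.hinge_residues else [],
        true_stabilised_contacts=[(int(a), int(b)) for a, b in spec.rigidify_pairs],
        replica_seeds=seeds,
        fragment_ids=[fid(b) for b in range(spec.n_blocks)],
        states=states,
    )
    return ensembles, truth


def generate_ligand_fixture(spec: SyntheticSpec, occupancy: float,
                            condition: str = "bound", replica: int = 0) -> CoordinateEnsemble:
    """Toy ligand trajectory: one atom per pocket residue.

    In exactly ``round(occupancy * n_frames)`` frames (chosen at random but
    deterministically) every ligand atom sits 2.5 Å above its pocket residue's
    (pre-noise) position in the matching protein replica (< 4 Å contact); in
    all other frames the ligand is displaced 30 Å out of the pocket (> 6 Å
    from every pocket residue).
    """
    spec.validate()
    if not spec.ligand_pocket_residues:
        raise ConfigurationError("spec has no ligand_pocket_residues")
    if not 0.0 <= occupancy <= 1.0:
        raise ConfigurationError("occupancy must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(9,)))
    f = spec.n_frames
    n_contact = int(round(occupancy * f))
    contact_frames = np.sort(rng.permutation(f)[:n_contact])
    protein_coords, _, _ = _build_replica(spec, condition, replica)
    resnums = spec.residue_numbers()
    index_of = {int(r): i for i, r in enumerate(resnums)}
    pocket_idx = [index_of[int(r)] for r in spec.ligand_pocket_residues]
    anchors = protein_coords[:, pocket_idx, :]            # (F, P, 3)
    coords = anchors + np.array([0.0, 0.0, 30.0])
    coords[contact_frames] = anchors[contact_frames] + np.array([0.0, 0.0, 2.5])
    elements = ["C", "N", "O"]
    n = len(spec.ligand_pocket_residues)
    meta = pd.DataFrame({
        "residue_number": [900] * n,
        "residue_name": "LIG",
        "atom_name": [f"L{i + 1}" for i in range(n)],
        "chain_id": "X",
        "element": [elements[i % 3] for i in range(n)],
    })
    return CoordinateEnsemble(coords=coords, atom_meta=meta,
                              frame_spacing_ps=spec.frame_spacing_ps, label="ligand")


def default_spec(seed: int = 0, n_frames: int = 2000,
                 n_replicas: int = 4) -> SyntheticSpec:
    """Default two-condition preset with planted signal of every kind.

    24 blocks in 4 rows of 6.  Block 2 is the "pocket" (source) fragment; a
    chain of moderate couplings (c = 0.6) around it exists in both conditions,
    and the bound condition adds strong couplings (c = 0.9) from the pocket to
    five distant "functional" blocks.  Two residue pairs are rigidified in
    the bound condition, and the last row is a mobile domain whose hinge
    rotation is damped from 12° (apo) to 2° (bound).
    """
    return SyntheticSpec(
        n_residues=96,
        n_replicas_per_condition=n_replicas,
        n_frames=n_frames,
        coupled_pairs=[(2, 1, 0.6), (1, 0, 0.6), (2, 3, 0.6), (3, 4, 0.6)],
        bound_extra_couplings=[(2, 8, 0.9), (2, 9, 0.9), (2, 10, 0.9),
                               (2, 14, 0.9), (2, 15, 0.9)],
        mobile_domain=(91, 119),
        hinge_residues=(81, 89),
        rigidify_pairs=[(34, 61), (39, 66)],
        ligand_pocket_residues=[11, 12, 13, 14],
        seed=seed,
    )


def independent_spec(seed: int = 0, n_blocks: int = 40, n_frames: int = 2000,
                     n_replicas: int = 1) -> SyntheticSpec:
    """Fully independent system: no couplings, no hinge, no planted contacts.

    Used for significance-filter calibration: every mutual-information edge
    that survives filtering is, by construction, a false positive.
    """
    return SyntheticSpec(
        n_residues=n_blocks * BLOCK,
        n_replicas_per_condition=n_replicas,
        n_frames=n_frames,
        seed=seed,
    )
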