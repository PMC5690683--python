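# Methods

`mdnets` compares the dynamics of a protein sampled in two conditions
(conventionally "apo" and "bound") across replicated trajectories, at four
levels: local backbone-state correlations (structural-alphabet mutual
information networks), preferential network connection to a source site
(ζ profiles), global displacement correlations (block-averaged DCCM), and
inter-residue contact rearrangements (contact-change networks and paths).
This note documents the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic validation system does and does
not establish.

## Structural-alphabet encoding

A structural alphabet is a library of prototypical conformations of fragments
of 4 consecutive Cα atoms, each labelled with a letter.  A Cα trajectory is
encoded by assigning every overlapping 4-residue fragment, in every frame, the
letter of the prototype with minimal RMSD after optimal (Kabsch) superposition;
ties are broken by library order, so encoding is deterministic.  Fragments are
never built across chain breaks, jumps in author residue numbering, or
residues explicitly excluded (e.g. modelled loops); fragments are labelled by
the author residue number of their first residue.

Best-fit RMSD was chosen as the assignment metric (rather than an
internal-coordinate distance) because it is invariant under global rigid
motion by construction; the metric is isolated in one kernel so an alternative
can be swapped in.

The default library name `M32K25` resolves to a packaged **synthetic
stand-in**: the published 25-letter alphabet's prototype coordinates are not
redistributed with this package, so `data/m32k25_synthetic.txt` provides 25
distinct 4-point prototypes on a 5×5 grid of pseudo-bond-angle (88–144°) and
pseudo-torsion (−160° to 100°) values with 3.8 Å virtual Cα–Cα bonds, spanning
the helical-to-extended range.  Nearest-neighbour prototype separations are
0.28–0.62 Å, so assignments are stable against coordinate noise well above
typical encoding noise levels.  Any user library in the same plain-text format
(`>letter` header, four `x y z` lines) can be supplied instead; conclusions
about *which* letter a fragment adopts depend on the library, but all
downstream statistics only use letter identities.

## Normalized mutual information

For two fragments with letter sequences X, Y over N frames, the package
computes the plug-in mutual information I(X;Y) from the joint letter
histogram and normalizes by the joint entropy:

    nMI(X,Y) = clamp( (I(X;Y) − ε) / H(X,Y), 0, 1 )

with the Roulston finite-sampling bias correction
ε = (B_XY − B_X − B_Y + 1) / (2N) nats, where B counts occupied histogram
bins.  Joint-entropy normalization keeps nMI in [0,1] and makes nMI(X,X) = 1
for non-constant X.  The correction can be slightly negative (e.g. a
perfectly coupled two-letter pair has B_XY − B_X − B_Y + 1 = −1), hence the
upper clamp.  Constant (zero-entropy) fragments carry no information; their
rows are zero and they are recorded in the matrix provenance.  The
normalization lives in one function (`nmi_from_counts`) so a different
convention (e.g. min-entropy normalization) is a one-line swap.

## Significance filtering

Each off-diagonal nMI entry is tested against a randomised background in
which each fragment's frame order is randomised independently, destroying
inter-fragment correlation while preserving letter composition.  Two null
models are provided:

* **Circular shift (default).**  Each column is rotated by an independent
  uniform random offset.  This preserves each fragment's temporal
  autocorrelation.  Letter sequences from trajectories are strongly
  autocorrelated (a fragment's state persists over many consecutive frames),
  and under full permutation the background MI between two independent,
  slowly switching fragments is systematically *lower* than the MI they reach
  by chance, making the test anti-conservative.  Measured on independent
  two-state chains with per-frame switch probability 0.1 (N = 2000, α = 0.01,
  Benjamini–Hochberg), the permutation null retains ~13% of null edges; the
  circular-shift null retains ~0.1%.
* **Full permutation** (`null_model="permute"`), the classical
  exchangeable-frames null, kept for sequences without temporal structure.

By default the background pools `n_samples` (default 1000) values across
randomly chosen fragment pairs — one randomised pair per sample — which keeps
the cost linear in `n_samples` rather than quadratic in fragments; this is
accurate when fragments have comparable letter-composition entropy, as they
do both in the synthetic systems and in a homogeneously sampled protein.  An
exact per-pair background is available (`per_pair=True`) for small systems.
The p-value is the fraction of background values ≥ observed (so a value
exceeding the whole background gets p = 0), p-values are Benjamini–Hochberg
adjusted over all pairs, and entries with adjusted p ≥ α (default 0.01) are
zeroed.

## Replica consensus

Per-condition matrices (filtered nMI, contact frequencies) are combined into
a consensus: entry (i,j) is the mean over replicas when it is nonzero in at
least `min_support` of them, else 0.  The default `min_support = ⌈n/2⌉ + 1`
(3 of 4 replicas) keeps only reproducible signal; with a single replica it is
clamped to 1 with a warning.

## Networks, ζ and paths

A matrix with entries s ∈ [0,1] becomes a weighted undirected graph with an
edge per nonzero off-diagonal entry, strength s, and path weight
w = max(1 − s, 10⁻⁶), so strong correlations are short distances; −log(s) is
available as an alternative transform (the choice is a convention, not a
result of the analysis, and both are monotone).

For a source fragment, network distances d_i are weighted shortest-path
(Dijkstra) distances and the preferential-connection score is

    ζ_i = min(0, d_i − ⟨d⟩),

where ⟨d⟩ averages the finite distances over all nodes except the source.
Negative ζ marks nodes closer to the source than average; nodes at or beyond
the mean, and disconnected nodes, carry ζ = 0 ("no preferential connection").
Disconnected nodes are excluded from ⟨d⟩.  The unclamped deviations
d_i − ⟨d⟩ are also retained so a different clamping or normalisation
convention can be recovered.  Δζ = ζ(bound) − ζ(apo) per node; negative Δζ
means the bound state is more preferentially connected to the source.  ζ is
computed from a single source node; a minimum-over-source-set variant can be
obtained by adding a pseudo-node, but profiles for grouped binding-site
fragments are reported per fragment.

Single shortest paths, k-shortest loopless paths (Yen, default k = 5) and
per-node traversal counts (hub scores) come from the same graph; equal-cost
ties are broken by the lexicographically smallest node sequence for
determinism across platforms.  Node degeneracy of a residue set is the
fraction of paths containing at least one member, with optional
fragment-span matching (a fragment node labelled by its first residue covers
four residues).

## DCCM

The dynamical cross-correlation matrix on Cα atoms is computed per
consecutive time block: frames are fit to the block-mean structure (fitting
is optional; with `fit_selection=None` raw displacements are used, which is
also what the trivial limits — all-atom co-translation giving C ≡ 1 —
assume), displacement covariances are normalized to
C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩), and the final matrix is the unweighted
mean over full blocks; a trailing partial block is dropped.  Difference
matrices ΔDCCM = bound − apo are computed per replica pairing (replica r of
each condition, matched by position) and thresholded at |Δ| > 0.16 by
default.  Zero-variance atoms get zero off-diagonal correlation and unit
diagonal.

## Contacts

Two residues are in contact in a frame when the minimum distance over their
non-hydrogen atom pairs is < 4 Å; frequencies are fractions of frames.
Sequence neighbours (|i−j| ≤ 2, same chain) are excluded to remove trivially
permanent backbone contacts.  Threshold wording is followed literally:
"at least 70%" (stable contacts) and "at least 50%" (hydrophobic fingerprint)
are inclusive ≥; "larger than 0.1/0.5" (contact change, fingerprint labels)
are strict >.  The contact-change network is |Δf| = |f_bound − f_apo| of the
consensus matrices with entries ≤ 0.1 zeroed (the signed matrix is kept
alongside), and is analysed with the shared 1 − s transform and top-k paths.

Hydrogen bonds use donor–acceptor heavy-atom (N/O/S) distance < 3.5 Å plus a
donor–H···acceptor angle > 120° when explicit hydrogens are present; without
explicit hydrogens the distance criterion alone applies (the common
heavy-atom criterion).  Idealized hydrogen reconstruction was deliberately
not implemented: the typical inputs here are Cα or heavy-atom trajectories,
and a guessed proton position adds model error without changing the
frequency estimates the fingerprints need.

## Geometry

RMSF uses the iteratively refitted average structure as reference (fit to the
running mean until it moves < 10⁻⁶ Å, max 10 iterations) — the use of an
average-structure reference is fixed; the iteration is this package's
procedure.  PCA diagonalises the unweighted covariance of fitted Cα
coordinates about their mean (no mass weighting — the standard choice for Cα
covariance analysis); `combine_window_ps` restricts the covariance to each
trajectory's trailing window, emulating pooled late-trajectory analyses.
Conformational clustering is GROMOS-style: iteratively take the frame with
most neighbours within a pairwise superposed-RMSD cutoff (default 1.0 Å for
ligands; the cutoff is exposed) as a representative, remove the cluster,
repeat.

## Synthetic validation system

The generator builds a chain of rigid 4-residue blocks on a serpentine grid
(one numbering gap between blocks, so each block is exactly one
structural-alphabet fragment and blocks are statistically independent unless
coupled).  Signal is planted as follows, with defaults chosen to be
comfortably detectable at desk scale yet far from trivial:

* **Local couplings.**  Each block switches between two fixed local
  conformations (internal RMSD 1.49 Å, each equal to a library prototype) as
  a two-state Markov chain with per-frame switch probability 0.1; a coupled
  pair (coupling c) draws the follower's state with P(same) = (1+c)/2 per
  frame.  The default comparison plants a c = 0.6 backbone present in both
  conditions and five c = 0.9 couplings from the "pocket" fragment that exist
  only in the bound condition.
* **Hinge motion.**  A mobile domain (the last row of blocks) rotates rigidly
  (Rodrigues) about an axis through two hinge residues by a per-frame
  N(0, amplitude) angle; amplitudes default to 12° (apo) vs 2° (bound),
  planting the rigidification signal read out by RMSF and DCCM.
* **Contact changes.**  A rigidified pair holds its two residues at exactly
  3.5 Å ("on") or 8.0 Å ("off"), with on-fractions 0.40 (apo) vs 0.95
  (bound), i.e. a planted |Δf| ≈ 0.55.  The partner block is pitched 60° out
  of the sheet and approaches along a tilted axis so that *no other* atom
  pair can cross the 4 Å cutoff in any state combination (verified margin
  > 5.5 Å) — the change network contains exactly the planted edges.
* **Noise and replicas.**  Isotropic Gaussian noise (default 0.1 Å per
  coordinate) is added last; replicas differ only by their random stream,
  keyed on (seed, condition, replica), so everything is bit-reproducible.
* **Ligand.**  A toy ligand (one atom per pocket residue, 2.5 Å above the
  pocket in contact frames, 30 Å away otherwise) occupies the pocket in
  exactly `round(occupancy × n_frames)` frames, making fingerprint
  frequencies exact by construction.

Default problem sizes — 24 blocks (96 residues), 2000 frames at 1 ps spacing,
4 replicas per condition — are the package's desk-scale emulation of a
replicated simulation study; the full default comparison runs in a few
minutes on one CPU.

**What passing these tests shows — and what it does not.**  The synthetic
system validates the statistics (calibration of the significance filter,
recovery of planted couplings and contacts, exactness of ζ/path machinery and
of the geometric estimators) under known ground truth.  It does not emulate a
force field, solvent, anisotropic or correlated noise, letter distributions
over more than a few effective states, gradual conformational drift, or
coupling between local states and large-scale motion; real trajectories will
show weaker, noisier signal and letter statistics with higher entropy, so
real-data thresholds (α, consensus support, ΔDCCM and contact-change cutoffs)
deserve sensitivity checks rather than blind reuse.

## Numerical conventions and degenerate inputs

* Superposition is Kabsch SVD with reflection correction; collinear fit sets
  raise an error.  Batched minimal RMSD uses the singular-value identity
  n·rmsd² = G_x + G_y − 2(σ₁+σ₂+sign(det H)σ₃).
* PDB round-trips preserve coordinates to the format's 3 decimal places and
  metadata verbatim (author residue numbering is never re-indexed).
* Strides subsample frames and scale the frame spacing; a stride longer than
  the trajectory leaves the first frame.
* The pipeline's significance-filter stream is keyed on (seed, replica index)
  and *not* on the condition, so identical trajectories fed as both
  conditions produce exactly zero Δζ, no ΔDCCM edges and an empty
  contact-change network.
* Empty selections, mismatched atom sets, label/kind mismatches, and
  configuration errors raise typed exceptions naming the offending input; a
  disconnected ζ source is a degenerate-profile error, while unreachable path
  targets are reported, not raised.

## Known limitations

* The packaged M32K25-named library is a synthetic stand-in (above); encode
  against the published alphabet by supplying its coordinates as a file.
* The pooled significance background assumes roughly homogeneous fragment
  entropies; use `per_pair=True` when fragments differ wildly (e.g. mixed
  rigid/disordered segments).
* DCCM fitting, when enabled, uses the block-mean reference with a fixed
  small number of refit iterations; long blocks with large rigid-body drift
  should be pre-aligned.
* Hydrogen-bond detection does not reconstruct missing hydrogens.
* Binary trajectory reading requires mdtraj and supports XTC/DCD/TRR.
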