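# mdnets

Comparative correlation-network analysis of molecular dynamics trajectories.

`mdnets` is for structural bioinformaticians who have replicated MD
trajectories of a protein in two conditions — typically apo vs. ligand-bound —
and want to quantify how binding rewires the protein's dynamics: which local
backbone motions become correlated, which regions become preferentially
connected to the binding site, how global displacement correlations and
inter-residue contacts change, and along which residue chains those changes
propagate.

## What it computes

* **Structural-alphabet MI networks.**  Cα trajectories are encoded as letter
  sequences over a library of prototypical 4-residue fragment conformations
  (25-letter `M32K25`-style alphabet by default; bring your own library).
  Local correlation between fragments X and Y is scored as normalized mutual
  information, nMI = clamp((I(X;Y) − ε)/H(X,Y), 0, 1), with a finite-sampling
  bias correction ε and significance assessed against a 1000-sample
  randomised background with Benjamini–Hochberg control.  Replica networks
  are merged into a consensus (entries supported by ≥ 3 of 4 replicas by
  default).
* **Preferential connection (ζ).**  On the consensus network with edge
  weights w = 1 − nMI, ζ_i = min(0, d_i − ⟨d⟩) measures how much closer node
  i is to a source fragment than the average node; Δζ = ζ_bound − ζ_apo < 0
  flags regions whose connection to the source strengthens upon binding.
  Shortest and k-shortest (Yen, k = 5) paths and per-node traversal counts
  identify the communication routes and hubs.
* **ΔDCCM.**  Block-averaged dynamical cross-correlation matrices
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) per replica, differenced between
  conditions and thresholded (|Δ| > 0.16 by default).
* **Contact-change networks.**  Residue contact frequencies (min heavy-atom
  distance < 4 Å), per-condition consensus, stable contacts (≥ 70%), ligand
  contact/H-bond/hydrophobic fingerprints, and the |bound − apo|
  contact-change network (changes > 0.1) analysed with top-k paths.
* **Geometry.**  RMSF about the iteratively fitted average structure, RMSD
  series, bend angles, Cα PCA (optionally on trailing windows of combined
  trajectories), and GROMOS-style conformational clustering.
* **Synthetic two-condition generator.**  A toy system with planted local
  couplings, a damped hinge domain, stabilised contacts and a pocket ligand,
  so every stage can be validated against known ground truth.

## Worked example

Generate a small synthetic two-condition study (2 replicas × 600 frames per
condition; the bound state adds strong couplings from the pocket fragment 11
to fragments 41–76, stabilises two contacts and damps the hinge), then run
the full comparison:

```bash
mdnets simulate --preset default --n-frames 600 --n-replicas 2 --seed 7 --out demo
mdnets compare --config demo/config.yaml
```

```
wrote 4 replicas and demo/config.yaml
wrote 18 output files to demo/results
```

`demo/results/delta_zeta_src11.tsv` holds the Δζ profile from source
fragment 11.  The five fragments planted as newly coupled to the pocket in
the bound state all come out negative — preferentially connected upon
binding — while unrelated fragments sit at 0 or drift positive:

```
fragment  delta_zeta
41        -0.0711514
46        -0.078305
51        -0.0156882
71        -0.1108
76        -0.0654766
```

`demo/results/paths.json` contains the contact-change paths; here the planted
stabilised contact is recovered as the direct route
`34 → 61` with path length 0.466 (= 1 − |Δf|, so |Δf| ≈ 0.53 against a
planted on-fraction change of 0.95 − 0.40 = 0.55).  Per-replica RMSF tables
(`rmsf_<condition>_<replica>.tsv`), consensus nMI/contact matrices, stable
contacts and ΔDCCM edge lists are written alongside.

The same operations are available as a library:

```python
from mdnets import (default_spec, generate_two_state_system, encode,
                    load_fragment_library, mutual_information_matrix,
                    significance_filter, build_graph, zeta_scores)

ens, truth = generate_two_state_system(default_spec(seed=7))
enc = encode(ens["bound"][0], load_fragment_library())
mi = mutual_information_matrix(enc)
filtered, pvalues = significance_filter(mi, enc, n_samples=1000, alpha=0.01)
profile = zeta_scores(build_graph(filtered), source=11)
```

## Documentation

`docs/methods.md` describes the models and statistics in detail — the nMI
normalization and bias correction, the circular-shift null model and why it
replaces full permutation for autocorrelated letter sequences, consensus and
threshold conventions, the ζ definition and tie-breaking rules, what the
synthetic generator does and does not emulate, and known limitations
(including that the packaged 25-letter library is a synthetic stand-in, not
the published alphabet's coordinates).
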