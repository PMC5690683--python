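"""End-to-end two-condition comparison pipeline.

Runs, per condition and replica: structural-alphabet encoding -> normalized
mutual information -> permutation significance filtering -> replica consensus;
residue contact frequencies -> consensus; then across conditions: Δζ
preferential-connection profiles per configured source fragment, difference
DCCM edge lists per replica pairing (replica r of the bound condition against
replica r of the apo one, matched by position/label suffix), the
|bound - apo| contact-change network with top-k paths, and per-replica
geometry (RMSF, optional bend angle, combined PCA).

The permutation-filter random stream is keyed on (seed, replica index) and is
identical across conditions, so feeding the same trajectories as both
conditions yields exactly zero differences everywhere — the pipeline's null
is clean by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import correlations, contacts, geometry, networks
from .alphabet import encode, load_fragment_library
from .exceptions import ConfigurationError, DegenerateProfileError
from .trajectory_io import CALPHA, CoordinateEnsemble, read_binary_trajectory, read_multimodel_pdb

__all__ = ["RunConfig", "RunReport", "run_compare", "load_config"]


@dataclass
class ReplicaSource:
    label: str
    pdb: str | None = None
    topology: str | None = None
    trajectory: str | None = None
    stride: int = 1


@dataclass
class RunConfig:
    """Everything a comparison run needs; YAML-serialisable."""

    replicas: dict = field(default_factory=dict)        # condition -> [ReplicaSource]
    source_fragments: list = field(default_factory=list)
    functional_targets: list = field(default_factory=list)
    change_source_residue: object = None
    change_target_residues: list = field(default_factory=list)
    exclude_residues: list = field(default_factory=list)
    bend_triplet: list | None = None
    library: str = "M32K25"
    sa_stride: int = 1
    geometry_stride: int = 1
    mi_alpha: float = 0.01
    n_shuffles: int = 1000
    dccm_block_ps: float | None = None
    ddccm_threshold: float = 0.16
    contact_cutoff: float = 4.0
    stable_contact_freq: float = 0.7
    contact_change_min: float = 0.1
    k_paths: int = 5
    consensus_min_support: int | None = None
    combine_window_ps: float | None = None
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if not 0 < self.mi_alpha < 1:
            raise ConfigurationError("mi_alpha must lie in (0, 1)")
        for name in ("ddccm_threshold", "contact_cutoff", "stable_contact_freq",
                     "contact_change_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.k_paths < 1:
            raise ConfigurationError("k_paths must be >= 1")
        if self.sa_stride < 1 or self.geometry_stride < 1:
            raise ConfigurationError("strides must be >= 1")


_CONFIG_KEYS = {f for f in RunConfig.__dataclass_fields__}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    replicas = {}
    for cond, items in (raw.pop("replicas", {}) or {}).items():
        replicas[cond] = [ReplicaSource(**item) for item in items]
    cfg = RunConfig(replicas=replicas, **raw)
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    """In-memory results of a comparison run (also written to output_dir)."""

    rmsf: dict = field(default_factory=dict)            # (condition, label) -> array
    rmsf_residues: dict = field(default_factory=dict)
    bend_angles: dict = field(default_factory=dict)
    pca_variance_fractions: np.ndarray | None = None
    consensus_nmi: dict = field(default_factory=dict)   # condition -> LabeledMatrix
    filtered_nmi: dict = field(default_factory=dict)    # condition -> [LabeledMatrix]
    zeta: dict = field(default_factory=dict)            # (condition, source) -> ZetaProfile
    delta_zeta: dict = field(default_factory=dict)      # source -> {node: Δζ}
    mi_paths: dict = field(default_factory=dict)        # (condition, source) -> PathSet
    ddccm_edges: dict = field(default_factory=dict)     # pairing label -> edge list
    consensus_contacts: dict = field(default_factory=dict)
    stable_contact_edges: dict = field(default_factory=dict)
    change_matrix: object = None
    change_paths: object = None
    provenance: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)


def _load_replica(src: ReplicaSource) -> CoordinateEnsemble:
    if src.pdb:
        ens = read_multimodel_pdb(src.pdb)
        if src.stride > 1:
            ens = ens.subset_frames(range(0, ens.n_frames, src.stride))
        ens.label = src.label
        return ens
    if src.topology and src.trajectory:
        return read_binary_trajectory(src.topology, src.trajectory, stride=src.stride,
                                      label=src.label)
    raise ConfigurationError(f"replica {src.label!r} needs either 'pdb' or "
                             "'topology' + 'trajectory'")


def _stride(ens: CoordinateEnsemble, stride: int) -> CoordinateEnsemble:
    if stride <= 1:
        return ens
    out = ens.subset_frames(range(0, ens.n_frames, stride))
    out.frame_spacing_ps = ens.frame_spacing_ps * stride
    return out


def run_compare(config: RunConfig, ensembles: dict[str, list[CoordinateEnsemble]] | None = None) -> RunReport:
    """Execute the full two-condition comparison.

    ``ensembles`` (condition -> replica list) bypasses file loading; otherwise
    replicas are read from the config paths.  Expects exactly two conditions;
    the one named "apo" (or listed first) is the reference subtracted from the
    other.
    """
    config.validate()
    if ensembles is None:
        if not config.replicas:
            raise ConfigurationError("no replicas configured")
        ensembles = {cond: [_load_replica(s) for s in srcs]
                     for cond, srcs in config.replicas.items()}
    conditions = list(ensembles)
    if len(conditions) != 2:
        raise ConfigurationError(f"expected exactly 2 conditions, got {conditions}")
    ref_cond = "apo" if "apo" in conditions else conditions[0]
    alt_cond = next(c for c in conditions if c != ref_cond)
    for cond, reps in ensembles.items():
        if not reps:
            raise ConfigurationError(f"condition {cond!r} has no replicas")

    library = load_fragment_library(config.library)
    report = RunReport()
    report.provenance = {"config": {k: v for k, v in asdict(config).items() if k != "replicas"},
                         "conditions": conditions, "reference": ref_cond}

    dccms: dict = {c: [] for c in conditions}
    contact_mats: dict = {c: [] for c in conditions}
    for cond in conditions:
        filtered = []
        for rep_idx, ens in enumerate(ensembles[cond]):
            sa_ens = _stride(ens, config.sa_stride)
            enc = encode(sa_ens, library, exclude_residues=config.exclude_residues)
            mi = correlations.mutual_information_matrix(enc)
            # filter stream keyed on replica index only: identical across conditions
            filt, _pvals = correlations.significance_filter(
                mi, enc, n_samples=config.n_shuffles, alpha=config.mi_alpha,
                seed=np.random.default_rng(np.random.SeedSequence(
                    config.seed, spawn_key=(rep_idx,))))
            filtered.append(filt)

            geo_ens = _stride(ens, config.geometry_stride)
            report.rmsf[(cond, ens.label)] = geometry.rmsf(geo_ens, CALPHA)
            from .trajectory_io import select
            ca = select(geo_ens, CALPHA)
            report.rmsf_residues[(cond, ens.label)] = [rn for _, rn in ca.residue_ids()]
            if config.bend_triplet:
                report.bend_angles[(cond, ens.label)] = geometry.bend_angle(
                    geo_ens, tuple(config.bend_triplet)).angles
            dccms[cond].append(correlations.dccm(geo_ens, fit_selection=None,
                                                 block_length_ps=config.dccm_block_ps))
            contact_mats[cond].append(contacts.contact_frequency(
                ens, cutoff=config.contact_cutoff))
        report.filtered_nmi[cond] = filtered
        report.consensus_nmi[cond] = correlations.consensus_matrix(
            filtered, min_support=config.consensus_min_support)
        cons_contacts = correlations.consensus_matrix(
            contact_mats[cond], min_support=config.consensus_min_support)
        report.consensus_contacts[cond] = cons_contacts
        report.stable_contact_edges[cond] = contacts.stable_contacts(
            cons_contacts, min_freq=config.stable_contact_freq)

    # ζ / Δζ per source fragment on the consensus MI networks
    graphs = {c: networks.build_graph(report.consensus_nmi[c]) for c in conditions}
    for source in config.source_fragments:
        profiles = {}
        for cond in conditions:
            try:
                profiles[cond] = networks.zeta_scores(graphs[cond], source)
            except DegenerateProfileError:
                warnings.warn(f"source {source!r} disconnected in condition {cond!r}")
                profiles[cond] = None
            report.zeta[(cond, source)] = profiles[cond]
            if profiles[cond] is not None and config.functional_targets:
                report.mi_paths[(cond, source)] = networks.shortest_paths(
                    graphs[cond], source, config.functional_targets)
        if profiles[ref_cond] is not None and profiles[alt_cond] is not None:
            report.delta_zeta[source] = networks.delta_zeta(
                profiles[alt_cond], profiles[ref_cond])

    # ΔDCCM per replica pairing (bound_r vs apo_r)
    for rep_idx, (alt_m, ref_m) in enumerate(zip(dccms[alt_cond], dccms[ref_cond])):
        edges, _delta = correlations.delta_matrix(alt_m, ref_m, threshold=config.ddccm_threshold)
        pairing = f"{alt_m.provenance.get('source')}-vs-{ref_m.provenance.get('source')}"
        report.ddccm_edges[pairing] = edges

    # contact-change network and paths
    change, signed = contacts.contact_change_matrix(
        report.consensus_contacts[alt_cond], report.consensus_contacts[ref_cond],
        min_change=config.contact_change_min)
    report.change_matrix = change
    report.provenance["change_signed_nonzero"] = int(np.count_nonzero(signed.values) // 2)
    if config.change_source_residue is not None and config.change_target_residues \
            and np.any(change.values > 0):
        report.change_paths = contacts.contact_change_paths(
            change, config.change_source_residue, config.change_target_residues,
            k=config.k_paths)

    # combined PCA across all replicas of both conditions
    try:
        pca_res = geometry.pca([_stride(e, config.geometry_stride)
                                for c in conditions for e in ensembles[c]],
                               selection=CALPHA, combine_window_ps=config.combine_window_ps)
        report.pca_variance_fractions = pca_res.variance_fractions
    except Exception as exc:  # heterogeneous replicas: report, do not abort
        warnings.warn(f"combined PCA skipped: {exc}")

    if config.output_dir:
        _write_outputs(report, config)
    return report


def _write_outputs(report: RunReport, config: RunConfig) -> None:
    import os

    out = config.output_dir
    os.makedirs(out, exist_ok=True)

    def _register(path):
        report.manifest.append(path)

    for (cond, label), arr in report.rmsf.items():
        path = os.path.join(out, f"rmsf_{cond}_{label}.tsv")
        with open(path, "w") as fh:
            fh.write("residue\trmsf_A\n")
            for rn, v in zip(report.rmsf_residues[(cond, label)], arr):
                fh.write(f"{rn}\t{v:.6f}\n")
        _register(path)
    for cond, mat in report.consensus_nmi.items():
        path = os.path.join(out, f"consensus_nmi_{cond}.tsv")
        mat.to_tsv(path)
        _register(path)
    for cond, mat in report.consensus_contacts.items():
        path = os.path.join(out, f"consensus_contacts_{cond}.tsv")
        mat.to_tsv(path)
        _register(path)
    for (cond, source), prof in report.zeta.items():
        if prof is None:
            continue
        path = os.path.join(out, f"zeta_{cond}_src{source}.tsv")
        prof.to_tsv(path)
        _register(path)
    for source, dz in report.delta_zeta.items():
        path = os.path.join(out, f"delta_zeta_src{source}.tsv")
        with open(path, "w") as fh:
            fh.write("fragment\tdelta_zeta\n")
            for node, v in dz.items():
                fh.write(f"{node}\t{v:.6g}\n")
        _register(path)
    for pairing, edges in report.ddccm_edges.items():
        path = os.path.join(out, f"ddccm_edges_{pairing}.tsv")
        correlations.write_edge_list(edges, path)
        _register(path)
    for cond, edges in report.stable_contact_edges.items():
        path = os.path.join(out, f"stable_contacts_{cond}.tsv")
        correlations.write_edge_list(edges, path)
        _register(path)
    if report.change_matrix is not None:
        path = os.path.join(out, "contact_change_matrix.tsv")
        report.change_matrix.to_tsv(path)
        _register(path)
    paths_payload = {}
    if report.change_paths is not None:
        paths_payload["contact_change"] = report.change_paths.to_json_dict()
    for (cond, source), ps in report.mi_paths.items():
        paths_payload[f"mi_{cond}_src{source}"] = ps.to_json_dict()
    path = os.path.join(out, "paths.json")
    with open(path, "w") as fh:
        json.dump(paths_payload, fh, indent=2, sort_keys=True)
    _register(path)
    path = os.path.join(out, "report.json")
    with open(path, "w") as fh:
        json.dump({
            "provenance": _jsonable(report.provenance),
            "delta_zeta": {str(s): {str(k): v for k, v in dz.items()}
                           for s, dz in report.delta_zeta.items()},
            "ddccm_edge_counts": {k: len(v) for k, v in report.ddccm_edges.items()},
            "pca_variance_fractions": (report.pca_variance_fractions[:10].tolist()
                                       if report.pca_variance_fractions is not None else None),
        }, fh, indent=2, sort_keys=True)
    _register(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
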