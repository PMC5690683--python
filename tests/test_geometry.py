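import numpy as np
import pytest

from mdnets.exceptions import ContractError, SelectionError
from mdnets.geometry import (bend_angle, cluster_conformations, pairwise_rmsd_matrix,
                             pca, rmsd_series, rmsf, superpose)
from mdnets.trajectory_io import CALPHA, Selection

from conftest import chain_coords, make_ensemble, random_rotation


def quaternion_fit_rmsd(mobile, reference):
    """Independent quaternion-based superposition RMSD (Horn's method)."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    gx = (p ** 2).sum() + (q ** 2).sum()
    return np.sqrt(max(gx - 2 * lam, 0.0) / len(p))


class TestSuperpose:
    def test_identity(self, rng):
        x = rng.normal(size=(6, 3))
        rot, trans, rmsd = superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_exact_rigid_motion_recovered(self, rng):
        ref = rng.normal(size=(8, 3))
        applied = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # 90° about z
        mobile = ref @ applied.T + [1.0, -2.0, 3.0]
        rot, trans, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, applied.T, atol=1e-9)  # inverse of applied

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            ref = rng.normal(size=(10, 3))
            mobile = ref + rng.normal(scale=0.5, size=(10, 3))
            _, _, rmsd = superpose(mobile, ref)
            assert rmsd == pytest.approx(quaternion_fit_rmsd(mobile, ref), abs=1e-10)

    def test_collinear_raises(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ContractError):
            superpose(line, line)


class TestRMSF:
    def test_identical_frames_zero(self, rng):
        frame = chain_coords(10)
        ens = make_ensemble(np.tile(frame, (5, 1, 1)))
        np.testing.assert_allclose(rmsf(ens), 0.0, atol=1e-10)

    def test_two_point_oscillation_without_fit(self):
        frame = chain_coords(12)
        up, down = frame.copy(), frame.copy()
        d = 0.8
        up[5, 0] += d
        down[5, 0] -= d
        ens = make_ensemble(np.stack([up, down]))
        values = rmsf(ens, fit=False)
        assert values[5] == pytest.approx(d, abs=1e-12)
        assert np.all(values[np.arange(12) != 5] < 1e-12)

    def test_gaussian_noise_gives_sigma_sqrt3(self, rng):
        sigma = 0.3
        frame = chain_coords(50)
        ens = make_ensemble(frame[None] + rng.normal(0, sigma, size=(3000, 50, 3)))
        values = rmsf(ens)
        assert values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_single_frame_rejected(self):
        ens = make_ensemble(chain_coords(5)[None])
        with pytest.raises(ContractError):
            rmsf(ens)

    def test_invariance_under_global_rigid_transform(self, rng):
        coords = chain_coords(15)[None] + rng.normal(0, 0.2, size=(40, 15, 3))
        ens = make_ensemble(coords)
        rot = random_rotation(rng)
        moved = make_ensemble(coords @ rot.T + np.array([5.0, -3.0, 9.0]))
        np.testing.assert_allclose(rmsf(ens), rmsf(moved), atol=1e-6)


class TestRmsdSeries:
    def test_reference_frame_zero_and_rigid_copies(self, rng):
        frame = chain_coords(8)
        frames = [frame]
        for _ in range(4):
            frames.append(frame @ random_rotation(rng).T + rng.normal(size=3))
        ens = make_ensemble(np.stack(frames))
        series = rmsd_series(ens)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_fit_and_measure_subsets_match_bruteforce(self, rng):
        from mdnets._superpose import apply_transform, kabsch

        coords = chain_coords(12)[None] + rng.normal(0, 0.5, size=(6, 12, 3))
        ens = make_ensemble(coords)
        fit_sel = Selection(residue_ranges=[(1, 6)])
        meas_sel = Selection(residue_ranges=[(7, 12)])
        series = rmsd_series(ens, fit_selection=fit_sel, measure_selection=meas_sel)
        fit_idx, meas_idx = np.arange(6), np.arange(6, 12)
        for f in range(6):
            rot, trans, _ = kabsch(coords[f, fit_idx], coords[0, fit_idx])
            moved = apply_transform(coords[f, meas_idx], rot, trans)
            expected = np.sqrt(np.mean(np.sum((moved - coords[0, meas_idx]) ** 2, axis=1)))
            assert series[f] == pytest.approx(expected, abs=1e-10)


class TestBendAngle:
    @pytest.mark.parametrize("points,expected", [
        ([(0, 0, 0), (1, 0, 0), (2, 0, 0)], 180.0),
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0)], 90.0),
        ([(1, 0, 0), (0, 0, 0), (np.cos(np.pi / 3), np.sin(np.pi / 3), 0)], 60.0),
    ], ids=["collinear", "right-angle", "sixty"])
    def test_analytic_angles(self, points, expected):
        coords = np.array(points, dtype=float)[None]
        if expected == 90.0:
            triplet = (1, 2, 3)  # angle at residue 2
        elif expected == 60.0:
            triplet = (1, 2, 3)
        else:
            triplet = (1, 2, 3)
        ens = make_ensemble(coords, resnums=[1, 2, 3])
        series = bend_angle(ens, triplet)
        assert series.angles[0] == pytest.approx(expected, abs=1e-10)

    def test_symmetric_under_outer_swap(self, rng):
        ens = make_ensemble(rng.normal(size=(4, 5, 3)))
        a = bend_angle(ens, (1, 3, 5)).angles
        b = bend_angle(ens, (5, 3, 1)).angles
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_missing_calpha_raises(self, rng):
        ens = make_ensemble(rng.normal(size=(1, 3, 3)), atom_names=["CA", "CB", "CA"])
        with pytest.raises(SelectionError):
            bend_angle(ens, (1, 2, 3))


class TestPCA:
    def test_rank_one_motion(self):
        frame = chain_coords(10)
        frames = []
        for a in np.linspace(-1, 1, 20):
            f = frame.copy()
            f[4, 0] += a
            frames.append(f)
        res = pca([make_ensemble(np.stack(frames))], fit=False)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.eigenvalues[1:] < 1e-12)

    def test_duplicated_frames_invariance(self, rng):
        coords = chain_coords(8)[None] + rng.normal(0, 0.3, size=(15, 8, 3))
        res1 = pca([make_ensemble(coords)])
        res2 = pca([make_ensemble(np.concatenate([coords, coords]))])
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-9)
        np.testing.assert_allclose(res1.variance_fractions, res2.variance_fractions, atol=1e-9)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        from mdnets.geometry import average_structure

        coords = chain_coords(6)[None] + rng.normal(0, 0.4, size=(30, 6, 3))
        res = pca([make_ensemble(coords)])
        mean, fitted = average_structure(coords)
        x = (fitted - mean).reshape(30, -1)
        evals = np.sort(np.linalg.eigvalsh((x.T @ x) / 30))[::-1]
        np.testing.assert_allclose(res.eigenvalues, np.maximum(evals, 0), atol=1e-10)

    def test_trace_identity_and_fraction_sum(self, rng):
        coords = chain_coords(7)[None] + rng.normal(0, 0.3, size=(25, 7, 3))
        res = pca([make_ensemble(coords)])
        from mdnets.geometry import average_structure

        mean, fitted = average_structure(coords)
        total_var = np.sum((fitted - mean) ** 2) / 25
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-8)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_combine_window_uses_trailing_frames(self, rng):
        coords = chain_coords(6)[None] + rng.normal(0, 0.2, size=(40, 6, 3))
        full = pca([make_ensemble(coords, spacing=1.0)])
        tail = pca([make_ensemble(coords, spacing=1.0)], combine_window_ps=10.0)
        tail_direct = pca([make_ensemble(coords[30:], spacing=1.0)])
        np.testing.assert_allclose(tail.eigenvalues, tail_direct.eigenvalues, atol=1e-10)
        assert not np.allclose(full.eigenvalues, tail.eigenvalues)


class TestClustering:
    def test_identical_frames_single_cluster(self):
        ens = make_ensemble(np.tile(chain_coords(5), (8, 1, 1)))
        clusters = cluster_conformations(ens, cutoff=1.0)
        assert len(clusters) == 1
        assert clusters[0]["population"] == pytest.approx(1.0)

    def test_two_separated_conformers(self, rng):
        a = chain_coords(5)
        b = a.copy()
        b[3:, 2] += 6.0  # kinked conformer: internal change survives superposition
        frames = [a + rng.normal(0, 0.05, a.shape) for _ in range(6)]
        frames += [b + rng.normal(0, 0.05, a.shape) for _ in range(4)]
        ens = make_ensemble(np.stack(frames))
        clusters = cluster_conformations(ens, cutoff=1.0)
        assert sorted(len(c["members"]) for c in clusters) == [4, 6]
        assert sum(c["population"] for c in clusters) == pytest.approx(1.0)

    def test_matches_bruteforce_neighbour_counting(self, rng):
        coords = chain_coords(6)[None] + rng.normal(0, 0.8, size=(20, 6, 3))
        ens = make_ensemble(coords)
        d = pairwise_rmsd_matrix(coords)
        cutoff = float(np.median(d[d > 0]))
        clusters = cluster_conformations(ens, cutoff=cutoff)
        # independent reimplementation of the GROMOS loop
        nb = d < cutoff
        np.fill_diagonal(nb, True)
        remaining = set(range(20))
        expected = []
        while remaining:
            counts = {i: len([j for j in remaining if nb[i, j]]) for i in remaining}
            rep = min(remaining, key=lambda i: (-counts[i], i))
            members = sorted(j for j in remaining if nb[rep, j])
            expected.append((rep, members))
            remaining -= set(members)
        assert [(c["representative"], c["members"]) for c in clusters] == expected

    def test_invalid_cutoff(self):
        ens = make_ensemble(np.tile(chain_coords(4), (2, 1, 1)))
        with pytest.raises(ContractError):
            cluster_conformations(ens, cutoff=0.0)
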