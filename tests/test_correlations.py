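import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdnets.alphabet import SAEncoding
from mdnets.correlations import (LabeledMatrix, consensus_matrix, dccm, delta_matrix,
                                 mutual_information_matrix, nmi_from_counts,
                                 significance_filter)
from mdnets.exceptions import ContractError

from conftest import chain_coords, make_ensemble


def encoding_from_codes(codes, toy_library, ids=None):
    codes = np.asarray(codes, dtype=np.int16)
    ids = ids or list(range(1, codes.shape[1] + 1))
    return SAEncoding(codes=codes, fragment_ids=ids, library=toy_library)


def plugin_entropies(joint):
    """Independent entropy computation for the oracle tests."""
    n = joint.sum()
    p = joint / n
    px, py = p.sum(1), p.sum(0)
    h = lambda q: -sum(v * np.log(v) for v in q.ravel() if v > 0)
    return h(px), h(py), h(p)


class TestNMI:
    def test_identity_is_one(self, toy_library):
        col = np.array([0, 1, 0, 1, 2, 0, 1, 2] * 50)
        enc = encoding_from_codes(np.stack([col, col], axis=1), toy_library)
        mat = mutual_information_matrix(enc)
        assert mat.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert mat.values[0, 0] == 1.0

    def test_independent_columns_vanish(self, toy_library, rng):
        codes = rng.integers(0, 2, size=(20000, 2))
        mat = mutual_information_matrix(encoding_from_codes(codes, toy_library))
        assert mat.values[0, 1] < 0.01

    def test_exact_joint_table_oracle(self, toy_library):
        # P = [[0.4, 0.1], [0.1, 0.4]] realised exactly at N = 1000
        joint = np.array([[400, 100], [100, 400]])
        x = np.repeat([0, 0, 1, 1], [400, 100, 100, 400])
        y = np.repeat([0, 1, 0, 1], [400, 100, 100, 400])
        mat = mutual_information_matrix(encoding_from_codes(np.stack([x, y], 1), toy_library))
        hx, hy, hxy = plugin_entropies(joint)
        eps = (4 - 2 - 2 + 1) / (2 * 1000)
        expected = max(0.0, (hx + hy - hxy - eps) / hxy)
        assert mat.values[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_constant_column_zeroed_and_recorded(self, toy_library):
        codes = np.stack([np.zeros(100, int), np.arange(100) % 2], axis=1)
        mat = mutual_information_matrix(encoding_from_codes(codes, toy_library))
        assert mat.values[0, 0] == 0.0 and mat.values[0, 1] == 0.0
        assert mat.provenance["constant_fragments"] == [1]

    def test_coarsening_never_increases_information(self, toy_library, rng):
        # merging letters on fixed samples is a data-processing step
        x = rng.integers(0, 3, size=500)
        y = (x + rng.integers(0, 2, size=500)) % 3
        k = 3
        joint = np.zeros((k, k))
        np.add.at(joint, (x, y), 1)
        hx, hy, hxy = plugin_entropies(joint)
        i_full = hx + hy - hxy
        merged = joint.copy()
        merged[:, 1] += merged[:, 2]
        merged = merged[:, :2]
        hx2, hy2, hxy2 = plugin_entropies(merged)
        assert hx2 + hy2 - hxy2 <= i_full + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        joint = rng.integers(0, 50, size=(3, 3))
        if joint.sum() == 0:
            joint[0, 0] = 1
        v = nmi_from_counts(joint)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(nmi_from_counts(joint.T), abs=1e-12)


class TestSignificance:
    def test_perfectly_coupled_pair_retained(self, toy_library, rng):
        x = rng.integers(0, 2, size=2000)
        z = rng.integers(0, 2, size=(2000, 3))
        codes = np.column_stack([x, x, z])
        enc = encoding_from_codes(codes, toy_library)
        mat = mutual_information_matrix(enc)
        filt, pvals = significance_filter(mat, enc, n_samples=1000, alpha=0.01, seed=0)
        assert pvals.values[0, 1] < 1 / 1000
        assert filt.values[0, 1] > 0

    def test_zero_nmi_gets_p_one(self, toy_library):
        codes = np.stack([np.arange(200) % 2, np.zeros(200, int)], axis=1)
        enc = encoding_from_codes(codes, toy_library)
        mat = mutual_information_matrix(enc)
        filt, pvals = significance_filter(mat, enc, n_samples=200, alpha=0.05, seed=1)
        assert pvals.values[0, 1] == 1.0
        assert filt.values[0, 1] == 0.0

    def test_independent_system_mostly_filtered(self, toy_library, rng):
        codes = rng.integers(0, 2, size=(1000, 12))
        enc = encoding_from_codes(codes, toy_library)
        mat = mutual_information_matrix(enc)
        filt, _ = significance_filter(mat, enc, n_samples=500, alpha=0.01, seed=2)
        off = filt.values[np.triu_indices(12, 1)]
        assert np.mean(off > 0) <= 0.05

    def test_per_pair_mode_agrees_on_strong_signal(self, toy_library, rng):
        x = rng.integers(0, 2, size=500)
        codes = np.column_stack([x, x, rng.integers(0, 2, size=500)])
        enc = encoding_from_codes(codes, toy_library)
        mat = mutual_information_matrix(enc)
        filt, _ = significance_filter(mat, enc, n_samples=200, alpha=0.01,
                                      seed=3, per_pair=True)
        assert filt.values[0, 1] > 0 and filt.values[0, 2] == 0.0

    def test_alpha_validation(self, toy_library, rng):
        codes = rng.integers(0, 2, size=(200, 3))
        enc = encoding_from_codes(codes, toy_library)
        mat = mutual_information_matrix(enc)
        with pytest.raises(ContractError):
            significance_filter(mat, enc, alpha=1.5)
        with pytest.raises(ContractError):
            significance_filter(mat, enc, n_samples=10)


class TestDCCM:
    def test_cotranslating_atoms_fully_correlated(self, rng):
        base = chain_coords(5)
        shifts = rng.normal(size=(40, 1, 3))
        ens = make_ensemble(base[None] + shifts)
        mat = dccm(ens)
        np.testing.assert_allclose(mat.values, 1.0, atol=1e-10)

    def test_antiphase_pair_anticorrelated(self):
        frames = []
        for a in np.linspace(-1, 1, 20):
            f = np.array([[0.0, 0, 0], [10.0, 0, 0]])
            f[0, 0] += a
            f[1, 0] -= a
            frames.append(f)
        ens = make_ensemble(np.stack(frames), resnums=[1, 2])
        mat = dccm(ens)
        assert mat.values[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_block_average_equals_per_block_oracle(self, rng):
        coords = chain_coords(5)[None] + rng.normal(0, 0.5, size=(40, 5, 3))
        ens = make_ensemble(coords, spacing=1.0)
        mat = dccm(ens, block_length_ps=20.0)
        acc = np.zeros((5, 5))
        for blk in (coords[:20], coords[20:]):
            delta = blk - blk.mean(axis=0)
            dots = np.einsum("fia,fja->ij", delta, delta) / 20
            acc += dots / np.sqrt(np.outer(np.diag(dots), np.diag(dots)))
        np.testing.assert_allclose(mat.values, acc / 2, atol=1e-10)

    def test_time_reversal_invariance(self, rng):
        coords = chain_coords(4)[None] + rng.normal(0, 0.3, size=(30, 4, 3))
        a = dccm(make_ensemble(coords), block_length_ps=None)
        b = dccm(make_ensemble(coords[::-1]), block_length_ps=None)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_block_longer_than_trajectory_rejected(self, rng):
        ens = make_ensemble(chain_coords(4)[None] + rng.normal(0, 0.1, (10, 4, 3)))
        with pytest.raises(ContractError):
            dccm(ens, block_length_ps=100.0)


class TestConsensusAndDelta:
    def _mat(self, values, kind="nMI"):
        values = np.asarray(values, dtype=float)
        return LabeledMatrix(values=values, labels=list(range(len(values))), kind=kind)

    def test_identical_inputs_reproduced(self, rng):
        v = rng.random((4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        m = self._mat(v)
        cons = consensus_matrix([m, m, m, m])
        np.testing.assert_allclose(cons.values, v, atol=1e-12)

    def test_low_support_entry_dropped(self):
        zero = np.zeros((3, 3))
        one = zero.copy()
        one[0, 1] = one[1, 0] = 0.8
        mats = [self._mat(one), self._mat(zero), self._mat(zero), self._mat(zero)]
        cons = consensus_matrix(mats, min_support=3)
        assert cons.values[0, 1] == 0.0

    def test_mixed_support_matches_counting_oracle(self, rng):
        mats = []
        for _ in range(4):
            v = rng.random((5, 5)) * (rng.random((5, 5)) > 0.5)
            v = np.triu(v, 1)
            v = v + v.T
            mats.append(self._mat(v))
        cons = consensus_matrix(mats, min_support=3)
        stack = np.stack([m.values for m in mats])
        for i in range(5):
            for j in range(5):
                support = int((stack[:, i, j] > 0).sum())
                expected = stack[:, i, j].mean() if support >= 3 else 0.0
                assert cons.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_single_replica_clamps_support_with_warning(self, rng):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.5
        m = self._mat(v)
        with pytest.warns(UserWarning, match="clamped"):
            cons = consensus_matrix([m])
        np.testing.assert_allclose(cons.values, v)

    def test_delta_trivial_cases(self):
        a = self._mat(np.zeros((3, 3)), kind="DCCM")
        edges, lm = delta_matrix(a, a, threshold=0.16)
        assert edges == []
        b = np.zeros((3, 3))
        b[0, 2] = b[2, 0] = 0.2
        edges, _ = delta_matrix(self._mat(b, "DCCM"), a, threshold=0.16)
        assert edges == [(0, 2, pytest.approx(0.2))]

    def test_delta_matches_elementwise_oracle(self, rng):
        x = rng.uniform(-0.3, 0.3, (6, 6))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 1.0)
        y = rng.uniform(-0.3, 0.3, (6, 6))
        y = (y + y.T) / 2
        np.fill_diagonal(y, 1.0)
        edges, lm = delta_matrix(self._mat(x, "DCCM"), self._mat(y, "DCCM"), threshold=0.16)
        expected = {(i, j): x[i, j] - y[i, j] for i in range(6) for j in range(i + 1, 6)
                    if abs(x[i, j] - y[i, j]) > 0.16}
        assert {(i, j): pytest.approx(v) for i, j, v in edges} == expected

    def test_kind_mismatch_rejected(self):
        a = self._mat(np.zeros((2, 2)), kind="DCCM")
        b = self._mat(np.zeros((2, 2)), kind="nMI")
        with pytest.raises(ContractError):
            delta_matrix(a, b, threshold=0.1)
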