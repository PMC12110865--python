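"""Chemical-branch tests: interpolation exactness, the causal dilated
convolution against a brute-force oracle, TCN contracts and the temporal
receptive field."""

import numpy as np
import pytest

from freshfusion.chem_branch import (ChemBranch, ChemNormalizer, ChemSequence,
                                     MDFA1D, Tcn, TcnConfig,
                                     build_pseudo_sequence, dilated_conv1d)
from freshfusion.nn import Tensor


class TestPseudoSequence:
    def test_midpoint_of_a_line(self):
        seq = build_pseudo_sequence(
            np.array([[6.2, 6.5], [5.0, 8.0], [4.5, 5.0]]),
            np.array([0.0, 5.0]), target_t=3)
        assert seq.values[0, 1] == pytest.approx(6.35)
        assert seq.times[1] == pytest.approx(2.5)

    def test_identity_on_uniform_grid(self):
        times = np.linspace(0, 25, 6)
        vals = np.vstack([np.linspace(6.2, 7.5, 6),
                          np.linspace(5, 60, 6),
                          np.linspace(4.5, 9.5, 6)])
        seq = build_pseudo_sequence(vals, times, target_t=6)
        assert np.allclose(seq.values, vals)
        assert np.allclose(seq.times, times)

    def test_doubling_inserts_pairwise_midpoints(self, rng):
        times = np.linspace(0, 25, 6)
        vals = rng.random((3, 6))
        seq = build_pseudo_sequence(vals, times, target_t=11)
        assert np.allclose(seq.values[:, ::2], vals)
        mids = 0.5 * (vals[:, :-1] + vals[:, 1:])
        assert np.allclose(seq.values[:, 1::2], mids)

    def test_endpoints_preserved_and_affine_exact(self):
        times = np.array([0.0, 4.0, 25.0])  # non-uniform grid
        vals = np.vstack([2 + 0.1 * times, 1 - 0.2 * times, 0.3 * times])
        for target in (3, 7, 20):
            seq = build_pseudo_sequence(vals, times, target)
            expected = np.vstack([2 + 0.1 * seq.times, 1 - 0.2 * seq.times,
                                  0.3 * seq.times])
            assert np.allclose(seq.values, expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            build_pseudo_sequence(np.ones((3, 1)), np.array([0.0]), 6)
        with pytest.raises(ValueError):
            build_pseudo_sequence(np.ones((3, 3)),
                                  np.array([0.0, 2.0, 1.0]), 6)


class TestDilatedConv1d:
    def test_worked_example(self):
        y = dilated_conv1d(np.array([1.0, 2, 3, 4, 5]), np.ones(3), d=2)
        assert y[4] == pytest.approx(9.0)  # 5 + 3 + 1

    def test_single_tap_identity(self, rng):
        x = rng.normal(size=11)
        for d in (1, 3, 5):
            assert np.allclose(dilated_conv1d(x, np.array([1.0]), d), x)

    def test_d1_matches_standard_causal_convolution(self, rng):
        x = rng.normal(size=9)
        w = rng.normal(size=3)
        y = dilated_conv1d(x, w, d=1)
        expected = np.convolve(x, w)[:x.size]
        assert np.allclose(y, expected)

    def test_brute_force_oracle_over_random_draws(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            t = int(rng.integers(1, 21))
            k = int(rng.integers(1, 5))
            d = int(rng.integers(1, 6))
            x = rng.normal(size=t)
            w = rng.normal(size=k)
            y = dilated_conv1d(x, w, d)
            expected = np.zeros(t)
            for ti in range(t):
                for ki in range(k):
                    src = ti - d * ki
                    if src >= 0:
                        expected[ti] += w[ki] * x[src]
            assert np.abs(y - expected).max() < 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dilated_conv1d(np.array([]), np.ones(3), 1)


@pytest.fixture(scope="module")
def tcn():
    return Tcn(TcnConfig(), np.random.default_rng(3))


class TestTcn:
    def test_hidden_width_and_length_preserved(self, tcn, rng):
        out = tcn(Tensor(rng.random((2, 3, 6))))
        assert out.shape == (2, 64, 6)

    def test_zero_input_zero_biases_gives_zero(self):
        t = Tcn(TcnConfig(), np.random.default_rng(4))
        t.expand.bias.data[:] = 0.0
        t.eval()
        out = t(Tensor(np.zeros((1, 3, 6))))
        assert np.all(out.data == 0.0)

    def test_temporal_receptive_field_is_29_steps(self):
        """Impulse probing: the last output step must see exactly the last
        1 + 2*(2+4+8) = 29 input steps."""
        cfg = TcnConfig()
        t = Tcn(cfg, np.random.default_rng(5))
        # positive weights and identity-mode BN so signals cannot cancel
        for _, p in t.named_parameters():
            p.data = np.abs(p.data) + 0.01
        for bn in t.bns:
            bn.weight.data[:] = 1.0
            bn.bias.data[:] = 0.0
        t.eval()
        length = 40
        base = t(Tensor(np.zeros((1, 3, length)))).data[0, :, -1]
        def response(pos):
            x = np.zeros((1, 3, length))
            x[0, :, pos] = 1.0
            return np.abs(t(Tensor(x)).data[0, :, -1] - base).max()
        assert response(length - 29) > 1e-8
        assert response(length - 30) == 0.0

    def test_deterministic_forward(self, tcn, rng):
        x = rng.random((3, 3, 6))
        tcn.eval()
        assert np.array_equal(tcn(Tensor(x)).data, tcn(Tensor(x)).data)


class TestMDFA1D:
    def test_shape_preserved_and_attention_bounded(self, rng):
        m = MDFA1D(64, np.random.default_rng(6))
        h = Tensor(rng.normal(size=(2, 64, 6)))
        out = m(h)
        assert out.shape == (2, 64, 6)
        attention = 1.0 / (1.0 + np.exp(-m.attn(
            Tensor(np.zeros((1, 64, 6)))).data))
        assert np.all((attention > 0) & (attention < 1))

    def test_wrong_width_rejected(self, rng):
        m = MDFA1D(64, np.random.default_rng(6))
        with pytest.raises(ValueError):
            m(Tensor(rng.random((1, 32, 6))))


class TestChemBranch:
    def test_projects_to_256(self, rng):
        branch = ChemBranch(TcnConfig(), np.random.default_rng(7))
        out = branch(Tensor(rng.random((4, 3, 6))))
        assert out.shape == (4, 256)

    def test_end_to_end_deterministic(self, rng):
        branch = ChemBranch(TcnConfig(), np.random.default_rng(8))
        branch.eval()
        x = rng.random((2, 3, 6))
        assert np.array_equal(branch(Tensor(x)).data, branch(Tensor(x)).data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TcnConfig(dilations=(8, 4, 2))
        with pytest.raises(ValueError):
            TcnConfig(out_dim=128)


class TestNormalizer:
    def test_zscore_and_roundtrip(self, rng):
        seqs = rng.normal(loc=[[6.5], [20.0], [6.0]],
                          scale=[[0.5], [15.0], [1.5]], size=(50, 3, 6))
        norm = ChemNormalizer().fit(seqs)
        z = norm.transform(seqs)
        assert np.abs(z.mean(axis=(0, 2))).max() < 1e-9
        assert np.abs(z.std(axis=(0, 2)) - 1).max() < 1e-9
        restored = ChemNormalizer.from_state(norm.state())
        assert np.allclose(restored.transform(seqs), z)

    def test_unfitted_rejected(self, rng):
        with pytest.raises(RuntimeError):
            ChemNormalizer().transform(rng.random((2, 3, 6)))


def test_chem_sequence_validation():
    with pytest.raises(ValueError):
        ChemSequence(np.ones((2, 6)), np.arange(6))
    with pytest.raises(ValueError):
        ChemSequence(np.ones((3, 1)), np.array([0.0]))
    with pytest.raises(ValueError):
        ChemSequence(np.full((3, 6), np.nan), np.arange(6))
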