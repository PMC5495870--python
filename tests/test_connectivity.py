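"""gPDC: closed-form oracle equivalence, column normalization, ROI
means, network discretization, node strength and condition-wise ANS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import balancenet as bn
from balancenet.connectivity import gpdc_from_coefficients
from balancenet.tvmvar import grand_mean_model

from conftest import PDC_FREQS


def brute_force_gpdc(A, sigma2, freq, fs):
    """Independent elementwise evaluation of the gPDC formula."""
    p, D, _ = A.shape
    Ab = np.eye(D, dtype=complex)
    for k in range(1, p + 1):
        Ab -= A[k - 1] * np.exp(-2j * np.pi * freq * k / fs)
    out = np.zeros((D, D))
    for i in range(D):
        for j in range(D):
            num = abs(Ab[i, j]) / np.sqrt(sigma2[i])
            den = np.sqrt(sum(abs(Ab[m, j]) ** 2 / sigma2[m] for m in range(D)))
            out[i, j] = num / den
    return out


class TestGpdcOracle:
    def test_matches_brute_force_to_1e10(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((3, 4, 4)) * 0.15
        sigma2 = rng.uniform(0.5, 2.0, 4)
        freqs = np.arange(1.0, 49.0, 1.0)
        pi = gpdc_from_coefficients(A, sigma2, freqs, 100.0)
        for k, f in enumerate(freqs[::5]):
            ref = brute_force_gpdc(A, sigma2, f, 100.0)
            assert np.abs(pi[:, :, 5 * k] - ref).max() < 1e-10

    def test_identity_model_zero_offdiagonal(self):
        pi = gpdc_from_coefficients(np.zeros((1, 3, 3)), np.ones(3),
                                    np.arange(1, 40.0), 100.0)
        off = pi.copy()
        for i in range(3):
            off[i, i] = 0
        assert np.allclose(off, 0.0)

    def test_structural_zero_stays_zero(self):
        # upper-triangular VAR: no coupling 2→1, so π(1←2) ≡ 0
        A = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        pi = gpdc_from_coefficients(A, np.ones(2), np.arange(1, 50.0), 100.0)
        assert np.allclose(pi[0, 1], 0.0, atol=1e-14)

    def test_estimated_model_close_to_truth(self, stationary_var1):
        rec, A_true = stationary_var1
        res = bn.TimeVaryingVAR(rec, order=1).fit()
        pdc = res.gpdc(freqs=np.arange(2.0, 40.0, 2.0), t_step=5)
        truth = gpdc_from_coefficients(A_true[None], np.ones(2),
                                       np.arange(2.0, 40.0, 2.0), 100.0)
        est = pdc.values[:, :, pdc.times > 2.0, :].mean(axis=2)
        assert np.abs(est - truth).max() < 0.05

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_column_normalization_any_stable_var(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((2, 3, 3)) * 0.2
        sigma2 = rng.uniform(0.2, 3.0, 3)
        pi = gpdc_from_coefficients(A, sigma2, np.arange(1.0, 50.0, 2.5), 100.0)
        norms = (pi**2).sum(axis=0)
        assert np.abs(norms - 1.0).max() < 1e-8
        assert pi.min() >= 0 and pi.max() <= 1 + 1e-12


class TestPDCTensorContracts:
    def test_column_norms_and_range_on_fit(self, coupled_pdc):
        for pdc in coupled_pdc:
            assert np.abs(pdc.column_norms() - 1.0).max() < 1e-8
            assert pdc.values.min() >= 0.0
            assert pdc.values.max() <= 1.0

    def test_offdiagonal_zeroed(self, coupled_pdc):
        off = coupled_pdc[0].offdiagonal()
        i = np.arange(off.shape[0])
        assert np.all(off[i, i] == 0.0)
        # raw values keep the diagonal
        assert coupled_pdc[0].values[0, 0].max() > 0


class TestRoiMean:
    def _tensor(self, values):
        return bn.PDCTensor(values, np.arange(0, 8, 0.5), np.arange(1.0, 21.0),
                            ["a", "b", "c"])

    def test_constant_tensor(self):
        pdc = self._tensor(np.full((3, 3, 16, 20), 0.3))
        m = bn.roi_mean(pdc, bn.ROISpec((5, 7), (4.0, 6.0)))
        off = m[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.3)
        assert np.all(np.diag(m) == 0)

    def test_two_level_mean(self):
        v = np.full((3, 3, 16, 20), 0.2)
        v[:, :, 8:] = 0.4  # second half of time axis
        pdc = self._tensor(v)
        m = bn.roi_mean(pdc, bn.ROISpec((5, 7), (2.0, 6.0)))  # half 0.2, half 0.4
        assert m[0, 1] == pytest.approx(0.3)

    def test_empty_roi_rejected(self):
        pdc = self._tensor(np.zeros((3, 3, 16, 20)))
        with pytest.raises(ValueError):
            bn.roi_mean(pdc, bn.ROISpec((30, 40), (4.0, 6.0)))

    def test_planted_pair_is_top_edge(self, coupled_fits):
        grand = grand_mean_model(coupled_fits)
        pdc = grand.gpdc(freqs=PDC_FREQS, t_step=5)
        m = bn.roi_mean(pdc, bn.ROISpec((5, 7), (6.5, 7.5), "theta-TI4"))
        off = m.copy()
        np.fill_diagonal(off, -np.inf)
        i, j = np.unravel_index(np.argmax(off), off.shape)
        assert (pdc.channel_names[i], pdc.channel_names[j]) == ("Cz", "CPz")
        # directionality: forward exceeds reverse
        rev = m[j, i]
        assert m[i, j] > rev


class TestDiscretize:
    @pytest.mark.parametrize(
        "value,expected_level",
        [(0.07, None), (0.08, 1), (0.09, 1), (0.10, 2), (0.11, 2), (0.12, 3), (0.5, 3)],
    )
    def test_bin_assignment(self, value, expected_level):
        m = np.zeros((2, 2))
        m[0, 1] = value
        net = bn.discretize(m, ["a", "b"])
        if expected_level is None:
            assert net.edges == []
        else:
            assert len(net.edges) == 1
            src, tgt, w, level = net.edges[0]
            assert (src, tgt) == ("b", "a")
            assert level == expected_level

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            bn.discretize(np.zeros((2, 2)), ["a", "b"], thresholds=(0.1, 0.1))

    def test_no_self_edges(self):
        m = np.full((3, 3), 0.2)
        net = bn.discretize(m, list("abc"))
        assert all(s != t for s, t, *_ in net.edges)
        assert len(net.edges) == 6


class TestNodeStrength:
    def test_single_edge(self):
        W = np.zeros((2, 2))
        W[0, 1] = 0.1  # edge b -> a
        s = bn.node_strength(W)
        assert np.allclose(s, [0.1, 0.1])
        assert bn.average_node_strength(W) == pytest.approx(0.1)

    def test_complete_digraph_brute_force(self):
        W = np.full((3, 3), 0.2)
        np.fill_diagonal(W, 0.0)
        # brute-force edge enumeration oracle
        s_expected = np.zeros(3)
        for i in range(3):
            for j in range(3):
                if i != j:
                    s_expected[i] += W[i, j] + W[j, i]
        assert np.allclose(bn.node_strength(W), s_expected)
        assert np.allclose(s_expected, 0.8)
        assert bn.average_node_strength(W) == pytest.approx(0.8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_scaling_linearity(self, c):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 1, (4, 4))
        np.fill_diagonal(W, 0.0)
        assert bn.average_node_strength(c * W) == pytest.approx(
            c * bn.average_node_strength(W), rel=1e-12
        )


class TestConditionANS:
    def _tensor(self, values):
        return bn.PDCTensor(values, np.arange(0, 8, 0.5), np.arange(1.0, 11.0),
                            ["a", "b"])

    def test_time_constant_tensor_equal_ans(self):
        pdc = self._tensor(np.full((2, 2, 16, 10), 0.2))
        ans = bn.condition_ans(pdc, 3.0)
        assert np.allclose(ans["bss"], ans["bus"])

    def test_doubled_after_onset(self):
        v = np.full((2, 2, 16, 10), 0.2)
        v[:, :, 6:] = 0.4  # onset at t=3 s is index 6
        ans = bn.condition_ans(self._tensor(v), 3.0)
        assert np.allclose(ans["bus"], 2 * ans["bss"])

    def test_planted_band_ans_increases(self, coupled_pdc):
        band = (PDC_FREQS >= 5) & (PDC_FREQS <= 7)
        bss, bus = [], []
        for pdc in coupled_pdc:
            ans = bn.condition_ans(pdc, 3.0)
            bss.append(ans["bss"][band].mean())
            bus.append(ans["bus"][band].mean())
        assert np.mean(bus) > np.mean(bss)


def test_null_simulation_grand_network_has_no_strong_edges():
    """Without planted couplings the cohort-scale (37-subject) grand-mean
    network has no edge reaching the lowest discretization level, the
    stable-surface baseline behaviour the thresholds were designed on."""
    from conftest import fit_cohort, small_config

    fits = fit_cohort(small_config(seed=202, couple=False, n_subjects=37, n_trials=10))
    pdc = grand_mean_model(fits).gpdc(freqs=PDC_FREQS, t_step=5)
    for band in [(5, 7), (9, 11)]:
        m = bn.roi_mean(pdc, bn.ROISpec(band, (1.5, 3.0), "pre-onset"))
        net = bn.discretize(m, pdc.channel_names)
        assert net.edges == []
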