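"""4-mode PDC tensor construction and nonnegative PARAFAC."""

import numpy as np
import pytest

import balancenet as bn
from balancenet.tensorfac import _reconstruct, build_tensor, factor_congruence

from conftest import PDC_FREQS


def random_nn_factors(rng, shape, rank):
    return [np.abs(rng.standard_normal((d, rank))) for d in shape]


class TestBuildTensor:
    def test_pair_dimension_11_subset(self, coupled_pdc):
        # only 5 channels in the reduced montage; check the formula D(D-1)
        t = build_tensor(coupled_pdc)
        D = len(coupled_pdc[0].channel_names)
        assert t.values.shape[0] == D * (D - 1)
        assert t.values.shape[-1] == len(coupled_pdc)

    def test_eleven_channel_subset_gives_110_pairs(self):
        from balancenet.synthdata import DEFAULT_SUBSET

        rng = np.random.default_rng(1)
        D = len(DEFAULT_SUBSET)
        v = rng.uniform(0, 1, (D, D, 3, 2))
        pdc = bn.PDCTensor(v, np.arange(3.0), np.arange(1.0, 3.0), list(DEFAULT_SUBSET))
        t = build_tensor([pdc], electrode_subset=list(DEFAULT_SUBSET))
        assert t.values.shape[0] == 110

    def test_two_channel_labels(self):
        v = np.random.default_rng(0).uniform(0, 1, (2, 2, 4, 3))
        for i in range(2):
            v[i, i] = 0
        pdc = bn.PDCTensor(v, np.arange(4.0), np.arange(1.0, 4.0), ["a", "b"])
        t = build_tensor([pdc])
        assert t.pair_labels == ["a->b", "b->a"]

    def test_round_trip_unvectorize(self, coupled_pdc):
        t = build_tensor(coupled_pdc)
        ti, fi, si = 3, 5, 0
        M, chans = t.unvectorize(t.values[:, ti, fi, si])
        off = coupled_pdc[si].offdiagonal()
        idx = [coupled_pdc[si].channel_names.index(c) for c in chans]
        expected = off[np.ix_(idx, idx)][:, :, ti, fi]
        assert np.allclose(M, expected)

    def test_axis_mismatch_rejected(self, coupled_pdc):
        other = bn.PDCTensor(
            coupled_pdc[0].values[:, :, :3, :],
            coupled_pdc[0].times[:3],
            coupled_pdc[0].freqs,
            coupled_pdc[0].channel_names,
        )
        with pytest.raises(ValueError):
            build_tensor([coupled_pdc[0], other])


class TestParafac:
    def test_exact_rank1_recovery(self):
        rng = np.random.default_rng(0)
        facs = random_nn_factors(rng, (8, 7, 6, 5), 1)
        X = _reconstruct(facs)
        res = bn.Parafac(X, rank=1, n_restarts=3, seed=1).fit()
        assert res.fit >= 0.999
        scores, _ = factor_congruence(res.factors, facs)
        assert scores[0] >= 0.999

    def test_planted_rank3_with_noise(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            facs = random_nn_factors(rng, (15, 12, 10, 8), 3)
            X = _reconstruct(facs)
            X += 0.05 * np.linalg.norm(X) / np.sqrt(X.size) * rng.standard_normal(X.shape)
            X = np.maximum(X, 0.0)
            res = bn.Parafac(X, rank=3, n_restarts=5, seed=seed).fit()
            scores, _ = factor_congruence(res.factors, facs)
            if min(scores) >= 0.95:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_error_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.standard_normal((6, 5, 4, 3)))
        res = bn.Parafac(X, rank=2, n_restarts=2, seed=0).fit()
        assert np.all(np.diff(res.error_history) <= 1e-10)

    def test_fit_improves_with_rank(self):
        rng = np.random.default_rng(3)
        facs = random_nn_factors(rng, (8, 7, 6, 5), 4)
        X = _reconstruct(facs)
        fits = [bn.Parafac(X, rank=m, n_restarts=3, seed=0).fit().fit for m in (1, 2, 4)]
        assert fits[1] >= fits[0] - 1e-6
        assert fits[2] >= fits[1] - 1e-6

    def test_redecomposition_of_reconstruction(self):
        rng = np.random.default_rng(4)
        facs = random_nn_factors(rng, (9, 8, 7, 6), 2)
        X = _reconstruct(facs)
        res1 = bn.Parafac(X, rank=2, n_restarts=4, seed=5).fit()
        res2 = bn.Parafac(res1.reconstruct(), rank=2, n_restarts=4, seed=6).fit()
        scores, _ = factor_congruence(res1, res2)
        assert min(scores) >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = np.abs(rng.standard_normal((5, 4, 3, 3)))
        a = bn.Parafac(X, rank=2, n_restarts=2, seed=9).fit()
        b = bn.Parafac(X, rank=2, n_restarts=2, seed=9).fit()
        for fa, fb in zip(a.factors, b.factors):
            assert np.array_equal(fa, fb)

    def test_unconstrained_als_option(self):
        rng = np.random.default_rng(6)
        facs = random_nn_factors(rng, (6, 5, 4, 3), 2)
        X = _reconstruct(facs)
        res = bn.Parafac(X, rank=2, nonnegative=False, n_restarts=3, seed=0).fit()
        assert res.fit >= 0.999

    def test_scale_absorbed_in_first_mode(self):
        rng = np.random.default_rng(7)
        X = np.abs(rng.standard_normal((6, 5, 4, 3)))
        res = bn.Parafac(X, rank=2, n_restarts=2, seed=0).fit()
        for U in res.factors[1:]:
            assert np.allclose(np.linalg.norm(U, axis=0), 1.0)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            bn.Parafac(np.ones((2, 2, 2, 2)), rank=0)


class TestFactorCongruence:
    def test_self_congruence_is_one(self):
        rng = np.random.default_rng(8)
        facs = random_nn_factors(rng, (6, 5, 4), 3)
        scores, match = factor_congruence(facs, facs)
        assert np.allclose(scores, 1.0)
        assert set(match) == {(i, i) for i in range(3)}

    def test_orthogonal_factors_score_zero(self):
        f_a = [np.eye(4)[:, :2] for _ in range(3)]
        f_b = [np.eye(4)[:, 2:4] for _ in range(3)]
        scores, _ = factor_congruence(f_a, f_b)
        assert np.allclose(scores, 0.0)

    def test_permutation_recovered_brute_force(self):
        """Greedy matching finds the same assignment as exhaustive
        permutation search for M <= 5."""
        from itertools import permutations

        rng = np.random.default_rng(9)
        M = 4
        facs = random_nn_factors(rng, (8, 7, 6), M)
        perm = [2, 0, 3, 1]
        permuted = [f[:, perm] for f in facs]
        scores, match = factor_congruence(facs, permuted)
        # brute-force: best total congruence over all permutations
        def total(assign):
            tot = 1.0
            prod = np.ones(M)
            for A, B in zip(facs, permuted):
                for r, s in enumerate(assign):
                    prod[r] *= (A[:, r] @ B[:, s]) / (
                        np.linalg.norm(A[:, r]) * np.linalg.norm(B[:, s])
                    )
            return prod.sum()

        best = max(permutations(range(M)), key=total)
        assert {r: s for r, s in match} == {r: s for r, s in enumerate(best)}
        assert np.allclose(sorted(scores), 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            factor_congruence([np.ones((3, 2))], [np.ones((4, 2))])


def test_pipeline_tensor_factor_finds_coupling_pair(coupled_pdc):
    """PARAFAC of the coupled cohort tensor: some factor's space loading
    peaks on the planted CPz→Cz pair and its time loading rises after
    the onset."""
    t = build_tensor(coupled_pdc)
    res = bn.Parafac(t, rank=3, n_restarts=4, seed=0).fit()
    pair = t.pair_labels.index("CPz->Cz")
    space = res.loadings["space"]
    r = int(np.argmax(space[pair] / (np.abs(space).max(axis=0) + 1e-12)))
    assert np.argmax(space[:, r]) == pair
    time_load = res.loadings["time"][:, r]
    onset_idx = np.searchsorted(t.times, 3.0)
    assert time_load[onset_idx + 2 :].mean() > time_load[2:onset_idx].mean()
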