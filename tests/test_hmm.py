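"""Transition/emission closed forms and the scaled forward likelihood,
checked against matrix-exponential and path-enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.stats import binom

from xcontam import (
    ForwardModel,
    ModelParams,
    forward_loglik,
    genotype_prob,
    p_alt_given_genotype,
    site_emission,
    simulate_copy_path,
    simulate_read_counts,
    synthetic_panel,
    transition_probs,
    SimConfig,
)
from xcontam.hmm import forward_pass
from xcontam.io import ReadCountTable, ReferencePanel


def random_instance(rng, n, L):
    """A tiny random panel plus full-coverage random counts."""
    panel = synthetic_panel(n=n, L=L, seed=int(rng.integers(2**31)))
    depth = rng.integers(1, 4, size=L)
    n_alt = rng.binomial(depth, rng.random(L))
    counts = ReadCountTable(
        marker_index=np.arange(L), n_ref=depth - n_alt, n_alt=n_alt
    )
    return panel, counts


def enumerate_loglik(counts, panel, params):
    """Exact likelihood by summing over every state path (oracle)."""
    idx = counts.marker_index
    n = panel.n_hap
    S = len(idx)
    gaps = np.diff(panel.genetic_map[idx])
    p = panel.pop_freqs[params.contaminant_pop][idx]
    emis = np.array(
        [
            site_emission(
                counts.n_ref[s], counts.n_alt[s],
                panel.haplotypes[:, idx[s]], params, p[s],
            )
            for s in range(S)
        ]
    )
    total = 0.0
    for path in itertools.product(range(n), repeat=S):
        prob = 1.0 / n * emis[0][path[0]]
        for s in range(1, S):
            stay, switch = transition_probs(gaps[s - 1], n, params.q)
            prob *= (stay if path[s] == path[s - 1] else switch) * emis[s][path[s]]
        total += prob
    return np.log(total)


class TestTransitionProbs:
    def test_zero_distance_is_identity(self):
        assert transition_probs(0.0, 5, 300.0) == (1.0, 0.0)

    def test_long_distance_reaches_uniform(self):
        stay, switch = transition_probs(1.0, 4, 300.0)
        assert stay == pytest.approx(0.25, abs=1e-12)
        assert switch == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 10])
    @pytest.mark.parametrize("r", [0.0, 1e-4, 1e-3, 1e-2])
    def test_matches_matrix_exponential(self, n, r):
        q = 300.0
        Q = np.full((n, n), q)
        np.fill_diagonal(Q, -(n - 1) * q)
        T = expm(Q * r)
        stay, switch = transition_probs(r, n, q)
        np.testing.assert_allclose(np.diag(T), stay, atol=1e-12)
        off = T[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, switch, atol=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_probs(-1e-9, 4, 300.0)

    @given(
        r=st.floats(0.0, 0.1),
        n=st.integers(2, 200),
        q=st.floats(1.0, 1000.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, r, n, q):
        stay, switch = transition_probs(r, n, q)
        assert stay + (n - 1) * switch == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= switch <= stay <= 1.0


class TestEmissionLayers:
    def test_genotype_prob(self):
        assert genotype_prob(0, 1e-3) == (0.999, 0.001)
        assert genotype_prob(1, 0.0) == (0.0, 1.0)
        assert genotype_prob(0, 0.5) == (0.5, 0.5)

    def test_p_alt_given_genotype(self):
        assert p_alt_given_genotype(0, 0.0, 0.0, 0.7) == 0.0
        assert p_alt_given_genotype(1, 1.0, 0.0, 0.3) == pytest.approx(0.3)
        # (1-c) eps_g + c (p(1-eps_g) + (1-p) eps_g) at c=0.1, eps_g=0.01, p=0.5
        assert p_alt_given_genotype(0, 0.1, 0.01, 0.5) == pytest.approx(0.059)

    def test_site_emission_perfect_match(self):
        params = ModelParams(c=0.0, eps_g=0.0, eps_r=0.0)
        e = site_emission(1, 0, np.array([0]), params, 0.5)
        np.testing.assert_allclose(e, [1.0])
        e = site_emission(0, 1, np.array([0]), params, 0.5)
        np.testing.assert_allclose(e, [0.0])

    def test_site_emission_composed_closed_form(self):
        params = ModelParams(c=0.1, eps_g=0.01, eps_r=1e-3)
        p = 0.5
        # independent evaluation of the layered mixture for hap allele 0
        p_t0, p_t1 = genotype_prob(0, params.eps_r)
        pi = (
            p_alt_given_genotype(0, params.c, params.eps_g, p) * p_t0
            + p_alt_given_genotype(1, params.c, params.eps_g, p) * p_t1
        )
        expected = 3 * (1 - pi) ** 2 * pi
        e = site_emission(2, 1, np.array([0]), params, p)
        np.testing.assert_allclose(e, [expected], rtol=1e-12)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            site_emission(0, 0, np.array([0]), ModelParams(c=0.0, eps_g=0.0), 0.5)

    @given(
        c=st.floats(0.0, 0.5),
        eps_g=st.floats(1e-6, 0.49),
        eps_r=st.floats(1e-6, 0.49),
        p=st.floats(0.0, 1.0),
        n_ref=st.integers(0, 5),
        n_alt=st.integers(0, 5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_emission_in_unit_interval(self, c, eps_g, eps_r, p, n_ref, n_alt):
        if n_ref + n_alt == 0:
            n_ref = 1
        params = ModelParams(c=c, eps_g=eps_g, eps_r=eps_r)
        e = site_emission(n_ref, n_alt, np.array([0, 1]), params, p)
        assert ((e > 0) & (e <= 1)).all()


class TestForwardLoglik:
    def test_single_site_two_states(self):
        panel = ReferencePanel(
            haplotypes=np.array([[0], [1]], dtype=np.uint8),
            chrom="X",
            positions=np.array([100]),
            ref_allele=np.array(["A"]),
            alt_allele=np.array(["T"]),
            genetic_map=np.array([0.0]),
            pop_freqs={"CEU": np.array([0.5])},
        )
        counts = ReadCountTable(np.array([0]), np.array([1]), np.array([0]))
        params = ModelParams(c=0.0, eps_g=0.0, eps_r=0.0, contaminant_pop="CEU")
        ll, n_used = forward_loglik(counts, panel, params)
        assert n_used == 1
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(2, 5))
            L = int(rng.integers(2, 7))
            panel, counts = random_instance(rng, n, L)
            params = ModelParams(
                c=float(rng.uniform(0, 0.5)),
                eps_g=float(rng.uniform(0.001, 0.05)),
                eps_r=1e-3,
                q=float(rng.uniform(10, 500)),
                contaminant_pop="CEU",
            )
            ll, _ = forward_loglik(counts, panel, params)
            assert ll == pytest.approx(enumerate_loglik(counts, panel, params),
                                       abs=1e-12)

    def test_collapsed_update_equals_dense_recursion(self):
        rng = np.random.default_rng(5)
        panel, counts = random_instance(rng, 6, 30)
        params = ModelParams(c=0.08, eps_g=0.01, contaminant_pop="CEU")
        fm = ForwardModel(counts, panel, "CEU", eps_g=0.01)
        # dense oracle: explicit transition matrices
        emis = fm.emissions(params.c)
        n = panel.n_hap
        a = emis[0] / n
        ll = np.log(a.sum())
        a = a / a.sum()
        for s in range(1, counts.n_sites):
            T = np.full((n, n), fm.switch[s - 1])
            np.fill_diagonal(T, fm.stay[s - 1])
            a = emis[s] * (a @ T)
            ll += np.log(a.sum())
            a = a / a.sum()
        assert fm.loglik(params.c) == pytest.approx(ll, abs=1e-10)

    def test_zero_map_identical_haplotypes_factorizes(self):
        # r = 0 everywhere and a panel of identical haplotypes: the chain
        # collapses and the likelihood is a product of site likelihoods
        L = 12
        hap = np.zeros((4, L), dtype=np.uint8)
        hap[:, ::3] = 1
        panel = ReferencePanel(
            haplotypes=hap,
            chrom="X",
            positions=np.arange(1, L + 1) * 10,
            ref_allele=np.array(["A"] * L),
            alt_allele=np.array(["G"] * L),
            genetic_map=np.zeros(L),
            pop_freqs={"CEU": np.full(L, 0.3)},
        )
        rng = np.random.default_rng(7)
        depth = rng.integers(1, 3, size=L)
        n_alt = rng.binomial(depth, 0.4)
        counts = ReadCountTable(np.arange(L), depth - n_alt, n_alt)
        params = ModelParams(c=0.1, eps_g=0.02, contaminant_pop="CEU")
        ll, _ = forward_loglik(counts, panel, params)
        expected = sum(
            np.log(
                site_emission(
                    counts.n_ref[s], counts.n_alt[s], hap[:1, s], params, 0.3
                )[0]
            )
            for s in range(L)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_haplotype_permutation(self, rng):
        panel, counts = random_instance(rng, 8, 50)
        params = ModelParams(c=0.12, eps_g=0.01, contaminant_pop="CEU")
        ll, _ = forward_loglik(counts, panel, params)
        perm = rng.permutation(panel.n_hap)
        shuffled = ReferencePanel(
            haplotypes=panel.haplotypes[perm],
            chrom=panel.chrom,
            positions=panel.positions,
            ref_allele=panel.ref_allele,
            alt_allele=panel.alt_allele,
            genetic_map=panel.genetic_map,
            pop_freqs=panel.pop_freqs,
        )
        ll_perm, _ = forward_loglik(counts, shuffled, params)
        assert ll_perm == pytest.approx(ll, rel=1e-12)

    def test_chain_splitting_continuity(self, rng):
        panel, counts = random_instance(rng, 5, 40)
        fm = ForwardModel(counts, panel, "CEU", eps_g=0.02)
        emis = fm.emissions(0.07)
        init = np.full(panel.n_hap, 1.0 / panel.n_hap)
        ll_full, _ = forward_pass(emis, fm.stay, fm.switch, init)
        k = 17
        ll1, alpha = forward_pass(emis[:k], fm.stay[: k - 1], fm.switch[: k - 1], init)
        bridged = fm.switch[k - 1] + (fm.stay[k - 1] - fm.switch[k - 1]) * alpha
        ll2, _ = forward_pass(emis[k:], fm.stay[k:], fm.switch[k:], bridged)
        assert ll1 + ll2 == pytest.approx(ll_full, abs=1e-10)
        assert fm.loglik(0.07) == pytest.approx(ll_full, abs=1e-10)

    def test_single_site_equals_two_consensus(self):
        # with one covered marker there is no linkage information and the
        # likelihood reduces to a two-allele mixture with panel-frequency
        # prior (the two-consensus limit)
        panel = synthetic_panel(n=20, L=5, seed=42)
        counts = ReadCountTable(np.array([2]), np.array([1]), np.array([1]))
        params = ModelParams(c=0.15, eps_g=0.02, eps_r=1e-3, contaminant_pop="CEU")
        ll, _ = forward_loglik(counts, panel, params)

        f = panel.haplotypes[:, 2].mean()  # panel alt-allele frequency
        p = panel.pop_freqs["CEU"][2]
        two_consensus = 0.0
        for allele, prior in ((0, 1 - f), (1, f)):
            pi = sum(
                p_alt_given_genotype(t, params.c, params.eps_g, p) * pt
                for t, pt in zip((0, 1), genotype_prob(allele, params.eps_r))
            )
            two_consensus += prior * binom.pmf(1, 2, pi)
        assert ll == pytest.approx(np.log(two_consensus), abs=1e-12)

    def test_loglik_prefers_true_contamination(self):
        # with enough markers the likelihood at the generating c exceeds
        # the likelihood at c = 0
        panel = synthetic_panel(n=20, L=5000, seed=8)
        path = simulate_copy_path(panel, seed=9)
        counts = simulate_read_counts(
            panel, path,
            SimConfig(coverage=0.5, c_true=0.1, eps_g=0.01,
                      contaminant_pop="CEU", seed=10),
        )
        fm = ForwardModel(counts, panel, "CEU", eps_g=0.01)
        assert fm.loglik(0.1) > fm.loglik(0.0)

    def test_empty_counts_rejected(self, small_panel):
        empty = ReadCountTable(np.array([], dtype=int), np.array([], dtype=int),
                               np.array([], dtype=int))
        with pytest.raises(ValueError):
            ForwardModel(empty, small_panel, "CEU", eps_g=0.01)
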