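import numpy as np
import pytest

from bandpop.admixture import (
    align_runs,
    call_admixed,
    delta_k,
    fit_admixture,
    run_k_grid,
)
from bandpop.synthetic_data import simulate, two_cluster_config


@pytest.fixture(scope="module")
def two_cluster_fit():
    """One moderate two-cluster fit shared by several checks."""
    cfg = two_cluster_config(n_per_group=10, divergence=0.4, noise_rate=0.0, seed=0)
    m, pops, truth = simulate(cfg)
    fit = fit_admixture(m, K=2, burn_in=2000, samples=2000, seed=0)
    return m, pops, truth, fit


def aligned_q_error(q, q_true):
    """Mean |Q - Q_true| after the best column permutation (K=2)."""
    e1 = np.abs(q - q_true).mean()
    e2 = np.abs(q[:, ::-1] - q_true).mean()
    return min(e1, e2)


class TestFitAdmixture:
    def test_k1_closed_form_frequency(self):
        cfg = two_cluster_config(n_per_group=6, divergence=0.0, seed=53)
        m, _, _ = simulate(cfg)
        fit = fit_admixture(m, K=1, burn_in=500, samples=4000, seed=53)
        assert np.allclose(fit.Q, 1.0)
        n1 = m.calls.sum(axis=0)
        n = m.n_accessions
        expected = (n1 + 1.0) / (n + 2.0)  # Beta posterior mean, lambda = 1
        se = np.sqrt(expected * (1 - expected) / (n + 3))
        assert (np.abs(fit.F[0] - expected) < 4 * se + 0.02).all()

    def test_q_rows_sum_to_one_and_f_interior(self, two_cluster_fit):
        _, _, _, fit = two_cluster_fit
        assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert ((fit.F > 0) & (fit.F < 1)).all()
        assert fit.loglik_trace.shape == (2000,)

    def test_two_cluster_recovery(self):
        # posterior-mean Q carries irreducible shrinkage (~0.07 at this
        # divergence), so the bound is on the mean over seeds
        errs = []
        for seed in (0, 1, 2):
            cfg = two_cluster_config(
                n_per_group=10, divergence=0.4, noise_rate=0.0, seed=seed
            )
            m, _, truth = simulate(cfg)
            fit = fit_admixture(m, K=2, burn_in=2000, samples=2000, seed=seed)
            errs.append(aligned_q_error(fit.Q, truth.true_q))
        assert np.mean(errs) < 0.1
        assert max(errs) < 0.15

    def test_no_systematic_trend_after_burn_in(self, two_cluster_fit):
        # Geweke-style check: means of the two trace halves agree within noise
        _, _, _, fit = two_cluster_fit
        tr = fit.loglik_trace
        half = len(tr) // 2
        a, b = tr[:half], tr[half:]
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        # traces are autocorrelated; allow a generous effective-sample factor
        assert abs(a.mean() - b.mean()) < 3 * se * 5

    def test_k_exceeding_n_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            fit_admixture(tiny_matrix, K=10, burn_in=10, samples=10)

    def test_deterministic_under_seed(self, tiny_matrix):
        f1 = fit_admixture(tiny_matrix, K=2, burn_in=50, samples=50, seed=9)
        f2 = fit_admixture(tiny_matrix, K=2, burn_in=50, samples=50, seed=9)
        assert np.array_equal(f1.Q, f2.Q)
        assert np.array_equal(f1.loglik_trace, f2.loglik_trace)

    def test_recovery_improves_with_divergence(self):
        errs = []
        for d in (0.1, 0.3, 0.5):
            per_seed = []
            for seed in (61, 62, 63):
                cfg = two_cluster_config(
                    n_per_group=10, divergence=d, noise_rate=0.0, seed=seed
                )
                m, _, truth = simulate(cfg)
                fit = fit_admixture(m, K=2, burn_in=1000, samples=1000, seed=seed)
                per_seed.append(aligned_q_error(fit.Q, truth.true_q))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]


class TestDeltaK:
    def test_hand_built_table(self):
        runs = {
            2: [-100.0, -102.0],
            3: [-60.0, -61.0],
            4: [-58.0, -59.0],
            5: [-57.5, -58.5],
        }
        tab = delta_k(runs)
        assert tab.best_k == 3
        means = dict(zip(tab.ks, tab.mean_loglik))
        assert means == {2: -101.0, 3: -60.5, 4: -58.5, 5: -58.0}
        lsec = dict(zip(tab.ks, tab.l_second_abs))
        assert lsec[3] == pytest.approx(38.5)
        assert lsec[4] == pytest.approx(1.5)
        dk = dict(zip(tab.ks, tab.delta_k))
        assert dk[3] == pytest.approx(38.5 / np.std([-60.0, -61.0], ddof=1))
        assert np.isnan(dk[2]) and np.isnan(dk[5])

    def test_flat_linear_likelihood_has_no_best_k(self):
        runs = {k: [-10.0 * k, -10.0 * k] for k in range(2, 6)}
        tab = delta_k(runs)
        assert tab.best_k is None
        assert np.isnan(tab.delta_k[1:-1]).all()  # sd = 0 -> undefined, not inf

    def test_non_consecutive_grid_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            delta_k({2: [-1.0, -2.0], 4: [-1.0, -2.0], 5: [-1.0, -2.0]})

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ValueError, match="2 runs"):
            delta_k({2: [-1.0], 3: [-1.0], 4: [-1.0]})


class TestAlignRuns:
    def test_permuted_copies_align_to_first(self, two_cluster_fit):
        _, _, _, fit = two_cluster_fit
        import copy

        flipped = copy.deepcopy(fit)
        flipped.Q = fit.Q[:, ::-1].copy()
        agg = align_runs([fit, flipped])
        assert np.allclose(agg, fit.Q, atol=1e-12)

    def test_single_run_identity(self, two_cluster_fit):
        _, _, _, fit = two_cluster_fit
        assert np.allclose(align_runs([fit]), fit.Q)

    def test_aggregation_not_worse_than_best_run(self):
        cfg = two_cluster_config(n_per_group=10, divergence=0.4, noise_rate=0.0, seed=57)
        m, _, truth = simulate(cfg)
        fits = [
            fit_admixture(m, K=2, burn_in=1000, samples=1000, seed=s)
            for s in (1, 2, 3, 4, 5)
        ]
        agg = align_runs(fits)
        best_single = min(aligned_q_error(f.Q, truth.true_q) for f in fits)
        assert aligned_q_error(agg, truth.true_q) <= best_single + 0.02

    def test_k_mismatch_rejected(self, two_cluster_fit, tiny_matrix):
        _, _, _, fit = two_cluster_fit
        other = fit_admixture(tiny_matrix, K=3, burn_in=20, samples=20, seed=1)
        with pytest.raises(ValueError, match="same K"):
            align_runs([fit, other])


class TestCallAdmixed:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((0.9, 0.1), "cluster1"),
            ((0.55, 0.45), "admixed"),
            ((0.6, 0.4), "cluster1"),  # threshold boundary is inclusive
            ((0.4, 0.6), "cluster2"),
        ],
    )
    def test_threshold_rule(self, row, expected):
        out = call_admixed(np.array([row]), threshold=0.6)
        assert out.iloc[0] == expected

    def test_threshold_must_exceed_uniform(self):
        with pytest.raises(ValueError, match="threshold"):
            call_admixed(np.array([[0.5, 0.5]]), threshold=0.4)


class TestModelBehaviour:
    def test_posterior_matches_mean_field_oracle_for_admixed_genotype(self):
        """The sampled posterior-mean ancestry of a planted 50/50 hybrid agrees
        with a mean-field fixed point computed at the true cluster frequencies."""

        def mean_field_q(x_row, freqs, alpha=1.0):
            k, l = freqs.shape
            q = np.full(k, 1.0 / k)
            for _ in range(300):
                lik = np.where(x_row[None, :] == 1, freqs, 1 - freqs)
                w = q[:, None] * lik
                w /= w.sum(0, keepdims=True)
                q = (alpha + w.sum(1)) / (k * alpha + l)
                q /= q.sum()
            return q

        for seed in (0, 1, 2):
            cfg = two_cluster_config(
                n_per_group=10, divergence=0.4, noise_rate=0.0, seed=seed, admixed=1
            )
            m, _, truth = simulate(cfg)
            fit = fit_admixture(m, K=2, burn_in=3000, samples=3000, seed=seed)
            i = m.accession_ids.index("H1")
            oracle = mean_field_q(m.calls[i].astype(float), truth.cluster_freqs)
            assert abs(fit.Q[i].max() - oracle.max()) < 0.15

    def test_small_groups_identifiable_only_at_high_divergence(self):
        """Exact marginal likelihood (cluster frequencies integrated out) of
        hard partitions: on the ten-group panel design the model prefers
        merging the 2-4-member species groups at moderate divergence and
        separating all five clusters at species-level divergence."""
        from scipy.special import betaln

        from bandpop.synthetic_data import rose_panel_config

        def hard_marginal(m, pops, partition, lam=1.0):
            calls = m.calls.astype(float)
            total = 0.0
            for groups in partition:
                idx = [
                    m.accession_ids.index(a)
                    for g in groups
                    for a in pops.members(g)
                ]
                n1 = calls[idx].sum(0)
                n0 = len(idx) - n1
                total += np.sum(betaln(n1 + lam, n0 + lam) - betaln(lam, lam))
            return total

        five_way = [["Kl"], ["G", "R"], ["P", "I", "Y", "E", "SV"], ["A"], ["C"]]
        three_way = [["Kl"], ["P", "I", "Y", "E", "SV", "R"], ["G", "A", "C"]]
        for d, expect_five in ((0.3, False), (0.5, True)):
            margin = 0.0
            for seed in (100, 101):
                cfg = rose_panel_config(divergence=d, seed=seed)
                m, pops, _ = simulate(cfg)
                margin += hard_marginal(m, pops, five_way) - hard_marginal(
                    m, pops, three_way
                )
            assert (margin > 0) == expect_five


def test_run_k_grid_structure(tiny_matrix):
    grid = run_k_grid(tiny_matrix, 2, 4, runs=2, burn_in=20, samples=20, seed=3)
    assert sorted(grid) == [2, 3, 4]
    assert all(len(v) == 2 for v in grid.values())
    # distinct run seeds
    assert grid[2][0].seed != grid[2][1].seed
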