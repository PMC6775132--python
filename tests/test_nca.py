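import numpy as np
import pandas as pd
import pytest

from conftest import diagonal_connectivity
from metscreen import nca
from metscreen.model_io import ConnectivityMatrix, GLOBAL_REGULATOR_ID


def tight_settings(**kw):
    kw.setdefault("convergence_relative_tolerance", 1e-10)
    kw.setdefault("max_iterations", 3000)
    return nca.NcaSettings(**kw)


class TestSettingsValidation:
    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_tolerance_bounds(self, bad):
        with pytest.raises(ValueError):
            nca.NcaSettings(convergence_relative_tolerance=bad)

    def test_restart_count(self):
        with pytest.raises(ValueError):
            nca.NcaSettings(n_restarts=0)


class TestAlternatingLeastSquares:
    def test_noiseless_system_factorizes_to_machine_precision(
        self, small_truth_parts
    ):
        """An exact factorization exists, so the best of a few random
        restarts must drive the residual to ~0 relative to ||E||^2."""
        net, _, expr = small_truth_parts
        e = expr.mean_profiles().loc[net.gene_ids].to_numpy()
        bound = 1e-8 * np.sum(e**2)
        best = np.inf
        for seed in range(8):  # restarts exist precisely because some
            restart = nca.run_nca_single(expr, net, tight_settings(), seed)
            best = min(best, restart.residual)
            if best <= bound:  # ALS runs stall in local optima
                break
        assert best <= bound

    def test_residual_trace_monotone_noiseless(self, small_truth_parts):
        net, _, expr = small_truth_parts
        restart = nca.run_nca_single(expr, net, tight_settings(), 3)
        assert np.all(np.diff(restart.residual_trace) <= 1e-9)

    def test_residual_trace_monotone_on_random_data(self, small_truth_parts):
        """ALS guarantees non-increasing residuals on any input."""
        net, _, expr = small_truth_parts
        rng = np.random.default_rng(0)
        noisy = expr.mean_profiles().loc[net.gene_ids] + rng.normal(
            0, 0.5, size=(len(net.gene_ids), 29)
        )
        noisy.columns = expr.time_points
        for seed in range(3):
            restart = nca.run_nca_single(
                noisy, net, nca.NcaSettings(), seed
            )
            assert np.all(np.diff(restart.residual_trace) <= 1e-9)

    def test_zero_pattern_preserved(self, small_truth_parts):
        net, _, expr = small_truth_parts
        restart = nca.run_nca_single(expr, net, nca.NcaSettings(), 1)
        pattern = net.pattern().T
        assert np.all(restart.A[~pattern] == 0.0)

    def test_single_global_regulator_matches_closed_form(self):
        """With one fully-connected regulator, ALS must agree with the
        rank-one least-squares projection computed in closed form."""
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        e = pd.DataFrame(
            rng.normal(size=(30, 12)), index=genes,
            columns=np.arange(12, dtype=float),
        )
        conn = ConnectivityMatrix(
            pd.DataFrame(1.0, index=[GLOBAL_REGULATOR_ID], columns=genes)
        )
        restart = nca.run_nca_single(e, conn, tight_settings(), 0)
        # oracle: best rank-one fit a p' of E via one ALS sweep from the
        # converged a, using the normal equations directly
        a = restart.A[:, 0]
        p_oracle = a @ e.to_numpy() / (a @ a)
        np.testing.assert_allclose(restart.P[0], p_oracle, rtol=1e-8)
        # and the fit equals the SVD rank-one approximation error
        u, s, vt = np.linalg.svd(e.to_numpy(), full_matrices=False)
        svd_resid = np.sum(s[1:] ** 2)
        assert restart.residual == pytest.approx(svd_resid, rel=1e-6)

    def test_more_regulators_than_genes_rejected(self):
        conn = diagonal_connectivity(4)
        e = pd.DataFrame(
            np.ones((4, 5)), index=conn.gene_ids,
            columns=np.arange(5, dtype=float),
        )
        with pytest.raises(ValueError, match="more genes"):
            nca.run_nca_single(e, conn, nca.NcaSettings(), 0)


class TestAlignAndSummarize:
    def _restart(self, p, residual=1.0):
        a = np.ones((p.shape[0] + 1, p.shape[0]))
        return nca.NcaRestart(
            a, p, np.asarray([residual * 2, residual]), True
        )

    def test_scaled_and_flipped_restarts_collapse_to_zero_width(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(2, 10))
        restarts = [
            self._restart(c * base) for c in (1.0, -2.0, 0.5, -0.1)
        ]
        ens = nca.align_and_summarize(
            restarts, ["r1", "r2"], np.arange(10, dtype=float)
        )
        np.testing.assert_allclose(
            (ens.ci_high - ens.ci_low).to_numpy(), 0.0, atol=1e-12
        )
        np.testing.assert_allclose(
            ens.relative_ci_width.to_numpy(), 0.0, atol=1e-12
        )

    def test_single_restart_gives_degenerate_band(self):
        rng = np.random.default_rng(2)
        restarts = [self._restart(rng.normal(size=(2, 8)))]
        ens = nca.align_and_summarize(
            restarts, ["r1", "r2"], np.arange(8, dtype=float)
        )
        pd.testing.assert_frame_equal(ens.ci_low, ens.mean)
        pd.testing.assert_frame_equal(ens.ci_high, ens.mean)

    def test_band_contains_mean(self, small_ensemble):
        assert (small_ensemble.ci_low.to_numpy()
                <= small_ensemble.mean.to_numpy() + 1e-12).all()
        assert (small_ensemble.mean.to_numpy()
                <= small_ensemble.ci_high.to_numpy() + 1e-12).all()

    def test_no_converged_restart_rejected(self):
        bad = nca.NcaRestart(
            np.ones((3, 2)), np.ones((2, 5)), np.asarray([1.0]), False
        )
        with pytest.raises(ValueError, match="converged"):
            nca.align_and_summarize([bad], ["a", "b"], np.arange(5.0))


class TestRecovery:
    def test_noiseless_ensemble_recovers_planted_activities(
        self, small_truth_parts, small_ensemble
    ):
        """Aligned mean activities of an identifiable noiseless system
        correlate almost perfectly with the planted truth."""
        net, act, _ = small_truth_parts
        for tf in net.tf_ids:
            truth = act.mean.loc[tf].to_numpy()
            recovered = small_ensemble.mean.loc[tf].to_numpy()
            assert np.corrcoef(truth, recovered)[0, 1] > 0.99

    def test_sign_orientation_matches_annotated_network(
        self, small_truth_parts, small_ensemble
    ):
        """Profiles are oriented by the annotated signs, so recovered
        activities correlate positively (not just in magnitude)."""
        net, act, _ = small_truth_parts
        signs = [
            np.corrcoef(
                act.mean.loc[tf], small_ensemble.mean.loc[tf]
            )[0, 1]
            for tf in net.tf_ids
        ]
        assert all(s > 0 for s in signs)


class TestVarianceExplained:
    def test_perfect_fit_is_one(self, small_truth_parts):
        net, act, expr = small_truth_parts
        a = net.weights.to_numpy().T
        p = act.mean.loc[net.regulator_ids].to_numpy()
        restart = nca.NcaRestart(a, p, np.asarray([0.0]), True)
        assert nca.variance_explained(expr, net, restart) == pytest.approx(1.0)

    def test_zero_activities_explain_nothing(self, small_truth_parts):
        net, _, expr = small_truth_parts
        e = expr.mean_profiles().loc[net.gene_ids]
        centered = e - e.mean(axis=1).to_numpy()[:, None]
        restart = nca.NcaRestart(
            np.ones((len(net.gene_ids), len(net.regulator_ids))),
            np.zeros((len(net.regulator_ids), e.shape[1])),
            np.asarray([1.0]),
            True,
        )
        assert nca.variance_explained(
            centered, net, restart
        ) == pytest.approx(0.0)

    def test_three_to_one_signal_noise_gives_three_quarters(
        self, small_truth_parts
    ):
        """Noise with variance one third of the signal variance leaves
        ~75% of the dynamics explained by the true factorization."""
        net, act, expr = small_truth_parts
        e = expr.mean_profiles().loc[net.gene_ids]
        signal_var = float(
            ((e - e.mean(axis=1).to_numpy()[:, None]) ** 2).to_numpy().mean()
        )
        rng = np.random.default_rng(11)
        noisy = e + rng.normal(0, np.sqrt(signal_var / 3.0), size=e.shape)
        a = net.weights.to_numpy().T
        p = act.mean.loc[net.regulator_ids].to_numpy()
        restart = nca.NcaRestart(a, p, np.asarray([0.0]), True)
        frac = nca.variance_explained(noisy, net, restart)
        assert frac == pytest.approx(0.75, abs=0.05)


class TestIdentifiabilityReport:
    def test_duplicate_target_sets_flagged(self):
        weights = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=["r1", "r2", "r3"],
            columns=["g1", "g2", "g3"],
        )
        report = nca.check_identifiability(ConnectivityMatrix(weights))
        assert not report["identifiable"]
        assert ["r1", "r2"] in report["duplicated_target_sets"]

    def test_diagonal_topology_is_clean(self):
        report = nca.check_identifiability(diagonal_connectivity(4))
        assert report["identifiable"]
        assert not report["duplicated_target_sets"]
        assert not report["fully_covered_regulators"]

    def test_global_row_does_not_hide_covered_regulator(self):
        weights = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 0.0, 1.0], [1.0, 0.0, 0.0]],
            index=["r1", "r2", "r3"],
            columns=["g1", "g2", "g3"],
        )
        report = nca.check_identifiability(ConnectivityMatrix(weights))
        assert "r3" in report["fully_covered_regulators"]

    def test_empty_matrix_rejected(self):
        conn = diagonal_connectivity(2)
        conn.weights.loc[:, :] = 0.0
        with pytest.raises(ValueError, match="empty"):
            nca.check_identifiability(conn)
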