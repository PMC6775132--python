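import numpy as np
import pandas as pd
import pytest

from metscreen import hill_fit, metnet_distance, nca, synthetic_data as sd
from metscreen.model_io import GLOBAL_REGULATOR_ID


class TestScenarioValidation:
    def test_phase_boundaries_must_be_inside_grid(self):
        with pytest.raises(ValueError, match="boundaries"):
            sd.SyntheticScenario(phase_boundaries=(25, 8))
        with pytest.raises(ValueError, match="boundaries"):
            sd.SyntheticScenario(phase_boundaries=(8, 29))

    def test_more_genes_than_regulators_required(self):
        with pytest.raises(ValueError, match="more genes"):
            sd.SyntheticScenario(n_genes=10, n_regulators=10)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            sd.SyntheticScenario(noise_sd=-0.1)

    def test_planted_interaction_validation(self):
        with pytest.raises(ValueError, match="mode"):
            sd.PlantedInteraction("met00", "tf01", "boost", 50.0, 2.0)
        with pytest.raises(ValueError, match="K_H"):
            sd.PlantedInteraction("met00", "tf01", "activation", -1.0, 2.0)
        with pytest.raises(ValueError, match="Hill"):
            sd.PlantedInteraction("met00", "tf01", "activation", 50.0, 11.0)


class TestRegulatoryNetwork:
    def test_shape_and_full_gene_coverage(self):
        sc = sd.SyntheticScenario(
            n_genes=50, n_regulators=5, n_metabolites=4,
            planted_interactions=[], seed=1,
        )
        conn = sd.generate_regulatory_network(sc)
        assert conn.weights.shape == (6, 50)
        assert GLOBAL_REGULATOR_ID in conn.regulator_ids
        assert (conn.weights != 0).any(axis=0).all()

    def test_seed_determinism(self):
        sc = sd.SyntheticScenario(seed=42)
        a = sd.generate_regulatory_network(sc)
        b = sd.generate_regulatory_network(sc)
        pd.testing.assert_frame_equal(a.weights, b.weights)

    def test_zero_regulators_leaves_only_global_row(self):
        sc = sd.SyntheticScenario(
            n_genes=10, n_regulators=0, n_metabolites=2,
            planted_interactions=[], two_component_regulators=(), seed=0,
        )
        conn = sd.generate_regulatory_network(sc)
        assert conn.regulator_ids == [GLOBAL_REGULATOR_ID]

    def test_generated_topology_is_identifiable(self):
        sc = sd.SyntheticScenario(seed=3)
        conn = sd.generate_regulatory_network(sc)
        report = nca.check_identifiability(conn)
        assert report["identifiable"]


class TestTfActivities:
    def test_on_off_on_profile_tracks_phases(self):
        sc = sd.SyntheticScenario(seed=2)
        act = sd.generate_tf_activities(sc)
        profile = act.mean.loc["tf00"].to_numpy()
        phases = sc.phase_of(sc.transcriptome_times)
        lo = profile.min() + 0.25 * np.ptp(profile)
        hi = profile.min() + 0.75 * np.ptp(profile)
        assert (profile[phases != 1] >= hi).all()
        assert (profile[phases == 1] <= lo).all()

    def test_constant_profile_request(self):
        sc = sd.SyntheticScenario(seed=2)
        act = sd.generate_tf_activities(sc, constant_regulators=("tf03",))
        assert act.mean.loc["tf03"].std() == 0.0

    def test_seed_determinism(self):
        sc = sd.SyntheticScenario(seed=9)
        a = sd.generate_tf_activities(sc)
        b = sd.generate_tf_activities(sc)
        pd.testing.assert_frame_equal(a.mean, b.mean)


class TestExpression:
    def test_zero_noise_reproduces_product_exactly(self, small_scenario,
                                                   small_truth_parts):
        net, act, expr = small_truth_parts
        expected = net.weights.to_numpy().T @ act.mean.loc[
            net.regulator_ids
        ].to_numpy()
        means = expr.mean_profiles().loc[net.gene_ids].to_numpy()
        np.testing.assert_allclose(means, expected, atol=1e-12)

    def test_replicates_share_noiseless_mean(self, small_truth_parts):
        _, _, expr = small_truth_parts
        r1 = expr.values.filter(regex="_r1$")
        r2 = expr.values.filter(regex="_r2$")
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_noise_moments_match_declared_sd(self):
        sc = sd.SyntheticScenario(
            n_genes=100, n_regulators=5, n_metabolites=2, noise_sd=0.1,
            planted_interactions=[], two_component_regulators=(), seed=4,
        )
        net = sd.generate_regulatory_network(sc)
        act = sd.generate_tf_activities(sc)
        expr = sd.generate_expression(act, net, sc)
        clean = net.weights.to_numpy().T @ act.mean.loc[
            net.regulator_ids
        ].to_numpy()
        resid = []
        for k in range(sc.n_timepoints):
            for r in range(sc.replicate_count):
                col = expr.values.iloc[:, k * sc.replicate_count + r]
                resid.append(col.to_numpy() - clean[:, k])
        resid = np.concatenate(resid)
        assert resid.size >= 1000
        assert abs(resid.std() - 0.1) < 0.02  # within 20%

    def test_scale_ambiguity_is_exact(self, small_scenario, small_truth_parts):
        """Doubling P while halving A reproduces the same expression:
        the factorization is only identified up to per-regulator scale."""
        net, act, _ = small_truth_parts
        base = sd.generate_expression(act, net, small_scenario)
        doubled = nca.ActivityEnsemble.from_truth(
            act.mean * 2.0, act.time_points
        )
        halved = type(net)(net.weights / 2.0, net.global_regulator)
        scaled = sd.generate_expression(doubled, halved, small_scenario)
        np.testing.assert_allclose(
            base.values.to_numpy(), scaled.values.to_numpy(), atol=1e-12
        )

    def test_dimension_mismatch_rejected(self, small_scenario,
                                         small_truth_parts):
        net, act, _ = small_truth_parts
        short = nca.ActivityEnsemble.from_truth(
            act.mean.iloc[:, :10], act.time_points[:10]
        )
        with pytest.raises(ValueError):
            sd.generate_expression(short, net, small_scenario)


class TestMetabolites:
    def test_hill_midpoint(self):
        x = sd.invert_hill(np.array([0.5]), K_H=50.0, h=1.0, mode="activation")
        assert x[0] == pytest.approx(50.0)

    def test_planted_activation_round_trip(self, small_scenario,
                                           small_truth_parts):
        """Noiseless planted couplings are recovered by the Hill fitter
        to within 1% of K_H with near-perfect R^2."""
        net, act, _ = small_truth_parts
        table, truth = sd.generate_metabolites(act, small_scenario)
        aligned = hill_fit.align_series(table, act, window=1.0)
        for planted in truth["planted"]:
            if planted["lag"]:
                continue
            x = aligned.metabolites.loc[planted["metabolite_id"]].to_numpy()
            y = aligned.activities.loc[planted["regulator_id"]].to_numpy()
            fit = hill_fit.fit_hill_pair(x, y, seed=0)
            assert fit.model.mode == planted["mode"]
            assert fit.model.K_H == pytest.approx(planted["K_H"], rel=0.01)
            assert fit.r_squared > 0.999

    def test_inhibition_gives_negative_correlation(self, small_scenario,
                                                   small_truth_parts):
        net, act, _ = small_truth_parts
        table, truth = sd.generate_metabolites(act, small_scenario)
        inhib = [p for p in truth["planted"]
                 if p["mode"] == "inhibition" and p["lag"] == 0]
        assert inhib
        for planted in inhib:
            x = np.interp(
                small_scenario.transcriptome_times,
                small_scenario.metabolome_times,
                table.mean_profiles().loc[planted["metabolite_id"]].to_numpy(),
            )
            y = act.mean.loc[planted["regulator_id"]].to_numpy()
            assert np.corrcoef(x, y)[0, 1] < 0

    def test_constant_activity_warns_and_skips(self):
        sc = sd.SyntheticScenario(
            n_metabolites=2,
            planted_interactions=[
                sd.PlantedInteraction("met00", "tf01", "activation", 50.0, 2.0)
            ],
            seed=5,
        )
        act = sd.generate_tf_activities(sc, constant_regulators=("tf01",))
        with pytest.warns(UserWarning, match="constant"):
            _, truth = sd.generate_metabolites(act, sc)
        assert truth["planted"] == []

    def test_seed_determinism(self, small_scenario, small_truth_parts):
        _, act, _ = small_truth_parts
        a, _ = sd.generate_metabolites(act, small_scenario)
        b, _ = sd.generate_metabolites(act, small_scenario)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestToyMetabolicModel:
    def test_structure(self, small_scenario, small_truth_parts):
        net, _, _ = small_truth_parts
        model = sd.generate_toy_metabolic_model(small_scenario, net)
        assert len(set(model.subsystems.values())) >= 3
        assert model.cofactors
        compartments = set(model.compartments.values())
        assert {"p", "e"} <= compartments
        assert model.geneless_reactions

    def test_planted_metabolite_adjacent_to_target_gene(self, small_scenario,
                                                        small_truth_parts):
        net, _, _ = small_truth_parts
        model = sd.generate_toy_metabolic_model(small_scenario, net)
        f_prime, _ = metnet_distance.build_adjacency(model)
        for planted in small_scenario.planted_interactions:
            row = f_prime.loc[planted.metabolite_id]
            hit = set(row.index[row]) & net.targets_of(planted.regulator_id)
            assert hit, planted

    def test_linear_pathway_distance(self):
        """m0 -r0- m1 -r1- m2 -r2- m3 -r3- m4 with one gene per reaction:
        the first metabolite is 7 steps from the last reaction's gene on
        the alternating metabolite/gene graph."""
        mets = [f"m{i}" for i in range(5)]
        rxns = [f"r{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(4)]
        n = pd.DataFrame(0.0, index=mets, columns=rxns)
        g = pd.DataFrame(False, index=rxns, columns=genes)
        for i in range(4):
            n.iloc[i, i] = -1.0
            n.iloc[i + 1, i] = 1.0
            g.iloc[i, i] = True
        model = metnet_distance.MetabolicModel(n, g)
        _, graph = metnet_distance.build_adjacency(model)
        dist = metnet_distance.all_pairs_distance(graph)
        assert dist.distance("m0", "g3") == 7
        assert dist.distance("m0", "g0") == 1

    def test_cofactor_pruned_from_graph(self, small_scenario,
                                        small_truth_parts):
        net, _, _ = small_truth_parts
        model = sd.generate_toy_metabolic_model(small_scenario, net)
        f_prime, graph = metnet_distance.build_adjacency(model)
        for cof in model.cofactors:
            assert cof not in f_prime.index
            assert ("met", cof) not in graph
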