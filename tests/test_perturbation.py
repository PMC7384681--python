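import numpy as np
import pytest

import perturbnet as pn
from perturbnet.perturbation import (
    DEFAULT_DOSE_GRID,
    HillFit,
    InhibitionSpec,
    estimate_ec50_map,
    hill_curve,
)


@pytest.fixture(scope="module")
def toy_ensemble():
    """Two small models sharing the node set (3 molecular + 2 phenotypes)."""
    return [
        pn.generate_ground_truth(
            pn.GroundTruthSpec(
                n_molec=3, n_phen=2, n_drug=2, edge_density=0.6,
                drug_target_count=2, phen_in_degree=2, seed=s,
            )
        )
        for s in (31, 32)
    ]


class TestSimulateInhibition:
    def test_zero_dose_changes_nothing(self, toy_ensemble):
        out = pn.simulate_inhibition(
            toy_ensemble[0], InhibitionSpec(targets={"node000": 0.0})
        )
        assert all(v == 0.0 for v in out.values())

    def test_pair_with_zero_dose_equals_single(self, toy_ensemble):
        p = toy_ensemble[0]
        single = pn.simulate_inhibition(p, InhibitionSpec(targets={"node000": 2.0}))
        padded = pn.simulate_inhibition(
            p, InhibitionSpec(targets={"node000": 2.0, "node001": 0.0})
        )
        assert single == padded

    def test_phenotype_target_rejected(self, toy_ensemble):
        with pytest.raises(ValueError, match="molecular"):
            pn.simulate_inhibition(
                toy_ensemble[0], InhibitionSpec(targets={"apoptosis": 1.0})
            )

    def test_agrees_with_adaptive_reference(self, toy_ensemble):
        from scipy.integrate import solve_ivp

        p = toy_ensemble[0]
        c = 1.5
        idx = 1
        pert = np.zeros(p.n_meas)
        pert[idx] = -c

        def rhs(t, x):
            return p.eps * np.tanh(p.W @ x + pert) - p.alpha * x

        ref = solve_ivp(
            rhs, (0, 72.0), np.zeros(p.n_meas), t_eval=[72.0],
            rtol=1e-10, atol=1e-12,
        ).y[:, 0]
        got = pn.simulate_inhibition(
            p, InhibitionSpec(targets={"node001": c}), step_h=0.01
        )
        for i, name in enumerate(p.phenotype_names):
            assert abs(got[name] - ref[p.n_molec + i]) < 1e-3

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            InhibitionSpec(targets={"node000": -1.0})


class TestHillFit:
    def test_recovers_exact_hill_curve(self):
        doses = np.geomspace(0.01, 100, 12)
        true = dict(e1=-1.0, ec50=0.5, n=2.0)
        fit = pn.fit_hill(doses, hill_curve(doses, true["e1"], true["ec50"], true["n"]))
        assert fit.e1 == pytest.approx(true["e1"], rel=1e-6)
        assert fit.ec50 == pytest.approx(true["ec50"], rel=1e-6)
        assert fit.hill_n == pytest.approx(true["n"], rel=1e-6)
        assert not fit.no_effect

    def test_half_effect_at_ec50(self):
        fit = HillFit(e1=-0.8, ec50=1.3, hill_n=2.5, residual=0.0, no_effect=False)
        assert fit.curve(np.array([1.3]))[0] == pytest.approx(-0.4)

    def test_zero_dose_response_is_zero(self):
        assert hill_curve(np.array([0.0]), e1=5.0, ec50=1.0, n=2.0)[0] == 0.0

    def test_flat_curve_flagged_no_effect(self):
        doses = np.geomspace(0.01, 100, 12)
        fit = pn.fit_hill(doses, np.full(12, 0.001))
        assert fit.no_effect and np.isnan(fit.ec50)

    def test_monotone_along_fitted_curve(self):
        doses = np.geomspace(0.01, 100, 12)
        fit = pn.fit_hill(doses, hill_curve(doses, -0.7, 2.0, 1.5))
        curve = np.abs(fit.curve(doses))
        assert np.all(np.diff(curve) >= -1e-12)


class TestDoseResponse:
    def test_mean_curve_and_fits(self, toy_ensemble):
        dr = pn.dose_response(toy_ensemble, "node000")
        assert set(dr.mean_response) == {"cell_growth", "apoptosis"}
        assert all(len(v) == len(dr.doses) for v in dr.mean_response.values())
        assert set(dr.fits) == {"cell_growth", "apoptosis"}

    def test_grid_validation(self, toy_ensemble):
        with pytest.raises(ValueError, match="decade"):
            pn.dose_response(toy_ensemble, "node000", dose_grid=np.linspace(1, 2, 8))


class TestScreen:
    def test_counts_bookkeeping(self):
        counts = pn.screen_counts(124, 101)
        assert counts["pair_conditions"] == 15_252
        assert counts["responses_per_phenotype"] == 1_540_452

    def test_matches_per_pair_brute_force(self, toy_ensemble):
        ec50 = {"node000": 1.0, "node001": 0.5, "node002": 2.0}
        screen = pn.combinatorial_screen(toy_ensemble, ec50, "cell_growth")
        nodes = screen.nodes
        for i in range(3):
            for j in range(i, 3):
                targets = {nodes[i]: ec50[nodes[i]]}
                if j != i:
                    targets[nodes[j]] = ec50[nodes[j]]
                vals = [
                    pn.simulate_inhibition(p, InhibitionSpec(targets=targets))[
                        "cell_growth"
                    ]
                    for p in toy_ensemble
                ]
                assert screen.matrix[i, j] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_symmetric_with_single_diagonal(self, toy_ensemble):
        ec50 = {"node000": 1.0, "node001": 0.5, "node002": 2.0}
        screen = pn.combinatorial_screen(toy_ensemble, ec50, "apoptosis")
        assert np.array_equal(screen.matrix, screen.matrix.T)
        assert screen.n_pair_conditions == 6
        assert screen.n_simulated_responses == 12

    def test_missing_ec50_without_fallback_listed(self, toy_ensemble):
        with pytest.raises(ValueError, match="node002"):
            pn.combinatorial_screen(
                toy_ensemble, {"node000": 1.0, "node001": 0.5}, "cell_growth"
            )

    def test_fallback_dose_fills_gaps(self, toy_ensemble):
        screen = pn.combinatorial_screen(
            toy_ensemble, {"node000": 1.0}, "cell_growth", fallback_dose=1.0
        )
        assert np.all(np.isfinite(screen.matrix))

    def test_ec50_map_batches_all_nodes(self, toy_ensemble):
        ec50, fits = estimate_ec50_map(toy_ensemble, "cell_growth")
        assert set(ec50) == {"node000", "node001", "node002"}
        for n, f in fits.items():
            assert f.no_effect or f.ec50 > 0


class TestRanking:
    def _screen(self, matrix, phenotype="cell_growth"):
        n = matrix.shape[0]
        return pn.ScreenResult(
            phenotype=phenotype, nodes=[f"n{i}" for i in range(n)],
            matrix=matrix, doses={}, n_models=1,
        )

    def test_single_best_pair_ranked_first(self):
        m = np.zeros((3, 3))
        m[0, 2] = m[2, 0] = -5.0
        ranked = pn.rank_targets(self._screen(m), top_unique=3)
        assert (ranked[0].node_a, ranked[0].node_b) == ("n0", "n2")
        assert ranked[0].effect == -5.0

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        ranked = pn.rank_targets(self._screen(m), top_unique=6)
        oracle = sorted(
            ((m[i, j], f"n{i}", f"n{j}") for i in range(6) for j in range(i + 1, 6))
        )
        got = [(r.effect, r.node_a, r.node_b) for r in ranked]
        assert got == [o for o in oracle[: len(got)]]

    def test_walks_until_top_unique_nodes(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(8, 8))
        m = (m + m.T) / 2
        ranked = pn.rank_targets(self._screen(m), top_unique=4)
        nodes = set()
        for r in ranked:
            nodes.update((r.node_a, r.node_b))
        assert len(nodes) >= 4
        # removing the last combination leaves fewer than top_unique nodes
        nodes_before = set()
        for r in ranked[:-1]:
            nodes_before.update((r.node_a, r.node_b))
        assert len(nodes_before) < 4

    def test_apoptosis_direction_is_ascending_desirability(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 3.0
        ranked = pn.rank_targets(self._screen(m, "apoptosis"), top_unique=2)
        assert ranked[0].effect == 3.0  # most-positive first for apoptosis

    def test_default_top_unique_is_twenty(self):
        import inspect

        assert inspect.signature(pn.rank_targets).parameters["top_unique"].default == 20
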