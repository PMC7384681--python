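import numpy as np
import pandas as pd
import pytest

import perturbnet as pn
from perturbnet import normalization as norm
from perturbnet import synthetic as syn


from _oracles import brute_force_cooks


class TestDilutionFit:
    def test_pseudoinverse_rows_match_closed_form(self):
        for c in (1.0, 0.2, 3.7):
            P = norm.dilution_pseudoinverse(c)
            assert np.allclose(P[0], [1.0, 0.5, 0.0, -0.5])
            assert np.allclose(P[1], np.array([-6, -2, 2, 6]) / (5 * c))

    def test_exactly_linear_spots(self):
        fit = norm.fit_dilution_series(np.array([1.0, 2.0, 3.0, 4.0]), 1.0)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-12)
        assert fit.beta1 == pytest.approx(4.0, abs=1e-12)

    def test_constant_spots(self):
        fit = norm.fit_dilution_series(np.array([5.0, 5.0, 5.0, 5.0]), 0.37)
        assert fit.beta0 == pytest.approx(5.0) and fit.beta1 == pytest.approx(0.0, abs=1e-9)

    def test_matches_generic_least_squares(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.uniform(0.05, 2.0)
            spots = rng.uniform(0, 100, 4)
            fit = norm.fit_dilution_series(spots, c)
            A = np.column_stack([np.ones(4), np.array(syn.DILUTION_FRACTIONS) * c])
            beta, *_ = np.linalg.lstsq(A, spots, rcond=None)
            assert abs(fit.beta0 - beta[0]) <= 1e-10 * max(1, abs(beta[0]))
            assert abs(fit.beta1 - beta[1]) <= 1e-10 * max(1, abs(beta[1]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            norm.fit_dilution_series(np.array([1.0, np.nan, 3.0, 4.0]), 1.0)


class TestCooksDistance:
    def test_collinear_spots_unflagged(self):
        spots = np.array([2.0, 4.0, 6.0, 8.0])
        assert not norm.detect_outlier_spots(spots, 1.0).any()

    def test_gross_endpoint_deviation_flagged_and_repaired(self):
        # an endpoint outlier is always among the flagged spots, the flags
        # match the leave-one-out oracle, and the refit on the surviving
        # clean spots reproduces the uncorrupted RFI exactly
        clean = np.array([2.0, 4.0, 6.0, 8.0])
        spots = clean.copy()
        spots[3] = 80.0
        flagged = norm.detect_outlier_spots(spots, 1.0)
        assert flagged[3]
        assert np.array_equal(flagged, brute_force_cooks(spots, 1.0) > 0.8)
        assert norm.sample_rfi(spots, 1.0) == pytest.approx(
            norm.sample_rfi(clean, 1.0), abs=1e-9
        )

    def test_interior_deviation_flags_match_oracle(self):
        # Cook's distances depend only on the residual *pattern*, so an
        # interior outlier shifts suspicion to the high-leverage endpoint;
        # the implementation must reproduce exactly what the textbook
        # formula says, not an idealized expectation
        spots = np.array([2.0, 40.0, 6.0, 8.0])
        flagged = norm.detect_outlier_spots(spots, 1.0)
        assert np.array_equal(flagged, brute_force_cooks(spots, 1.0) > 0.8)

    def test_matches_leave_one_out_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            c = rng.uniform(0.1, 1.0)
            spots = rng.uniform(0, 50, 4)
            assert np.allclose(
                norm.cooks_distances(spots, c), brute_force_cooks(spots, c),
                rtol=1e-9, atol=1e-12,
            )

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        for _ in range(20):
            c = rng.uniform(0.1, 1.0)
            spots = rng.uniform(0, 50, 4)
            conc = np.array(syn.DILUTION_FRACTIONS) * c
            ols = sm.OLS(spots, sm.add_constant(conc)).fit()
            ref = ols.get_influence().cooks_distance[0]
            assert np.allclose(norm.cooks_distances(spots, c), ref, rtol=1e-9)

    def test_unusable_sample_propagates_nan(self):
        spots = np.array([1.0, 30.0, 2.0, 45.0])
        # absurdly strict cutoff: >2 spots flagged -> unusable -> NaN
        assert norm.detect_outlier_spots(spots, 1.0, cutoff=1e-6) is None
        assert np.isnan(norm.sample_rfi(spots, 1.0, cutoff=1e-6))


class TestRfi:
    def test_direct_arithmetic(self):
        assert norm.compute_rfi(norm.LinearFit(0.0, 4.0, np.ones(4, bool)), 0.2) == pytest.approx(0.5)

    def test_slope_free_case(self):
        fit = norm.LinearFit(7.0, 0.0, np.ones(4, bool))
        for c_bar in (0.1, 0.2, 5.0):
            assert norm.compute_rfi(fit, c_bar) == 7.0

    def test_default_reference_concentration(self):
        assert norm.REFERENCE_CONC == 0.2


class TestDoubleMedian:
    def test_hand_computed_2x2(self):
        m = pd.DataFrame([[1.0, 3.0], [2.0, 6.0]])
        out = norm.double_median_normalize(m)
        assert np.allclose(out.to_numpy(), [[0.5, -0.5], [-0.5, 0.5]])

    def test_centered_input_unchanged(self):
        m = pd.DataFrame([[0.5, -0.5], [-0.5, 0.5]])
        assert np.allclose(norm.double_median_normalize(m).to_numpy(), m.to_numpy())

    def test_per_sample_median_is_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = pd.DataFrame(rng.normal(2, 5, size=(rng.integers(3, 9), rng.integers(3, 9))))
            out = norm.double_median_normalize(m)
            assert np.allclose(out.median(axis=0).to_numpy(), 0.0, atol=1e-12)

    def test_all_missing_row_named_in_error(self):
        m = pd.DataFrame(np.ones((3, 3)), index=["a", "bad", "c"])
        m.loc["bad"] = np.nan
        with pytest.raises(ValueError, match="bad"):
            norm.double_median_normalize(m)


class TestProteinFactors:
    def test_unit_factors_identity(self):
        m = pd.DataFrame(np.arange(6.0).reshape(2, 3), columns=list("abc"))
        out = norm.protein_factor_normalize(m, pd.Series(1.0, index=list("abc")))
        assert np.allclose(out.to_numpy(), m.to_numpy())

    def test_factor_two_shifts_log2_by_minus_one(self):
        m = pd.DataFrame([[8.0, 8.0, 8.0]], columns=list("abc"))
        out = norm.protein_factor_normalize(
            m, pd.Series([1.0, 1.0, 2.0], index=list("abc"))
        )
        shift = np.log2(out["c"]) - np.log2(m["c"])
        assert shift.iloc[0] == pytest.approx(-1.0)

    def test_recentring_enforces_unit_median(self):
        rng = np.random.default_rng(4)
        factors = pd.Series(rng.uniform(0.5, 2.0, 7), index=[f"s{i}" for i in range(7)])
        m = pd.DataFrame(np.ones((2, 7)), columns=factors.index)
        out = norm.protein_factor_normalize(m, factors)
        centered = factors / factors.median()
        assert centered.median() == pytest.approx(1.0)
        assert np.allclose(out.to_numpy(), (m / centered).to_numpy())

    def test_nonpositive_factor_rejected(self):
        m = pd.DataFrame(np.ones((2, 2)), columns=list("ab"))
        with pytest.raises(ValueError, match="positive"):
            norm.protein_factor_normalize(m, pd.Series([1.0, 0.0], index=list("ab")))


class TestControlNormalize:
    def _dataset(self, values):
        values = np.asarray(values, dtype=float)
        return pn.ResponseDataset(
            nodes=[f"n{i}" for i in range(values.shape[0])],
            n_phen=0,
            conditions=[f"c{i}" for i in range(values.shape[1])],
            times=np.arange(1.0, values.shape[2] + 1),
            values=values,
            mask=np.ones_like(values, dtype=bool),
        )

    def test_control_column_becomes_zero(self):
        ds = self._dataset(np.random.default_rng(0).normal(size=(3, 4, 2)))
        out = norm.control_normalize(ds, "c0")
        assert np.all(out.values[:, 0, :] == 0.0)

    def test_log2_ratio_identity(self):
        # raw value exactly 2x control on the linear scale -> log2 diff of 1
        ds = self._dataset([[[3.0], [4.0]]])
        out = norm.control_normalize(ds, "c0")
        assert out.values[0, 1, 0] == pytest.approx(1.0)

    def test_missing_control_time_listed(self):
        ds = self._dataset(np.ones((2, 2, 3)))
        ds.mask[:, 0, 1] = False
        ds.values[:, 0, 1] = np.nan
        with pytest.raises(ValueError, match="2.0"):
            norm.control_normalize(ds, "c0")


class TestMergeDatasets:
    def _panel(self, names, value, conditions=("DMSO", "x"), times=(1.0, 2.0)):
        shape = (len(names), len(conditions), len(times))
        return pn.ResponseDataset(
            nodes=list(names), n_phen=0, conditions=list(conditions),
            times=np.array(times), values=np.full(shape, float(value)),
            mask=np.ones(shape, dtype=bool),
        )

    def test_disjoint_union(self):
        merged = norm.merge_datasets(
            self._panel(["a", "b", "c"], 1.0), self._panel(["d", "e", "f", "g"], 2.0)
        )
        assert len(merged.nodes) == 7

    def test_overlap_count_and_mean_rule(self):
        ds1 = self._panel([f"ab{i}" for i in range(71)], 1.0)
        ds2 = self._panel([f"ab{i}" for i in range(38, 124)], 3.0)  # 86 antibodies, 33 shared
        merged = norm.merge_datasets(ds1, ds2)
        assert len(merged.nodes) == 124
        shared_idx = merged.nodes.index("ab40")
        assert np.all(merged.values[shared_idx] == 2.0)  # mean of the two panels

    def test_design_mismatch_rejected(self):
        with pytest.raises(ValueError, match="design"):
            norm.merge_datasets(
                self._panel(["a"], 1.0), self._panel(["b"], 1.0, conditions=("DMSO",))
            )


class TestPhenotypeNormalization:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["phenotype", "condition", "time_h", "count"])

    def test_equal_counts_give_zero(self):
        counts = self._counts(
            [["cells", "DMSO", 3.0, 500], ["cells", "drugA", 3.0, 500]]
        )
        out = norm.normalize_phenotype(counts, "DMSO")
        assert out.loc[out.condition == "drugA", "value"].iloc[0] == 0.0

    def test_half_of_control_is_minus_one(self):
        counts = self._counts(
            [["cells", "DMSO", 9.0, 800], ["cells", "drugA", 9.0, 400]]
        )
        out = norm.normalize_phenotype(counts, "DMSO")
        assert out.loc[out.condition == "drugA", "value"].iloc[0] == pytest.approx(-1.0)

    def test_replicate_median_of_log2_ratios(self):
        # replicate log2 ratios (1, 2, 9) -> median 2
        rows = []
        for rep, count in enumerate([2, 4, 512]):
            rows.append(["cells", "drugA", 3.0, count, rep])
            rows.append(["cells", "DMSO", 3.0, 1, rep])
        counts = pd.DataFrame(
            rows, columns=["phenotype", "condition", "time_h", "count", "replicate"]
        )
        out = norm.normalize_phenotype(counts, "DMSO")
        assert out.loc[out.condition == "drugA", "value"].iloc[0] == pytest.approx(2.0)

    def test_subsampled_to_phenotype_grid(self):
        rows = [["cells", "DMSO", t, 100] for t in (0.5, 1.0, 2.0, 3.0, 67.0)]
        rows += [["cells", "drugA", t, 200] for t in (0.5, 1.0, 2.0, 3.0, 67.0)]
        out = norm.normalize_phenotype(self._counts(rows), "DMSO")
        assert sorted(out["time_h"].unique()) == [1.0, 3.0, 67.0]

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            norm.normalize_phenotype(
                self._counts([["cells", "DMSO", 3.0, 0]]), "DMSO"
            )


class TestFullChainRoundTrip:
    def test_recovers_generating_values_up_to_median_offsets(self):
        design = syn.demo_design(2, include_control=True)
        truth = pn.generate_ground_truth(
            pn.GroundTruthSpec(n_molec=6, n_phen=1, n_drug=2, edge_density=0.3, seed=5)
        )
        ds = pn.simulate_dataset(
            truth, design, time_points_h=[1.0, 4.0], phenotype_times_h=[4.0],
            noise_sd=0.0, seed=0,
        )
        molec = pn.ResponseDataset(
            nodes=ds.molecular_nodes, n_phen=0, conditions=ds.conditions,
            times=ds.times, values=ds.values[: ds.n_molec],
            mask=ds.mask[: ds.n_molec], design=ds.design, control_label="DMSO",
        )
        raw = pn.generate_raw_spot_table(molec, outlier_rate=0.0, seed=9)
        chain = norm.normalize_raw_spot_table(raw, "DMSO", design=ds.design)

        # oracle: recompute the chain from the exact RFI values
        rfi = norm.spot_table_to_rfi(raw)
        rfi["sample"] = list(zip(rfi["condition"], rfi["time_h"], rfi["replicate"]))
        wide = np.log2(rfi.pivot(index="antibody", columns="sample", values="rfi"))
        dm = norm.double_median_normalize(wide)
        # per-sample offset introduced by the median passes, relative to control
        sample_cols = list(dm.columns)
        node_order = [molec.nodes.index(a) for a in dm.index]
        expected = {}
        for cond, t, _rep in sample_cols:
            ci = molec.condition_index(cond)
            ti = list(molec.times).index(t)
            expected[(cond, t)] = molec.values[node_order, ci, ti]
        offsets = {
            s: np.median(dm[s].to_numpy() - expected[(s[0], s[1])])
            for s in sample_cols
        }
        for cond, t, _rep in sample_cols:
            ci = chain.condition_index(cond)
            ti = list(chain.times).index(t)
            got = chain.values[:, ci, ti]
            want = (
                expected[(cond, t)]
                - expected[("DMSO", t)][:]
                + offsets[(cond, t, 0)]
                - offsets[("DMSO", t, 0)]
            )
            reordered = np.array([got[chain.nodes.index(a)] for a in dm.index])
            assert np.allclose(reordered, want, atol=1e-9)

    def test_outliers_are_absorbed(self):
        truth = pn.generate_ground_truth(
            pn.GroundTruthSpec(n_molec=8, n_phen=1, n_drug=2, edge_density=0.3, seed=6)
        )
        design = syn.demo_design(2, include_control=True)
        ds = pn.simulate_dataset(
            truth, design, time_points_h=[2.0], phenotype_times_h=[2.0],
            noise_sd=0.0, seed=0,
        )
        molec = pn.ResponseDataset(
            nodes=ds.molecular_nodes, n_phen=0, conditions=ds.conditions,
            times=ds.times, values=ds.values[: ds.n_molec],
            mask=ds.mask[: ds.n_molec], design=ds.design, control_label="DMSO",
        )
        clean_raw = pn.generate_raw_spot_table(molec, outlier_rate=0.0, seed=2)
        # corrupt only endpoint spots: Cook's flags the endpoints, the refit
        # runs through the two clean interior spots and the chain output is
        # bit-identical to the clean one
        dirty_raw = clean_raw.copy()
        hit = (dirty_raw["spot_index"] == 3) & (
            dirty_raw["antibody"].isin(["node000", "node003"])
        )
        dirty_raw.loc[hit, "intensity"] *= 10.0
        clean = norm.normalize_raw_spot_table(clean_raw, "DMSO", design=ds.design)
        dirty = norm.normalize_raw_spot_table(dirty_raw, "DMSO", design=ds.design)
        assert np.array_equal(clean.mask, dirty.mask)
        assert np.allclose(
            clean.values[clean.mask], dirty.values[dirty.mask], atol=1e-9
        )
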