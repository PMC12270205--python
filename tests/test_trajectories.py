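"""Regional composites, baseline GLM, and longitudinal mixed models."""

import numpy as np
import pandas as pd
import pytest

from neurobag import synth, trajectories as traj


class TestNormalizeAndAggregate:
    def _volumetrics(self):
        return pd.DataFrame({
            "scan_id": ["a", "b"],
            "hippocampus": [4.847, 4.0], "entorhinal": [2.334, 2.0],
            "amygdala": [1.997, 1.8], "parahippocampal": [2.503, 2.2],
            "icv": [1500.0, 1500.0],
        })

    def test_division_rule(self):
        out = traj.normalize_and_aggregate(self._volumetrics())
        assert out.loc[0, "hippocampus_norm"] == pytest.approx(4.847 / 1500.0)
        assert out.loc[0, "hippocampus_norm"] == pytest.approx(3.231e-3, rel=1e-3)

    def test_composite_is_sum_of_constituents(self):
        out = traj.normalize_and_aggregate(self._volumetrics())
        expected = (4.847 + 2.334 + 1.997 + 2.503) / 1500.0
        assert out.loc[0, "mtl"] == pytest.approx(expected)

    def test_zero_constituents_zero_composite(self):
        df = self._volumetrics()
        for c in ("hippocampus", "entorhinal", "amygdala", "parahippocampal"):
            df[c] = 0.0
        out = traj.normalize_and_aggregate(df)
        assert (out["mtl"] == 0.0).all()

    def test_doubling_icv_halves_values(self):
        df = self._volumetrics()
        out1 = traj.normalize_and_aggregate(df)
        df2 = df.assign(icv=df["icv"] * 2)
        out2 = traj.normalize_and_aggregate(df2)
        assert np.allclose(out2["mtl"], out1["mtl"] / 2)

    def test_missing_constituent_marks_composite_missing(self):
        df = self._volumetrics().drop(columns="amygdala")
        out = traj.normalize_and_aggregate(df)
        assert out["mtl"].isna().all()

    def test_nonpositive_icv_rejected(self):
        df = self._volumetrics().assign(icv=[1500.0, 0.0])
        with pytest.raises(ValueError):
            traj.normalize_and_aggregate(df)

    def test_mean_aggregation_flag(self):
        out = traj.normalize_and_aggregate(self._volumetrics(), aggregate="mean")
        expected = (4.847 + 2.334 + 1.997 + 2.503) / 1500.0 / 4
        assert out.loc[0, "mtl"] == pytest.approx(expected)


def _long_table(group_effect=None, n_per_group=25, n_visits=4, seed=0,
                noise=0.5, slope_effect=None, quad_effect=None,
                groups=synth.GROUPS_CI):
    """Hand-rolled longitudinal generator used as an independent fixture."""
    rng = np.random.default_rng(seed)
    group_effect = group_effect or {}
    slope_effect = slope_effect or {}
    quad_effect = quad_effect or {}
    rows = []
    for g in groups:
        for i in range(n_per_group):
            sid = f"{g}_{i}"
            age = rng.uniform(60, 85)
            sex = "F" if rng.uniform() < 0.5 else "M"
            cs = "MCI" if rng.uniform() < 0.7 else "dementia"
            edu = rng.uniform(12, 20)
            b0 = rng.normal(0, 1.0) if noise else 0.0
            b1 = rng.normal(0, 0.1) if noise else 0.0
            for t in range(n_visits):
                mu = (10.0 + group_effect.get(g, 0.0)
                      + (0.2 + slope_effect.get(g, 0.0)) * t
                      + quad_effect.get(g, 0.0) * t * t + b0 + b1 * t)
                if noise:
                    mu += rng.normal(0, noise)
                rows.append({"subject_id": sid, "group": g, "time": float(t),
                             "value": mu, "baseline_age": age, "sex": sex,
                             "cognitive_state": cs, "education": edu})
    return pd.DataFrame(rows)


class TestBaselineGLM:
    def test_noise_free_indicator_recovered_exactly(self):
        df = _long_table(group_effect={"AD+LB+": 1.0}, noise=0.0, n_visits=1)
        out = traj.fit_baseline_glm(df)
        coefs = out["coefficients"]["beta"]
        assert coefs["group[AD+LB+]"] == pytest.approx(1.0, abs=1e-10)
        assert coefs["group[AD+LB-]"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_baseline_offsets_recovered(self):
        """Reported baseline BAG contrasts (AD+LB- = 2.25, AD+LB+ = 3.53)
        are recovered within 2 SE at reference-cohort group sizes."""
        rng_sizes = synth.DEFAULT_CI_SIZES
        df = []
        for g, n in rng_sizes.items():
            df.append(_long_table(
                group_effect={"AD-LB+": 0.94, "AD+LB-": 2.25, "AD+LB+": 3.53},
                n_per_group=n, n_visits=1, seed=1, noise=3.0, groups=[g]))
        df = pd.concat(df, ignore_index=True)
        out = traj.fit_baseline_glm(df)
        coefs, se = out["coefficients"]["beta"], out["coefficients"]["se"]
        assert abs(coefs["group[AD+LB-]"] - 2.25) < 2 * se["group[AD+LB-]"]
        assert abs(coefs["group[AD+LB+]"] - 3.53) < 2 * se["group[AD+LB+]"]

    def test_contrast_table_covers_all_pairs(self):
        df = _long_table(n_visits=1, seed=2)
        out = traj.fit_baseline_glm(df)
        assert len(out["contrasts"]) == 6

    def test_rank_deficient_design_names_columns(self):
        df = _long_table(n_visits=1, seed=3)
        df["education"] = df["baseline_age"]  # alias two covariates
        with pytest.raises(ValueError, match="aliased"):
            traj.fit_baseline_glm(df)


class TestFitLMM:
    def test_noise_free_single_group_recovers_slope(self):
        df = _long_table(noise=0.0, groups=["AD+LB-"], slope_effect={"AD+LB-": 0.13})
        fit = traj.fit_lmm(df, order="linear")
        assert fit.params["time"] == pytest.approx(0.33, abs=1e-4)

    def test_group_slopes_recovered_within_3se(self):
        df = _long_table(slope_effect={"AD-LB+": 0.11, "AD+LB-": 0.26,
                                       "AD+LB+": 0.51}, seed=4, n_per_group=40)
        fit = traj.fit_lmm(df, order="linear")
        for g, truth in (("AD-LB+", 0.11), ("AD+LB-", 0.26), ("AD+LB+", 0.51)):
            name = f"group[{g}]:time"
            assert abs(fit.params[name] - truth) < 3 * fit.se[name]

    def test_quadratic_nests_linear(self):
        df = _long_table(seed=5, quad_effect={"AD+LB+": 0.05})
        lin = traj.fit_lmm(df, order="linear")
        quad = traj.fit_lmm(df, order="quadratic")
        assert quad.llf >= lin.llf - 1e-6

    def test_bic_selects_generating_order(self):
        lin_df = _long_table(seed=6, slope_effect={"AD+LB+": 0.5}, n_per_group=40)
        quad_df = _long_table(seed=7, quad_effect={g: 0.3 for g in synth.GROUPS_CI},
                              n_per_group=40)
        assert traj.fit_trajectory(lin_df, order="auto").order == "linear"
        assert traj.fit_trajectory(quad_df, order="auto").order == "quadratic"

    def test_tie_goes_to_linear(self):
        df = _long_table(seed=8)
        lin = traj.fit_lmm(df, order="linear")
        quad = traj.fit_lmm(df, order="quadratic")
        quad.bic = lin.bic
        assert traj.select_model_bic(lin, quad) is lin

    def test_failed_rival_returns_survivor_with_warning(self):
        df = _long_table(seed=9)
        lin = traj.fit_lmm(df, order="linear")
        with pytest.warns(UserWarning):
            assert traj.select_model_bic(lin, None) is lin


class TestPairwiseContrasts:
    def test_contrast_table_structure(self):
        df = _long_table(seed=10, slope_effect={"AD+LB+": 0.6})
        fit = traj.fit_lmm(df, order="linear")
        tab = fit.contrast_table
        assert set(tab["family"]) == {"baseline", "slope"}
        assert (tab.groupby("family").size() == 6).all()

    def test_bh_adjustment_hand_example(self):
        assert np.allclose(traj.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_bh_all_ones(self):
        assert np.allclose(traj.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_bh_monotone_after_sorting(self):
        rng = np.random.default_rng(11)
        raw = rng.uniform(0, 1, 9)
        adj = traj.benjamini_hochberg(raw)
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_strong_slope_contrast_detected(self):
        df = _long_table(seed=12, slope_effect={"AD+LB+": 0.8}, n_per_group=40)
        fit = traj.fit_lmm(df, order="linear")
        tab = fit.contrast_table
        row = tab[(tab["family"] == "slope") & (tab["group_a"] == "AD+LB+")
                  | (tab["family"] == "slope") & (tab["group_b"] == "AD+LB+")]
        assert row["significant"].all()


class TestGeneratorRoundTrip:
    def test_planted_mtl_contrast_sign(self, gen_params):
        """The co-pathology vs AD-only MTL slope contrast is negative when
        fit on generator output with defaults."""
        rng = np.random.default_rng(13)
        _, subjects = synth.generate_cohort(
            0, {"AD-LB-": 60, "AD-LB+": 20, "AD+LB-": 60, "AD+LB+": 60},
            synth.GeneratorParams(seed=13, intermediate_frac=0.0,
                                  visit_count_range=(3, 5)))
        df = synth.generate_trajectories(subjects, gen_params, rng=rng,
                                         outcomes=["mtl"])
        fit = traj.fit_lmm(df, order="linear")
        tab = fit.contrast_table
        row = tab[(tab["family"] == "slope")
                  & (tab["group_a"].isin(["AD+LB-", "AD+LB+"]))
                  & (tab["group_b"].isin(["AD+LB-", "AD+LB+"]))].iloc[0]
        # the co-pathology group declines faster, so (AD+LB+ minus AD+LB-)
        # is negative
        beta = row["beta"] if row["group_a"] == "AD+LB+" else -row["beta"]
        assert beta < 0
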