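"""Z-scoring against controls, co-localization profiles, group test, ROC."""

import numpy as np
import pandas as pd
import pytest

from neurocoloc import coloc
from neurocoloc.stats import fisher_z, partial_spearman, spearman_rho


def frame(rows, regions=None):
    rows = np.atleast_2d(rows)
    cols = regions if regions is not None else pd.RangeIndex(1, rows.shape[1] + 1)
    return pd.DataFrame(rows, columns=cols)


class TestZScore:
    def test_patient_at_control_mean_is_zero(self, rng):
        ctl = frame(rng.normal(size=(6, 10)))
        z = coloc.zscore_vs_controls(ctl.mean(axis=0), ctl)
        np.testing.assert_allclose(z, 0, atol=1e-12)

    def test_one_sd_above_is_one(self, rng):
        ctl = frame(rng.normal(size=(6, 10)))
        patient = ctl.mean(axis=0) + ctl.std(axis=0, ddof=1)
        z = coloc.zscore_vs_controls(patient, ctl)
        np.testing.assert_allclose(z, 1, atol=1e-12)

    def test_matches_per_region_loop(self, rng):
        ctl = frame(rng.normal(size=(5, 8)))
        patient = pd.Series(rng.normal(size=8), index=ctl.columns)
        z = coloc.zscore_vs_controls(patient, ctl)
        for r in ctl.columns:
            vals = ctl[r].to_numpy()
            expected = (patient[r] - vals.mean()) / vals.std(ddof=1)
            assert z[r] == pytest.approx(expected, abs=1e-12)

    def test_zero_control_sd_is_missing(self, rng):
        ctl = frame(rng.normal(size=(4, 3)))
        ctl.iloc[:, 1] = 2.5
        z = coloc.zscore_vs_controls(pd.Series([0, 0, 0.0], index=ctl.columns), ctl)
        assert np.isnan(z.iloc[1])

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(ValueError):
            coloc.zscore_vs_controls(pd.Series([1.0]), frame([[1.0]]))


class TestLeaveOneOut:
    def test_contract_one_zmap_per_control(self, rng):
        ctl = frame(rng.normal(size=(5, 6)))
        loo = coloc.loo_control_zscores(ctl)
        assert loo.shape == (5, 6)

    def test_identical_controls_degenerate_to_missing(self):
        ctl = frame(np.ones((4, 5)))
        loo = coloc.loo_control_zscores(ctl)
        assert loo.isna().all().all()

    def test_matches_hold_one_out_recomputation(self, rng):
        ctl = frame(rng.normal(size=(6, 7)))
        loo = coloc.loo_control_zscores(ctl)
        for i in range(6):
            rest = ctl.drop(index=i)
            expected = (ctl.iloc[i] - rest.mean(axis=0)) / rest.std(axis=0, ddof=1)
            np.testing.assert_allclose(loo.iloc[i], expected, atol=1e-12)

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(ValueError):
            coloc.loo_control_zscores(frame(rng.normal(size=(2, 5))))


class TestColocProfile:
    def test_perfectly_monotone_gives_clipped_large_z(self, rng):
        t = pd.Series(rng.normal(size=20), index=range(1, 21))
        z = t.rank()
        out = coloc.coloc_profile(z, t)
        assert out == pytest.approx(fisher_z(1.0))

    def test_independent_vectors_near_zero(self, rng):
        z = pd.Series(rng.normal(size=200), index=range(200))
        t = pd.Series(rng.normal(size=200), index=range(200))
        assert abs(coloc.coloc_profile(z, t)) < 0.2

    def test_monotone_invariance_unadjusted(self, rng):
        z = pd.Series(rng.normal(size=30), index=range(30))
        t = pd.Series(rng.normal(size=30), index=range(30))
        base = coloc.coloc_profile(z, t)
        assert coloc.coloc_profile(np.exp(z), t**3 + 5 * t) == pytest.approx(base, abs=1e-12)

    def test_gm_adjustment_matches_rank_residual_oracle(self, rng):
        n = 60
        idx = range(n)
        z = pd.Series(rng.normal(size=n), index=idx)
        t = pd.Series(rng.normal(size=n), index=idx)
        g = pd.Series(rng.normal(size=n), index=idx)
        got = coloc.coloc_profile(z, t, gm_rv=g, adjust_gm=True)
        expected = fisher_z(partial_spearman(z.to_numpy(), t.to_numpy(), g.to_numpy()))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_missing_regions_deleted_pairwise(self, rng):
        z = pd.Series(rng.normal(size=10), index=range(10))
        t = pd.Series(rng.normal(size=10), index=range(10))
        z.iloc[3] = np.nan
        got = coloc.coloc_profile(z, t)
        keep = z.notna()
        expected = fisher_z(spearman_rho(z[keep].to_numpy(), t[keep].to_numpy()))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_too_few_regions_rejected(self, rng):
        z = pd.Series([1, 2, 3.0])
        with pytest.raises(ValueError, match="4"):
            coloc.coloc_profile(z, z)


class TestGroupTest:
    def build(self, rng, n_pat=10, n_ctl=6, n_reg=30, n_templates=3, effect=0.0):
        tmpl = frame(rng.normal(size=(n_reg, n_templates)).T).T
        tmpl.columns = [f"t{k}" for k in range(n_templates)]
        tmpl.index = pd.RangeIndex(1, n_reg + 1)
        ctl = rng.normal(size=(n_ctl, n_reg))
        pat = rng.normal(size=(n_pat, n_reg)) - effect * tmpl["t0"].to_numpy()
        return frame(pat), frame(ctl), tmpl

    def test_fast_and_general_paths_agree(self, rng):
        pat, ctl, tmpl = self.build(rng, effect=0.8)
        fast = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=150, seed=5)
        general = coloc._coloc_group_test_general(
            pat, ctl, tmpl, None, False, 150, 5, 0.05
        )
        np.testing.assert_allclose(
            fast.table["mean_z"], general.table["mean_z"], atol=1e-10
        )
        # same seed, same permutation stream => identical p-values
        np.testing.assert_allclose(fast.table["p"], general.table["p"], atol=1e-12)

    def test_planted_template_detected(self, rng):
        pat, ctl, tmpl = self.build(rng, effect=1.0)
        res = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=300, seed=2)
        row = res.table.set_index("template").loc["t0"]
        assert row["significant"]
        assert row["mean_r"] < 0

    def test_profiles_match_direct_computation(self, rng):
        pat, ctl, tmpl = self.build(rng)
        res = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=150, seed=1)
        for i in range(len(pat)):
            z = coloc.zscore_vs_controls(pat.iloc[i], ctl)
            for t in tmpl.columns:
                expected = coloc.coloc_profile(z, tmpl[t])
                assert res.profiles.iloc[i][t] == pytest.approx(expected, abs=1e-10)

    def test_mean_r_is_backtransformed_mean_z(self, rng):
        pat, ctl, tmpl = self.build(rng)
        res = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=150, seed=1)
        np.testing.assert_allclose(
            res.table["mean_r"], np.tanh(res.table["mean_z"]), atol=1e-12
        )

    def test_q_at_least_p(self, rng):
        pat, ctl, tmpl = self.build(rng, effect=0.4)
        res = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=200, seed=3)
        assert (res.table["q"] >= res.table["p"] - 1e-12).all()

    def test_p_floor_convention(self, rng):
        pat, ctl, tmpl = self.build(rng, effect=3.0)
        res = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=200, seed=4)
        assert res.table["p"].min() >= 1 / (res.n_perm + 1) - 1e-12

    def test_exact_enumeration_for_tiny_groups(self, rng):
        # C(7, 4) - 1 = 34 distinct reassignments: enumeration kicks in
        pat, ctl, tmpl = self.build(rng, n_pat=4, n_ctl=3, n_reg=12)
        res = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=100, seed=6)
        assert res.n_perm == 34

    def test_gm_adjusted_variant_runs_and_differs(self, rng):
        pat, ctl, tmpl = self.build(rng, effect=0.5)
        gm = pd.Series(rng.normal(size=tmpl.shape[0]), index=tmpl.index)
        plain = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=150, seed=7)
        adj = coloc.coloc_group_test(
            pat, ctl, tmpl, gm_rv=gm, adjust_gm=True, n_perm=150, seed=7
        )
        assert list(adj.table.columns) == list(plain.table.columns)
        assert not np.allclose(adj.table["mean_z"], plain.table["mean_z"])

    def test_missing_data_falls_back_pairwise(self, rng):
        pat, ctl, tmpl = self.build(rng, n_pat=5, n_ctl=4, n_reg=15)
        pat.iloc[0, 3] = np.nan
        res = coloc.coloc_group_test(pat, ctl, tmpl, n_perm=120, seed=8)
        assert np.isfinite(res.table["mean_z"]).all()

    def test_empty_group_rejected(self, rng):
        pat, ctl, tmpl = self.build(rng)
        with pytest.raises(ValueError):
            coloc.coloc_group_test(pat.iloc[:0], ctl, tmpl, n_perm=100, seed=0)


class TestROC:
    def test_identical_distributions_auc_half(self):
        p = frame([[0.5], [0.5]], regions=["t0"])
        c = frame([[0.5], [0.5]], regions=["t0"])
        res = coloc.coloc_roc(p, c)
        assert res.table["auc"].iloc[0] == 0.5

    def test_perfect_separation(self):
        p = frame([[0.9], [0.8]], regions=["t0"])
        c = frame([[0.1], [0.2]], regions=["t0"])
        assert coloc.coloc_roc(p, c).table["auc"].iloc[0] == 1.0

    def test_pair_counting_case(self):
        p = frame([[0.9], [0.8]], regions=["t0"])
        c = frame([[0.7], [0.85]], regions=["t0"])
        assert coloc.coloc_roc(p, c).table["auc"].iloc[0] == pytest.approx(0.75)

    def test_orientation_flag(self):
        # patients score LOWER: raw AUC 0 -> reported 1.0 with flipped flag
        p = frame([[0.1], [0.2]], regions=["t0"])
        c = frame([[0.8], [0.9]], regions=["t0"])
        res = coloc.coloc_roc(p, c)
        assert res.table["auc"].iloc[0] == 1.0
        assert res.table["flipped"].iloc[0]
        assert res.table["auc_raw"].iloc[0] == 0.0

    def test_auc_equals_mann_whitney_identity(self, rng):
        from neurocoloc.stats import auc_mann_whitney

        p = frame(rng.normal(size=(8, 2)), regions=["t0", "t1"])
        c = frame(rng.normal(size=(5, 2)), regions=["t0", "t1"])
        res = coloc.coloc_roc(p, c)
        for t in ("t0", "t1"):
            raw = auc_mann_whitney(p[t], c[t])
            assert res.table.set_index("template").loc[t, "auc_raw"] == pytest.approx(raw)

    def test_empty_input_rejected(self, rng):
        p = frame(rng.normal(size=(3, 1)), regions=["t0"])
        with pytest.raises(ValueError):
            coloc.coloc_roc(p, p.iloc[:0])
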