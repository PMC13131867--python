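"""Cohort statistics: stratification, cluster tests, deltas, LME, responders."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gpalpha.simulate import synthetic_lme_table
from gpalpha.stats import (best_session_contrast, classify_responder,
                           cluster_permutation_spectra, fit_lme,
                           frequencywise_correlation, session_deltas,
                           spearman_bootstrap, stratify_severity)

FREQS = np.arange(1.0, 65.01, 0.5)


class TestStratifySeverity:
    def test_median_split(self):
        t = pd.DataFrame({"patient_id": list("ABCD"),
                          "ybocs": [20, 25, 32, 38]})
        g = stratify_severity(t)
        assert g["less_severe"] == ["A", "B"]
        assert g["more_severe"] == ["C", "D"]

    def test_threshold_override_at_30(self):
        t = pd.DataFrame({"patient_id": ["A", "B"], "ybocs": [29, 30]})
        g = stratify_severity(t, threshold=30)
        assert g["less_severe"] == ["A"] and g["more_severe"] == ["B"]

    def test_label_invariance(self):
        t1 = pd.DataFrame({"patient_id": ["A", "B"], "ybocs": [20, 35]})
        t2 = pd.DataFrame({"patient_id": ["X", "Y"], "ybocs": [20, 35]})
        assert len(stratify_severity(t1)["less_severe"]) == \
               len(stratify_severity(t2)["less_severe"]) == 1

    def test_identical_scores_error(self):
        t = pd.DataFrame({"patient_id": ["A", "B"], "ybocs": [30, 30]})
        with pytest.raises(ValueError):
            stratify_severity(t)


class TestClassifyResponder:
    @pytest.mark.parametrize("baseline,ybocs,expected", [
        (40, 24, True),    # 40% improvement
        (40, 26, True),    # exactly 35%, inclusive
        (40, 30, False),   # 25%
    ])
    def test_rule(self, baseline, ybocs, expected):
        assert classify_responder(baseline, ybocs) is expected

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError):
            classify_responder(0, 10)


class TestClusterPermutation:
    def test_paired_identical_groups_no_clusters(self, rng):
        a = rng.normal(0, 1, (8, FREQS.size))
        res = cluster_permutation_spectra(a, a.copy(), FREQS, paired=True,
                                          n_perm=200, seed=0)
        assert res.clusters == []

    def test_planted_difference_recovers_its_band(self, rng):
        a = rng.normal(0, 1, (12, FREQS.size))
        b = rng.normal(0, 1, (12, FREQS.size))
        band = (FREQS >= 9) & (FREQS <= 11)
        b[:, band] += 2.5
        res = cluster_permutation_spectra(b, a, FREQS, n_perm=2000, seed=1)
        sig = res.significant
        assert len(sig) >= 1
        spans = [(c["f_lo"], c["f_hi"]) for c in sig]
        assert any(lo <= 9.0 and hi >= 11.0 for lo, hi in spans)

    @pytest.mark.parametrize("paired", [False, True])
    def test_family_wise_error_rate_controlled(self, paired):
        rng = np.random.default_rng(11)
        n_rep, false_pos = 100, 0
        for _ in range(n_rep):
            a = rng.normal(0, 1, (10, FREQS.size))
            b = rng.normal(0, 1, (10, FREQS.size))
            res = cluster_permutation_spectra(a, b, FREQS, paired=paired,
                                              alpha_fw=0.05, n_perm=300,
                                              seed=rng.integers(2**31))
            false_pos += bool(res.significant)
        hi = sps.binom.ppf(0.975, n_rep, 0.05)
        assert false_pos <= hi

    def test_too_few_units_error(self, rng):
        with pytest.raises(ValueError):
            cluster_permutation_spectra(rng.normal(size=(1, FREQS.size)),
                                        rng.normal(size=(5, FREQS.size)), FREQS)


class TestFrequencywiseCorrelation:
    def test_noiseless_monotone_coupling_gives_r_one(self, rng):
        n = 12
        drive = rng.uniform(0, 1, n)
        spectra = rng.normal(0, 0.1, (n, FREQS.size))
        spectra[:, FREQS == 10.0] = drive[:, None]
        ybocs = 10 + 25 * drive**2  # strictly monotone in the 10 Hz power
        res = frequencywise_correlation(spectra, ybocs, FREQS, n_boot=100,
                                        n_perm=100, seed=0)
        assert res["r"][FREQS == 10.0][0] == pytest.approx(1.0)

    def test_rank_invariance_to_outcome_transform(self, rng):
        spectra = rng.normal(0, 1, (10, FREQS.size))
        ybocs = rng.uniform(10, 38, 10)
        r1 = frequencywise_correlation(spectra, ybocs, FREQS, n_boot=50,
                                       n_perm=50, seed=3)["r"]
        r2 = frequencywise_correlation(spectra, np.exp(ybocs / 10), FREQS,
                                       n_boot=50, n_perm=50, seed=3)["r"]
        np.testing.assert_allclose(r1, r2)

    def test_independent_outcome_rarely_significant(self):
        rng = np.random.default_rng(5)
        n_rep, false_pos = 60, 0
        for _ in range(n_rep):
            spectra = rng.normal(0, 1, (12, FREQS.size))
            ybocs = rng.uniform(10, 38, 12)
            res = frequencywise_correlation(spectra, ybocs, FREQS, n_boot=10,
                                            n_perm=300, alpha_fw=0.01,
                                            seed=rng.integers(2**31))
            false_pos += bool(res["clusters"].significant)
        assert false_pos <= max(3, sps.binom.ppf(0.975, n_rep, 0.01))

    def test_constant_outcome_errors(self, rng):
        with pytest.raises(ValueError):
            frequencywise_correlation(rng.normal(size=(8, FREQS.size)),
                                      np.full(8, 20.0), FREQS)


class TestSessionDeltas:
    def _table(self):
        return pd.DataFrame({
            "patient_id": ["A"] * 3, "hemisphere": ["L"] * 3,
            "session_index": [1, 2, 3], "ybocs": [30, 15, 24],
            "alpha": [2.0, 1.0, 2.0],
        })

    def test_values(self):
        deltas, shift = session_deltas(self._table())
        assert shift == 0.0
        row2 = deltas[deltas["session_index"] == 2].iloc[0]
        assert row2["dybocs_pct"] == pytest.approx(50.0)
        assert row2["dalpha_log"] == pytest.approx(np.log(0.5))
        assert (deltas["session_index"] != 1).all()

    def test_log_ratio_antisymmetric_under_session_swap(self):
        t = self._table()
        deltas, _ = session_deltas(t)
        swapped = t.copy()
        swapped.loc[swapped["session_index"] == 1, "session_index"] = 99
        swapped.loc[swapped["session_index"] == 2, "session_index"] = 1
        swapped.loc[swapped["session_index"] == 99, "session_index"] = 2
        deltas_sw, _ = session_deltas(swapped)
        a = deltas[deltas["session_index"] == 2]["dalpha_log"].iloc[0]
        b = deltas_sw[deltas_sw["session_index"] == 2]["dalpha_log"].iloc[0]
        assert b == pytest.approx(-a)

    def test_nonpositive_alpha_shifted_once(self):
        t = self._table()
        t["alpha"] = [-0.5, 0.0, 0.5]  # periodic power can be <= 0
        deltas, shift = session_deltas(t)
        assert shift > 0.5
        assert np.isfinite(deltas["dalpha_log"]).all()

    def test_zero_baseline_ybocs_dropped(self, caplog):
        t = self._table()
        t.loc[0, "ybocs"] = 0
        with caplog.at_level("WARNING", logger="gpalpha"):
            deltas, _ = session_deltas(t)
        assert deltas.empty


class TestSpearmanBootstrap:
    def test_perfect_correlation(self, rng):
        x = rng.uniform(0, 1, 20)
        res = spearman_bootstrap(x, 2 * x + 1, n_boot=500, n_perm=500, seed=0)
        assert res["r"] == 1.0 and res["ci95"][1] == 1.0

    def test_perfect_anticorrelation(self, rng):
        x = rng.uniform(0, 1, 20)
        res = spearman_bootstrap(x, -x, n_boot=200, n_perm=200, seed=0)
        assert res["r"] == -1.0

    def test_independent_inputs_calibrated(self):
        rng = np.random.default_rng(9)
        n_rep, rejections = 200, 0
        for _ in range(n_rep):
            x = rng.normal(0, 1, 24)
            y = rng.normal(0, 1, 24)
            res = spearman_bootstrap(x, y, n_boot=10, n_perm=400,
                                     seed=rng.integers(2**31))
            rejections += res["p"] <= 0.05
        lo = sps.binom.ppf(0.025, n_rep, 0.05)
        hi = sps.binom.ppf(0.975, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman_bootstrap(np.ones(10), np.arange(10))


class TestBestSessionContrast:
    def _inputs(self, rng, improvement_at=3):
        # enough patients that a sign-flip null can resolve p < alpha_fw
        patients = [f"P{i}" for i in range(12)]
        rows, spectra = [], {}
        for pid in patients:
            for s in (1, 2, 3):
                ybocs = 30 if s != improvement_at else 12
                rows.append({"patient_id": pid, "session_index": s,
                             "ybocs": ybocs, "baseline_ybocs": 36})
                spec = rng.normal(0, 0.3, FREQS.size)
                if s == improvement_at:
                    spec[(FREQS >= 8) & (FREQS <= 12)] -= 2.0  # suppression
                spectra[(pid, s)] = spec
        return pd.DataFrame(rows), spectra

    def test_alpha_suppression_yields_negative_cluster(self, rng):
        table, spectra = self._inputs(rng)
        res = best_session_contrast(table, spectra, FREQS, n_perm=500, seed=0)
        assert all(s == 3 for s in res["best_sessions"].values())
        sig = res["clusters"].significant
        assert any(c["mass"] < 0 and c["f_lo"] <= 10 <= c["f_hi"] for c in sig)

    def test_tie_breaks_to_earlier_session(self, rng):
        table, spectra = self._inputs(rng)
        table.loc[(table["patient_id"] == "P0") & (table["session_index"] == 2),
                  "ybocs"] = 12  # now tied with session 3
        res = best_session_contrast(table, spectra, FREQS, n_perm=200, seed=0)
        assert res["best_sessions"]["P0"] == 2

    def test_best_is_s1_excluded(self, rng):
        table, spectra = self._inputs(rng)
        mask = table["patient_id"] == "P0"
        table.loc[mask, "ybocs"] = [10, 30, 30]  # best session is S1 itself
        res = best_session_contrast(table, spectra, FREQS, n_perm=200, seed=0)
        assert "P0" not in res["best_sessions"]


class TestFitLme:
    def test_recovers_generating_alpha_coefficient(self):
        t = synthetic_lme_table(beta_alpha=15.0, seed=0)
        res = fit_lme(t, "pooled_interaction")
        b, se = res["beta"]["alpha"], res["se"]["alpha"]
        assert abs(b - 15.0) <= 2.5 * se
        assert res["ftests"]["alpha"]["p"] < 0.01

    def test_noise_alpha_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(2)
        n_rep, rejections = 40, 0
        for _ in range(n_rep):
            t = synthetic_lme_table(beta_alpha=0.0, seed=rng.integers(2**31))
            res = fit_lme(t, "pooled_interaction")
            rejections += res["ftests"]["alpha"]["p"] <= 0.05
        assert rejections <= sps.binom.ppf(0.99, n_rep, 0.05)

    def test_duplicating_rows_moves_estimates_only_marginally(self):
        # exact replication is NOT a no-op for a random-intercept model:
        # doubled group sizes change the implied covariance weighting.  The
        # point estimates must still move by far less than their SEs.
        t = synthetic_lme_table(seed=4)
        res1 = fit_lme(t, "pooled_interaction")
        res2 = fit_lme(pd.concat([t, t], ignore_index=True),
                       "pooled_interaction")
        for name in res1["beta"]:
            delta = abs(res2["beta"][name] - res1["beta"][name])
            assert delta < 0.05 * max(res1["se"][name], 1e-12)

    def test_rank_deficient_design_names_columns(self):
        t = synthetic_lme_table(seed=5)
        t["stim_amplitude_mA"] = t["days_since_dbs_onset"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            fit_lme(t, "pooled_interaction")

    def test_needs_repeated_measurements(self):
        t = synthetic_lme_table(n_sessions=2, seed=6)
        # keep a second session for one patient only
        t = t[(t["session_index"] == 1) | (t["patient_id"] == "P01")]
        with pytest.raises(ValueError, match="2 sessions"):
            fit_lme(t, "per_hemisphere")

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_lmerTest_reference(self, tmp_path):
        """Independent oracle: lme4/lmerTest REML fit with Satterthwaite df."""
        from gpalpha.stats import _build_design

        t = synthetic_lme_table(beta_alpha=15.0, beta_interaction=-5.0,
                                beta_hemi=2.0, seed=3)
        X, names, tt = _build_design(t, "pooled_interaction", "alpha")
        df = pd.DataFrame(X, columns=["icpt", "hemiR", "alpha_c", "inter",
                                      "stim_c", "days_c"])
        df["ybocs"] = tt["ybocs"].to_numpy()
        df["pid"] = tt["patient_id"].to_numpy()
        csv = tmp_path / "design.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
            suppressMessages({{library(lme4); library(lmerTest)}})
            d <- read.csv("{csv}")
            m <- lmer(ybocs ~ hemiR + alpha_c + inter + stim_c + days_c +
                      (1|pid), data=d, REML=TRUE)
            co <- summary(m)$coefficients
            write.csv(co, "{tmp_path / 'coef.csv'}")
        """)
        subprocess.run(["Rscript", str(rscript)], check=True,
                       capture_output=True, timeout=300)
        ref = pd.read_csv(tmp_path / "coef.csv", index_col=0)

        res = fit_lme(t, "pooled_interaction")
        mapping = {"(Intercept)": "Intercept", "hemiR": "Hemisphere[R]",
                   "alpha_c": "alpha", "inter": "Hemisphere[R]:alpha",
                   "stim_c": "stim_amplitude", "days_c": "days_since_onset"}
        for rname, pname in mapping.items():
            assert res["beta"][pname] == pytest.approx(
                ref.loc[rname, "Estimate"], rel=1e-3)
            assert res["se"][pname] == pytest.approx(
                ref.loc[rname, "Std. Error"], rel=5e-3)
            if pname in res["ftests"]:
                # F = t² and Satterthwaite df agree with lmerTest
                assert res["ftests"][pname]["F"] == pytest.approx(
                    ref.loc[rname, "t value"] ** 2, rel=5e-3)
                assert res["ftests"][pname]["df2"] == pytest.approx(
                    ref.loc[rname, "df"], rel=0.02)
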