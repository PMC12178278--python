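"""Modulation indices, slopes, effect sizes and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psft.stats import (
    ami,
    anova_conditions,
    bonferroni,
    build_modulation_table,
    cohens_d,
    condition_contrasts,
    dissimilarity_octaves,
    fit_slope,
    hemisphere_ranksum,
    min_detectable_effect,
    rm_corr,
    subject_slopes,
)

pos = st.floats(min_value=1e-6, max_value=1e6)


class TestAMI:
    def test_examples(self):
        assert ami(1.0, 1.0) == 0.0
        assert ami(3.0, 1.0) == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=100)
    @given(a=pos, b=pos)
    def test_antisymmetry_and_bounds(self, a, b):
        assert ami(a, b) == pytest.approx(-ami(b, a), abs=1e-9)
        assert abs(ami(a, b)) < 100.0

    def test_undefined(self):
        with pytest.raises(ValueError):
            ami(1.0, -1.0)


class TestDissimilarity:
    def test_octave_examples(self):
        assert dissimilarity_octaves(0.5, 0.5) == 0.0
        assert dissimilarity_octaves(1.0, 0.5) == pytest.approx(1.0)
        assert dissimilarity_octaves(1.0, 2.0) == pytest.approx(-1.0)
        assert dissimilarity_octaves(4.0, 2.0) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dissimilarity_octaves(-1.0, 0.5)


class TestModulationTable:
    @pytest.fixture()
    def fits(self):
        rows = []
        for vid, mu in enumerate([0.5, 1.0, 2.0]):
            for cond, shift in [("AttendFixation", 1.0), ("AttendLSF", 0.9),
                                ("AttendHSF", 1.1)]:
                rows.append({
                    "subject": 0, "voxel_id": vid, "roi": "V1",
                    "condition": cond, "mu": mu * shift, "sigma": 1.0,
                })
        return pd.DataFrame(rows)

    def test_octave_gap_between_attended_sfs(self, fits):
        mod = build_modulation_table(fits)
        assert np.allclose(mod["dissim_hsf"] - mod["dissim_lsf"], -2.0)

    def test_ami_orientation(self, fits):
        mod = build_modulation_table(fits)
        lsf = mod[mod["condition"] == "AttendLSF"]
        assert np.allclose(lsf["ami_peak"], 100 * (0.9 - 1.0) / (0.9 + 1.0))
        assert np.allclose(lsf["ami_bandwidth"], 0.0)


class TestSlopes:
    def test_exact_line_and_closed_form(self, rng):
        x = rng.normal(size=30)
        slope, intercept = fit_slope(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        y = rng.normal(size=30)
        s, _ = fit_slope(x, y)
        xc = x - x.mean()
        assert s == pytest.approx(float(xc @ (y - y.mean()) / (xc @ xc)))

    def test_uncorrelated_slope_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20000)
        y = rng.normal(size=20000)
        s, _ = fit_slope(x, y - y.mean())
        assert abs(s) < 0.03

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_slope([1.0, 1.0], [0.0, 1.0])

    def test_subject_slopes_grouping(self):
        df = pd.DataFrame({
            "subject": [0] * 4 + [1] * 4,
            "roi": ["V1"] * 8,
            "condition": ["AttendLSF"] * 8,
            "dissimilarity": [0, 1, 2, 3] * 2,
            "ami_peak": [0, -10, -20, -30] + [1, -9, -19, -29],
        })
        out = subject_slopes(df)
        assert len(out) == 2
        assert np.allclose(out["slope"], -10.0)


class TestEffectSizes:
    def test_hand_computed_d(self):
        es = cohens_d([2.0, 4.0], n_boot=10)
        assert es.d == pytest.approx(3 / np.sqrt(2))

    def test_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="zero SD"):
            es = cohens_d([1.0, 1.0, 1.0])
        assert np.isnan(es.d)

    def test_point_estimate_inside_ci(self, rng):
        vals = rng.normal(2.0, 1.0, 12)
        es = cohens_d(vals, seed=3)
        assert es.ci_low <= es.d <= es.ci_high

    def test_paired(self):
        a = np.array([3.0, 4.0, 5.0, 7.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        d = (a - b).mean() / (a - b).std(ddof=1)
        assert cohens_d(a, b, n_boot=10).d == pytest.approx(d)


class TestPower:
    def test_study_value(self):
        assert round(min_detectable_effect(8, 0.05, 0.80), 2) == 1.16

    def test_inversion_and_monotonicity(self):
        from scipy import stats as sps
        d = min_detectable_effect(8, 0.05, 0.80)
        tcrit = sps.t.ppf(0.975, 7)
        nc = d * np.sqrt(8)
        achieved = 1 - sps.nct.cdf(tcrit, 7, nc) + sps.nct.cdf(-tcrit, 7, nc)
        assert achieved == pytest.approx(0.80, abs=1e-6)
        ds = [min_detectable_effect(n) for n in (4, 8, 16, 64)]
        assert all(a > b for a, b in zip(ds, ds[1:]))
        assert min_detectable_effect(8, 0.05, 0.051) < 0.1

    def test_against_statsmodels(self):
        from statsmodels.stats.power import TTestPower
        ref = TTestPower().solve_power(nobs=8, alpha=0.05, power=0.80,
                                       alternative="two-sided")
        assert min_detectable_effect(8) == pytest.approx(float(ref), abs=1e-5)

    def test_invalid(self):
        with pytest.raises(ValueError):
            min_detectable_effect(8, 0.05, 0.01)


class TestRMCorr:
    def test_perfect_within_subject(self):
        subj = [0] * 5 + [1] * 5 + [2] * 5
        x = list(range(5)) * 3
        offsets = (10, -3, 4)
        y = [v + o for o in offsets for v in range(5)]
        r, p, dof = rm_corr(subj, x, y)
        assert r == pytest.approx(1.0)
        assert dof == 15 - 3 - 1
        y_neg = [-v for v in y]
        assert rm_corr(subj, x, y_neg)[0] == pytest.approx(-1.0)

    def test_simpsons_paradox_sign(self):
        # within each subject y falls with x; across subjects the clusters rise
        subj = np.repeat([0, 1, 2], 10)
        base = np.linspace(0, 1, 10)
        x = np.concatenate([base, base + 5, base + 10])
        y = np.concatenate([1 - base, 11 - base, 21 - base])
        assert np.corrcoef(x, y)[0, 1] > 0  # pooled correlation positive
        r, _, _ = rm_corr(subj, x, y)
        assert r == pytest.approx(-1.0)

    def test_small_subject_dropped(self):
        subj = [0, 0, 0, 1, 1, 1, 2, 2, 2, 3]
        x = [1, 2, 3] * 3 + [9]
        y = [1, 2, 3, 2, 3, 4, 5, 6, 7, 9]
        with pytest.warns(UserWarning, match="observations"):
            r, _, _ = rm_corr(subj, x, y)
        assert r == pytest.approx(1.0)


class TestGroupTests:
    def test_bonferroni(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 3) == 1.0

    def test_paired_identical_samples(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(1, 0.5, 8)
        df = pd.concat([
            pd.DataFrame({"subject": range(8), "condition": c, "value": vals})
            for c in ("AttendLSF", "AttendHSF")
        ])
        out = condition_contrasts(df, by=())
        paired = out[out["test"] == "AttendLSF vs AttendHSF"].iloc[0]
        assert paired["t"] == 0.0 and paired["p_raw"] == 1.0
        one = out[out["test"] == "AttendLSF vs 0"].iloc[0]
        assert one["p_bonf"] == pytest.approx(min(one["p_raw"] * 3, 1.0))

    def test_anova_degenerate_flagged(self):
        df = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3, "value": [1.0] * 6})
        with pytest.warns(UserWarning, match="undefined"):
            f, p = anova_conditions(df)
        assert np.isnan(f)

    def test_anova_detects_condition_difference(self, rng):
        df = pd.DataFrame({
            "condition": np.repeat(["a", "b", "c"], 10),
            "value": np.concatenate([rng.normal(m, 0.1, 10) for m in (0, 0, 5)]),
        })
        f, p = anova_conditions(df)
        assert p < 1e-6

    def test_ranksum_shift(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        _, p = hemisphere_ranksum(a, b)
        assert p < 1e-6
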