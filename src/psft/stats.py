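"""Attentional modulation indices, slopes and group-level statistics.

The attentional modulation index (AMI) compares a tuning parameter under
attention (A) with its baseline value (B)::

    AMI(%) = 100 * (A - B) / (A + B)

so a negative peak-AMI is a downward shift of the preferred SF relative
to the attend-fixation baseline.  Preference dependence is expressed
against the octave dissimilarity between a voxel's baseline peak and the
attended SF, ``log2(mu_baseline / attended_sf)``; per subject, ROI and
condition a first-degree least-squares line relates dissimilarity (or a
pRF attribute) to AMI, and group inference runs on the subject-level
slopes and means (t tests with Bonferroni correction, bootstrap Cohen's
d, repeated-measures correlation between peak and bandwidth changes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import optimize, stats as sps

from .design import ATTENDED_SF

BASELINE = "AttendFixation"
ATTENTION_CONDITIONS = ("AttendLSF", "AttendHSF")


def ami(a, b):
    """Attentional modulation index, percent: 100 (a - b)/(a + b).

    ``a`` is the attention-condition estimate, ``b`` the baseline.
    Undefined (ValueError) when a + b = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    s = a + b
    if np.any(s == 0):
        raise ValueError("AMI undefined where a + b = 0")
    return 100.0 * (a - b) / s


def dissimilarity_octaves(mu_baseline, attended_sf):
    """Octave distance of the baseline peak from the attended SF:
    log2(mu_baseline / attended_sf)."""
    mu_baseline = np.asarray(mu_baseline, float)
    if np.any(mu_baseline <= 0) or np.any(np.asarray(attended_sf, float) <= 0):
        raise ValueError("frequencies must be positive")
    return np.log2(mu_baseline / attended_sf)


def build_modulation_table(
    fits: pd.DataFrame,
    baseline: str = BASELINE,
    attended_sf: dict | None = None,
) -> pd.DataFrame:
    """Per-voxel AMI and dissimilarity records for the attention conditions.

    ``fits`` is tidy (one row per voxel x condition with ``mu``/``sigma``).
    Voxels lacking a baseline row, or with a zero parameter sum (AMI
    undefined), are dropped.
    """
    att = attended_sf or ATTENDED_SF
    keys = (["subject"] if "subject" in fits.columns else []) + ["voxel_id"]
    carry = [c for c in ("roi", "prf_ecc", "prf_size") if c in fits.columns]
    base = fits[fits["condition"] == baseline].set_index(keys)
    rows = []
    for cond in ATTENTION_CONDITIONS:
        sub = fits[fits["condition"] == cond].set_index(keys)
        joined = sub.join(base, rsuffix="_base", how="inner")
        ok = ((joined["mu"] + joined["mu_base"]) != 0) & (
            (joined["sigma"] + joined["sigma_base"]) != 0
        )
        joined = joined[ok]
        out = pd.DataFrame(index=joined.index)
        out["condition"] = cond
        for c in carry:
            out[c] = joined[c]
        out["mu_baseline"] = joined["mu_base"]
        out["ami_peak"] = ami(joined["mu"], joined["mu_base"])
        out["ami_bandwidth"] = ami(joined["sigma"], joined["sigma_base"])
        out["dissim_lsf"] = dissimilarity_octaves(joined["mu_base"], att["AttendLSF"])
        out["dissim_hsf"] = dissimilarity_octaves(joined["mu_base"], att["AttendHSF"])
        out["dissimilarity"] = dissimilarity_octaves(joined["mu_base"], att[cond])
        rows.append(out.reset_index())
    return pd.concat(rows, ignore_index=True)


def fit_slope(x, y) -> tuple[float, float]:
    """First-degree least-squares line; returns (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 2:
        raise ValueError("slope undefined for a constant predictor")
    coef = np.polyfit(x, y, 1)
    return float(coef[0]), float(coef[1])


def subject_slopes(
    modulation: pd.DataFrame,
    predictor: str = "dissimilarity",
    outcome: str = "ami_peak",
) -> pd.DataFrame:
    """One least-squares slope per subject x ROI x condition."""
    keys = [k for k in ("subject", "roi", "condition") if k in modulation.columns]
    rows = []
    skipped = 0
    for key, grp in modulation.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        if grp[predictor].nunique() < 2:
            skipped += 1
            continue
        slope, intercept = fit_slope(grp[predictor], grp[outcome])
        rows.append(
            dict(zip(keys, key))
            | {
                "predictor": predictor,
                "outcome": outcome,
                "slope": slope,
                "intercept": intercept,
                "n_voxels": len(grp),
            }
        )
    if skipped:
        warnings.warn(
            f"{skipped} group(s) with a constant/singleton predictor skipped",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    n_boot: int


def cohens_d(
    values,
    paired_with=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> EffectSize:
    """One-sample (or paired) Cohen's d with a percentile bootstrap CI.

    d = mean / SD (sample SD); for paired data, on the differences.  The
    CI spans the 2.5/97.5 percentiles over ``n_boot`` seeded resamples
    with replacement, d recomputed per resample.
    """
    x = np.asarray(values, float)
    if paired_with is not None:
        y = np.asarray(paired_with, float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        x = x - y
    if x.size < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD: Cohen's d undefined", stacklevel=2)
        return EffectSize(np.nan, np.nan, np.nan, n_boot)
    d = x.mean() / sd
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        r = x[rng.integers(0, x.size, x.size)]
        s = r.std(ddof=1)
        boot[i] = r.mean() / s if s > 0 else np.nan
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return EffectSize(float(d), float(lo), float(hi), n_boot)


def min_detectable_effect(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Minimum detectable one-sample effect size via the noncentral t.

    Solves for the Cohen's d at which a two-sided one-sample t test with
    ``df = n - 1`` achieves the requested power.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("requested power not above the test size")
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)

    def achieved(d):
        nc = d * np.sqrt(n)
        return 1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)

    # expand the bracket only as far as needed (the noncentral-t cdf loses
    # accuracy at extreme noncentrality)
    hi = 0.5
    while achieved(hi) < power:
        hi *= 2
        if hi > 1e3:
            raise ValueError("requested power unattainable")
    return float(optimize.brentq(lambda d: achieved(d) - power, 1e-9, hi, xtol=1e-12))


def rm_corr(subjects, x, y):
    """Repeated-measures correlation (subject-as-factor ANCOVA form).

    Returns ``(r, p, dof)`` with ``dof = N - k - 1`` for N observations
    over k subjects.  Subjects with fewer than two observations are
    dropped with a warning.
    """
    df = pd.DataFrame({"subject": subjects, "x": x, "y": y})
    counts = df.groupby("subject").size()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"dropping {len(small)} subject(s) with < 2 observations",
                      stacklevel=2)
        df = df[~df["subject"].isin(small)]
    if df["subject"].nunique() < 3:
        raise ValueError("repeated-measures correlation needs >= 3 subjects")
    res = pg.rm_corr(data=df, x="x", y="y", subject="subject")
    return float(res["r"].iloc[0]), float(res["pval"].iloc[0]), int(res["dof"].iloc[0])


def bonferroni(p, family: int):
    """Bonferroni-corrected p: multiplied by the family size, capped at 1."""
    return np.minimum(np.asarray(p, float) * family, 1.0)


def anova_conditions(
    df: pd.DataFrame, value: str = "value", condition: str = "condition"
):
    """One-way ANOVA across condition groups of per-subject summaries."""
    groups = [g[value].to_numpy() for _, g in df.groupby(condition)]
    if any(np.ptp(g) == 0 for g in groups) and all(np.ptp(g) == 0 for g in groups):
        warnings.warn("zero within-group variance: F undefined", stacklevel=2)
        return np.nan, np.nan
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def condition_contrasts(
    summary: pd.DataFrame,
    value: str = "value",
    by: tuple[str, ...] = ("roi",),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """The standard three-test family per panel.

    For each group of ``by`` (e.g. one outcome in one ROI): one-sample t
    tests of the AttendLSF and AttendHSF subject values against zero, and
    a paired t test between them; Bonferroni correction over the family
    of three; bootstrap Cohen's d per test.  Subjects missing a condition
    are excluded listwise (with a warning) from the paired test.
    """
    by = [b for b in by if b in summary.columns]
    rows = []
    family = 3
    for key, grp in summary.groupby(by) if by else [((), summary)]:
        key = key if isinstance(key, tuple) else (key,)
        wide = grp.pivot_table(index="subject", columns="condition", values=value)
        tests = []
        for cond in ATTENTION_CONDITIONS:
            if cond not in wide.columns:
                continue
            v = wide[cond].dropna().to_numpy()
            if v.size < 2:
                continue
            t, p = sps.ttest_1samp(v, 0.0)
            es = cohens_d(v, n_boot=n_boot, seed=seed)
            tests.append((f"{cond} vs 0", v.size, t, p, es))
        both = wide.reindex(columns=list(ATTENTION_CONDITIONS)).dropna()
        if len(both) < len(wide):
            warnings.warn("subjects missing a condition excluded from paired test",
                          stacklevel=2)
        if len(both) >= 2:
            a = both["AttendLSF"].to_numpy()
            b = both["AttendHSF"].to_numpy()
            diffs = a - b
            if diffs.std(ddof=1) == 0:
                t, p = (0.0, 1.0) if np.allclose(diffs, 0) else (np.nan, np.nan)
                es = EffectSize(np.nan, np.nan, np.nan, n_boot)
            else:
                t, p = sps.ttest_rel(a, b)
                es = cohens_d(a, b, n_boot=n_boot, seed=seed)
            tests.append(("AttendLSF vs AttendHSF", len(both), t, p, es))
        for name, n, t, p, es in tests:
            rows.append(
                dict(zip(by, key))
                | {
                    "test": name,
                    "n": n,
                    "t": float(t),
                    "p_raw": float(p),
                    "p_bonf": float(bonferroni(p, family)),
                    "d": es.d,
                    "d_ci_low": es.ci_low,
                    "d_ci_high": es.ci_high,
                }
            )
    return pd.DataFrame(rows)


def hemisphere_ranksum(values_left, values_right):
    """Wilcoxon rank-sum comparison between hemisphere groupings."""
    stat, p = sps.ranksums(np.asarray(values_left, float), np.asarray(values_right, float))
    return float(stat), float(p)
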