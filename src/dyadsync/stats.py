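"""Channel-wise statistical campaign on the synchrony table.

Condition contrasts (SEP vs TOG) use the two-sided Mann-Whitney test per
channel — the unit of analysis is one trial-averaged MCC2 value per
(dyad, stimulus) — with Benjamini-Hochberg FDR over the 20 channels.
Follow-ups run one-sided per-stimulus tests (FDR over 6 stimuli) inside
significant channels, and covariate analyses (parity Mann-Whitney,
Spearman correlations with the parent-ratio score and parental ages)
pooled over channels and per significant channel (FDR over the
significant channels).  Everything is repeated on the randomly re-paired
control dyads as a negative control.  Effect sizes are pooled-SD Cohen's
d (TOG minus SEP, (n-1)-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_core import (
    STIMULI,
    AnalysisConfig,
    CovariateRecord,
    Montage,
    ValidationError,
    default_montage,
    get_logger,
)

__all__ = [
    "StatTestResult",
    "mann_whitney",
    "bh_adjust",
    "cohens_d_pooled",
    "cohens_d_from_samples",
    "spearman",
    "power_two_sample",
    "code_parent_ratio",
    "run_condition_analysis",
    "run_stimulus_analysis",
    "run_covariate_analysis",
    "results_to_frame",
    "condition_report",
]

logger = get_logger()


@dataclass
class StatTestResult:
    """One hypothesis test: statistic, raw/adjusted p, effect size, group Ns."""

    test: str
    scope: dict = field(default_factory=dict)
    statistic: float = np.nan
    p_raw: float = np.nan
    p_adjusted: float = np.nan
    m_tests: int = 1
    effect_size: float = np.nan
    group_summaries: dict = field(default_factory=dict)
    testable: bool = True
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.testable and np.isfinite(self.p_adjusted) and self.p_adjusted < 0.05


# --------------------------------------------------------------------------
# Elementary tests
# --------------------------------------------------------------------------


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    sided: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U of ``sample_a`` against ``sample_b``.

    Exact enumeration when both groups have n <= 8 and no ties span the
    groups; otherwise the normal approximation with tie correction and
    continuity correction.  ``sided`` in {'two-sided', 'greater', 'less'},
    where 'greater' tests a stochastically larger ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    exact_ok = a.size <= 8 and b.size <= 8 and np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if exact_ok else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative=sided, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with family size ``m``.

    ``m`` may exceed the number of supplied p-values when only the k
    smallest of a family of m are available; ranks 1..k are then used with
    divisor m (valid when the supplied values are the smallest of the
    family).  Adjusted values are monotone in raw-p rank and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    k = p.size
    m = k if m is None else int(m)
    if m < k:
        raise ValidationError(f"family size m={m} smaller than the {k} supplied p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(k)
    out[order] = adjusted_sorted
    return out


def cohens_d_pooled(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> float:
    """Pooled-SD Cohen's d: (mean2 - mean1) / s_pooled, (n-1)-weighted."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("Cohen's d needs at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    pooled_var = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0
        raise ValidationError("zero pooled SD with unequal means: effect size undefined")
    return float((mean2 - mean1) / np.sqrt(pooled_var))


def cohens_d_from_samples(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    return cohens_d_pooled(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p via the
    t approximation.  Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("Spearman correlation needs >= 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    res = sstats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def power_two_sample(
    d: float,
    n_per_group: int,
    alpha: float,
    method: str = "analytic_noncentral_t",
    n_reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Power of the two-sided two-sample comparison of means.

    Analytic route: noncentral-t with df = 2n-2 and noncentrality
    d*sqrt(n/2).  Monte-Carlo route: repeated unit-SD normal draws whose
    means differ by d, tested with the two-sample t test at ``alpha``.
    """
    if d <= 0 or n_per_group < 2 or not (0 < alpha < 1):
        raise ValidationError("need d > 0, n >= 2 and alpha in (0, 1)")
    if method == "analytic_noncentral_t":
        df = 2 * n_per_group - 2
        nc = d * np.sqrt(n_per_group / 2.0)
        tcrit = sstats.t.ppf(1 - alpha / 2, df)
        upper = sstats.nct.sf(tcrit, df, nc)
        # lower-tail mass via the sign-flip symmetry of the noncentral t,
        # which stays numerically stable for large noncentrality
        lower = sstats.nct.sf(tcrit, df, -nc)
        return float(upper + lower)
    if method == "monte_carlo":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rejections = 0
        block = 500
        done = 0
        while done < n_reps:
            k = min(block, n_reps - done)
            a = rng.standard_normal((k, n_per_group))
            b = rng.standard_normal((k, n_per_group)) + d
            res = sstats.ttest_ind(a, b, axis=1)
            rejections += int((res.pvalue < alpha).sum())
            done += k
        return rejections / n_reps
    raise ValidationError(f"unknown power method {method!r}")


def code_parent_ratio(choice: str) -> float:
    """Code a mother:father lead-taking ratio option ('0:5' ... '5:0') into
    the mother's share, in {0, 0.2, 0.4, 0.6, 0.8, 1.0}."""
    try:
        left_s, right_s = choice.split(":")
        left, right = int(left_s), int(right_s)
    except (ValueError, AttributeError) as exc:
        raise ValidationError(f"unrecognised ratio option {choice!r}") from exc
    if left < 0 or right < 0 or left + right != 5:
        raise ValidationError(f"ratio option {choice!r} must be among 0:5 ... 5:0")
    return left / (left + right)


# --------------------------------------------------------------------------
# Campaign over the synchrony table
# --------------------------------------------------------------------------


def _summary(x: np.ndarray) -> tuple[float, float, int]:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan, 0
    sd = x.std(ddof=1) if x.size > 1 else np.nan
    return float(x.mean()), float(sd), int(x.size)


def run_condition_analysis(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    pairing: str = "true",
) -> list[StatTestResult]:
    """Per-channel two-sided Mann-Whitney of SEP vs TOG MCC2, pooled over
    stimuli, BH-adjusted over the 20-channel family; Cohen's d (TOG - SEP)
    and per-group (mean, SD, N) attached.  ``pairing='control'`` runs the
    identical campaign on the re-paired control dyads."""
    config = config or AnalysisConfig()
    sub = table[table["pairing"] == pairing]
    channels = sorted(sub["channel"].unique())
    results: list[StatTestResult] = []
    for ch in channels:
        rows = sub[sub["channel"] == ch]
        sep = rows.loc[rows.condition == "SEP", "mcc2"].to_numpy(dtype=float)
        tog = rows.loc[rows.condition == "TOG", "mcc2"].to_numpy(dtype=float)
        sep, tog = sep[np.isfinite(sep)], tog[np.isfinite(tog)]
        res = StatTestResult(
            test="mann_whitney_two_sided",
            scope={"channel": int(ch), "stimulus": "all", "pairing": pairing},
            m_tests=config.n_channels_tested,
            group_summaries={"SEP": _summary(sep), "TOG": _summary(tog)},
        )
        if sep.size < 2 or tog.size < 2:
            res.testable = False
            res.note = "fewer than 2 values in a group"
        else:
            res.statistic, res.p_raw = mann_whitney(sep, tog, "two-sided")
            res.effect_size = cohens_d_from_samples(sep, tog)
        results.append(res)
    testable = [r for r in results if r.testable]
    if testable:
        adj = bh_adjust([r.p_raw for r in testable], m=config.n_channels_tested)
        for r, p in zip(testable, adj):
            r.p_adjusted = float(p)
    return results


def run_stimulus_analysis(
    table: pd.DataFrame,
    significant_channels: Sequence[int],
    config: AnalysisConfig | None = None,
    pairing: str = "true",
) -> list[StatTestResult]:
    """Within each significant channel, one-sided (TOG > SEP) Mann-Whitney
    per stimulus with BH over the 6-stimulus family."""
    config = config or AnalysisConfig()
    sub = table[table["pairing"] == pairing]
    results: list[StatTestResult] = []
    for ch in significant_channels:
        ch_rows = sub[sub["channel"] == ch]
        ch_results: list[StatTestResult] = []
        for stimulus in STIMULI:
            rows = ch_rows[ch_rows["stimulus"] == stimulus]
            sep = rows.loc[rows.condition == "SEP", "mcc2"].to_numpy(dtype=float)
            tog = rows.loc[rows.condition == "TOG", "mcc2"].to_numpy(dtype=float)
            sep, tog = sep[np.isfinite(sep)], tog[np.isfinite(tog)]
            res = StatTestResult(
                test="mann_whitney_one_sided",
                scope={"channel": int(ch), "stimulus": stimulus, "pairing": pairing},
                m_tests=len(STIMULI),
                group_summaries={"SEP": _summary(sep), "TOG": _summary(tog)},
            )
            if sep.size < 2 or tog.size < 2:
                res.testable = False
                res.note = "fewer than 2 values in a group"
            else:
                # alternative: TOG stochastically greater than SEP
                res.statistic, res.p_raw = mann_whitney(tog, sep, "greater")
                res.effect_size = cohens_d_from_samples(sep, tog)
            ch_results.append(res)
        testable = [r for r in ch_results if r.testable]
        if testable:
            adj = bh_adjust([r.p_raw for r in testable], m=len(STIMULI))
            for r, p in zip(testable, adj):
                r.p_adjusted = float(p)
        results.extend(ch_results)
    return results


def _covariate_frame(
    table: pd.DataFrame, covariates: Sequence[CovariateRecord], pairing: str,
    condition: str,
) -> pd.DataFrame:
    cov = pd.DataFrame(
        {
            "dyad_id": [c.dyad_id for c in covariates],
            "average_parent_ratio": [c.average_parent_ratio for c in covariates],
            "mother_age": [c.mother_age for c in covariates],
            "father_age": [c.father_age for c in covariates],
            "mean_parent_age": [(c.mother_age + c.father_age) / 2 for c in covariates],
            "parity": [c.parity for c in covariates],
        }
    )
    sub = table[(table["pairing"] == pairing) & (table["condition"] == condition)].copy()
    if pairing == "control":
        # a control row is keyed by 'motherxfather'; covariates are couple-
        # level, so attach the mother's couple record
        sub["dyad_id"] = sub["dyad_id"].str.split("x").str[0]
    return sub.merge(cov, on="dyad_id", how="inner")


SPEARMAN_COVARIATES = ("average_parent_ratio", "mother_age", "father_age", "mean_parent_age")


def run_covariate_analysis(
    table: pd.DataFrame,
    covariates: Sequence[CovariateRecord],
    significant_channels: Sequence[int],
    config: AnalysisConfig | None = None,
    pairing: str = "true",
    condition: str = "TOG",
) -> list[StatTestResult]:
    """Parent-related covariates against MCC2.

    Parity: two-sided Mann-Whitney (primiparous vs multiparous).  Ratio
    score and ages: Spearman correlations.  Each test runs once pooled
    over all channels (unadjusted) and once per significant channel with
    BH over the family of significant channels.
    """
    config = config or AnalysisConfig()
    merged = _covariate_frame(table, covariates, pairing, condition)
    merged = merged[np.isfinite(merged["mcc2"])]
    results: list[StatTestResult] = []
    m_family = max(len(significant_channels), 1)

    def scopes():
        yield "all-channels", merged, 1
        for ch in significant_channels:
            yield int(ch), merged[merged["channel"] == ch], m_family

    # Parity contrast
    parity_family: list[StatTestResult] = []
    for label, rows, m in scopes():
        primi = rows.loc[rows.parity == "primiparous", "mcc2"].to_numpy(dtype=float)
        multi = rows.loc[rows.parity == "multiparous", "mcc2"].to_numpy(dtype=float)
        res = StatTestResult(
            test="mann_whitney_two_sided",
            scope={"channel": label, "covariate": "parity", "pairing": pairing},
            m_tests=m,
            group_summaries={"primiparous": _summary(primi), "multiparous": _summary(multi)},
        )
        if primi.size < 2 or multi.size < 2:
            res.testable = False
            res.note = "fewer than 2 values in a group"
        else:
            res.statistic, res.p_raw = mann_whitney(primi, multi, "two-sided")
            res.effect_size = cohens_d_from_samples(multi, primi)
        if label == "all-channels":
            res.p_adjusted = res.p_raw
        else:
            parity_family.append(res)
        results.append(res)
    _adjust_family(parity_family, m_family)

    # Spearman correlations
    for covariate in SPEARMAN_COVARIATES:
        family: list[StatTestResult] = []
        for label, rows, m in scopes():
            res = StatTestResult(
                test="spearman",
                scope={"channel": label, "covariate": covariate, "pairing": pairing},
                m_tests=m,
                group_summaries={"all": _summary(rows["mcc2"].to_numpy(dtype=float))},
            )
            if len(rows) < 3:
                res.testable = False
                res.note = "fewer than 3 pairs"
            else:
                rho, p = spearman(rows[covariate], rows["mcc2"])
                res.statistic = res.effect_size = rho
                res.p_raw = p
                if not np.isfinite(p):
                    res.testable = False
                    res.note = "constant covariate"
            if label == "all-channels":
                res.p_adjusted = res.p_raw
            else:
                family.append(res)
            results.append(res)
        _adjust_family(family, m_family)
    return results


def _adjust_family(family: list[StatTestResult], m: int) -> None:
    testable = [r for r in family if r.testable]
    if testable:
        adj = bh_adjust([r.p_raw for r in testable], m=max(m, len(testable)))
        for r, p in zip(testable, adj):
            r.p_adjusted = float(p)


def results_to_frame(results: Sequence[StatTestResult]) -> pd.DataFrame:
    """Flatten results into a report table (one row per test)."""
    rows = []
    for r in results:
        row = {
            "test": r.test,
            **{f"scope_{k}": v for k, v in r.scope.items()},
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "m_tests": r.m_tests,
            "effect_size": r.effect_size,
            "testable": r.testable,
            "note": r.note,
        }
        for group, (mean, sd, n) in r.group_summaries.items():
            row[f"{group}_mean"] = mean
            row[f"{group}_sd"] = sd
            row[f"{group}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def condition_report(
    results: Sequence[StatTestResult],
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Human-readable per-channel condition contrast: area label,
    per-condition mean/SD/N, raw and adjusted p, Cohen's d."""
    montage = montage or default_montage()
    rows = []
    for r in results:
        ch = r.scope.get("channel")
        sep = r.group_summaries.get("SEP", (np.nan, np.nan, 0))
        tog = r.group_summaries.get("TOG", (np.nan, np.nan, 0))
        rows.append({
            "channel": ch,
            "area": montage.label_of(ch) if isinstance(ch, int) else "",
            "SEP_mean": sep[0], "SEP_sd": sep[1], "SEP_n": sep[2],
            "TOG_mean": tog[0], "TOG_sd": tog[1], "TOG_n": tog[2],
            "p_raw": r.p_raw, "p_adjusted": r.p_adjusted, "d": r.effect_size,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)
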