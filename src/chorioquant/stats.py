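"""Cohort statistics for pre/post near-work choroidal metrics.

Implements the study-level statistical layer: per-subject change scores and
percent changes, paired pre/post t tests with Bonferroni correction,
one-way repeated-measures ANOVA with the Greenhouse–Geisser sphericity
correction, an axial-length-adjusted between-group contrast on percent
changes (linear model with cluster-robust variance — the estimand of a GEE
group effect with one observation per subject-duration), and repeatability
statistics (absolute-agreement ICC and Bland–Altman limits of agreement).

The group contrast is exposed statsmodels-style: build a
:class:`NearWorkChangeModel` from a long-format cohort table, call
``fit()``, and read estimates and robust standard errors off the returned
:class:`NearWorkChangeResults` (``summary()`` prints the table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf

__all__ = [
    "percent_change",
    "paired_change_test",
    "bonferroni",
    "rm_anova_gg",
    "RmAnovaResult",
    "GroupContrast",
    "group_contrast_ancova",
    "NearWorkChangeModel",
    "NearWorkChangeResults",
    "icc_absolute_agreement",
    "bland_altman",
    "changes_table",
]


def percent_change(pre: float, post: float) -> float:
    """Percent change from pre to post: ``100 * (post - pre) / pre``."""
    pre_arr = np.asarray(pre, dtype=float)
    if np.any(pre_arr == 0):
        raise ValueError("percent change undefined for pre = 0")
    return 100.0 * (np.asarray(post, dtype=float) - pre_arr) / pre_arr


def paired_change_test(deltas: np.ndarray) -> tuple[float, float]:
    """One-sample t test of per-subject change scores against zero.

    Returns ``(t, p)``; the two-sided p value.  Testing the deltas against
    zero is identical to the paired pre/post t test.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two change scores")
    res = sps.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: ``min(1, m * p)``.

    ``m`` defaults to the number of p values supplied.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


@dataclass(frozen=True)
class RmAnovaResult:
    """Within-subject F test with Greenhouse–Geisser adjusted degrees of freedom."""

    F: float
    df1: float
    df2: float
    epsilon_gg: float
    p: float


def rm_anova_gg(data: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse–Geisser correction.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, k_levels)
        Complete-case wide table, one column per within-subject level.

    Notes
    -----
    Box's epsilon is computed from the double-centered sample covariance S̃
    of the k levels, ``eps = tr(S̃)² / ((k-1) Σ S̃²)``, clamped to
    [1/(k-1), 1]; both F degrees of freedom are multiplied by epsilon
    before the p value is read from the F distribution.  For k = 2 the
    single within-subject contrast makes epsilon exactly 1.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D (subjects x levels) array")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells: repeated-measures ANOVA needs complete cases")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    if n <= k:
        raise ValueError("need more subjects than levels")

    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    time = x.mean(axis=0, keepdims=True)
    ss_time = n * float(((time - grand) ** 2).sum())
    resid = x - subj - time + grand
    ss_err = float((resid**2).sum())
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)

    if ss_err == 0.0:
        f = 0.0 if ss_time == 0.0 else np.inf
    else:
        f = (ss_time / df1) / (ss_err / df2)

    s = np.cov(x, rowvar=False, ddof=1)
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = (k - 1.0) * float((s_dc**2).sum())
    eps = 1.0 if denom == 0.0 else float(np.trace(s_dc)) ** 2 / denom
    eps = float(np.clip(eps, 1.0 / (k - 1.0), 1.0))

    if np.isinf(f):
        p = 0.0
    elif f == 0.0 and ss_err == 0.0:
        p = 1.0
    else:
        p = float(sps.f.sf(f, eps * df1, eps * df2))
    return RmAnovaResult(F=float(f), df1=eps * df1, df2=eps * df2, epsilon_gg=eps, p=p)


@dataclass(frozen=True)
class GroupContrast:
    """Covariate-adjusted between-group difference in mean change."""

    adjusted_mean_difference: float
    se: float
    p: float
    covariates: tuple[str, ...] = ("al_mm",)
    groups: tuple[str, str] = ("adult", "child")  # difference is groups[1] - groups[0]


class NearWorkChangeModel:
    """Linear model for between-group comparison of near-work changes.

    The model is ``change ~ group + AL`` (plus duration main effect and a
    group × duration interaction when several durations are supplied), fit
    by OLS with cluster-robust (sandwich) variance by subject.  With one
    observation per subject and duration this targets the same estimand as
    a GEE group effect adjusted for axial length.
    """

    def __init__(
        self,
        changes: np.ndarray,
        group: np.ndarray,
        al_mm: np.ndarray,
        time: np.ndarray | None = None,
        subject: np.ndarray | None = None,
    ):
        df = pd.DataFrame({
            "change": np.asarray(changes, dtype=float),
            "group": np.asarray(group).astype(str),
            "al_mm": np.asarray(al_mm, dtype=float),
        })
        if time is not None:
            df["time"] = np.asarray(time)
        if subject is not None:
            df["subject"] = np.asarray(subject).astype(str)
        levels = sorted(df["group"].unique())
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        if len(df) < 4:
            raise ValueError("need at least four observations")
        self.data = df
        self.group_levels = (levels[0], levels[1])

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metric: str, durations=(20, 40, 60)
    ) -> "NearWorkChangeModel":
        """Build from a long cohort table (``generate_cohort`` layout).

        Percent changes are computed per subject and duration for the given
        metric, then pooled across the requested durations.
        """
        sub = df[(df["metric"] == metric) & (df["visit_min"].isin(durations))]
        wide = sub.pivot_table(
            index=["subject", "group", "visit_min", "al_mm"],
            columns="phase", values="value", aggfunc="first",
        ).reset_index()
        if wide[["pre", "post"]].isna().any().any():
            raise ValueError(f"incomplete pre/post pairs for metric {metric!r}")
        changes = percent_change(wide["pre"].to_numpy(), wide["post"].to_numpy())
        return cls(
            changes,
            wide["group"].to_numpy(),
            wide["al_mm"].to_numpy(),
            time=wide["visit_min"].to_numpy(),
            subject=wide["subject"].to_numpy(),
        )

    def fit(self) -> "NearWorkChangeResults":
        df = self.data
        terms = [f"C(group, Treatment('{self.group_levels[0]}'))"]
        dropped_al = False
        if df["al_mm"].nunique() > 1:
            terms.append("al_mm")
        else:
            dropped_al = True
            warnings.warn("axial length has zero variance; covariate dropped", stacklevel=2)
        multi_time = "time" in df.columns and df["time"].nunique() > 1
        if multi_time:
            terms += ["C(time)", f"C(group, Treatment('{self.group_levels[0]}')):C(time)"]
        formula = "change ~ " + " + ".join(terms)
        model = smf.ols(formula, data=df)
        if "subject" in df.columns and df["subject"].nunique() < len(df):
            res = model.fit(cov_type="cluster", cov_kwds={"groups": df["subject"]})
        elif "subject" in df.columns:
            res = model.fit(cov_type="HC1")
        else:
            res = model.fit(cov_type="HC1")
        return NearWorkChangeResults(self, res, dropped_al=dropped_al)


class NearWorkChangeResults:
    """Fitted between-group change model.

    ``contrast`` holds the adjusted mean group difference (second group
    minus reference group, averaged over durations when an interaction is
    present) with its cluster-robust SE and p value.
    """

    def __init__(self, model: NearWorkChangeModel, sm_results, dropped_al: bool = False):
        self.model = model
        self._res = sm_results
        self.dropped_al = dropped_al
        self.contrast = self._group_contrast()

    def _group_contrast(self) -> GroupContrast:
        res = self._res
        names = list(res.params.index)
        g0, g1 = self.model.group_levels
        main = next(n for n in names if n.startswith("C(group") and ":" not in n)
        # Average the group effect over duration levels when interactions exist.
        inter = [n for n in names if n.startswith("C(group") and ":" in n]
        L = np.zeros(len(names))
        L[names.index(main)] = 1.0
        if inter:
            n_levels = len(inter) + 1
            for n in inter:
                L[names.index(n)] = 1.0 / n_levels
        ct = res.t_test(L)
        return GroupContrast(
            adjusted_mean_difference=float(np.atleast_1d(ct.effect)[0]),
            se=float(np.atleast_1d(ct.sd).ravel()[0]),
            p=float(np.atleast_1d(ct.pvalue).ravel()[0]),
            covariates=() if self.dropped_al else ("al_mm",),
            groups=(g0, g1),
        )

    @property
    def params(self):
        return self._res.params

    @property
    def bse(self):
        return self._res.bse

    @property
    def pvalues(self):
        return self._res.pvalues

    def summary(self):
        return self._res.summary()


def group_contrast_ancova(
    changes, group, al_mm, time=None, subject=None
) -> GroupContrast:
    """Functional wrapper: fit :class:`NearWorkChangeModel` and return the contrast."""
    return NearWorkChangeModel(changes, group, al_mm, time=time, subject=subject).fit().contrast


def icc_absolute_agreement(series1, series2) -> float:
    """Two-way mixed, absolute-agreement, single-measure ICC of two sessions.

    Computed from the two-way ANOVA mean squares (subjects × sessions):
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` with k = 2.
    """
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least three paired measurements")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row = x.mean(axis=1)
    col = x.mean(axis=0)
    msr = k * ((row - grand) ** 2).sum() / (n - 1)
    msc = n * ((col - grand) ** 2).sum() / (k - 1)
    resid = x - row[:, None] - col[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def bland_altman(series1, series2) -> tuple[float, float, float]:
    """Bland–Altman bias and 95% limits of agreement.

    Returns ``(bias, loa_low, loa_high)`` where bias is the mean difference
    (series1 - series2) and the limits are bias ± 1.96 × SD(differences).
    """
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least three paired measurements")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def changes_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject change scores from a long cohort table.

    Returns one row per (subject, group, visit_min, metric) with columns
    ``pre, post, delta, pct_change, al_mm``.
    """
    wide = df.pivot_table(
        index=["subject", "group", "visit_min", "metric", "al_mm"],
        columns="phase", values="value", aggfunc="first",
    ).reset_index()
    missing = wide[["pre", "post"]].isna().any(axis=1)
    if missing.any():
        bad = wide.loc[missing, ["subject", "visit_min", "metric"]].iloc[0].tolist()
        raise ValueError(f"incomplete pre/post pair, first at {bad}")
    wide["delta"] = wide["post"] - wide["pre"]
    wide["pct_change"] = percent_change(wide["pre"].to_numpy(), wide["post"].to_numpy())
    return wide
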