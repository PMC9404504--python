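"""Statistical layer: t-tests, exact power, sphericity, and split-plot ANOVA.

The central object is :class:`MixedAnova`, a model in the statsmodels style:
it is constructed from the tidy stage table (or any long DataFrame with a
subject, a between-group and a within-condition column), and ``fit()`` returns
a :class:`MixedAnovaResults` carrying the F table, Mauchly's sphericity test,
the Huynh-Feldt epsilon, omega-squared effect sizes and a ``summary()``.

The design is the classical split-plot decomposition: the between-subjects
effect (age group) is tested against subjects-within-groups, the
within-subject effect (anesthesia stage) and the interaction against the
subject x stage residual.  When Mauchly's test rejects sphericity at the
configured alpha, within-effect degrees of freedom are multiplied by the
Huynh-Feldt epsilon (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "ttest_independent",
    "ttest_from_summary",
    "power_two_sample_t",
    "contrast_covariance",
    "mauchly_sphericity",
    "greenhouse_geisser_epsilon",
    "huynh_feldt_epsilon",
    "omega_squared",
    "MixedAnova",
    "MixedAnovaResults",
]


# ---------------------------------------------------------------------------
# t-tests and power


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    variant: str

    def __str__(self):
        return (f"t({self.df:.4g}) = {self.t:.4g}, p = {self.p:.4g} "
                f"({self.variant}; mean diff {self.mean_diff:.4g})")


def ttest_independent(group_a, group_b, variant: str = "welch") -> TTestResult:
    """Two-sided independent-samples t-test (Student pooled or Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups: t undefined")
    equal_var = variant == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = res.df
    return TTestResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()), variant=variant,
    )


def ttest_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "student",
) -> TTestResult:
    """t-test from summary statistics (reproduces printed group tables)."""
    res = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "student")
    )
    if variant == "student":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TTestResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        mean_diff=mean_a - mean_b, variant=variant,
    )


def power_two_sample_t(
    n_per_group: int, delta: float, sd: float, alpha: float = 0.05
) -> float:
    """Exact power of the two-sided two-sample t-test (noncentral t).

    ``delta`` is the true difference in means, ``sd`` the common within-group
    standard deviation; df = 2n - 2 and noncentrality
    ``delta / (sd * sqrt(2/n))``.
    """
    if n_per_group < 2 or sd <= 0 or not 0 < alpha < 1:
        raise ValueError("need n >= 2, sd > 0, alpha in (0, 1)")
    df = 2 * n_per_group - 2
    nc = delta / (sd * np.sqrt(2.0 / n_per_group))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    if not np.isfinite(power):  # extreme df/noncentrality: normal limit
        power = sps.norm.sf(tcrit - nc) + sps.norm.cdf(-tcrit - nc)
    return float(power)


# ---------------------------------------------------------------------------
# sphericity


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) orthonormal basis of the contrast space (Helmert-based)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def contrast_covariance(data, groups=None):
    """Pooled within-group covariance of the orthonormal contrast scores.

    ``data`` is subjects x k conditions; with ``groups`` the covariance pools
    the per-group sample covariances with their degrees of freedom (the mixed
    design).  Returns ``(T, error_df)`` where T = C' S C.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    c = _orthonormal_contrasts(k)
    scores = x @ c
    if groups is None:
        groups = np.zeros(n)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    t = np.zeros((k - 1, k - 1))
    err_df = 0
    for g in labels:
        sub = scores[groups == g]
        if sub.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 complete subjects")
        t += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
        err_df += sub.shape[0] - 1
    return t / err_df, err_df


def mauchly_sphericity(data, groups=None):
    """Mauchly's test of sphericity; returns ``(W, chi2, df, p)``.

    W = det(T) / (tr(T)/(k-1))^(k-1) on the contrast covariance T, with the
    standard chi-square approximation on k(k-1)/2 - 1 degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    k = x.shape[1]
    if k < 3:
        raise ValueError("sphericity needs at least 3 within-subject conditions")
    t, err_df = contrast_covariance(x, groups)
    eig = np.linalg.eigvalsh(t)
    if eig.min() <= 0:
        raise np.linalg.LinAlgError(
            "contrast covariance is singular (too few subjects or "
            "linearly dependent conditions); Mauchly W undefined"
        )
    d = k - 1
    w = float(np.prod(eig) / (eig.mean() ** d))
    chi_df = k * (k - 1) // 2 - 1
    f_corr = 1.0 - (2 * d * d + d + 2) / (6.0 * d * err_df)
    chi2 = -err_df * f_corr * np.log(w)
    p = float(sps.chi2.sf(chi2, chi_df))
    return w, float(chi2), chi_df, p


def greenhouse_geisser_epsilon(data, groups=None) -> float:
    """Greenhouse-Geisser epsilon from the contrast covariance."""
    t, _ = contrast_covariance(data, groups)
    eig = np.linalg.eigvalsh(t)
    d = t.shape[0]
    if (eig**2).sum() <= 0:  # zero contrast variance: sphericity trivially holds
        return 1.0
    return float(eig.sum() ** 2 / (d * (eig**2).sum()))


def huynh_feldt_epsilon(data, groups=None) -> float:
    """Huynh-Feldt epsilon for the split-plot design, capped at 1.

    Generalizes the classical formula to g groups by replacing the subject
    count with the between-subjects error df N - g + 1 in the numerator (the
    one-group case reduces to the textbook expression).
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    g = 1 if groups is None else len(pd.unique(np.asarray(groups)))
    d = k - 1
    eps_gg = greenhouse_geisser_epsilon(x, groups)
    num = (n - g + 1) * d * eps_gg - 2.0
    den = d * (n - g - d * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(num / den, 1.0))


def omega_squared(ss_effect: float, df_effect: float, ms_error: float,
                  ss_total: float) -> float:
    """Omega-squared effect size against a chosen error stratum.

    ``(SS_eff - df_eff * MS_err) / (SS_total + MS_err)``; may be slightly
    negative when F < 1 and is reported as computed.
    """
    denom = ss_total + ms_error
    if denom <= 0:
        return float("nan")
    return float((ss_effect - df_effect * ms_error) / denom)


# ---------------------------------------------------------------------------
# split-plot (mixed-design) ANOVA


class MixedAnova:
    """Two-way mixed-design (split-plot) ANOVA model.

    Parameters
    ----------
    data : DataFrame
        Long format with one observation per subject x condition.
    dv, within, between, subject : str
        Column names of the dependent variable, the within-subject factor,
        the between-subjects factor, and the subject identifier.

    Subjects missing any within-subject condition are dropped listwise; the
    count is reported on the results object.
    """

    def __init__(self, data: pd.DataFrame, dv: str = "value",
                 within: str = "stage", between: str = "age_group",
                 subject: str = "subject_id"):
        for col in (dv, within, between, subject):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data
        self.dv, self.within, self.between, self.subject = dv, within, between, subject

    @classmethod
    def from_stage_table(cls, table: pd.DataFrame, measure: str) -> "MixedAnova":
        """Build the model for one measure from the tidy stage table."""
        sub = table[table["measure"] == measure]
        if sub.empty:
            raise ValueError(f"measure {measure!r} not present in stage table")
        return cls(sub, dv="value", within="stage", between="age_group",
                   subject="subject_id")

    def _wide(self):
        wide = self.data.pivot_table(
            index=self.subject, columns=self.within, values=self.dv,
            aggfunc="mean", observed=True,
        )
        # keep the within-factor order of first appearance, not alphabetical
        order = list(dict.fromkeys(self.data[self.within]))
        wide = wide[order]
        n_before = wide.shape[0]
        wide = wide.dropna()
        groups = (
            self.data.drop_duplicates(self.subject)
            .set_index(self.subject)[self.between]
            .loc[wide.index]
        )
        return wide, groups, n_before - wide.shape[0]

    def fit(self, sphericity_alpha: float = 0.05,
            correction: str = "auto") -> "MixedAnovaResults":
        """Fit the split-plot decomposition.

        ``correction``: "auto" applies Huynh-Feldt df scaling to the within
        effects when Mauchly p < ``sphericity_alpha``; "none" never; "always"
        unconditionally.
        """
        wide, groups, n_dropped = self._wide()
        y = wide.to_numpy(float)
        n, k = y.shape
        glabels = list(dict.fromkeys(groups))
        g = len(glabels)
        if g < 2:
            raise ValueError("between-subjects factor needs at least 2 groups")
        n_j = np.array([(groups == lab).sum() for lab in glabels])
        if n_j.min() < 2:
            raise ValueError("each group needs at least 2 complete subjects")

        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        subj_means = y.mean(axis=1)
        ss_between_subj = k * ((subj_means - grand) ** 2).sum()
        gmask = [np.asarray(groups == lab) for lab in glabels]
        group_means = np.array([subj_means[m].mean() for m in gmask])
        ss_group = k * float(n_j @ (group_means - grand) ** 2)
        ss_subj_within = ss_between_subj - ss_group
        cond_means = y.mean(axis=0)
        # weighted stage means (all subjects) -> Type I/II identical here
        ss_within_cond = n * ((cond_means - grand) ** 2).sum()
        cell_means = np.array([y[m].mean(axis=0) for m in gmask])  # g x k
        ss_cells = float(np.sum(n_j[:, None] * (cell_means - grand) ** 2))
        ss_inter = ss_cells - ss_group - ss_within_cond
        ss_err_within = ss_total - ss_between_subj - ss_within_cond - ss_inter

        df_group, df_subj = g - 1, n - g
        df_cond, df_inter = k - 1, (g - 1) * (k - 1)
        df_err = (n - g) * (k - 1)
        ms_subj = ss_subj_within / df_subj
        ms_err = ss_err_within / df_err

        degenerate = ms_subj <= 1e-300 or ms_err <= 1e-300

        def frow(ss, dfn, ms_e, dfd):
            if degenerate or ms_e <= 0:
                return np.nan, np.nan
            f = (ss / dfn) / ms_e
            return f, float(sps.f.sf(f, dfn, dfd))

        # sphericity on the within-subject conditions, pooled within groups
        try:
            w, chi2, chi_df, w_p = mauchly_sphericity(y, groups.to_numpy())
        except np.linalg.LinAlgError:
            w, chi2, chi_df, w_p = np.nan, np.nan, k * (k - 1) // 2 - 1, np.nan
        eps_hf = huynh_feldt_epsilon(y, groups.to_numpy())
        if correction == "auto":
            apply_corr = bool(w_p < sphericity_alpha) if np.isfinite(w_p) else False
        elif correction == "always":
            apply_corr = True
        elif correction == "none":
            apply_corr = False
        else:
            raise ValueError(f"unknown correction {correction!r}")
        eps_used = eps_hf if apply_corr else 1.0

        rows = []
        f, p = frow(ss_group, df_group, ms_subj, df_subj)
        rows.append(("group", ss_group, df_group, ss_subj_within, df_subj, f, p,
                     omega_squared(ss_group, df_group, ms_subj, ss_total)))
        for name, ss, dfn in (("stage", ss_within_cond, df_cond),
                              ("interaction", ss_inter, df_inter)):
            f, p = frow(ss, dfn, ms_err, df_err)
            if apply_corr and np.isfinite(f):
                p = float(sps.f.sf(f, dfn * eps_used, df_err * eps_used))
            rows.append((name, ss, dfn * eps_used, ss_err_within, df_err * eps_used,
                         f, p, omega_squared(ss, dfn, ms_err, ss_total)))
        table = pd.DataFrame(
            rows, columns=["effect", "ss", "df_num", "ss_error", "df_den", "F",
                           "p", "omega_sq"],
        )
        return MixedAnovaResults(
            anova_table=table, mauchly_w=w, mauchly_chi2=chi2,
            mauchly_df=chi_df, mauchly_p=w_p, epsilon_hf=eps_hf,
            correction_applied=apply_corr, n_subjects=n, n_dropped=n_dropped,
            group_sizes=dict(zip(glabels, n_j.tolist())),
            degenerate=bool(degenerate), ss_total=ss_total,
        )


@dataclass
class MixedAnovaResults:
    """Split-plot ANOVA results: F table, sphericity diagnostics, effect sizes."""

    anova_table: pd.DataFrame
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    epsilon_hf: float
    correction_applied: bool
    n_subjects: int
    n_dropped: int
    group_sizes: dict
    degenerate: bool
    ss_total: float

    def effect(self, name: str) -> pd.Series:
        row = self.anova_table[self.anova_table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def summary(self) -> str:
        lines = [
            "Mixed-design (split-plot) ANOVA",
            f"  subjects: {self.n_subjects} "
            f"(dropped listwise: {self.n_dropped}); groups: {self.group_sizes}",
            f"  Mauchly W = {self.mauchly_w:.4g}, "
            f"chi2({self.mauchly_df}) = {self.mauchly_chi2:.4g}, "
            f"p = {self.mauchly_p:.4g}",
            f"  Huynh-Feldt epsilon = {self.epsilon_hf:.4g} "
            f"({'applied' if self.correction_applied else 'not applied'})",
        ]
        if self.degenerate:
            lines.append("  WARNING: zero error variance; F undefined")
        hdr = f"  {'effect':<12}{'F':>10}{'df_num':>9}{'df_den':>9}{'p':>12}{'omega_sq':>10}"
        lines.append(hdr)
        for _, r in self.anova_table.iterrows():
            lines.append(
                f"  {r['effect']:<12}{r['F']:>10.4g}{r['df_num']:>9.4g}"
                f"{r['df_den']:>9.4g}{r['p']:>12.4g}{r['omega_sq']:>10.4g}"
            )
        return "\n".join(lines)
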