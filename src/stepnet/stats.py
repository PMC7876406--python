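"""Group-comparison statistics.

The inference layer applied to every score (behavioral, STEP percentile,
ERPv): mixed group × visit ANOVA (group between-subjects, visit
within-subjects), Levene's variance-homogeneity test with Welch statistics
as the heteroscedasticity-robust follow-up, ROC discrimination (AUC,
Youden-optimal sensitivity/specificity, patients as positives), two-visit
intraclass correlation for test–retest reliability, Cohen's d effect sizes
and demographic summaries. p-values are reported unadjusted, as is standard
for per-score clinical ERP tables; Benjamini–Hochberg is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve


@dataclass
class GroupComparison:
    score_id: str
    F: float
    df1: float
    df2: float
    p: float
    effect_size: float
    levene_p: float | None = None
    welch_t: float | None = None
    welch_p: float | None = None


@dataclass
class ROCResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    orientation: int  # +1: patients score higher; −1: lower


@dataclass
class ICCResult:
    icc: float
    model: str = "two-way mixed, absolute agreement, single measurement"


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference (x − y) with pooled n−1 SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def mixed_anova(
    scores: pd.DataFrame,
    dv: str = "score",
    subject: str = "subject",
    group: str = "group",
    visit: str = "visit",
    score_id: str = "",
) -> GroupComparison:
    """Between-group F from a two-level mixed (split-plot) design.

    ``scores`` is long-format with one row per subject × visit. Subjects
    missing a visit are dropped listwise. The effect size is Cohen's d on
    subject-mean scores, patients minus healthy.
    """
    import pingouin as pg

    df = scores.dropna(subset=[dv]).copy()
    counts = df.groupby(subject)[visit].nunique()
    complete = counts[counts == df[visit].nunique()].index
    df = df[df[subject].isin(complete)]
    groups = df.groupby(subject)[group].first()
    sizes = groups.value_counts()
    if len(sizes) < 2 or sizes.min() < 2:
        raise ValueError("need at least 2 subjects per group")

    if df.groupby([group])[dv].var().max() == 0 and df[dv].nunique() == 1:
        # degenerate: all scores identical → no group effect
        n = len(complete)
        return GroupComparison(score_id, 0.0, 1.0, n - 2, 1.0, 0.0, levene_p=1.0)

    aov = pg.mixed_anova(
        data=df, dv=dv, within=visit, subject=subject, between=group
    )
    row = aov.loc[aov["Source"] == group].iloc[0]

    means = df.groupby(subject)[dv].mean()
    g = groups.loc[means.index]
    pat = means[g == "patient"].to_numpy()
    hea = means[g == "healthy"].to_numpy()
    if pat.size and hea.size:
        d = cohens_d(pat, hea)
        _, lev_p = levene_test(means.to_numpy(), g.to_numpy())
    else:  # generic two-group labels
        labels = g.unique()
        d = cohens_d(means[g == labels[0]].to_numpy(), means[g == labels[1]].to_numpy())
        _, lev_p = levene_test(means.to_numpy(), g.to_numpy())

    return GroupComparison(
        score_id=score_id,
        F=float(row["F"]),
        df1=float(row["DF1"]),
        df2=float(row["DF2"]),
        p=float(row["p_unc" if "p_unc" in row else "p-unc"]),
        effect_size=d,
        levene_p=lev_p,
    )


def levene_test(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Levene's test on absolute deviations from the group means."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if min(len(s) for s in samples) < 2:
        raise ValueError("need at least 2 observations per group")
    stat, p = sps.levene(*samples, center="mean")
    return float(stat), float(p)


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Welch's t and Welch–Satterthwaite df from group summaries."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n ≥ 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df)


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC discrimination of patients from controls.

    AUC uses the rank (Mann–Whitney) formulation with tie correction and is
    oriented so auc ≥ 0.5; the reported operating point maximizes Youden's
    J = sensitivity + specificity − 1, with patients as positives.
    """
    scores = np.asarray(scores, float)
    y = (np.asarray(labels) == "patient").astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")

    n1, n0 = int(y.sum()), int((1 - y).sum())
    # Mann–Whitney U via midranks (tie-corrected)
    ranks = sps.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)

    orientation = 1
    if auc < 0.5:
        orientation = -1
        auc = 1.0 - auc
        scores = -scores

    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    k = int(np.argmax(j))
    return ROCResult(
        auc=float(auc),
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
        threshold=float(orientation * thresholds[k]),
        orientation=orientation,
    )


def icc_two_visit(visit1: np.ndarray, visit2: np.ndarray) -> ICCResult:
    """Test–retest ICC: two-way mixed effects, absolute agreement, single
    measurement (ICC(A,1))."""
    import pingouin as pg

    v1 = np.asarray(visit1, float)
    v2 = np.asarray(visit2, float)
    if v1.size != v2.size or v1.size < 3:
        raise ValueError("need paired values for ≥ 3 subjects")
    if np.var(np.r_[v1, v2]) == 0:
        raise ValueError("zero total variance; ICC undefined")
    n = v1.size
    df = pd.DataFrame(
        {
            "subject": np.r_[np.arange(n), np.arange(n)],
            "visit": np.r_[np.ones(n), 2 * np.ones(n)],
            "score": np.r_[v1, v2],
        }
    )
    icc = pg.intraclass_corr(
        data=df, targets="subject", raters="visit", ratings="score"
    )
    val = float(icc.loc[icc["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    return ICCResult(icc=val)


def describe_ages(ages: "list[tuple[int, int]]") -> tuple[float, float]:
    """Mean and sample SD of ages given as (years, months), in decimal years,
    rounded to reporting precision (mean 1 dp, SD 2 dp)."""
    if len(ages) < 2:
        raise ValueError("need at least 2 ages")
    dec = np.array([y + m / 12.0 for y, m in ages])
    return round(float(dec.mean()), 1), round(float(dec.std(ddof=1)), 2)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in reporting)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def compare_scores(
    table: pd.DataFrame,
    dv: str,
    by: list[str],
    subject: str = "subject",
    group: str = "group",
    visit: str = "visit",
) -> pd.DataFrame:
    """Run the full comparison bundle for every score in a tidy table.

    For each combination of the ``by`` columns: mixed ANOVA F/df/p with
    Cohen's d and Levene p (Welch t added when Levene p < 0.05), ROC
    AUC/sensitivity/specificity on subject×visit observations, and the
    two-visit ICC. Mirrors the layout of a per-score results table.
    """
    rows = []
    for key, sub in table.dropna(subset=[dv]).groupby(by):
        key = key if isinstance(key, tuple) else (key,)
        try:
            cmp_ = mixed_anova(sub, dv=dv, subject=subject, group=group,
                               visit=visit, score_id="/".join(map(str, key)))
        except ValueError:
            continue
        if cmp_.levene_p is not None and cmp_.levene_p < 0.05:
            g = sub.groupby(subject).agg({dv: "mean", group: "first"})
            h = g.loc[g[group] == "healthy", dv]
            p_ = g.loc[g[group] == "patient", dv]
            if h.std(ddof=1) > 0 and p_.std(ddof=1) > 0:
                t, wdf = welch_t_from_summary(
                    h.mean(), h.std(ddof=1), len(h),
                    p_.mean(), p_.std(ddof=1), len(p_),
                )
                cmp_.welch_t = t
                cmp_.welch_p = float(2 * sps.t.sf(abs(t), wdf))
        roc = roc_analysis(sub[dv].to_numpy(), sub[group].to_numpy())
        icc_val = np.nan
        wide = sub.pivot_table(index=subject, columns=visit, values=dv)
        if wide.shape[1] == 2 and wide.dropna().shape[0] >= 3:
            w = wide.dropna()
            try:
                icc_val = icc_two_visit(w.iloc[:, 0].to_numpy(),
                                        w.iloc[:, 1].to_numpy()).icc
            except ValueError:
                pass
        rows.append(
            {
                **{c: v for c, v in zip(by, key)},
                "F": cmp_.F, "df1": cmp_.df1, "df2": cmp_.df2, "p": cmp_.p,
                "levene_p": cmp_.levene_p, "welch_t": cmp_.welch_t,
                "auc": roc.auc, "sensitivity": roc.sensitivity,
                "specificity": roc.specificity, "icc": icc_val,
                "effect_size": cmp_.effect_size,
            }
        )
    return pd.DataFrame(rows)


def multiparameter_radar(
    table: pd.DataFrame, dv: str, label_col: str, group: str = "group",
    ax=None, title: str = "",
):
    """Radar plot of group-mean percentile scores (patients vs healthy)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    labels = list(table[label_col].unique())
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for grp, color in (("healthy", "gray"), ("patient", "tab:orange")):
        sub = table[table[group] == grp]
        means = [sub.loc[sub[label_col] == lb, dv].mean() for lb in labels]
        ax.plot(np.r_[angles, angles[:1]], np.r_[means, means[:1]],
                color=color, label=grp)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=7)
    return ax
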