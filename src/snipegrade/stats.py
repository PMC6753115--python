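"""Group-comparison statistics: ANOVA, Tukey, Cohen's d, chi-square,
Benjamini-Hochberg FDR, and symptom-by-complaint interaction models.

The battery mirrors a standard clinical-neuroimaging analysis: one-way
ANOVA with Tukey-Kramer post-hoc pairwise tests for the main outcomes,
BH-FDR across a many-region scan, Cohen's d (pooled SD) for effect sizes
versus the healthy reference group, chi-square for sex tables, and linear
models testing whether anxiety/depression scores interact with the
presence of cognitive complaints in predicting a biomarker.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class FdrResult:
    pvalues: np.ndarray  # original order
    reject: np.ndarray  # original order
    q: float
    critical_index: int  # 1-based index into the sorted p-values; 0 = none

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


@dataclass
class GroupComparison:
    measure: str
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj
    effect_sizes_vs_ref: dict[str, float] = field(default_factory=dict)
    group_means: dict[str, float] = field(default_factory=dict)
    stars_vs_ref: list[str] = field(default_factory=list)


@dataclass
class InteractionResult:
    estimate: float
    se: float
    t_stat: float
    p_value: float
    dropped: bool = False  # True when the interaction term was degenerate


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {k!r} contains non-finite values")
    return out


def anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA: F statistic and p-value."""
    groups = _check_groups(groups)
    f, p = sps.f_oneway(*groups.values())
    return float(f), float(p)


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range adjusted p-values
    (Tukey-Kramer for unbalanced groups)."""
    groups = _check_groups(groups)
    names = list(groups)
    res = sps.tukey_hsd(*groups.values())
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def cohens_d(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var <= 0:
        raise FloatingPointError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up: reject p(1..k) for the largest k with
    p(k) <= k*q/m."""
    p = np.asarray(pvalues, dtype=float)
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    order = np.argsort(p, kind="stable")
    sorted_reject = reject[order]
    critical = int(np.max(np.nonzero(sorted_reject)[0]) + 1) if reject.any() else 0
    return FdrResult(pvalues=p, reject=reject, q=q, critical_index=critical)


def chi_square_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column is all zero")
    x2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(x2), float(p)


def interaction_model(
    biomarker: np.ndarray,
    group: np.ndarray,
    symptom: np.ndarray,
) -> InteractionResult:
    """Least-squares fit of ``biomarker ~ group + symptom + group:symptom``.

    ``group`` is a binary indicator (e.g. 0 = no complaint/CH, 1 = SCD).
    Reports the interaction coefficient's estimate, SE, t and p. A constant
    symptom score makes the interaction inestimable; the term is dropped
    and flagged instead of failing.
    """
    import statsmodels.api as sm

    y = np.asarray(biomarker, dtype=float)
    g = np.asarray(group, dtype=float)
    s = np.asarray(symptom, dtype=float)
    if y.size != g.size or y.size != s.size:
        raise ValueError("inputs must have equal length")
    for lvl in (0.0, 1.0):
        if (g == lvl).sum() < 10:
            raise ValueError("need >= 10 subjects per complaint group")
    if np.ptp(s) == 0:
        return InteractionResult(np.nan, np.nan, np.nan, np.nan, dropped=True)
    x = np.column_stack([np.ones_like(y), g, s, g * s])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design: interaction not estimable")
    fit = sm.OLS(y, x).fit()
    return InteractionResult(
        estimate=float(fit.params[3]),
        se=float(fit.bse[3]),
        t_stat=float(fit.tvalues[3]),
        p_value=float(fit.pvalues[3]),
    )


def gradient_report(
    scores: pd.DataFrame,
    measures: list[str],
    reference: str = "CH",
    group_col: str = "group",
    alpha: float = 0.05,
    group_order: list[str] | None = None,
) -> dict[str, GroupComparison]:
    """Per-measure group-gradient battery: ANOVA, Tukey pairs, Cohen's d and
    significance stars versus the reference group.

    ``scores`` is wide: one row per subject, one column per measure plus the
    group column. Subjects with a missing measure are dropped measure-wise.
    """
    if reference not in set(scores[group_col]):
        raise ValueError(f"reference group {reference!r} missing from the table")
    order = group_order or list(dict.fromkeys(scores[group_col]))
    out: dict[str, GroupComparison] = {}
    for measure in measures:
        sub = scores[[group_col, measure]].dropna()
        groups = {
            g: sub.loc[sub[group_col] == g, measure].to_numpy()
            for g in order
            if (sub[group_col] == g).sum() >= 2
        }
        if len(groups) < 2 or reference not in groups:
            out[measure] = GroupComparison(
                measure=measure,
                f_stat=float("nan"),
                p_value=float("nan"),
                pairwise=pd.DataFrame(
                    columns=["group_a", "group_b", "mean_diff", "p_adj"]
                ),
            )
            continue
        f, p = anova_oneway(groups)
        pairs = tukey_hsd(groups)
        d_vs_ref = {
            g: cohens_d(groups[reference], groups[g])
            for g in groups
            if g != reference
        }
        stars = []
        for _, row in pairs.iterrows():
            if reference in (row["group_a"], row["group_b"]) and row["p_adj"] < alpha:
                other = row["group_b"] if row["group_a"] == reference else row["group_a"]
                stars.append(other)
        out[measure] = GroupComparison(
            measure=measure,
            f_stat=f,
            p_value=p,
            pairwise=pairs,
            effect_sizes_vs_ref=d_vs_ref,
            group_means={g: float(v.mean()) for g, v in groups.items()},
            stars_vs_ref=stars,
        )
    return out


def fdr_scan(
    scores: pd.DataFrame,
    measures: list[str],
    group_a: str = "CH",
    group_b: str = "SCD",
    group_col: str = "group",
    q: float = 0.05,
) -> pd.DataFrame:
    """Two-group ANOVA per measure across a region battery, BH-corrected.

    Mirrors the whole-brain scan between healthy controls and subjective
    decliners: per-region p-values plus FDR rejection flags at level q.
    """
    rows = []
    for measure in measures:
        sub = scores[[group_col, measure]].dropna()
        a = sub.loc[sub[group_col] == group_a, measure].to_numpy()
        b = sub.loc[sub[group_col] == group_b, measure].to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append((measure, np.nan, np.nan))
            continue
        _, p = anova_oneway({group_a: a, group_b: b})
        rows.append((measure, p, cohens_d(a, b)))
    out = pd.DataFrame(rows, columns=["measure", "p_raw", "cohens_d"])
    ok = out["p_raw"].notna()
    out["significant_raw"] = out["p_raw"] < q
    out["significant_fdr"] = False
    if ok.any():
        res = fdr_bh(out.loc[ok, "p_raw"].to_numpy(), q=q)
        out.loc[ok, "significant_fdr"] = res.reject
    return out
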