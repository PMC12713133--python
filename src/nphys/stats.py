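"""Group-comparison statistics shared across the pipeline.

Mann-Whitney U (exact by enumeration for small tie-free samples, normal
approximation with tie and continuity corrections otherwise), two-way
mixed ANOVA for input-output curves (between-subject genotype x
within-subject current step), Benjamini-Hochberg FDR, and mean +/- SEM
descriptive summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MWU_MAX_N = 16     # combined n at or below which the exact p is used


@dataclass
class GroupComparison:
    metric: str
    test: str                      # mann_whitney_exact | mann_whitney_normal
    statistic: float               # U (of sample a) or F
    p_value: float
    n_a: int
    n_b: int
    extra: dict | None = None


def mann_whitney_u(a, b, *, metric: str = "",
                   mode: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    The U statistic is computed from midrank sums. The p-value is exact
    (full enumeration of labelings) when the combined sample size is at
    most 16 and there are no ties, else a normal approximation with tie
    correction and continuity correction. ``mode`` forces
    ``"exact"``/``"normal"`` when not ``"auto"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if mode == "auto":
        exact = (a.size + b.size <= EXACT_MWU_MAX_N) and not has_ties
    else:
        exact = mode == "exact"
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return GroupComparison(metric=metric,
                           test=f"mann_whitney_{'exact' if exact else 'normal'}",
                           statistic=float(res.statistic),
                           p_value=float(min(res.pvalue, 1.0)),
                           n_a=a.size, n_b=b.size)


def mixed_two_way_anova(io_table: pd.DataFrame, *, dv: str = "value",
                        within: str = "step", subject: str = "subject",
                        between: str = "group") -> GroupComparison:
    """Two-way mixed ANOVA on per-cell response curves.

    ``io_table`` is long format: one row per (subject, within-level)
    with the between-group label. Subjects missing any within level are
    dropped listwise. Reports the between-subject main-effect F on
    (k-1, n-k) degrees of freedom with its p, plus the interaction F, no
    sphericity correction.
    """
    df = io_table[[subject, within, between, dv]].dropna()
    levels = df[within].nunique()
    complete = df.groupby(subject)[within].nunique()
    df = df[df[subject].isin(complete[complete == levels].index)]
    counts = df.groupby(between)[subject].nunique()
    if len(counts) != 2 or (counts < 2).any():
        raise ValueError("need two groups with at least 2 complete subjects")
    import pingouin as pg
    with warnings.catch_warnings():
        # pandas FutureWarnings from pingouin internals; RuntimeWarnings
        # on degenerate (zero-variance) inputs where F = 0 is still valid
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.mixed_anova(data=df, dv=dv, within=within,
                             subject=subject, between=between)
    betw = aov[aov["Source"] == between].iloc[0]
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    n = df[subject].nunique()
    return GroupComparison(
        metric=dv, test="mixed_two_way_anova",
        statistic=float(betw["F"]), p_value=float(betw["p_unc"]),
        n_a=int(counts.iloc[0]), n_b=int(counts.iloc[1]),
        extra={"df_between": (int(betw["DF1"]), int(betw["DF2"])),
               "n_subjects": n,
               "interaction_F": float(inter["F"]),
               "interaction_p": float(inter["p_unc"])})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def describe(values) -> dict:
    """Mean, SEM (sample s.d. / sqrt(n)), and n; SEM is None at n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
    return {"mean": float(v.mean()), "sem": sem, "n": int(v.size)}


def comparisons_to_table(comps: list[GroupComparison], path=None,
                         fdr: bool = False) -> pd.DataFrame:
    rows = [{"metric": c.metric, "test": c.test, "stat": c.statistic,
             "p": c.p_value, "n_a": c.n_a, "n_b": c.n_b} for c in comps]
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy()) if (fdr and len(df)) else np.nan
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
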