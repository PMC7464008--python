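"""Cohort-level statistics.

Group comparisons (pooled-variance t test, Pearson chi-square), Pearson
correlations with significance flags, a 2x2 mixed-design ANOVA interaction
(group x time), and the measure-by-parameter correlation table relating
questionnaire/interoception scores to estimated EWA parameters.

Conventions: Student's pooled-variance t (two groups of 27 and 25 give
df = 50), chi-square without continuity correction, two-sided p values,
no multiple-testing correction by default (a Holm option is available).
Interoceptive awareness is arcsine-square-root transformed before entering
correlations, as is standard for proportion-like scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ewa import EWAParams
from .psychometrics import ParticipantProfile, arcsine_transform

__all__ = [
    "CorrelationCell",
    "significance_flag",
    "two_sample_t",
    "chi_square_2x2",
    "pearson_r_with_p",
    "mixed_anova_interaction",
    "correlation_table",
    "holm_adjust",
]

#: Flag thresholds: (cutoff, symbol), checked in order.
_FLAG_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "†"))


def significance_flag(p: float) -> str:
    """Significance symbol for a p-value: ***, **, *, † or ns."""
    for cutoff, symbol in _FLAG_LEVELS:
        if p < cutoff:
            return symbol
    return "ns"


@dataclass(frozen=True)
class CorrelationCell:
    """One correlation-table cell: r, two-sided p, pair count and flag."""

    r: float
    p: float
    n: int
    flag: str

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t test.

    Returns (t, df, two-sided p) with df = n_x + n_y - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, len(x) + len(y) - 2, 1.0
    res = sps.ttest_ind(x, y, equal_var=True)
    df = len(x) + len(y) - 2
    if not np.isfinite(res.statistic):
        raise ValueError("zero pooled variance with unequal means")
    return float(res.statistic), df, float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return float(chi2), float(p)


def pearson_r_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationCell:
    """Pearson correlation with a two-sided t-based p-value and flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationCell(float(r), float(p), len(x), significance_flag(float(p)))


def mixed_anova_interaction(
    scores: pd.DataFrame, group: Sequence[str] | None = None
) -> tuple[float, int, int, float]:
    """Group x time interaction from a 2(between) x 2(within) mixed ANOVA.

    ``scores`` is a DataFrame with columns 'pre' and 'post' (one row per
    participant) and either a 'group' column or a separate ``group``
    label sequence. Returns (F, df1, df2, p).
    """
    df = scores.copy()
    if group is not None:
        df = df.assign(group=list(group))
    if not {"pre", "post", "group"} <= set(df.columns):
        raise ValueError("scores must provide 'pre', 'post' and group labels")
    if df[["pre", "post"]].isna().any().any():
        raise ValueError("missing time point")
    if df["group"].nunique() != 2 or (df["group"].value_counts() < 2).any():
        raise ValueError("need two groups with at least 2 participants each")
    import pingouin as pg

    long = df.reset_index(drop=True).rename_axis("subject").reset_index()
    long = long.melt(
        id_vars=["subject", "group"],
        value_vars=["pre", "post"],
        var_name="time",
        value_name="score",
    )
    aov = pg.mixed_anova(
        data=long, dv="score", within="time", between="group", subject="subject"
    )
    row = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    return float(row["F"]), int(row["DF1"]), int(row["DF2"]), float(row["p_unc"])


def correlation_table(
    profiles: Sequence[ParticipantProfile],
    params: Sequence[EWAParams],
    holm: bool = False,
) -> pd.DataFrame:
    """Measure-by-parameter correlation table with significance flags.

    Rows are the six participant measures (CES-D, DAMS-D, PANAS-PA,
    PANAS-NA, attention, awareness), columns the three EWA parameters.
    Awareness is arcsine-square-root transformed first. Participants with
    missing values are dropped pairwise per cell. Cells are
    :class:`CorrelationCell`; with ``holm=True`` flags use Holm-adjusted
    p-values (the reported p stays unadjusted).
    """
    if len(profiles) != len(params):
        raise ValueError("profiles and params must align")
    if len(profiles) < 3:
        raise ValueError("need at least 3 participants")
    measures = {
        "ces_d": np.array([p.ces_d for p in profiles], dtype=float),
        "dams_d": np.array([p.dams_d for p in profiles], dtype=float),
        "panas_pa": np.array([p.panas_pa for p in profiles], dtype=float),
        "panas_na": np.array([p.panas_na for p in profiles], dtype=float),
        "attention": np.array([p.attention for p in profiles], dtype=float),
        "awareness": np.array(
            [arcsine_transform(p.awareness) if np.isfinite(p.awareness) else np.nan
             for p in profiles]
        ),
    }
    param_cols = {
        "alpha": np.array([q.alpha for q in params], dtype=float),
        "rho": np.array([q.rho for q in params], dtype=float),
        "beta": np.array([q.beta for q in params], dtype=float),
    }
    cells: dict[str, dict[str, CorrelationCell]] = {}
    pvals = []
    for mname, mv in measures.items():
        cells[mname] = {}
        for pname, pv in param_cols.items():
            mask = np.isfinite(mv) & np.isfinite(pv)
            try:
                cell = pearson_r_with_p(mv[mask], pv[mask])
            except ValueError:
                # degenerate column (e.g. a parameter whose posterior
                # collapsed to a boundary for every participant)
                cell = CorrelationCell(float("nan"), float("nan"), int(mask.sum()), "na")
            cells[mname][pname] = cell
            pvals.append(cell.p)
    if holm:
        adjusted = holm_adjust([p if np.isfinite(p) else 1.0 for p in pvals])
        k = 0
        for mname in cells:
            for pname in cells[mname]:
                c = cells[mname][pname]
                if np.isfinite(c.p):
                    cells[mname][pname] = CorrelationCell(
                        c.r, c.p, c.n, significance_flag(adjusted[k])
                    )
                k += 1
    return pd.DataFrame(cells).T[list(param_cols)]


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests(list(pvalues), method="holm")
    return list(adj)
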