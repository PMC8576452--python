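"""Group-comparison statistics for the clinical table.

Two-sample pooled-variance Student's t-tests — computable either from raw
columns or directly from printed summary statistics (n, mean, SD) — and 2x2
contingency tests (chi-square with or without Yates correction, Fisher
exact).  The pooled t from the published group moments reproduces the
printed p-values (age 0.062 / 0.23, education 0.88); Welch's form is
available behind a flag for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import SubjectRecord, records_to_frame


class StatsError(ValueError):
    """Raised for degenerate or inconsistent statistical inputs."""


@dataclass
class SummaryStats:
    """Printed-style group summary: n, mean, SD (and optional range)."""

    n: int
    mean: float
    sd: float
    min: float | None = None
    max: float | None = None

    def validate(self) -> "SummaryStats":
        if self.n < 2:
            raise StatsError(f"need n >= 2, got {self.n}")
        if self.sd < 0:
            raise StatsError(f"sd must be >= 0, got {self.sd}")
        return self

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "SummaryStats":
        x = np.asarray(x, dtype=np.float64)
        if len(x) < 2:
            raise StatsError(f"need n >= 2, got {len(x)}")
        return cls(
            n=len(x),
            mean=float(x.mean()),
            sd=float(x.std(ddof=1)),
            min=float(x.min()),
            max=float(x.max()),
        )


@dataclass
class GroupComparison:
    """One test's outcome: statistic, degrees of freedom, two-sided p."""

    statistic: float
    df: float
    p: float
    test_name: str

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def ttest_from_summary(
    a: SummaryStats, b: SummaryStats, equal_var: bool = True
) -> GroupComparison:
    """Two-sample t-test from group summaries (pooled variance by default).

    Pooled form: sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2),
    t = (m1 - m2) / (sp sqrt(1/n1 + 1/n2)), df = n1 + n2 - 2, two-sided p.
    Zero pooled variance: equal means give t=0, p=1; unequal means give p=0
    with a warning (the limiting behavior).
    """
    a.validate()
    b.validate()
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            df = a.n + b.n - 2
            return GroupComparison(0.0, df, 1.0, "pooled t (degenerate)")
        warnings.warn(
            "zero pooled variance with unequal means: p reported as 0",
            stacklevel=2,
        )
        return GroupComparison(
            float(np.inf) if a.mean > b.mean else float(-np.inf),
            a.n + b.n - 2,
            0.0,
            "pooled t (degenerate)",
        )
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = a.n + b.n - 2
        name = "pooled t"
    else:
        v1, v2 = a.sd**2 / a.n, b.sd**2 / b.n
        df = (v1 + v2) ** 2 / (v1**2 / (a.n - 1) + v2**2 / (b.n - 1))
        name = "Welch t"
    return GroupComparison(float(t), float(df), float(p), name)


def ttest_from_raw(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> GroupComparison:
    """Raw-data twin of :func:`ttest_from_summary` (identical formula).

    Feeding the sample moments to the summary form gives the same result to
    machine precision.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each group needs n >= 2")
    return ttest_from_summary(
        SummaryStats.from_sample(x), SummaryStats.from_sample(y), equal_var=equal_var
    )


def contingency_test(
    table: Sequence[Sequence[int]], method: str = "chi2"
) -> GroupComparison:
    """2x2 contingency test: plain chi-square, Yates-corrected, or Fisher.

    The exact test behind published categorical p-values is often
    unidentifiable, so all three standard methods are exposed.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {tab.shape}")
    if (tab < 0).any():
        raise StatsError("counts must be >= 0")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise StatsError("both margins must be positive")
    if method == "chi2":
        chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
        return GroupComparison(float(chi2), float(dof), float(p), "chi2")
    if method == "chi2_yates":
        chi2, p, dof, _ = sps.chi2_contingency(tab, correction=True)
        return GroupComparison(float(chi2), float(dof), float(p), "chi2 (Yates)")
    if method == "fisher":
        odds, p = sps.fisher_exact(tab, alternative="two-sided")
        return GroupComparison(float(odds), 1.0, float(p), "Fisher exact")
    raise StatsError(f"unknown method {method!r}; use chi2, chi2_yates or fisher")


# ---------------------------------------------------------------------------
# Table-1-style report
# ---------------------------------------------------------------------------

_CONTRASTS = {
    "T2DM_vs_NT": ("diagnosis", "T2DM", "NT"),
    "CI_vs_NC": ("cognition", "CI", "NC"),
}


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _fmt_mean_range(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ({x.min():.0f}, {x.max():.0f})"


def _fmt_p(p: float) -> str:
    return "<0.0001" if p < 0.0001 else f"{p:.3g}"


def build_table1(
    records: Sequence[SubjectRecord] | pd.DataFrame,
    gender_method: str = "chi2",
) -> pd.DataFrame:
    """Clinical-characteristics comparison table for both contrasts.

    One row per variable (age, gender, education, MoCA); for each contrast a
    per-group summary column, the two-sided p-value and a star when
    p < 0.05.  Continuous variables use the pooled t-test; gender uses the
    chosen 2x2 contingency method.  MoCA is summarized as mean (min, max)
    as is conventional for bounded scores.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rows: dict[str, dict] = {v: {} for v in ("Age (years)", "Gender (M/F)", "Education (years)", "MoCA")}
    for contrast, (col, pos, neg) in _CONTRASTS.items():
        g1 = df[df[col] == pos]
        g2 = df[df[col] == neg]
        if g1.empty or g2.empty:
            raise StatsError(f"empty stratum for contrast {contrast}")
        for var, column, fmt in (
            ("Age (years)", "age", _fmt_mean_sd),
            ("Education (years)", "education", _fmt_mean_sd),
            ("MoCA", "moca", _fmt_mean_range),
        ):
            x = g1[column].to_numpy(dtype=np.float64)
            y = g2[column].to_numpy(dtype=np.float64)
            comp = ttest_from_raw(x, y)
            rows[var][f"{pos} (n={len(g1)})"] = fmt(x)
            rows[var][f"{neg} (n={len(g2)})"] = fmt(y)
            rows[var][f"P ({contrast})"] = _fmt_p(comp.p) + ("*" if comp.significant else "")
            rows[var][f"p_raw ({contrast})"] = comp.p
        tab = [
            [int((g1["gender"] == "M").sum()), int((g1["gender"] == "F").sum())],
            [int((g2["gender"] == "M").sum()), int((g2["gender"] == "F").sum())],
        ]
        comp = contingency_test(tab, method=gender_method)
        rows["Gender (M/F)"][f"{pos} (n={len(g1)})"] = f"{tab[0][0]}/{tab[0][1]}"
        rows["Gender (M/F)"][f"{neg} (n={len(g2)})"] = f"{tab[1][0]}/{tab[1][1]}"
        rows["Gender (M/F)"][f"P ({contrast})"] = _fmt_p(comp.p) + (
            "*" if comp.significant else ""
        )
        rows["Gender (M/F)"][f"p_raw ({contrast})"] = comp.p
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "Characteristic"
    return out
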