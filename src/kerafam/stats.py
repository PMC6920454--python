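"""Group-comparison statistics and small derived measures for phenotype reporting.

Two-sample comparisons default to the classical equal-variance Student's
t-test (two-sided), with Welch's correction behind a flag; the significance
convention is p <= 0.05.  No multiple-testing correction is applied by
default; an optional Bonferroni factor is available and recorded in the
output when used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Two-sided significance level used for flags throughout.
ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA


def group_compare(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test (equal-variance by default).

    Raises ``ValueError`` for groups of fewer than two observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            df = float(a.size + b.size - 2)
        else:
            df = (va + vb) ** 2 / (
                va**2 / (a.size - 1) + vb**2 / (b.size - 1)
            )
    else:
        df = float(a.size + b.size - 2)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def contrast_sensitivity(min_percent_contrast: float) -> float:
    """Contrast sensitivity: 100 over the minimum percent contrast that
    still elicits optokinetic tracking (e.g. 25% threshold -> sensitivity 4)."""
    if not 0 < min_percent_contrast <= 100:
        raise ValueError("minimum percent contrast must lie in (0, 100]")
    return 100.0 / min_percent_contrast


def _sem(x: np.ndarray) -> float:
    return float(sps.sem(x)) if x.size > 1 else float("nan")


def cohort_report(
    phenotypes: pd.DataFrame,
    group_column: str = "group",
    groups: Sequence[str] | None = None,
    bonferroni: bool = False,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group phenotype summary plus pairwise comparisons.

    ``phenotypes`` needs a group column, a boolean ``irregular`` column, and
    any of the numeric columns ``cct_um``, ``acd_um``, ``r_c_mm``.  Returns
    ``(summary, pairwise)``: prevalence of the irregular flag and mean +/-
    SEM per group, and two-sided t-test p-values for every group pair and
    numeric measure (Bonferroni-scaled when requested).
    """
    if groups is None:
        groups = list(dict.fromkeys(phenotypes[group_column]))
    unknown = set(phenotypes[group_column]) - set(groups)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    numeric = [c for c in ("cct_um", "acd_um", "r_c_mm") if c in phenotypes.columns]

    rows = []
    for g in groups:
        sub = phenotypes[phenotypes[group_column] == g]
        row: dict[str, object] = {"group": g, "n": len(sub)}
        if "irregular" in sub.columns:
            row["irregular_prevalence"] = float(np.mean(sub["irregular"].astype(bool)))
        for c in numeric:
            x = sub[c].dropna().to_numpy(dtype=float)
            row[f"{c}_mean"] = float(x.mean()) if x.size else float("nan")
            row[f"{c}_sem"] = _sem(x)
        rows.append(row)
    summary = pd.DataFrame(rows)

    pairs = []
    n_tests = max(1, len(numeric) * (len(groups) * (len(groups) - 1)) // 2)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            for c in numeric:
                xa = phenotypes.loc[phenotypes[group_column] == ga, c].dropna()
                xb = phenotypes.loc[phenotypes[group_column] == gb, c].dropna()
                if len(xa) < 2 or len(xb) < 2:
                    continue
                res = group_compare(xa, xb, welch=welch)
                p = min(1.0, res.p * n_tests) if bonferroni else res.p
                pairs.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "measure": c,
                        "t": res.t,
                        "df": res.df,
                        "p": p,
                        "significant": p <= ALPHA,
                        "bonferroni": bonferroni,
                    }
                )
    return summary, pd.DataFrame(pairs)
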