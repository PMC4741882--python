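"""Group comparisons of locus expression across clinical strata.

Two-sample t-tests (Welch by default) compare scaled relative expression
between tumor and normal tissue, MSI and MSS tumors, and lymph-node
negative versus positive tumors, with the conventional star coding
(* p < 0.05, ** p < 0.01, *** p < 0.001).  A per-sample combined HERV-H
value summarizes all target systems into one number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p_value: float) -> str:
    """Significance stars: strict thresholds at 0.05 / 0.01 / 0.001."""
    for cutoff, mark in STAR_LEVELS:
        if p_value < cutoff:
            return mark
    return "ns"


def welch_t_test(x, y, pooled: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    Welch's unequal-variance form with Satterthwaite degrees of freedom by
    default; ``pooled=True`` gives the classical Student form.  Both groups
    need at least two finite observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"need n >= 2 per group (got {len(x)}, {len(y)})")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in t-test input")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        return 0.0, 1.0
    return t, p


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group expression comparison."""

    system: str
    factor: str
    groups: tuple[str, str]
    n_per_group: tuple[int, int]
    statistic: float
    p_value: float
    stars: str


_FACTORS = ("tissue", "msi", "n_status")


def _factor_groups(annotations: pd.DataFrame, factor: str,
                   dichotomize_n: bool) -> tuple[tuple[str, pd.Index], ...]:
    """Sample index per group level for a clinical factor."""
    if factor == "tissue":
        t = annotations["tissue_class"]
        return (("tumor", annotations.index[t == "tumor"]),
                ("normal", annotations.index[t == "normal"]))
    tumors = annotations[annotations["tissue_class"] == "tumor"]
    if factor == "msi":
        m = tumors["msi_status"]
        return (("MSI", tumors.index[m == "MSI"]),
                ("MSS", tumors.index[m == "MSS"]))
    if factor == "n_status":
        n = tumors["n_status"]
        if dichotomize_n:
            return (("N0", tumors.index[n == "N0"]),
                    ("N1+N2", tumors.index[n.isin(["N1", "N2"])]))
        return tuple((lvl, tumors.index[n == lvl]) for lvl in ("N0", "N1", "N2"))
    raise ValueError(f"unknown factor {factor!r}; expected one of {_FACTORS}")


def compare_groups(scaled: pd.DataFrame, annotations: pd.DataFrame,
                   factor: str, systems: Sequence[str] | None = None,
                   transform: str | None = None, pooled: bool = False,
                   dichotomize_n: bool = True) -> list[GroupComparison]:
    """Per-system two-group t-tests for one clinical factor.

    ``factor`` is ``tissue`` (tumor vs normal), ``msi`` (MSI vs MSS tumors)
    or ``n_status`` (N0 vs N1+N2 tumors by default).  ``transform='log2'``
    applies log2(RE + 1) before testing, appropriate for the strongly
    right-skewed scale of relative expression.  Systems with a missing or
    underpopulated group level are skipped with a log entry.
    """
    if transform not in (None, "log2"):
        raise ValueError(f"unknown transform {transform!r}")
    ann = annotations.loc[scaled.index]
    pairs = _factor_groups(ann, factor, dichotomize_n)
    if len(pairs) != 2:
        raise ValueError("compare_groups requires exactly two group levels; "
                         "use dichotomize_n=True for n_status")
    (name_a, idx_a), (name_b, idx_b) = pairs
    out: list[GroupComparison] = []
    for system in (systems or scaled.columns):
        a = scaled.loc[idx_a, system].dropna().to_numpy(float)
        b = scaled.loc[idx_b, system].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("skipping %s/%s: group sizes %d vs %d",
                           system, factor, len(a), len(b))
            continue
        if transform == "log2":
            a, b = np.log2(a + 1.0), np.log2(b + 1.0)
        t, p = welch_t_test(a, b, pooled=pooled)
        out.append(GroupComparison(
            system=system, factor=factor, groups=(name_a, name_b),
            n_per_group=(len(a), len(b)), statistic=t, p_value=p,
            stars=stars(p)))
    return out


COMBINATION_RULES: dict[str, Callable] = {
    "max": lambda df: df.max(axis=1),
    "mean": lambda df: df.mean(axis=1),
    "sum": lambda df: df.sum(axis=1),
}


def combined_herv_value(scaled: pd.DataFrame, target_systems: Sequence[str],
                        rule: str = "max") -> pd.Series:
    """One combined HERV-H expression value per sample.

    Collapses the target systems into a single series by the chosen rule
    (``max`` by default: a sample is as HERV-H-high as its most expressed
    locus).  The rule used is recorded in ``result.attrs['rule']``.
    """
    if not list(target_systems):
        raise ValueError("empty target system list")
    if rule not in COMBINATION_RULES:
        raise ValueError(f"unknown combination rule {rule!r}; "
                         f"choose from {sorted(COMBINATION_RULES)}")
    combined = COMBINATION_RULES[rule](scaled[list(target_systems)])
    combined.name = f"HERV-H_{rule}"
    combined.attrs["rule"] = rule
    combined.attrs["systems"] = list(target_systems)
    return combined


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate GroupComparison results for reporting."""
    return pd.DataFrame([{
        "system": c.system, "factor": c.factor,
        "group_a": c.groups[0], "group_b": c.groups[1],
        "n_a": c.n_per_group[0], "n_b": c.n_per_group[1],
        "t": c.statistic, "p_value": c.p_value, "stars": c.stars,
    } for c in comparisons])
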