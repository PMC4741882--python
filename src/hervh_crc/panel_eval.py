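"""Diagnostic panel evaluation for binary expression calls.

A panel is a set of assay systems combined by the OR rule: a sample is
panel-positive when at least one member is called positive.  Performance is
an apparent (in-sample) confusion matrix of panel calls against tissue
class, with Wilson 95% confidence intervals on sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class PanelDefinition:
    """A named marker panel combined by the any-positive (OR) rule."""

    name: str
    members: tuple[str, ...]
    rule: str = "any_positive"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a panel needs at least one member")
        if self.rule != "any_positive":
            raise ValueError(f"unsupported combination rule {self.rule!r}")


@dataclass(frozen=True)
class PanelPerformance:
    panel: PanelDefinition
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sensitivity_ci95: tuple[float, float]
    specificity_ci95: tuple[float, float]


def evaluate_panel(calls: pd.DataFrame, annotations: pd.DataFrame,
                   panel: PanelDefinition, case_class: str = "tumor",
                   control_class: str = "normal") -> PanelPerformance:
    """Confusion matrix of OR-rule panel calls against tissue class.

    Cases are samples of ``case_class`` (sensitivity denominator), controls
    of ``control_class`` (specificity denominator); other tissue classes
    are ignored.  Wilson score intervals are used for both proportions.
    """
    unknown = [m for m in panel.members if m not in calls.columns]
    if unknown:
        raise KeyError(f"panel members absent from call matrix: {unknown}")
    tissue = annotations.loc[calls.index, "tissue_class"]
    cases = calls.loc[tissue == case_class]
    controls = calls.loc[tissue == control_class]
    if cases.empty or controls.empty:
        raise ValueError(
            f"empty class: {case_class}={len(cases)}, "
            f"{control_class}={len(controls)}")
    pos_cases = cases[list(panel.members)].any(axis=1)
    pos_controls = controls[list(panel.members)].any(axis=1)
    tp = int(pos_cases.sum())
    fn = int(len(cases) - tp)
    fp = int(pos_controls.sum())
    tn = int(len(controls) - fp)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=0.05, method="wilson")
    return PanelPerformance(
        panel=panel, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        sensitivity_ci95=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci95=(float(spec_ci[0]), float(spec_ci[1])))


def select_top_expressed(calls: pd.DataFrame, annotations: pd.DataFrame,
                         k: int, class_label: str = "tumor",
                         roles: Mapping[str, str] | None = None,
                         scaled: pd.DataFrame | None = None,
                         name: str | None = None) -> PanelDefinition:
    """Panel of the ``k`` most frequently positive target systems.

    Frequency is measured among ``class_label`` samples.  Ties are broken
    by higher mean scaled expression in that class (when ``scaled`` is
    given), then lexicographic system name; the ordering used is recorded
    in the panel name.  ``roles`` restricts candidates to ``target``
    systems; without it every column is a candidate.
    """
    candidates = [s for s in calls.columns
                  if roles is None or roles.get(s) == "target"]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidate systems")
    tissue = annotations.loc[calls.index, "tissue_class"]
    sub = calls.loc[tissue == class_label, candidates]
    freq = sub.mean(axis=0)
    if scaled is not None:
        mean_re = scaled.loc[tissue == class_label, candidates].mean(axis=0)
    else:
        mean_re = pd.Series(0.0, index=candidates)
    ranked = sorted(candidates,
                    key=lambda s: (-freq[s], -mean_re[s], s))
    members = tuple(ranked[:k])
    return PanelDefinition(name=name or f"top{k}_{class_label}",
                           members=members)


def performance_to_frame(perfs: Sequence[PanelPerformance]) -> pd.DataFrame:
    """Tabulate panel performances for reporting."""
    return pd.DataFrame([{
        "panel": p.panel.name, "members": "+".join(p.panel.members),
        "rule": p.panel.rule, "tp": p.tp, "fp": p.fp, "tn": p.tn, "fn": p.fn,
        "sensitivity": p.sensitivity, "specificity": p.specificity,
        "sens_ci_low": p.sensitivity_ci95[0],
        "sens_ci_high": p.sensitivity_ci95[1],
        "spec_ci_low": p.specificity_ci95[0],
        "spec_ci_high": p.specificity_ci95[1],
    } for p in perfs])
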