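"""Data-driven positivity calling for relative-expression tables.

A sample is called positive for an assay system when its scaled relative
expression strictly exceeds the system's threshold, defined as the mean
expression over normal-tissue samples plus three standard deviations.  The
rule is set per system from normal colon tissue only, so its false-positive
rate on normals is fixed by construction (about the Gaussian three-sigma
tail when normal expression is roughly Gaussian).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Added to zero-variance thresholds so samples sitting exactly at the
#: shared floor value are never called positive.
ZERO_VARIANCE_EPS = 1e-9


def compute_thresholds(scaled: pd.DataFrame, annotations: pd.DataFrame,
                       normal_class: str = "normal", n_sd: float = 3.0,
                       ddof: int = 1) -> pd.DataFrame:
    """Per-system positivity thresholds: mean + ``n_sd`` * SD over normals.

    Uses the sample standard deviation (``ddof=1``) by default.  Systems
    whose normal samples all share one value (e.g. everything censored at
    the floor) get a tiny epsilon added so floor-valued samples stay
    negative.  Raises ``ValueError`` when a system has fewer than two
    normal-tissue measurements.
    """
    normals = scaled.loc[
        annotations.loc[scaled.index, "tissue_class"] == normal_class]
    out = {}
    for system in scaled.columns:
        values = normals[system].dropna()
        if len(values) < 2:
            raise ValueError(
                f"system {system!r}: {len(values)} normal-tissue samples "
                f"(need >= 2) to set a positivity threshold")
        mean = float(values.mean())
        sd = float(values.std(ddof=ddof))
        threshold = mean + n_sd * sd
        if sd == 0.0:
            threshold += ZERO_VARIANCE_EPS
            logger.info("system %s: zero variance among normals, threshold "
                        "nudged by %g", system, ZERO_VARIANCE_EPS)
        out[system] = {"n_normals": len(values), "mean_normal": mean,
                       "sd_normal": sd, "threshold": threshold}
    table = pd.DataFrame(out).T
    table["n_normals"] = table["n_normals"].astype(int)
    table.index.name = "system"
    return table


def call_positivity(scaled: pd.DataFrame, thresholds: pd.DataFrame
                    ) -> pd.DataFrame:
    """Boolean call matrix: scaled RE strictly greater than the threshold.

    The threshold table used is attached as ``result.attrs['thresholds']``.
    Raises ``KeyError`` for systems without a threshold.
    """
    missing = [s for s in scaled.columns if s not in thresholds.index]
    if missing:
        raise KeyError(f"no thresholds for systems: {missing}")
    calls = scaled.gt(thresholds["threshold"].reindex(scaled.columns), axis=1)
    calls.attrs["thresholds"] = thresholds
    return calls


@dataclass
class FrequencyReport:
    """Expression-frequency summary of a call matrix."""

    #: (tissue_class, system) -> n_positive, n_total, fraction
    per_class_system: pd.DataFrame
    #: number of positive *target* loci per sample
    per_sample_locus_count: pd.Series
    #: histogram of per-sample target-locus counts: keys "0", "1", "2-5", "6+"
    locus_count_histogram: dict = field(default_factory=dict)


def summarize_frequencies(calls: pd.DataFrame, annotations: pd.DataFrame,
                          roles: Mapping[str, str]) -> FrequencyReport:
    """Positivity counts per tissue class and system, plus per-sample load.

    ``roles`` maps each system to its study role; only ``target`` systems
    enter the per-sample locus counts and the 0 / 1 / 2-5 histogram
    (controls and tumor markers are still reported in the per-class table).
    Empty strata are reported as 0 of 0.
    """
    tissue = annotations.loc[calls.index, "tissue_class"]
    records = []
    for cls in tissue.unique():
        sub = calls.loc[tissue == cls]
        for system in calls.columns:
            n_pos = int(sub[system].sum())
            n_tot = int(len(sub))
            records.append((cls, system, roles.get(system, "target"),
                            n_pos, n_tot,
                            n_pos / n_tot if n_tot else 0.0))
    per_class = pd.DataFrame(
        records, columns=["tissue_class", "system", "role",
                          "n_positive", "n_total", "fraction"])

    targets = [s for s in calls.columns if roles.get(s) == "target"]
    counts = calls[targets].sum(axis=1).astype(int)
    hist = {"0": int((counts == 0).sum()),
            "1": int((counts == 1).sum()),
            "2-5": int(((counts >= 2) & (counts <= 5)).sum()),
            "6+": int((counts > 5).sum())}
    return FrequencyReport(per_class_system=per_class,
                           per_sample_locus_count=counts,
                           locus_count_histogram=hist)
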