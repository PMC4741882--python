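"""Relative quantification of locus-specific qRT-PCR data.

Implements the analysis chain used for SYBR-green locus-specific assays:

1. Ct calling by the second-derivative-maximum (SDM) of the amplification
   curve, obtained from a four-parameter logistic model fitted to all 45
   cycles.
2. Per-system amplification efficiency (``Eff``) estimated from the
   log-linear exponential phase of each reaction.
3. Cohort-specific Ct ceilings: Ct values above a per-cohort cutoff are
   clamped to the cutoff and flagged as censored, so that extremely low
   expression is never over-interpreted.
4. Relative expression ``RE = Eff ** (Ct_min_series - Ct_sample)``, so the
   sample with the lowest Ct in a series has RE = 1 and all others fall
   below it by a factor of Eff per cycle.
5. Normalization by the geometric mean of three housekeeping assays.
6. Rescaling so the lowest positive normalized value in the series is
   exactly 1 ("scale to minimum").

All batch operations work on pandas objects: a Ct table is a DataFrame with
samples as rows and assay systems as columns; the annotation table is a
DataFrame indexed by sample id with at least a ``cohort`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats

logger = logging.getLogger(__name__)

#: Offset between the logistic midpoint and its second-derivative maximum:
#: for F(c) = B + A / (1 + exp(-(c - m)/s)) the second derivative peaks at
#: c = m - s * ln(2 + sqrt(3)) (root of the third derivative).
SDM_OFFSET = float(np.log(2.0 + np.sqrt(3.0)))

#: Default per-cycle amplification factor assumed when a reaction's
#: efficiency cannot be estimated (perfect doubling).
DEFAULT_EFFICIENCY = 2.0

#: Hard sanity bounds on a per-cycle amplification factor.
EFF_MIN, EFF_MAX = 1.0, 2.2


@dataclass(frozen=True)
class CtRecord:
    """A single crossing-cycle measurement for one reaction."""

    sample: str
    system: str
    ct: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.ct <= 45.0):
            raise ValueError(f"Ct {self.ct} outside (0, 45] for "
                             f"{self.sample}/{self.system}")


def _logistic(c: np.ndarray, baseline: float, amplitude: float,
              midpoint: float, slope: float) -> np.ndarray:
    return baseline + amplitude / (1.0 + np.exp(-(c - midpoint) / slope))


def _as_curve(curve, cycles) -> tuple[np.ndarray, np.ndarray]:
    """Accept an AmplificationCurve-like object or a raw fluorescence array."""
    if hasattr(curve, "fluorescence"):
        f = np.asarray(curve.fluorescence, dtype=float)
        c = np.asarray(curve.cycles, dtype=float)
    else:
        f = np.asarray(curve, dtype=float)
        c = (np.arange(1, len(f) + 1, dtype=float) if cycles is None
             else np.asarray(cycles, dtype=float))
    if len(f) != len(c):
        raise ValueError("cycles and fluorescence differ in length")
    if len(f) < 10:
        raise ValueError(f"amplification series too short ({len(f)} points)")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite fluorescence values")
    return c, f


def fit_logistic(curve, cycles=None):
    """Fit the four-parameter logistic model to an amplification curve.

    Returns ``(baseline, amplitude, midpoint, slope)`` or ``None`` when the
    optimizer fails or converges to a non-amplifying shape.
    """
    c, f = _as_curve(curve, cycles)
    b0 = float(np.min(f))
    a0 = float(np.max(f) - b0)
    half = b0 + 0.5 * a0
    m0 = float(c[np.argmin(np.abs(f - half))])
    try:
        popt, _ = curve_fit(_logistic, c, f, p0=[b0, a0, m0, 1.5],
                            maxfev=10_000)
    except RuntimeError:
        return None
    baseline, amplitude, midpoint, slope = (float(x) for x in popt)
    if amplitude <= 0 or slope <= 0:
        return None
    return baseline, amplitude, midpoint, slope


def sdm_ct(curve, cycles=None, min_amplitude: float = 0.05) -> float:
    """Crossing cycle at the second-derivative maximum of the curve.

    The curve is modelled as a four-parameter logistic; the SDM position is
    then analytic: ``midpoint - slope * ln(2 + sqrt(3))``.  Curves whose
    dynamic range stays below ``min_amplitude`` (fluorescence units), or for
    which no rising sigmoid can be fitted inside the cycle window, carry no
    amplification signal and return ``nan`` (the censored marker).
    """
    c, f = _as_curve(curve, cycles)
    if float(np.max(f) - np.min(f)) < min_amplitude:
        return float("nan")
    fit = fit_logistic(f, c)
    if fit is None:
        return float("nan")
    _, amplitude, midpoint, slope = fit
    if amplitude < min_amplitude:
        return float("nan")
    ct = midpoint - slope * SDM_OFFSET
    if not (c[0] <= ct <= c[-1]):
        return float("nan")
    return float(ct)


def estimate_efficiency(curve, cycles=None, default: float = DEFAULT_EFFICIENCY,
                        signal_window: tuple[float, float] = (0.01, 0.15),
                        min_points: int = 3) -> float:
    """Per-cycle amplification factor from the exponential phase.

    Baseline-subtracted fluorescence is regressed on cycle number in log
    space over the cycles where the signal lies between 1% and 15% of the
    curve amplitude (the log-linear window before plateau curvature).
    Because even that window is not perfectly exponential, the raw slope is
    divided by ``1 - mean(signal fraction)``, the first-order logistic
    curvature correction, before exponentiating.

    Falls back to ``default`` (with a logged warning) when the curve is
    censored or the window holds fewer than ``min_points`` cycles.
    """
    c, f = _as_curve(curve, cycles)
    ct = sdm_ct(f, c)
    if not np.isfinite(ct):
        logger.warning("efficiency fallback to %.2f: no amplification signal",
                       default)
        return float(default)
    baseline = float(np.mean(f[:5]))
    amplitude = float(np.max(f)) - baseline
    if amplitude <= 0:
        logger.warning("efficiency fallback to %.2f: non-positive amplitude",
                       default)
        return float(default)
    frac = (f - baseline) / amplitude
    lo, hi = signal_window
    mask = (c <= ct + 1.0) & (frac > lo) & (frac < hi)
    if int(mask.sum()) < min_points:
        logger.warning("efficiency fallback to %.2f: %d exponential-phase "
                       "points (< %d)", default, int(mask.sum()), min_points)
        return float(default)
    slope = float(np.polyfit(c[mask], np.log(f[mask] - baseline), 1)[0])
    slope /= 1.0 - float(np.mean(frac[mask]))
    eff = float(np.exp(slope))
    if not (EFF_MIN < eff <= EFF_MAX):
        logger.warning("efficiency fallback to %.2f: estimate %.3f outside "
                       "(%.1f, %.1f]", default, eff, EFF_MIN, EFF_MAX)
        return float(default)
    return eff


def system_efficiencies(curves: Iterable, default: float = DEFAULT_EFFICIENCY
                        ) -> pd.Series:
    """Median per-system efficiency over an iterable of amplification curves.

    ``curves`` yields objects with ``system``, ``cycles`` and
    ``fluorescence`` attributes.  Systems without a single estimable
    reaction get the default efficiency.
    """
    per_system: dict[str, list[float]] = {}
    for curve in curves:
        eff = estimate_efficiency(curve)
        per_system.setdefault(curve.system, []).append(eff)
    if not per_system:
        raise ValueError("no curves supplied")
    return pd.Series({sys: float(np.median(v)) for sys, v in per_system.items()},
                     name="efficiency")


def apply_ct_ceiling(ct_table: pd.DataFrame, annotations: pd.DataFrame,
                     ceilings: Mapping[str, float]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clamp Ct values above the per-cohort ceiling.

    Values strictly greater than the ceiling of the sample's cohort are set
    to the ceiling and flagged censored; a value exactly equal to the
    ceiling is kept uncensored.  Returns ``(clamped table, censored mask)``.
    Raises ``KeyError`` for a cohort without a ceiling.
    """
    cohorts = annotations.loc[ct_table.index, "cohort"]
    missing = set(cohorts.unique()) - set(ceilings)
    if missing:
        raise KeyError(f"no Ct ceiling configured for cohort(s): "
                       f"{sorted(missing)}")
    ceil = cohorts.map(ceilings).astype(float)
    clamped = ct_table.clip(upper=ceil, axis=0)
    censored = ct_table.gt(ceil, axis=0)
    return clamped, censored


def relative_expression(ct_table: pd.DataFrame,
                        efficiencies: Mapping[str, float] | pd.Series | float
                        ) -> pd.DataFrame:
    """RE = Eff ** (Ct_min_series - Ct_sample), column-wise.

    ``Ct_min_series`` is the minimum Ct of each system over the analyzed
    series (the full table), so the most strongly expressed sample of each
    system has RE = 1 and lower expression decays by Eff per cycle.  The
    per-system series minima are stored in ``result.attrs['series_min_ct']``.
    """
    if ct_table.empty:
        raise ValueError("empty Ct table")
    if np.isscalar(efficiencies):
        eff = pd.Series(float(efficiencies), index=ct_table.columns)
    else:
        eff = pd.Series(efficiencies).reindex(ct_table.columns)
        if eff.isna().any():
            raise KeyError(f"efficiency missing for systems: "
                           f"{list(eff.index[eff.isna()])}")
    if not ((eff > EFF_MIN) & (eff <= EFF_MAX)).all():
        raise ValueError("efficiencies must lie in (1, 2.2]")
    min_ct = ct_table.min(axis=0)
    re = pd.DataFrame(
        np.power(eff.to_numpy()[None, :],
                 (min_ct - ct_table).to_numpy()),
        index=ct_table.index, columns=ct_table.columns)
    re.attrs["series_min_ct"] = min_ct
    return re


def geometric_mean(values: np.ndarray | pd.DataFrame, axis=None):
    """Geometric mean of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(arr), axis=axis))


def normalize_housekeeping(re_table: pd.DataFrame,
                           housekeeping: Sequence[str],
                           censored: pd.DataFrame | None = None
                           ) -> pd.DataFrame:
    """Divide each sample's REs by the geometric mean of its housekeeping REs.

    Samples with a censored or non-positive housekeeping measurement are
    excluded (dropped from the output) with a log entry; the dropped sample
    ids are recorded in ``result.attrs['excluded_samples']``.  Housekeeping
    columns are removed from the normalized layer.
    """
    missing = [h for h in housekeeping if h not in re_table.columns]
    if missing:
        raise KeyError(f"housekeeping systems absent from table: {missing}")
    hk = re_table[list(housekeeping)]
    bad = (hk <= 0).any(axis=1)
    if censored is not None:
        bad |= censored[list(housekeeping)].any(axis=1)
    excluded = list(re_table.index[bad])
    if excluded:
        logger.warning("excluding %d sample(s) with invalid housekeeping "
                       "measurements: %s", len(excluded), excluded)
    kept = re_table.loc[~bad]
    factors = np.exp(np.log(kept[list(housekeeping)]).mean(axis=1))
    targets = [c for c in re_table.columns if c not in set(housekeeping)]
    norm = kept[targets].div(factors, axis=0)
    norm.attrs["excluded_samples"] = excluded
    norm.attrs["normalizer"] = list(housekeeping)
    return norm


def scale_to_min(norm_table: pd.DataFrame) -> pd.DataFrame:
    """Rescale a series so its lowest positive value is exactly 1.

    Every value is divided by the minimum positive value of the whole
    batch.  Idempotent once the minimum is 1.  Raises on an all-zero batch.
    """
    values = norm_table.to_numpy(dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("cannot scale an all-zero series")
    scaled = norm_table / float(positive.min())
    scaled.attrs["scale_factor"] = float(positive.min())
    return scaled


@dataclass
class ExpressionTable:
    """All layers of the relative-quantification pipeline for one batch."""

    ct: pd.DataFrame
    censored: pd.DataFrame
    re: pd.DataFrame
    norm_re: pd.DataFrame
    scaled_re: pd.DataFrame
    series_min_ct: pd.Series
    efficiencies: pd.Series
    excluded_samples: list = field(default_factory=list)

    @property
    def layers(self) -> dict[str, pd.DataFrame]:
        return {"ct": self.ct, "re": self.re,
                "norm_re": self.norm_re, "scaled_re": self.scaled_re}


def quantify(ct_table: pd.DataFrame, annotations: pd.DataFrame,
             ceilings: Mapping[str, float],
             housekeeping: Sequence[str],
             efficiencies: Mapping[str, float] | pd.Series | float = DEFAULT_EFFICIENCY
             ) -> ExpressionTable:
    """Run the full relative-quantification pipeline on a Ct table.

    Ceiling clamping -> RE -> housekeeping normalization -> scale-to-min,
    keeping every intermediate layer.  ``efficiencies`` may be a single
    factor (applied to all systems) or a per-system mapping.
    """
    ct, censored = apply_ct_ceiling(ct_table, annotations, ceilings)
    re = relative_expression(ct, efficiencies)
    norm = normalize_housekeeping(re, housekeeping, censored=censored)
    scaled = scale_to_min(norm)
    eff = (pd.Series(float(efficiencies), index=ct.columns)
           if np.isscalar(efficiencies) else pd.Series(efficiencies))
    return ExpressionTable(
        ct=ct, censored=censored, re=re, norm_re=norm, scaled_re=scaled,
        series_min_ct=re.attrs["series_min_ct"], efficiencies=eff,
        excluded_samples=norm.attrs.get("excluded_samples", []))
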