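"""Overlap of 5' LTR intervals with chromatin-mark peak sets.

For each histone mark, the fraction of each LTR covered by the union of
that mark's peaks is computed per cell line and averaged across cell
lines.  Activating-mark coverage is then compared between locus categories
(tumor-specific versus silent/constitutive) by rank-sum test.  Coordinates
follow the BED convention: 0-based, half-open, strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_age import rank_sum_test

logger = logging.getLogger(__name__)

#: The twelve histone modifications scored.
HISTONE_MARKS = ("H2az", "H3k4me1", "H3k4me2", "H3k4me3", "H3k9ac",
                 "H3k27ac", "H3k79me2", "H3k9me3", "H3k27me3", "H3k9me1",
                 "H3k36me3", "H4k20me1")

#: Conventional partition into transcription-associated and
#: silencing-associated marks; configurable in every consumer.
ACTIVATING_MARKS = ("H2az", "H3k4me1", "H3k4me2", "H3k4me3",
                    "H3k9ac", "H3k27ac")
REPRESSIVE_MARKS = ("H3k9me3", "H3k27me3")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _merge(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping intervals into a disjoint union."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def interval_overlap(query: GenomicInterval,
                     peaks: Sequence[GenomicInterval]) -> tuple[int, bool]:
    """Bases of ``query`` covered by the union of ``peaks``.

    Peaks on other chromosomes are ignored; overlapping peaks are merged
    first so shared bases are never double counted.  Returns
    ``(covered bases, covered bases > 0)``.
    """
    same = [(p.start, p.end) for p in peaks if p.chrom == query.chrom]
    bases = 0
    for start, end in _merge(same):
        bases += max(0, min(end, query.end) - max(start, query.start))
    return bases, bases > 0


def mean_mark_overlap(ltr_intervals: Sequence[GenomicInterval],
                      peak_sets: Mapping[tuple[str, str],
                                         Sequence[GenomicInterval]]
                      ) -> pd.DataFrame:
    """Mean per-mark LTR coverage fraction across cell lines.

    ``peak_sets`` maps ``(mark, cell_line)`` to that experiment's peaks.
    The score of an LTR for one experiment is covered bases divided by LTR
    length (in [0, 1]); the mark score is the arithmetic mean over the
    cell lines with data for that mark.  Marks without any cell line are
    dropped with a warning.  Per-cell-line layers are kept in
    ``result.attrs['per_cell_line']``.
    """
    loci = [q.name for q in ltr_intervals]
    marks = sorted({mark for mark, _ in peak_sets})
    per_cell: dict[str, pd.DataFrame] = {}
    mean_cols = {}
    for mark in marks:
        cells = sorted(c for m, c in peak_sets if m == mark)
        if not cells:
            logger.warning("mark %s: no cell-line data, dropped", mark)
            continue
        layer = pd.DataFrame(index=loci, columns=cells, dtype=float)
        for cell in cells:
            peaks = peak_sets[(mark, cell)]
            for q in ltr_intervals:
                bases, _ = interval_overlap(q, peaks)
                layer.loc[q.name, cell] = bases / len(q)
        per_cell[mark] = layer
        mean_cols[mark] = layer.mean(axis=1)
    if not mean_cols:
        raise ValueError("no peak data for any mark")
    matrix = pd.DataFrame(mean_cols, index=loci)
    matrix.attrs["per_cell_line"] = per_cell
    return matrix


@dataclass(frozen=True)
class EnrichmentComparison:
    """Rank-sum comparison of a mark-class score between locus groups."""

    mark_class: str
    marks: tuple[str, ...]
    groups: tuple[str, str]
    n_per_group: tuple[int, int]
    median_scores: tuple[float, float]
    u_statistic: float
    p_value: float


def mark_class_enrichment(matrix: pd.DataFrame,
                          categories: Mapping[str, str],
                          case_category: str = "crc_specific",
                          control_categories: Sequence[str] = (
                              "silent", "constitutive"),
                          activating: Sequence[str] = ACTIVATING_MARKS,
                          repressive: Sequence[str] = REPRESSIVE_MARKS
                          ) -> list[EnrichmentComparison]:
    """Compare activating- and repressive-mark scores between categories.

    Per locus, the class score is the mean coverage over the class's marks
    present in ``matrix``.  Case loci (``case_category``) are compared to
    the union of ``control_categories`` with the two-sided rank-sum test.
    Raises when either group is empty.
    """
    cat = pd.Series({locus: categories.get(str(locus))
                     for locus in matrix.index})
    case_idx = matrix.index[cat == case_category]
    ctrl_idx = matrix.index[cat.isin(control_categories)]
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise ValueError(
            f"empty group: {case_category}={len(case_idx)}, "
            f"{'+'.join(control_categories)}={len(ctrl_idx)}")
    out = []
    for label, marks in (("activating", tuple(activating)),
                         ("repressive", tuple(repressive))):
        present = [m for m in marks if m in matrix.columns]
        if not present:
            logger.warning("no %s marks present in matrix, skipped", label)
            continue
        score = matrix[present].mean(axis=1)
        a = score.loc[case_idx].to_numpy(float)
        b = score.loc[ctrl_idx].to_numpy(float)
        u, p = rank_sum_test(a, b)
        out.append(EnrichmentComparison(
            mark_class=label, marks=tuple(present),
            groups=(case_category, "+".join(control_categories)),
            n_per_group=(len(a), len(b)),
            median_scores=(float(np.median(a)), float(np.median(b))),
            u_statistic=u, p_value=p))
    return out
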