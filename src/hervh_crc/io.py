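"""Plain-text readers and writers for the pipeline's tabular formats.

Everything is TSV (tables), BED (intervals) or JSON (ground truth /
reports); all tables round-trip through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .regulome_overlap import GenomicInterval
from .synthetic_cohort import CohortConfig, SystemDef


def write_table(df: pd.DataFrame, path, index_label: str = "sample") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_ct_table(path) -> pd.DataFrame:
    """Ct table: rows = samples, columns = assay systems."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotations(path) -> pd.DataFrame:
    """Sample annotation table indexed by sample id."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_curve(curve, path) -> None:
    pd.DataFrame({"cycle": curve.cycles.astype(int),
                  "fluorescence": curve.fluorescence}
                 ).to_csv(path, sep="\t", index=False)


def read_curve(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_presence(presence: pd.DataFrame, path) -> None:
    presence.astype(int).to_csv(path, sep="\t", index_label="locus")


def read_presence(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write intervals as 6-column BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{iv.name or '.'}\t0\t{iv.strand}\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read 3-6 column BED into GenomicInterval objects."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    out = []
    for row in df.itertuples(index=False):
        out.append(GenomicInterval(
            chrom=str(row.chrom), start=int(row.start), end=int(row.end),
            name=str(getattr(row, "name", "") or ""),
            strand=str(getattr(row, "strand", ".") or ".")))
    return out


def write_ground_truth(truth, outdir) -> None:
    """Persist generator ground truth (expressed flags, probabilities)."""
    outdir = Path(outdir)
    truth.expressed.astype(int).to_csv(outdir / "truth_expressed.tsv",
                                       sep="\t", index_label="sample")
    truth.probs.to_csv(outdir / "truth_probs.tsv", sep="\t",
                       index_label="sample")
    summary = {
        "seed": truth.config.seed,
        "n_pairs_per_cohort": dict(truth.config.n_pairs_per_cohort),
        "ct_ceiling": {k: float(v)
                       for k, v in truth.config.ct_ceiling.items()},
        "expressed_ct_range": list(truth.config.expressed_ct_range),
    }
    (outdir / "truth_config.json").write_text(json.dumps(summary, indent=2))


def load_cohort_config(path) -> CohortConfig:
    """Build a CohortConfig from a YAML file.

    Recognized keys mirror the CohortConfig fields; ``positivity_probs``
    entries are written as ``system/tissue/msi/n: prob`` with ``*``
    wildcards.  Unspecified fields keep their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "systems" in raw:
        kwargs["systems"] = tuple(SystemDef(d["name"], d["role"])
                                  for d in raw.pop("systems"))
    if "positivity_probs" in raw:
        probs = {}
        for key, p in raw.pop("positivity_probs").items():
            parts = key.split("/")
            if len(parts) != 4:
                raise ValueError(
                    f"positivity key {key!r} must be system/tissue/msi/n")
            probs[tuple(parts)] = float(p)
        kwargs["positivity_probs"] = probs
    for field_name in ("n_pairs_per_cohort", "ct_ceiling", "seed",
                       "msi_prevalence", "n_status_probs"):
        if field_name in raw:
            kwargs[field_name] = raw.pop(field_name)
    for field_name in ("expressed_ct_range", "hk_ct_mean_sd"):
        if field_name in raw:
            kwargs[field_name] = tuple(raw.pop(field_name))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    config = CohortConfig(**kwargs)
    config.validate()
    return config
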