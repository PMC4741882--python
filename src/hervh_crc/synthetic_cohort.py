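"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a two-center colorectal-carcinoma qRT-PCR
study: paired tumor/adjacent-normal samples from two cohorts with distinct
Ct ceilings, five target HERV-H loci plus family-level positive/negative
controls, two conventional tumor markers and three housekeeping genes.
Per-locus tumor positivity probabilities are modulated by microsatellite
status (MSI/MSS) and lymph-node status (N0/N1/N2).  The module also
simulates logistic amplification curves, primate presence/absence matrices
with category-dependent insertion ages, and histone-mark peak files with
configurable activating-mark enrichment.

Every generator takes or derives a :class:`numpy.random.Generator`; a fixed
seed reproduces all outputs exactly.  Ground truth (which reactions are
truly expressed, which node each locus inserted at, which LTRs carry peaks)
is returned alongside the data so downstream stages can be tested without
any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr_quant import SDM_OFFSET

TISSUE_CLASSES = ("tumor", "normal", "adenoma", "metastasis")
ROLES = ("target", "herv_pos_control", "herv_neg_control",
         "tumor_marker", "housekeeping")

N_CYCLES = 45


@dataclass(frozen=True)
class SystemDef:
    """One qRT-PCR assay system and its role in the study design."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown system role {self.role!r}")


#: Default assay panel: five CRC-associated HERV-H loci (chromosomes X, 20,
#: 5, 14 and 13), the HERV-H colon positive / testis-restricted negative
#: controls, the conventional tumor markers MMP7 and OPN, and the three
#: reference genes used for geometric-mean normalization.
DEFAULT_SYSTEMS: tuple[SystemDef, ...] = (
    SystemDef("X00041_h_gag", "target"),
    SystemDef("2000045_h", "target"),
    SystemDef("500502_h", "target"),
    SystemDef("1400035_h", "target"),
    SystemDef("1300360_h_gag", "target"),
    SystemDef("1900007_h_L5U3", "herv_pos_control"),
    SystemDef("1900006_h_env", "herv_neg_control"),
    SystemDef("MMP7", "tumor_marker"),
    SystemDef("OPN", "tumor_marker"),
    SystemDef("G6PD", "housekeeping"),
    SystemDef("GAPDH", "housekeeping"),
    SystemDef("HPRT", "housekeeping"),
)


def default_positivity_probs() -> dict:
    """Stratified expression probabilities for the default assay panel.

    Keys are ``(system, tissue_class, msi, n)`` where ``msi`` and ``n`` may
    be ``'*'`` wildcards.  Target-locus tumor baselines follow the observed
    frequency ordering (0.50, 0.33, 0.27, 0.22, 0.17); MSI tumors get a
    boost at the three MSI-associated loci (chromosomes X, 20 and 14) and
    node-positive tumors at the chromosome 5 and 20 loci.  Normal colon is
    transcriptionally silent for the target loci: apparent positives in
    normal tissue arise downstream from measurement noise, not from true
    expression.
    """
    probs: dict = {}

    base = {"X00041_h_gag": 0.50, "2000045_h": 0.33, "500502_h": 0.27,
            "1400035_h": 0.22, "1300360_h_gag": 0.17}
    msi_boost = {"X00041_h_gag": 0.40, "2000045_h": 0.45, "1400035_h": 0.43}
    n_boost = {"500502_h": 0.30, "2000045_h": 0.12}

    for system, p in base.items():
        probs[(system, "tumor", "*", "*")] = p
        probs[(system, "normal", "*", "*")] = 0.0
        if system in msi_boost:
            probs[(system, "tumor", "MSI", "*")] = min(p + msi_boost[system], 0.95)
        if system in n_boost:
            for n in ("N1", "N2"):
                probs[(system, "tumor", "*", n)] = min(p + n_boost[system], 0.95)

    # family-level controls: positive control marks colonic origin in both
    # tissue classes; negative control is essentially absent in colon
    probs[("1900007_h_L5U3", "tumor", "*", "*")] = 0.65
    probs[("1900007_h_L5U3", "normal", "*", "*")] = 0.65
    probs[("1900006_h_env", "tumor", "*", "*")] = 0.005
    probs[("1900006_h_env", "normal", "*", "*")] = 0.005

    # conventional tumor markers
    probs[("MMP7", "tumor", "*", "*")] = 0.63
    probs[("MMP7", "normal", "*", "*")] = 0.04
    probs[("OPN", "tumor", "*", "*")] = 0.79
    probs[("OPN", "normal", "*", "*")] = 0.01
    return probs


@dataclass
class CohortConfig:
    """Study design of a synthetic two-center paired cohort.

    Parameters
    ----------
    n_pairs_per_cohort
        Tumor/normal pairs per named cohort (default 99 + 40 = 139 pairs).
    systems
        Assay panel; exactly the housekeeping systems are always expressed.
    positivity_probs
        ``(system, tissue, msi, n) -> probability`` with ``'*'`` wildcards;
        resolution order is exact, then msi-specific, then n-specific, then
        fully wildcarded, then 0.
    ct_ceiling
        Per-cohort censoring cutoff in cycles; non-expressed reactions are
        reported exactly at the ceiling.
    expressed_ct_range
        Uniform Ct range for truly expressed reactions.
    hk_ct_mean_sd
        Normal-distribution parameters for housekeeping Cts.
    msi_prevalence, n_status_probs
        Tumor stratum frequencies.
    """

    n_pairs_per_cohort: Mapping[str, int] = field(
        default_factory=lambda: {"rostock": 99, "reims": 40})
    systems: Sequence[SystemDef] = DEFAULT_SYSTEMS
    positivity_probs: Mapping = field(default_factory=default_positivity_probs)
    ct_ceiling: Mapping[str, float] = field(
        default_factory=lambda: {"rostock": 33.0, "reims": 32.0})
    expressed_ct_range: tuple[float, float] = (22.0, 30.0)
    hk_ct_mean_sd: tuple[float, float] = (20.0, 1.0)
    msi_prevalence: float = 0.22
    n_status_probs: Mapping[str, float] = field(
        default_factory=lambda: {"N0": 0.45, "N1": 0.35, "N2": 0.20})
    seed: int = 0

    def validate(self) -> None:
        for cohort, n in self.n_pairs_per_cohort.items():
            if n < 0:
                raise ValueError(f"negative cohort size for {cohort!r}")
            if cohort not in self.ct_ceiling:
                raise ValueError(f"cohort {cohort!r} has no Ct ceiling")
        for key, p in self.positivity_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"positivity probability {p} outside [0, 1] "
                                 f"for {key}")
        lo, hi = self.expressed_ct_range
        if not (0.0 < lo < hi < 45.0):
            raise ValueError("expressed_ct_range must lie within (0, 45)")
        for ceiling in self.ct_ceiling.values():
            if not (0.0 < ceiling < 45.0):
                raise ValueError("Ct ceilings must lie within (0, 45)")
        if not (0.0 <= self.msi_prevalence <= 1.0):
            raise ValueError("msi_prevalence outside [0, 1]")

    def resolve_prob(self, system: str, tissue: str, msi: str, n: str) -> float:
        """Most specific matching positivity probability (0 if none)."""
        for key in ((system, tissue, msi, n),
                    (system, tissue, msi, "*"),
                    (system, tissue, "*", n),
                    (system, tissue, "*", "*")):
            if key in self.positivity_probs:
                return float(self.positivity_probs[key])
        return 0.0


@dataclass
class GroundTruth:
    """What the generator actually did, reaction by reaction."""

    expressed: pd.DataFrame          # samples x systems booleans
    probs: pd.DataFrame              # samples x systems resolved probabilities
    config: CohortConfig


def generate_cohort(config: CohortConfig | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate Ct tables and annotations for a paired two-center cohort.

    Returns ``(ct_table, annotations, ground_truth)``.  Expressed reactions
    draw Ct uniformly from ``expressed_ct_range``; non-expressed reactions
    sit exactly at their cohort's ceiling; housekeeping genes are always
    expressed with normally distributed Cts.
    """
    config = config or CohortConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_levels = list(config.n_status_probs)
    n_p = np.array([config.n_status_probs[k] for k in n_levels], dtype=float)
    n_p = n_p / n_p.sum()

    rows = []
    for cohort in sorted(config.n_pairs_per_cohort):
        for i in range(config.n_pairs_per_cohort[cohort]):
            patient = f"{cohort}_p{i:04d}"
            msi = "MSI" if rng.random() < config.msi_prevalence else "MSS"
            n_status = str(rng.choice(n_levels, p=n_p))
            rows.append((f"{patient}_T", patient, "tumor", "colon", cohort,
                         msi, n_status))
            rows.append((f"{patient}_N", patient, "normal", "colon", cohort,
                         "unknown", "unknown"))
    annotations = pd.DataFrame(
        rows, columns=["sample", "patient", "tissue_class", "organ",
                       "cohort", "msi_status", "n_status"]).set_index("sample")

    systems = [s.name for s in config.systems]
    roles = {s.name: s.role for s in config.systems}
    is_hk = np.array([roles[s] == "housekeeping" for s in systems])
    lo, hi = config.expressed_ct_range
    hk_mean, hk_sd = config.hk_ct_mean_sd
    n_samples = len(annotations)

    # resolve every reaction's expression probability up front
    prob = np.empty((n_samples, len(systems)))
    for j, system in enumerate(systems):
        if is_hk[j]:
            prob[:, j] = 1.0
            continue
        cache: dict[tuple, float] = {}
        for i, (tissue, msi, n) in enumerate(zip(
                annotations["tissue_class"], annotations["msi_status"],
                annotations["n_status"])):
            key = (tissue, msi, n)
            if key not in cache:
                cache[key] = config.resolve_prob(system, *key)
            prob[i, j] = cache[key]

    ceiling = annotations["cohort"].map(config.ct_ceiling).to_numpy(float)
    expressed = rng.random(prob.shape) < prob
    expressed[:, is_hk] = True
    ct = np.where(expressed, rng.uniform(lo, hi, size=prob.shape),
                  ceiling[:, None])
    hk_ct = rng.normal(hk_mean, hk_sd, size=(n_samples, int(is_hk.sum())))
    ct[:, is_hk] = np.minimum(hk_ct, ceiling[:, None])

    idx = annotations.index
    truth = GroundTruth(
        expressed=pd.DataFrame(expressed, index=idx, columns=systems),
        probs=pd.DataFrame(prob, index=idx, columns=systems),
        config=config)
    ct_table = pd.DataFrame(ct, index=idx, columns=systems).round(2)
    return ct_table, annotations, truth


@dataclass
class AmplificationCurve:
    """Per-reaction fluorescence series over 45 cycles, with ground truth."""

    system: str
    sample: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.cycles) != N_CYCLES or len(self.fluorescence) != N_CYCLES:
            raise ValueError(f"amplification curves must span {N_CYCLES} cycles")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("non-finite fluorescence")


def generate_amplification_curve(system: str, sample: str, target_ct: float,
                                 efficiency: float = 2.0,
                                 noise_sd: float = 0.0,
                                 amplitude: float = 1.0,
                                 baseline: float = 0.05,
                                 rng: np.random.Generator | None = None
                                 ) -> AmplificationCurve:
    """Logistic amplification curve whose SDM falls exactly at ``target_ct``.

    The curve is ``F(c) = B + A / (1 + exp(-(c - m)/s)) + noise`` with
    ``s = 1 / ln(efficiency)`` (so the early phase grows by the requested
    factor per cycle) and the midpoint placed at
    ``m = target_ct + s * ln(2 + sqrt(3))`` so the noiseless
    second-derivative maximum sits at ``target_ct``.
    """
    if efficiency <= 1.0:
        raise ValueError(f"efficiency {efficiency} <= 1 means no amplification")
    if not (5.0 < target_ct < 40.0):
        raise ValueError(f"target_ct {target_ct} outside (5, 40)")
    slope = 1.0 / np.log(efficiency)
    midpoint = target_ct + slope * SDM_OFFSET
    cycles = np.arange(1, N_CYCLES + 1, dtype=float)
    f = baseline + amplitude / (1.0 + np.exp(-(cycles - midpoint) / slope))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        f = f + rng.normal(0.0, noise_sd, size=N_CYCLES)
    truth = {"midpoint": float(midpoint), "slope": float(slope),
             "amplitude": float(amplitude), "baseline": float(baseline),
             "target_ct": float(target_ct), "efficiency": float(efficiency)}
    return AmplificationCurve(system=system, sample=sample, cycles=cycles,
                              fluorescence=f, truth=truth)


# ---------------------------------------------------------------------------
# primate presence/absence matrices

#: Default insertion-node distributions per locus category, as probability
#: vectors over the eleven non-human species of the default panel (chimp
#: first, bushbaby last).  Tumor-specific loci are young (hominine nodes,
#: median age well under 10 My); silent and constitutively expressed loci
#: are older (great-ape to New World monkey nodes); gonad-restricted loci
#: sit in between.
DEFAULT_AGE_NODE_PROBS: dict[str, tuple[float, ...]] = {
    "crc_specific": (0.55, 0.30, 0.10, 0.05, 0, 0, 0, 0, 0, 0, 0),
    "silent": (0, 0, 0.10, 0.20, 0.20, 0.15, 0.15, 0.10, 0.05, 0.05, 0),
    "constitutive": (0, 0, 0.10, 0.20, 0.20, 0.15, 0.15, 0.10, 0.05, 0.05, 0),
    "gonads": (0, 0.20, 0.40, 0.30, 0.10, 0, 0, 0, 0, 0, 0),
}


def generate_presence_matrix(loci: Mapping[str, str],
                             species: Sequence[str],
                             node_probs: Mapping[str, Sequence[float]],
                             rng: np.random.Generator | None = None,
                             dropout: float = 0.0
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Phylogenetically consistent presence/absence of loci across primates.

    Parameters
    ----------
    loci
        ``locus -> category`` mapping.
    species
        Species ordered by divergence from human (human first).
    node_probs
        Per category, a probability vector over insertion nodes: entry *i*
        is the probability that the locus inserted just before the split
        with ``species[i]`` (i >= 1), i.e. it is present in species[1..i].
    dropout
        In noisy mode, probability that a non-human presence is lost
        (simulating orthology-check failures); default 0 (clean mode).

    Returns ``(presence matrix, true defining species per locus)``.  In
    clean mode a locus present in a species is present in every species
    that diverged more recently, and human is always present.
    """
    if rng is None:
        rng = np.random.default_rng()
    if species[0] != "human":
        raise ValueError("species list must start with 'human'")
    n = len(species)
    presence = pd.DataFrame(False, index=list(loci), columns=list(species))
    true_node = pd.Series(index=list(loci), dtype=object, name="defining_species")
    for locus, category in loci.items():
        if category not in node_probs:
            raise KeyError(f"unknown locus category {category!r}")
        p = np.asarray(node_probs[category], dtype=float)
        if len(p) != n - 1 or p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"node probabilities for {category!r} must be a "
                             f"distribution over the {n - 1} non-human species")
        node = int(rng.choice(np.arange(1, n), p=p))
        row = np.zeros(n, dtype=bool)
        row[: node + 1] = True
        if dropout > 0:
            lost = rng.random(n) < dropout
            lost[0] = False
            row &= ~lost
        presence.loc[locus] = row
        true_node[locus] = species[node]
    return presence, true_node


# ---------------------------------------------------------------------------
# histone-mark peak simulation


def generate_peaks(ltr_intervals: Sequence, marks: Sequence[str],
                   cell_lines: Sequence[str],
                   enrichment: Mapping[str, float],
                   categories: Mapping[str, str],
                   activating: Sequence[str] = ("H3k9ac", "H3k27ac"),
                   background: float = 0.05,
                   rng: np.random.Generator | None = None):
    """Simulate per-mark, per-cell-line peak sets over a set of 5' LTRs.

    ``enrichment`` maps a locus category (e.g. ``'crc_specific'``) to the
    probability that an *activating*-mark peak covers the locus's LTR in a
    given cell line; all other locus/mark combinations use ``background``.
    A covering peak spans the full LTR plus random flanks, so the
    ground-truth per-hit coverage fraction is 1.

    Returns ``(peak_sets, truth)`` where ``peak_sets`` maps
    ``(mark, cell_line)`` to a list of :class:`~hervh_crc.regulome_overlap.
    GenomicInterval` and ``truth`` is a loci x marks DataFrame of true mean
    coverage fractions across cell lines.
    """
    from .regulome_overlap import GenomicInterval

    if rng is None:
        rng = np.random.default_rng()
    for cat, p in enrichment.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"enrichment {p} outside [0, 1] for {cat!r}")
    activating = set(activating)
    peak_sets: dict[tuple[str, str], list] = {}
    hits = {mark: pd.DataFrame(0.0, index=[q.name for q in ltr_intervals],
                               columns=list(cell_lines))
            for mark in marks}
    for mark in marks:
        for cell in cell_lines:
            peaks = []
            for q in ltr_intervals:
                if q.start >= q.end:
                    raise ValueError(f"malformed interval for {q.name}")
                cat = categories.get(q.name)
                p = (float(enrichment.get(cat, background))
                     if mark in activating else background)
                if rng.random() < p:
                    pad_l = int(rng.integers(0, 200))
                    pad_r = int(rng.integers(0, 200))
                    peaks.append(GenomicInterval(
                        q.chrom, max(0, q.start - pad_l), q.end + pad_r,
                        name=f"{mark}_{cell}_{q.name}"))
                    hits[mark].loc[q.name, cell] = 1.0
            peak_sets[(mark, cell)] = peaks
    truth = pd.DataFrame({mark: hits[mark].mean(axis=1) for mark in marks})
    return peak_sets, truth
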