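"""Genomic-complexity scoring and risk classification.

The complexity score of a patient is the number of countable curated
abnormalities (deduplicated dual calls counted once, artifact-flagged
translocations excluded).  Two classification schemes are supported:

* OGM: two tiers at a cut-off of >= 10 abnormalities (non-complex NC-OGM
  vs complex C-OGM);
* CBA / CMA: the three conventional tiers, low (0-2), intermediate (3-4)
  and high (>= 5) abnormalities.

`compare_groups` produces the standard clinical comparison of the two OGM
tiers: Fisher/chi-square for categorical covariates (chi-square only when
all expected counts are >= 5), Mann-Whitney with medians and ranges for
count covariates, with per-row denominators when covariates are missing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import AbClass, AbnormalityRecord, ClinicalRecord
from .stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    expected_counts,
    fisher_exact_2x2,
    mann_whitney_u,
)


@dataclass
class RiskScheme:
    name: str
    bin_edges: list[int]  # strictly increasing cutoffs; count >= edge moves up
    labels: list[str]     # len(labels) == len(bin_edges) + 1

    def __post_init__(self):
        if sorted(set(self.bin_edges)) != list(self.bin_edges):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.labels) != len(self.bin_edges) + 1:
            raise ValueError("need one more label than edges")


OGM_SCHEME = RiskScheme("OGM", [10], ["NC_OGM", "C_OGM"])
CBA_SCHEME = RiskScheme("CBA", [3, 5], ["low", "intermediate", "high"])
CMA_SCHEME = RiskScheme("CMA", [3, 5], ["low", "intermediate", "high"])


def classify_risk(count: int, scheme: RiskScheme) -> str:
    if count < 0:
        raise ValueError("abnormality count must be non-negative")
    idx = sum(count >= edge for edge in scheme.bin_edges)
    return scheme.labels[idx]


@dataclass
class AbnormalityCounts:
    n_total: int = 0
    n_cnv: int = 0          # countable CNV gains/losses + deletions/duplications
    n_transloc: int = 0     # intra + inter translocations
    n_other: int = 0        # insertions, inversions


@dataclass
class PatientProfile:
    patient_id: str
    n_ogm: int
    n_ogm_cnv: int
    n_ogm_transloc: int
    n_ogm_other: int
    ogm_class: str
    chromothripsis: bool = False
    cba_class: Optional[str] = None
    cma_class: Optional[str] = None
    combined_high: Optional[bool] = None
    clinical: Optional[ClinicalRecord] = None


_CNV_LIKE = {AbClass.cnv_gain, AbClass.cnv_loss, AbClass.deletion, AbClass.duplication}
_TRANSLOC = {AbClass.intra_translocation, AbClass.inter_translocation}


def count_abnormalities(records: list[AbnormalityRecord]
                        ) -> dict[str, AbnormalityCounts]:
    """Per-patient tallies over countable records only: deduplicated records
    are tombstones of a surviving merged record and therefore do not count,
    nor do artifact-flagged or filtered records."""
    out: dict[str, AbnormalityCounts] = defaultdict(AbnormalityCounts)
    for rec in records:
        if not rec.countable:
            continue
        c = out[rec.patient_id]
        c.n_total += 1
        if rec.ab_class in _CNV_LIKE:
            c.n_cnv += 1
        elif rec.ab_class in _TRANSLOC:
            c.n_transloc += 1
        else:
            c.n_other += 1
    return dict(out)


def build_patient_profiles(records: list[AbnormalityRecord],
                           clinical: list[ClinicalRecord],
                           chromothripsis: Optional[dict] = None,
                           high_cutoff: int = 5) -> list[PatientProfile]:
    """Combine curated counts with the clinical table into one profile per
    clinical patient (patients with no countable record score 0).
    ``combined_high`` flags >= `high_cutoff` abnormalities by CBA and/or CMA."""
    counts = count_abnormalities(records)
    ct_by_patient: dict[str, bool] = defaultdict(bool)
    for (pid, _chrom), flag in (chromothripsis or {}).items():
        ct_by_patient[pid] |= flag
    profiles = []
    for clin in clinical:
        c = counts.get(clin.patient_id, AbnormalityCounts())
        combined = clin.n_abn_cba >= high_cutoff or (
            clin.n_abn_cma is not None and clin.n_abn_cma >= high_cutoff)
        profiles.append(PatientProfile(
            patient_id=clin.patient_id,
            n_ogm=c.n_total, n_ogm_cnv=c.n_cnv, n_ogm_transloc=c.n_transloc,
            n_ogm_other=c.n_other,
            ogm_class=classify_risk(c.n_total, OGM_SCHEME),
            chromothripsis=ct_by_patient[clin.patient_id],
            cba_class=classify_risk(clin.n_abn_cba, CBA_SCHEME),
            cma_class=(classify_risk(clin.n_abn_cma, CMA_SCHEME)
                       if clin.n_abn_cma is not None else None),
            combined_high=combined,
            clinical=clin,
        ))
    return profiles


def cross_classification(profiles: list[PatientProfile]) -> ContingencyTable2x2:
    """2x2 of OGM complexity vs highest-risk by CBA and/or CMA, with cell
    (0,0) = complex by both conventions."""
    a = b = c = d = 0
    for p in profiles:
        complex_ogm = p.ogm_class == "C_OGM"
        high_std = bool(p.combined_high)
        if complex_ogm and high_std:
            a += 1
        elif complex_ogm:
            b += 1
        elif high_std:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


# ----------------------------------------------------- group comparison

@dataclass
class ComparisonRow:
    covariate: str
    kind: str                      # "categorical" | "count"
    group_summaries: dict          # per group: n/percent or median/range
    test: str                      # "fisher" | "chi_square" | "mann_whitney"
    statistic: Optional[float]
    p_value: float
    denominators: dict             # per group: non-missing n


def compare_groups(profiles: list[PatientProfile],
                   categorical: Optional[dict] = None,
                   counts: Optional[dict] = None) -> list[ComparisonRow]:
    """Compare NC-OGM vs C-OGM patients covariate by covariate.

    ``categorical`` maps a covariate name to a profile -> bool-or-None
    accessor; ``counts`` likewise for numeric covariates.  Missing values
    are excluded per row and the denominators reported.  Fisher's exact test
    is used unless every expected count is >= 5, in which case the Pearson
    chi-square is reported.
    """
    groups = {"NC_OGM": [p for p in profiles if p.ogm_class == "NC_OGM"],
              "C_OGM": [p for p in profiles if p.ogm_class == "C_OGM"]}
    if not groups["NC_OGM"] or not groups["C_OGM"]:
        raise ValueError("both complexity groups must be non-empty")

    categorical = categorical if categorical is not None else {
        "tp53_abnormal": lambda p: p.clinical.tp53_abnormal if p.clinical else None,
        "chromothripsis": lambda p: p.chromothripsis,
        "high_complexity_cba_or_cma": lambda p: p.combined_high,
    }
    counts = counts if counts is not None else {
        "n_ogm": lambda p: p.n_ogm,
        "n_ogm_cnv": lambda p: p.n_ogm_cnv,
        "n_ogm_transloc": lambda p: p.n_ogm_transloc,
    }

    rows = []
    for name, get in categorical.items():
        vals = {g: [v for v in (get(p) for p in members) if v is not None]
                for g, members in groups.items()}
        pos = {g: sum(v) for g, v in vals.items()}
        tot = {g: len(v) for g, v in vals.items()}
        table = ContingencyTable2x2(
            pos["NC_OGM"], tot["NC_OGM"] - pos["NC_OGM"],
            pos["C_OGM"], tot["C_OGM"] - pos["C_OGM"])
        if (expected_counts(table) >= 5).all():
            stat, p = chi_square_2x2(table)
            test = "chi_square"
        else:
            res = fisher_exact_2x2(table)
            stat, p, test = None, res.p_value, "fisher"
        rows.append(ComparisonRow(
            covariate=name, kind="categorical",
            group_summaries={g: {"n": pos[g],
                                 "pct": 100.0 * pos[g] / tot[g] if tot[g] else None}
                             for g in groups},
            test=test, statistic=stat, p_value=p, denominators=tot))
    for name, get in counts.items():
        vals = {g: [v for v in (get(p) for p in members) if v is not None]
                for g, members in groups.items()}
        u, p = mann_whitney_u(vals["NC_OGM"], vals["C_OGM"])
        rows.append(ComparisonRow(
            covariate=name, kind="count",
            group_summaries={g: {"median": float(np.median(v)) if v else None,
                                 "range": ((min(v), max(v)) if v else None)}
                             for g, v in vals.items()},
            test="mann_whitney", statistic=u, p_value=p,
            denominators={g: len(v) for g, v in vals.items()}))
    return rows
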