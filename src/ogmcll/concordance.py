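"""Cross-technique concordance: build the known-aberration inventory from
karyotype (CBA), FISH and microarray (CMA) records, match curated OGM
abnormalities against it, explain the misses, and classify novel
translocation calls.

Matching is deliberately tolerant: the techniques describe the same lesion
at very different resolutions (CBA at band level, ~5-10 Mb; CMA at probe
level; OGM at label level), and telomeric masking alone can shift OGM CNV
boundaries by 2-5 Mb, so "same abnormality" allows configurable variability
in size and breakpoints.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .records import (
    AbClass,
    AbnormalityRecord,
    CnvType,
    DiscrepancyReason,
    GenomicInterval,
    KnownAberration,
    KnownClass,
    NovelCategory,
    RegionSet,
    Status,
    Technique,
)

log = logging.getLogger(__name__)


@dataclass
class MatchCriteria:
    cnv_reciprocal_overlap_min: float = 0.25
    cnv_bp_tolerance_bp: int = 5_000_000
    cba_bp_tolerance_bp: int = 10_000_000
    require_same_sign: bool = True

    def __post_init__(self):
        if self.cnv_bp_tolerance_bp < 0 or self.cba_bp_tolerance_bp < 0:
            raise ValueError("tolerances must be non-negative")
        if not 0 < self.cnv_reciprocal_overlap_min <= 1:
            raise ValueError("reciprocal overlap threshold must be in (0,1]")


@dataclass
class MatchResult:
    known_id: str
    patient_id: str
    known_class: KnownClass
    matched: bool
    ogm_ids: list[str] = field(default_factory=list)
    discrepancy_reason: Optional[DiscrepancyReason] = None
    coord_diff_bp: Optional[int] = None


@dataclass
class NovelCallClass:
    ogm_id: str
    category: NovelCategory


# --------------------------------------------------------- inventory

def build_known_inventory(cba_records: list[KnownAberration],
                          fish_records: list[KnownAberration],
                          cma_records: list[KnownAberration]
                          ) -> list[KnownAberration]:
    """Compile one inventory entry per distinct previously known abnormality.

    CMA coordinates are prioritized for CNVs: a FISH or CBA CNV entry that
    overlaps a same-sign CMA entry in the same patient describes the same
    lesion and is dropped in favour of the CMA record.  FISH/CBA-only CNVs
    are retained.  Balanced rearrangements and "add" breakpoints come from
    the karyotype.  Same-region entries with conflicting signs are both
    retained with a warning.
    """
    inventory = list(cma_records)
    cma_by_patient: dict[str, list[KnownAberration]] = defaultdict(list)
    for k in cma_records:
        cma_by_patient[k.patient_id].append(k)

    for rec in list(fish_records) + list(cba_records):
        if rec.sign is not None and rec.interval is not None:
            absorbed = False
            for cma in cma_by_patient.get(rec.patient_id, ()):
                if cma.interval is None:
                    continue
                if cma.interval.overlap_bp(rec.interval) > 0:
                    if cma.sign == rec.sign:
                        absorbed = True
                        break
                    log.warning(
                        "conflicting CNV signs for %s vs %s (patient %s); "
                        "both retained", rec.ab_id, cma.ab_id, rec.patient_id)
            if absorbed:
                continue
        inventory.append(rec)
    return inventory


# ----------------------------------------------------------- matching

_CNV_MATCH_CLASSES = {
    CnvType.gain: {AbClass.cnv_gain, AbClass.duplication},
    CnvType.loss: {AbClass.cnv_loss, AbClass.deletion},
}


def _score_cnv(known: KnownAberration, rec: AbnormalityRecord,
               crit: MatchCriteria) -> Optional[tuple[float, int]]:
    """(reciprocal overlap, max boundary diff) if the pair matches, else None."""
    fp = rec.footprint
    if fp is None or known.interval is None or fp.chrom != known.interval.chrom:
        return None
    if crit.require_same_sign and rec.ab_class not in _CNV_MATCH_CLASSES[known.sign]:
        return None
    ro = known.interval.reciprocal_overlap(fp)
    diff = max(abs(fp.start - known.interval.start),
               abs(fp.end - known.interval.end))
    if ro >= crit.cnv_reciprocal_overlap_min or diff <= crit.cnv_bp_tolerance_bp:
        return (ro, diff)
    return None


def _score_rearrangement(known: KnownAberration, rec: AbnormalityRecord,
                         crit: MatchCriteria) -> Optional[int]:
    """Max breakpoint distance if the rearrangement matches, else None.

    A translocation matches when each of its known breakpoints is hit by a
    curated breakpoint within tolerance; an "add" entry (one known
    breakpoint) needs a single hit.  Large intra-chromosomal translocation
    calls may also represent inversions, so known inversions accept them.
    """
    if not rec.is_translocation and rec.ab_class != AbClass.inversion:
        return None
    if known.ab_class == KnownClass.inversion and \
            rec.ab_class not in (AbClass.inversion, AbClass.intra_translocation):
        return None
    tol = max(crit.cba_bp_tolerance_bp, known.bp_tolerance_bp or 0)
    dists = []
    for kc, kp in known.breakpoints:
        best = None
        for rc, rp in rec.breakpoints:
            if rc == kc and abs(rp - kp) <= tol:
                best = abs(rp - kp) if best is None else min(best, abs(rp - kp))
        if best is None:
            return None
        dists.append(best)
    return max(dists) if dists else None


def match_calls(known: list[KnownAberration],
                curated: list[AbnormalityRecord],
                crit: Optional[MatchCriteria] = None) -> list[MatchResult]:
    """Match each known aberration to its best-scoring curated OGM record.

    Each known entry matches at most one curated record, but one curated
    record may confirm several known entries (the same deletion may appear
    as both a FISH and a CMA inventory entry in edge cases).  Only countable
    curated records participate.
    """
    crit = crit or MatchCriteria()
    usable = [r for r in curated if r.countable]
    by_patient: dict[str, list[AbnormalityRecord]] = defaultdict(list)
    for rec in usable:
        by_patient[rec.patient_id].append(rec)

    results = []
    for k in known:
        candidates = []
        for rec in by_patient.get(k.patient_id, ()):
            if k.sign is not None:
                score = _score_cnv(k, rec, crit)
                if score is not None:
                    ro, diff = score
                    candidates.append((-ro, diff, rec.ab_id, rec, diff))
            else:
                dist = _score_rearrangement(k, rec, crit)
                if dist is not None:
                    candidates.append((0.0, dist, rec.ab_id, rec, None))
        if candidates:
            candidates.sort(key=lambda t: t[:3])
            _, _, _, best, diff = candidates[0]
            results.append(MatchResult(k.ab_id, k.patient_id, k.ab_class,
                                       True, [best.ab_id], coord_diff_bp=diff))
        else:
            results.append(MatchResult(k.ab_id, k.patient_id, k.ab_class, False))
    return results


# --------------------------------------------- discrepancy explanation

def assign_discrepancy_reasons(
        results: list[MatchResult],
        known_by_id: dict[str, KnownAberration],
        masks: RegionSet,
        centromere_telomere: RegionSet,
        chromothripsis: Optional[dict[tuple[str, str], bool]] = None,
        proximity_bp: int = 1_000_000,
        sensitivity_floor: float = 0.20,
        small_cnv_bp: int = 150_000) -> list[MatchResult]:
    """Attach a cause to each unmatched known aberration.

    Precedence (fixed, so reports are deterministic): breakpoints near a
    centromere/telomere annotation → involvement of unmappable regions;
    mostly masked interval → masked region; clone fraction below the
    platform's reliable range → sensitivity; a small CNV on a
    chromothripsis chromosome → lost inside the shattered region; else
    unknown.
    """
    chromothripsis = chromothripsis or {}
    out = []
    for res in results:
        if res.matched:
            out.append(res)
            continue
        k = known_by_id[res.known_id]
        points = list(k.breakpoints)
        if k.interval is not None:
            points += [(k.interval.chrom, k.interval.start),
                       (k.interval.chrom, k.interval.end)]
        if any(centromere_telomere.contains_point(c, p, slop=proximity_bp)
               for c, p in points):
            reason = DiscrepancyReason.centromeric_telomeric
        elif k.interval is not None and masks.covered_fraction(k.interval) >= 0.5:
            reason = DiscrepancyReason.masked_region
        elif k.clone_fraction is not None and k.clone_fraction < sensitivity_floor:
            reason = DiscrepancyReason.sensitivity
        elif k.interval is not None and k.interval.size < small_cnv_bp and \
                chromothripsis.get((k.patient_id, k.interval.chrom), False):
            reason = DiscrepancyReason.small_within_chromothripsis
        else:
            reason = DiscrepancyReason.unknown
        res.discrepancy_reason = reason
        out.append(res)
    return out


# ------------------------------------------------------------- summary

@dataclass
class ConcordanceSummary:
    n_total: int
    n_matched: int
    per_class: dict
    per_stratum: dict
    reason_histogram: dict
    median_coord_diff_bp: Optional[float]

    @property
    def detection_rate(self) -> float:
        return self.n_matched / self.n_total

    @property
    def detection_pct(self) -> float:
        return 100.0 * self.detection_rate


def summarize_concordance(results: list[MatchResult],
                          strata: Optional[dict[str, str]] = None
                          ) -> ConcordanceSummary:
    """Detection rates overall, per known class and per patient stratum,
    plus the histogram of discrepancy reasons.  ``strata`` maps patient id
    to a group label (e.g. CK vs non-CK)."""
    if not results:
        raise ValueError("no match results: detection rate undefined")
    per_class: dict[str, dict] = {}
    for r in results:
        d = per_class.setdefault(r.known_class.value, {"total": 0, "matched": 0})
        d["total"] += 1
        d["matched"] += r.matched
    per_stratum: dict[str, dict] = {}
    if strata:
        for r in results:
            label = strata.get(r.patient_id, "unstratified")
            d = per_stratum.setdefault(label, {"total": 0, "matched": 0})
            d["total"] += 1
            d["matched"] += r.matched
    for d in list(per_class.values()) + list(per_stratum.values()):
        d["rate"] = d["matched"] / d["total"]
    reasons = Counter(r.discrepancy_reason.value for r in results
                      if not r.matched and r.discrepancy_reason is not None)
    diffs = sorted(r.coord_diff_bp for r in results
                   if r.matched and r.coord_diff_bp is not None)
    median_diff = None
    if diffs:
        m = len(diffs) // 2
        median_diff = float(diffs[m]) if len(diffs) % 2 else \
            (diffs[m - 1] + diffs[m]) / 2
    return ConcordanceSummary(
        n_total=len(results),
        n_matched=sum(r.matched for r in results),
        per_class=per_class,
        per_stratum=per_stratum,
        reason_histogram=dict(reasons),
        median_coord_diff_bp=median_diff,
    )


# -------------------------------------------- novel translocations

def classify_novel_translocations(
        curated: list[AbnormalityRecord],
        known: list[KnownAberration],
        cma_segments: list[KnownAberration],
        crit: Optional[MatchCriteria] = None,
        invalidated_ids: Optional[set] = None) -> list[NovelCallClass]:
    """Sort translocation calls that do not confirm a known rearrangement
    into: real, potentially real (a breakpoint at the limit of a known
    CNV/CMA segment), false positive (externally invalidated by targeted
    FISH), or potential false positive (artifact-flagged and unsupported).

    Categories are mutually exclusive with precedence real > potentially_real
    > false_positive > potential_false_positive.  Unsupported calls with
    solid label support and no invalidation default to real (whole-chromosome
    painting indirectly validates such calls).
    """
    crit = crit or MatchCriteria()
    invalidated_ids = invalidated_ids or set()
    rearr_known = [k for k in known if k.sign is None]
    cnv_known = [k for k in known if k.sign is not None] + list(cma_segments)
    out = []
    for rec in curated:
        if not rec.is_translocation:
            continue
        if rec.status not in (Status.kept, Status.rescued, Status.artifact_flagged):
            continue
        category = None
        for k in rearr_known:
            if k.patient_id == rec.patient_id and \
                    _score_rearrangement(k, rec, crit) is not None:
                category = NovelCategory.real
                break
        if category is None:
            for k in cnv_known:
                if k.patient_id != rec.patient_id or k.interval is None:
                    continue
                hits = any(
                    c == k.interval.chrom and
                    min(abs(p - k.interval.start), abs(p - k.interval.end))
                    <= crit.cnv_bp_tolerance_bp
                    for c, p in rec.breakpoints)
                if hits:
                    category = NovelCategory.potentially_real
                    break
        if category is None and rec.ab_id in invalidated_ids:
            category = NovelCategory.false_positive
        if category is None and rec.status == Status.artifact_flagged:
            category = NovelCategory.potential_false_positive
        if category is None:
            category = NovelCategory.real
        out.append(NovelCallClass(rec.ab_id, category))
    return out
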