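"""Curation of raw OGM call tables into the countable abnormality set.

The pipeline mirrors the manual review workflow used with rare-variant
pipeline exports, as a deterministic composition of stages:

1. confidence prefilter (per-type keep-if-≥ thresholds),
2. size filters (SVs ≥ 100 Kb; CNVs strictly > 500 Kb; translocations exempt),
3. masked-region and benign-polymorphism exclusion,
4. merging of segmented CNVs (same sign, gap-bounded, transitive),
5. SV/CNV duplicate resolution (SV coordinates win; large intra-chromosomal
   translocations bracketing a loss are re-labeled as deletions),
6. translocation artifact flagging (few mapped labels or low raw confidence
   on either partner; the supporting-molecule count is deliberately not used),
7. optional targeted rescue of known aberrations under permissive thresholds,
8. chromothripsis flagging (breakpoint burden plus oscillating copy state).

Every raw call ends up in exactly one terminal status, reachable through the
``provenance`` lists, so filter-step accounting is conserved end to end.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional

from .records import (
    AbClass,
    AbnormalityRecord,
    CnvCall,
    CnvType,
    GenomicInterval,
    KnownAberration,
    RegionSet,
    SIZED_SV_TYPES,
    Status,
    SvCall,
    SvType,
    TRANSLOCATION_TYPES,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Recommended per-type confidence thresholds (Bionano Access 1.6 defaults).
DEFAULT_CONF_THRESHOLDS = {
    SvType.insertion: 0.0,
    SvType.deletion: 0.0,
    SvType.inversion: 0.7,
    SvType.duplication: -1.0,
    SvType.intra_translocation: 0.3,
    SvType.inter_translocation: 0.65,
}
DEFAULT_CNV_CONF_THRESHOLD = 0.99


@dataclass
class CurationConfig:
    conf_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_CONF_THRESHOLDS))
    cnv_conf_threshold: float = DEFAULT_CNV_CONF_THRESHOLD
    sv_min_size_bp: int = 100_000        # keep if size ≥ this
    cnv_min_size_bp: int = 500_000       # keep if size strictly > this
    mask_cnv_fraction: float = 0.5       # CNV filtered if ≥ this fraction masked
    polymorphism_reciprocal_overlap: float = 0.7
    label_artifact_max: int = 10         # flag translocation if min labels ≤ this
    rawconf_artifact_min: float = 10.0   # flag if min raw confidence < this
    cnv_merge_gap_bp: int = 500_000
    dedup_reciprocal_overlap: float = 0.5
    dedup_bp_tolerance_bp: int = 500_000
    intra_reinterpret_min_bp: int = 5_000_000
    chromothripsis_min_breakpoints: int = 10
    chromothripsis_min_state_switches: int = 2

    def __post_init__(self):
        if self.sv_min_size_bp < 0 or self.cnv_min_size_bp < 0:
            raise ValidationError("size thresholds must be non-negative")
        if self.label_artifact_max < 0:
            raise ValidationError("label_artifact_max must be non-negative")


@dataclass
class Partition:
    """Exhaustive, disjoint split of the raw calls after a filter stage."""

    sv_kept: list[SvCall] = field(default_factory=list)
    cnv_kept: list[CnvCall] = field(default_factory=list)
    sv_dropped: list[tuple[SvCall, Status]] = field(default_factory=list)
    cnv_dropped: list[tuple[CnvCall, Status]] = field(default_factory=list)


# ------------------------------------------------------------ stage 1-3

def prefilter_confidence(sv: list[SvCall], cnv: list[CnvCall],
                         cfg: CurationConfig) -> Partition:
    """Keep calls whose confidence meets the per-type threshold (inclusive)."""
    part = Partition()
    for call in sv:
        if call.sv_type not in cfg.conf_thresholds:
            raise ValidationError(f"no confidence threshold for {call.sv_type}")
        if call.confidence >= cfg.conf_thresholds[call.sv_type]:
            part.sv_kept.append(call)
        else:
            part.sv_dropped.append((call, Status.filtered_confidence))
    for call in cnv:
        if call.confidence >= cfg.cnv_conf_threshold:
            part.cnv_kept.append(call)
        else:
            part.cnv_dropped.append((call, Status.filtered_confidence))
    return part


def apply_size_filters(part: Partition, cfg: CurationConfig) -> Partition:
    """SVs with a size (ins/del/inv/dup) kept iff ≥ 100 Kb; CNVs kept iff
    strictly larger than 500 Kb; translocations are exempt."""
    out = Partition(sv_dropped=list(part.sv_dropped),
                    cnv_dropped=list(part.cnv_dropped))
    for call in part.sv_kept:
        if call.sv_type in SIZED_SV_TYPES and call.size_bp < cfg.sv_min_size_bp:
            out.sv_dropped.append((call, Status.filtered_size))
        else:
            out.sv_kept.append(call)
    for call in part.cnv_kept:
        if call.size > cfg.cnv_min_size_bp:
            out.cnv_kept.append(call)
        else:
            out.cnv_dropped.append((call, Status.filtered_size))
    return out


def filter_regions(part: Partition, masks: RegionSet,
                   polymorphisms: RegionSet,
                   cfg: Optional[CurationConfig] = None) -> Partition:
    """Drop calls in masked regions and benign-polymorphism overlaps.

    An SV is masked out when either breakpoint falls inside a masked region;
    a CNV when ≥50% of its length is masked.  A CNV (or sized deletion /
    duplication) is polymorphism-filtered on ≥70% reciprocal overlap with a
    same-sign polymorphism record.
    """
    cfg = cfg or CurationConfig()
    out = Partition(sv_dropped=list(part.sv_dropped),
                    cnv_dropped=list(part.cnv_dropped))

    def poly_hit(interval: GenomicInterval, sign: CnvType) -> bool:
        for region in polymorphisms:
            if region.sign is not None and region.sign != sign:
                continue
            if interval.reciprocal_overlap(region.interval) >= \
                    cfg.polymorphism_reciprocal_overlap:
                return True
        return False

    sv_sign = {SvType.deletion: CnvType.loss, SvType.duplication: CnvType.gain}
    for call in part.sv_kept:
        if masks.contains_point(*call.bp1) or masks.contains_point(*call.bp2):
            out.sv_dropped.append((call, Status.filtered_masked))
        elif call.sv_type in sv_sign and call.span is not None and \
                poly_hit(call.span, sv_sign[call.sv_type]):
            out.sv_dropped.append((call, Status.filtered_polymorphism))
        else:
            out.sv_kept.append(call)
    for call in part.cnv_kept:
        if masks.covered_fraction(call.interval) >= cfg.mask_cnv_fraction:
            out.cnv_dropped.append((call, Status.filtered_masked))
        elif poly_hit(call.interval, call.cnv_type):
            out.cnv_dropped.append((call, Status.filtered_polymorphism))
        else:
            out.cnv_kept.append(call)
    return out


# ------------------------------------------------------------ stage 4

def merge_segmented_cnvs(cnv: list[CnvCall], cfg: CurationConfig) -> list[CnvCall]:
    """Merge same-sign CNV segments on one chromosome whose gaps are
    ≤ ``cnv_merge_gap_bp`` into a single spanning call.

    Merging is transitive (chained segments collapse), order-independent and
    idempotent; the merged record's provenance lists every member call id.
    """
    groups: dict[tuple, list[CnvCall]] = defaultdict(list)
    for call in cnv:
        groups[(call.patient_id, call.interval.chrom, call.cnv_type)].append(call)
    merged: list[CnvCall] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2].value)):
        members = sorted(groups[key], key=lambda c: (c.interval.start,
                                                     c.interval.end, c.call_id))
        cluster: list[CnvCall] = []
        cluster_end = None
        for call in members:
            if cluster and call.interval.start - cluster_end - 1 > cfg.cnv_merge_gap_bp:
                merged.append(_merge_cluster(cluster))
                cluster, cluster_end = [], None
            cluster.append(call)
            cluster_end = call.interval.end if cluster_end is None else \
                max(cluster_end, call.interval.end)
        if cluster:
            merged.append(_merge_cluster(cluster))
    return merged


def _merge_cluster(cluster: list[CnvCall]) -> CnvCall:
    if len(cluster) == 1:
        return cluster[0]
    first = cluster[0]
    prov = sorted({cid for c in cluster for cid in c.provenance})
    fractions = [c.cell_fraction for c in cluster if c.cell_fraction is not None]
    return CnvCall(
        call_id=first.call_id,
        interval=GenomicInterval(first.interval.chrom,
                                 min(c.interval.start for c in cluster),
                                 max(c.interval.end for c in cluster)),
        cnv_type=first.cnv_type,
        confidence=min(c.confidence for c in cluster),
        cell_fraction=max(fractions) if fractions else None,
        patient_id=first.patient_id,
        provenance=prov,
    )


# ------------------------------------------------------------ stage 5

def _sv_to_record(call: SvCall, status: Status = Status.kept) -> AbnormalityRecord:
    return AbnormalityRecord(
        ab_id=f"sv:{call.call_id}", patient_id=call.patient_id,
        source="sv_pipeline", ab_class=AbClass(call.sv_type.value),
        status=status, provenance=[call.call_id],
        bp1=call.bp1, bp2=call.bp2,
        labels_bp1=call.labels_bp1, labels_bp2=call.labels_bp2,
        raw_conf_left=call.raw_conf_left, raw_conf_right=call.raw_conf_right,
    )


def _cnv_to_record(call: CnvCall, status: Status = Status.kept,
                   dedup_into: Optional[str] = None) -> AbnormalityRecord:
    return AbnormalityRecord(
        ab_id=f"cnv:{call.call_id}", patient_id=call.patient_id,
        source="cnv_pipeline",
        ab_class=AbClass.cnv_gain if call.cnv_type == CnvType.gain else AbClass.cnv_loss,
        status=status, provenance=list(call.provenance), interval=call.interval,
        dedup_into=dedup_into,
    )


def _dedup_candidates(cnv: CnvCall, sv: SvCall, cfg: CurationConfig
                      ) -> Optional[float]:
    """Return a match score (reciprocal overlap) if `sv` dual-calls `cnv`."""
    if sv.patient_id != cnv.patient_id:
        return None
    span = sv.span
    if span is None or span.chrom != cnv.interval.chrom:
        return None
    if cnv.cnv_type == CnvType.gain and sv.sv_type == SvType.duplication:
        ro = cnv.interval.reciprocal_overlap(span)
        return ro if ro >= cfg.dedup_reciprocal_overlap else None
    if cnv.cnv_type == CnvType.loss and sv.sv_type == SvType.deletion:
        ro = cnv.interval.reciprocal_overlap(span)
        return ro if ro >= cfg.dedup_reciprocal_overlap else None
    if cnv.cnv_type == CnvType.loss and sv.sv_type == SvType.intra_translocation:
        tol = cfg.dedup_bp_tolerance_bp
        if abs(sv.bp1[1] - cnv.interval.start) <= tol and \
                abs(sv.bp2[1] - cnv.interval.end) <= tol:
            return cnv.interval.reciprocal_overlap(span)
    return None


def deduplicate_sv_cnv(sv_kept: list[SvCall], cnv_kept: list[CnvCall],
                       cfg: CurationConfig) -> list[AbnormalityRecord]:
    """Resolve dual-called abnormalities between the SV and CNV pipelines.

    A CNV gain overlapping a duplication (reciprocal overlap ≥50%), or a CNV
    loss overlapping a deletion or bracketed by an intra-chromosomal
    translocation's breakpoints (within 500 Kb per boundary), is the same
    abnormality; the record keeps the SV coordinates.  Intra-chromosomal
    translocations spanning ≥5 Mb that absorb a loss this way are re-labeled
    as deletions (the SV caller reports large interstitial deletions as
    intra-chromosomal translocations).  A CNV matching several SVs goes to
    the highest-overlap SV (tie → smaller SV span).  Every input call
    surfaces exactly once: survivors plus ``deduplicated`` tombstones.
    """
    sv_records = {sv.call_id: _sv_to_record(sv) for sv in sv_kept}
    out: list[AbnormalityRecord] = []
    for cnv in cnv_kept:
        scored = []
        for sv in sv_kept:
            score = _dedup_candidates(cnv, sv, cfg)
            if score is not None:
                span = sv.span
                scored.append((-score, span.size if span else 0, sv.call_id, sv))
        if not scored:
            out.append(_cnv_to_record(cnv))
            continue
        scored.sort()
        winner = scored[0][3]
        rec = sv_records[winner.call_id]
        rec.source = "merged"
        rec.provenance = sorted(set(rec.provenance) | set(cnv.provenance))
        if winner.sv_type == SvType.intra_translocation and \
                winner.bp2[1] - winner.bp1[1] >= cfg.intra_reinterpret_min_bp:
            rec.ab_class = AbClass.deletion
        log.debug("dedup: CNV %s absorbed by SV %s", cnv.call_id, winner.call_id)
        out.append(_cnv_to_record(cnv, Status.deduplicated,
                                  dedup_into=rec.ab_id))
    return [sv_records[sv.call_id] for sv in sv_kept] + out


# ------------------------------------------------------------ stage 6

def flag_translocation_artifacts(records: list[AbnormalityRecord],
                                 cfg: CurationConfig) -> list[AbnormalityRecord]:
    """Flag translocations with ≤10 mapped labels on either partner or raw
    confidence <10 on either side.  Supporting-molecule counts are not
    consulted: validated rearrangements can rest on as few as 5 molecules,
    so that signal does not separate artifacts from true calls."""
    out = []
    for rec in records:
        if rec.status == Status.kept and rec.is_translocation:
            if rec.labels_bp1 is None or rec.labels_bp2 is None:
                log.warning("%s: label counts missing, artifact rule not "
                            "evaluable; record passes", rec.ab_id)
            elif min(rec.labels_bp1, rec.labels_bp2) <= cfg.label_artifact_max or \
                    min(rec.raw_conf_left, rec.raw_conf_right) < cfg.rawconf_artifact_min:
                rec = replace(rec, status=Status.artifact_flagged)
        out.append(rec)
    return out


def _is_artifact_sv(call: SvCall, cfg: CurationConfig) -> bool:
    if call.sv_type not in TRANSLOCATION_TYPES:
        return False
    if call.min_labels is None:
        return False
    return call.min_labels <= cfg.label_artifact_max or \
        call.min_raw_conf < cfg.rawconf_artifact_min


# ------------------------------------------------------------ stage 7

def _near_known(call, known: list[KnownAberration], slop: int) -> bool:
    if isinstance(call, CnvCall):
        points = [(call.interval.chrom, call.interval.start),
                  (call.interval.chrom, call.interval.end)]
        interval = call.interval
    else:
        points = [call.bp1, call.bp2]
        interval = call.span
    for k in known:
        if k.patient_id != call.patient_id:
            continue
        tol = max(slop, k.bp_tolerance_bp or 0)
        if k.interval is not None:
            if interval is not None and interval.overlap_bp(k.interval) > 0:
                return True
            if any(k.interval.contains(c, p) or
                   (c == k.interval.chrom and
                    min(abs(p - k.interval.start), abs(p - k.interval.end)) <= tol)
                   for c, p in points):
                return True
        for kc, kp in k.breakpoints:
            if any(c == kc and abs(p - kp) <= tol for c, p in points):
                return True
    return False


def targeted_rescue(raw_sv: list[SvCall], raw_cnv: list[CnvCall],
                    known: list[KnownAberration],
                    permissive_cfg: CurationConfig,
                    default_cfg: Optional[CurationConfig] = None,
                    already_kept: Optional[set] = None,
                    bp_slop: int = 1_000_000) -> list[AbnormalityRecord]:
    """Re-run the confidence and size filters with permissive thresholds,
    restricted to calls overlapping known-aberration regions, and rescue
    calls that the default thresholds dropped.  Artifact-like translocations
    are never rescued."""
    default_cfg = default_cfg or CurationConfig()
    for t, thr in permissive_cfg.conf_thresholds.items():
        if thr > default_cfg.conf_thresholds[t]:
            raise ValidationError(
                f"permissive confidence threshold for {t.value} exceeds default")
    if permissive_cfg.cnv_conf_threshold > default_cfg.cnv_conf_threshold or \
            permissive_cfg.sv_min_size_bp > default_cfg.sv_min_size_bp or \
            permissive_cfg.cnv_min_size_bp > default_cfg.cnv_min_size_bp:
        raise ValidationError("permissive thresholds exceed defaults")

    already_kept = already_kept or set()
    part = apply_size_filters(
        prefilter_confidence(raw_sv, raw_cnv, permissive_cfg), permissive_cfg)
    rescued = []
    for call in part.sv_kept:
        if call.call_id in already_kept or _is_artifact_sv(call, default_cfg):
            continue
        if _near_known(call, known, bp_slop):
            rescued.append(_sv_to_record(call, Status.rescued))
    for call in part.cnv_kept:
        if call.call_id in already_kept:
            continue
        if _near_known(call, known, bp_slop):
            rescued.append(_cnv_to_record(call, Status.rescued))
    return rescued


# ------------------------------------------------------------ stage 8

def detect_chromothripsis(records: list[AbnormalityRecord],
                          cfg: CurationConfig) -> dict[tuple[str, str], bool]:
    """Flag (patient, chromosome) pairs consistent with chromothripsis:
    ≥ ``chromothripsis_min_breakpoints`` SV breakpoints on the chromosome
    AND copy-state oscillation (≥ ``chromothripsis_min_state_switches``
    transitions along the ordered CNV-like segments, counting the normal
    state in gaps between segments)."""
    bp_count: dict[tuple, int] = defaultdict(int)
    segments: dict[tuple, list] = defaultdict(list)
    for rec in records:
        if not rec.countable:
            continue
        if rec.ab_class in (AbClass.cnv_gain, AbClass.cnv_loss, AbClass.deletion,
                            AbClass.duplication) and rec.footprint is not None:
            fp = rec.footprint
            state = "gain" if rec.ab_class in (AbClass.cnv_gain, AbClass.duplication) \
                else "loss"
            segments[(rec.patient_id, fp.chrom)].append((fp.start, fp.end, state))
        if rec.ab_class in (AbClass.cnv_gain, AbClass.cnv_loss):
            continue  # segment boundaries are not assembly breakpoints
        for chrom, _pos in rec.breakpoints:
            bp_count[(rec.patient_id, chrom)] += 1
    flags: dict[tuple[str, str], bool] = {}
    for key in set(bp_count) | set(segments):
        states = []
        prev_end = None
        for start, end, state in sorted(segments.get(key, [])):
            if prev_end is not None and start > prev_end + 1:
                states.append("normal")
            states.append(state)
            prev_end = end if prev_end is None else max(prev_end, end)
        switches = sum(1 for a, b in zip(states, states[1:]) if a != b)
        flags[key] = (bp_count.get(key, 0) >= cfg.chromothripsis_min_breakpoints
                      and switches >= cfg.chromothripsis_min_state_switches)
    return flags


# ------------------------------------------------------------ composition

@dataclass
class CurationResult:
    records: list[AbnormalityRecord]
    chromothripsis: dict[tuple[str, str], bool]

    @property
    def countable(self) -> list[AbnormalityRecord]:
        return [r for r in self.records if r.countable]

    def summary(self) -> dict:
        by_status: dict[str, int] = defaultdict(int)
        by_class: dict[str, int] = defaultdict(int)
        for r in self.records:
            by_status[r.status.value] += 1
            if r.countable:
                by_class[r.ab_class.value] += 1
        return {
            "n_records": len(self.records),
            "n_countable": len(self.countable),
            "by_status": dict(sorted(by_status.items())),
            "countable_by_class": dict(sorted(by_class.items())),
            "n_chromothripsis_chromosomes":
                sum(bool(v) for v in self.chromothripsis.values()),
        }


def curate(sv: list[SvCall], cnv: list[CnvCall],
           masks: Optional[RegionSet] = None,
           polymorphisms: Optional[RegionSet] = None,
           known: Optional[list[KnownAberration]] = None,
           cfg: Optional[CurationConfig] = None,
           permissive_cfg: Optional[CurationConfig] = None) -> CurationResult:
    """Run the full curation pipeline; see the module docstring for stages.

    Targeted rescue runs only when both ``known`` and ``permissive_cfg`` are
    supplied.  Every raw call id appears in exactly one record's provenance.
    """
    cfg = cfg or CurationConfig()
    masks = masks or RegionSet("masked")
    polymorphisms = polymorphisms or RegionSet("polymorphism")

    part = prefilter_confidence(sv, cnv, cfg)
    part = apply_size_filters(part, cfg)
    part = filter_regions(part, masks, polymorphisms, cfg)
    merged_cnv = merge_segmented_cnvs(part.cnv_kept, cfg)
    records = deduplicate_sv_cnv(part.sv_kept, merged_cnv, cfg)
    records = flag_translocation_artifacts(records, cfg)

    dropped = [_sv_to_record(c, s) for c, s in part.sv_dropped]
    dropped += [_cnv_to_record(c, s) for c, s in part.cnv_dropped]
    records = records + dropped

    if known is not None and permissive_cfg is not None:
        rescuable = {Status.filtered_confidence, Status.filtered_size}
        kept_ids = {cid for r in records if r.status not in rescuable
                    for cid in r.provenance}
        rescued = targeted_rescue(sv, cnv, known, permissive_cfg, cfg,
                                  already_kept=kept_ids)
        # a rescued call's filtered tombstone is superseded, not duplicated
        rescued_ids = {cid for r in rescued for cid in r.provenance}
        records = [r for r in records
                   if not (r.status in rescuable
                           and set(r.provenance) <= rescued_ids)]
        records += rescued

    records.sort(key=lambda r: (r.patient_id, r.ab_id))
    flags = detect_chromothripsis(records, cfg)
    n_raw = len(sv) + len(cnv)
    n_seen = len({cid for r in records for cid in r.provenance})
    if n_seen != n_raw:
        log.warning("curation accounting: %d raw calls, %d traced", n_raw, n_seen)
    return CurationResult(records, flags)
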