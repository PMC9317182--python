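"""Shared data model: validated records for SV/CNV calls, region sets,
known aberrations, clinical covariates and curated abnormalities.

Conventions
-----------
* Coordinates are 1-based inclusive on hg19; chromosome names are bare
  ("1".."22", "X", "Y").  BED I/O converts at the boundary (see ``io``).
* An *inter*-chromosomal translocation is exactly a call whose two
  breakpoints sit on different chromosomes; every other type is
  same-chromosome with bp1 ≤ bp2.
* ``AbnormalityRecord`` is the unit the complexity score counts: a record
  contributes iff ``countable`` is True, which in turn holds iff its
  terminal curation status is ``kept`` or ``rescued``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .genome import CHROM_LENGTHS


class ValidationError(ValueError):
    """A record violates a model invariant."""


class SvType(str, enum.Enum):
    insertion = "insertion"
    deletion = "deletion"
    inversion = "inversion"
    duplication = "duplication"
    intra_translocation = "intra_translocation"
    inter_translocation = "inter_translocation"


TRANSLOCATION_TYPES = frozenset(
    {SvType.intra_translocation, SvType.inter_translocation}
)
SIZED_SV_TYPES = frozenset(
    {SvType.insertion, SvType.deletion, SvType.inversion, SvType.duplication}
)


class CnvType(str, enum.Enum):
    gain = "gain"
    loss = "loss"


class AbClass(str, enum.Enum):
    """Class of a curated abnormality: the SV types plus the two CNV signs."""

    insertion = "insertion"
    deletion = "deletion"
    inversion = "inversion"
    duplication = "duplication"
    intra_translocation = "intra_translocation"
    inter_translocation = "inter_translocation"
    cnv_gain = "cnv_gain"
    cnv_loss = "cnv_loss"


class Status(str, enum.Enum):
    kept = "kept"
    filtered_confidence = "filtered_confidence"
    filtered_size = "filtered_size"
    filtered_masked = "filtered_masked"
    filtered_polymorphism = "filtered_polymorphism"
    deduplicated = "deduplicated"
    artifact_flagged = "artifact_flagged"
    rescued = "rescued"


COUNTABLE_STATUSES = frozenset({Status.kept, Status.rescued})


class Technique(str, enum.Enum):
    CMA = "CMA"
    FISH = "FISH"
    CBA = "CBA"


class KnownClass(str, enum.Enum):
    cnv_gain = "cnv_gain"
    cnv_loss = "cnv_loss"
    translocation = "translocation"
    inversion = "inversion"
    trisomy = "trisomy"
    add_breakpoint = "add_breakpoint"


class DiscrepancyReason(str, enum.Enum):
    centromeric_telomeric = "centromeric_telomeric"
    masked_region = "masked_region"
    sensitivity = "sensitivity"
    small_within_chromothripsis = "small_within_chromothripsis"
    unknown = "unknown"


class NovelCategory(str, enum.Enum):
    real = "real"
    potentially_real = "potentially_real"
    false_positive = "false_positive"
    potential_false_positive = "potential_false_positive"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.chrom not in CHROM_LENGTHS:
            raise ValidationError(f"chromosome {self.chrom!r} not in reference set")
        if self.start < 1:
            raise ValidationError(f"start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(f"end {self.end} < start {self.start}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len1, overlap/len2), the standard SV-equivalence measure."""
        ov = self.overlap_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.size, ov / other.size)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


Breakpoint = tuple[str, int]  # (chrom, 1-based position)


@dataclass
class SvCall:
    call_id: str
    sv_type: SvType
    bp1: Breakpoint
    bp2: Breakpoint
    size_bp: int
    confidence: float
    raw_conf_left: float = 0.0
    raw_conf_right: float = 0.0
    labels_bp1: Optional[int] = None
    labels_bp2: Optional[int] = None
    self_molecules: int = 0
    vaf: Optional[float] = None
    patient_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        c1, p1 = self.bp1
        c2, p2 = self.bp2
        for c in (c1, c2):
            if c not in CHROM_LENGTHS:
                raise ValidationError(f"{self.call_id}: unknown chromosome {c!r}")
        if (c1 != c2) != (self.sv_type == SvType.inter_translocation):
            raise ValidationError(
                f"{self.call_id}: chromosomes {c1}/{c2} inconsistent with "
                f"type {self.sv_type.value}"
            )
        if c1 == c2 and p1 > p2:
            raise ValidationError(f"{self.call_id}: bp1 {p1} > bp2 {p2}")
        if self.size_bp < 0:
            raise ValidationError(f"{self.call_id}: negative size")
        if self.sv_type in (SvType.deletion, SvType.duplication, SvType.inversion):
            if self.size_bp != p2 - p1:
                raise ValidationError(
                    f"{self.call_id}: size {self.size_bp} inconsistent with "
                    f"breakpoints ({p2 - p1})"
                )
        if self.raw_conf_left < 0 or self.raw_conf_right < 0:
            raise ValidationError(f"{self.call_id}: negative raw confidence")
        for lab in (self.labels_bp1, self.labels_bp2):
            if lab is not None and lab < 0:
                raise ValidationError(f"{self.call_id}: negative label count")
        if self.self_molecules < 0:
            raise ValidationError(f"{self.call_id}: negative molecule count")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"{self.call_id}: VAF {self.vaf} outside [0,1]")

    @property
    def span(self) -> Optional[GenomicInterval]:
        """bp1..bp2 as an interval for same-chromosome calls, else None."""
        if self.sv_type == SvType.inter_translocation:
            return None
        return GenomicInterval(self.bp1[0], self.bp1[1], max(self.bp1[1], self.bp2[1]))

    @property
    def min_labels(self) -> Optional[int]:
        if self.labels_bp1 is None or self.labels_bp2 is None:
            return None
        return min(self.labels_bp1, self.labels_bp2)

    @property
    def min_raw_conf(self) -> float:
        return min(self.raw_conf_left, self.raw_conf_right)


@dataclass
class CnvCall:
    call_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    confidence: float
    cell_fraction: Optional[float] = None
    patient_id: str = ""
    provenance: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cell_fraction is not None and not 0.0 <= self.cell_fraction <= 1.0:
            raise ValidationError(
                f"{self.call_id}: cell fraction {self.cell_fraction} outside [0,1]"
            )
        if not self.provenance:
            self.provenance = [self.call_id]

    @property
    def size(self) -> int:
        return self.interval.size


@dataclass
class Region:
    interval: GenomicInterval
    name: Optional[str] = None  # polymorphism records carry "gain"/"loss" here

    @property
    def sign(self) -> Optional[CnvType]:
        if self.name in (CnvType.gain.value, CnvType.loss.value):
            return CnvType(self.name)
        return None


@dataclass
class RegionSet:
    label: str  # "masked" | "polymorphism" | other annotation labels
    regions: list[Region] = field(default_factory=list)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)

    def contains_point(self, chrom: str, pos: int, slop: int = 0) -> bool:
        return any(
            r.interval.chrom == chrom
            and r.interval.start - slop <= pos <= r.interval.end + slop
            for r in self.regions
        )

    def covered_fraction(self, interval: GenomicInterval) -> float:
        """Fraction of `interval` covered by the union of the set's regions."""
        pieces = sorted(
            (max(interval.start, r.interval.start), min(interval.end, r.interval.end))
            for r in self.regions
            if r.interval.chrom == interval.chrom
            and r.interval.overlap_bp(interval) > 0
        )
        covered, cur_s, cur_e = 0, None, None
        for s, e in pieces:
            if cur_e is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        if cur_e is not None:
            covered += cur_e - cur_s + 1
        return covered / interval.size


@dataclass
class KnownAberration:
    ab_id: str
    patient_id: str
    technique: Technique
    ab_class: KnownClass
    interval: Optional[GenomicInterval] = None
    bp1: Optional[Breakpoint] = None
    bp2: Optional[Breakpoint] = None
    bp_tolerance_bp: Optional[int] = None  # band-resolution slop for CBA breakpoints
    clone_fraction: Optional[float] = None

    def __post_init__(self):
        if self.ab_class in (KnownClass.cnv_gain, KnownClass.cnv_loss, KnownClass.trisomy):
            if self.interval is None:
                raise ValidationError(f"{self.ab_id}: {self.ab_class.value} requires an interval")
        elif self.ab_class in (KnownClass.translocation, KnownClass.inversion):
            if self.bp1 is None and self.bp2 is None:
                raise ValidationError(f"{self.ab_id}: {self.ab_class.value} requires a breakpoint")
        elif self.ab_class == KnownClass.add_breakpoint:
            if (self.bp1 is None) == (self.bp2 is None):
                raise ValidationError(
                    f"{self.ab_id}: add_breakpoint requires exactly one known breakpoint"
                )
        if self.clone_fraction is not None and not 0.0 <= self.clone_fraction <= 1.0:
            raise ValidationError(f"{self.ab_id}: clone fraction outside [0,1]")

    @property
    def breakpoints(self) -> list[Breakpoint]:
        return [bp for bp in (self.bp1, self.bp2) if bp is not None]

    @property
    def sign(self) -> Optional[CnvType]:
        if self.ab_class in (KnownClass.cnv_gain, KnownClass.trisomy):
            return CnvType.gain
        if self.ab_class == KnownClass.cnv_loss:
            return CnvType.loss
        return None


@dataclass
class ClinicalRecord:
    patient_id: str
    treated: bool
    pre_treated: bool
    tp53_abnormal: bool
    ck_by_cba: bool
    n_abn_cba: int
    ttft_months: Optional[float] = None
    n_abn_cma: Optional[int] = None
    follow_up_months: Optional[float] = None  # censoring time for untreated patients

    def __post_init__(self):
        if self.treated and self.ttft_months is None:
            raise ValidationError(f"{self.patient_id}: treated but TTFT missing")
        if self.ttft_months is not None and self.ttft_months < 0:
            raise ValidationError(f"{self.patient_id}: negative TTFT")
        if self.n_abn_cba < 0 or (self.n_abn_cma is not None and self.n_abn_cma < 0):
            raise ValidationError(f"{self.patient_id}: negative abnormality count")


@dataclass
class AbnormalityRecord:
    """A curated abnormality with full provenance.

    Exactly one record is emitted per surviving abnormality; calls absorbed
    by merging or deduplication appear in the survivor's ``provenance`` and,
    for SV/CNV dedup, additionally as a tombstone record with
    ``status=deduplicated`` pointing at the survivor via ``dedup_into``.
    """

    ab_id: str
    patient_id: str
    source: str  # "sv_pipeline" | "cnv_pipeline" | "merged"
    ab_class: AbClass
    status: Status
    provenance: list[str]
    interval: Optional[GenomicInterval] = None
    bp1: Optional[Breakpoint] = None
    bp2: Optional[Breakpoint] = None
    labels_bp1: Optional[int] = None
    labels_bp2: Optional[int] = None
    raw_conf_left: Optional[float] = None
    raw_conf_right: Optional[float] = None
    dedup_into: Optional[str] = None

    def __post_init__(self):
        if not self.provenance:
            raise ValidationError(f"{self.ab_id}: empty provenance")
        if self.status == Status.deduplicated and not self.dedup_into:
            raise ValidationError(f"{self.ab_id}: deduplicated without survivor")

    @property
    def countable(self) -> bool:
        return self.status in COUNTABLE_STATUSES

    @property
    def is_translocation(self) -> bool:
        return self.ab_class in (AbClass.intra_translocation, AbClass.inter_translocation)

    @property
    def is_cnv_like(self) -> bool:
        return self.ab_class in (
            AbClass.cnv_gain, AbClass.cnv_loss, AbClass.deletion, AbClass.duplication
        )

    @property
    def footprint(self) -> Optional[GenomicInterval]:
        """Interval representation: the stored interval, else bp1..bp2 when
        both breakpoints share a chromosome."""
        if self.interval is not None:
            return self.interval
        if self.bp1 and self.bp2 and self.bp1[0] == self.bp2[0]:
            lo, hi = sorted((self.bp1[1], self.bp2[1]))
            return GenomicInterval(self.bp1[0], lo, max(hi, lo))
        return None

    @property
    def breakpoints(self) -> list[Breakpoint]:
        if self.bp1 or self.bp2:
            return [bp for bp in (self.bp1, self.bp2) if bp is not None]
        if self.interval is not None:
            return [
                (self.interval.chrom, self.interval.start),
                (self.interval.chrom, self.interval.end),
            ]
        return []
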