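"""Synthetic CLL cohort generator with full truth tracking.

The generator emulates what the downstream pipeline actually consumes: the
per-patient set of true cytogenomic abnormalities with clonal fractions,
and the platform-specific observations of that truth —

* the OGM SV channel (detects abnormalities above a ~5% clonal fraction,
  ramping linearly to certain detection at 20%),
* the OGM CNV coverage channel (floor ~10%, same ramp top; true CNVs may be
  emitted as 2-3 segments that curation must merge, and may be dual-called
  by the SV channel, which dedup must resolve),
* artifact inter-chromosomal translocations with few mapped labels or low
  raw confidence on one partner,
* benign polymorphism CNVs drawn from a fixed catalog (which is also the
  polymorphism region set the curation stage filters against),
* CBA (band-resolution karyotyping with clone-selection noise, "add"
  entries for one-breakpoint rearrangements), FISH at the four classic CLL
  loci, and CMA (exact coordinates, hard 20% sensitivity floor),
* clinical outcome: exponential TTFT with a multiplicative hazard for
  genomically complex patients, uniform censoring.

Every observed call carries a truth pointer (or an artifact/polymorphism
label), so recovery of counts, risk classes and filter decisions can be
scored exactly.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome import CHROM_LENGTHS, centromere_telomere_intervals
from .records import (
    AbClass,
    ClinicalRecord,
    CnvCall,
    CnvType,
    GenomicInterval,
    KnownAberration,
    KnownClass,
    Region,
    RegionSet,
    SvCall,
    SvType,
    Technique,
)
from .curation import DEFAULT_CONF_THRESHOLDS

#: Classic CLL FISH-panel lesions (hg19): locus interval and per-patient prevalence.
CLASSIC_LESIONS = (
    ("del13q14", AbClass.cnv_loss, GenomicInterval("13", 49_500_000, 51_500_000), 0.60),
    ("tri12", AbClass.cnv_gain, GenomicInterval("12", 3_000_001, 130_851_895), 0.19),
    ("del11q22", AbClass.cnv_loss, GenomicInterval("11", 107_500_000, 110_500_000), 0.29),
    ("del17p13", AbClass.cnv_loss, GenomicInterval("17", 4_000_000, 10_000_000), 0.17),
)

#: Curated class mix of a rare-variant-pipeline output after filtering
#: (deletions, inversions, duplications, intra- and inter-chromosomal
#: translocations, CNV gains and losses).
CLASS_WEIGHTS = {
    AbClass.deletion: 36, AbClass.inversion: 3, AbClass.duplication: 4,
    AbClass.intra_translocation: 142, AbClass.inter_translocation: 185,
    AbClass.cnv_gain: 59, AbClass.cnv_loss: 150,
}


@dataclass
class SimConfig:
    n_patients: int = 42
    ck_fraction: float = 18 / 42
    mean_abn_nonck: float = 4.0          # zero-truncated negative binomial means
    mean_abn_ck: float = 20.0
    nb_dispersion: float = 3.0           # NB shape r; larger = tighter
    clone_fraction_range: tuple = (0.02, 1.0)
    sv_detect_floor: float = 0.05
    cnv_detect_floor: float = 0.10
    soft_sensitivity_top: float = 0.20   # certain detection from here up
    cma_floor: float = 0.20
    fish_floor: float = 0.03
    artifact_translocation_rate: float = 1.2   # per patient (Poisson mean)
    polymorphism_rate: float = 1.5
    cnv_segmentation_prob: float = 0.3
    dual_call_prob: float = 0.2          # CNV also emitted by the SV channel
    chromothripsis_prob_ck: float = 0.25
    cba_detect_scale: float = 0.25       # CBA detection prob = min(1, cf/scale)*0.9
    cba_add_prob: float = 0.3            # translocation recorded as "add"
    cba_band_jitter_bp: int = 2_000_000
    ttft_median_nonck_months: float = 43.0
    complex_hazard_ratio: float = 3.0
    pre_treated_rate: float = 2 / 42
    mask_flank_bp: int = 3_000_000
    seed: int = 0

    def __post_init__(self):
        for p in (self.ck_fraction, self.sv_detect_floor, self.cnv_detect_floor,
                  self.cma_floor, self.cnv_segmentation_prob, self.dual_call_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.soft_sensitivity_top <= max(self.sv_detect_floor,
                                            self.cnv_detect_floor):
            raise ValueError("detection floors must lie below the soft band top")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        lo, hi = self.clone_fraction_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("clone fraction range must satisfy 0 < lo <= hi <= 1")


@dataclass
class TrueAbnormality:
    truth_id: str
    ab_class: AbClass
    clone_fraction: float
    interval: Optional[GenomicInterval] = None
    bp1: Optional[tuple] = None
    bp2: Optional[tuple] = None


@dataclass
class PatientTruth:
    patient_id: str
    is_ck: bool
    abnormalities: list[TrueAbnormality]
    chromothripsis_chrom: Optional[str]
    ttft_months: Optional[float]
    follow_up_months: float
    treated: bool
    pre_treated: bool
    tp53_abnormal: bool

    @property
    def n_true(self) -> int:
        return len(self.abnormalities)

    @property
    def risk_class(self) -> str:
        return "C_OGM" if self.n_true >= 10 else "NC_OGM"

    @property
    def min_clone_fraction(self) -> float:
        return min((a.clone_fraction for a in self.abnormalities), default=1.0)


@dataclass
class TruthSet:
    patients: dict[str, PatientTruth]
    #: observed call_id -> truth_id, or "artifact:<n>" / "polymorphism:<n>"
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    config: SimConfig
    truth: TruthSet
    sv_calls: list[SvCall]
    cnv_calls: list[CnvCall]
    cba_records: list[KnownAberration]
    fish_records: list[KnownAberration]
    cma_records: list[KnownAberration]
    clinical: list[ClinicalRecord]
    masks: RegionSet
    polymorphisms: RegionSet


# ------------------------------------------------------------ helpers

def detection_probability(cf: float, floor: float, top: float) -> float:
    """Zero below the floor, then a linear ramp to certain detection at the
    top of the soft sensitivity band."""
    if cf < floor:
        return 0.0
    return min(1.0, (cf - floor) / (top - floor))


def _mappable_windows(flank: int) -> list[tuple[str, int, int]]:
    """Chromosome-arm windows clear of the telomeric/peri-centromeric masks."""
    masked = defaultdict(list)
    for chrom, s, e in centromere_telomere_intervals(flank):
        masked[chrom].append((s, e))
    windows = []
    for chrom, length in CHROM_LENGTHS.items():
        pieces = sorted(masked[chrom])
        cursor = 1
        for s, e in pieces:
            if s > cursor:
                windows.append((chrom, cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= length:
            windows.append((chrom, cursor, length))
    return windows


def polymorphism_catalog(flank: int = 3_000_000) -> RegionSet:
    """Fixed catalog of benign CNV regions, one per autosome arm window in
    a deterministic layout; the sign alternates gain/loss."""
    regions = []
    for i, (chrom, lo, hi) in enumerate(_mappable_windows(flank)):
        if chrom in ("X", "Y") or hi - lo < 20_000_000:
            continue
        size = 600_000 + (i % 5) * 200_000
        start = lo + (hi - lo) // 3
        sign = CnvType.gain if i % 2 == 0 else CnvType.loss
        regions.append(Region(GenomicInterval(chrom, start, start + size - 1),
                              sign.value))
    return RegionSet("polymorphism", regions)


class _Placer:
    def __init__(self, rng: np.random.Generator, flank: int,
                 poly: RegionSet):
        self.rng = rng
        self.windows = _mappable_windows(flank)
        self.weights = np.array([hi - lo + 1 for _, lo, hi in self.windows],
                                dtype=float)
        self.weights /= self.weights.sum()
        self.poly = poly

    def interval(self, size: int) -> GenomicInterval:
        for _ in range(200):
            i = self.rng.choice(len(self.windows), p=self.weights)
            chrom, lo, hi = self.windows[i]
            if hi - lo + 1 < size:
                continue
            start = int(self.rng.integers(lo, hi - size + 2))
            iv = GenomicInterval(chrom, start, start + size - 1)
            # avoid colliding with the benign-polymorphism catalog
            if all(iv.reciprocal_overlap(r.interval) < 0.5 for r in self.poly):
                return iv
        raise RuntimeError(f"could not place an interval of {size} bp")

    def point(self) -> tuple[str, int]:
        i = self.rng.choice(len(self.windows), p=self.weights)
        chrom, lo, hi = self.windows[i]
        return chrom, int(self.rng.integers(lo, hi + 1))


def _zt_negbin(rng: np.random.Generator, mean: float, r: float) -> int:
    """Zero-truncated negative binomial draw with the given mean and shape."""
    p = r / (r + mean)
    for _ in range(1000):
        k = int(rng.negative_binomial(r, p))
        if k > 0:
            return k
    return 1


def _logu(rng, lo: float, hi: float) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


# -------------------------------------------------------- truth drawing

def _draw_true_abnormalities(rng, placer: _Placer, pid: str, is_ck: bool,
                             cfg: SimConfig) -> tuple[list[TrueAbnormality],
                                                      Optional[str]]:
    cf_lo, cf_hi = cfg.clone_fraction_range
    abns: list[TrueAbnormality] = []
    counter = 0

    def next_id():
        nonlocal counter
        counter += 1
        return f"{pid}:T{counter:03d}"

    def draw_cf() -> float:
        return float(rng.uniform(cf_lo, cf_hi))

    # classic CLL lesions first (the FISH panel exists to find these)
    for name, ab_class, locus, prev in CLASSIC_LESIONS:
        if rng.random() < prev:
            abns.append(TrueAbnormality(next_id(), ab_class, draw_cf(),
                                        interval=locus))

    # general abnormality burden
    mean = cfg.mean_abn_ck if is_ck else cfg.mean_abn_nonck
    n_general = max(0, _zt_negbin(rng, mean, cfg.nb_dispersion) - len(abns))
    classes = list(CLASS_WEIGHTS)
    weights = np.array([CLASS_WEIGHTS[c] for c in classes], dtype=float)
    weights /= weights.sum()
    for _ in range(n_general):
        ab_class = classes[int(rng.choice(len(classes), p=weights))]
        cf = draw_cf()
        tid = next_id()
        if ab_class in (AbClass.cnv_gain, AbClass.cnv_loss):
            iv = placer.interval(_logu(rng, 600_000, 30_000_000))
            abns.append(TrueAbnormality(tid, ab_class, cf, interval=iv))
        elif ab_class in (AbClass.deletion, AbClass.duplication, AbClass.inversion):
            iv = placer.interval(_logu(rng, 100_000, 4_500_000))
            abns.append(TrueAbnormality(tid, ab_class, cf, interval=iv,
                                        bp1=(iv.chrom, iv.start),
                                        bp2=(iv.chrom, iv.end)))
        elif ab_class == AbClass.intra_translocation:
            iv = placer.interval(_logu(rng, 6_000_000, 50_000_000))
            abns.append(TrueAbnormality(tid, ab_class, cf,
                                        bp1=(iv.chrom, iv.start),
                                        bp2=(iv.chrom, iv.end)))
        else:  # inter-chromosomal translocation
            bp1 = placer.point()
            bp2 = placer.point()
            while bp2[0] == bp1[0]:
                bp2 = placer.point()
            abns.append(TrueAbnormality(tid, ab_class, cf, bp1=bp1, bp2=bp2))

    # chromothripsis: clustered breakpoints with oscillating losses
    ct_chrom = None
    if is_ck and rng.random() < cfg.chromothripsis_prob_ck:
        region = placer.interval(60_000_000)
        ct_chrom = region.chrom
        cf = float(rng.uniform(0.4, cf_hi))
        cursor = region.start
        for j in range(4):  # 4 losses with gaps > merge distance
            size = _logu(rng, 800_000, 2_500_000)
            iv = GenomicInterval(ct_chrom, cursor, cursor + size - 1)
            abns.append(TrueAbnormality(next_id(), AbClass.cnv_loss, cf,
                                        interval=iv))
            cursor = iv.end + _logu(rng, 1_000_000, 4_000_000)
        for j in range(6):  # 6 intra-chromosomal rearrangements (12 breakpoints)
            p1 = int(rng.integers(region.start, region.end - 6_000_000))
            p2 = p1 + _logu(rng, 5_000_001, 20_000_000)
            abns.append(TrueAbnormality(
                next_id(), AbClass.intra_translocation, cf,
                bp1=(ct_chrom, p1), bp2=(ct_chrom, min(p2, region.end))))
    return abns, ct_chrom


# ------------------------------------------------------- observation

def inject_segmentation(cnv_calls: list[CnvCall], cfg: SimConfig,
                        rng: np.random.Generator) -> list[CnvCall]:
    """With probability ``cnv_segmentation_prob``, replace a CNV call with
    2-3 same-sign segments whose internal gaps stay below the curation merge
    distance, so that merging recovers the original span exactly."""
    out = []
    min_piece = 1_200_000  # keeps every emitted segment above the caller's 500 Kb floor
    for call in cnv_calls:
        if rng.random() >= cfg.cnv_segmentation_prob or call.size < 2 * min_piece:
            out.append(call)
            continue
        n_seg = int(rng.integers(2, 4)) if call.size >= 3 * min_piece else 2
        iv = call.interval
        max_gap = 480_000
        cuts = None
        for _ in range(20):
            trial = sorted(rng.integers(iv.start + min_piece, iv.end - min_piece + 1,
                                        size=n_seg - 1).tolist())
            spacing = [b - a for a, b in zip([iv.start] + trial, trial + [iv.end])]
            if min(spacing) >= min_piece:
                cuts = trial
                break
        if cuts is None:
            out.append(call)
            continue
        bounds = [iv.start] + cuts + [iv.end]
        segs = []
        for j in range(n_seg):
            s = bounds[j] if j == 0 else bounds[j] + int(rng.integers(1, max_gap // 2))
            e = bounds[j + 1] if j == n_seg - 1 else bounds[j + 1] - \
                int(rng.integers(1, max_gap // 2))
            if e <= s:  # degenerate cut; fall back to the unsplit call
                segs = None
                break
            segs.append(CnvCall(
                call_id=f"{call.call_id}.s{j+1}", interval=GenomicInterval(iv.chrom, s, e),
                cnv_type=call.cnv_type, confidence=call.confidence,
                cell_fraction=call.cell_fraction, patient_id=call.patient_id))
        if segs is None:
            out.append(call)
        else:
            segs[0].interval = GenomicInterval(iv.chrom, iv.start, segs[0].interval.end)
            segs[-1].interval = GenomicInterval(iv.chrom, segs[-1].interval.start, iv.end)
            out.extend(segs)
    return out


def _observe_patient(rng, truth: PatientTruth, cfg: SimConfig,
                     poly: RegionSet, prov: dict):
    """OGM channels for one patient: SV calls, CNV calls, artifacts,
    polymorphisms.  Returns (sv_calls, cnv_calls)."""
    pid = truth.patient_id
    sv_calls: list[SvCall] = []
    cnv_calls: list[CnvCall] = []
    seq = iter(range(1, 10_000))

    def sv_conf(sv_type: SvType) -> float:
        thr = DEFAULT_CONF_THRESHOLDS[sv_type]
        return float(rng.uniform(thr, 1.0))

    def good_support():
        return dict(
            raw_conf_left=float(rng.uniform(10.0, 60.0)),
            raw_conf_right=float(rng.uniform(10.0, 60.0)),
            labels_bp1=int(rng.integers(11, 61)),
            labels_bp2=int(rng.integers(11, 61)),
            self_molecules=int(rng.integers(5, 176)),
        )

    def emit_sv(truth_id, sv_type, bp1, bp2, size, cf, support=None):
        cid = f"{pid}.sv{next(seq)}"
        sv_calls.append(SvCall(
            call_id=cid, sv_type=sv_type, bp1=bp1, bp2=bp2, size_bp=size,
            confidence=sv_conf(sv_type), vaf=cf, patient_id=pid,
            **(support or good_support())))
        prov[cid] = truth_id

    def emit_cnv(truth_id, interval, sign, cf):
        cid = f"{pid}.cnv{next(seq)}"
        cnv_calls.append(CnvCall(
            call_id=cid, interval=interval, cnv_type=sign,
            confidence=float(rng.uniform(0.99, 1.0)), cell_fraction=cf,
            patient_id=pid))
        prov[cid] = truth_id

    for ab in truth.abnormalities:
        cf = ab.clone_fraction
        p_sv = detection_probability(cf, cfg.sv_detect_floor,
                                     cfg.soft_sensitivity_top)
        p_cnv = detection_probability(cf, cfg.cnv_detect_floor,
                                      cfg.soft_sensitivity_top)
        if ab.ab_class in (AbClass.cnv_gain, AbClass.cnv_loss):
            sign = CnvType.gain if ab.ab_class == AbClass.cnv_gain else CnvType.loss
            if rng.random() < p_cnv:
                emit_cnv(ab.truth_id, ab.interval, sign, cf)
            # the SV channel may dual-call the same lesion
            if rng.random() < cfg.dual_call_prob and rng.random() < p_sv:
                jitter = int(rng.integers(0, 20_000))
                s = ab.interval.start + jitter
                e = max(s, ab.interval.end - int(rng.integers(0, 20_000)))
                if sign == CnvType.loss and e - s >= 5_000_000:
                    emit_sv(ab.truth_id, SvType.intra_translocation,
                            (ab.interval.chrom, s), (ab.interval.chrom, e), 0, cf)
                else:
                    svt = SvType.duplication if sign == CnvType.gain else SvType.deletion
                    emit_sv(ab.truth_id, svt, (ab.interval.chrom, s),
                            (ab.interval.chrom, e), e - s, cf)
        else:
            if rng.random() >= p_sv:
                continue
            svt = SvType(ab.ab_class.value)
            if svt in (SvType.deletion, SvType.duplication, SvType.inversion):
                emit_sv(ab.truth_id, svt, ab.bp1, ab.bp2,
                        ab.bp2[1] - ab.bp1[1], cf)
            elif svt == SvType.intra_translocation:
                emit_sv(ab.truth_id, svt, ab.bp1, ab.bp2, 0, cf)
            else:
                emit_sv(ab.truth_id, svt, ab.bp1, ab.bp2, 0, cf)

    # artifact translocations: low labels or low raw confidence on a partner
    for j in range(rng.poisson(cfg.artifact_translocation_rate)):
        placer = _Placer(rng, cfg.mask_flank_bp, poly)
        bp1, bp2 = placer.point(), placer.point()
        while bp2[0] == bp1[0]:
            bp2 = placer.point()
        support = good_support()
        if rng.random() < 0.5:
            support["labels_bp1"] = int(rng.integers(1, 11))
        else:
            support["labels_bp1"] = int(rng.integers(1, 11))
            support["raw_conf_left"] = float(rng.uniform(0.0, 9.9))
        cid = f"{pid}.sv{next(seq)}"
        sv_calls.append(SvCall(
            call_id=cid, sv_type=SvType.inter_translocation, bp1=bp1, bp2=bp2,
            size_bp=0, confidence=float(rng.uniform(0.65, 1.0)),
            patient_id=pid, **support))
        prov[cid] = f"artifact:{pid}.a{j+1}"

    # benign polymorphism CNVs at exact catalog coordinates
    for j in range(rng.poisson(cfg.polymorphism_rate)):
        region = poly.regions[int(rng.integers(0, len(poly.regions)))]
        cid = f"{pid}.cnv{next(seq)}"
        cnv_calls.append(CnvCall(
            call_id=cid, interval=region.interval, cnv_type=region.sign,
            confidence=float(rng.uniform(0.99, 1.0)),
            cell_fraction=float(rng.uniform(0.3, 0.6)), patient_id=pid))
        prov[cid] = f"polymorphism:{pid}.p{j+1}"

    cnv_calls = inject_segmentation(cnv_calls, cfg, rng)
    for call in cnv_calls:  # segmentation renames call ids; keep pointers
        if call.call_id not in prov:
            prov[call.call_id] = prov[call.call_id.rsplit(".s", 1)[0]]
    return sv_calls, cnv_calls


def _band_round(rng, pos: int, jitter: int) -> int:
    return max(1, pos + int(rng.integers(-jitter, jitter + 1)))


def _known_records(rng, truth: PatientTruth, cfg: SimConfig):
    """CBA / FISH / CMA observations of the truth."""
    pid = truth.patient_id
    cba, fish, cma = [], [], []
    seq = iter(range(1, 10_000))

    for ab in truth.abnormalities:
        cf = ab.clone_fraction
        # --- CMA: unbalanced lesions only, hard sensitivity floor
        if ab.ab_class in (AbClass.cnv_gain, AbClass.cnv_loss, AbClass.deletion,
                           AbClass.duplication) and ab.interval is not None \
                and cf >= cfg.cma_floor:
            sign = KnownClass.cnv_gain if ab.ab_class in (
                AbClass.cnv_gain, AbClass.duplication) else KnownClass.cnv_loss
            j = int(rng.integers(0, 50_000))
            iv = GenomicInterval(ab.interval.chrom,
                                 max(1, ab.interval.start - j),
                                 ab.interval.end + int(rng.integers(0, 50_000)))
            cma.append(KnownAberration(
                ab_id=f"{pid}.cma{next(seq)}", patient_id=pid,
                technique=Technique.CMA, ab_class=sign, interval=iv,
                clone_fraction=cf))
        # --- FISH: classic loci only
        for name, cls, locus, _ in CLASSIC_LESIONS:
            if ab.interval is not None and ab.ab_class == cls and \
                    ab.interval.overlap_bp(locus) > 0 and cf >= cfg.fish_floor:
                kc = KnownClass.trisomy if name == "tri12" else KnownClass.cnv_loss
                fish.append(KnownAberration(
                    ab_id=f"{pid}.fish{next(seq)}", patient_id=pid,
                    technique=Technique.FISH, ab_class=kc,
                    interval=ab.interval, clone_fraction=cf))
        # --- CBA: band resolution, clone-selection noise
        p_cba = min(1.0, cf / cfg.cba_detect_scale) * 0.9
        if rng.random() >= p_cba:
            continue
        jit = cfg.cba_band_jitter_bp
        if ab.ab_class == AbClass.inter_translocation:
            if rng.random() < cfg.cba_add_prob:
                cba.append(KnownAberration(
                    ab_id=f"{pid}.cba{next(seq)}", patient_id=pid,
                    technique=Technique.CBA, ab_class=KnownClass.add_breakpoint,
                    bp1=(ab.bp1[0], _band_round(rng, ab.bp1[1], jit)),
                    bp_tolerance_bp=10_000_000, clone_fraction=cf))
            else:
                cba.append(KnownAberration(
                    ab_id=f"{pid}.cba{next(seq)}", patient_id=pid,
                    technique=Technique.CBA, ab_class=KnownClass.translocation,
                    bp1=(ab.bp1[0], _band_round(rng, ab.bp1[1], jit)),
                    bp2=(ab.bp2[0], _band_round(rng, ab.bp2[1], jit)),
                    bp_tolerance_bp=10_000_000, clone_fraction=cf))
        elif ab.ab_class == AbClass.inversion:
            cba.append(KnownAberration(
                ab_id=f"{pid}.cba{next(seq)}", patient_id=pid,
                technique=Technique.CBA, ab_class=KnownClass.inversion,
                bp1=(ab.bp1[0], _band_round(rng, ab.bp1[1], jit)),
                bp2=(ab.bp2[0], _band_round(rng, ab.bp2[1], jit)),
                bp_tolerance_bp=10_000_000, clone_fraction=cf))
        elif ab.interval is not None and ab.interval.size >= 10_000_000:
            sign = KnownClass.cnv_gain if ab.ab_class in (
                AbClass.cnv_gain, AbClass.duplication) else KnownClass.cnv_loss
            cba.append(KnownAberration(
                ab_id=f"{pid}.cba{next(seq)}", patient_id=pid,
                technique=Technique.CBA, ab_class=sign,
                interval=GenomicInterval(
                    ab.interval.chrom,
                    max(1, _band_round(rng, ab.interval.start, jit)),
                    _band_round(rng, ab.interval.end, jit) + jit),
                bp_tolerance_bp=10_000_000, clone_fraction=cf))
    return cba, fish, cma


# ------------------------------------------------------------- cohort

def simulate_cohort(cfg: Optional[SimConfig] = None,
                    seed: Optional[int] = None) -> SimulatedCohort:
    """Generate a fully tracked cohort; reproducible given (config, seed)."""
    cfg = cfg or SimConfig()
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    streams = root.spawn(cfg.n_patients + 1)
    poly = polymorphism_catalog(cfg.mask_flank_bp)
    masks = RegionSet("masked", [
        Region(GenomicInterval(c, s, e))
        for c, s, e in centromere_telomere_intervals(cfg.mask_flank_bp)])

    patients: dict[str, PatientTruth] = {}
    prov: dict[str, str] = {}
    sv_all: list[SvCall] = []
    cnv_all: list[CnvCall] = []
    cba_all, fish_all, cma_all, clinical = [], [], [], []

    h0 = math.log(2) / cfg.ttft_median_nonck_months
    for i in range(cfg.n_patients):
        rng = streams[i]
        pid = f"P{i+1:03d}"
        is_ck = bool(rng.random() < cfg.ck_fraction)
        placer = _Placer(rng, cfg.mask_flank_bp, poly)
        abns, ct_chrom = _draw_true_abnormalities(rng, placer, pid, is_ck, cfg)

        n_true = len(abns)
        hazard = h0 * (cfg.complex_hazard_ratio if n_true >= 10 else 1.0)
        t_event = float(rng.exponential(1.0 / hazard))
        t_censor = float(rng.uniform(6.0, 95.0))
        treated = t_event <= t_censor
        tp53 = bool(rng.random() < (0.6 if n_true >= 10 else 0.05)) or any(
            a.ab_class == AbClass.cnv_loss and a.interval is not None
            and a.interval.chrom == "17" and a.interval.start < 11_000_000
            for a in abns)
        truth = PatientTruth(
            patient_id=pid, is_ck=is_ck, abnormalities=abns,
            chromothripsis_chrom=ct_chrom,
            ttft_months=round(t_event, 1) if treated else None,
            follow_up_months=round(t_censor, 1),
            treated=treated,
            pre_treated=bool(rng.random() < cfg.pre_treated_rate),
            tp53_abnormal=tp53)
        patients[pid] = truth

        sv_calls, cnv_calls = _observe_patient(rng, truth, cfg, poly, prov)
        sv_all.extend(sv_calls)
        cnv_all.extend(cnv_calls)
        cba, fish, cma = _known_records(rng, truth, cfg)
        cba_all.extend(cba)
        fish_all.extend(fish)
        cma_all.extend(cma)
        clinical.append(ClinicalRecord(
            patient_id=pid,
            ttft_months=truth.ttft_months,
            treated=treated, pre_treated=truth.pre_treated,
            tp53_abnormal=tp53,
            ck_by_cba=len(cba) >= 3, n_abn_cba=len(cba), n_abn_cma=len(cma),
            follow_up_months=truth.follow_up_months))

    return SimulatedCohort(cfg, TruthSet(patients, prov), sv_all, cnv_all,
                           cba_all, fish_all, cma_all, clinical, masks, poly)


# ------------------------------------------------------------- scoring

@dataclass
class RecoveryReport:
    count_error: dict[str, int]          # observed countable - true, per patient
    risk_confusion: dict[tuple, int]     # (true class, observed class) -> n
    risk_recovery: float                 # fraction of patients classed correctly
    risk_recovery_clonal: float          # same, among all-clonal (cf>=floor) patients
    n_clonal_patients: int
    detection_by_cf: list[tuple]         # (cf bin midpoint, rate, n)
    artifact_precision: float
    artifact_recall: float


def evaluate_recovery(cohort: SimulatedCohort, records,
                      clonal_floor: float = 0.3) -> RecoveryReport:
    """Score pipeline output against the generator's truth."""
    from .complexity import count_abnormalities, classify_risk, OGM_SCHEME

    prov = cohort.truth.provenance
    counts = count_abnormalities(records)
    count_error, confusion = {}, defaultdict(int)
    ok = total = ok_clonal = n_clonal = 0
    for pid, truth in cohort.truth.patients.items():
        n_obs = counts[pid].n_total if pid in counts else 0
        count_error[pid] = n_obs - truth.n_true
        obs_class = classify_risk(n_obs, OGM_SCHEME)
        confusion[(truth.risk_class, obs_class)] += 1
        total += 1
        ok += obs_class == truth.risk_class
        if truth.min_clone_fraction >= clonal_floor:
            n_clonal += 1
            ok_clonal += obs_class == truth.risk_class

    # detection rate as a function of clone fraction (true abnormalities)
    detected_truth = set()
    for rec in records:
        if rec.countable:
            for cid in rec.provenance:
                tid = prov.get(cid, "")
                if ":" in tid and not tid.startswith(("artifact", "polymorphism")):
                    detected_truth.add(tid)
    bins = np.linspace(0.0, 1.0, 11)
    per_bin = defaultdict(lambda: [0, 0])
    for truth in cohort.truth.patients.values():
        for ab in truth.abnormalities:
            b = min(9, int(ab.clone_fraction * 10))
            per_bin[b][1] += 1
            per_bin[b][0] += ab.truth_id in detected_truth
    detection_by_cf = [((bins[b] + bins[b + 1]) / 2, hit / n, n)
                       for b, (hit, n) in sorted(per_bin.items()) if n]

    # artifact filter scored on flagged vs truth-labeled artifact calls
    tp = fp = fn = 0
    from .records import Status
    for rec in records:
        if not rec.is_translocation:
            continue
        is_true_artifact = all(
            prov.get(cid, "").startswith("artifact") for cid in rec.provenance)
        if rec.status == Status.artifact_flagged:
            tp += is_true_artifact
            fp += not is_true_artifact
        elif is_true_artifact:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0

    return RecoveryReport(
        count_error=count_error,
        risk_confusion=dict(confusion),
        risk_recovery=ok / total,
        risk_recovery_clonal=ok_clonal / n_clonal if n_clonal else 1.0,
        n_clonal_patients=n_clonal,
        detection_by_cf=detection_by_cf,
        artifact_precision=precision,
        artifact_recall=recall,
    )
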