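"""Concordance: inventory compilation, matching rules, discrepancy reasons,
summaries and novel-translocation classification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ogmcll.concordance import (
    MatchCriteria,
    assign_discrepancy_reasons,
    build_known_inventory,
    classify_novel_translocations,
    match_calls,
    summarize_concordance,
)
from ogmcll.records import (
    AbClass,
    AbnormalityRecord,
    DiscrepancyReason,
    GenomicInterval,
    KnownAberration,
    KnownClass,
    NovelCategory,
    Region,
    RegionSet,
    Status,
    Technique,
)


def make_rec(ab_id="a1", ab_class=AbClass.cnv_loss, chrom="13",
             start=50_000_000, end=50_900_000, bp1=None, bp2=None,
             status=Status.kept, patient_id="P1", labels=(30, 30)):
    interval = None
    if bp1 is None:
        interval = GenomicInterval(chrom, start, end)
    return AbnormalityRecord(
        ab_id=ab_id, patient_id=patient_id, source="cnv_pipeline",
        ab_class=ab_class, status=status, provenance=[ab_id],
        interval=interval, bp1=bp1, bp2=bp2,
        labels_bp1=labels[0], labels_bp2=labels[1])


def known_cnv(ab_id="k1", technique=Technique.CMA, chrom="13",
              start=50_000_000, end=50_900_000, sign="loss",
              clone_fraction=0.5, patient_id="P1"):
    cls = KnownClass.cnv_loss if sign == "loss" else KnownClass.cnv_gain
    return KnownAberration(ab_id, patient_id, technique, cls,
                           interval=GenomicInterval(chrom, start, end),
                           clone_fraction=clone_fraction)


def known_transloc(ab_id="t1", bp1=("11", 69_000_000), bp2=("14", 106_000_000),
                   tolerance=10_000_000, patient_id="P1"):
    return KnownAberration(ab_id, patient_id, Technique.CBA,
                           KnownClass.translocation, bp1=bp1, bp2=bp2,
                           bp_tolerance_bp=tolerance)


# ------------------------------------------------------------ inventory

def test_inventory_prefers_cma_coordinates():
    fish = known_cnv("f1", Technique.FISH, start=50_100_000, end=50_500_000)
    cma = known_cnv("m1", Technique.CMA)
    inv = build_known_inventory([], [fish], [cma])
    assert [k.ab_id for k in inv] == ["m1"]


def test_inventory_keeps_fish_only_and_conflicting_signs(caplog):
    fish_only = known_cnv("f1", Technique.FISH, chrom="17", start=7_400_000,
                          end=7_700_000)
    fish_conflict = known_cnv("f2", Technique.FISH, sign="gain")
    cma = known_cnv("m1", Technique.CMA)
    with caplog.at_level("WARNING"):
        inv = build_known_inventory([], [fish_only, fish_conflict], [cma])
    assert {k.ab_id for k in inv} == {"m1", "f1", "f2"}
    assert "conflicting" in caplog.text


def test_inventory_passes_balanced_rearrangements_through():
    inv = build_known_inventory([known_transloc()], [], [known_cnv("m1")])
    assert {k.ab_id for k in inv} == {"t1", "m1"}


# ------------------------------------------------------------- matching

def test_cnv_match_by_reciprocal_overlap():
    known = [known_cnv()]
    rec = make_rec(start=50_200_000, end=51_100_000)  # RO ~0.64
    (res,) = match_calls(known, [rec])
    assert res.matched and res.ogm_ids == ["a1"]
    assert res.coord_diff_bp == 200_000


def test_cnv_match_by_boundary_tolerance_when_overlap_fails():
    # tiny known lesion inside a much larger OGM call: RO < 0.25 but both
    # boundaries are within 5 Mb
    known = [known_cnv(start=50_000_000, end=50_100_000)]
    rec = make_rec(start=49_000_000, end=53_000_000)
    (res,) = match_calls(known, [rec])
    assert res.matched


def test_cnv_no_match_wrong_sign_or_patient():
    known = [known_cnv()]
    assert not match_calls(known, [make_rec(ab_class=AbClass.cnv_gain)])[0].matched
    assert not match_calls(known, [make_rec(patient_id="P2")])[0].matched


def test_cnv_boundary_tolerance_is_sharp():
    known = [known_cnv(start=50_000_000, end=50_100_000)]
    just_in = make_rec(start=45_000_000, end=55_100_000)
    just_out = make_rec(start=44_999_999, end=55_100_000)
    assert match_calls(known, [just_in])[0].matched
    assert not match_calls(known, [just_out])[0].matched


def test_translocation_match_within_band_tolerance():
    known = [known_transloc()]
    rec = make_rec(ab_class=AbClass.inter_translocation,
                   bp1=("11", 69_022_000), bp2=("14", 101_000_000))
    (res,) = match_calls(known, [rec])
    assert res.matched
    # coordinate differences are summarized for CNV matches only: band-level
    # karyotype breakpoints make the comparison meaningless here
    assert res.coord_diff_bp is None


def test_translocation_requires_both_breakpoints():
    known = [known_transloc()]
    rec = make_rec(ab_class=AbClass.inter_translocation,
                   bp1=("11", 69_000_000), bp2=("2", 50_000_000))
    assert not match_calls(known, [rec])[0].matched


def test_add_breakpoint_needs_single_hit():
    known = [KnownAberration("k", "P1", Technique.CBA, KnownClass.add_breakpoint,
                             bp1=("8", 128_000_000), bp_tolerance_bp=10_000_000)]
    rec = make_rec(ab_class=AbClass.inter_translocation,
                   bp1=("8", 125_000_000), bp2=("3", 10_000_000))
    assert match_calls(known, [rec])[0].matched


def test_known_inversion_accepts_intra_translocation_call():
    known = [KnownAberration("k", "P1", Technique.CBA, KnownClass.inversion,
                             bp1=("2", 30_000_000), bp2=("2", 90_000_000),
                             bp_tolerance_bp=10_000_000)]
    rec = make_rec(ab_class=AbClass.intra_translocation,
                   bp1=("2", 31_000_000), bp2=("2", 88_000_000))
    assert match_calls(known, [rec])[0].matched
    cnv = make_rec(ab_class=AbClass.cnv_loss, chrom="2",
                   start=30_000_000, end=90_000_000)
    assert not match_calls(known, [cnv])[0].matched


def test_best_candidate_wins_and_non_countable_excluded():
    known = [known_cnv()]
    tight = make_rec("tight", start=50_010_000, end=50_890_000)
    loose = make_rec("loose", start=50_000_000, end=52_000_000)
    dropped = make_rec("gone", status=Status.filtered_size,
                       start=50_000_000, end=50_900_000)
    # 'gone' would be perfect but is not countable
    (res,) = match_calls(known, [loose, dropped, tight])
    assert res.ogm_ids == ["tight"]


def test_match_is_invariant_under_record_order():
    known = [known_cnv(), known_transloc()]
    recs = [make_rec("a", start=50_100_000, end=50_800_000),
            make_rec("b", ab_class=AbClass.inter_translocation,
                     bp1=("11", 69_000_100), bp2=("14", 106_000_100)),
            make_rec("c", start=49_000_000, end=50_500_000)]
    base = [(r.known_id, r.matched, tuple(r.ogm_ids))
            for r in match_calls(known, recs)]
    for perm in itertools.permutations(recs):
        got = [(r.known_id, r.matched, tuple(r.ogm_ids))
               for r in match_calls(known, list(perm))]
        assert got == base


@settings(max_examples=40, deadline=None)
@given(st.integers(-20_000_000, 20_000_000))
def test_match_is_invariant_under_coordinate_shift(shift):
    """Shifting the known lesion and the call together never changes the
    outcome (coordinates clipped to stay positive)."""
    base = 60_000_000
    k_start, k_end = base + shift, base + 900_000 + shift
    r_start, r_end = base + 200_000 + shift, base + 1_100_000 + shift
    if k_start < 1 or r_start < 1:
        return
    known = [known_cnv(start=k_start, end=k_end)]
    rec = make_rec(start=r_start, end=r_end)
    assert match_calls(known, [rec])[0].matched


@settings(max_examples=30, deadline=None)
@given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
def test_loosening_criteria_is_monotone(ro_a, ro_b):
    lo, hi = sorted((ro_a, ro_b))
    known = [known_cnv()]
    rec = make_rec(start=50_300_000, end=56_000_000)
    strict = match_calls(known, [rec], MatchCriteria(
        cnv_reciprocal_overlap_min=hi, cnv_bp_tolerance_bp=0))
    loose = match_calls(known, [rec], MatchCriteria(
        cnv_reciprocal_overlap_min=lo, cnv_bp_tolerance_bp=0))
    assert loose[0].matched or not strict[0].matched


def _brute_force_cnv_match(known, rec, crit):
    """Literal restatement of the matching definition."""
    if rec.footprint is None or known.interval is None:
        return False
    if rec.patient_id != known.patient_id:
        return False
    if rec.footprint.chrom != known.interval.chrom:
        return False
    sign_ok = {("loss", AbClass.cnv_loss), ("loss", AbClass.deletion),
               ("gain", AbClass.cnv_gain), ("gain", AbClass.duplication)}
    if (known.sign.value, rec.ab_class) not in sign_ok:
        return False
    a, b = known.interval, rec.footprint
    inter = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    ro = min(inter / a.size, inter / b.size)
    diff = max(abs(a.start - b.start), abs(a.end - b.end))
    return ro >= crit.cnv_reciprocal_overlap_min or \
        diff <= crit.cnv_bp_tolerance_bp


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 60), st.integers(1, 40), st.integers(0, 60),
       st.integers(1, 40), st.booleans())
def test_cnv_match_agrees_with_definition(ks, kw, rs, rw, same_sign):
    crit = MatchCriteria()
    known = known_cnv(start=10_000_000 + ks * 250_000,
                      end=10_000_000 + ks * 250_000 + kw * 250_000)
    rec = make_rec(start=10_000_000 + rs * 250_000,
                   end=10_000_000 + rs * 250_000 + rw * 250_000,
                   ab_class=AbClass.cnv_loss if same_sign else AbClass.cnv_gain)
    (res,) = match_calls([known], [rec], crit)
    assert res.matched == _brute_force_cnv_match(known, rec, crit)


# ------------------------------------------------- discrepancy reasons

def _reason_for(k, masks=None, cen_tel=None, chromo=None):
    results = match_calls([k], [])
    out = assign_discrepancy_reasons(
        results, {k.ab_id: k}, masks or RegionSet("masked"),
        cen_tel or RegionSet("centromere_telomere"), chromo)
    return out[0].discrepancy_reason


def test_reason_precedence_chain():
    near_cen = known_cnv(chrom="13", start=17_500_000, end=18_000_000,
                         clone_fraction=0.1)
    cen_tel = RegionSet("centromere_telomere",
                        [Region(GenomicInterval("13", 16_000_000, 19_000_000))])
    masks = RegionSet("masked",
                      [Region(GenomicInterval("13", 17_000_000, 19_000_000))])
    # centromeric/telomeric outranks both masking and sensitivity
    assert _reason_for(near_cen, masks, cen_tel) == \
        DiscrepancyReason.centromeric_telomeric
    # without the annotation, masking outranks sensitivity
    assert _reason_for(near_cen, masks) == DiscrepancyReason.masked_region
    # without masking, low clone fraction explains the miss
    assert _reason_for(near_cen) == DiscrepancyReason.sensitivity


def test_reason_small_cnv_in_chromothripsis_then_unknown():
    small = known_cnv(start=50_000_000, end=50_100_000, clone_fraction=0.6)
    chromo = {("P1", "13"): True}
    assert _reason_for(small, chromo=chromo) == \
        DiscrepancyReason.small_within_chromothripsis
    assert _reason_for(small) == DiscrepancyReason.unknown
    big = known_cnv(start=50_000_000, end=52_000_000, clone_fraction=0.6)
    assert _reason_for(big, chromo=chromo) == DiscrepancyReason.unknown


def test_sensitivity_floor_is_strict():
    at_floor = known_cnv(clone_fraction=0.20)
    below = known_cnv(clone_fraction=0.19)
    assert _reason_for(at_floor) == DiscrepancyReason.unknown
    assert _reason_for(below) == DiscrepancyReason.sensitivity


# --------------------------------------------------------------- summary

def test_summary_counts_classes_strata_and_reasons():
    known = [known_cnv("k1"), known_cnv("k2", patient_id="P2"),
             known_transloc("k3")]
    recs = [make_rec("a", start=50_100_000, end=50_800_000)]
    results = match_calls(known, recs)
    results = assign_discrepancy_reasons(
        results, {k.ab_id: k for k in known}, RegionSet("masked"),
        RegionSet("centromere_telomere"))
    s = summarize_concordance(results, strata={"P1": "CK", "P2": "non-CK"})
    assert s.n_total == 3 and s.n_matched == 1
    assert s.detection_pct == pytest.approx(100 / 3)
    assert s.per_class["cnv_loss"] == {"total": 2, "matched": 1, "rate": 0.5}
    assert s.per_stratum["CK"]["total"] == 2
    assert s.per_stratum["non-CK"]["matched"] == 0
    assert sum(s.reason_histogram.values()) == 2
    assert s.median_coord_diff_bp == 100_000


def test_summary_refuses_empty_results():
    with pytest.raises(ValueError):
        summarize_concordance([])


# ------------------------------------------ novel translocation classes

def test_novel_classification_precedence():
    confirming = make_rec("conf", ab_class=AbClass.inter_translocation,
                          bp1=("11", 69_000_000), bp2=("14", 106_000_000))
    near_cnv = make_rec("near", ab_class=AbClass.inter_translocation,
                        bp1=("13", 50_010_000), bp2=("2", 30_000_000))
    invalidated = make_rec("bad", ab_class=AbClass.inter_translocation,
                           bp1=("4", 10_000_000), bp2=("7", 20_000_000))
    flagged = make_rec("flag", ab_class=AbClass.inter_translocation,
                       bp1=("5", 10_000_000), bp2=("9", 20_000_000),
                       status=Status.artifact_flagged)
    solid = make_rec("ok", ab_class=AbClass.inter_translocation,
                     bp1=("6", 10_000_000), bp2=("10", 20_000_000))
    not_transloc = make_rec("cnv")
    out = classify_novel_translocations(
        [confirming, near_cnv, invalidated, flagged, solid, not_transloc],
        known=[known_transloc()], cma_segments=[known_cnv("m1")],
        invalidated_ids={"bad"})
    got = {c.ogm_id: c.category for c in out}
    assert "cnv" not in got
    assert got == {
        "conf": NovelCategory.real,
        "near": NovelCategory.potentially_real,
        "bad": NovelCategory.false_positive,
        "flag": NovelCategory.potential_false_positive,
        "ok": NovelCategory.real,
    }
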