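"""Curation stages: printed-threshold boundaries, merging, deduplication,
artifact flagging, rescue, chromothripsis, and the pipeline invariants."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ogmcll.curation import (
    CurationConfig,
    apply_size_filters,
    curate,
    deduplicate_sv_cnv,
    detect_chromothripsis,
    flag_translocation_artifacts,
    merge_segmented_cnvs,
    prefilter_confidence,
    targeted_rescue,
)
from ogmcll.records import (
    AbClass,
    CnvType,
    GenomicInterval,
    KnownAberration,
    KnownClass,
    Region,
    RegionSet,
    Status,
    SvType,
    Technique,
    ValidationError,
)

from conftest import make_cnv, make_sv


# ---------------------------------------------------------- thresholds

@pytest.mark.parametrize("sv_type,conf,kept", [
    ("inversion", 0.69, False), ("inversion", 0.70, True),
    ("inter_translocation", 0.64, False), ("inter_translocation", 0.65, True),
    ("intra_translocation", 0.29, False), ("intra_translocation", 0.30, True),
    ("deletion", -0.01, False), ("deletion", 0.0, True),
    ("duplication", -0.5, True),  # the duplication threshold admits all >= -1
])
def test_confidence_prefilter_boundaries(sv_type, conf, kept, default_cfg):
    if sv_type == "inversion":
        sv = make_sv(sv_type=sv_type, pos1=10_000_000, pos2=11_000_000,
                     confidence=conf)
    elif sv_type == "inter_translocation":
        sv = make_sv(sv_type=sv_type, chrom="1", chrom2="2", confidence=conf)
    else:
        sv = make_sv(sv_type=sv_type, pos1=10_000_000, pos2=10_500_000,
                     confidence=conf)
    part = prefilter_confidence([sv], [], default_cfg)
    assert bool(part.sv_kept) == kept
    if not kept:
        assert part.sv_dropped[0][1] == Status.filtered_confidence


@pytest.mark.parametrize("conf,kept", [(0.98, False), (0.99, True)])
def test_cnv_confidence_boundary(conf, kept, default_cfg):
    part = prefilter_confidence([], [make_cnv(confidence=conf)], default_cfg)
    assert bool(part.cnv_kept) == kept


def test_unknown_threshold_type_is_an_error():
    cfg = CurationConfig(conf_thresholds={SvType.deletion: 0.0})
    with pytest.raises(ValidationError):
        prefilter_confidence([make_sv(sv_type="inversion", pos1=1_000_000,
                                      pos2=2_000_000)], [], cfg)


@pytest.mark.parametrize("size,kept", [(99_999, False), (100_000, True)])
def test_sv_size_boundary_inclusive_at_100kb(size, kept, default_cfg):
    sv = make_sv(sv_type="deletion", pos1=10_000_000, pos2=10_000_000 + size)
    part = apply_size_filters(prefilter_confidence([sv], [], default_cfg),
                              default_cfg)
    assert bool(part.sv_kept) == kept


@pytest.mark.parametrize("size,kept", [(500_000, False), (500_001, True)])
def test_cnv_size_boundary_strict_above_500kb(size, kept, default_cfg):
    cnv = make_cnv(start=50_000_000, end=50_000_000 + size - 1)
    part = apply_size_filters(prefilter_confidence([], [cnv], default_cfg),
                              default_cfg)
    assert bool(part.cnv_kept) == kept


def test_translocations_exempt_from_size_filter(default_cfg):
    sv = make_sv(sv_type="inter_translocation", chrom="1", chrom2="2", size=0)
    part = apply_size_filters(prefilter_confidence([sv], [], default_cfg),
                              default_cfg)
    assert part.sv_kept


# ------------------------------------------------------ region filters

def _mask(chrom, start, end):
    return RegionSet("masked", [Region(GenomicInterval(chrom, start, end))])


def test_sv_masked_when_breakpoint_in_mask(default_cfg):
    from ogmcll.curation import filter_regions
    sv = make_sv(pos1=50_000_000, pos2=50_200_000)
    part = prefilter_confidence([sv], [], default_cfg)
    out = filter_regions(part, _mask("13", 49_900_000, 50_100_000),
                         RegionSet("polymorphism"), default_cfg)
    assert out.sv_dropped[0][1] == Status.filtered_masked


@pytest.mark.parametrize("poly_sign,filtered", [("loss", True), ("gain", False)])
def test_polymorphism_filter_requires_same_sign(poly_sign, filtered, default_cfg):
    from ogmcll.curation import filter_regions
    cnv = make_cnv(start=50_000_000, end=50_900_000, cnv_type="loss")
    poly = RegionSet("polymorphism", [
        Region(GenomicInterval("13", 50_050_000, 50_850_000), poly_sign)])
    part = prefilter_confidence([], [cnv], default_cfg)
    out = filter_regions(part, RegionSet("masked"), poly, default_cfg)
    assert bool(out.cnv_dropped) == filtered
    if filtered:
        assert out.cnv_dropped[0][1] == Status.filtered_polymorphism


# ------------------------------------------------------------- merging

def test_merge_segmented_cnvs_respects_gap_and_sign(default_cfg):
    a = make_cnv("a", start=50_000_000, end=50_900_000)
    b = make_cnv("b", start=51_000_000, end=51_800_000)   # gap 100 Kb -> merge
    g = make_cnv("g", start=52_000_000, end=52_900_000, cnv_type="gain")
    merged = merge_segmented_cnvs([a, b, g], default_cfg)
    losses = [c for c in merged if c.cnv_type == CnvType.loss]
    assert len(losses) == 1
    assert (losses[0].interval.start, losses[0].interval.end) == \
        (50_000_000, 51_800_000)
    assert losses[0].provenance == ["a", "b"]
    assert len(merged) == 2  # the gain is untouched


def _brute_force_merge(calls, gap):
    """Union-find over all pairs: the independent oracle for gap-merging."""
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(calls)), 2):
        a, b = calls[i], calls[j]
        if a.cnv_type != b.cnv_type or a.interval.chrom != b.interval.chrom \
                or a.patient_id != b.patient_id:
            continue
        gap_ij = max(a.interval.start, b.interval.start) - \
            min(a.interval.end, b.interval.end) - 1
        if gap_ij <= gap:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(calls[i])
    return sorted(
        (g[0].interval.chrom, g[0].cnv_type.value,
         min(c.interval.start for c in g), max(c.interval.end for c in g))
        for g in groups.values())


@settings(max_examples=60, deadline=None)
@given(st.lists(
    st.tuples(st.integers(0, 40), st.integers(1, 30), st.booleans()),
    min_size=0, max_size=12))
def test_merge_matches_union_find_oracle_and_is_idempotent(segments):
    cfg = CurationConfig()
    calls = [
        make_cnv(f"c{i}", chrom="4", start=60_000_000 + s * 400_000,
                 end=60_000_000 + s * 400_000 + w * 300_000,
                 cnv_type="loss" if is_loss else "gain")
        for i, (s, w, is_loss) in enumerate(segments)]
    merged = merge_segmented_cnvs(calls, cfg)
    got = sorted((c.interval.chrom, c.cnv_type.value, c.interval.start,
                  c.interval.end) for c in merged)
    assert got == _brute_force_merge(calls, cfg.cnv_merge_gap_bp)
    again = merge_segmented_cnvs(merged, cfg)
    assert sorted((c.interval.start, c.interval.end) for c in again) == \
        sorted((c.interval.start, c.interval.end) for c in merged)


# ------------------------------------------------------------- dedup

def test_cnv_loss_absorbed_by_deletion_keeps_sv_coordinates(default_cfg):
    cnv = make_cnv(start=50_000_000, end=50_950_000)
    sv = make_sv(sv_type="deletion", pos1=50_020_000, pos2=50_930_000)
    records = deduplicate_sv_cnv([sv], [cnv], default_cfg)
    survivors = [r for r in records if r.countable]
    assert len(survivors) == 1
    assert survivors[0].source == "merged"
    assert survivors[0].footprint.start == 50_020_000
    assert survivors[0].footprint.end == 50_930_000
    tombs = [r for r in records if r.status == Status.deduplicated]
    assert len(tombs) == 1 and tombs[0].dedup_into == survivors[0].ab_id


def test_large_intra_translocation_bracketing_loss_relabeled_deletion(default_cfg):
    cnv = make_cnv(chrom="11", start=60_000_000, end=70_000_000)
    sv = make_sv(sv_type="intra_translocation", chrom="11",
                 pos1=60_100_000, pos2=69_800_000, size=0)
    records = deduplicate_sv_cnv([sv], [cnv], default_cfg)
    survivor = next(r for r in records if r.countable)
    assert survivor.ab_class == AbClass.deletion
    assert survivor.source == "merged"


def test_gain_does_not_deduplicate_against_deletion(default_cfg):
    cnv = make_cnv(cnv_type="gain", start=50_000_000, end=50_950_000)
    sv = make_sv(sv_type="deletion", pos1=50_020_000, pos2=50_930_000)
    records = deduplicate_sv_cnv([sv], [cnv], default_cfg)
    assert sum(r.countable for r in records) == 2


def test_cnv_matching_two_svs_goes_to_highest_overlap(default_cfg):
    cnv = make_cnv(start=50_000_000, end=51_000_000)
    close = make_sv("close", "deletion", pos1=50_010_000, pos2=50_990_000)
    loose = make_sv("loose", "deletion", pos1=50_000_000, pos2=51_500_000)
    records = deduplicate_sv_cnv([close, loose], [cnv], default_cfg)
    tomb = next(r for r in records if r.status == Status.deduplicated)
    assert tomb.dedup_into == "sv:close"
    assert sum(r.countable for r in records) == 2  # the other SV untouched


# ----------------------------------------------------------- artifacts

@pytest.mark.parametrize("labels,rawconf,molecules,flagged", [
    ((8, 25), (30.0, 30.0), 20, True),    # few labels on one partner
    ((12, 25), (9.5, 40.0), 20, True),    # low raw confidence on one side
    ((15, 20), (30.0, 30.0), 6, False),   # low molecule support is NOT used
    ((11, 11), (10.0, 10.0), 20, False),  # both rules at their kept boundary
    ((10, 40), (30.0, 30.0), 20, True),   # exactly 10 labels flags
])
def test_translocation_artifact_rule(labels, rawconf, molecules, flagged,
                                     default_cfg):
    sv = make_sv(sv_type="inter_translocation", chrom="1", chrom2="2",
                 labels=labels, rawconf=rawconf, molecules=molecules)
    records = flag_translocation_artifacts(
        deduplicate_sv_cnv([sv], [], default_cfg), default_cfg)
    assert (records[0].status == Status.artifact_flagged) == flagged
    assert records[0].countable == (not flagged)


def test_missing_labels_pass_with_warning(default_cfg, caplog):
    sv = make_sv(sv_type="inter_translocation", chrom="1", chrom2="2",
                 labels=(None, None))
    with caplog.at_level("WARNING"):
        records = flag_translocation_artifacts(
            deduplicate_sv_cnv([sv], [], default_cfg), default_cfg)
    assert records[0].status == Status.kept
    assert "not evaluable" in caplog.text


# -------------------------------------------------------------- rescue

def _known_gain_11q():
    return KnownAberration(
        "k1", "P1", Technique.CMA, KnownClass.cnv_gain,
        interval=GenomicInterval("11", 106_600_681, 106_991_146),
        clone_fraction=0.25)


def test_small_known_cnv_rescued_under_permissive_size():
    cnv = make_cnv(chrom="11", start=106_600_681, end=106_991_146,
                   cnv_type="gain")  # 390 Kb: below the default CNV cut-off
    permissive = CurationConfig(cnv_min_size_bp=250_000)
    rescued = targeted_rescue([], [cnv], [_known_gain_11q()], permissive)
    assert len(rescued) == 1
    assert rescued[0].status == Status.rescued and rescued[0].countable


def test_rescue_requires_overlap_with_known_region():
    cnv = make_cnv(chrom="4", start=50_000_000, end=50_390_000, cnv_type="gain")
    permissive = CurationConfig(cnv_min_size_bp=250_000)
    assert targeted_rescue([], [cnv], [_known_gain_11q()], permissive) == []


def test_low_confidence_translocation_rescued_at_known_breakpoint():
    sv = make_sv(sv_type="inter_translocation", chrom="14", pos1=106_000_000,
                 chrom2="18", pos2=60_000_000, confidence=0.5)
    known = KnownAberration(
        "t1", "P1", Technique.CBA, KnownClass.translocation,
        bp1=("14", 105_500_000), bp2=("18", 60_500_000),
        bp_tolerance_bp=10_000_000)
    permissive = CurationConfig(conf_thresholds={
        **CurationConfig().conf_thresholds, SvType.inter_translocation: 0.3})
    rescued = targeted_rescue([sv], [], [known], permissive)
    assert len(rescued) == 1 and rescued[0].status == Status.rescued


def test_rescue_never_revives_artifact_like_translocations():
    sv = make_sv(sv_type="inter_translocation", chrom="14", pos1=106_000_000,
                 chrom2="18", pos2=60_000_000, confidence=0.5, labels=(5, 30))
    known = KnownAberration(
        "t1", "P1", Technique.CBA, KnownClass.translocation,
        bp1=("14", 105_500_000), bp2=("18", 60_500_000),
        bp_tolerance_bp=10_000_000)
    permissive = CurationConfig(conf_thresholds={
        **CurationConfig().conf_thresholds, SvType.inter_translocation: 0.3})
    assert targeted_rescue([sv], [], [known], permissive) == []


def test_permissive_config_must_not_exceed_defaults():
    permissive = CurationConfig(cnv_min_size_bp=900_000)
    with pytest.raises(ValidationError):
        targeted_rescue([], [], [], permissive)


# ------------------------------------------------------ chromothripsis

def _ct_records(n_breakpoints, losses, default_cfg):
    svs = [make_sv(f"t{i}", "intra_translocation", chrom="3",
                   pos1=80_000_000 + i * 2_000_000,
                   pos2=81_000_000 + i * 2_000_000, size=0)
           for i in range(n_breakpoints // 2)]
    cnvs = [make_cnv(f"l{i}", chrom="3", start=s, end=e)
            for i, (s, e) in enumerate(losses)]
    recs = deduplicate_sv_cnv(svs, cnvs, default_cfg)
    return recs


def test_chromothripsis_needs_breakpoints_and_oscillation(default_cfg):
    oscillating = [(60_000_000, 61_000_000), (63_000_000, 64_000_000),
                   (66_000_000, 67_000_000)]  # loss/normal x4 switches
    recs = _ct_records(12, oscillating, default_cfg)
    flags = detect_chromothripsis(recs, default_cfg)
    assert flags[("P1", "3")] is True

    recs = _ct_records(4, oscillating, default_cfg)  # too few breakpoints
    assert detect_chromothripsis(recs, default_cfg).get(("P1", "3")) is False

    recs = _ct_records(12, [(60_000_000, 67_000_000)], default_cfg)  # monotone
    assert detect_chromothripsis(recs, default_cfg)[("P1", "3")] is False


# -------------------------------------------------- composed pipeline

def test_curate_empty_input_is_empty(default_cfg):
    result = curate([], [], cfg=default_cfg)
    assert result.records == [] and result.summary()["n_countable"] == 0


def test_curate_identity_when_no_filter_applies(default_cfg):
    sv = [make_sv("a", pos1=10_000_000, pos2=10_200_000),
          make_sv("b", "inter_translocation", chrom="1", pos1=50_000_000,
                  chrom2="5", pos2=40_000_000)]
    cnv = [make_cnv("c", chrom="2", start=30_000_000, end=31_000_000)]
    result = curate(sv, cnv, cfg=default_cfg)
    assert all(r.status == Status.kept for r in result.records)
    assert len(result.countable) == 3


def test_curate_conserves_every_raw_call(small_cohort, default_cfg):
    result = curate(small_cohort.sv_calls, small_cohort.cnv_calls,
                    small_cohort.masks, small_cohort.polymorphisms,
                    cfg=default_cfg)
    raw_ids = {c.call_id for c in small_cohort.sv_calls} | \
        {c.call_id for c in small_cohort.cnv_calls}
    traced = {cid for r in result.records for cid in r.provenance}
    assert traced == raw_ids


def test_curate_is_order_independent(small_cohort, default_cfg):
    def signature(result):
        return sorted((tuple(sorted(r.provenance)), r.status.value,
                       r.ab_class.value) for r in result.records)

    a = curate(small_cohort.sv_calls, small_cohort.cnv_calls,
               small_cohort.masks, small_cohort.polymorphisms, cfg=default_cfg)
    b = curate(list(reversed(small_cohort.sv_calls)),
               list(reversed(small_cohort.cnv_calls)),
               small_cohort.masks, small_cohort.polymorphisms, cfg=default_cfg)
    assert signature(a) == signature(b)


def test_tightening_thresholds_never_admits_new_calls(small_cohort):
    base = curate(small_cohort.sv_calls, small_cohort.cnv_calls,
                  small_cohort.masks, small_cohort.polymorphisms)
    tighter = CurationConfig(sv_min_size_bp=200_000, cnv_min_size_bp=1_000_000,
                             label_artifact_max=15)
    tightened = curate(small_cohort.sv_calls, small_cohort.cnv_calls,
                       small_cohort.masks, small_cohort.polymorphisms,
                       cfg=tighter)
    base_ids = {cid for r in base.countable for cid in r.provenance}
    tight_ids = {cid for r in tightened.countable for cid in r.provenance}
    assert tight_ids <= base_ids
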