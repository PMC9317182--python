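#!/usr/bin/env python
"""Step 3: concordance of curated OGM abnormalities with the known set.

Builds the known-aberration inventory from the karyotype/FISH/microarray
records (microarray coordinates win for CNVs), matches the curated records
against it, explains every miss, classifies unconfirmed translocation calls,
and writes results/concordance/.
"""

import argparse
import json
from pathlib import Path

from ogmcll.concordance import (
    assign_discrepancy_reasons,
    build_known_inventory,
    classify_novel_translocations,
    match_calls,
    summarize_concordance,
)
from ogmcll.curation import curate
from ogmcll.genome import centromere_telomere_intervals
from ogmcll.io import read_bed, read_call_tables, read_clinical_table, read_known_table
from ogmcll.records import GenomicInterval, Region, RegionSet, Technique

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "concordance")
    args = ap.parse_args()

    tables = read_call_tables(args.cohort / "sv_calls.tsv",
                              args.cohort / "cnv_calls.tsv")
    known, rej = read_known_table(args.cohort / "known_aberrations.tsv")
    clinical, rej_c = read_clinical_table(args.cohort / "clinical.tsv")
    if rej or rej_c:
        raise SystemExit("invalid known/clinical rows")
    masks = read_bed(args.cohort / "masked.bed", "masked")
    poly = read_bed(args.cohort / "polymorphisms.bed", "polymorphism")

    result = curate(tables.sv, tables.cnv, masks, poly)
    by_tech = {t: [k for k in known if k.technique == t] for t in Technique}
    inventory = build_known_inventory(by_tech[Technique.CBA],
                                      by_tech[Technique.FISH],
                                      by_tech[Technique.CMA])
    results = match_calls(inventory, result.records)
    results = assign_discrepancy_reasons(
        results, {k.ab_id: k for k in inventory}, masks,
        RegionSet("centromere_telomere",
                  [Region(GenomicInterval(c, s, e))
                   for c, s, e in centromere_telomere_intervals()]),
        result.chromothripsis)
    summary = summarize_concordance(
        results, strata={c.patient_id: "CK" if c.ck_by_cba else "non-CK"
                         for c in clinical})
    confirmed_ids = {oid for r in results if r.matched for oid in r.ogm_ids}
    novel = classify_novel_translocations(
        [r for r in result.records if r.ab_id not in confirmed_ids],
        inventory, by_tech[Technique.CMA])

    args.outdir.mkdir(parents=True, exist_ok=True)
    with open(args.outdir / "matches.tsv", "w") as fh:
        fh.write("known_id\tpatient_id\tknown_class\tmatched\togm_ids\t"
                 "coord_diff_bp\tdiscrepancy_reason\n")
        for r in results:
            fh.write("\t".join([
                r.known_id, r.patient_id, r.known_class.value,
                str(int(r.matched)), ",".join(r.ogm_ids),
                "" if r.coord_diff_bp is None else str(r.coord_diff_bp),
                r.discrepancy_reason.value if r.discrepancy_reason else ""])
                + "\n")
    payload = {
        "n_known": summary.n_total,
        "n_detected": summary.n_matched,
        "detection_pct": round(summary.detection_pct, 1),
        "per_class": summary.per_class,
        "per_stratum": summary.per_stratum,
        "discrepancy_reasons": summary.reason_histogram,
        "median_coord_diff_bp": summary.median_coord_diff_bp,
        "novel_translocations": {
            c.ogm_id: c.category.value for c in novel},
    }
    (args.outdir / "summary.json").write_text(
        json.dumps(payload, indent=2) + "\n")
    print(f"detection: {summary.n_matched}/{summary.n_total} "
          f"({summary.detection_pct:.1f}%); misses by reason: "
          f"{summary.reason_histogram}")


if __name__ == "__main__":
    main()
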