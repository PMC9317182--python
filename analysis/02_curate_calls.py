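#!/usr/bin/env python
"""Step 2: curate the raw call tables into countable abnormalities.

Reads results/cohort/, applies the full curation stack (confidence and size
filters, masked-region and polymorphism exclusion, segment merging, SV/CNV
deduplication, translocation artifact flagging, chromothripsis detection)
and writes the curated record table plus a filter-accounting summary to
results/curation/.
"""

import argparse
import json
from pathlib import Path

from ogmcll.curation import curate
from ogmcll.io import read_bed, read_call_tables

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "curation")
    args = ap.parse_args()

    tables = read_call_tables(args.cohort / "sv_calls.tsv",
                              args.cohort / "cnv_calls.tsv")
    if tables.rejected_sv or tables.rejected_cnv:
        raise SystemExit(f"invalid rows: {len(tables.rejected_sv)} SV, "
                         f"{len(tables.rejected_cnv)} CNV")
    masks = read_bed(args.cohort / "masked.bed", "masked")
    poly = read_bed(args.cohort / "polymorphisms.bed", "polymorphism")

    result = curate(tables.sv, tables.cnv, masks, poly)

    args.outdir.mkdir(parents=True, exist_ok=True)
    with open(args.outdir / "curated.tsv", "w") as fh:
        fh.write("ab_id\tpatient_id\tab_class\tstatus\tcountable\t"
                 "chrom\tstart_or_bp1\tend_or_bp2\tprovenance\tdedup_into\n")
        for r in result.records:
            fp = r.footprint
            if fp is not None:
                loc = (fp.chrom, str(fp.start), str(fp.end))
            elif r.bp1 and r.bp2:
                loc = (f"{r.bp1[0]};{r.bp2[0]}", str(r.bp1[1]), str(r.bp2[1]))
            else:
                loc = ("", "", "")
            fh.write("\t".join([
                r.ab_id, r.patient_id, r.ab_class.value, r.status.value,
                str(int(r.countable)), *loc, ",".join(r.provenance),
                r.dedup_into or ""]) + "\n")

    summary = result.summary()
    summary["chromothripsis"] = sorted(
        f"{pid}:{chrom}" for (pid, chrom), flag
        in result.chromothripsis.items() if flag)
    (args.outdir / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")

    print(f"curated {summary['n_records']} records, "
          f"{summary['n_countable']} countable; by status: "
          f"{summary['by_status']}")


if __name__ == "__main__":
    main()
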