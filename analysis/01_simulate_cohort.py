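#!/usr/bin/env python
"""Step 1: generate the synthetic 42-patient cohort.

Writes raw SV/CNV call tables, the known-aberration and clinical tables,
the masked-region and polymorphism BEDs, and a truth summary under
results/cohort/.  Everything downstream reads from there, so rerunning this
script with the same seed reproduces the whole analysis byte for byte.
"""

import argparse
import json
from pathlib import Path

from ogmcll.io import (
    write_bed,
    write_clinical_table,
    write_cnv_table,
    write_known_table,
    write_sv_table,
)
from ogmcll.simulate import SimConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(SimConfig(n_patients=args.n_patients,
                                       seed=args.seed))

    write_sv_table(out / "sv_calls.tsv", cohort.sv_calls)
    write_cnv_table(out / "cnv_calls.tsv", cohort.cnv_calls)
    write_known_table(out / "known_aberrations.tsv",
                      cohort.cba_records + cohort.fish_records
                      + cohort.cma_records)
    write_clinical_table(out / "clinical.tsv", cohort.clinical)
    write_bed(out / "masked.bed", cohort.masks)
    write_bed(out / "polymorphisms.bed", cohort.polymorphisms)

    truth = {
        "seed": args.seed,
        "n_patients": args.n_patients,
        "n_sv_calls": len(cohort.sv_calls),
        "n_cnv_calls": len(cohort.cnv_calls),
        "patients": {pid: {"n_true": t.n_true, "risk_class": t.risk_class,
                           "is_ck": t.is_ck}
                     for pid, t in sorted(cohort.truth.patients.items())},
        "call_provenance": dict(sorted(cohort.truth.provenance.items())),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    n_ck = sum(t.is_ck for t in cohort.truth.patients.values())
    print(f"cohort: {args.n_patients} patients ({n_ck} CK), "
          f"{len(cohort.sv_calls)} SV calls, {len(cohort.cnv_calls)} CNV calls "
          f"-> {out}")


if __name__ == "__main__":
    main()
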