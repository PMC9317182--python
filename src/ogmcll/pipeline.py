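"""End-to-end orchestration: simulate → curate → concord → complexity →
survive, as a pure function of (config, seed), with a machine-readable run
manifest recording config, file digests, stage timings and versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

from . import __version__
from .complexity import (
    build_patient_profiles,
    compare_groups,
    cross_classification,
)
from .concordance import (
    MatchCriteria,
    assign_discrepancy_reasons,
    build_known_inventory,
    match_calls,
    summarize_concordance,
)
from .curation import CurationConfig, curate
from .io import (
    write_bed,
    write_clinical_table,
    write_cnv_table,
    write_known_table,
    write_sv_table,
)
from .records import RegionSet, Status
from .simulate import SimConfig, evaluate_recovery, simulate_cohort
from .stats import cohen_kappa
from .survival import SurvivalRecord, analyze_ttft

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_from_dict(data: dict) -> tuple[SimConfig, CurationConfig, MatchCriteria]:
    def build(cls, section):
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - fields
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**section)

    sim = build(SimConfig, data.get("simulate", {}))
    cur = build(CurationConfig, data.get("curation", {}))
    match = build(MatchCriteria, data.get("concordance", {}))
    return sim, cur, match


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config: Optional[dict] = None, outdir="results/pipeline",
                 seed: Optional[int] = None) -> dict:
    """Run all stages on a simulated cohort and write a manifest.

    Returns the manifest dict; raises StageError on the first failing stage
    (the manifest, including the failure, is written regardless).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or {}
    manifest: dict = {"version": __version__, "config": config, "seed": seed,
                      "stages": {}, "files": {}}
    written: list[Path] = []

    def finish_stage(name, t0, **info):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}

    try:
        sim_cfg, cur_cfg, crit = _config_from_dict(config)

        t0 = time.time()
        cohort = simulate_cohort(sim_cfg, seed=seed)
        write_sv_table(outdir / "sv_calls.tsv", cohort.sv_calls)
        write_cnv_table(outdir / "cnv_calls.tsv", cohort.cnv_calls)
        write_known_table(outdir / "known_aberrations.tsv",
                          cohort.cba_records + cohort.fish_records
                          + cohort.cma_records)
        write_clinical_table(outdir / "clinical.tsv", cohort.clinical)
        write_bed(outdir / "masked.bed", cohort.masks)
        write_bed(outdir / "polymorphisms.bed", cohort.polymorphisms)
        written += [outdir / f for f in
                    ("sv_calls.tsv", "cnv_calls.tsv", "known_aberrations.tsv",
                     "clinical.tsv", "masked.bed", "polymorphisms.bed")]
        finish_stage("simulate", t0, n_patients=sim_cfg.n_patients,
                     n_sv=len(cohort.sv_calls), n_cnv=len(cohort.cnv_calls))

        t0 = time.time()
        result = curate(cohort.sv_calls, cohort.cnv_calls, cohort.masks,
                        cohort.polymorphisms, cfg=cur_cfg)
        finish_stage("curate", t0, **result.summary())

        t0 = time.time()
        inventory = build_known_inventory(cohort.cba_records,
                                          cohort.fish_records,
                                          cohort.cma_records)
        results = match_calls(inventory, result.records, crit)
        results = assign_discrepancy_reasons(
            results, {k.ab_id: k for k in inventory}, cohort.masks,
            RegionSet("centromere_telomere", cohort.masks.regions),
            result.chromothripsis)
        summary = summarize_concordance(
            results, strata={c.patient_id: "CK" if c.ck_by_cba else "non-CK"
                             for c in cohort.clinical})
        finish_stage("concord", t0, n_known=summary.n_total,
                     detection_pct=round(summary.detection_pct, 1))

        t0 = time.time()
        profiles = build_patient_profiles(result.records, cohort.clinical,
                                          result.chromothripsis)
        table = cross_classification(profiles)
        kappa, kappa_p = cohen_kappa(table)
        comparison = compare_groups(profiles)
        recovery = evaluate_recovery(cohort, result.records)
        finish_stage("complexity", t0,
                     n_complex=sum(p.ogm_class == "C_OGM" for p in profiles),
                     kappa=round(kappa, 3),
                     risk_recovery=round(recovery.risk_recovery, 3))

        t0 = time.time()
        records = []
        for p in profiles:
            clin = p.clinical
            if clin.pre_treated:
                continue  # treated before genetic testing: excluded from TTFT
            t = clin.ttft_months if clin.treated else clin.follow_up_months
            if t is None:
                continue
            records.append(SurvivalRecord(p.patient_id, t, clin.treated,
                                          predictor=p.n_ogm, group=p.ogm_class))
        if len({r.group for r in records}) == 2:
            report = analyze_ttft(records, predictors={
                "n_ogm": {p.patient_id: p.n_ogm for p in profiles}})
            finish_stage("survive", t0,
                         medians=report.medians,
                         logrank_p=report.logrank_p,
                         c_index=report.c_index_by_predictor)
        else:
            finish_stage("survive", t0, skipped="fewer than two risk groups")

        manifest["status"] = "ok"
    except Exception as exc:  # manifest records the failure and is re-raised
        stage = getattr(exc, "stage", None) or \
            (list(manifest["stages"])[-1] + "+1" if manifest["stages"] else "setup")
        manifest["status"] = "failed"
        manifest["error"] = {"stage": stage, "message": str(exc)}
        raise StageError(stage, exc) from exc
    finally:
        for f in written:
            manifest["files"][f.name] = _digest(f)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
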