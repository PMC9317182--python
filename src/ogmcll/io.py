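"""Tabular I/O: SMAP-like SV tables, CNV tables, BED region files,
known-aberration and clinical tables.

All readers are strict: every rejected row is reported with its (1-based,
data-row) number and a reason, and accepted + rejected always equals the
number of input rows.  All writers emit a deterministic column order and
number formatting so that write∘read is the identity on validated tables.

The SV reader targets a configurable SMAP-like dialect: a mapping from the
semantic columns the pipeline needs (type, the two breakpoints, confidence,
the per-partner raw confidences and label counts, supporting molecules) to
the column names actually present, so real Bionano SMAP headers can be
mapped without code change.  Unknown columns are preserved as opaque
attributes and round-trip unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from .genome import normalize_chrom
from .records import (
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
    ValidationError,
)


class FormatError(ValueError):
    """A file does not conform to its declared tabular format."""


@dataclass
class RejectedRow:
    row_number: int  # 1-based over data rows (header and comments excluded)
    reason: str
    raw: dict


@dataclass
class SmapDialect:
    """Column map from semantic fields to the file's column names."""

    call_id: str = "Id"
    sv_type: str = "Type"
    chrom1: str = "RefcontigID1"
    pos1: str = "RefStartPos"
    chrom2: str = "RefcontigID2"
    pos2: str = "RefEndPos"
    size: str = "SVsize"
    confidence: str = "Confidence"
    raw_conf_left: str = "RawConfidenceLeft"
    raw_conf_right: str = "RawConfidenceRight"
    labels1: str = "LabelsChim1"
    labels2: str = "LabelsChim2"
    molecules: str = "SelfMoleculeCount"
    vaf: str = "VAF"
    patient: str = "Sample"
    # file type-string -> SvType name; extended/overridden per deployment
    type_map: dict = field(default_factory=dict)

    OPTIONAL = ("vaf", "patient", "labels1", "labels2", "molecules")

    def required_columns(self) -> list[str]:
        out = []
        for fname, col in self._columns().items():
            if fname not in self.OPTIONAL:
                out.append(col)
        return out

    def _columns(self) -> dict:
        return {
            f: getattr(self, f)
            for f in (
                "call_id", "sv_type", "chrom1", "pos1", "chrom2", "pos2",
                "size", "confidence", "raw_conf_left", "raw_conf_right",
                "labels1", "labels2", "molecules", "vaf", "patient",
            )
        }

    def parse_type(self, raw: str) -> SvType:
        name = self.type_map.get(raw, raw)
        try:
            return SvType(name)
        except ValueError:
            raise ValidationError(f"unknown sv_type {raw!r}") from None


DEFAULT_SMAP_DIALECT = SmapDialect()

CNV_COLUMNS = ["Id", "Sample", "Chromosome", "Start", "End", "Type",
               "Confidence", "CellFraction"]
KNOWN_COLUMNS = ["ab_id", "patient_id", "technique", "ab_class", "chrom",
                 "start", "end", "bp1_chrom", "bp1_pos", "bp2_chrom",
                 "bp2_pos", "bp_tolerance_bp", "clone_fraction"]
CLINICAL_COLUMNS = ["patient_id", "ttft_months", "treated", "pre_treated",
                    "tp53_abnormal", "ck_by_cba", "n_abn_cba", "n_abn_cma",
                    "follow_up_months"]


# ---------------------------------------------------------------- helpers

def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _opt_float(s: str) -> Optional[float]:
    return float(s) if s not in ("", None) else None


def _opt_int(s: str) -> Optional[int]:
    return int(s) if s not in ("", None) else None


def _bool(s: str) -> bool:
    if s in ("1", "true", "True", "TRUE"):
        return True
    if s in ("0", "false", "False", "FALSE"):
        return False
    raise ValidationError(f"not a boolean: {s!r}")


def _read_tsv(path, required: list[str]) -> tuple[list[str], list[dict]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    if not rows:
        return [], []
    header = rows[0]
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    data = [dict(zip(header, r)) for r in rows[1:]]
    return header, data


def _write_tsv(path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for r in rows:
            w.writerow([_fmt(x) for x in r])


# ------------------------------------------------------------- SV / CNV

@dataclass
class CallTables:
    sv: list[SvCall]
    cnv: list[CnvCall]
    rejected_sv: list[RejectedRow] = field(default_factory=list)
    rejected_cnv: list[RejectedRow] = field(default_factory=list)


def read_sv_table(path, dialect: SmapDialect = DEFAULT_SMAP_DIALECT
                  ) -> tuple[list[SvCall], list[RejectedRow]]:
    header, data = _read_tsv(path, dialect.required_columns())
    known_cols = set(dialect._columns().values())
    calls, rejected = [], []
    for i, row in enumerate(data, start=1):
        try:
            d = dialect
            call = SvCall(
                call_id=row[d.call_id],
                sv_type=d.parse_type(row[d.sv_type]),
                bp1=(normalize_chrom(row[d.chrom1]), int(float(row[d.pos1]))),
                bp2=(normalize_chrom(row[d.chrom2]), int(float(row[d.pos2]))),
                size_bp=int(float(row[d.size])),
                confidence=float(row[d.confidence]),
                raw_conf_left=float(row[d.raw_conf_left]),
                raw_conf_right=float(row[d.raw_conf_right]),
                labels_bp1=_opt_int(row.get(d.labels1, "")),
                labels_bp2=_opt_int(row.get(d.labels2, "")),
                self_molecules=_opt_int(row.get(d.molecules, "")) or 0,
                vaf=_opt_float(row.get(d.vaf, "")),
                patient_id=row.get(d.patient, ""),
                extra={k: v for k, v in row.items() if k not in known_cols},
            )
            calls.append(call)
        except (ValidationError, ValueError, KeyError) as exc:
            rejected.append(RejectedRow(i, str(exc), row))
    return calls, rejected


def read_cnv_table(path) -> tuple[list[CnvCall], list[RejectedRow]]:
    _, data = _read_tsv(path, [c for c in CNV_COLUMNS if c != "CellFraction"])
    calls, rejected = [], []
    for i, row in enumerate(data, start=1):
        try:
            calls.append(CnvCall(
                call_id=row["Id"],
                interval=GenomicInterval(
                    normalize_chrom(row["Chromosome"]),
                    int(float(row["Start"])), int(float(row["End"]))),
                cnv_type=CnvType(row["Type"]),
                confidence=float(row["Confidence"]),
                cell_fraction=_opt_float(row.get("CellFraction", "")),
                patient_id=row.get("Sample", ""),
            ))
        except (ValidationError, ValueError, KeyError) as exc:
            rejected.append(RejectedRow(i, str(exc), row))
    return calls, rejected


def read_call_tables(sv_path, cnv_path,
                     dialect: SmapDialect = DEFAULT_SMAP_DIALECT) -> CallTables:
    sv, rej_sv = read_sv_table(sv_path, dialect)
    cnv, rej_cnv = read_cnv_table(cnv_path)
    return CallTables(sv, cnv, rej_sv, rej_cnv)


def write_sv_table(path, calls: list[SvCall],
                   dialect: SmapDialect = DEFAULT_SMAP_DIALECT) -> None:
    d = dialect
    extra_cols = sorted({k for c in calls for k in c.extra})
    header = [d.call_id, d.sv_type, d.chrom1, d.pos1, d.chrom2, d.pos2,
              d.size, d.confidence, d.raw_conf_left, d.raw_conf_right,
              d.labels1, d.labels2, d.molecules, d.vaf, d.patient] + extra_cols
    inverse = {v: k for k, v in d.type_map.items()}
    rows = []
    for c in calls:
        rows.append([
            c.call_id, inverse.get(c.sv_type.value, c.sv_type.value),
            c.bp1[0], c.bp1[1], c.bp2[0], c.bp2[1], c.size_bp, c.confidence,
            c.raw_conf_left, c.raw_conf_right, c.labels_bp1, c.labels_bp2,
            c.self_molecules, c.vaf, c.patient_id,
        ] + [c.extra.get(k, "") for k in extra_cols])
    _write_tsv(path, header, rows)


def write_cnv_table(path, calls: list[CnvCall]) -> None:
    rows = [[c.call_id, c.patient_id, c.interval.chrom, c.interval.start,
             c.interval.end, c.cnv_type.value, c.confidence, c.cell_fraction]
            for c in calls]
    _write_tsv(path, CNV_COLUMNS, rows)


# ----------------------------------------------------------------- BED

def read_bed(path, label: str) -> RegionSet:
    """Read a BED file (0-based half-open) into the internal 1-based
    inclusive convention.  An optional 4th column becomes the region name
    (polymorphism sets use it for the CNV sign)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                chrom = normalize_chrom(parts[0])
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from None
            if start0 < 0 or end0 <= start0:
                raise FormatError(f"{path}:{ln}: invalid BED coordinates "
                                  f"{start0}-{end0}")
            name = parts[3] if len(parts) > 3 else None
            regions.append(Region(GenomicInterval(chrom, start0 + 1, end0), name))
    return RegionSet(label, regions)


def write_bed(path, region_set: RegionSet) -> None:
    with open(path, "w") as fh:
        for r in region_set.regions:
            cols = [r.interval.chrom, str(r.interval.start - 1), str(r.interval.end)]
            if r.name is not None:
                cols.append(r.name)
            fh.write("\t".join(cols) + "\n")


def read_region_sets(bed_paths: dict) -> list[RegionSet]:
    """Read labeled BED files, e.g. {"masked": path, "polymorphism": path}."""
    return [read_bed(p, label) for label, p in bed_paths.items()]


# ------------------------------------------------- known / clinical

def read_known_table(path) -> tuple[list[KnownAberration], list[RejectedRow]]:
    _, data = _read_tsv(path, ["ab_id", "patient_id", "technique", "ab_class"])
    records, rejected, seen = [], [], set()
    for i, row in enumerate(data, start=1):
        try:
            if row["ab_id"] in seen:
                raise ValidationError(f"duplicate ab_id {row['ab_id']!r}")
            interval = None
            if row.get("chrom"):
                interval = GenomicInterval(
                    normalize_chrom(row["chrom"]),
                    int(float(row["start"])), int(float(row["end"])))
            bp1 = bp2 = None
            if row.get("bp1_chrom"):
                bp1 = (normalize_chrom(row["bp1_chrom"]), int(float(row["bp1_pos"])))
            if row.get("bp2_chrom"):
                bp2 = (normalize_chrom(row["bp2_chrom"]), int(float(row["bp2_pos"])))
            records.append(KnownAberration(
                ab_id=row["ab_id"], patient_id=row["patient_id"],
                technique=Technique(row["technique"]),
                ab_class=KnownClass(row["ab_class"]),
                interval=interval, bp1=bp1, bp2=bp2,
                bp_tolerance_bp=_opt_int(row.get("bp_tolerance_bp", "")),
                clone_fraction=_opt_float(row.get("clone_fraction", "")),
            ))
            seen.add(row["ab_id"])
        except (ValidationError, ValueError, KeyError) as exc:
            rejected.append(RejectedRow(i, str(exc), row))
    return records, rejected


def write_known_table(path, records: list[KnownAberration]) -> None:
    rows = []
    for r in records:
        rows.append([
            r.ab_id, r.patient_id, r.technique.value, r.ab_class.value,
            r.interval.chrom if r.interval else None,
            r.interval.start if r.interval else None,
            r.interval.end if r.interval else None,
            r.bp1[0] if r.bp1 else None, r.bp1[1] if r.bp1 else None,
            r.bp2[0] if r.bp2 else None, r.bp2[1] if r.bp2 else None,
            r.bp_tolerance_bp, r.clone_fraction,
        ])
    _write_tsv(path, KNOWN_COLUMNS, rows)


def read_clinical_table(path) -> tuple[list[ClinicalRecord], list[RejectedRow]]:
    _, data = _read_tsv(path, [c for c in CLINICAL_COLUMNS if c != "n_abn_cma"])
    records, rejected = [], []
    for i, row in enumerate(data, start=1):
        try:
            records.append(ClinicalRecord(
                patient_id=row["patient_id"],
                ttft_months=_opt_float(row.get("ttft_months", "")),
                treated=_bool(row["treated"]),
                pre_treated=_bool(row["pre_treated"]),
                tp53_abnormal=_bool(row["tp53_abnormal"]),
                ck_by_cba=_bool(row["ck_by_cba"]),
                n_abn_cba=int(row["n_abn_cba"]),
                n_abn_cma=_opt_int(row.get("n_abn_cma", "")),
                follow_up_months=_opt_float(row.get("follow_up_months", "")),
            ))
        except (ValidationError, ValueError, KeyError) as exc:
            rejected.append(RejectedRow(i, str(exc), row))
    return records, rejected


def write_clinical_table(path, records: list[ClinicalRecord]) -> None:
    rows = [[r.patient_id, r.ttft_months, r.treated, r.pre_treated,
             r.tp53_abnormal, r.ck_by_cba, r.n_abn_cba, r.n_abn_cma,
             r.follow_up_months]
            for r in records]
    _write_tsv(path, CLINICAL_COLUMNS, rows)


def read_cohort(known_path, clinical_path
                ) -> tuple[list[KnownAberration], list[ClinicalRecord]]:
    """Read the known-aberration and clinical tables, cross-validating ids.

    Raises FormatError when the known table references patients absent from
    the clinical table, or on duplicate ab_ids / invariant violations.
    """
    known, rej_k = read_known_table(known_path)
    clinical, rej_c = read_clinical_table(clinical_path)
    if rej_k or rej_c:
        msgs = [f"known row {r.row_number}: {r.reason}" for r in rej_k]
        msgs += [f"clinical row {r.row_number}: {r.reason}" for r in rej_c]
        raise FormatError("; ".join(msgs))
    clin_ids = {c.patient_id for c in clinical}
    orphans = sorted({k.patient_id for k in known} - clin_ids)
    if orphans:
        raise FormatError(f"known-aberration patients missing from clinical "
                          f"table: {', '.join(orphans)}")
    return known, clinical
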