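"""Cohort CSV schema, readers/writers, run configuration and orchestration.

One strictly enforced CSV dialect: comma delimiter, dot decimal point,
mandatory header, '#' comment lines.  Ambiguous locales (e.g. comma
decimals) are rejected row-by-row with line numbers rather than guessed.
Sex is coded F/M, case-insensitive on read, canonical uppercase on write.

``run_compute`` writes the full output bundle (per-patient derived
table, stratified summaries, sex comparisons, correlation matrix, audit
table) together with the serialized run configuration and a machine-
readable manifest, so every bundle documents the configuration that
produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cohort as co
from .conversion import (
    ConversionTable,
    FFactorTable,
    Phantom,
    body_32cm_table,
    default_f_factors,
)
from .core import PatientRecord, Sex
from .synthetic import SyntheticConfig, calibration_report, default_config, generate_cohort

__all__ = [
    "SchemaError",
    "RowError",
    "RunConfig",
    "COHORT_COLUMNS",
    "read_cohort",
    "read_cohort_detailed",
    "write_cohort",
    "run_compute",
    "run_simulate",
]

logger = logging.getLogger("ctdose")

#: Required cohort columns, in canonical order (units documented in the
#: header comments written by :func:`write_cohort`).
COHORT_COLUMNS = (
    "id", "sex", "age", "height", "weight", "bmi", "ap", "lat",
    "topogram_length", "diagnostic_length", "ctdi_vol",
    "dlp_topogram", "dlp_diagnostic",
)

_UNITS = {
    "age": "years", "height": "cm", "weight": "kg", "bmi": "kg/m2",
    "ap": "cm", "lat": "cm", "topogram_length": "mm",
    "diagnostic_length": "mm", "ctdi_vol": "mGy",
    "dlp_topogram": "mGy.cm", "dlp_diagnostic": "mGy.cm",
}


class SchemaError(ValueError):
    """The cohort file violates the documented schema."""


@dataclass(frozen=True)
class RowError:
    line: int          # 1-based physical line number in the file
    record_id: str
    message: str


@dataclass
class RunConfig:
    """Configuration of one compute run; serialized next to the outputs."""

    phantom: str = Phantom.BODY_32CM.value
    protocol: str = "chest"
    dlp_source: str = "diagnostic"      # "diagnostic" | "total"
    alpha: float = 0.05
    interpolation: str = "table"        # "table" | "fit"
    out_dir: str = "."
    seed: int | None = None             # for simulate only

    def validate(self) -> None:
        errors = []
        if self.phantom not in (p.value for p in Phantom):
            errors.append(f"phantom must be one of {[p.value for p in Phantom]}")
        if self.dlp_source not in ("diagnostic", "total"):
            errors.append("dlp_source must be 'diagnostic' or 'total'")
        if self.interpolation not in ("table", "fit"):
            errors.append("interpolation must be 'table' or 'fit'")
        if not 0 < self.alpha < 1:
            errors.append("alpha must be in (0, 1)")
        if errors:
            raise SchemaError("; ".join(errors))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# CSV round-trip


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("# ctdose cohort file; units: "
                 + ", ".join(f"{k} [{v}]" for k, v in _UNITS.items()) + "\n")
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for r in records:
            fields = [r.id, r.sex.value] + [
                format(getattr(r, c), ".10g")
                for c in COHORT_COLUMNS[2:]
            ]
            fh.write(",".join(fields) + "\n")


def read_cohort_detailed(path) -> tuple[list[PatientRecord], list[RowError]]:
    """Parse a cohort CSV; collect row-level failures with line numbers.

    Raises :class:`SchemaError` when a required column is missing or the
    file has no parseable header; individual bad rows (unparseable
    numerics, domain violations, duplicate ids) are skipped and reported
    so the rest of the file still loads.
    """
    path = Path(path)
    header: list[str] | None = None
    records: list[PatientRecord] = []
    errors: list[RowError] = []
    seen_ids: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                missing = [c for c in COHORT_COLUMNS if c not in header]
                if missing:
                    raise SchemaError(
                        f"missing required column(s): {', '.join(missing)}")
                continue
            if len(cells) != len(header):
                errors.append(RowError(lineno, "?",
                                       f"expected {len(header)} fields, got {len(cells)}"))
                continue
            row = dict(zip(header, cells))
            try:
                rec = _parse_row(row)
            except Exception as exc:
                errors.append(RowError(lineno, row.get("id", "?"), str(exc)))
                continue
            if rec.id in seen_ids:
                errors.append(RowError(lineno, rec.id, "duplicate id"))
                continue
            seen_ids.add(rec.id)
            records.append(rec)
    if header is None:
        raise SchemaError(f"{path}: no header found")
    for err in errors:
        logger.warning("%s:%d (%s): %s", path.name, err.line, err.record_id, err.message)
    return records, errors


def read_cohort(path) -> list[PatientRecord]:
    """Like :func:`read_cohort_detailed`, logging row errors and returning
    only the successfully parsed records."""
    records, _ = read_cohort_detailed(path)
    return records


def _parse_row(row: dict[str, str]) -> PatientRecord:
    sex = row["sex"].strip().upper()
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be F or M, got {row['sex']!r}")
    values = {}
    for col in COHORT_COLUMNS[2:]:
        cell = row[col]
        try:
            values[col] = float(cell)
        except ValueError:
            raise ValueError(
                f"column {col!r}: unparseable numeric {cell!r} "
                "(decimal point must be '.')") from None
    return PatientRecord(id=row["id"], sex=Sex(sex), **values)


# ---------------------------------------------------------------------------
# orchestration


def _summary_table(frame: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    rows = []
    for var in variables:
        for stratum in ("all", "F", "M"):
            n = len(frame) if stratum == "all" else int((frame["sex"] == stratum).sum())
            if n < 2:
                logger.warning("summary row skipped for %s/%s (n=%d < 2)",
                               var, stratum, n)
                continue
            s = co.summarize(frame, var, stratum)
            rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


_ANALYSIS_VARIABLES = (
    "age", "weight", "height", "bmi", "ap", "lat", "d_eff",
    "topogram_length", "diagnostic_length",
    "ctdi_vol", "ssde", "dlp_topogram", "dlp_diagnostic", "dlp_ss", "ed",
)


def run_compute(cohort_path, config: RunConfig,
                k_table: ConversionTable | None = None,
                f_table: FFactorTable | None = None) -> dict[str, Path]:
    """Full pipeline over a cohort file; returns the written bundle paths.

    With fewer than two records per sex the comparison and correlation
    tables are skipped with a logged reason; the per-patient derived
    table is always written.  Nothing is written when the input is
    empty or fails schema validation.
    """
    config.validate()
    if k_table is None:
        k_table = body_32cm_table()
    if f_table is None:
        f_table = default_f_factors()
    records, row_errors = read_cohort_detailed(cohort_path)
    if not records:
        raise SchemaError(f"{cohort_path}: no valid records")
    derived, failures = co.derive_all(
        records, k_table, f_table,
        protocol=config.protocol,
        include_topogram_dlp=(config.dlp_source == "total"),
        use_fit=(config.interpolation == "fit"),
    )
    frame = co.cohort_frame(derived)
    logger.info("compute: phantom=%s protocol=%s dlp_source=%s interpolation=%s "
                "(%d records, %d row errors, %d derive failures)",
                config.phantom, config.protocol, config.dlp_source,
                config.interpolation, len(records), len(row_errors), len(failures))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["derived"] = out / "derived.csv"
    frame.to_csv(paths["derived"], index=False)

    paths["summary"] = out / "summary.csv"
    _summary_table(frame, _ANALYSIS_VARIABLES).to_csv(paths["summary"], index=False)

    n_f = int((frame["sex"] == "F").sum())
    n_m = int((frame["sex"] == "M").sum())
    if n_f >= 3 and n_m >= 3:
        comp_rows = []
        for var in _ANALYSIS_VARIABLES:
            c = co.compare_groups(
                frame.loc[frame["sex"] == "F", var],
                frame.loc[frame["sex"] == "M", var],
                variable=var, alpha=config.alpha,
            )
            comp_rows.append(dataclasses.asdict(c))
        paths["comparisons"] = out / "comparisons.csv"
        pd.DataFrame(comp_rows).to_csv(paths["comparisons"], index=False)
    else:
        logger.warning("comparison tables skipped: need >= 3 records per sex "
                       "(have F=%d, M=%d)", n_f, n_m)

    corr_rows = []
    for stratum in ("all", "F", "M"):
        n_s = len(frame) if stratum == "all" else int((frame["sex"] == stratum).sum())
        if n_s < 5:
            logger.warning("correlation table skipped for stratum %s (n=%d < 5)",
                           stratum, n_s)
            continue
        for r in co.spearman_matrix(frame, stratum=stratum):
            corr_rows.append(dataclasses.asdict(r))
    if corr_rows:
        paths["correlations"] = out / "correlations.csv"
        pd.DataFrame(corr_rows).to_csv(paths["correlations"], index=False)

    audit = co.audit_cohort(frame)
    paths["audit"] = out / "audit.json"
    paths["audit"].write_text(json.dumps(dataclasses.asdict(audit), indent=2))

    paths["run_config"] = out / "run_config.yaml"
    config.to_yaml(paths["run_config"])
    manifest = {
        "input": str(cohort_path),
        "n_records": len(records),
        "n_row_errors": len(row_errors),
        "n_derive_failures": len(failures),
        "outputs": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def run_simulate(config: SyntheticConfig | str | Path | None,
                 out_path, *, seed: int | None = None) -> dict[str, Path]:
    """Generate a cohort file plus its calibration report.

    ``config`` may be a :class:`SyntheticConfig`, a YAML path, or None
    for the shipped defaults; ``seed`` overrides the config seed.
    Deterministic: same config and seed give byte-identical files.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, SyntheticConfig):
        cfg = config
    else:
        cfg = SyntheticConfig.from_yaml(config)
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    records = generate_cohort(cfg)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_cohort(records, out_path)
    report = calibration_report(records, cfg)
    report_path = out_path.with_suffix(".calibration.csv")
    report.to_csv(report_path, index=False)
    config_path = out_path.with_suffix(".config.yaml")
    cfg.to_yaml(config_path)
    return {"cohort": out_path, "calibration": report_path, "config": config_path}
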