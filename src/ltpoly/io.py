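"""Reading, thresholding and serialisation of ligand-target activity tables.

Two input dialects are supported: raw measurement tables (Kd/Ki affinities in
molar units, pKd/pKi on the log scale, or a qualitative "not active" flag)
and pre-thresholded status tables.  Raw measurements are converted to
active/inactive calls with an affinity cutoff (default 3 uM, pK 5.5); when a
pair carries conflicting calls, its status is set to null — a disagreement
is treated as an absence of knowledge, never resolved by majority.

Serialisation formats are plain TSV: a sparse triplet table (ligand, target,
status) and a dense status grid using tokens "1" (active), "0" (inactive)
and "." (null).  Both round-trip exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .completeness import CompletenessReport
from .polypharm import JointPolypharmEstimate, PolypharmEstimate
from .relation import ActivityState, TernaryRelation

__all__ = [
    "MeasurementRecord",
    "StatusTriple",
    "Dialect",
    "RunConfig",
    "read_measurements",
    "threshold_records",
    "read_status_triples",
    "write_status_triples",
    "write_dense_matrix",
    "read_dense_matrix",
    "write_completeness_report",
    "write_polypharm_report",
    "write_joint_report",
    "load_config",
    "DEFAULT_THRESHOLD_M",
    "DEFAULT_PK_THRESHOLD",
]

DEFAULT_THRESHOLD_M = 3e-6
DEFAULT_PK_THRESHOLD = 5.5

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

_QUANTITATIVE_TYPES = {"kd": "Kd", "ki": "Ki", "pkd": "pKd", "pki": "pKi"}
_PK_TYPES = {"pKd", "pKi"}

_STATUS_TOKENS = {
    "active": ActivityState.ACTIVE,
    "inactive": ActivityState.INACTIVE,
    "null": ActivityState.NULL,
}


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw bioactivity measurement for a ligand-target pair."""

    ligand: str
    target: str
    kind: str  # "quantitative" | "qualitative"
    measure_type: str | None = None  # Kd | Ki | pKd | pKi
    value: float | None = None  # molar for Kd/Ki, log10 units for pKd/pKi
    qualitative_flag: str | None = None  # "not_active"

    def __post_init__(self) -> None:
        if self.kind == "quantitative":
            if self.measure_type is None or self.value is None or self.qualitative_flag:
                raise ValueError("quantitative records carry measure_type and value only")
        elif self.kind == "qualitative":
            if self.qualitative_flag != "not_active" or self.measure_type or self.value is not None:
                raise ValueError("qualitative records carry only the not_active flag")
        else:
            raise ValueError(f"unknown record kind {self.kind!r}")


@dataclass(frozen=True)
class StatusTriple:
    ligand: str
    target: str
    status: ActivityState


@dataclass(frozen=True)
class Dialect:
    """Column names of a raw measurement table."""

    ligand_col: str = "ligand_id"
    target_col: str = "target_id"
    type_col: str = "type"
    value_col: str = "value"
    units_col: str = "units"
    qualifier_col: str = "qualifier"
    delimiter: str = "\t"


class ParseError(ValueError):
    """A malformed row; the message carries the 1-based line number."""


def _fail(line_no: int, message: str) -> None:
    raise ParseError(f"line {line_no}: {message}")


def read_measurements(path: str | Path, dialect: Dialect | None = None) -> list[MeasurementRecord]:
    """Parse a raw measurement table into records with molar-normalised values.

    Quantitative rows need a recognised measure type (Kd/Ki with a unit token
    M, mM, uM, nM or pM; pKd/pKi unitless) and a positive value; qualitative
    rows carry the qualifier ``not active``.  Every defect is reported with
    its line number.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    records: list[MeasurementRecord] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise ParseError("line 1: empty file, no header")
        missing = {dialect.ligand_col, dialect.target_col, dialect.type_col} - set(reader.fieldnames)
        if missing:
            raise ParseError(f"line 1: header lacks required columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            ligand = (row.get(dialect.ligand_col) or "").strip()
            target = (row.get(dialect.target_col) or "").strip()
            if not ligand or not target:
                _fail(line_no, "missing ligand or target identifier")
            qualifier = (row.get(dialect.qualifier_col) or "").strip().lower().replace("_", " ")
            type_token = (row.get(dialect.type_col) or "").strip()
            if qualifier == "not active":
                records.append(
                    MeasurementRecord(ligand, target, "qualitative", qualitative_flag="not_active")
                )
                continue
            if qualifier:
                _fail(line_no, f"unknown qualifier {qualifier!r}")
            measure_type = _QUANTITATIVE_TYPES.get(type_token.lower())
            if measure_type is None:
                _fail(line_no, f"unsupported measurement type {type_token!r} (expected Kd/Ki/pKd/pKi)")
            raw_value = (row.get(dialect.value_col) or "").strip()
            try:
                value = float(raw_value)
            except ValueError:
                _fail(line_no, f"malformed value {raw_value!r}")
            if measure_type in _PK_TYPES:
                records.append(
                    MeasurementRecord(ligand, target, "quantitative", measure_type, value)
                )
                continue
            if value <= 0:
                _fail(line_no, f"non-positive affinity value {raw_value!r}")
            unit = (row.get(dialect.units_col) or "").strip()
            factor = _UNIT_TO_MOLAR.get(unit)
            if factor is None:
                _fail(line_no, f"unknown unit token {unit!r}")
            records.append(
                MeasurementRecord(ligand, target, "quantitative", measure_type, value * factor)
            )
    return records


def _record_status(
    record: MeasurementRecord, threshold: float, pk_threshold: float
) -> ActivityState:
    if record.kind == "qualitative":
        return ActivityState.INACTIVE
    assert record.value is not None
    if record.measure_type in _PK_TYPES:
        # higher pK = stronger binding; below the pK cutoff is inactive
        return ActivityState.INACTIVE if record.value < pk_threshold else ActivityState.ACTIVE
    # affinity constants: strictly weaker than the cutoff is inactive
    return ActivityState.INACTIVE if record.value > threshold else ActivityState.ACTIVE


def threshold_records(
    records: Iterable[MeasurementRecord],
    threshold: float = DEFAULT_THRESHOLD_M,
    pk_threshold: float = DEFAULT_PK_THRESHOLD,
) -> list[StatusTriple]:
    """Convert measurements to per-pair status calls with conflict handling.

    Each record is called active or inactive against the cutoff ("larger
    than" the affinity threshold is inactive, so the boundary value itself is
    active; pK mirrors with >= ``pk_threshold`` active).  All calls for a
    pair must agree; any disagreement sets that pair's status to null.
    Output order is first appearance of each pair, independent of how
    duplicate records are interleaved.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    calls: dict[tuple[str, str], set[ActivityState]] = {}
    for rec in records:
        key = (rec.ligand, rec.target)
        calls.setdefault(key, set()).add(_record_status(rec, threshold, pk_threshold))
    out = []
    for (ligand, target), statuses in calls.items():
        status = statuses.pop() if len(statuses) == 1 else ActivityState.NULL
        out.append(StatusTriple(ligand, target, status))
    return out


# ---------------------------------------------------------------------------
# status triplet TSV
# ---------------------------------------------------------------------------


def read_status_triples(path: str | Path) -> list[StatusTriple]:
    """Read a triplet TSV with columns ligand_id, target_id, status."""
    path = Path(path)
    triples: list[StatusTriple] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError("line 1: empty file, no header")
        required = {"ligand_id", "target_id", "status"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ParseError(f"line 1: header lacks required columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            ligand = (row["ligand_id"] or "").strip()
            target = (row["target_id"] or "").strip()
            token = (row["status"] or "").strip().lower()
            status = _STATUS_TOKENS.get(token)
            if status is None:
                _fail(line_no, f"unknown status token {row['status']!r}")
            if not ligand or not target:
                _fail(line_no, "missing ligand or target identifier")
            triples.append(StatusTriple(ligand, target, status))
    return triples


def write_status_triples(
    rel: TernaryRelation, path: str | Path, include_null: bool = False
) -> None:
    """Write the relation as a triplet TSV; null rows are optional.

    Omitted null rows are restored on reconstruction because unmentioned
    pairs are null by definition, so the round trip is exact either way —
    provided the reference sets are passed back explicitly when nulls are
    omitted.
    """
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["ligand_id", "target_id", "status"])
        for ligand, target, state in rel.to_triples(include_null=include_null):
            writer.writerow([ligand, target, state.value])


# ---------------------------------------------------------------------------
# dense status matrix TSV
# ---------------------------------------------------------------------------

_DENSE_TOKEN = {ActivityState.ACTIVE: "1", ActivityState.INACTIVE: "0", ActivityState.NULL: "."}
_DENSE_STATE = {v: k for k, v in _DENSE_TOKEN.items()}


def write_dense_matrix(rel: TernaryRelation, path: str | Path) -> None:
    """Write the full L x T status grid (tokens 1 / 0 / '.')."""
    path = Path(path)
    code_token = {0: "1", 1: "0", 2: "."}
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["ligand_id", *rel.targets])
        for i, ligand in enumerate(rel.ligands):
            writer.writerow([ligand, *(code_token[int(c)] for c in rel.codes[i])])


def read_dense_matrix(path: str | Path) -> TernaryRelation:
    """Read a dense status grid back into a relation (round-trip inverse)."""
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("line 1: empty file, no header") from None
        targets = [t.strip() for t in header[1:]]
        ligands: list[str] = []
        rows: list[list[int]] = []
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(targets) + 1:
                _fail(line_no, f"ragged row: expected {len(targets) + 1} cells, got {len(row)}")
            ligands.append(row[0].strip())
            codes = []
            for col, token in enumerate(row[1:], start=2):
                state = _DENSE_STATE.get(token.strip())
                if state is None:
                    _fail(line_no, f"column {col}: unknown cell token {token!r}")
                codes.append({ActivityState.ACTIVE: 0, ActivityState.INACTIVE: 1, ActivityState.NULL: 2}[state])
            rows.append(codes)
    import numpy as np

    matrix = np.array(rows, dtype=np.int8).reshape(len(ligands), len(targets))
    return TernaryRelation(ligands, targets, matrix)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def write_completeness_report(
    rel: TernaryRelation,
    report: CompletenessReport,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Per-ligand and per-target completeness TSV plus a JSON summary block."""
    with Path(tsv_path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["kind", "id", "n_active", "n_inactive", "n_null", "ldc"])
        for ligand in rel.ligands:
            a, i, n = rel.ligand_profile(ligand).counts()
            writer.writerow(["ligand", ligand, a, i, n, f"{report.ldc_ligand[ligand]:.10g}"])
        for target in rel.targets:
            a, i, n = rel.target_profile(target).counts()
            writer.writerow(["target", target, a, i, n, f"{report.ldc_target[target]:.10g}"])
    if json_path is not None:
        summary = {
            "gdc": report.gdc,
            "mean_ldc_ligand": report.mean_ldc_ligand,
            "mean_ldc_target": report.mean_ldc_target,
            "median_ldc_ligand": report.median_ldc_ligand,
            "median_ldc_target": report.median_ldc_target,
            "ligand_cdf": report.ligand_cdf,
            "target_cdf": report.target_cdf,
        }
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.10g}"


def write_polypharm_report(
    rel: TernaryRelation, estimates: Sequence[PolypharmEstimate], path: str | Path
) -> None:
    """Per-ligand polypharmacology TSV."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "id", "n_active", "n_inactive", "n_null",
                "p_min", "p_hat", "p_hat_source", "p_tilde_max",
                "ci_low", "ci_high", "p_max",
            ]
        )
        for est in estimates:
            a, i, n = rel.ligand_profile(est.ligand).counts()
            writer.writerow(
                [
                    est.ligand, a, i, n,
                    est.p_min, _fmt(est.p_hat), est.p_hat_source.value, _fmt(est.p_tilde_max),
                    _fmt(est.ci_low), _fmt(est.ci_high), est.p_max,
                ]
            )


_CELL_NAMES = [
    "n_pp", "n_pm", "n_p0",
    "n_mp", "n_mm", "n_m0",
    "n_0p", "n_0m", "n_00",
]


def write_joint_report(estimates: Sequence[JointPolypharmEstimate], path: str | Path) -> None:
    """Per-pair joint polypharmacology TSV with the nine partition counts."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["id1", "id2", *_CELL_NAMES,
             "p_min", "p_tilde_max_joint", "p_tilde_max_indep",
             "ci_low", "ci_high", "p_max"]
        )
        for est in estimates:
            writer.writerow(
                [
                    est.pair[0], est.pair[1],
                    *(int(c) for c in est.partition.counts.ravel()),
                    est.p_min, _fmt(est.p_tilde_max_joint), _fmt(est.p_tilde_max_indep),
                    _fmt(est.ci_low), _fmt(est.ci_high), est.p_max,
                ]
            )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Run parameters; the defaults match the standard analysis protocol."""

    threshold: float = DEFAULT_THRESHOLD_M
    pk_threshold: float = DEFAULT_PK_THRESHOLD
    alpha: float = 0.05
    joint_mode: str = "joint"
    strict: bool = False
    seed: int = 0
    n_draws: int = 4000
    dialect: Dialect = field(default_factory=Dialect)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent keys keep their defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    dialect_data = data.pop("dialect", {}) or {}
    config = RunConfig(dialect=Dialect(**dialect_data))
    for key, value in data.items():
        if not hasattr(config, key):
            raise ValueError(f"unknown configuration key {key!r}")
        setattr(config, key, value)
    return config
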