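"""Cq-table parsing, run configuration, and result serialisation.

Instrument exports vary in column naming and delimiter; this module reads
comma- or tab-delimited tables with case-insensitive ``Sample``, ``Target``
and ``Cq`` columns (``Well``/``Plate`` optional), maps instrument target
names to the autosome/sex roles through a configurable alias table, and
treats ``Undetermined`` or blank Cq cells as missing wells.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from zdose.genotyping import (
    CohortResult,
    CqMeasurement,
    GenotypeConfig,
    TargetRole,
)

__all__ = [
    "RunConfig",
    "ParseResult",
    "parse_cq_export",
    "results_frame",
    "write_results",
    "run_report",
]

DEFAULT_ALIASES: dict[str, str] = {
    "autosome": "autosome",
    "auto": "autosome",
    "autosomal": "autosome",
    "sex": "sex",
    "z": "sex",
}

_MISSING_TOKENS = {"", "undetermined", "undet", "na", "nan", "n/a"}

_REQUIRED_COLUMNS = ("sample", "target", "cq")


@dataclass
class RunConfig:
    """Declarative run configuration (YAML key/value file).

    Unknown keys are rejected so typos cannot silently change a run; the
    full parsed configuration is echoed into every run report.
    """

    target_aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ALIASES)
    )
    outlier_threshold: float = 1.0
    threshold: float = -0.5
    male_standard: float | None = None
    min_cluster_gap: float = 0.3
    preset: str = "geneious2025"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a key/value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(unknown)}; "
                f"known keys: {', '.join(sorted(known))}"
            )
        if "target_aliases" in data:
            data["target_aliases"] = {
                str(k).lower(): str(v) for k, v in data["target_aliases"].items()
            }
        return cls(**data)

    def genotype_config(self) -> GenotypeConfig:
        return GenotypeConfig(
            outlier_threshold=self.outlier_threshold,
            threshold=self.threshold,
            male_standard=self.male_standard,
            min_cluster_gap=self.min_cluster_gap,
        )

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class ParseResult:
    measurements: list[CqMeasurement]
    unmapped_targets: Counter
    n_rows: int

    @property
    def n_unmapped(self) -> int:
        return sum(self.unmapped_targets.values())


def _parse_cq_cell(value: Any) -> float | None:
    if value is None:
        return None
    text = str(value).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"unparseable Cq value {value!r}") from exc


def parse_cq_export(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> ParseResult:
    """Read a Cq replicate table (CSV or TSV, auto-detected delimiter).

    Column matching is case-insensitive on Sample/Target/Cq (Well
    optional).  Target names are lower-cased and mapped to roles via
    ``aliases``; rows whose target has no alias are counted in
    ``unmapped_targets`` rather than silently dropped.
    """
    aliases = {k.lower(): v for k, v in (aliases or DEFAULT_ALIASES).items()}
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    colmap = {str(c).strip().lower(): c for c in df.columns}
    missing = [c for c in _REQUIRED_COLUMNS if c not in colmap]
    if missing:
        raise ValueError(
            f"missing required column(s) {missing} in {path}; "
            f"found columns: {list(df.columns)}"
        )
    well_col = colmap.get("well")
    measurements: list[CqMeasurement] = []
    unmapped: Counter = Counter()
    for _, row in df.iterrows():
        target_raw = str(row[colmap["target"]]).strip()
        role = aliases.get(target_raw.lower())
        if role is None:
            unmapped[target_raw] += 1
            continue
        measurements.append(
            CqMeasurement(
                sample_id=str(row[colmap["sample"]]).strip(),
                target_role=TargetRole(role),
                well_id=str(row[well_col]).strip() if well_col else "",
                cq=_parse_cq_cell(row[colmap["cq"]]),
            )
        )
    return ParseResult(
        measurements=measurements,
        unmapped_targets=unmapped,
        n_rows=len(df),
    )


def results_frame(result: CohortResult) -> pd.DataFrame:
    """Per-sample results table (one row per animal)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in result.samples],
            "delta_cq": [s.delta_cq for s in result.samples],
            "ddcq": [s.ddcq for s in result.samples],
            "sem_total": [s.sem_total for s in result.samples],
            "call": [s.call.value for s in result.samples],
            "reference_used": [s.reference_used for s in result.samples],
            "flags": [";".join(s.flags) for s in result.samples],
        }
    )


def write_results(result: CohortResult, path: str | Path) -> None:
    results_frame(result).to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_report(
    result: CohortResult,
    config: RunConfig | None = None,
    extra: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """JSON-ready run report with cluster diagnostics and the run log."""
    from zdose import __version__

    calls = Counter(s.call.value for s in result.samples)
    report: dict[str, Any] = {
        "version": __version__,
        "n_samples": len(result.samples),
        "calls": dict(calls),
        "reference_used": result.reference_used,
        "normalization_offset": result.normalization_offset,
        "threshold": result.threshold,
        "cluster": {
            "male_ids": result.male_cluster_ids,
            "female_ids": result.female_cluster_ids,
            "gap": result.cluster_gap,
            "median_distance": result.cluster_median_distance,
            "unimodal_flag": result.unimodal_flag,
        },
        "excluded": result.excluded,
        "log": result.log,
    }
    if config is not None:
        report["config"] = config.as_dict()
    if extra:
        report.update(extra)
    return report


def write_json(obj: Any, path: str | Path) -> None:
    def _default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, float):
            return o
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
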