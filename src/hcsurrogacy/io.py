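"""CSV input/output and run configuration.

Trial data travel as two plain CSV files: a long-format surrogate file (one
row per subject-visit) and an endpoint file (one row per subject).  Reports
are written as CSV with a ``#``-prefixed provenance header (config hash,
seed, package version) so a run can be reproduced byte-for-byte, plus a
fixed-width text rendering for human comparison (4 decimals, matching the
usual table style).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .longitudinal import DesignSubset, SurrogacyReport, TrialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "DEFAULT_COLUMN_MAPPING",
    "read_trial_csv",
    "write_trial_csv",
    "write_report",
    "read_report",
]

DEFAULT_COLUMN_MAPPING: dict[str, str] = {
    "subject_id": "subject_id",
    "arm": "arm",
    "week": "week",
    "surrogate": "surrogate",
    "endpoint": "endpoint",
}


@dataclass
class RunConfig:
    """Settings for an evaluation run, loadable from YAML or JSON."""

    alphas: tuple[float, ...] = (0.5, 1.0, 2.0)
    designs: tuple[tuple[int, ...], ...] = (
        (0, 24),
        (0, 24, 48),
        (0, 24, 48, 72),
        (0, 24, 48, 72, 96),
        (0, 48),
        (0, 72),
        (0, 24, 72),
        (0, 48, 72),
    )
    seed: int = 20220131
    permutations: int = 200
    column_mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAPPING))

    def __post_init__(self) -> None:
        self.alphas = tuple(float(a) for a in self.alphas)
        if any(a <= 0 for a in self.alphas):
            raise ValueError("entropy orders must be positive")
        self.designs = tuple(tuple(int(w) for w in d) for d in self.designs)

    def design_subsets(self) -> list[DesignSubset]:
        return [DesignSubset(d) for d in self.designs]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "alphas": self.alphas,
                "designs": self.designs,
                "seed": self.seed,
                "permutations": self.permutations,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _apply_mapping(df: pd.DataFrame, mapping: Mapping[str, str], needed: Sequence[str], path) -> pd.DataFrame:
    rename = {mapping.get(k, k): k for k in needed}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df.rename(columns=rename)[list(needed)]


def read_trial_csv(
    surrogate_path: str | Path,
    endpoint_path: str | Path,
    mapping: Mapping[str, str] | None = None,
) -> TrialDataset:
    """Read and validate the two trial CSVs into a :class:`TrialDataset`.

    ``mapping`` translates canonical column names (``subject_id``, ``arm``,
    ``week``, ``surrogate``, ``endpoint``) to the file's own headers.
    Malformed rows are reported with their file line numbers.
    """
    mapping = {**DEFAULT_COLUMN_MAPPING, **(mapping or {})}
    surr_raw = pd.read_csv(surrogate_path, comment="#")
    ep_raw = pd.read_csv(endpoint_path, comment="#")
    surr = _apply_mapping(surr_raw, mapping, ["subject_id", "arm", "week", "surrogate"], surrogate_path)
    ep = _apply_mapping(ep_raw, mapping, ["subject_id", "endpoint"], endpoint_path)

    bad = surr["surrogate"].isna() | surr["week"].isna()
    if bad.any():
        lines = (surr.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{surrogate_path}: malformed rows at lines {lines}")
    dup = surr.duplicated(subset=["subject_id", "week"])
    if dup.any():
        row = surr.loc[dup].iloc[0]
        line = int(surr.index[dup][0]) + 2
        raise ValueError(
            f"{surrogate_path}: duplicate visit (subject {row['subject_id']!r}, "
            f"week {row['week']}) at line {line}"
        )
    for name, frame, col in (("arm", surr, "arm"), ("endpoint", ep, "endpoint")):
        if not frame[col].isin((0, 1)).all():
            line = int(frame.index[~frame[col].isin((0, 1))][0]) + 2
            raise ValueError(f"{name} column must be 0/1 (first offence at line {line})")

    dataset = TrialDataset(surr, ep)
    logger.info(
        "read %d observations on %d subjects (arms %s)",
        len(dataset.observations),
        dataset.n_subjects,
        dataset.arm_sizes(),
    )
    return dataset


def write_trial_csv(
    data: TrialDataset, surrogate_path: str | Path, endpoint_path: str | Path
) -> None:
    data.observations.to_csv(surrogate_path, index=False)
    data.endpoints.reset_index().to_csv(endpoint_path, index=False)


def _provenance_lines(meta: Mapping[str, object]) -> list[str]:
    from . import __version__

    lines = [f"# hcsurrogacy {__version__}"]
    for key, value in meta.items():
        lines.append(f"# {key}: {value}")
    return lines


def write_report(
    report: SurrogacyReport,
    path: str | Path,
    measure: str = "both",
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a report as CSV (full precision) plus a ``.txt`` rendering (4 decimals).

    The CSV carries a ``#`` provenance header; :func:`read_report` reproduces
    the stored values exactly.
    """
    if report.table.empty:
        raise ValueError("cannot write an empty report")
    path = Path(path)
    wide = report.wide_frame(measure=measure)
    header = _provenance_lines(
        {
            "n_control": report.n_control,
            "n_treatment": report.n_treatment,
            "alphas": list(report.alphas),
            **(meta or {}),
        }
    )
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        wide.to_csv(fh)  # default float formatting is the shortest exact repr
    text_path = path.with_suffix(".txt")
    with text_path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(wide.to_string(float_format=lambda v: f"{v:.4f}"))
        fh.write("\n")
        if report.failures:
            fh.write("\nfailed designs:\n")
            for design, msg in report.failures.items():
                fh.write(f"  {design}: {msg}\n")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="design", float_precision="round_trip")
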