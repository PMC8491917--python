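"""Reading and writing tensile records, specimen metadata and result tables.

Internal canonical units are fixed to seconds / millimetres / newtons; any
unit conversion declared by a :class:`Dialect` happens at the I/O boundary so
downstream curve analysis never carries unit logic.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "FormatError",
    "SpecimenGeometry",
    "TensileRecord",
    "ValidationError",
    "get_logger",
    "read_geometry_table",
    "read_record",
    "setup_logging",
    "write_record",
    "write_summary_table",
]

DEFAULT_TECHNIQUES = ("PT", "FR", "WF")

#: Multiplicative factors to canonical units (s, mm, N).
_TIME_FACTORS = {"s": 1.0, "ms": 1e-3, "min": 60.0}
_LENGTH_FACTORS = {"mm": 1.0, "m": 1e3, "cm": 10.0, "um": 1e-3}
_FORCE_FACTORS = {"N": 1.0, "kN": 1e3, "mN": 1e-3}


class FormatError(ValueError):
    """A file does not match the declared dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


def get_logger(name: str = "tenomech") -> logging.Logger:
    return logging.getLogger(name)


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> logging.Logger:
    """Configure timestamped, level-tagged logging to stderr and optional file."""
    logger = get_logger()
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s [%(levelname)s] %(name)s: %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


@dataclass(frozen=True)
class Dialect:
    """Column names, units and layout of a delimited tensile-machine export.

    The default dialect is this project's canonical CSV
    (``time_s,displacement_mm,force_N``). Vendor exports are expressed as a
    dialect instance rather than a bespoke parser.
    """

    time_col: str = "time_s"
    displacement_col: str = "displacement_mm"
    force_col: str = "force_N"
    time_unit: str = "s"
    displacement_unit: str = "mm"
    force_unit: str = "N"
    delimiter: str = ","
    decimal: str = "."
    skip_rows: int = 0

    def factors(self) -> tuple[float, float, float]:
        try:
            return (
                _TIME_FACTORS[self.time_unit],
                _LENGTH_FACTORS[self.displacement_unit],
                _FORCE_FACTORS[self.force_unit],
            )
        except KeyError as exc:  # pragma: no cover - config typo path
            raise FormatError(f"unknown unit in dialect: {exc.args[0]!r}") from exc


@dataclass
class TensileRecord:
    """One specimen's sampled load-deformation trace in canonical s/mm/N units.

    ``preload`` is the slack-removal force applied before the test (2 N in the
    emulated protocol) and ``ramp_velocity`` the failure-ramp crosshead speed
    in mm/min; both are metadata the analysis thresholds refer back to.
    """

    specimen_id: str
    time_s: np.ndarray
    displacement_mm: np.ndarray
    force_n: np.ndarray
    preload: float = 2.0
    ramp_velocity: float = 100.0
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)

    def __len__(self) -> int:
        return self.time_s.size

    def validate(self, min_samples: int = 2) -> "TensileRecord":
        """Check domain invariants; returns self for chaining."""
        n = len(self)
        if not (self.displacement_mm.size == n == self.force_n.size):
            raise ValidationError(f"{self.specimen_id}: column lengths differ")
        if n < min_samples:
            raise ValidationError(f"{self.specimen_id}: only {n} samples (< {min_samples})")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError(f"{self.specimen_id}: time not strictly increasing")
        if not np.all(np.isfinite(self.force_n)):
            raise ValidationError(f"{self.specimen_id}: non-finite force values")
        if not np.all(np.isfinite(self.displacement_mm)):
            raise ValidationError(f"{self.specimen_id}: non-finite displacement values")
        return self

    def with_samples(
        self, time_s: np.ndarray, displacement_mm: np.ndarray, force_n: np.ndarray
    ) -> "TensileRecord":
        return replace(
            self, time_s=np.asarray(time_s, float),
            displacement_mm=np.asarray(displacement_mm, float),
            force_n=np.asarray(force_n, float),
        )


@dataclass(frozen=True)
class SpecimenGeometry:
    """Caliper measurements of one tenorrhaphy.

    Two orthogonal diameters (mm) for the donor tendon, the recipient tendon
    and the sutured repair zone, plus the tendon-tendon overlap length
    (target 30 mm in the emulated protocol).
    """

    specimen_id: str
    technique: str
    d_donor_1: float
    d_donor_2: float
    d_recip_1: float
    d_recip_2: float
    d_repair_1: float
    d_repair_2: float
    overlap: float

    def __post_init__(self) -> None:
        for name in ("d_donor_1", "d_donor_2", "d_recip_1", "d_recip_2", "d_repair_1", "d_repair_2"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{self.specimen_id}: diameter {name} must be > 0")
        if not self.overlap > 0:
            raise ValidationError(f"{self.specimen_id}: overlap must be > 0")


def read_record(path: str | Path, dialect: Dialect = Dialect(), *,
                specimen_id: str | None = None, preload: float = 2.0,
                ramp_velocity: float = 100.0) -> TensileRecord:
    """Read one specimen's tensile trace from a delimited text export.

    Columns are located by the dialect's names; units are converted so the
    returned record is always in s/mm/N. A missing column raises
    :class:`FormatError` naming the column; non-monotone time raises
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal,
                     skiprows=dialect.skip_rows)
    for col in (dialect.time_col, dialect.displacement_col, dialect.force_col):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r} (found {list(df.columns)})")
    ft, fd, ff = dialect.factors()
    rec = TensileRecord(
        specimen_id=specimen_id or path.stem,
        time_s=df[dialect.time_col].to_numpy(float) * ft,
        displacement_mm=df[dialect.displacement_col].to_numpy(float) * fd,
        force_n=df[dialect.force_col].to_numpy(float) * ff,
        preload=preload,
        ramp_velocity=ramp_velocity,
    )
    rec.validate(min_samples=2)
    if len(rec) < 10:
        get_logger().warning("%s: only %d samples; analysis operations need more", rec.specimen_id, len(rec))
    return rec


def write_record(record: TensileRecord, path: str | Path, dialect: Dialect = Dialect()) -> Path:
    """Write a record back to delimited text (canonical units, full precision)."""
    path = Path(path)
    ft, fd, ff = dialect.factors()
    df = pd.DataFrame({
        dialect.time_col: record.time_s / ft,
        dialect.displacement_col: record.displacement_mm / fd,
        dialect.force_col: record.force_n / ff,
    })
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.12g")
    return path


_GEOM_COLS = ["specimen_id", "technique", "d_donor_1", "d_donor_2",
              "d_recip_1", "d_recip_2", "d_repair_1", "d_repair_2", "overlap_mm"]


def read_geometry_table(path: str | Path,
                        techniques: Sequence[str] = DEFAULT_TECHNIQUES) -> list[SpecimenGeometry]:
    """Read the specimen metadata table (one row per tenorrhaphy).

    Technique labels are validated against ``techniques`` (default PT/FR/WF,
    extensible via config). An empty table returns an empty list with a
    logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _GEOM_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    if df.empty:
        get_logger().warning("%s: geometry table is empty", path.name)
        return []
    out: list[SpecimenGeometry] = []
    for _, row in df.iterrows():
        tech = str(row["technique"])
        if tech not in techniques:
            raise ValidationError(
                f"{row['specimen_id']}: unknown technique {tech!r}; allowed: {sorted(techniques)}")
        out.append(SpecimenGeometry(
            specimen_id=str(row["specimen_id"]), technique=tech,
            d_donor_1=float(row["d_donor_1"]), d_donor_2=float(row["d_donor_2"]),
            d_recip_1=float(row["d_recip_1"]), d_recip_2=float(row["d_recip_2"]),
            d_repair_1=float(row["d_repair_1"]), d_repair_2=float(row["d_repair_2"]),
            overlap=float(row["overlap_mm"]),
        ))
    return out


def write_geometry_table(geometries: Iterable[SpecimenGeometry], path: str | Path) -> Path:
    path = Path(path)
    rows = [{
        "specimen_id": g.specimen_id, "technique": g.technique,
        "d_donor_1": g.d_donor_1, "d_donor_2": g.d_donor_2,
        "d_recip_1": g.d_recip_1, "d_recip_2": g.d_recip_2,
        "d_repair_1": g.d_repair_1, "d_repair_2": g.d_repair_2,
        "overlap_mm": g.overlap,
    } for g in geometries]
    pd.DataFrame(rows, columns=_GEOM_COLS).to_csv(path, index=False, float_format="%.12g")
    return path


def write_summary_table(comparisons: Mapping[str, "object"], path: str | Path,
                        group_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Write the technique-comparison summary: one row per metric, one column
    per group holding ``mean (SD) letters``.

    ``comparisons`` maps a metric name (e.g. ``"stiffness_N_per_mm"``) to a
    :class:`tenomech.stats.GroupComparison`. Letter superscripts come from the
    comparison's letter assignment verbatim. Groups of size one are reported
    with SD 0 and flagged in the log.
    """
    logger = get_logger()
    rows = []
    groups: list[str] = list(group_order) if group_order else []
    for metric, comp in comparisons.items():
        if not groups:
            groups = list(comp.summaries)
        row: dict[str, object] = {"metric": metric}
        for g in groups:
            mean, sd = comp.summaries[g]
            if comp.n[g] == 1:
                logger.warning("metric %s group %s has n=1; SD reported as 0", metric, g)
            letters = comp.letters.get(g, "")
            row[g] = f"{mean:.2f} ({sd:.2f}) {letters}".rstrip()
        row["anova_p"] = comp.anova.p
        rows.append(row)
    df = pd.DataFrame(rows, columns=["metric", *groups, "anova_p"])
    df.to_csv(path, index=False, float_format="%.6g")
    return df
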