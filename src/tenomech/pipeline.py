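"""End-to-end orchestration: simulate or ingest, analyze, compare, report.

``run`` produces the study-style report bundle: a per-specimen feature table
(curve metrics joined with bulk geometry), one group-comparison table per
metric (mean, SD, Tukey–Kramer letters), a compact summary table with one
row per metric, and letter-annotated bar charts (means with SD bars). All
outputs are plain CSV/SVG and byte-reproducible given the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "tenomech"  # byte-reproducible figures
import matplotlib.pyplot as plt

from tenomech.curves import AnalysisThresholds, CurveFeatures, analyze_record
from tenomech.geometry import bulk_result
from tenomech.io import (
    Dialect,
    SpecimenGeometry,
    TensileRecord,
    ValidationError,
    get_logger,
    read_geometry_table,
    read_record,
    write_geometry_table,
    write_record,
    write_summary_table,
)
from tenomech.simulate import CohortParams, CurveParams, GroupParams, simulate_experiment, truths_to_frame
from tenomech.stats import GroupComparison, compare_groups

__all__ = ["ReportBundle", "RunConfig", "run", "load_config"]

#: Metrics compared across technique groups, with display units.
METRICS = {
    "bulk_ratio_pct": "bulk ratio (%)",
    "stiffness_n_per_mm": "stiffness (N/mm)",
    "first_failure_load_n": "first failure load (N)",
    "ultimate_load_n": "ultimate load (N)",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs.

    When ``records_dir`` is None the cohort is simulated from ``cohort``;
    otherwise record CSVs and the geometry table are read from disk using
    ``dialect``.
    """

    cohort: CohortParams = CohortParams()
    thresholds: AnalysisThresholds = AnalysisThresholds()
    dialect: Dialect = Dialect()
    alpha: float = 0.05
    seed: int = 0
    records_dir: str | None = None
    geometry_file: str | None = None
    bulk_denominator: str = "sum"
    write_records: bool = False
    make_figures: bool = True

    def validate(self) -> "RunConfig":
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        self.thresholds.validate()
        return self


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML key/value tree (missing keys default)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups = {
        label: GroupParams(**gp) for label, gp in raw.get("groups", {}).items()
    }
    protocol = CurveParams(**raw.get("protocol", {}))
    seed = int(raw.get("seed", 0))
    cohort_kwargs: dict = {"protocol": protocol, "seed": seed}
    if groups:
        cohort_kwargs["groups"] = groups
    return RunConfig(
        cohort=CohortParams(**cohort_kwargs),
        thresholds=AnalysisThresholds(**raw.get("thresholds", {})),
        dialect=Dialect(**raw.get("dialect", {})),
        alpha=float(raw.get("alpha", 0.05)),
        seed=seed,
        records_dir=raw.get("records_dir"),
        geometry_file=raw.get("geometry_file"),
        bulk_denominator=raw.get("bulk_denominator", "sum"),
        write_records=bool(raw.get("write_records", False)),
        make_figures=bool(raw.get("make_figures", True)),
    )


@dataclass
class ReportBundle:
    """In-memory results plus the paths written under the output directory."""

    features: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    truths: pd.DataFrame | None
    paths: dict[str, Path] = field(default_factory=dict)


def _features_frame(feats: list[CurveFeatures]) -> pd.DataFrame:
    return pd.DataFrame([{
        "specimen_id": f.specimen_id,
        "stiffness_n_per_mm": f.stiffness,
        "r2_linear": f.r2_linear,
        "linear_start_mm": f.linear_region[0],
        "linear_end_mm": f.linear_region[1],
        "first_failure_load_n": f.first_failure_load,
        "first_failure_displacement_mm": f.first_failure_displacement,
        "ultimate_load_n": f.ultimate_load,
        "ultimate_displacement_mm": f.ultimate_displacement,
        "failure_mode": f.failure_mode,
        "n_partial_failures": f.n_partial_failures,
    } for f in feats])


def _figure(comp: GroupComparison, ylabel: str, path: Path, group_order: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(4, 3.2))
    means = [comp.summaries[g][0] for g in group_order]
    sds = [comp.summaries[g][1] for g in group_order]
    x = np.arange(len(group_order))
    ax.bar(x, means, yerr=sds, capsize=4, color="#9bb7d4", edgecolor="black")
    for xi, g, m, s in zip(x, group_order, means, sds):
        ax.text(xi, m + s + 0.03 * max(means), comp.letters[g], ha="center",
                fontweight="bold")
    ax.set_xticks(x, group_order)
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 1.25 * max(m + s for m, s in zip(means, sds)))
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def run(config: RunConfig, out_dir: str | Path) -> ReportBundle:
    """Execute the whole pipeline into ``out_dir``; reproducible given seeds."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = get_logger()

    truths_df: pd.DataFrame | None = None
    if config.records_dir is None:
        logger.info("simulating cohort (seed %d)", config.cohort.seed)
        records, geometries, truths = simulate_experiment(config.cohort)
        truths_df = truths_to_frame(truths)
        truths_df.to_csv(out / "truths.csv", index=False, float_format="%.12g")
        if config.write_records:
            rec_dir = out / "records"
            rec_dir.mkdir(exist_ok=True)
            for rec in records:
                write_record(rec, rec_dir / f"{rec.specimen_id}.csv", config.dialect)
        write_geometry_table(geometries, out / "geometry.csv")
    else:
        if config.geometry_file is None:
            raise ValidationError("records_dir given without geometry_file")
        geometries = read_geometry_table(config.geometry_file)
        records = [read_record(p, config.dialect) for p in sorted(Path(config.records_dir).glob("*.csv"))]
        if not records:
            raise ValidationError(f"no record CSVs under {config.records_dir}")

    technique = {g.specimen_id: g.technique for g in geometries}
    group_order = list(dict.fromkeys(technique.values()))

    try:
        feats = [analyze_record(r, config.thresholds) for r in records]
    except ValidationError as exc:
        raise ValidationError(f"curve analysis stage failed: {exc}") from exc
    features = _features_frame(feats)
    bulks = pd.DataFrame([{
        "specimen_id": b.specimen_id,
        "area_donor_mm2": b.area_donor,
        "area_recipient_mm2": b.area_recipient,
        "area_repair_mm2": b.area_repair,
        "bulk_ratio_pct": b.bulk_ratio,
    } for b in (bulk_result(g, config.bulk_denominator) for g in geometries)])
    features = features.merge(bulks, on="specimen_id", how="left")
    features.insert(1, "technique", features.specimen_id.map(technique))
    features.to_csv(out / "features.csv", index=False, float_format="%.12g")

    comparisons: dict[str, GroupComparison] = {}
    for metric in METRICS:
        by_group = {
            g: features.loc[(features.technique == g) & features[metric].notna(), metric].to_numpy()
            for g in group_order
        }
        dropped = int(features[metric].isna().sum())
        if dropped:
            logger.warning("%s: %d specimens excluded (no valid value)", metric, dropped)
        try:
            comparisons[metric] = compare_groups(by_group, config.alpha, metric)
        except ValidationError as exc:
            raise ValidationError(f"statistics stage failed for {metric}: {exc}") from exc
        pd.DataFrame([{
            "group_a": r.group_a, "group_b": r.group_b, "mean_diff": r.mean_diff,
            "q_stat": r.q_stat, "p_adj": r.p_adj, "significant": r.significant,
        } for r in comparisons[metric].pairwise]).to_csv(
            out / f"pairwise_{metric}.csv", index=False, float_format="%.6g")

    summary = write_summary_table(comparisons, out / "summary.csv", group_order)
    logger.info("summary:\n%s", summary.to_string(index=False))

    paths = {"features": out / "features.csv", "summary": out / "summary.csv"}
    if config.make_figures:
        for metric, label in METRICS.items():
            fig_path = out / f"{metric}.svg"
            _figure(comparisons[metric], label, fig_path, group_order)
            paths[f"fig_{metric}"] = fig_path
    return ReportBundle(features=features, comparisons=comparisons,
                        truths=truths_df, paths=paths)
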