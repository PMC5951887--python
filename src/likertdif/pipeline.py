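"""Full-study orchestration: contrasts x subscales.

A study analysis is a grid of cells, one per (contrast, subscale):
listwise deletion, sparse-category collapsing, GRM calibration,
Monte-Carlo thresholds, iterative DIF purification, and — when items
are flagged — a DIF-adjusted recalibration with individual-level
impact.  Dimensionality checks run per subscale.  Cells are
independent: each derives its own seed deterministically from the
master seed and the cell name, so removing one cell from a plan never
changes another cell's output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    DataError,
    GroupAssignment,
    ResponseMatrix,
    ScaleDefinition,
    collapse_sparse_categories,
    listwise_subset,
)
from .dif_engine import DIFConfig, DIFRunResult, run_dif_purification
from .dimensionality import EigenReport, dimensionality_report
from .grm import FitError
from .impact import DEFAULT_SALIENCE_CUTOFF, ImpactSummary, cumulative_impact, purified_calibration


@dataclass
class Contrast:
    """A grouping variable (and optional level subset) to test for DIF."""

    name: str
    column: str
    levels: list[str] | None = None  # None: all observed levels


@dataclass
class AnalysisPlan:
    contrasts: list[Contrast]
    subscales: list[str] | None = None  # None: all subscales of the scale
    cfg: DIFConfig = field(default_factory=DIFConfig)
    min_cell: int = 5
    salience_cutoff: float = DEFAULT_SALIENCE_CUTOFF
    dimensionality_reps: int = 100
    out_dir: Path | None = None

    def validate(self, covariates: pd.DataFrame, scale: ScaleDefinition) -> None:
        if not self.contrasts:
            raise DataError("plan needs >= 1 contrast")
        for c in self.contrasts:
            if c.column not in covariates.columns:
                raise DataError(f"contrast {c.name!r} references missing column {c.column!r}")
        for s in self.subscales or []:
            if s not in scale.subscales:
                raise DataError(f"plan references unknown subscale {s!r}")


def cell_seed(master_seed: int, contrast: str, subscale: str) -> int:
    """Deterministic per-cell seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{contrast}:{subscale}".encode()) & 0x7FFFFFFF


@dataclass
class CellResult:
    contrast: str
    subscale: str
    seed: int
    n_used: int = 0
    dif: DIFRunResult | None = None
    impact: ImpactSummary | None = None
    error: str | None = None
    log: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.error is None

    @property
    def converged(self) -> bool:
        return self.dif is not None and self.dif.converged


@dataclass
class ReportBundle:
    cells: list[CellResult]
    dimensionality: dict[str, EigenReport]
    plan: AnalysisPlan

    @property
    def any_failed(self) -> bool:
        return any(not c.ok or not c.converged for c in self.cells)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "contrast": c.contrast,
                    "subscale": c.subscale,
                    "n": c.n_used,
                    "seed": c.seed,
                    "threshold": c.dif.thresholds.shared if c.dif else np.nan,
                    "n_flagged": len(c.dif.flagged_items) if c.dif else np.nan,
                    "flagged_items": ",".join(sorted(c.dif.flagged_items)) if c.dif else "",
                    "iterations": c.dif.n_iterations if c.dif else np.nan,
                    "converged": c.converged,
                    "n_salient": c.impact.n_salient if c.impact else 0,
                    "error": c.error or "",
                }
            )
        return pd.DataFrame(rows)


def group_from_column(covariates: pd.DataFrame, contrast: Contrast) -> GroupAssignment:
    col = covariates[contrast.column]
    labels = []
    for v in col:
        s = None if pd.isna(v) or str(v).strip() == "" else str(v)
        if s is not None and contrast.levels is not None and s not in contrast.levels:
            s = None  # outside the requested subset: treated as missing
        labels.append(s)
    return GroupAssignment(np.array(labels, dtype=object))


def _write_cell(out_dir: Path, cell: CellResult, cfg: DIFConfig, salience_cutoff: float) -> None:
    stem = out_dir / f"{cell.contrast}__{cell.subscale}"
    provenance = {
        "contrast": cell.contrast,
        "subscale": cell.subscale,
        "seed": cell.seed,
        "n_used": cell.n_used,
        "config": {
            "n_mc_replications": cfg.n_mc_replications,
            "threshold_grid": cfg.threshold_grid,
            "flag_rule": cfg.flag_rule,
            "max_iterations": cfg.max_iterations,
            "salience_cutoff": salience_cutoff,
        },
        "log": cell.log,
        "error": cell.error,
    }
    stem.with_suffix(".provenance.json").write_text(json.dumps(provenance, indent=2))
    if cell.dif is not None:
        cell.dif.write_tsv(stem.with_suffix(".dif.tsv"))
        cell.dif.to_json(stem.with_suffix(".dif.json"))
    if cell.impact is not None:
        cell.impact.write_csv(
            stem.with_suffix(".impact.csv"), stem.with_suffix(".impact_groups.csv")
        )


def run_analysis(
    plan: AnalysisPlan,
    m: ResponseMatrix,
    covariates: pd.DataFrame,
    scale: ScaleDefinition,
    do_impact: bool = True,
    do_dimensionality: bool = True,
) -> ReportBundle:
    """Run every (contrast x subscale) cell of the plan.

    ``covariates`` holds one row per person with the grouping columns
    the contrasts reference.  A failed stage is recorded in its cell
    and the remaining cells continue.  Impact analysis runs only for
    cells with flagged items (a note is logged otherwise).
    """
    plan.validate(covariates, scale)
    if len(covariates) != m.n_persons:
        raise DataError("covariates misaligned with responses")
    subscales = plan.subscales or list(scale.subscales)
    out_dir = Path(plan.out_dir) if plan.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    cells: list[CellResult] = []
    for contrast in plan.contrasts:
        g_full = group_from_column(covariates, contrast)
        for subscale in subscales:
            seed = cell_seed(plan.cfg.seed, contrast.name, subscale)
            cell = CellResult(contrast.name, subscale, seed)
            cfg = replace(plan.cfg, seed=seed)
            try:
                sub, g = listwise_subset(m, g_full, scale.subscales[subscale])
                g.validate()
                cell.n_used = sub.n_persons
                collapsed, report = collapse_sparse_categories(sub, g, plan.min_cell)
                if report.any_collapsed:
                    cell.log.append(
                        f"collapsed categories: {[(x.item_id, x.merged_code, x.into_code) for x in report.merges]}"
                    )
                cell.dif = run_dif_purification(collapsed, g, cfg, log=cell.log)
                if not do_impact:
                    pass
                elif cell.dif.flagged_items:
                    initial, _ = purified_calibration(collapsed, g, set())
                    purified, _ = purified_calibration(collapsed, g, cell.dif.flagged_items)
                    cell.impact = cumulative_impact(
                        initial, purified, g, plan.salience_cutoff, sub.person_ids
                    )
                    cell.log.append(
                        f"impact: {cell.impact.n_salient}/{sub.n_persons} salient at {plan.salience_cutoff}"
                    )
                else:
                    cell.log.append("no items flagged; impact analysis skipped")
            except (DataError, FitError) as exc:
                cell.error = str(exc)
            if out_dir is not None:
                _write_cell(out_dir, cell, cfg, plan.salience_cutoff)
            cells.append(cell)

    dim_reports: dict[str, EigenReport] = {}
    for subscale in subscales if do_dimensionality else []:
        seed = cell_seed(plan.cfg.seed, "dimensionality", subscale)
        items = scale.subscales[subscale]
        complete = ~np.isnan(m.subset_items(items).responses).any(axis=1)
        sub = m.subset_items(items).subset_persons(complete)
        rep = dimensionality_report(sub, R=plan.dimensionality_reps, seed=seed)
        dim_reports[subscale] = rep
        if out_dir is not None:
            rep.to_json(out_dir / f"dimensionality__{subscale}.json")

    bundle = ReportBundle(cells, dim_reports, plan)
    if out_dir is not None:
        bundle.summary_frame().to_csv(out_dir / "summary.csv", index=False)
    return bundle
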