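"""Monte-Carlo DIF thresholds and iterative purification.

Empirical flagging thresholds are generated from DIF-free samples: the
observed calibration is used to simulate replicate datasets in which
every group shares the same item parameters (group trait differences
are preserved by resampling trait values within group), the nested-
model pseudo-R2 changes are computed for every simulated item, and the
threshold is set on a fixed grid strictly above the largest statistic
seen anywhere in the simulation.  One threshold is used for all items
of an analysis; uniform (d12) and non-uniform (d23) changes share it.

Purification then iterates: items flagged against the threshold are
removed from the trait calibration, trait scores are re-estimated from
the anchor (non-flagged) items, all items are re-tested with the
updated scores, and the loop stops when two successive rounds flag the
same set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import DataError, GroupAssignment, ResponseMatrix
from .grm import (
    EAPScorer,
    FitError,
    GRMItemParams,
    ThetaScores,
    eap_scores,
    fit_grm,
    simulate_grm_codes,
)
from .ordinal_regression import DIFItemStats, batch_dif_statistics

FLAG_RULES = ("uniform", "nonuniform", "either")


@dataclass
class DIFConfig:
    """Settings for threshold generation and purification."""

    n_mc_replications: int = 100
    threshold_grid: float = 0.01
    flag_rule: str = "either"
    max_iterations: int = 10
    seed: int = 0
    fixed_threshold: float | None = None  # bypass Monte Carlo when set
    min_mc_success: float = 0.9

    def __post_init__(self) -> None:
        if self.n_mc_replications < 1:
            raise DataError("n_mc_replications must be >= 1")
        if self.threshold_grid <= 0:
            raise DataError("threshold_grid must be > 0")
        if self.flag_rule not in FLAG_RULES:
            raise DataError(f"flag_rule must be one of {FLAG_RULES}")


@dataclass
class MonteCarloThresholds:
    """Grid-ceiling threshold shared by the two pseudo-R2 changes."""

    d12: float
    d23: float
    max_simulated_d12: float
    max_simulated_d23: float
    n_replications_used: int
    n_replications_requested: int

    @property
    def shared(self) -> float:
        return self.d12


def _grid_ceiling(value: float, grid: float) -> float:
    """Smallest positive multiple of ``grid`` strictly greater than ``value``."""
    k = int(np.floor(value / grid + 1e-12)) + 1
    return round(max(k, 1) * grid, 10)


def monte_carlo_thresholds(
    params: Sequence[GRMItemParams],
    theta: ThetaScores,
    g: GroupAssignment,
    cfg: DIFConfig,
) -> MonteCarloThresholds:
    """Empirical DIF thresholds from DIF-free simulated samples.

    Each replication keeps the observed group sizes, draws trait values
    with replacement from the observed EAP scores within each group
    (preserving true group trait differences), simulates responses from
    the fitted item parameters shared by all groups, re-scores the
    simulated persons by EAP under those parameters, and computes
    single-pass d12/d23 for every item.  The returned threshold is the
    smallest multiple of ``cfg.threshold_grid`` strictly above the
    largest simulated statistic.
    """
    g.validate()
    if g.missing_mask.any():
        raise DataError("persons with missing group must be removed before Monte Carlo")
    rng = np.random.default_rng(cfg.seed)
    by_level = g.indices_by_level()
    n = g.n_persons
    scorer = EAPScorer(params)
    item_ids = [p.item_id for p in params]

    max_d12 = 0.0
    max_d23 = 0.0
    n_ok = 0
    failures: list[str] = []
    warm: dict = {}
    for _ in range(cfg.n_mc_replications):
        theta_sim = np.empty(n)
        for idx in by_level.values():
            theta_sim[idx] = rng.choice(theta.theta[idx], size=idx.size, replace=True)
        sim = simulate_grm_codes(params, theta_sim, rng)
        try:
            theta_hat = scorer.score(sim)
            stats = batch_dif_statistics(sim, theta_hat, g, item_ids, warm=warm)
            for st in stats:
                max_d12 = max(max_d12, st.d12)
                max_d23 = max(max_d23, st.d23)
        except (FitError, DataError) as exc:
            failures.append(str(exc))
            continue
        n_ok += 1
    if n_ok < cfg.min_mc_success * cfg.n_mc_replications:
        raise FitError(
            f"only {n_ok}/{cfg.n_mc_replications} Monte-Carlo replications succeeded; "
            f"example failure: {failures[0] if failures else 'n/a'}"
        )
    shared = _grid_ceiling(max(max_d12, max_d23), cfg.threshold_grid)
    return MonteCarloThresholds(shared, shared, max_d12, max_d23, n_ok, cfg.n_mc_replications)


@dataclass
class ItemFlag:
    item_id: str
    uniform: bool
    nonuniform: bool

    @property
    def flagged(self) -> bool:
        return self.uniform or self.nonuniform


@dataclass
class DIFRunResult:
    """Outcome of one purification run (one subscale x one contrast)."""

    thresholds: MonteCarloThresholds
    iterations: list[set[str]]
    final_flags: dict[str, ItemFlag]
    stats_table: list[DIFItemStats]
    anchor_items: list[str]
    converged: bool
    item_params: list[GRMItemParams]
    theta: ThetaScores
    flag_rule: str

    @property
    def flagged_items(self) -> set[str]:
        return {i for i, f in self.final_flags.items() if f.flagged}

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "item": s.item_id,
                "d12": s.d12,
                "d23": s.d23,
                "flagged_uniform": self.final_flags[s.item_id].uniform,
                "flagged_nonuniform": self.final_flags[s.item_id].nonuniform,
                "threshold": self.thresholds.shared,
            }
            for s in self.stats_table
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.thresholds.shared,
            "max_simulated_d12": self.thresholds.max_simulated_d12,
            "max_simulated_d23": self.thresholds.max_simulated_d23,
            "iterations": [sorted(s) for s in self.iterations],
            "converged": self.converged,
            "flag_rule": self.flag_rule,
            "anchor_items": list(self.anchor_items),
            "flags": {
                i: {"uniform": f.uniform, "nonuniform": f.nonuniform}
                for i, f in self.final_flags.items()
            },
            "stats": [
                {"item": s.item_id, "d12": s.d12, "d23": s.d23, "d13": s.d13, "n": s.n}
                for s in self.stats_table
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _stats_all_items(
    m: ResponseMatrix, theta: ThetaScores, g: GroupAssignment
) -> list[DIFItemStats]:
    return batch_dif_statistics(m.responses, theta, g, list(m.item_ids))


def _flags_from_stats(
    stats: Sequence[DIFItemStats], threshold: float, flag_rule: str
) -> dict[str, ItemFlag]:
    flags = {}
    for s in stats:
        uni = s.d12 >= threshold
        non = s.d23 >= threshold
        if flag_rule == "uniform":
            non = False
        elif flag_rule == "nonuniform":
            uni = False
        flags[s.item_id] = ItemFlag(s.item_id, uni, non)
    return flags


def run_dif_purification(
    m: ResponseMatrix,
    g: GroupAssignment,
    cfg: DIFConfig,
    log: list[str] | None = None,
) -> DIFRunResult:
    """Iterative DIF detection with anchor-based trait purification.

    ``m`` must already be listwise-complete and category-collapsed for
    the analysis.  Round 0 calibrates the graded response model on all
    items, scores persons by EAP, generates Monte-Carlo thresholds from
    that calibration (held fixed afterwards), and flags items whose
    pseudo-R2 change meets the threshold.  Each later round recalibrates
    on the non-flagged anchors, re-scores, re-tests all items, and the
    loop ends when two successive rounds agree.  Hitting
    ``max_iterations`` returns a result marked non-converged.
    """
    g.validate()
    if m.n_persons != g.n_persons:
        raise DataError("responses and groups misaligned")
    if g.missing_mask.any() or np.isnan(m.responses).any():
        raise DataError("run listwise_subset before DIF purification")
    msg = log.append if log is not None else (lambda s: None)

    params0, _ = fit_grm(m)
    theta0 = eap_scores(params0, m)
    if cfg.fixed_threshold is not None:
        thr = MonteCarloThresholds(
            cfg.fixed_threshold, cfg.fixed_threshold, np.nan, np.nan, 0, 0
        )
    else:
        thr = monte_carlo_thresholds(params0, theta0, g, cfg)
    msg(f"threshold={thr.shared} (max simulated d12={thr.max_simulated_d12:.4f}, d23={thr.max_simulated_d23:.4f})")

    stats = _stats_all_items(m, theta0, g)
    flags = _flags_from_stats(stats, thr.shared, cfg.flag_rule)
    flagged = {i for i, f in flags.items() if f.flagged}
    iterations = [set(flagged)]
    msg(f"round 0: flagged {sorted(flagged) or 'none'}")
    params_t, theta_t = params0, theta0

    converged = not flagged  # nothing flagged: round 0 is final
    while not converged:
        if len(iterations) > cfg.max_iterations:
            break
        anchors = [i for i in m.item_ids if i not in flagged]
        if not anchors:
            raise FitError(
                "all items flagged for DIF; no anchor items remain "
                f"(threshold {thr.shared}, rounds {[sorted(s) for s in iterations]})"
            )
        if len(anchors) == 1:
            raise FitError(
                f"only one anchor item ({anchors[0]}) remains; trait recalibration needs >= 2"
            )
        sub = m.subset_items(anchors)
        init = [params0[m.item_index(i)] for i in anchors]
        params_anchor, _ = fit_grm(sub, init=init)
        theta_t = eap_scores(params_anchor, sub)
        params_t = params_anchor
        stats = _stats_all_items(m, theta_t, g)
        flags = _flags_from_stats(stats, thr.shared, cfg.flag_rule)
        new_flagged = {i for i, f in flags.items() if f.flagged}
        iterations.append(set(new_flagged))
        msg(f"round {len(iterations) - 1}: flagged {sorted(new_flagged) or 'none'}")
        if new_flagged == flagged:
            converged = True
        flagged = new_flagged

    anchors = [i for i in m.item_ids if i not in flagged]
    if converged and not anchors:
        raise FitError("all items flagged for DIF; no anchor items remain")
    if not converged:
        msg(f"no agreement after {cfg.max_iterations} rounds; marked non-converged")
    return DIFRunResult(
        thresholds=thr,
        iterations=iterations,
        final_flags=flags,
        stats_table=stats,
        anchor_items=anchors,
        converged=converged,
        item_params=list(params_t),
        theta=theta_t,
        flag_rule=cfg.flag_rule,
    )
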