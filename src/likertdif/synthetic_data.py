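"""Synthetic multi-cohort Likert study generator.

Stands in for the raw multi-site HIV Stigma Scale data the analysis
pipeline expects: three cohorts (default sizes 250 / 188 / 598 with
modest trait-mean differences), a 32-item four-subscale instrument on
a 4-point Likert scale, a binary gender column with cohort-specific
female proportions, missing-completely-at-random cells, and optional
injected DIF.  Uniform DIF shifts every threshold of one item for one
group by a constant; non-uniform DIF multiplies that group's
discrimination.  The full generating truth (trait values, item
parameters, injections) is recorded for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import DataError, GroupAssignment, ResponseMatrix, ScaleDefinition, bundled_scale
from .grm import GRMItemParams, simulate_grm

DEFAULT_GROUPS = [
    ("IN", 250, 0.25, 1.0),
    ("SE", 188, -0.25, 1.0),
    ("US", 598, 0.0, 1.0),
]
DEFAULT_FEMALE_PROPS = {"IN": 0.50, "SE": 0.43, "US": 0.34}


@dataclass
class GroupSpec:
    name: str
    n: int
    theta_mean: float = 0.0
    theta_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError(f"group {self.name!r}: n must be >= 1")
        if self.theta_sd <= 0:
            raise DataError(f"group {self.name!r}: theta_sd must be > 0")


@dataclass
class DIFInjection:
    """Planted DIF on one item for one group.

    ``uniform``: ``magnitude`` is added to every threshold of the item
    for that group (the item becomes harder/easier to endorse at all
    trait levels).  ``nonuniform``: the group's discrimination is
    multiplied by ``magnitude`` (> 0), so the group effect varies with
    the trait.
    """

    item_id: str
    group: str
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "nonuniform"):
            raise DataError("injection kind must be 'uniform' or 'nonuniform'")
        if not np.isfinite(self.magnitude):
            raise DataError("injection magnitude must be finite")
        if self.kind == "nonuniform" and self.magnitude <= 0:
            raise DataError("nonuniform magnitude multiplies a discrimination; must be > 0")


@dataclass
class StudySpec:
    """Design of a synthetic study."""

    groups: list[GroupSpec] = field(
        default_factory=lambda: [GroupSpec(*g) for g in DEFAULT_GROUPS]
    )
    scale: ScaleDefinition = field(default_factory=bundled_scale)
    K: int = 4
    a_range: tuple[float, float] = (1.2, 2.5)
    threshold_sd: float = 1.0
    min_threshold_gap: float = 0.3
    dif_injections: list[DIFInjection] = field(default_factory=list)
    missing_rate: float = 0.0
    female_props: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FEMALE_PROPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must be in [0, 1)")
        items = set(self.scale.all_items)
        groups = {g.name for g in self.groups}
        for inj in self.dif_injections:
            if inj.item_id not in items:
                raise DataError(f"injection on unknown item {inj.item_id!r}")
            if inj.group not in groups:
                raise DataError(f"injection on unknown group {inj.group!r}")


@dataclass
class StudyData:
    """A generated study with its full generating truth."""

    responses: ResponseMatrix
    groups: GroupAssignment
    gender: np.ndarray
    scale: ScaleDefinition
    truth: dict


def _draw_item_params(rng: np.random.Generator, spec: StudySpec, item_id: str) -> GRMItemParams:
    a = rng.uniform(*spec.a_range)
    for _ in range(1000):
        b = np.sort(rng.normal(0.0, spec.threshold_sd, size=spec.K - 1))
        if spec.K == 2 or np.diff(b).min() >= spec.min_threshold_gap:
            return GRMItemParams(item_id, a, b)
    raise DataError("could not draw thresholds with the requested minimum gap")


def _injected(base: GRMItemParams, inj: DIFInjection) -> GRMItemParams:
    if inj.kind == "uniform":
        return GRMItemParams(base.item_id, base.a, base.b + inj.magnitude)
    return GRMItemParams(base.item_id, base.a * inj.magnitude, base.b.copy())


def generate_study(spec: StudySpec) -> StudyData:
    """Draw a full study: traits, item parameters, responses, gender.

    Persons are blocked by group in the listed order.  All groups share
    the base item parameters except where an injection applies.
    Reproducible: the same spec (including seed) gives identical data.
    """
    rng = np.random.default_rng(spec.seed)
    items = spec.scale.all_items
    base_params = {i: _draw_item_params(rng, spec, i) for i in items}

    theta_parts = []
    labels = []
    gender_parts = []
    for gspec in spec.groups:
        theta_parts.append(rng.normal(gspec.theta_mean, gspec.theta_sd, size=gspec.n))
        labels.extend([gspec.name] * gspec.n)
        p_female = spec.female_props.get(gspec.name, 0.5)
        gender_parts.append(np.where(rng.random(gspec.n) < p_female, "female", "male"))
    theta = np.concatenate(theta_parts)
    gender = np.concatenate(gender_parts)
    groups = GroupAssignment(np.array(labels, dtype=object))

    inj_map = {(inj.item_id, inj.group): inj for inj in spec.dif_injections}
    n_total = theta.size
    mat = np.empty((n_total, len(items)))
    row0 = 0
    for gspec in spec.groups:
        rows = slice(row0, row0 + gspec.n)
        params_g = [
            _injected(base_params[i], inj_map[(i, gspec.name)])
            if (i, gspec.name) in inj_map
            else base_params[i]
            for i in items
        ]
        block = simulate_grm(params_g, theta[rows], rng)
        mat[rows] = block.responses
        row0 += gspec.n

    if spec.missing_rate > 0:
        mask = rng.random(mat.shape) < spec.missing_rate
        mat[mask] = np.nan

    person_ids = [f"p{i:04d}" for i in range(n_total)]
    responses = ResponseMatrix(mat, person_ids, list(items), spec.K)
    truth = {
        "seed": spec.seed,
        "groups": [asdict(g) for g in spec.groups],
        "theta": theta.tolist(),
        "item_params": {
            i: {"a": p.a, "b": p.b.tolist()} for i, p in base_params.items()
        },
        "dif_injections": [asdict(inj) for inj in spec.dif_injections],
        "missing_rate": spec.missing_rate,
    }
    return StudyData(responses, groups, gender, spec.scale, truth)


def write_study(study: StudyData, directory: str | Path) -> dict[str, Path]:
    """Write responses CSV, scale YAML and truth JSON to a directory.

    The CSV holds one row per respondent: ``person_id``, ``group``,
    ``gender``, then one column per item with blank cells for missing.
    Round-trips through :func:`likertdif.core_io.load_responses`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m = study.responses

    df = pd.DataFrame({"person_id": m.person_ids, "group": study.groups.labels, "gender": study.gender})
    resp = m.to_frame().reset_index(drop=True)
    resp = resp.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df = pd.concat([df, resp], axis=1)
    paths = {
        "responses": directory / "responses.csv",
        "scale": directory / "scale.yaml",
        "truth": directory / "truth.json",
    }
    df.to_csv(paths["responses"], index=False)
    study.scale.to_yaml(paths["scale"])
    paths["truth"].write_text(json.dumps(study.truth, indent=2))
    return paths
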