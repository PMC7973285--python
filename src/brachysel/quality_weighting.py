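"""Per-fraction training weights from dosimetric plan quality.

Each treatment fraction carries eight EMBRACE-style dosimetric metrics
(D90/D98 of the targets, Point A EQD2, and the 2-cc doses of bladder, rectum
and sigmoid). A fraction whose plan violates more than two planning aims is
down-weighted to 0.5, and any hard dose-constraint violation down-weights it
to 0.25; otherwise the fraction trains at full weight. The weighting lets
the classifier learn preferentially from fractions whose applicator choice
produced a high-quality plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "EMBRACE_METRICS",
    "Bound",
    "ConstraintConfig",
    "ViolationCount",
    "count_violations",
    "assign_weight",
    "weight_fraction",
    "DosimetricWeighter",
]

#: The eight plan-quality metrics, Gy (EQD2 where applicable).
EMBRACE_METRICS = (
    "D90 HR-CTV",
    "D98 HR-CTV",
    "D98 GTV",
    "D98 IR-CTV",
    "Point A EQD2",
    "Bladder D2cc",
    "Rectum D2cc",
    "Sigmoid D2cc",
)

#: The three weight strata, best to worst plan quality.
WEIGHT_LEVELS = (1.0, 0.5, 0.25)


@dataclass(frozen=True)
class Bound:
    """A one-sided dose bound: the metric satisfies it when ``value op bound``."""

    op: str  # ">=" or "<="
    value: float

    def __post_init__(self) -> None:
        if self.op not in (">=", "<="):
            raise ValueError(f"bound op must be '>=' or '<=', got {self.op!r}")

    def satisfied_by(self, x: float) -> bool:
        return x >= self.value if self.op == ">=" else x <= self.value


@dataclass
class ConstraintConfig:
    """Planning aims and optional hard dose constraints per metric.

    For a metric with both bounds the hard constraint must be no stricter
    than the planning aim in the aim's direction (a value violating the hard
    constraint necessarily violates the aim).
    """

    aims: dict[str, Bound] = field(default_factory=dict)
    hard: dict[str, Bound] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metric, hb in self.hard.items():
            aim = self.aims.get(metric)
            if aim is None:
                continue
            if aim.op != hb.op:
                raise ValueError(f"{metric}: aim and constraint directions differ")
            lax = hb.value <= aim.value if aim.op == ">=" else hb.value >= aim.value
            if not lax:
                raise ValueError(
                    f"{metric}: hard constraint ({hb.value}) is stricter than "
                    f"the planning aim ({aim.value})"
                )

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self.aims)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ConstraintConfig":
        aims, hard = {}, {}
        for metric, spec in payload.items():
            if "planning_aim" not in spec:
                raise ValueError(f"{metric}: missing planning_aim")
            a = spec["planning_aim"]
            aims[metric] = Bound(op=a["op"], value=float(a["value"]))
            if "dose_constraint" in spec:
                h = spec["dose_constraint"]
                hard[metric] = Bound(op=h["op"], value=float(h["value"]))
        return cls(aims=aims, hard=hard)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstraintConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "ConstraintConfig":
        """The packaged EMBRACE II reference bounds (external reference
        values; override with a site-specific YAML for clinical use)."""
        text = (
            resources.files("brachysel")
            .joinpath("data/embrace2_constraints.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class ViolationCount:
    """Number of metrics violating their planning aim / hard constraint."""

    n_aim: int
    n_hard: int

    def __post_init__(self) -> None:
        if self.n_aim < 0 or self.n_hard < 0:
            raise ValueError("violation counts must be non-negative")


def count_violations(
    record: Mapping[str, float], config: ConstraintConfig
) -> ViolationCount:
    """Count per-metric aim and hard-constraint violations for one fraction.

    ``record`` maps metric names to dose values (Gy); metrics missing from
    the record count as no violation. Counting is per metric: a metric that
    fails both its aim and its hard bound adds one to each counter.
    """
    shared = [m for m in config.metrics if m in record and record[m] is not None]
    if not shared:
        raise ValueError(
            "dosimetric record shares no metrics with the constraint config"
        )
    n_aim = n_hard = 0
    for metric in shared:
        x = float(record[metric])
        if not config.aims[metric].satisfied_by(x):
            n_aim += 1
        hb = config.hard.get(metric)
        if hb is not None and not hb.satisfied_by(x):
            n_hard += 1
    return ViolationCount(n_aim=n_aim, n_hard=n_hard)


def assign_weight(v: ViolationCount) -> float:
    """Map violation counts to the training weight.

    Any hard-constraint violation yields 0.25 regardless of aim count; more
    than two aim violations (with no hard violation) yields 0.5; otherwise
    1.0. Total over all count pairs, and monotone non-increasing in each
    count.
    """
    if v.n_hard >= 1:
        return 0.25
    if v.n_aim > 2:
        return 0.5
    return 1.0


def weight_fraction(
    record: Mapping[str, float], config: ConstraintConfig | None = None
) -> float:
    """Convenience: violation counting + weight assignment for one record."""
    if config is None:
        config = ConstraintConfig.default()
    return assign_weight(count_violations(record, config))


class DosimetricWeighter:
    """Vectorized weight assignment over a cohort of dosimetric records.

    Parameters
    ----------
    config : ConstraintConfig, optional
        Dose bounds; defaults to the packaged EMBRACE II reference values.
    """

    def __init__(self, config: ConstraintConfig | None = None):
        self.config = config if config is not None else ConstraintConfig.default()

    def weights(self, records: Iterable[Mapping[str, float]]) -> list[float]:
        return [assign_weight(count_violations(r, self.config)) for r in records]
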