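"""Filter-width calculus for the multi-dimensional U-CNN.

Each encoder/decoder level of the network owns a width budget
``M = beta * F_n``, where ``F_n`` is the matched U-Net stage width and
``beta`` (default 1.56) scales it so that the full model stays smaller than
the matched U-Net.  The budget is split ``M/6, M/3, M/2`` across the three
chained 3x3 convolutions of the level's multi-dimensional block; the block's
1x1 residual projection must produce exactly the sum of the triple so that
the residual addition is shape-compatible.

Two modes exist: ``formula`` derives the triples from ``beta`` and
``base_filters``; ``table_literal`` returns the published five-level 2D
schedule verbatim.  The published 1x1 widths differ slightly from the triple
sums and are unusable for a residual addition, so they are retained only as
``printed_res1`` metadata while the normative width is the sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ScheduleConfig",
    "LevelAllocation",
    "PathPlan",
    "level_width",
    "allocate_block_filters",
    "table_literal_schedule",
    "build_schedule",
    "path_plan",
    "schedule_to_yaml",
    "schedule_from_yaml",
]

_ROUNDERS = {
    "floor": math.floor,
    "ceil": math.ceil,
    "nearest": lambda v: int(round(v)),
}

#: Published five-level 2D schedule: 3x3 triples and printed 1x1 widths.
_TABLE_TRIPLES = [(7, 18, 26), (18, 36, 54), (36, 73, 107),
                  (72, 144, 216), (146, 292, 428)]
_TABLE_PRINTED_RES1 = [52, 106, 214, 428, 856]

#: Skip-path unit widths for the five-level 2D model (path-1..4).
TABLE_PATH_WIDTHS = [32, 64, 128, 256]


@dataclass(frozen=True)
class LevelAllocation:
    """Filter counts of one multi-dimensional block level."""

    level: int
    M: float
    conv3_filters: tuple[int, int, int]
    res1_filters: int
    printed_res1: int | None = None

    def __post_init__(self):
        n1, n2, n3 = self.conv3_filters
        if not (1 <= n1 <= n2 <= n3):
            raise ValueError(f"triple must be >=1 and non-decreasing, got {self.conv3_filters}")
        if self.res1_filters != n1 + n2 + n3:
            raise ValueError(
                f"res1_filters must equal the triple sum {n1 + n2 + n3}, got {self.res1_filters}")


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of the filter-width rule."""

    beta: float = 1.56
    base_filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    fractions: tuple[float, float, float] = (1 / 6, 1 / 3, 1 / 2)
    rounding: str = "floor"
    mode: str = "table_literal"

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.rounding not in _ROUNDERS:
            raise ValueError(f"rounding must be one of {sorted(_ROUNDERS)}")
        if self.mode not in ("formula", "table_literal"):
            raise ValueError("mode must be 'formula' or 'table_literal'")
        bf = self.base_filters
        if any(b2 != 2 * b1 for b1, b2 in zip(bf, bf[1:])):
            raise ValueError("base_filters must double at every level")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class PathPlan:
    """Residual-unit layout of the skip paths, shallowest level first."""

    unit_counts: tuple[int, ...]
    unit_widths: tuple[int, ...]

    def __post_init__(self):
        if len(self.unit_counts) != len(self.unit_widths):
            raise ValueError("unit_counts and unit_widths must align")
        if any(c < 1 for c in self.unit_counts):
            raise ValueError("every path needs at least one unit")
        if any(a <= b for a, b in zip(self.unit_counts, self.unit_counts[1:])):
            raise ValueError("unit counts must strictly decrease with depth")

    @property
    def depth(self) -> int:
        return len(self.unit_counts)


def level_width(beta: float, F: int) -> float:
    """Width budget of one level: ``M = beta * F``."""
    if beta <= 0 or F < 1:
        raise ValueError(f"beta and F must be positive, got beta={beta}, F={F}")
    return beta * F


def allocate_block_filters(M: float, config: ScheduleConfig | None = None,
                           level: int = 1) -> LevelAllocation:
    """Split a width budget ``M`` into the block's three 3x3 filter counts.

    The three chained convolutions receive the rounded fractions of ``M``
    (defaults 1/6, 1/3, 1/2 — progressively wider), and the 1x1 residual
    projection receives their sum.
    """
    config = config or ScheduleConfig(mode="formula")
    rounder = _ROUNDERS[config.rounding]
    triple = tuple(int(rounder(M * f)) for f in sorted(config.fractions))
    if any(n < 1 for n in triple):
        raise ValueError(f"M={M} too small: rounded allocation {triple} has a zero count")
    return LevelAllocation(level=level, M=M, conv3_filters=triple,
                           res1_filters=sum(triple))


def table_literal_schedule() -> list[LevelAllocation]:
    """The published five-level 2D schedule, verbatim.

    ``res1_filters`` is the triple sum (51, 108, 216, 432, 866), which the
    residual addition requires; the published 1x1 widths (52, 106, 214, 428,
    856) are carried as ``printed_res1``.
    """
    out = []
    base = ScheduleConfig()
    for i, (triple, printed) in enumerate(zip(_TABLE_TRIPLES, _TABLE_PRINTED_RES1)):
        M = level_width(base.beta, base.base_filters[i])
        out.append(LevelAllocation(level=i + 1, M=M, conv3_filters=triple,
                                   res1_filters=sum(triple), printed_res1=printed))
    return out


def build_schedule(config: ScheduleConfig, levels: int | None = None) -> list[LevelAllocation]:
    """Materialize per-level allocations under ``config``.

    ``levels`` defaults to ``len(config.base_filters)``; in ``table_literal``
    mode it must be 5 (the published depth).
    """
    n = levels if levels is not None else len(config.base_filters)
    if config.mode == "table_literal":
        table = table_literal_schedule()
        if n != len(table):
            raise ValueError(f"table_literal mode defines exactly {len(table)} levels, "
                             f"requested {n}")
        return table
    if n > len(config.base_filters):
        raise ValueError(f"requested {n} levels but base_filters has {len(config.base_filters)}")
    return [
        allocate_block_filters(level_width(config.beta, config.base_filters[i]),
                               config, level=i + 1)
        for i in range(n)
    ]


def path_plan(depth: int, base_widths: list[int] | tuple[int, ...]) -> PathPlan:
    """Skip-path layout: ``depth - level + 1`` residual units at each level
    (the deepest path has one), unit width read from ``base_widths``."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(base_widths) < depth:
        raise ValueError(f"need {depth} base widths, got {len(base_widths)}")
    counts = tuple(depth - lvl for lvl in range(depth))
    return PathPlan(unit_counts=counts, unit_widths=tuple(base_widths[:depth]))


# ---------------------------------------------------------------------------
# YAML round-trip


def schedule_to_yaml(config: ScheduleConfig, levels: list[LevelAllocation]) -> str:
    doc = {
        "beta": config.beta,
        "base_filters": list(config.base_filters),
        "rounding": config.rounding,
        "mode": config.mode,
        "levels": [
            {"conv3": list(a.conv3_filters), "res1": a.res1_filters,
             "printed_res1": a.printed_res1}
            for a in levels
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def schedule_from_yaml(text: str) -> tuple[ScheduleConfig, list[LevelAllocation]]:
    doc = yaml.safe_load(text)
    config = ScheduleConfig(beta=doc["beta"], base_filters=tuple(doc["base_filters"]),
                            rounding=doc["rounding"], mode=doc["mode"])
    levels = [
        LevelAllocation(level=i + 1,
                        M=level_width(config.beta, config.base_filters[i]),
                        conv3_filters=tuple(entry["conv3"]),
                        res1_filters=entry["res1"],
                        printed_res1=entry.get("printed_res1"))
        for i, entry in enumerate(doc["levels"])
    ]
    return config, levels
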