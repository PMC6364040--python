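"""Polar geometry of the circular plot.

Every population receives the same angular span (360/P degrees) regardless of
how many individuals it holds, so the figure stays a circle of fixed perimeter
whatever the sampling design.  Within a population, individuals get
equal-width wedges tiling the population's span; each individual's bar has a
fixed radial length partitioned into K segments proportional to its ancestry
vector.  An optional target population is summarized as a pie at the center,
with slice angles of 360 x mean proportion.

Angles are stored in standard math convention (degrees, counterclockwise
positive, 0 = east) as *unwrapped* values along the winding direction: with
the defaults (start at 90, clockwise) population i spans
``[90 - i*span, 90 - (i+1)*span]``.  Unwrapped angles keep widths exact;
anything user-facing (label anchors) is normalized into [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import UnknownLabelError, ValidationError
from .ordering import PlotOrder, PopulationSummary
from .qio import AncestryMatrix

__all__ = [
    "GeometryConfig",
    "PopulationSpan",
    "Wedge",
    "LabelPlacement",
    "PieSlice",
    "CircularLayout",
    "compute_layout",
    "compute_center_pie",
    "place_labels",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Tunable geometry of the figure, all in relative figure units/degrees."""

    start_angle: float = 90.0  # top of the circle
    clockwise: bool = True
    inner_radius: float = 0.45
    outer_radius: float = 1.0
    label_radius: float = 1.04
    pie_radius: float = 0.40
    separators: bool = True
    target_in_ring: bool = True  # highlighted target also stays in the ring

    def __post_init__(self) -> None:
        if not (0 <= self.inner_radius < self.outer_radius):
            raise ValidationError("need 0 <= inner_radius < outer_radius")
        if self.label_radius <= 0 or self.pie_radius <= 0:
            raise ValidationError("radii must be positive")

    @property
    def direction(self) -> float:
        return -1.0 if self.clockwise else 1.0


@dataclass(frozen=True)
class PopulationSpan:
    label: str
    start_angle: float
    end_angle: float

    @property
    def width(self) -> float:
        return abs(self.end_angle - self.start_angle)

    @property
    def midpoint(self) -> float:
        return (self.start_angle + self.end_angle) / 2.0


@dataclass(frozen=True)
class Wedge:
    """One individual's bar: an angular slot plus its K radial fractions."""

    row_index: int
    start_angle: float
    end_angle: float
    segments: tuple[float, ...]  # K fractions of the bar length, sum to 1

    @property
    def width(self) -> float:
        return abs(self.end_angle - self.start_angle)


@dataclass(frozen=True)
class LabelPlacement:
    label: str
    anchor_angle: float  # normalized to [0, 360)
    rotation: float
    flip: bool


@dataclass(frozen=True)
class PieSlice:
    ancestry: int
    start_angle: float
    end_angle: float

    @property
    def width(self) -> float:
        return abs(self.end_angle - self.start_angle)


@dataclass(frozen=True)
class CircularLayout:
    """Fully resolved geometry, ready to draw."""

    populations: tuple[PopulationSpan, ...]
    wedges: tuple[Wedge, ...]
    separators: tuple[float, ...]
    labels: tuple[LabelPlacement, ...]
    center_pie: Optional[tuple[PieSlice, ...]]
    config: GeometryConfig = field(default_factory=GeometryConfig)

    @property
    def inner_radius(self) -> float:
        return self.config.inner_radius

    @property
    def outer_radius(self) -> float:
        return self.config.outer_radius

    @property
    def label_radius(self) -> float:
        return self.config.label_radius


def _label_for_span(span: PopulationSpan, config: GeometryConfig) -> LabelPlacement:
    anchor = span.midpoint % 360.0
    # Left half-circle in screen convention: flip so text reads outward.
    flip = 90.0 < anchor <= 270.0
    rotation = anchor - 180.0 if flip else anchor
    return LabelPlacement(span.label, anchor, rotation, flip)


def place_labels(
    layout: CircularLayout, config: Optional[GeometryConfig] = None
) -> tuple[LabelPlacement, ...]:
    """One label per population at the angular midpoint of its span."""
    cfg = config or layout.config
    return tuple(_label_for_span(span, cfg) for span in layout.populations)


def _pie_from_mean(
    mean: np.ndarray, config: GeometryConfig
) -> tuple[PieSlice, ...]:
    d = config.direction
    slices = []
    cursor = config.start_angle
    for a, frac in enumerate(mean):
        extent = 360.0 * float(frac)
        slices.append(PieSlice(a, cursor, cursor + d * extent))
        cursor += d * extent
    return tuple(slices)


def compute_center_pie(dataset, target: str, config: Optional[GeometryConfig] = None):
    """Pie slices for a target population: 360 x its mean proportion vector.

    Slices are emitted in ancestry-index order starting at the configured
    start angle.  For a single-individual target the mean is the individual's
    own ancestry vector.
    """
    from .ordering import summarize_population

    cfg = config or GeometryConfig()
    summary = summarize_population(dataset, target)
    return _pie_from_mean(summary.mean_proportions, cfg)


def compute_layout(
    order: PlotOrder,
    matrix: AncestryMatrix,
    target: Optional[str] = None,
    config: Optional[GeometryConfig] = None,
) -> CircularLayout:
    """Turn a plotting order into resolved polar geometry.

    Each population's span is exactly 360/P degrees; individual wedges within
    population p are (360/P)/n_p wide.  When a ``target`` is given its mean
    composition becomes the center pie; with ``config.target_in_ring`` off the
    target is dropped from the ring and shown only as the pie.
    """
    cfg = config or GeometryConfig()
    if order.n_populations == 0:
        raise ValidationError("cannot lay out an empty plotting order")

    target_summary: Optional[PopulationSummary] = None
    if target is not None:
        for s in order.population_sequence:
            if s.label == target:
                target_summary = s
                break
        if target_summary is None:
            raise UnknownLabelError(f"target population not in plot: {target!r}")

    seq = list(zip(order.population_sequence, order.members_by_population))
    if target_summary is not None and not cfg.target_in_ring:
        seq = [(s, m) for s, m in seq if s.label != target]
        if not seq:
            raise ValidationError("removing the target from the ring leaves nothing")

    p = len(seq)
    span = 360.0 / p
    d = cfg.direction

    spans: list[PopulationSpan] = []
    wedges: list[Wedge] = []
    separators: list[float] = []
    for i, (summary, members) in enumerate(seq):
        a0 = cfg.start_angle + d * i * span
        a1 = cfg.start_angle + d * (i + 1) * span
        spans.append(PopulationSpan(summary.label, a0, a1))
        separators.append(a0)
        n = len(members)
        w = span / n
        for j, row in enumerate(members):
            w0 = a0 + d * j * w
            w1 = a0 + d * (j + 1) * w
            wedges.append(Wedge(row, w0, w1, tuple(float(v) for v in matrix.values[row])))

    pie = (
        _pie_from_mean(target_summary.mean_proportions, cfg)
        if target_summary is not None
        else None
    )

    layout = CircularLayout(
        populations=tuple(spans),
        wedges=tuple(wedges),
        separators=tuple(separators) if cfg.separators else (),
        labels=(),
        center_pie=pie,
        config=cfg,
    )
    return replace(layout, labels=place_labels(layout))
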