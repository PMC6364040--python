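"""Figure drawing and the declarative PlotSpec.

The PlotSpec is a canonical, ordered, plain-text description of every drawn
primitive (annular sector, separator line, label, pie slice) with coordinates
rounded to six decimals.  It fully determines the drawing, is byte-stable
across runs, and is the artifact golden-file tests and determinism checks
compare.  The figure itself (PDF, PNG or SVG) is drawn from the same layout
with matplotlib.
"""

from __future__ import annotations

import colorsys
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.collections import LineCollection, PatchCollection
from matplotlib.figure import Figure
from matplotlib.patches import Wedge as MplWedge

from .errors import FormatError, ValidationError
from .layout import CircularLayout
from .qio import read_color_scheme_lines

__all__ = [
    "ColorScheme",
    "PlotSpec",
    "RenderOptions",
    "default_palette",
    "read_color_scheme",
    "build_plot_spec",
    "render_figure",
]

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")

#: Curated categorical palette used for K <= 12; chosen for pairwise contrast.
_BASE_PALETTE = (
    "#E41A1C",  # red
    "#377EB8",  # blue
    "#4DAF4A",  # green
    "#984EA3",  # purple
    "#FF7F00",  # orange
    "#A65628",  # brown
    "#F781BF",  # pink
    "#999999",  # grey
    "#66C2A5",  # teal
    "#FFD92F",  # yellow
    "#8DA0CB",  # periwinkle
    "#B15928",  # rust
)


@dataclass(frozen=True)
class ColorScheme:
    """Ordered mapping ancestry index -> hex color."""

    colors: tuple[str, ...]
    source: Literal["default", "user_file"] = "default"

    def __post_init__(self) -> None:
        for c in self.colors:
            if not _HEX_RE.match(c):
                raise FormatError(f"not a #RRGGBB color: {c!r}")

    @property
    def k(self) -> int:
        return len(self.colors)


def default_palette(k: int) -> ColorScheme:
    """Deterministic palette for K ancestries.

    The first min(K, 12) colors come from a fixed curated list; further
    colors are generated by evenly spaced hue rotation so any K gets distinct
    colors without randomness.
    """
    if k < 2:
        raise ValidationError(f"need at least 2 ancestries, got {k}")
    colors = list(_BASE_PALETTE[:k])
    extra = k - len(colors)
    for i in range(extra):
        hue = (i / extra + 0.07) % 1.0
        r, g, b = colorsys.hsv_to_rgb(hue, 0.55, 0.80)
        colors.append(f"#{round(r*255):02X}{round(g*255):02X}{round(b*255):02X}")
    if len(set(colors)) != k:
        raise ValidationError(f"palette generation produced duplicate colors for K={k}")
    return ColorScheme(tuple(colors), source="default")


def read_color_scheme(path: str | Path, k: int) -> ColorScheme:
    """Read a user color-scheme file (the format write_color_scheme emits)."""
    colors = read_color_scheme_lines(path)
    if len(colors) != k:
        raise ValidationError(
            f"{path}: color scheme has {len(colors)} entries but data has K={k}"
        )
    for c in colors:
        if not _HEX_RE.match(c):
            raise FormatError(f"{path}: not a #RRGGBB color: {c!r}")
    return ColorScheme(tuple(colors), source="user_file")


@dataclass(frozen=True)
class PlotSpec:
    """Canonical textual form of a drawing; byte-identical for equal inputs."""

    lines: tuple[str, ...]

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.text, encoding="utf-8")

    def count(self, kind: str) -> int:
        prefix = kind + " "
        return sum(1 for ln in self.lines if ln.startswith(prefix))


def _f(x: float) -> str:
    s = f"{x:.6f}"
    return "0.000000" if s == "-0.000000" else s


def build_plot_spec(layout: CircularLayout, scheme: ColorScheme) -> PlotSpec:
    """List every primitive the figure contains, in canonical order.

    Order: annular sectors (by wedge, ancestry 0 innermost first), separator
    lines, labels, then pie slices.  Zero-proportion segments are skipped
    rather than emitted with zero extent.
    """
    k = len(layout.wedges[0].segments) if layout.wedges else scheme.k
    if scheme.k != k:
        raise ValidationError(f"color scheme has {scheme.k} colors but data has K={k}")

    cfg = layout.config
    bar = cfg.outer_radius - cfg.inner_radius
    lines: list[str] = [
        "plotspec v1",
        f"ring inner={_f(cfg.inner_radius)} outer={_f(cfg.outer_radius)}",
    ]
    for w in layout.wedges:
        cum = 0.0
        for a, frac in enumerate(w.segments):
            if frac == 0.0:
                continue
            r0 = cfg.inner_radius + cum * bar
            cum += frac
            r1 = cfg.inner_radius + cum * bar
            lines.append(
                f"sector row={w.row_index} anc={a} "
                f"t0={_f(w.start_angle)} t1={_f(w.end_angle)} "
                f"r0={_f(r0)} r1={_f(r1)} fill={scheme.colors[a]}"
            )
    for angle in layout.separators:
        lines.append(
            f"line t={_f(angle)} r0={_f(cfg.inner_radius)} "
            f"r1={_f(cfg.outer_radius)} stroke=#000000"
        )
    for lab in layout.labels:
        lines.append(
            f"text label={lab.label} angle={_f(lab.anchor_angle)} "
            f"r={_f(cfg.label_radius)} rot={_f(lab.rotation)} flip={int(lab.flip)}"
        )
    if layout.center_pie is not None:
        for sl in layout.center_pie:
            if sl.width == 0.0:
                continue
            lines.append(
                f"pie anc={sl.ancestry} t0={_f(sl.start_angle)} "
                f"t1={_f(sl.end_angle)} r={_f(cfg.pie_radius)} "
                f"fill={scheme.colors[sl.ancestry]}"
            )
    return PlotSpec(tuple(lines))


@dataclass(frozen=True)
class RenderOptions:
    """Figure output settings."""

    format: Literal["pdf", "png", "svg"] = "pdf"
    dpi: int = 300
    figsize: float = 10.0  # square canvas, logical units
    label_fontsize: float = 6.0

    def __post_init__(self) -> None:
        if self.format not in ("pdf", "png", "svg"):
            raise ValidationError(
                f"unknown output format {self.format!r} (use pdf, png or svg)"
            )


def render_figure(
    layout: CircularLayout,
    scheme: ColorScheme,
    path: str | Path,
    options: Optional[RenderOptions] = None,
) -> PlotSpec:
    """Draw the layout to a figure file and return its PlotSpec.

    The drawing is generated from exactly the primitives the PlotSpec lists;
    the layout is never mutated.
    """
    opts = options or RenderOptions()
    spec = build_plot_spec(layout, scheme)

    cfg = layout.config
    bar = cfg.outer_radius - cfg.inner_radius
    fig = Figure(figsize=(opts.figsize, opts.figsize))
    FigureCanvasAgg(fig)
    ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
    ax.set_aspect("equal")
    lim = max(cfg.label_radius, cfg.outer_radius) * 1.18
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axis("off")

    import math

    patches = []
    facecolors = []
    for w in layout.wedges:
        t_lo, t_hi = sorted((w.start_angle, w.end_angle))
        cum = 0.0
        for a, frac in enumerate(w.segments):
            if frac == 0.0:
                continue
            r0 = cfg.inner_radius + cum * bar
            cum += frac
            r1 = cfg.inner_radius + cum * bar
            patches.append(MplWedge((0, 0), r1, t_lo, t_hi, width=r1 - r0))
            facecolors.append(scheme.colors[a])
    ax.add_collection(
        PatchCollection(patches, facecolors=facecolors, linewidths=0)
    )
    if layout.separators:
        segs = []
        for angle in layout.separators:
            rad = math.radians(angle)
            segs.append(
                (
                    (cfg.inner_radius * math.cos(rad), cfg.inner_radius * math.sin(rad)),
                    (cfg.outer_radius * math.cos(rad), cfg.outer_radius * math.sin(rad)),
                )
            )
        ax.add_collection(LineCollection(segs, colors="#000000", linewidths=0.5))
    for lab in layout.labels:
        rad = math.radians(lab.anchor_angle)
        ax.text(
            cfg.label_radius * math.cos(rad),
            cfg.label_radius * math.sin(rad),
            lab.label,
            rotation=lab.rotation,
            rotation_mode="anchor",
            ha="right" if lab.flip else "left",
            va="center",
            fontsize=opts.label_fontsize,
        )
    if layout.center_pie is not None:
        for sl in layout.center_pie:
            if sl.width == 0.0:
                continue
            t_lo, t_hi = sorted((sl.start_angle, sl.end_angle))
            ax.add_patch(
                MplWedge(
                    (0, 0), cfg.pie_radius, t_lo, t_hi,
                    facecolor=scheme.colors[sl.ancestry],
                    linewidth=0,
                )
            )

    fig.savefig(Path(path), format=opts.format, dpi=opts.dpi)
    return spec
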