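"""Value-to-style mapping: breakpoints, color bins, thickness scales, histograms.

Each visual channel owns a :class:`ChannelState`: a set of strictly increasing
breakpoints partitioning the data range into k bins, bound either to k discrete
colors (color channels) or to a linear stroke-width ramp (thickness channels).
Colors are binned, not interpolated, because the legend is drawn as discrete
regions each reporting how many data points fall inside it.

Bin convention: half-open intervals [b_i, b_{i+1}); a value on an interior
boundary falls in the upper bin; the top boundary itself falls in the last
bin; out-of-range values clamp into the extreme bins (they are never errors —
dragging a breakpoint can legitimately push data outside the painted range).
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import yaml

from .network import MetabolicNetwork
from .omics import CHANNELS, SingleOmicsDataset

log = logging.getLogger(__name__)

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")

MISSING_COLOR = "#bbbbbb"
DEFAULT_N_BINS = 5
DEFAULT_THICKNESS_RANGE = (1.0, 10.0)

#: Shipped palettes as anchor colors; scales of any bin count are built by
#: linear RGB interpolation across the anchors.
PALETTES: dict[str, list[str]] = {
    "green-red": ["#1a9641", "#a6d96a", "#ffffbf", "#fdae61", "#d7191c"],
    "blue-red": ["#2c7bb6", "#abd9e9", "#ffffbf", "#fdae61", "#d7191c"],
    "white-red": ["#ffffff", "#fcae91", "#fb6a4a", "#de2d26", "#a50f15"],
    "white-blue": ["#ffffff", "#bdd7e7", "#6baed6", "#3182bd", "#08519c"],
}
DEFAULT_PALETTE = "green-red"


@dataclass(frozen=True)
class Breakpoints:
    """k+1 strictly increasing boundaries defining k bins over [lo, hi]."""

    boundaries: tuple[float, ...]

    def __post_init__(self):
        if len(self.boundaries) < 3:
            raise ValueError("need at least 2 bins (3 boundaries)")
        for a, b in zip(self.boundaries, self.boundaries[1:]):
            if not a < b:
                raise ValueError(f"boundaries not strictly increasing: {a} >= {b}")
        object.__setattr__(self, "boundaries", tuple(float(b) for b in self.boundaries))

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @property
    def lo(self) -> float:
        return self.boundaries[0]

    @property
    def hi(self) -> float:
        return self.boundaries[-1]

    def bin_index(self, v: float) -> int:
        """0-based bin for a value, clamping out-of-range into the end bins."""
        i = bisect_right(self.boundaries, v) - 1
        return min(max(i, 0), self.n_bins - 1)


@dataclass(frozen=True)
class ColorScale:
    name: str
    colors: tuple[str, ...]
    missing_color: str = MISSING_COLOR

    def __post_init__(self):
        for c in [*self.colors, self.missing_color]:
            if not _HEX_RE.match(c):
                raise ValueError(f"invalid hex color {c!r}")
        object.__setattr__(self, "colors", tuple(self.colors))


def _hex_to_rgb(c: str) -> tuple[int, int, int]:
    return int(c[1:3], 16), int(c[3:5], 16), int(c[5:7], 16)


def _rgb_to_hex(rgb) -> str:
    return "#%02x%02x%02x" % tuple(int(round(x)) for x in rgb)


def make_color_scale(palette: str, n_bins: int, missing_color: str = MISSING_COLOR) -> ColorScale:
    """Build an n-bin scale from a named palette by linear RGB interpolation."""
    anchors = [_hex_to_rgb(c) for c in PALETTES[palette]]
    if n_bins == 1:
        return ColorScale(palette, (PALETTES[palette][0],), missing_color)
    colors = []
    for i in range(n_bins):
        t = i / (n_bins - 1) * (len(anchors) - 1)
        j = min(int(t), len(anchors) - 2)
        f = t - j
        rgb = [a + (b - a) * f for a, b in zip(anchors[j], anchors[j + 1])]
        colors.append(_rgb_to_hex(rgb))
    return ColorScale(palette, tuple(colors), missing_color)


@dataclass(frozen=True)
class ChannelState:
    """Mapping configuration for one visual channel.

    Exactly one of ``color_scale`` / ``thickness_range`` is set, matching the
    channel kind.  Values are always clamped, never rejected.
    """

    channel: str
    breakpoints: Breakpoints
    color_scale: ColorScale | None = None
    thickness_range: tuple[float, float] | None = None
    clamp: bool = True

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        is_color = self.channel.endswith("_color")
        if is_color and (self.color_scale is None or self.thickness_range is not None):
            raise ValueError(f"{self.channel} needs a color scale only")
        if not is_color and (
            self.thickness_range is None or self.color_scale is not None
        ):
            raise ValueError(f"{self.channel} needs a thickness range only")
        if self.color_scale is not None and len(self.color_scale.colors) != self.breakpoints.n_bins:
            raise ValueError(
                f"{len(self.color_scale.colors)} colors for "
                f"{self.breakpoints.n_bins} bins"
            )
        if self.thickness_range is not None and not (
            0 <= self.thickness_range[0] <= self.thickness_range[1]
        ):
            raise ValueError(f"bad thickness range {self.thickness_range}")

    @property
    def is_color(self) -> bool:
        return self.channel.endswith("_color")


def default_channel_state(
    channel: str,
    values,
    signed: bool,
    n_bins: int = DEFAULT_N_BINS,
    palette: str = DEFAULT_PALETTE,
    thickness_range: tuple[float, float] = DEFAULT_THICKNESS_RANGE,
) -> ChannelState:
    """Default state: 5 bins, symmetric for signed data, green-to-red colors."""
    bp = default_breakpoints(values, n_bins, signed)
    if channel.endswith("_color"):
        return ChannelState(
            channel=channel, breakpoints=bp, color_scale=make_color_scale(palette, n_bins)
        )
    return ChannelState(channel=channel, breakpoints=bp, thickness_range=thickness_range)


# -- breakpoint construction ----------------------------------------------


def default_breakpoints(values, n_bins: int, signed: bool) -> Breakpoints:
    """Equally spaced bins over the data range.

    Signed data gets a range symmetric about zero, [-M, M] with M the largest
    absolute value, so the neutral color sits on zero.  Unsigned data spans
    [min(0, data min), data max].
    """
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("cannot derive breakpoints from all-missing data")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if signed:
        m = max(abs(v) for v in vals)
        if m == 0:
            m = 1.0
        lo, hi = -m, m
    else:
        lo = min(0.0, min(vals))
        hi = max(vals)
        if hi <= lo:
            hi = lo + 1.0
    step = (hi - lo) / n_bins
    bounds = [lo + i * step for i in range(n_bins)] + [hi]
    return Breakpoints(tuple(bounds))


def drag_breakpoint(breakpoints: Breakpoints, boundary_index: int, new_value: float) -> Breakpoints:
    """Move an interior boundary, affinely rescaling the boundaries on each side.

    Dragging a boundary grows the adjacent extreme region while every other
    region on that side shrinks proportionally; the overall [lo, hi] range and
    the bin count never change.
    """
    bounds = breakpoints.boundaries
    k = breakpoints.n_bins
    if not 0 < boundary_index < k:
        raise ValueError(f"boundary index {boundary_index} is not interior (1..{k - 1})")
    lo, hi, old = bounds[0], bounds[-1], bounds[boundary_index]
    if not lo < new_value < hi:
        raise ValueError(f"new boundary {new_value} outside open range ({lo}, {hi})")
    new_bounds = list(bounds)
    for i in range(1, boundary_index):
        new_bounds[i] = lo + (bounds[i] - lo) / (old - lo) * (new_value - lo)
    new_bounds[boundary_index] = new_value
    for i in range(boundary_index + 1, k):
        new_bounds[i] = hi - (hi - bounds[i]) / (hi - old) * (hi - new_value)
    return Breakpoints(tuple(new_bounds))


# -- value -> style --------------------------------------------------------


def value_to_color(v: float | None, state: ChannelState) -> str:
    if not state.is_color:
        raise ValueError(f"{state.channel} is not a color channel")
    if v is None:
        return state.color_scale.missing_color
    return state.color_scale.colors[state.breakpoints.bin_index(v)]


def value_to_thickness(v: float | None, state: ChannelState) -> float:
    if state.is_color:
        raise ValueError(f"{state.channel} is not a thickness channel")
    lo_px, hi_px = state.thickness_range
    if v is None:
        return lo_px
    lo, hi = state.breakpoints.lo, state.breakpoints.hi
    t = (v - lo) / (hi - lo)
    t = min(max(t, 0.0), 1.0)
    return lo_px + t * (hi_px - lo_px)


# -- omics -> diagram entities --------------------------------------------


@dataclass
class EntityValueSeries:
    """Per-frame values for one painted diagram entity (reaction or compound)."""

    target_id: str
    values: list[float | None]
    source_tokens: list[str] = field(default_factory=list)


class ResolvedDataset(list):
    """List of :class:`EntityValueSeries` with resolution bookkeeping."""

    def __init__(self, series, n_unmapped_tokens: int, channel: str):
        super().__init__(series)
        self.n_unmapped_tokens = n_unmapped_tokens
        self.channel = channel


AGGREGATIONS = ("max_magnitude", "mean", "first")


def _aggregate(values: list[float | None], how: str) -> float | None:
    present = [v for v in values if v is not None]
    if not present:
        return None
    if how == "max_magnitude":
        best = present[0]
        for v in present[1:]:
            if abs(v) > abs(best):
                best = v
        return best
    if how == "mean":
        return sum(present) / len(present)
    if how == "first":
        return present[0]
    raise ValueError(f"unknown aggregation {how!r}")


def resolve_targets(
    dataset: SingleOmicsDataset,
    network: MetabolicNetwork,
    aggregation: str = "max_magnitude",
    n_frames: int | None = None,
) -> ResolvedDataset:
    """Resolve each table row to diagram entities and build per-frame series.

    A gene/protein row paints every reaction the gene catalyzes; several rows
    landing on one entity are combined per frame by the aggregation policy
    (default ``max_magnitude``: keep the value of largest absolute magnitude,
    first occurrence winning ties).  Unmatched tokens are counted and warned
    about, never fatal.  Series are padded to ``n_frames`` by holding the last
    column, so short datasets stay static through later animation frames.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    n = n_frames if n_frames is not None else dataset.n_selected
    per_target: dict[str, list[tuple[str, list[float | None]]]] = {}
    n_unmapped = 0
    for token, raw_values in dataset.table.rows:
        targets = network.lookup_entity(token, dataset.spec.data_type)
        if not targets:
            n_unmapped += 1
            continue
        sel = dataset.selected_values(raw_values)
        padded = sel + [sel[-1]] * (n - len(sel)) if len(sel) < n else sel[:n]
        for tid in sorted(targets):
            per_target.setdefault(tid, []).append((token, padded))
    series = []
    for tid in sorted(per_target):
        contribs = per_target[tid]
        frames = [
            _aggregate([vals[f] for _, vals in contribs], aggregation) for f in range(n)
        ]
        series.append(
            EntityValueSeries(
                target_id=tid, values=frames, source_tokens=[t for t, _ in contribs]
            )
        )
    if n_unmapped:
        log.warning(
            "dataset %r: %d tokens matched nothing", dataset.spec.dataset_id, n_unmapped
        )
    return ResolvedDataset(series, n_unmapped, dataset.spec.target_channel)


# -- histogram -------------------------------------------------------------


@dataclass
class HistogramSummary:
    bin_counts: list[int]
    n_total: int
    n_missing: int
    n_unmapped_tokens: int = 0

    def __post_init__(self):
        if sum(self.bin_counts) != self.n_total - self.n_missing:
            raise ValueError("histogram counts do not conserve data points")


def compute_histogram(
    series: list[EntityValueSeries],
    frame: int,
    breakpoints: Breakpoints,
    n_unmapped_tokens: int = 0,
) -> HistogramSummary:
    """Count, per bin, the data points painted at one animation frame.

    Clamped values accumulate in the extreme bins, so counts always conserve:
    sum(bins) + missing = total.
    """
    counts = [0] * breakpoints.n_bins
    n_missing = 0
    n_total = 0
    for s in series:
        v = s.values[frame]
        n_total += 1
        if v is None:
            n_missing += 1
        else:
            counts[breakpoints.bin_index(v)] += 1
    return HistogramSummary(
        bin_counts=counts,
        n_total=n_total,
        n_missing=n_missing,
        n_unmapped_tokens=n_unmapped_tokens,
    )


# -- (de)serialization -----------------------------------------------------


def channel_state_to_dict(state: ChannelState) -> dict:
    d: dict = {
        "channel": state.channel,
        "breakpoints": list(state.breakpoints.boundaries),
    }
    if state.color_scale is not None:
        d["palette"] = state.color_scale.name
        d["colors"] = list(state.color_scale.colors)
        d["missing_color"] = state.color_scale.missing_color
    if state.thickness_range is not None:
        d["thickness_range"] = list(state.thickness_range)
    return d


def channel_state_from_dict(d: dict) -> ChannelState:
    bp = Breakpoints(tuple(d["breakpoints"]))
    if "colors" in d:
        scale = ColorScale(
            name=d.get("palette", "custom"),
            colors=tuple(d["colors"]),
            missing_color=d.get("missing_color", MISSING_COLOR),
        )
        return ChannelState(channel=d["channel"], breakpoints=bp, color_scale=scale)
    return ChannelState(
        channel=d["channel"],
        breakpoints=bp,
        thickness_range=tuple(d["thickness_range"]),
    )


def save_channel_states(states: dict[str, ChannelState], path) -> None:
    doc = {ch: channel_state_to_dict(st) for ch, st in states.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_channel_states(path) -> dict[str, ChannelState]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return {ch: channel_state_from_dict(d) for ch, d in doc.items()}
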