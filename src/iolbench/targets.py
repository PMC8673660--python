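"""Object/source fixtures: USAF-1951 resolution target and plane-wave input.

The three-bar chart is generated programmatically (binary chrome-on-glass
style, bars transmissive on an opaque background by default, so the bright
bars carry the light).  Spatial frequency of group g, element e is
2^(g + (e-1)/6) line pairs per mm; bar length is five bar widths.  The
layout follows the standard chart's structure — elements of a group in two
staggered columns with horizontal and vertical bar triplets — without the
engraved legend artwork.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_core import ComplexField

__all__ = ["TransmissionMask", "generate_usaf_target", "generate_plane_wave",
           "bar_frequency"]


@dataclass
class TransmissionMask:
    """Real transmission in [0, 1] on a uniform grid with pitch in mm."""

    transmission: np.ndarray
    pitch: float

    def __post_init__(self):
        self.transmission = np.asarray(self.transmission, dtype=float)
        if self.transmission.min() < -1e-9 or self.transmission.max() > 1 + 1e-9:
            raise ValueError("transmission values must lie in [0, 1]")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def extent(self):
        ny, nx = self.transmission.shape
        return (nx * self.pitch, ny * self.pitch)

    def x(self):
        n = self.transmission.shape[1]
        return (np.arange(n) - n // 2) * self.pitch

    def y(self):
        n = self.transmission.shape[0]
        return (np.arange(n) - n // 2) * self.pitch


def bar_frequency(group: int, element: int) -> float:
    """Line pairs per mm of a chart element (1-based element index)."""
    return 2.0 ** (group + (element - 1) / 6.0)


def _draw_rect(img, x, y, x0, x1, y0, y1):
    img[(x >= x0) & (x < x1) & (y >= y0) & (y < y1)] = 1.0


def _draw_element(img, xx, yy, cx, cy, width):
    """Three horizontal bars left of center, three vertical bars right.

    Each triplet occupies an L x L block (L = 5 x bar width, the standard
    bar length); the blocks are separated by one bar width."""
    L = 5.0 * width
    x0 = cx - L - width / 2
    for i in (-2, 0, 2):
        _draw_rect(img, xx, yy, x0, x0 + L,
                   cy + i * width - width / 2, cy + i * width + width / 2)
    x1 = cx + width / 2 + L / 2
    for i in (-2, 0, 2):
        _draw_rect(img, xx, yy, x1 + i * width - width / 2,
                   x1 + i * width + width / 2, cy - L / 2, cy + L / 2)


def generate_usaf_target(extent: float = 5.0, samples: int = 1024,
                         groups: tuple[int, ...] = (2, 3),
                         bars_transmissive: bool = True) -> TransmissionMask:
    """Binary USAF-1951-style three-bar target.

    ``extent`` is the square side in mm; ``groups`` the chart groups to
    render.  Each group is laid out as two sub-columns (elements 1-3 and
    4-6), mirroring the standard chart's element pairs.  The default groups
    are those whose bars stay resolvable through the bench.  Raises if the
    finest requested bar would span fewer than 2 samples.
    """
    pitch = extent / samples
    finest = 1.0 / (2.0 * bar_frequency(max(groups), 6))
    if finest < 2 * pitch:
        raise ValueError(
            f"finest element bar width {finest * 1e3:.1f} um needs >= 2 samples; "
            f"pitch is {pitch * 1e3:.1f} um — raise `samples` or drop groups")
    ax = (np.arange(samples) - samples // 2) * pitch
    xx, yy = np.meshgrid(ax, ax)
    img = np.zeros((samples, samples))
    groups = tuple(sorted(groups))
    widths1 = [1.0 / (2.0 * bar_frequency(g, 1)) for g in groups]
    col_widths = [2.6 * 5.0 * w for w in widths1]
    total = sum(col_widths)
    if total > 0.95 * extent:
        raise ValueError(
            f"groups {groups} span {total:.2f} mm and do not fit the "
            f"{extent} mm chart; drop coarse groups or enlarge the extent")
    scale_margin = 1.0
    x_cursor = -0.5 * total * scale_margin
    for g, w1, cw in zip(groups, widths1, col_widths):
        cw *= scale_margin
        for sub, elements in enumerate(((1, 2, 3), (4, 5, 6))):
            cx = x_cursor + (0.3 + 0.45 * sub) * cw
            heights = [1.4 * 5.0 / (2.0 * bar_frequency(g, e))
                       for e in elements]
            y = 0.5 * sum(heights)
            for e, hgt in zip(elements, heights):
                width = 1.0 / (2.0 * bar_frequency(g, e))
                _draw_element(img, xx, yy, cx, y - hgt / 2, width)
                y -= hgt
        x_cursor += cw
    if not bars_transmissive:
        img = 1.0 - img
    return TransmissionMask(img, pitch)


def generate_plane_wave(n: int, pitch: float, wavelength: float = 543.5,
                        amplitude: float = 1.0,
                        medium_index: float = 1.0) -> ComplexField:
    """Uniform unit-amplitude zero-phase field (the collimated laser)."""
    amp = np.full((n, n), amplitude, dtype=np.complex128)
    return ComplexField(amp, pitch, pitch, wavelength, medium_index=medium_index)
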