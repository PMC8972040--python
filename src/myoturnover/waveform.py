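"""Sarcomere line-scan waveform extraction and difference mapping.

A line scan along a myofibril yields a two-channel intensity profile.  Per
sarcomere, the green profile is smoothed with a polynomial; its two
turning points (local minima flanking the principal peak) define the
Z-bands; a straight baseline between the turning points is subtracted per
channel; each channel is rescaled to a maximum of 1; and the axial
coordinate is mapped affinely so the sarcomere centre (M-line) sits at 0
and the Z-bands at -1 and +1.  Red-minus-green difference profiles, and
their stacking over time into a difference map, localize where new (green)
versus old (red) label dominates along the thick filament.

Because each channel is normalized to its own maximum, a difference
profile compares waveform *shapes*, not label abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy import ndimage

from .errors import BoundaryError, InvalidConfigurationError

#: Number of samples of the normalized waveform grid on [-1, 1]; odd so
#: that x = 0 (the M-line) lies exactly on the grid.
GRID_POINTS = 201

DEFAULT_DEGREE = 6


@dataclass
class LineScan:
    """A two-channel mean-intensity profile sampled along a myofibril."""

    positions_um: np.ndarray
    green: np.ndarray
    red: np.ndarray
    time_min: float = np.nan
    source_id: str = ""
    myotube: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.positions_um) == len(self.green) == len(self.red)):
            raise InvalidConfigurationError("channel lengths must match positions")
        if np.any(np.diff(self.positions_um) <= 0):
            raise InvalidConfigurationError("positions must be strictly increasing")


@dataclass
class ChannelFit:
    """A least-squares polynomial smooth of one channel of a line scan."""

    poly: Polynomial
    window: tuple[float, float]
    degree: int

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.poly(x)


@dataclass
class ScanFit:
    green: ChannelFit
    red: ChannelFit
    scan: LineScan


@dataclass
class SarcomereWaveform:
    """One sarcomere's two-channel waveform in normalized coordinates.

    ``x`` spans [-1, 1] with the M-line at 0 and the Z-bands (turning
    points of the green curve) at ±1.  Non-empty channels are baseline
    subtracted and scaled to max 1; ``green_range``/``red_range`` keep the
    pre-normalization (post-baseline) dynamic range so that downstream
    classification can reason about relative signal levels.
    """

    x: np.ndarray
    green: np.ndarray
    red: np.ndarray
    green_range: float
    red_range: float
    turning_points_um: tuple[float, float]
    baseline_green: tuple[float, float]  # (slope per µm, intercept)
    baseline_red: tuple[float, float]
    degree: int
    green_empty: bool = False
    red_empty: bool = False
    time_min: float = np.nan
    source_id: str = ""
    myotube: int | None = None


@dataclass
class DifferenceMap:
    """Red-minus-green difference profiles stacked over time."""

    times_min: np.ndarray
    x: np.ndarray
    values: np.ndarray  # shape (n_times, n_x), clipped to [-1, 1]


def line_scan(
    image: np.ndarray,
    polyline: Sequence[Sequence[float]],
    width_px: int = 1,
    pixel_size_um: float = 0.05,
    time_min: float = np.nan,
    source_id: str = "",
) -> LineScan:
    """Mean two-channel intensity along a polyline, averaged across width.

    ``image`` has shape (2, height, width) with channel 0 = green and
    channel 1 = red; ``polyline`` is a sequence of (x, y) pixel vertices.
    The profile is sampled at unit-pixel arclength steps with bilinear
    interpolation, averaging ``width_px`` samples perpendicular to the
    local direction.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != 2:
        raise InvalidConfigurationError("image must have shape (2, height, width)")
    if width_px < 1:
        raise InvalidConfigurationError("width_px must be >= 1")
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InvalidConfigurationError("polyline needs >= 2 (x, y) vertices")
    h, w = image.shape[1:]
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1) or np.any(
        pts[:, 1] < 0
    ) or np.any(pts[:, 1] > h - 1):
        raise BoundaryError("polyline vertex outside image bounds")

    # resample the polyline at unit-pixel arclength steps
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    s = np.arange(0.0, total + 1e-9, 1.0)
    sx = np.interp(s, arclen, pts[:, 0])
    sy = np.interp(s, arclen, pts[:, 1])

    # unit tangent / normal per sample (finite differences along the path)
    tx = np.gradient(sx)
    ty = np.gradient(sy)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    profiles = np.empty((2, len(s)))
    for c in range(2):
        acc = np.zeros(len(s))
        for o in offsets:
            xi = sx + o * nx
            yi = sy + o * ny
            acc += ndimage.map_coordinates(
                image[c], np.vstack([yi, xi]), order=1, mode="nearest"
            )
        profiles[c] = acc / len(offsets)

    return LineScan(
        positions_um=s * pixel_size_um,
        green=profiles[0],
        red=profiles[1],
        time_min=time_min,
        source_id=source_id,
    )


def fit_polynomial(scan: LineScan, degree: int = DEFAULT_DEGREE) -> ScanFit:
    """Least-squares polynomial smooth of both channels over the scan."""
    x = scan.positions_um
    if len(x) < degree + 2:
        raise InvalidConfigurationError(
            f"degree {degree} needs >= {degree + 2} samples, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise InvalidConfigurationError("degenerate (constant) positions")
    window = (float(x[0]), float(x[-1]))
    fits = []
    for values in (scan.green, scan.red):
        poly = Polynomial.fit(x, values, deg=degree)
        fits.append(ChannelFit(poly=poly.convert(), window=window, degree=degree))
    return ScanFit(green=fits[0], red=fits[1], scan=scan)


def find_turning_points(
    green_fit: ChannelFit,
    scan: LineScan | None = None,
    valley_fraction: float = 0.5,
    refine_halfwidth_px: int = 3,
) -> tuple[float, float]:
    """The two local minima of the fitted green curve flanking its peak.

    Turning points are sub-pixel roots of the first derivative with a
    positive second derivative.  Candidate peaks are maxima above the
    lower ``valley_fraction`` of the fitted range; for each side of a
    peak the turning point is the *nearest minimum among those within a
    depth band of that side's deepest minimum* — Z-band valleys all sit
    near the profile floor, whereas mid-sarcomere dips (between two tip
    peaks, or polynomial ripple on the plateau) are shallower and must
    not terminate the window.  Among candidate peaks the pair maximizing
    the enclosed green area wins.  When ``scan`` is given, each turning
    point is refined by the vertex of a local quadratic fit of the raw
    samples within ``refine_halfwidth_px`` pixels.  Raises
    :class:`BoundaryError` when the sarcomere is truncated at the scan
    edge (no flanking pair exists).
    """
    lo, hi = green_fit.window
    span = hi - lo
    d1 = green_fit.poly.deriv()
    d2 = d1.deriv()
    roots = d1.roots()
    roots = np.sort(roots[np.isreal(roots)].real)
    eps = 1e-9 * max(span, 1.0)
    roots = roots[(roots >= lo - eps) & (roots <= hi + eps)]
    dense = green_fit.poly(np.linspace(lo, hi, 512))
    rng_v = dense.max() - dense.min()
    depth_cut = dense.min() + valley_fraction * rng_v
    minima = [r for r in roots if d2(r) > 0]
    maxima = [r for r in roots if d2(r) < 0 and green_fit.poly(r) > depth_cut]
    if not maxima:
        raise BoundaryError("fitted green curve has no interior maximum")

    def _side_pick(candidates: list[float], ref: float) -> float | None:
        # nearest minimum among those within a depth band of the side's
        # deepest minimum: Z-band valleys all sit near the profile floor,
        # whereas a mid-sarcomere dip (e.g. between two tip peaks) is much
        # shallower and must not terminate the window
        if not candidates:
            return None
        values = np.array([float(green_fit.poly(c)) for c in candidates])
        band = values.min() + 0.1 * rng_v
        eligible = [c for c, v in zip(candidates, values) if v <= band]
        return min(eligible, key=lambda c: abs(c - ref))

    best: tuple[float, tuple[float, float]] | None = None
    integ = green_fit.poly.integ()
    for m in maxima:
        left = _side_pick([r for r in minima if r < m], m)
        right = _side_pick([r for r in minima if r > m], m)
        if left is None or right is None:
            continue
        pair = (left, right)
        area = float(integ(pair[1]) - integ(pair[0]))
        if best is None or area > best[0] + eps:
            best = (area, pair)
    if best is None:
        raise BoundaryError("no flanking minima; sarcomere truncated at scan edge")
    pair = best[1]
    if scan is not None:
        pair = tuple(
            _refine_minimum(scan, p, refine_halfwidth_px) for p in pair
        )
    return (float(min(pair)), float(max(pair)))


def _refine_minimum(scan: LineScan, pos: float, halfwidth_px: int) -> float:
    """Sub-pixel valley refinement: vertex of a local quadratic in raw data."""
    x = scan.positions_um
    i = int(np.argmin(np.abs(x - pos)))
    sl = slice(max(i - halfwidth_px, 0), min(i + halfwidth_px + 1, len(x)))
    if sl.stop - sl.start < 3:
        return pos
    c2, c1, _ = np.polyfit(x[sl], scan.green[sl], 2)
    if c2 <= 0:  # not valley-shaped locally; keep the coarse estimate
        return pos
    vertex = -c1 / (2 * c2)
    if not (x[sl][0] <= vertex <= x[sl][-1]):
        return pos
    return float(vertex)


def extract_sarcomere(
    fit: ScanFit,
    turning_points: tuple[float, float],
    n_grid: int = GRID_POINTS,
) -> SarcomereWaveform:
    """Normalize one sarcomere's two channels between its turning points.

    Each channel is re-fitted with the same polynomial degree on the raw
    samples inside [left, right] (the single-sarcomere window, where a
    low-degree polynomial is faithful); the straight line through the
    channel's values at the two turning points is subtracted; the channel
    is divided by its post-subtraction maximum (max 1, endpoints 0
    exactly); and the axial coordinate is mapped affinely so the midpoint
    lands at 0 and the turning points at ±1.  Channels whose
    post-subtraction maximum is non-positive are flagged empty and left
    unscaled.
    """
    left, right = float(turning_points[0]), float(turning_points[1])
    lo, hi = fit.green.window
    if not (lo <= left < right <= hi):
        raise InvalidConfigurationError("turning points must lie inside the scan window")
    x_norm = np.linspace(-1.0, 1.0, n_grid)
    mid, half = (left + right) / 2.0, (right - left) / 2.0
    x_um = mid + half * x_norm

    scan = fit.scan
    degree = fit.green.degree
    mask = (scan.positions_um >= left) & (scan.positions_um <= right)
    out: dict[str, tuple[np.ndarray, float, tuple[float, float], bool]] = {}
    for name, chan, raw in (
        ("green", fit.green, scan.green),
        ("red", fit.red, scan.red),
    ):
        if mask.sum() >= degree + 2:
            poly = Polynomial.fit(scan.positions_um[mask], raw[mask], deg=degree).convert()
        else:  # window too narrow to refit; fall back to the global smooth
            poly = chan.poly
        v = np.asarray(poly(x_um), dtype=float)
        vl, vr = float(poly(left)), float(poly(right))
        slope = (vr - vl) / (right - left)
        intercept = vl - slope * left
        v = v - (slope * x_um + intercept)
        vmax = float(np.max(v))
        empty = vmax <= 0
        if not empty:
            v = np.clip(v / vmax, 0.0, 1.0)
        out[name] = (v, max(vmax, 0.0), (slope, intercept), empty)

    return SarcomereWaveform(
        x=x_norm,
        green=out["green"][0],
        red=out["red"][0],
        green_range=out["green"][1],
        red_range=out["red"][1],
        turning_points_um=(left, right),
        baseline_green=out["green"][2],
        baseline_red=out["red"][2],
        degree=fit.green.degree,
        green_empty=out["green"][3],
        red_empty=out["red"][3],
        time_min=fit.scan.time_min,
        source_id=fit.scan.source_id,
        myotube=fit.scan.myotube,
    )


def extract_from_scan(
    scan: LineScan, degree: int = DEFAULT_DEGREE, n_grid: int = GRID_POINTS
) -> SarcomereWaveform:
    """Convenience: polynomial fit, turning-point detection and extraction."""
    fit = fit_polynomial(scan, degree=degree)
    tp = find_turning_points(fit.green, scan=scan)
    return extract_sarcomere(fit, tp, n_grid=n_grid)


def subtract_waveforms(w: SarcomereWaveform) -> np.ndarray:
    """Difference profile d(x) = red(x) - green(x), clipped to [-1, 1]."""
    return np.clip(w.red - w.green, -1.0, 1.0)


def build_difference_map(waveforms: Sequence[SarcomereWaveform]) -> DifferenceMap:
    """Stack red-green differences over time into a difference map.

    Waveforms are grouped by ``time_min``; within a time point the
    normalized channels are averaged across sarcomeres *before*
    differencing.  Rows are ordered by time.
    """
    if not waveforms:
        raise InvalidConfigurationError("no waveforms supplied")
    x = waveforms[0].x
    by_time: dict[float, list[tuple[np.ndarray, np.ndarray]]] = {}
    for w in waveforms:
        g, r = w.green, w.red
        if len(w.x) != len(x) or not np.allclose(w.x, x):
            warnings.warn("waveform grid mismatch; resampling onto the first grid",
                          stacklevel=2)
            g = np.interp(x, w.x, g)
            r = np.interp(x, w.x, r)
        by_time.setdefault(float(w.time_min), []).append((g, r))
    times = np.array(sorted(by_time))
    rows = np.empty((len(times), len(x)))
    for i, t in enumerate(times):
        group = by_time[float(t)]
        g = np.mean([gg for gg, _ in group], axis=0)
        r = np.mean([rr for _, rr in group], axis=0)
        rows[i] = np.clip(r - g, -1.0, 1.0)
    return DifferenceMap(times_min=times, x=x.copy(), values=rows)
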