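"""FRAP / photoconversion trace normalization and recovery fitting.

After UV photoconversion of KikGR-tagged myosin, the green channel of the
converted region reports myosin insertion (recovery from 0) and the red
channel reports myosin release (decay from 1).  Raw ROI means carry two
instrument artifacts that are corrected before fitting:

* green — photobleaching, corrected by ratioing against a non-converted
  reference region;
* red — a slow additive linear drift, corrected by the "correction value"
  (minus the least-squares slope of the raw red signal over the 500-600 min
  window) multiplied by the elapsed time and added back.

Both normalized channels are then fitted with the single-exponential
recovery model ``FI(t) = Mf * (1 - exp(-b t)) + c`` (the red channel is
first mirrored to its change magnitude ``1 - y``), giving the mobile
fraction Mf — the maximum change of normalized fluorescence — and the
half-life ``t_1/2 = ln 2 / b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    CorrectionWindowError,
    DegenerateTraceError,
    InsufficientDataError,
    InvalidConfigurationError,
)

#: Drift-correction window (min of elapsed post-conversion time).
CORRECTION_WINDOW_MIN = (500.0, 600.0)

_FIT_BOUNDS = ([0.0, 1e-6, -0.5], [1.5, 100.0, 0.5])


@dataclass
class FrapTrace:
    """Raw two-channel ROI intensity time series around a conversion event.

    ``times_h`` is the full acquisition grid in hours (the pre-conversion
    frame has a negative time); ``pre_index``/``post_index`` point at the
    last pre-conversion and first post-conversion frames.  Intensities are
    ROI means in arbitrary units.
    """

    times_h: np.ndarray
    green_converted: np.ndarray
    green_reference: np.ndarray
    red_converted: np.ndarray
    red_nonconverted: np.ndarray
    pre_index: int = 0
    post_index: int = 1
    truth_replaced: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        arrays = (
            self.times_h,
            self.green_converted,
            self.green_reference,
            self.red_converted,
            self.red_nonconverted,
        )
        if len({len(a) for a in arrays}) != 1:
            raise InvalidConfigurationError("trace arrays must share one length")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidConfigurationError("times must be strictly increasing")
        if not 0 <= self.pre_index < self.post_index < len(self.times_h):
            raise InvalidConfigurationError("need pre_index < post_index in range")

    @property
    def elapsed_min(self) -> np.ndarray:
        """Elapsed time in minutes with t = 0 at the first post-conversion frame."""
        return (self.times_h - self.times_h[self.post_index]) * 60.0


@dataclass
class NormalizedTrace:
    """A normalized single-channel trace (green: 0 -> Mf; red: 1 -> 1 - Mf)."""

    times_h: np.ndarray
    values: np.ndarray
    channel: str
    post_index: int
    correction_value: float | None = None  # red only, intensity units per min
    source_id: str = ""

    @property
    def post_times_h(self) -> np.ndarray:
        """Post-conversion times in hours with origin at the post frame."""
        return self.times_h[self.post_index :] - self.times_h[self.post_index]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.post_index :]


@dataclass
class FitResult:
    """Result of the single-exponential recovery fit."""

    mf: float
    rate: float  # b, h^-1
    offset: float  # c
    t_half: float  # ln2 / b, h
    residual_rms: float
    converged: bool
    channel: str = ""
    message: str = ""
    source_id: str = ""

    def curve(self, t_h: np.ndarray) -> np.ndarray:
        """Fitted FI(t) = Mf (1 - e^{-b t}) + c on post-conversion time t (h)."""
        return _model(np.asarray(t_h, float), self.mf, self.rate, self.offset)


@dataclass
class GroupComparison:
    """Two-sample Student's t comparison of a fitted quantity."""

    quantity: str
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    t_statistic: float
    p_value: float


def _model(t: np.ndarray, mf: float, b: float, c: float) -> np.ndarray:
    return mf * (1.0 - np.exp(-b * t)) + c


def normalize_green(trace: FrapTrace) -> NormalizedTrace:
    """Bleach-correct and rescale the green (insertion) channel.

    The converted-ROI green signal is multiplied by reference(pre) /
    reference(t) — the non-converted region carries the photobleaching —
    and then affinely rescaled so the pre-conversion frame maps to 1 and
    the first post-conversion frame to 0.
    """
    ref = np.asarray(trace.green_reference, dtype=float)
    if np.any(ref <= 0):
        bad = int(np.argmax(ref <= 0))
        raise DegenerateTraceError(
            f"green reference is non-positive at sample {bad} (t = {trace.times_h[bad]:.3g} h)"
        )
    v = np.asarray(trace.green_converted, dtype=float) * (ref[trace.pre_index] / ref)
    span = v[trace.pre_index] - v[trace.post_index]
    if span == 0:
        raise DegenerateTraceError("zero dynamic range between pre and post frames")
    values = (v - v[trace.post_index]) / span
    return NormalizedTrace(
        times_h=trace.times_h.copy(),
        values=values,
        channel="green",
        post_index=trace.post_index,
        source_id=trace.source_id,
    )


def normalize_red(trace: FrapTrace) -> NormalizedTrace:
    """Drift-correct and rescale the red (release) channel.

    The correction value is minus the least-squares slope of the raw red
    converted-ROI signal over the 500-600 min window of elapsed time
    (falling back to the final 100 min, with a warning, for shorter
    traces).  The corrected signal raw(t) + correction_value * t is then
    rescaled so the first post-conversion frame maps to 1 and the
    non-photoconverted-area red level maps to 0 (per-time-point reference).
    """
    t_min = trace.elapsed_min
    lo, hi = CORRECTION_WINDOW_MIN
    if t_min[-1] < hi:
        hi = t_min[-1]
        lo = hi - (CORRECTION_WINDOW_MIN[1] - CORRECTION_WINDOW_MIN[0])
        warnings.warn(
            f"trace shorter than {CORRECTION_WINDOW_MIN[1]:.0f} min; "
            f"using correction window [{lo:.0f}, {hi:.0f}] min",
            stacklevel=2,
        )
    mask = (t_min >= lo) & (t_min <= hi)
    if mask.sum() < 3:
        raise CorrectionWindowError(
            f"correction window [{lo:.0f}, {hi:.0f}] min holds {int(mask.sum())} samples (< 3)"
        )
    raw = np.asarray(trace.red_converted, dtype=float)
    slope = np.polyfit(t_min[mask], raw[mask], 1)[0]
    correction_value = -slope
    corrected = raw + correction_value * t_min
    zero_ref = np.asarray(trace.red_nonconverted, dtype=float)
    num = corrected - zero_ref
    span = num[trace.post_index]
    if span == 0:
        raise DegenerateTraceError("red post-conversion level equals the zero reference")
    values = num / span
    return NormalizedTrace(
        times_h=trace.times_h.copy(),
        values=values,
        channel="red",
        post_index=trace.post_index,
        correction_value=float(correction_value),
        source_id=trace.source_id,
    )


def fit_recovery(norm: NormalizedTrace, max_restarts: int = 5) -> FitResult:
    """Fit FI(t) = Mf (1 - e^{-b t}) + c to the post-conversion samples.

    The red channel is first transformed to its change magnitude
    ``y' = 1 - y`` so both channels fit the same increasing form and Mf is
    always a positive change magnitude.  Nonlinear least squares with
    bounds Mf in [0, 1.5], b in (0, 100] h^-1, c in [-0.5, 0.5] and up to
    ``max_restarts`` rate-perturbed restarts.
    """
    t = norm.post_times_h
    y = norm.post_values
    if norm.channel == "red":
        y = 1.0 - y
    if len(t) < 5:
        raise InsufficientDataError(f"need >= 5 post-conversion samples, got {len(t)}")

    rng_y = float(np.ptp(y))
    if rng_y < 1e-8:
        return FitResult(
            mf=0.0, rate=np.nan, offset=float(y[0]), t_half=np.nan,
            residual_rms=0.0, converged=False, channel=norm.channel,
            message="flat series; rate unidentifiable", source_id=norm.source_id,
        )

    # initialization: Mf0 = range, b0 from the half-range crossing, c0 = y(post)
    half_target = y[0] + 0.5 * rng_y
    above = np.nonzero(y >= half_target)[0]
    t_half0 = t[above[0]] if len(above) and t[above[0]] > 0 else max(t[-1] / 4, 1e-3)
    b0 = np.log(2.0) / t_half0
    c0 = float(np.clip(y[0], *[b[2] for b in _FIT_BOUNDS]))

    best = None
    for factor in (1.0, 0.3, 3.0, 0.1, 10.0)[:max_restarts]:
        p0 = [min(rng_y, 1.5), float(np.clip(b0 * factor, 1e-6, 100.0)), c0]
        try:
            popt, _ = optimize.curve_fit(
                _model, t, y, p0=p0, bounds=_FIT_BOUNDS, maxfev=20000
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((_model(t, *popt) - y) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        return FitResult(
            mf=np.nan, rate=np.nan, offset=np.nan, t_half=np.nan,
            residual_rms=np.nan, converged=False, channel=norm.channel,
            message="nonlinear fit failed after restarts", source_id=norm.source_id,
        )
    (mf, b, c), rms = best
    flagged = b <= _FIT_BOUNDS[0][1] * 1.01 or b >= _FIT_BOUNDS[1][1] * 0.999
    return FitResult(
        mf=float(mf), rate=float(b), offset=float(c), t_half=float(np.log(2.0) / b),
        residual_rms=rms, converged=not flagged, channel=norm.channel,
        message="rate at bound" if flagged else "", source_id=norm.source_id,
    )


def _group_stats(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1) / np.sqrt(len(values)))


def compare_fits(
    fits_a: list[FitResult], fits_b: list[FitResult], quantity: str = "mf"
) -> GroupComparison:
    """Two-sample Student's t-test on a fitted quantity ('mf' or 't_half')."""
    a = np.array([getattr(f, quantity) for f in fits_a if f.converged])
    b = np.array([getattr(f, quantity) for f in fits_b if f.converged])
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 converged fits per group, got {len(a)} and {len(b)}"
        )
    tt = stats.ttest_ind(a, b, equal_var=True)
    t_stat, p = float(tt.statistic), float(tt.pvalue)
    if np.isnan(t_stat) and np.mean(a) == np.mean(b):
        t_stat, p = 0.0, 1.0  # identical degenerate groups
    ma, sa = _group_stats(a)
    mb, sb = _group_stats(b)
    return GroupComparison(
        quantity=quantity, mean_a=ma, se_a=sa, n_a=len(a),
        mean_b=mb, se_b=sb, n_b=len(b), t_statistic=t_stat, p_value=p,
    )


def compare_mf(fits_a: list[FitResult], fits_b: list[FitResult]) -> GroupComparison:
    """Student's t-test on the mobile fraction between two groups of fits."""
    return compare_fits(fits_a, fits_b, "mf")
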