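"""Stochastic thick-filament exchange simulation and synthetic rendering.

The exchange model treats each of the ~300 myosin sites on a bipolar
thick filament as an independent exchange unit: site i swaps its occupant
for one from the cytosolic pool as a Poisson process with rate ``k_i``
(h^-1), given either by a spatial rate profile k(|x|) or by pool
membership (fast/slow/immobile).  On every event exactly one occupant
leaves and one enters, so occupancy is conserved and the replaced
fraction is non-decreasing.  A labeling protocol decides the label of the
incoming myosin (photoconversion: green after the UV flip that turns all
incorporated label red; pulse-chase: red after the chase start).

Rendering converts simulation states into the two synthetic observables
the downstream analysis consumes: two-channel FRAP ROI traces (with
multiplicative green photobleaching, additive linear red drift and
Gaussian noise) and two-channel sarcomere line-scan profiles (Gaussian
point-spread per myosin, periodic neighbours so the green curve has
Z-band minima, background and noise).  Ground truth is retained for every
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .classify import ClassificationRules, PatternCategory, classify_pattern
from .errors import InvalidConfigurationError
from .frap import FrapTrace
from .geometry import FilamentGeometry
from .kinetics import ExchangeKinetics, preset
from .waveform import GRID_POINTS, LineScan, SarcomereWaveform, extract_from_scan

LABEL_GREEN, LABEL_RED, LABEL_DARK = 0, 1, 2


@dataclass(frozen=True)
class LabelProtocol:
    """Labeling schedule around a single event at ``event_time`` (h).

    ``photoconversion``: at the event all currently incorporated green
    label flips to red (each site independently with probability
    ``conversion_efficiency``) and incoming myosin is green before and
    after.  ``pulse_chase``: incorporated label stays green; incoming
    myosin is red from the event onward (green before).
    """

    mode: Literal["photoconversion", "pulse_chase"]
    event_time: float = 0.0
    conversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("photoconversion", "pulse_chase"):
            raise InvalidConfigurationError(f"unknown protocol mode {self.mode!r}")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise InvalidConfigurationError("conversion_efficiency must be in [0, 1]")

    def incoming_label(self, t: float) -> int:
        if self.mode == "pulse_chase" and t >= self.event_time:
            return LABEL_RED
        return LABEL_GREEN


@dataclass(frozen=True)
class RenderConfig:
    """Optics/noise plumbing for synthetic rendering.

    ``bleach_rate_green`` is a multiplicative exponential decay (h^-1)
    applied to the green channel of FRAP traces; ``red_linear_drift`` is
    an additive linear drift of the red channel in fractions of the
    post-conversion level per minute (negative = slow decay).  Both are
    the artifacts the normalization steps are built to remove.
    """

    pixel_size: float = 0.05  # µm
    psf_sigma: float = 0.1  # µm
    noise_sd: float = 0.02  # fraction of channel peak
    background: float = 0.05  # fraction of channel peak
    bleach_rate_green: float = 0.05  # h^-1
    red_linear_drift: float = -2e-4  # fraction/min

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.psf_sigma) <= 0:
            raise InvalidConfigurationError("pixel_size and psf_sigma must be positive")
        if self.noise_sd < 0 or self.background < 0 or self.bleach_rate_green < 0:
            raise InvalidConfigurationError("noise/background/bleach must be >= 0")


@dataclass
class SimulationResult:
    """Per-myosin exchange history with ground truth."""

    geometry: FilamentGeometry
    times_h: np.ndarray
    labels: np.ndarray  # (n_times, n_sites) int8 label codes
    replaced_fraction: np.ndarray  # fraction of sites exchanged >= once since event
    insertion_events: list[tuple[float, float]]  # (time h, normalized x) post-event
    site_rates: np.ndarray
    seed: int

    def labels_at(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times_h - t)))
        return self.labels[idx]


def simulate_exchange(
    geometry: FilamentGeometry,
    kinetics: ExchangeKinetics,
    protocol: LabelProtocol,
    duration: float,
    seed: int,
    record_times: Sequence[float] | None = None,
) -> SimulationResult:
    """Simulate per-site Poisson exchange on one filament.

    Each site draws independent exponential waiting times at its rate
    (equivalent to a Gillespie simulation for non-interacting sites); on
    every event the occupant's label becomes the protocol's incoming
    label at that time.  ``record_times`` (h, default a uniform 50-point
    grid over [0, duration]) selects the snapshots stored in the result.
    Identical seed and configuration give identical results.
    """
    if duration <= 0:
        raise InvalidConfigurationError("duration must be positive")
    rates = kinetics.site_rates(geometry)
    if np.any(~np.isfinite(rates)) or np.any(rates < 0):
        raise InvalidConfigurationError("site rates must be finite and >= 0")
    if record_times is None:
        record_times = np.linspace(0.0, duration, 51)
    times = np.asarray(record_times, dtype=float)

    rng = np.random.default_rng(seed)
    n = geometry.n_myosins
    x = geometry.positions()
    event_lists: list[np.ndarray] = []
    for i in range(n):
        if rates[i] <= 0:
            event_lists.append(np.empty(0))
            continue
        # draw enough exponentials to cover the duration, extend if unlucky
        t_acc: list[float] = []
        t_now = 0.0
        while t_now <= duration:
            t_now += rng.exponential(1.0 / rates[i])
            if t_now <= duration:
                t_acc.append(t_now)
        event_lists.append(np.asarray(t_acc))

    ev0 = protocol.event_time
    converted = (
        rng.random(n) < protocol.conversion_efficiency
        if protocol.mode == "photoconversion"
        else np.ones(n, dtype=bool)
    )
    insertion_events = [
        (float(t), float(x[i]))
        for i, evs in enumerate(event_lists)
        for t in evs
        if t >= ev0
    ]
    insertion_events.sort()

    labels = np.empty((len(times), n), dtype=np.int8)
    replaced = np.empty(len(times))
    for j, t in enumerate(times):
        lab = np.full(n, LABEL_GREEN, dtype=np.int8)
        exchanged = np.zeros(n, dtype=bool)
        for i, evs in enumerate(event_lists):
            evs_t = evs[evs <= t]
            if len(evs_t):
                lab[i] = protocol.incoming_label(float(evs_t[-1]))
                exchanged[i] = bool(np.any(evs_t >= ev0))
        if protocol.mode == "photoconversion" and t >= ev0:
            # the UV flip turned the incorporated label red (per-site with
            # the conversion efficiency); sites not exchanged since then
            # still carry that red label
            lab[~exchanged & converted] = LABEL_RED
        labels[j] = lab
        replaced[j] = exchanged.mean() if t >= ev0 else 0.0

    return SimulationResult(
        geometry=geometry,
        times_h=times,
        labels=labels,
        replaced_fraction=replaced,
        insertion_events=insertion_events,
        site_rates=rates,
        seed=int(seed),
    )


def simulate_frap_trace(
    kinetics: ExchangeKinetics,
    render: RenderConfig,
    times_h: Sequence[float],
    seed: int,
    geometry: FilamentGeometry | None = None,
    pre_offset_h: float = 10 / 60,
    level_green: float = 100.0,
    level_red: float = 100.0,
    source_id: str = "",
) -> FrapTrace:
    """Render a raw two-channel FRAP ROI trace for a photoconversion event.

    ``times_h`` are the post-conversion sample times (first entry is the
    "just after conversion" frame, typically 0); one pre-conversion frame
    is prepended ``pre_offset_h`` before it.  The converted-ROI green
    recovers with the kinetics' replaced fraction, the red decays as its
    complement scaled by the mobile fraction; the green channel carries a
    multiplicative photobleaching decay (shared with the reference ROI,
    which is how the normalization can undo it), the red channel an
    additive linear drift, and both Gaussian noise.  The ground-truth
    replaced-fraction curve is attached.
    """
    post = np.asarray(times_h, dtype=float)
    if post.size == 0:
        raise InvalidConfigurationError("times_h must not be empty")
    if np.any(np.diff(post) <= 0):
        raise InvalidConfigurationError("times_h must be strictly increasing")
    rng = np.random.default_rng(seed)
    t_all = np.concatenate([[post[0] - pre_offset_h], post])
    f = np.asarray(kinetics.replaced_fraction(post, geometry=geometry), dtype=float)

    bleach = np.exp(-render.bleach_rate_green * (t_all - t_all[0]))
    bg_g = render.background * level_green
    bg_r = render.background * level_red

    green_conv = np.concatenate([[level_green], level_green * f]) + bg_g
    green_conv *= bleach
    green_ref = (level_green + bg_g) * bleach
    t_min = np.concatenate([[post[0] - pre_offset_h], post]) * 60.0
    t_elapsed_min = t_min - post[0] * 60.0
    red_conv = np.concatenate([[0.0], level_red * (1.0 - f)]) + bg_r
    red_conv = red_conv + render.red_linear_drift * level_red * t_elapsed_min
    red_base = np.full(len(t_all), bg_r)

    def noisy(arr: np.ndarray, level: float) -> np.ndarray:
        return arr + rng.normal(0.0, render.noise_sd * level, size=arr.shape)

    return FrapTrace(
        times_h=t_all,
        green_converted=noisy(green_conv, level_green),
        green_reference=noisy(green_ref, level_green),
        red_converted=noisy(red_conv, level_red),
        red_nonconverted=noisy(red_base, level_red),
        pre_index=0,
        post_index=1,
        truth_replaced=f,
        source_id=source_id,
    )


def render_sarcomere_profile(
    labels: np.ndarray,
    geometry: FilamentGeometry,
    render: RenderConfig,
    seed: int | None = None,
    margin_um: float = 0.3,
    tile: bool = True,
    time_min: float = np.nan,
    source_id: str = "",
) -> LineScan:
    """Render a two-channel line-scan profile from per-site labels.

    Each myosin contributes a Gaussian of width ``psf_sigma`` at its
    axial position in its current label's channel.  With ``tile`` the
    filament is repeated at ±1 sarcomere so the green profile has local
    minima at the Z-bands, which is what turning-point detection needs.
    The profile spans one sarcomere plus ``margin_um`` on each side,
    sampled at ``pixel_size``; background and Gaussian noise are scaled
    to the peak of the dense (green + red) signal so the two channels
    share one intensity gain.
    """
    labels = np.asarray(labels)
    if len(labels) != geometry.n_myosins:
        raise InvalidConfigurationError("labels length must equal n_myosins")
    if render.pixel_size >= geometry.sarcomere_length:
        raise InvalidConfigurationError("pixel_size must be below sarcomere_length")
    half = geometry.sarcomere_length / 2.0
    grid = np.arange(-half - margin_um, half + margin_um + 1e-9, render.pixel_size)
    pos = geometry.positions_um()
    offsets = (-geometry.sarcomere_length, 0.0, geometry.sarcomere_length) if tile else (0.0,)

    channels = {}
    for name, code in (("green", LABEL_GREEN), ("red", LABEL_RED)):
        channels[name] = _gaussian_profile(
            grid, pos[labels == code], offsets, render.psf_sigma
        )

    total = channels["green"] + channels["red"]
    scale = float(np.max(total)) if np.max(total) > 0 else 1.0
    rng = np.random.default_rng(seed) if seed is not None else None
    for name in channels:
        channels[name] = channels[name] + render.background * scale
        if rng is not None and render.noise_sd > 0:
            channels[name] = channels[name] + rng.normal(
                0.0, render.noise_sd * scale, size=grid.shape
            )
    return LineScan(
        positions_um=grid - grid[0],  # scan coordinate starts at 0
        green=channels["green"],
        red=channels["red"],
        time_min=time_min,
        source_id=source_id,
    )


def _gaussian_profile(
    grid: np.ndarray, sites: np.ndarray, offsets: Sequence[float], sigma: float
) -> np.ndarray:
    """Sum of unit Gaussians at sites (tiled at offsets) sampled on grid."""
    if len(sites) == 0:
        return np.zeros_like(grid)
    centers = (np.asarray(sites)[:, None] + np.asarray(offsets)[None, :]).ravel()
    return np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / sigma) ** 2).sum(axis=0)


def truth_waveform(
    labels: np.ndarray,
    geometry: FilamentGeometry,
    render: RenderConfig,
    time_min: float = np.nan,
    source_id: str = "",
    myotube: int | None = None,
) -> SarcomereWaveform:
    """Noiseless ideal waveform with exact Z-band turning points.

    Renders the labels without noise or background, places the turning
    points exactly at the Z-bands (±half sarcomere) and applies the
    standard baseline/max normalization.  Used to assign ground-truth
    pattern categories with the same geometric rules as the classifier.
    """
    half = geometry.sarcomere_length / 2.0
    x_norm = np.linspace(-1.0, 1.0, GRID_POINTS)
    x_um = x_norm * half
    pos = geometry.positions_um()
    offsets = (-geometry.sarcomere_length, 0.0, geometry.sarcomere_length)
    chans = {}
    for name, code in (("green", LABEL_GREEN), ("red", LABEL_RED)):
        profile = _gaussian_profile(
            x_um, pos[np.asarray(labels) == code], offsets, render.psf_sigma
        )
        # baseline through the endpoint values, then scale to max 1
        base = profile[0] + (profile[-1] - profile[0]) * (x_norm + 1) / 2
        v = profile - base
        vmax = float(np.max(v))
        chans[name] = (np.clip(v / vmax, 0, 1) if vmax > 0 else v, max(vmax, 0.0), vmax <= 0)
    return SarcomereWaveform(
        x=x_norm,
        green=chans["green"][0],
        red=chans["red"][0],
        green_range=chans["green"][1],
        red_range=chans["red"][1],
        turning_points_um=(-half, half),
        baseline_green=(0.0, 0.0),
        baseline_red=(0.0, 0.0),
        degree=0,
        green_empty=chans["green"][2],
        red_empty=chans["red"][2],
        time_min=time_min,
        source_id=source_id,
        myotube=myotube,
    )


@dataclass(frozen=True)
class PopulationPreset:
    """Per-sarcomere kinetics sampler for heterogeneous populations.

    ``components`` are (weight, kinetics) pairs; each sarcomere draws one
    component and a lognormal rate multiplier with sigma
    ``rate_dispersion`` (unit mean), emulating sarcomere-to-sarcomere
    variability in expression and exchange rate.
    """

    components: tuple[tuple[float, ExchangeKinetics], ...]
    rate_dispersion: float = 0.5

    def __post_init__(self) -> None:
        w = [float(a) for a, _ in self.components]
        if not w or any(a < 0 for a in w) or abs(sum(w) - 1.0) > 1e-9:
            raise InvalidConfigurationError("component weights must be >= 0 and sum to 1")

    def sample(self, rng: np.random.Generator) -> ExchangeKinetics:
        weights = np.array([a for a, _ in self.components])
        idx = rng.choice(len(weights), p=weights)
        kin = self.components[idx][1]
        if self.rate_dispersion > 0:
            m = rng.lognormal(-0.5 * self.rate_dispersion**2, self.rate_dispersion)
            kin = _scaled(kin, float(m))
        return kin


#: Pulse-chase population preset: an 80% majority of sarcomeres with
#: tip-biased exchange plus a 20% minority with slow center-weighted
#: incorporation (whose red signal only clears the detection floor by
#: ~30 min of chase, reproducing the reported rise of the center pattern
#: while side groups stay near 80% throughout 7-30 min).
TIP_BIASED_PAPER_POPULATION = PopulationPreset(
    components=(
        (0.80, ExchangeKinetics.tip_biased(0.35, 6.0, 2.0)),
        (0.20, ExchangeKinetics.profile(1.2, 0.0, 1.0)),
    ),
    rate_dispersion=0.5,
)

POPULATION_PRESETS: dict[str, PopulationPreset] = {
    "tip_biased_paper": TIP_BIASED_PAPER_POPULATION,
}


@dataclass
class PulseChasePopulation:
    """Rendered pulse-chase line scans with per-sarcomere ground truth."""

    scans: list[LineScan]
    truth_waveforms: list[SarcomereWaveform]
    truth_categories: list[PatternCategory]
    myotubes: list[int]
    chase_time_min: float
    seed: int
    rate_multipliers: np.ndarray

    @property
    def truth_proportions(self) -> dict[str, float]:
        n = len(self.truth_categories)
        return {
            c.value: sum(1 for t in self.truth_categories if t is c) / n
            for c in PatternCategory
        }


def generate_pulse_chase_population(
    kinetics: ExchangeKinetics | PopulationPreset | str = "tip_biased_paper",
    chase_time_min: float = 15.0,
    n_sarcomeres: int = 150,
    n_myotubes: int = 6,
    seed: int = 0,
    geometry: FilamentGeometry | None = None,
    render: RenderConfig | None = None,
    rules: ClassificationRules | None = None,
) -> PulseChasePopulation:
    """Simulate and render a pulse-chase sarcomere population.

    Each sarcomere draws its kinetics (a fixed :class:`ExchangeKinetics`,
    or per-sarcomere from a :class:`PopulationPreset` — by name for
    shipped presets), runs an independent exchange simulation with
    incoming label red from the chase start, is rendered as a noisy
    two-channel line scan, and receives a ground-truth category by
    applying the classifier's geometric rules to the noiseless rendering
    of the same label state through the same extraction path.  Sarcomeres
    are assigned round-robin to ``n_myotubes`` pseudo-myotubes.
    """
    if n_sarcomeres < 1:
        raise InvalidConfigurationError("n_sarcomeres must be >= 1")
    if n_myotubes < 1:
        raise InvalidConfigurationError("n_myotubes must be >= 1")
    if isinstance(kinetics, str):
        kinetics = POPULATION_PRESETS.get(kinetics) or preset(kinetics)
    geometry = geometry or FilamentGeometry()
    render = render or RenderConfig()
    rules = rules or ClassificationRules()
    protocol = LabelProtocol(mode="pulse_chase", event_time=0.0)
    duration = max(chase_time_min, 1e-3) / 60.0

    children = np.random.SeedSequence(seed).spawn(n_sarcomeres)
    scans, truths, cats, tubes, mults = [], [], [], [], []
    for s in range(n_sarcomeres):
        sub = children[s].generate_state(3)
        if isinstance(kinetics, PopulationPreset):
            kin_s = kinetics.sample(np.random.default_rng(int(sub[2])))
        else:
            kin_s = kinetics
        sim = simulate_exchange(
            geometry, kin_s, protocol, duration, seed=int(sub[0]),
            record_times=[duration],
        )
        labels = sim.labels[-1]
        myotube = s % n_myotubes
        sid = f"sarc{s:04d}"
        scan = render_sarcomere_profile(
            labels, geometry, render, seed=int(sub[1]),
            time_min=chase_time_min, source_id=sid,
        )
        scan.myotube = myotube
        scans.append(scan)
        # ground truth: the same rendering and geometric rules, noise off
        clean = render_sarcomere_profile(
            labels, geometry, replace(render, noise_sd=0.0), seed=None,
            time_min=chase_time_min, source_id=sid,
        )
        clean.myotube = myotube
        tw = extract_from_scan(clean)
        truths.append(tw)
        cats.append(classify_pattern(tw, rules).category)
        tubes.append(myotube)
        mults.append(np.mean(kin_s.site_rates(geometry)))

    return PulseChasePopulation(
        scans=scans,
        truth_waveforms=truths,
        truth_categories=cats,
        myotubes=tubes,
        chase_time_min=float(chase_time_min),
        seed=int(seed),
        rate_multipliers=np.asarray(mults),
    )


def _scaled(kinetics: ExchangeKinetics, factor: float) -> ExchangeKinetics:
    """Scale all rates of a kinetics object by a positive factor."""
    if factor == 1.0:
        return kinetics
    if kinetics.pools is not None:
        return ExchangeKinetics.pool_model([(a, k * factor) for a, k in kinetics.pools])
    return ExchangeKinetics.profile(
        kinetics.k_center * factor, kinetics.k_tip * factor, kinetics.exponent
    )


def profile_to_image(scan: LineScan, height_px: int = 11) -> np.ndarray:
    """Broadcast a line-scan profile into a laterally uniform 2-channel image.

    Returns an array of shape (2, height_px, n_positions) whose rows all
    equal the profile — a minimal synthetic image for exercising the
    polyline line-scan operator.
    """
    return np.stack(
        [
            np.tile(scan.green, (height_px, 1)),
            np.tile(scan.red, (height_px, 1)),
        ]
    )
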