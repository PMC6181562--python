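"""Synthetic capacitance sessions and calcium transients with ground truth.

Stands in for the hardware and the flies: generates two-channel
capacitance sessions in which trapezoidal sip pulses ride on a noisy,
slowly drifting baseline, together with the exact planted event intervals
— so the closed-loop detector can be benchmarked against known truth —
plus cohorts of such sessions with programmable per-channel sip rates,
and indicator-like fluorescence transients on the 5 s baseline / 1 s
stimulus / 9 s post acquisition timeline.

Defaults are deliberately conservative relative to the detector: sip
amplitude 500 counts against a 100-count threshold, Gaussian noise of
SD 10 counts (an order of magnitude below the threshold, honouring the
"threshold set to exceed noise" design), sinusoidal drift far too slow
to produce a 100-count rise within a 100 ms window. Session duration
defaults to one hour, the standard closed-loop experiment length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .detector import detect
from .exceptions import InvalidParameterError
from .feeding_analytics import (
    MIN_SIPS_DEFAULT,
    SIP_DURATION_BOUNDS,
    FeedingSession,
    apply_inclusion,
    count_sips,
    strobe_preference,
)
from .calcium_quant import FluorescenceTrace
from .signal_model import (
    CapacitanceTrace,
    Channel,
    DetectorParams,
    to_samples,
)

__all__ = [
    "SipModel",
    "SessionConfig",
    "PlantedEvent",
    "CalciumConfig",
    "simulate_session",
    "simulate_cohort",
    "simulate_calcium_trace",
    "derive_fly_seed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SipModel:
    """Waveform and timing statistics of simulated sips on one channel.

    A sip is a trapezoidal capacitance pulse (linear rise, flat hold,
    linear fall). Inter-sip gaps are gamma distributed with mean
    ``1/rate``; ``burstiness`` is the gamma dispersion (shape = 1 /
    burstiness), so 1 gives a Poisson process and larger values give
    burst-like feeding.
    """

    amplitude: int = 500
    rise_time: float = 0.020
    hold_time: float = 0.060
    fall_time: float = 0.020
    rate: float = 0.05
    burstiness: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        for name in ("rise_time", "hold_time", "fall_time"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.rate < 0:
            raise InvalidParameterError(f"rate must be >= 0, got {self.rate}")
        if self.burstiness <= 0:
            raise InvalidParameterError(
                f"burstiness must be > 0, got {self.burstiness}"
            )

    def waveform(self, sample_period: float) -> np.ndarray:
        """The sampled pulse shape (counts), length rise + hold + fall."""
        r = to_samples(self.rise_time, sample_period)
        h = to_samples(self.hold_time, sample_period)
        f = to_samples(self.fall_time, sample_period)
        rise = self.amplitude * (np.arange(1, r + 1) / r) if r else np.empty(0)
        hold = np.full(h, float(self.amplitude))
        fall = (
            self.amplitude * (1.0 - np.arange(1, f + 1) / f) if f else np.empty(0)
        )
        return np.concatenate([rise, hold, fall])


@dataclass(frozen=True)
class SessionConfig:
    """Full configuration of one simulated two-channel session.

    The baseline is ``baseline_level`` counts plus a sinusoid of amplitude
    ``drift_amplitude`` and period ``drift_period`` (random phase per
    channel) emulating slow thermal/humidity drift of the sensor, plus
    white Gaussian noise of SD ``noise_sd`` rounded to integer counts.
    """

    duration: float = 3600.0
    sample_period: float = 0.010
    noise_sd: float = 10.0
    baseline_level: int = 1000
    drift_amplitude: float = 50.0
    drift_period: float = 600.0
    sip_food1: SipModel = field(default_factory=SipModel)
    sip_food2: SipModel = field(default_factory=SipModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.sample_period <= 0:
            raise InvalidParameterError(
                f"sample_period must be > 0, got {self.sample_period}"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.drift_period <= 0:
            raise InvalidParameterError(
                f"drift_period must be > 0, got {self.drift_period}"
            )

    @property
    def n_samples(self) -> int:
        return to_samples(self.duration, self.sample_period)


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth interval of one planted sip pulse."""

    channel: Channel
    onset_index: int
    offset_index: int
    amplitude: int

    def __post_init__(self) -> None:
        if self.onset_index < 0 or self.offset_index < self.onset_index:
            raise InvalidParameterError(
                f"need 0 <= onset <= offset, got "
                f"({self.onset_index}, {self.offset_index})"
            )
        object.__setattr__(self, "channel", Channel(self.channel))

    def overlaps(self, onset: int, offset: int) -> bool:
        return self.onset_index <= offset and onset <= self.offset_index


@dataclass(frozen=True)
class CalciumConfig:
    """Configuration of a simulated fluorescence transient.

    The acquisition timeline is 5 s baseline, 1 s stimulus, 9 s post by
    default. The response kernel is a difference of exponentials (rise
    and decay time constants) starting at stimulus onset, normalised to a
    continuous-time peak of 1, so ``true_dff`` is the true fractional
    amplitude: F(t) = f0 * (1 + true_dff * k(t)) + noise.
    """

    baseline_s: float = 5.0
    stim_s: float = 1.0
    post_s: float = 9.0
    frame_period: float = 0.1
    f0: float = 100.0
    true_dff: float = 0.5
    rise_tau: float = 0.2
    decay_tau: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stim_s", "post_s", "frame_period",
                     "rise_tau", "decay_tau"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.f0 <= 0:
            raise InvalidParameterError(f"f0 must be > 0, got {self.f0}")
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_frames(self) -> int:
        total = self.baseline_s + self.stim_s + self.post_s
        return to_samples(total, self.frame_period)


def _channel_rng(seed: int, channel_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), channel_index]))


def _plant_sips(
    n: int,
    model: SipModel,
    sample_period: float,
    channel: Channel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[PlantedEvent]]:
    """Additive pulse signal and ground-truth intervals for one channel."""
    signal = np.zeros(n)
    if model.rate <= 0 or model.amplitude == 0:
        return signal, []
    wave = model.waveform(sample_period)
    if wave.size == 0:
        return signal, []
    shape = 1.0 / model.burstiness
    scale = model.burstiness / model.rate
    duration = n * sample_period
    # draw gaps in batches until the session is covered
    onset_times: list[float] = []
    t = 0.0
    while True:
        gaps = rng.gamma(shape, scale, size=64)
        for g in gaps:
            t += g
            if t >= duration:
                break
            onset_times.append(t)
        if t >= duration:
            break
    raw: list[tuple[int, int]] = []
    for ot in onset_times:
        onset = to_samples(ot, sample_period)
        offset = min(onset + wave.size - 1, n - 1)
        if onset >= n:
            continue
        signal[onset : offset + 1] += wave[: offset - onset + 1]
        raw.append((onset, offset))
    # merge overlapping pulses into single ground-truth events
    events: list[PlantedEvent] = []
    n_merged = 0
    for onset, offset in raw:
        if events and onset <= events[-1].offset_index:
            prev = events.pop()
            events.append(
                PlantedEvent(
                    channel, prev.onset_index, max(prev.offset_index, offset),
                    model.amplitude,
                )
            )
            n_merged += 1
        else:
            events.append(PlantedEvent(channel, onset, offset, model.amplitude))
    if n_merged:
        logger.warning(
            "channel %s: merged %d overlapping sip pulses into longer events",
            channel.value, n_merged,
        )
    return signal, events


def simulate_session(
    config: SessionConfig,
) -> tuple[tuple[CapacitanceTrace, CapacitanceTrace], list[PlantedEvent]]:
    """Generate one two-channel session with ground truth.

    Each channel is baseline + sinusoidal drift (random phase) + Gaussian
    noise rounded to integer counts + trapezoidal sip pulses at gamma
    gaps. Identical configs (including seed) give bitwise-identical
    output. Returns the trace pair and the planted events of both
    channels (sorted by channel then onset).
    """
    n = config.n_samples
    t = np.arange(n) * config.sample_period
    traces = []
    planted: list[PlantedEvent] = []
    for idx, (channel, model) in enumerate(
        [(Channel.FOOD1, config.sip_food1), (Channel.FOOD2, config.sip_food2)]
    ):
        rng = _channel_rng(config.seed, idx)
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period + phase
        )
        noise = rng.normal(0, config.noise_sd, n) if config.noise_sd else 0.0
        pulses, events = _plant_sips(
            n, model, config.sample_period, channel, rng
        )
        raw = np.rint(config.baseline_level + drift + noise + pulses)
        values = np.clip(raw, 0, None).astype(np.int64)
        traces.append(
            CapacitanceTrace(values, config.sample_period, channel)
        )
        planted.extend(events)
    return (traces[0], traces[1]), planted


def derive_fly_seed(cohort_seed: int, fly_index: int) -> int:
    """Per-fly seed from a cohort seed by the (seed, index) counter scheme.

    Spawns a seed sequence keyed on the pair, so any single fly's session
    is reproducible in isolation without simulating the rest of the
    cohort.
    """
    ss = np.random.SeedSequence([int(cohort_seed), int(fly_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_flies: int,
    config1: SipModel,
    config2: SipModel,
    session: SessionConfig | None = None,
    seed: int = 0,
    detector_params: DetectorParams | None = None,
    min_sips: int = MIN_SIPS_DEFAULT,
    sip_bounds: tuple[float, float] = SIP_DURATION_BOUNDS,
    condition: str = "",
) -> list[FeedingSession]:
    """Simulate and analyse a cohort of independent single-fly sessions.

    Each fly gets a seed derived from ``seed`` and its index (see
    :func:`derive_fly_seed`), a fresh session with the given per-channel
    sip models, closed-loop detection with ``detector_params`` and the
    standard sip classification / preference / inclusion pipeline. The
    returned sessions carry the planted ground truth of both channels;
    raw traces are not retained.
    """
    if n_flies < 1:
        raise InvalidParameterError(f"n_flies must be >= 1, got {n_flies}")
    session = session or SessionConfig()
    detector_params = detector_params or DetectorParams(
        sample_period=session.sample_period
    )
    out: list[FeedingSession] = []
    for i in range(n_flies):
        cfg = replace(
            session,
            sip_food1=config1,
            sip_food2=config2,
            seed=derive_fly_seed(seed, i),
        )
        (tr1, tr2), planted = simulate_session(cfg)
        _, ev1 = detect(tr1, detector_params)
        _, ev2 = detect(tr2, detector_params)
        counts = count_sips(
            ev1 + ev2, session.sample_period, *sip_bounds
        )
        s1, s2 = counts[Channel.FOOD1], counts[Channel.FOOD2]
        fs = FeedingSession(
            fly_id=f"fly{i:03d}",
            sips_food1=s1,
            sips_food2=s2,
            preference=strobe_preference(s1, s2),
            condition=condition,
            events_food1=tuple(ev1),
            events_food2=tuple(ev2),
            ground_truth=tuple(planted),
        )
        out.append(apply_inclusion(fs, min_sips))
    return out


def simulate_calcium_trace(config: CalciumConfig) -> FluorescenceTrace:
    """Generate one indicator-like fluorescence transient.

    The response kernel k(t) is exp(-t/decay) - exp(-t/rise) for t past
    stimulus onset (an alpha function when the taus coincide), normalised
    so its continuous-time peak is exactly 1; the sampled peak is
    therefore at most ``true_dff`` in ΔF/F units.
    """
    n = config.n_frames
    t = np.arange(n) * config.frame_period
    dt = t - config.baseline_s
    k = np.zeros(n)
    after = dt >= 0
    tr, td = config.rise_tau, config.decay_tau
    if abs(td - tr) < 1e-12:
        # alpha function (t/tau) e^(1 - t/tau), peak 1 at t = tau
        k[after] = (dt[after] / tr) * np.exp(1.0 - dt[after] / tr)
    else:
        raw = np.exp(-dt[after] / td) - np.exp(-dt[after] / tr)
        t_peak = (tr * td / (td - tr)) * np.log(td / tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        k[after] = raw / peak
    values = config.f0 * (1.0 + config.true_dff * k)
    if config.noise_sd:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
        values = values + rng.normal(0, config.noise_sd, n)
    return FluorescenceTrace(
        values,
        frame_period=config.frame_period,
        stim_onset=config.baseline_s,
        stim_duration=config.stim_s,
    )
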