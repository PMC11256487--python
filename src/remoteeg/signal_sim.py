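"""Synthetic wearable-EEG generator.

Stands in for Muse-class hardware: four scalp channels of 1/f ("pink")
background noise, an occipito-temporal alpha rhythm whose amplitude depends
on the behavioral state (eyes open vs closed), stimulus-locked N200/P300
deflections added at oddball onsets, and optional mains interference.  All
signal levels are in microvolts; a :class:`SimulationPlan` with a fixed seed
produces a bit-identical :class:`~remoteeg.recording_io.Recording`.

The background noise is built by spectral shaping: white Gaussian noise is
transformed to the frequency domain, scaled by f^(-exponent/2) and
transformed back, which gives exact control of the power-law exponent.  ERP
components are Gaussian bumps parameterized by latency, width, peak
amplitude and polarity — the simplest shape with testable peak semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .acquisition import get_device_spec
from .recording_io import Recording
from .session_engine import (
    SessionConfig,
    overlay_markers,
    schedule_session,
    state_timeline,
)

__all__ = [
    "NoiseSpec",
    "OscillationSpec",
    "ErpTemplate",
    "ErpComponent",
    "SimulationPlan",
    "gen_colored_noise",
    "add_oscillation",
    "render_erp",
    "simulate_recording",
    "default_oddball_template",
    "default_alpha_spec",
    "MAX_SESSION_S",
]

MAX_SESSION_S = 3600.0


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise: power-law spectrum plus optional mains line."""

    amplitude_uV: float = 10.0  # RMS of the broadband component
    spectral_exponent: float = 1.0  # power ~ 1/f**exponent
    line_noise_uV: float = 0.0  # RMS at the mains frequency
    line_freq_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.amplitude_uV < 0:
            raise ValueError(f"amplitude_uV must be >= 0, got {self.amplitude_uV}")
        if self.spectral_exponent < 0:
            raise ValueError(f"spectral_exponent must be >= 0, got {self.spectral_exponent}")
        if self.line_noise_uV < 0:
            raise ValueError(f"line_noise_uV must be >= 0, got {self.line_noise_uV}")


@dataclass(frozen=True)
class OscillationSpec:
    """A narrowband rhythm whose amplitude is gated by behavioral state."""

    center_freq_hz: float = 10.0
    amplitude_uV: float = 5.0  # sinusoid amplitude at state gain 1
    state_gain: Mapping[str, float] = field(
        default_factory=lambda: {"eyes_open": 1.0, "eyes_closed": 2.0}
    )

    def __post_init__(self) -> None:
        if self.center_freq_hz <= 0:
            raise ValueError(f"center_freq_hz must be > 0, got {self.center_freq_hz}")
        if self.amplitude_uV < 0:
            raise ValueError(f"amplitude_uV must be >= 0, got {self.amplitude_uV}")
        if any(g < 0 for g in self.state_gain.values()):
            raise ValueError(f"state gains must be >= 0, got {dict(self.state_gain)}")
        object.__setattr__(self, "state_gain", dict(self.state_gain))

    def gain(self, state: str) -> float:
        return float(self.state_gain.get(state, 0.0))


@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian bump: (latency_s, width_s, amplitude_uV, polarity)."""

    latency_s: float
    width_s: float
    amplitude_uV: float
    polarity: int = 1  # +1 or -1

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError(f"width_s must be > 0, got {self.width_s}")
        if self.polarity not in (1, -1):
            raise ValueError(f"polarity must be +1 or -1, got {self.polarity}")


@dataclass(frozen=True)
class ErpTemplate:
    """Stimulus-locked waveform: a sum of Gaussian bumps per channel."""

    components: tuple[ErpComponent, ...] = ()
    channel_gains: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "channel_gains", tuple(float(g) for g in self.channel_gains))


def default_oddball_template(n_channels: int = 4) -> ErpTemplate:
    """N200 (negative, 200 ms) + P300 (positive, 300 ms) oddball response.

    Peak amplitudes 3 uV (N200) and 5 uV (P300); widths 30 and 50 ms.  All
    channels carry the response at unit gain.
    """
    return ErpTemplate(
        components=(
            ErpComponent(latency_s=0.2, width_s=0.03, amplitude_uV=3.0, polarity=-1),
            ErpComponent(latency_s=0.3, width_s=0.05, amplitude_uV=5.0, polarity=1),
        ),
        channel_gains=tuple(1.0 for _ in range(n_channels)),
    )


def default_alpha_spec(closed_gain: float = 2.0) -> OscillationSpec:
    """10 Hz alpha, 5 uV at eyes-open, amplified by *closed_gain* eyes-closed."""
    return OscillationSpec(
        center_freq_hz=10.0,
        amplitude_uV=5.0,
        state_gain={"eyes_open": 1.0, "eyes_closed": closed_gain},
    )


@dataclass(frozen=True)
class SimulationPlan:
    """Everything needed to synthesize one full session, reproducibly."""

    session_config: SessionConfig
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    oscillations: tuple[OscillationSpec, ...] = field(
        default_factory=lambda: (default_alpha_spec(),)
    )
    oddball_template: ErpTemplate = field(default_factory=default_oddball_template)
    standard_template: ErpTemplate | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "oscillations", tuple(self.oscillations))


def gen_colored_noise(
    n_samples: int, fs: float, spec: NoiseSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Generate one channel of power-law noise with RMS ``spec.amplitude_uV``.

    White Gaussian noise is shaped in the frequency domain by
    ``f**(-exponent/2)`` (DC excluded) and rescaled to the requested RMS,
    then any mains line is added as a fixed-phase sinusoid of RMS
    ``spec.line_noise_uV``.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    trace = np.zeros(n_samples)
    if spec.amplitude_uV > 0:
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-spec.spectral_exponent / 2.0)
        shaped = np.fft.irfft(spectrum * shaping, n=n_samples)
        rms = np.sqrt(np.mean(shaped**2))
        if rms > 0:
            trace = shaped * (spec.amplitude_uV / rms)
    if spec.line_noise_uV > 0:
        t = np.arange(n_samples) / fs
        trace = trace + spec.line_noise_uV * np.sqrt(2.0) * np.sin(
            2 * np.pi * spec.line_freq_hz * t
        )
    return trace


def add_oscillation(
    trace: np.ndarray,
    fs: float,
    spec: OscillationSpec,
    state_timeline: Sequence[tuple[float, float, str]],
) -> np.ndarray:
    """Add a state-gated sinusoid to a single-channel trace.

    Within each (start_s, end_s, state) interval the added component is
    ``amplitude_uV * state_gain(state) * sin(2 pi f t)`` with a phase
    continuous across intervals (t measured from the trace start); outside
    the listed intervals the trace is unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    if spec.center_freq_hz >= fs / 2:
        raise ValueError(
            f"center_freq_hz ({spec.center_freq_hz}) must be below the Nyquist "
            f"frequency ({fs / 2})"
        )
    duration = n / fs
    intervals = sorted(state_timeline)
    for (s0, e0, _), (s1, _, _) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise ValueError(f"state intervals overlap at {s1:.3f} s")
    out = trace.copy()
    t = np.arange(n) / fs
    carrier = np.sin(2 * np.pi * spec.center_freq_hz * t)
    for start_s, end_s, state in intervals:
        if start_s < -1e-12 or end_s > duration + 0.5 / fs:
            raise ValueError(
                f"interval ({start_s}, {end_s}) outside trace duration {duration:.3f} s"
            )
        i0 = int(np.ceil(start_s * fs - 1e-9))
        i1 = min(int(np.ceil(end_s * fs - 1e-9)), n)
        amp = spec.amplitude_uV * spec.gain(state)
        if amp > 0 and i1 > i0:
            out[i0:i1] += amp * carrier[i0:i1]
    return out


def render_erp(
    template: ErpTemplate, fs: float, window: tuple[float, float]
) -> np.ndarray:
    """Evaluate the template on a time grid; returns (channels, n_samples).

    Each component contributes ``polarity * amplitude_uV * channel_gain *
    exp(-(t - latency)^2 / (2 width^2))``; an empty template yields zeros.
    The grid runs from tmin to tmax inclusive at spacing 1/fs.
    """
    tmin, tmax = window
    if not tmin < tmax:
        raise ValueError(f"window must satisfy tmin < tmax, got {window}")
    n = int(round((tmax - tmin) * fs)) + 1
    t = tmin + np.arange(n) / fs
    gains = np.asarray(template.channel_gains, dtype=float)
    wave = np.zeros(n)
    for c in template.components:
        wave += c.polarity * c.amplitude_uV * np.exp(-((t - c.latency_s) ** 2) / (2 * c.width_s**2))
    return gains[:, None] * wave[None, :]


def simulate_recording(plan: SimulationPlan, max_duration_s: float = MAX_SESSION_S) -> Recording:
    """Synthesize a full session Recording from a plan.

    Per channel: independent colored noise, plus every oscillation gated by
    the behavioral state timeline the task sequence implies.  Each scheduled
    stimulus adds its template (oddball or standard) at the stimulus onset;
    the marker channel carries exactly one code per scheduled event.
    """
    config = plan.session_config
    device = get_device_spec(config.device)
    fs = device.sampling_rate_hz
    duration = config.total_duration_s
    if duration > max_duration_s:
        raise ValueError(
            f"session lasts {duration:.0f} s, above the configured maximum "
            f"{max_duration_s:.0f} s"
        )
    n = int(round(duration * fs))
    timestamps = np.arange(n) / fs
    timeline = state_timeline(config)
    events = schedule_session(config)

    # One independent child stream per channel keeps channels uncorrelated
    # while the whole recording stays reproducible from the single plan seed.
    children = np.random.SeedSequence(plan.seed).spawn(device.n_channels)
    data = np.empty((device.n_channels, n))
    for ch, child in enumerate(children):
        trace = gen_colored_noise(n, fs, plan.noise, np.random.default_rng(child))
        for osc in plan.oscillations:
            trace = add_oscillation(trace, fs, osc, timeline)
        data[ch] = trace

    templates = {"oddball": plan.oddball_template, "standard": plan.standard_template}
    erp_window = (0.0, 0.8)
    rendered = {
        k: render_erp(t, fs, erp_window) for k, t in templates.items() if t is not None
    }
    for ev in events:
        wave = rendered.get(ev.identity)
        if wave is None:
            continue
        i0 = int(round(ev.onset_s * fs))
        i1 = min(i0 + wave.shape[1], n)
        if i1 > i0:
            data[:, i0:i1] += wave[: data.shape[0], : i1 - i0]

    marker = overlay_markers(timestamps, events, fs)
    return Recording(
        timestamps=timestamps,
        data=data,
        marker=marker,
        device=device,
        session=config,
        metadata={"simulated": True, "seed": plan.seed},
    )
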