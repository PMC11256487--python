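"""Ready-made synthetic datasets for analysis benchmarks and examples.

These helpers compose the simulator primitives into the epoch sets the
analysis modules are validated on, without going through a full session:
independent colored-noise epochs with a stimulus-locked deflection added to
the oddball class.  They are the quickest route to a controlled
signal-to-noise ratio when the session machinery itself is not under test.
"""

from __future__ import annotations

import numpy as np

from .erp_stats import EpochSet
from .signal_sim import (
    ErpTemplate,
    NoiseSpec,
    default_oddball_template,
    gen_colored_noise,
    render_erp,
)

__all__ = ["synthetic_oddball_epochs", "boxcar_effect"]


def boxcar_effect(
    times: np.ndarray,
    n_channels: int,
    start_s: float = 0.25,
    end_s: float = 0.40,
    amplitude_uV: float = 5.0,
) -> np.ndarray:
    """A flat deflection of *amplitude_uV* on [start_s, end_s), all channels."""
    wave = np.where((times >= start_s) & (times < end_s), amplitude_uV, 0.0)
    return np.tile(wave, (n_channels, 1))


def synthetic_oddball_epochs(
    seed: int,
    n_oddball: int = 40,
    n_standard: int = 360,
    n_channels: int = 4,
    fs: float = 256.0,
    tmin: float = -0.2,
    tmax: float = 0.8,
    noise: NoiseSpec = NoiseSpec(amplitude_uV=10.0),
    template: ErpTemplate | np.ndarray | None = None,
    baseline: tuple[float, float] | None = (-0.2, 0.0),
    bandlimit: tuple[float, float] | None = (1.0, 55.0),
) -> EpochSet:
    """Noisy single-trial epochs with the oddball response added to one class.

    Each channel's background is one continuous colored-noise stream
    (defaults: 10 uV RMS, 1/f) that is bandpassed like a recorded session
    (zero-phase Butterworth over *bandlimit*; ``None`` disables) and then
    sliced into disjoint epochs, so epochs carry the spectral content the
    analysis pipeline actually sees.  Oddball epochs additionally carry
    *template*: an :class:`~remoteeg.signal_sim.ErpTemplate` (default: the
    standard N200+P300 shape), a raw (channels x times) array, or ``None``
    behaving as the default.  Pass an all-zero array for a null dataset.
    Epochs are baseline-corrected like extracted ERP epochs.
    """
    n_times = int(round((tmax - tmin) * fs)) + 1
    times = tmin + np.arange(n_times) / fs
    if template is None:
        template = default_oddball_template(n_channels)
    if isinstance(template, ErpTemplate):
        effect = render_erp(template, fs, (tmin, tmax))[:n_channels]
    else:
        effect = np.atleast_2d(np.asarray(template, dtype=float))
        if effect.shape != (n_channels, n_times):
            raise ValueError(
                f"template array must have shape {(n_channels, n_times)}, got {effect.shape}"
            )
    rng = np.random.default_rng(seed)
    n_total = n_oddball + n_standard
    pad = int(2 * fs)  # absorbs zero-phase filter edge transients
    n_long = n_total * n_times + 2 * pad
    epochs = np.empty((n_total, n_channels, n_times))
    for ch in range(n_channels):
        long = gen_colored_noise(n_long, fs, noise, rng)
        if bandlimit is not None:
            from scipy import signal as _signal

            sos = _signal.butter(10, bandlimit, btype="bandpass", fs=fs, output="sos")
            long = _signal.sosfiltfilt(sos, long)
        for e in range(n_total):
            epochs[e, ch] = long[pad + e * n_times : pad + (e + 1) * n_times]
    epochs[:n_oddball] += effect
    labels = np.asarray(["oddball"] * n_oddball + ["standard"] * n_standard, dtype=object)
    if baseline is not None:
        b0, b1 = baseline
        mask = (times >= b0) & (times <= b1)
        epochs = epochs - epochs[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        epochs=epochs,
        times=times,
        labels=labels,
        fs=fs,
        channel_names=tuple(f"ch{i}" for i in range(n_channels))
        if n_channels != 4
        else ("TP9", "AF7", "AF8", "TP10"),
    )
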