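"""Resting-state spectral analysis: filtering, epoching, band powers.

The pipeline mirrors a standard wearable-EEG resting-state analysis: a
zero-phase 1-55 Hz Butterworth bandpass (order chosen to keep 60 Hz mains
at least 20 dB down), segmentation of each rest
condition into consecutive two-second epochs, Welch power spectral
densities, and relative band powers over the canonical delta/theta/alpha/
beta/gamma bands (relative to total 1-55 Hz power, so each epoch's bands
sum to one).  Alpha blocking — higher relative alpha power with eyes
closed than open — is assessed with a Welch (unequal-variance) two-sample
t-test, and the scalp-wide band-change table reports every channel x band
cell with both raw and Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .erp_stats import EpochSet
from .recording_io import Recording
from .session_engine import TASK_END_BASE, TASK_START_BASE, TASK_STATE

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "AlphaBlockingResult",
    "bandpass",
    "segment_rest",
    "rest_intervals",
    "relative_band_powers",
    "band_power_table",
    "alpha_blocking_test",
    "band_change_table",
    "TOTAL_POWER_RANGE",
]

#: Frequency range the relative powers are normalized over (Hz).
TOTAL_POWER_RANGE = (1.0, 55.0)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo_hz, hi_hz)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got {self.lo_hz}, {self.hi_hz}")


#: Conventional band edges; together they tile the 1-55 Hz analysis range.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 55.0),
)


def _check_bands(bands: Sequence[BandDefinition]) -> None:
    ordered = sorted(bands, key=lambda b: b.lo_hz)
    for a, b in zip(ordered, ordered[1:]):
        if b.lo_hz < a.hi_hz:
            raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")


def bandpass(
    recording: Recording, lo_hz: float = 1.0, hi_hz: float = 55.0, order: int = 10
) -> Recording:
    """Zero-phase Butterworth bandpass, applied per channel.

    The default order (10 per edge, applied forward-backward) is chosen so
    that 60 Hz mains sits more than 20 dB below the passband even though
    the upper edge is only 55 Hz.  Markers and timestamps are untouched.
    Raises if *hi_hz* reaches the Nyquist frequency.
    """
    fs = recording.fs
    if hi_hz >= fs / 2:
        raise ValueError(f"hi_hz ({hi_hz}) must be below the Nyquist frequency ({fs / 2})")
    if not 0 < lo_hz < hi_hz:
        raise ValueError(f"need 0 < lo_hz < hi_hz, got {lo_hz}, {hi_hz}")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(
        timestamps=recording.timestamps,
        data=filtered,
        marker=recording.marker,
        device=recording.device,
        session=recording.session,
        metadata={**recording.metadata, "bandpass_hz": [lo_hz, hi_hz]},
    )


def rest_intervals(recording: Recording) -> list[tuple[float, float, str]]:
    """Rest intervals (start_s, end_s, state) from the recording's session.

    The interval bounds come from the task sequence's cumulative durations
    (the boundary markers themselves can be displaced by one sample when
    two events collide); each task's presence is verified via its start
    marker.  Only rest_eyes_open / rest_eyes_closed tasks are returned,
    labeled by their behavioral state.
    """
    if recording.session is None:
        raise ValueError("recording has no session config; pass intervals explicitly")
    out = []
    t = 0.0
    for i, task in enumerate(recording.session.tasks):
        if task.kind.startswith("rest_"):
            if recording.marker_onsets(TASK_START_BASE + i).size != 1:
                raise ValueError(f"task {i} start marker missing or duplicated")
            out.append((t, t + task.total_duration_s, TASK_STATE[task.kind]))
        t += task.total_duration_s
    return out


def segment_rest(
    recording: Recording,
    condition_intervals: Sequence[tuple[float, float, str]] | None = None,
    epoch_s: float = 2.0,
) -> EpochSet:
    """Cut each condition interval into consecutive fixed-length epochs.

    Windows are non-overlapping and aligned to the interval start; a
    partial trailing window is dropped.  An interval shorter than *epoch_s*
    simply contributes no epochs.  With ``condition_intervals=None`` the
    intervals are recovered from the recording's task-boundary markers.
    """
    if condition_intervals is None:
        condition_intervals = rest_intervals(recording)
    fs = recording.fs
    n_per = int(round(epoch_s * fs))
    epochs, labels = [], []
    for start_s, end_s, condition in condition_intervals:
        if not 0 <= start_s <= end_s <= recording.duration_s + 0.5 / fs:
            raise ValueError(
                f"interval ({start_s}, {end_s}) outside recording "
                f"(duration {recording.duration_s:.2f} s)"
            )
        i0 = int(round(start_s * fs))
        i_end = int(round(end_s * fs))
        for k in range((i_end - i0) // n_per):
            epochs.append(recording.data[:, i0 + k * n_per : i0 + (k + 1) * n_per])
            labels.append(condition)
    if epochs:
        arr = np.stack(epochs)
    else:
        arr = np.empty((0, recording.n_channels, n_per))
    return EpochSet(
        epochs=arr,
        times=np.arange(n_per) / fs,
        labels=np.asarray(labels, dtype=object),
        fs=fs,
        channel_names=recording.channel_names,
    )


def relative_band_powers(
    epoch: np.ndarray,
    fs: float,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> pd.Series:
    """Relative band powers of one single-channel window.

    The PSD is Welch-estimated with 1 s Hann segments at 50% overlap; the
    power in each band is the PSD integral over [lo, hi), and relative
    powers are normalized by the total over 1-55 Hz so the returned row
    sums to one.  Windows shorter than 1 s are rejected.
    """
    epoch = np.asarray(epoch, dtype=float).ravel()
    if epoch.shape[0] < fs:
        raise ValueError(
            f"window has {epoch.shape[0]} samples; need at least 1 s ({int(fs)} samples)"
        )
    _check_bands(bands)
    nperseg = int(round(fs))
    freqs, psd = signal.welch(
        epoch, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    df = freqs[1] - freqs[0]
    lo_tot, hi_tot = TOTAL_POWER_RANGE
    total = psd[(freqs >= lo_tot) & (freqs < hi_tot)].sum() * df
    if total <= 0:
        raise ValueError("window has no power in the 1-55 Hz analysis range")
    values = {
        b.name: psd[(freqs >= b.lo_hz) & (freqs < b.hi_hz)].sum() * df / total for b in bands
    }
    return pd.Series(values, name="relative_power")


def band_power_table(
    epochs: EpochSet,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relative band powers for every (epoch, channel), as a tidy DataFrame.

    Columns: ``epoch``, ``channel``, ``condition`` plus one column per band.
    """
    if channels is None:
        channels = epochs.channel_names or tuple(str(i) for i in range(epochs.n_channels))
    rows = []
    for e in range(epochs.n_epochs):
        for ch_name in channels:
            ch = epochs.channel_index(ch_name) if epochs.channel_names else int(ch_name)
            powers = relative_band_powers(epochs.epochs[e, ch], epochs.fs, bands)
            rows.append(
                {"epoch": e, "channel": ch_name, "condition": epochs.labels[e], **powers}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AlphaBlockingResult:
    """Welch t-test of eyes-closed vs eyes-open relative alpha power."""

    t: float
    p_value: float
    mean_difference: float  # closed minus open; positive = alpha blocking
    n_closed: int
    n_open: int
    degenerate: bool = False  # both groups constant and equal


def alpha_blocking_test(
    closed_rows: Sequence[float] | np.ndarray,
    open_rows: Sequence[float] | np.ndarray,
) -> AlphaBlockingResult:
    """Test whether relative alpha power is higher with eyes closed.

    Two-sample Welch (unequal-variance) t-test; positive mean difference
    means closed > open.  If both groups are constant with equal means the
    test is degenerate and p = 1 is reported with a flag.
    """
    closed = np.asarray(closed_rows, dtype=float).ravel()
    opened = np.asarray(open_rows, dtype=float).ravel()
    if closed.size < 2 or opened.size < 2:
        raise ValueError(
            f"need >= 2 epochs per condition, got closed: {closed.size}, open: {opened.size}"
        )
    diff = float(closed.mean() - opened.mean())
    # constant groups: the t statistic is undefined, not merely unstable
    if np.all(closed == closed[0]) and np.all(opened == opened[0]):
        if diff == 0:
            return AlphaBlockingResult(0.0, 1.0, 0.0, closed.size, opened.size, degenerate=True)
        return AlphaBlockingResult(
            np.inf if diff > 0 else -np.inf, 0.0, diff, closed.size, opened.size, degenerate=True
        )
    t, p = stats.ttest_ind(closed, opened, equal_var=False)
    return AlphaBlockingResult(float(t), float(p), diff, closed.size, opened.size)


#: Left/right homologous electrode pairs reported side by side.
SYMMETRIC_PAIRS = (("TP9", "TP10"), ("AF7", "AF8"))


def band_change_table(
    sessions: Sequence[Recording],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    channels: Sequence[str] | None = None,
    epoch_s: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Eyes-closed vs eyes-open change per (channel, band), pooled over sessions.

    Rest epochs from every session are pooled per condition; each channel x
    band cell gets the two condition means, the Welch t statistic, the raw
    p-value, and a Benjamini-Hochberg adjusted p across all cells.  Rows
    are ordered so left/right homologous electrodes (TP9/TP10, AF7/AF8)
    appear side by side.
    """
    if not sessions:
        raise ValueError("need at least one session")
    tables = []
    for rec in sessions:
        rest = segment_rest(rec, epoch_s=epoch_s)
        if rest.n_epochs:
            tables.append(band_power_table(rest, bands, channels))
    if not tables:
        raise ValueError("no rest epochs found in any session")
    pooled = pd.concat(tables, ignore_index=True)
    conditions = set(pooled["condition"])
    if not {"eyes_closed", "eyes_open"} <= conditions:
        raise ValueError(
            f"both rest conditions are required; found only {sorted(conditions)}"
        )

    if channels is None:
        ordered = [ch for pair in SYMMETRIC_PAIRS for ch in pair]
        present = list(dict.fromkeys(pooled["channel"]))
        channels = [c for c in ordered if c in present] + [
            c for c in present if c not in ordered
        ]
    rows = []
    for ch in channels:
        sub = pooled[pooled["channel"] == ch]
        closed = sub[sub["condition"] == "eyes_closed"]
        opened = sub[sub["condition"] == "eyes_open"]
        for band in bands:
            res = alpha_blocking_test(closed[band.name], opened[band.name])
            rows.append(
                {
                    "channel": ch,
                    "band": band.name,
                    "mean_closed": closed[band.name].mean(),
                    "mean_open": opened[band.name].mean(),
                    "mean_difference": res.mean_difference,
                    "t": res.t,
                    "p_raw": res.p_value,
                }
            )
    table = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(table["p_raw"], alpha=alpha, method="fdr_bh")
    table["p_adjusted"] = p_adj
    table["significant"] = table["p_adjusted"] < alpha
    return table
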