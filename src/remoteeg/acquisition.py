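"""Device abstraction and the pre-session electrode signal-quality gate.

Wearable headsets are represented by an immutable :class:`DeviceSpec` held in
a registry keyed by device name ("hard-coded but modifiable": new entries can
be registered at run time).  Live acquisition is abstracted as an ordered
stream of :class:`StreamChunk` objects; :func:`stream_recording` turns a
stored :class:`~remoteeg.recording_io.Recording` into such a stream so every
downstream consumer can be exercised without hardware.

The quality gate mirrors the traffic-light check a participant sees before a
session starts: each electrode's rolling standard deviation is compared with
an accept and a reject threshold, giving the states ``accepted`` (green),
``near`` (yellow) and ``rejected`` (red).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .recording_io import Recording

__all__ = [
    "DeviceSpec",
    "StreamChunk",
    "QualityStatus",
    "get_device_spec",
    "register_device",
    "list_devices",
    "assess_quality",
    "stream_recording",
    "QUALITY_STATES",
]

#: Quality states ordered from best to worst.
QUALITY_STATES = ("accepted", "near", "rejected")


@dataclass(frozen=True)
class DeviceSpec:
    """Static description of an EEG wearable.

    Parameters
    ----------
    name
        Registry identifier, e.g. ``"muse2"``.
    channel_names
        Ordered scalp electrode labels (10-20 nomenclature).
    sampling_rate_hz
        Nominal sampling rate in Hz.
    reference_position
        10-20 label of the reference electrode.
    provisional
        True when the channel layout is a best-effort guess rather than a
        vendor-documented fact.
    """

    name: str
    channel_names: tuple[str, ...]
    sampling_rate_hz: float
    reference_position: str
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names must be unique, got {self.channel_names}")
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channel_names": list(self.channel_names),
            "sampling_rate_hz": self.sampling_rate_hz,
            "reference_position": self.reference_position,
            "provisional": self.provisional,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DeviceSpec":
        return cls(
            name=d["name"],
            channel_names=tuple(d["channel_names"]),
            sampling_rate_hz=float(d["sampling_rate_hz"]),
            reference_position=d["reference_position"],
            provisional=bool(d.get("provisional", False)),
        )


# Registry of supported wearables.  Muse-class headbands expose four dry
# electrodes (TP9, AF7, AF8, TP10) referenced to Fpz; the EPOC X entry is
# provisional because only its name, not its layout, is pinned down here.
_MUSE_CHANNELS = ("TP9", "AF7", "AF8", "TP10")

_REGISTRY: dict[str, DeviceSpec] = {}


def register_device(spec: DeviceSpec, *, overwrite: bool = False) -> None:
    """Add a device to the registry (``overwrite=True`` to replace)."""
    if spec.name in _REGISTRY and not overwrite:
        raise ValueError(f"device {spec.name!r} already registered")
    _REGISTRY[spec.name] = spec


for _spec in (
    DeviceSpec("muse2", _MUSE_CHANNELS, 256.0, "Fpz"),
    DeviceSpec("muses", _MUSE_CHANNELS, 256.0, "Fpz"),
    DeviceSpec(
        "epocx",
        ("AF3", "F7", "F3", "FC5", "T7", "P7", "O1", "O2", "P8", "T8", "FC6", "F4", "F8", "AF4"),
        128.0,
        "CMS/DRL",
        provisional=True,
    ),
    # The virtual device mirrors the simulator defaults.
    DeviceSpec("virtual", _MUSE_CHANNELS, 256.0, "Fpz"),
):
    register_device(_spec)


def list_devices() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def get_device_spec(name: str) -> DeviceSpec:
    """Look up a registered device by name.

    Raises
    ------
    KeyError
        For unknown names; the message lists the registered devices.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown device {name!r}; registered devices: {{{', '.join(list_devices())}}}"
        ) from None


@dataclass
class StreamChunk:
    """Unit of data handed from the acquisition thread to consumers."""

    timestamps: np.ndarray  # (n,) seconds, strictly increasing
    samples: np.ndarray  # (channels, n) microvolts

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != self.timestamps.shape[0]:
            raise ValueError(
                f"samples have {self.samples.shape[1]} columns but "
                f"{self.timestamps.shape[0]} timestamps"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration_s(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class QualityStatus:
    """Per-electrode variability and traffic-light state."""

    variability_uV: np.ndarray  # (channels,) rolling standard deviation
    states: tuple[str, ...]  # each in QUALITY_STATES
    all_accepted: bool
    channel_names: tuple[str, ...] | None = None
    accept_uV: float = field(default=np.nan)
    reject_uV: float = field(default=np.nan)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        names = self.channel_names or tuple(f"ch{i}" for i in range(len(self.states)))
        lines = [
            f"{n:>6s}  sigma={v:8.2f} uV  {s}"
            for n, v, s in zip(names, self.variability_uV, self.states)
        ]
        lines.append("all accepted" if self.all_accepted else "NOT all accepted")
        return "\n".join(lines)


def _state_for(sigma: float, accept_uV: float, reject_uV: float) -> str:
    if sigma <= accept_uV:
        return "accepted"
    if sigma >= reject_uV:
        return "rejected"
    return "near"


def assess_quality(
    window: StreamChunk,
    accept_uV: float = 20.0,
    reject_uV: float = 40.0,
    min_duration_s: float = 1.0,
    channel_names: Sequence[str] | None = None,
) -> QualityStatus:
    """Grade each electrode by its signal variability over a short window.

    The variability metric is the sample standard deviation of the window;
    an electrode is ``accepted`` when sigma <= *accept_uV*, ``rejected`` when
    sigma >= *reject_uV* and ``near`` in between.  A flat (zero-variance)
    electrode is accepted: the gate measures variability only.

    Raises
    ------
    ValueError
        If ``accept_uV >= reject_uV`` or the window is shorter than
        *min_duration_s*.
    """
    if not accept_uV < reject_uV:
        raise ValueError(f"accept_uV ({accept_uV}) must be < reject_uV ({reject_uV})")
    if window.duration_s < min_duration_s:
        raise ValueError(
            f"window spans {window.duration_s:.3f} s but the quality assessment "
            f"needs at least {min_duration_s:.3f} s"
        )
    sigma = np.std(window.samples, axis=1, ddof=1)
    states = tuple(_state_for(float(s), accept_uV, reject_uV) for s in sigma)
    return QualityStatus(
        variability_uV=sigma,
        states=states,
        all_accepted=all(s == "accepted" for s in states),
        channel_names=tuple(channel_names) if channel_names is not None else None,
        accept_uV=accept_uV,
        reject_uV=reject_uV,
    )


def stream_recording(recording: "Recording", chunk_size: int) -> Iterator[StreamChunk]:
    """Replay a stored recording as an ordered chunk stream.

    Concatenating the yielded chunks reproduces the recording's timestamps
    and samples exactly; the final chunk may be shorter than *chunk_size*.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    n = recording.n_samples
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        yield StreamChunk(
            timestamps=recording.timestamps[start:stop],
            samples=recording.data[:, start:stop],
        )
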