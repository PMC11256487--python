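"""Session configuration, stimulus scheduling and marker overlay.

A session is an ordered list of tasks (eyes-open/eyes-closed rest, free
recording, visual oddball blocks).  The engine turns a validated
:class:`SessionConfig` into a deterministic schedule of
:class:`StimulusEvent` objects, and :func:`run_session` merges the events'
numerical marker codes into a timestamped sample stream, producing a
:class:`~remoteeg.recording_io.Recording`.

The engine never draws anything on screen: :func:`describe_stimulus` emits a
renderer-agnostic descriptor (the oddball paradigm uses a frequent green
circle and a rare blue circle) and leaves presentation to the caller.

Marker conventions
------------------
Code 0 is reserved for "no event".  Defaults: standard=1, oddball=2,
task boundaries 100+i / 200+i for task index i.  If two events fall on the
same sample, the later one is shifted to the next free sample so that no
marker is ever lost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .acquisition import StreamChunk, get_device_spec
from .errors import ConfigError, SessionTruncationError

__all__ = [
    "TaskSpec",
    "SessionConfig",
    "StimulusEvent",
    "StimulusDescriptor",
    "load_session_config",
    "save_session_config",
    "default_session_config",
    "build_oddball_sequence",
    "schedule_session",
    "state_timeline",
    "run_session",
    "describe_stimulus",
    "overlay_markers",
    "TASK_KINDS",
    "TASK_START_BASE",
    "TASK_END_BASE",
]

TASK_KINDS = ("rest_eyes_open", "rest_eyes_closed", "free_recording", "oddball")
TASK_START_BASE = 100
TASK_END_BASE = 200

#: Behavioral state implied by each task kind (drives simulated alpha).
TASK_STATE = {
    "rest_eyes_open": "eyes_open",
    "rest_eyes_closed": "eyes_closed",
    "free_recording": "eyes_open",
    "oddball": "eyes_open",
}


@dataclass(frozen=True)
class TaskSpec:
    """One task in the session sequence.

    Rest and free-recording tasks are specified by ``duration_s``; oddball
    blocks by ``n_trials`` plus their timing parameters.
    """

    kind: str
    duration_s: float | None = None
    n_trials: int | None = None
    p_oddball: float = 0.1
    isi_s: float = 1.0
    stim_duration_s: float = 0.2
    max_consecutive_oddballs: int | None = 2

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ConfigError(f"unknown task kind {self.kind!r}; expected one of {TASK_KINDS}")
        if self.kind == "oddball":
            if self.n_trials is None or self.duration_s is not None:
                raise ConfigError("oddball task requires n_trials (and no duration_s)")
            if self.n_trials < 1:
                raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
            if not 0.0 <= self.p_oddball <= 1.0:
                raise ConfigError(f"p_oddball must be in [0, 1], got {self.p_oddball}")
            if self.isi_s <= 0:
                raise ConfigError(f"isi_s must be > 0, got {self.isi_s}")
        else:
            if self.duration_s is None or self.n_trials is not None:
                raise ConfigError(f"{self.kind} task requires duration_s (and no n_trials)")
            if self.duration_s <= 0:
                raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def total_duration_s(self) -> float:
        if self.kind == "oddball":
            return self.n_trials * self.isi_s
        return float(self.duration_s)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "oddball":
            d.update(
                n_trials=self.n_trials,
                p_oddball=self.p_oddball,
                isi_s=self.isi_s,
                stim_duration_s=self.stim_duration_s,
                max_consecutive_oddballs=self.max_consecutive_oddballs,
            )
        else:
            d["duration_s"] = self.duration_s
        return d


DEFAULT_MARKER_MAP = {"standard": 1, "oddball": 2}


@dataclass(frozen=True)
class SessionConfig:
    """Validated, ordered description of a full recording session."""

    tasks: tuple[TaskSpec, ...]
    device: str = "virtual"
    marker_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MARKER_MAP))
    seed: int = 0
    version: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "tasks", tuple(self.tasks))
        object.__setattr__(self, "marker_map", dict(self.marker_map))
        if not self.tasks:
            raise ConfigError("tasks: a session needs at least one task")
        for identity in ("standard", "oddball"):
            if identity not in self.marker_map:
                raise ConfigError(f"marker_map: missing required identity {identity!r}")
        codes = list(self.marker_map.values())
        for identity, code in self.marker_map.items():
            if not isinstance(code, (int, np.integer)) or code <= 0:
                raise ConfigError(
                    f"marker_map[{identity!r}]: codes must be positive integers "
                    f"(0 is reserved for 'no event'), got {code!r}"
                )
        if len(set(codes)) != len(codes):
            raise ConfigError(f"marker_map: codes must be unique, got {self.marker_map}")
        boundary = set(range(TASK_START_BASE, TASK_START_BASE + len(self.tasks))) | set(
            range(TASK_END_BASE, TASK_END_BASE + len(self.tasks))
        )
        clash = boundary & set(codes)
        if clash:
            raise ConfigError(f"marker_map: codes {sorted(clash)} collide with task-boundary codes")

    @property
    def total_duration_s(self) -> float:
        return sum(t.total_duration_s for t in self.tasks)

    def task_start_code(self, i: int) -> int:
        return TASK_START_BASE + i

    def task_end_code(self, i: int) -> int:
        return TASK_END_BASE + i

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "device": self.device,
            "seed": self.seed,
            "markers": dict(self.marker_map),
            "tasks": [t.to_dict() for t in self.tasks],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionConfig":
        try:
            tasks = tuple(TaskSpec(**t) for t in d.get("tasks", []))
        except TypeError as e:
            raise ConfigError(f"tasks: {e}") from None
        return cls(
            tasks=tasks,
            device=d.get("device", "virtual"),
            marker_map=d.get("markers", dict(DEFAULT_MARKER_MAP)),
            seed=int(d.get("seed", 0)),
            version=int(d.get("version", 1)),
        )


@dataclass(frozen=True)
class StimulusEvent:
    """A scheduled marker: stimulus onset or task boundary."""

    onset_s: float
    identity: str  # standard | oddball | task_start | task_end
    marker_code: int


@dataclass(frozen=True)
class StimulusDescriptor:
    """Renderer-agnostic description of a visual stimulus."""

    shape: str
    color: str


_STIMULUS_DESCRIPTORS = {
    "standard": StimulusDescriptor(shape="circle", color="green"),
    "oddball": StimulusDescriptor(shape="circle", color="blue"),
    "task_start": None,
    "task_end": None,
}


def describe_stimulus(identity: str) -> StimulusDescriptor | None:
    """Display descriptor for a stimulus identity (None for non-visual events)."""
    try:
        return _STIMULUS_DESCRIPTORS[identity]
    except KeyError:
        raise KeyError(
            f"unknown stimulus identity {identity!r}; "
            f"known: {sorted(_STIMULUS_DESCRIPTORS)}"
        ) from None


def load_session_config(path: str | Path) -> SessionConfig:
    """Parse and validate a YAML session configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level, got {type(raw).__name__}")
    return SessionConfig.from_dict(raw)


def save_session_config(config: SessionConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_session_config(seed: int = 0, device: str = "virtual") -> SessionConfig:
    """The shipped default session: free recording, eyes-open and eyes-closed
    rest, and two oddball blocks separated by a short rest."""
    path = Path(__file__).parent / "configs" / "default_session.yaml"
    base = load_session_config(path)
    return dataclasses.replace(base, seed=seed, device=device)


def build_oddball_sequence(
    n_trials: int,
    p_oddball: float,
    seed: int,
    max_consecutive_oddballs: int | None = 2,
) -> list[str]:
    """Draw a trial sequence of ``standard`` / ``oddball`` identities.

    Each trial is independently an oddball with probability *p_oddball*;
    runs longer than *max_consecutive_oddballs* are then repaired by
    re-drawing the violating trials with the same generator, which keeps the
    sequence deterministic for a given seed.  ``None`` disables the cap.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if not 0.0 <= p_oddball <= 1.0:
        raise ValueError(f"p_oddball must be in [0, 1], got {p_oddball}")
    rng = np.random.default_rng(seed)
    is_odd = rng.random(n_trials) < p_oddball
    cap = max_consecutive_oddballs
    if cap is not None and 0 < p_oddball < 1:
        # Re-draw any trial that would extend an oddball run past the cap.
        run = 0
        for i in range(n_trials):
            if is_odd[i]:
                run += 1
                while run > cap:
                    is_odd[i] = rng.random() < p_oddball
                    if not is_odd[i]:
                        run = 0
            else:
                run = 0
    return ["oddball" if o else "standard" for o in is_odd]


def schedule_session(config: SessionConfig) -> list[StimulusEvent]:
    """Expand a session config into its full, deterministic event schedule.

    Trial j of an oddball block is presented at the center of its ISI slot,
    ``block_start + (j + 1/2) * isi``, so stimuli never coincide with the
    block boundaries.  Each task contributes a task_start event at its
    first instant and a task_end event one sample period before its end
    (i.e. on the task's last sample at the device rate), so that distinct
    events always map to distinct samples.
    """
    fs = get_device_spec(config.device).sampling_rate_hz
    events: list[StimulusEvent] = []
    t = 0.0
    for i, task in enumerate(config.tasks):
        events.append(StimulusEvent(t, "task_start", config.task_start_code(i)))
        if task.kind == "oddball":
            identities = build_oddball_sequence(
                task.n_trials,
                task.p_oddball,
                seed=_block_seed(config.seed, i),
                max_consecutive_oddballs=task.max_consecutive_oddballs,
            )
            for j, identity in enumerate(identities):
                onset = t + (j + 0.5) * task.isi_s
                events.append(StimulusEvent(onset, identity, config.marker_map[identity]))
        t += task.total_duration_s
        events.append(StimulusEvent(t - 1.0 / fs, "task_end", config.task_end_code(i)))
    return events


def _block_seed(session_seed: int, task_index: int) -> int:
    # Independent, reproducible stream per oddball block.
    return int(np.random.SeedSequence([session_seed, task_index]).generate_state(1)[0] % (2**31))


def state_timeline(config: SessionConfig) -> list[tuple[float, float, str]]:
    """Behavioral-state intervals (start_s, end_s, state) implied by the tasks."""
    timeline = []
    t = 0.0
    for task in config.tasks:
        timeline.append((t, t + task.total_duration_s, TASK_STATE[task.kind]))
        t += task.total_duration_s
    return timeline


def overlay_markers(
    timestamps: np.ndarray, events: Iterable[StimulusEvent], fs: float
) -> np.ndarray:
    """Place each event's code on the sample nearest its onset.

    Timestamps are assumed uniformly spaced at 1/fs.  When two events map to
    the same sample the later one moves to the next free sample, so every
    scheduled event appears exactly once.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    n = timestamps.shape[0]
    marker = np.zeros(n, dtype=np.int64)
    t0 = timestamps[0] if n else 0.0
    for ev in sorted(events, key=lambda e: e.onset_s):
        idx = int(round((ev.onset_s - t0) * fs))
        idx = min(max(idx, 0), n - 1)
        while idx < n and marker[idx] != 0:
            idx += 1
        if idx >= n:
            raise ValueError(f"no free sample for event at {ev.onset_s:.3f} s")
        marker[idx] = ev.marker_code
    return marker


def run_session(
    config: SessionConfig,
    source: Iterable[StreamChunk],
    clock: object | None = None,
):
    """Execute a session against a chunk stream and return the Recording.

    The *source* plays the role of the acquisition thread: an ordered
    iterable of :class:`StreamChunk`.  Sample timestamps are taken from the
    stream itself (for replayed or simulated sources the stream clock is the
    session clock; *clock* is accepted for interface compatibility and is
    unused here).  Marker codes for every scheduled event are overlaid on
    the nearest sample.

    Raises
    ------
    SessionTruncationError
        If the source runs out before the scheduled session duration; the
        error reports the last fully covered task.
    """
    from .recording_io import Recording  # local import to avoid a cycle

    device = get_device_spec(config.device)
    fs = device.sampling_rate_hz
    chunks = list(source)
    if not chunks:
        raise SessionTruncationError("source delivered no data", last_completed_task=None)
    timestamps = np.concatenate([c.timestamps for c in chunks])
    data = np.concatenate([c.samples for c in chunks], axis=1)

    total = config.total_duration_s
    covered = timestamps[-1] - timestamps[0] + 1.0 / fs
    if covered + 0.5 / fs < total:
        t_end = 0.0
        last_done = None
        for i, task in enumerate(config.tasks):
            t_end += task.total_duration_s
            if covered + 0.5 / fs >= t_end:
                last_done = i
        raise SessionTruncationError(
            f"source exhausted after {covered:.2f} s of a {total:.2f} s session "
            f"(last completed task: "
            f"{'none' if last_done is None else f'{last_done} ({config.tasks[last_done].kind})'})",
            last_completed_task=last_done,
        )

    events = schedule_session(config)
    marker = overlay_markers(timestamps, events, fs)
    return Recording(
        timestamps=timestamps,
        data=data,
        marker=marker,
        device=device,
        session=config,
        metadata={"engine": "run_session"},
    )
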