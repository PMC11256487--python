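"""ERP epoching, condition averaging and cluster-based permutation tests.

Event-related potentials are extracted as fixed windows around each stimulus
marker, baseline-corrected on the pre-stimulus interval, and averaged per
condition.  Oddball-vs-standard differences are tested with the standard
cluster-based permutation construction: a two-sample t statistic at every
time sample, clusters of contiguous samples whose |t| exceeds the
two-sided threshold at the cluster-forming p, cluster mass = sum of |t|,
and a max-cluster-mass permutation null obtained by shuffling the condition
labels.  The attainable p floor is 1/(n_permutations+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .recording_io import Recording

__all__ = [
    "EpochSet",
    "Cluster",
    "ClusterTestResult",
    "extract_erp_epochs",
    "average_erp",
    "cluster_permutation_test",
    "DEFAULT_ERP_CODES",
]

#: Default stimulus-identity -> marker-code mapping for ERP extraction.
DEFAULT_ERP_CODES = {"standard": 1, "oddball": 2}


@dataclass
class EpochSet:
    """Fixed-length, label-annotated signal windows sharing one time axis."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_times) microvolts
    times: np.ndarray  # (n_times,) seconds relative to lock point
    labels: np.ndarray  # (n_epochs,) condition strings
    fs: float
    channel_names: tuple[str, ...] = ()
    n_dropped: int = 0  # epochs discarded at recording edges

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError(f"epochs must be 3-D (epochs, channels, times), got {self.epochs.shape}")
        if self.epochs.shape[2] != self.times.shape[0]:
            raise ValueError(
                f"epochs have {self.epochs.shape[2]} samples but the time axis has "
                f"{self.times.shape[0]}"
            )
        if self.labels.shape[0] != self.epochs.shape[0]:
            raise ValueError(
                f"{self.labels.shape[0]} labels for {self.epochs.shape[0]} epochs"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.tolist())))

    def select(self, condition: str) -> np.ndarray:
        """(n, channels, times) array of the epochs labeled *condition*."""
        return self.epochs[self.labels == condition]

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"no channel {channel!r}; available: {self.channel_names}"
            ) from None


def extract_erp_epochs(
    recording: Recording,
    marker_codes: Mapping[str, int] | None = None,
    tmin: float = -0.2,
    tmax: float = 0.8,
    baseline: tuple[float, float] | None = (-0.2, 0.0),
) -> EpochSet:
    """Cut one epoch per stimulus marker and baseline-correct it.

    Epochs span ``tmin..tmax`` seconds around each marker sample (length
    ``round((tmax-tmin)*fs) + 1``).  The per-channel mean over the baseline
    interval is subtracted from each epoch.  Epochs that would cross a
    recording edge are dropped and counted in ``n_dropped``.
    """
    if marker_codes is None:
        marker_codes = DEFAULT_ERP_CODES
    fs = recording.fs
    n_before = int(round(-tmin * fs))
    n_after = int(round(tmax * fs))
    n_times = n_before + n_after + 1
    times = (np.arange(n_times) - n_before) / fs

    code_to_label = {code: label for label, code in marker_codes.items()}
    onsets = np.flatnonzero(np.isin(recording.marker, list(code_to_label)))
    epochs, labels, dropped = [], [], 0
    for idx in onsets:
        start = idx - n_before
        stop = idx + n_after + 1
        if start < 0 or stop > recording.n_samples:
            dropped += 1
            continue
        epochs.append(recording.data[:, start:stop])
        labels.append(code_to_label[int(recording.marker[idx])])
    if not epochs:
        warnings.warn(
            f"no markers with codes {sorted(code_to_label)} found; empty EpochSet",
            stacklevel=2,
        )
        arr = np.empty((0, recording.n_channels, n_times))
    else:
        arr = np.stack(epochs)
    if baseline is not None and arr.size:
        b0, b1 = baseline
        mask = (times >= b0) & (times <= b1)
        if not mask.any():
            raise ValueError(f"baseline {baseline} does not overlap the epoch window")
        arr = arr - arr[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        epochs=arr,
        times=times,
        labels=np.asarray(labels, dtype=object),
        fs=fs,
        channel_names=recording.channel_names,
        n_dropped=dropped,
    )


def average_erp(
    epochs: EpochSet,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-condition pointwise mean and standard error of the mean.

    Returns ``{condition: (mean, sem)}`` with arrays of shape
    (channels, times).  A single-epoch condition gets NaN standard errors;
    empty conditions are excluded with a warning.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond in epochs.conditions:
        x = epochs.select(cond)
        if x.shape[0] == 0:  # pragma: no cover - conditions come from labels
            warnings.warn(f"condition {cond!r} has no epochs; excluded", stacklevel=2)
            continue
        mean = x.mean(axis=0)
        if x.shape[0] > 1:
            sem = x.std(axis=0, ddof=1) / np.sqrt(x.shape[0])
        else:
            warnings.warn(f"condition {cond!r} has a single epoch; SE undefined", stacklevel=2)
            sem = np.full_like(mean, np.nan)
        out[cond] = (mean, sem)
    return out


@dataclass(frozen=True)
class Cluster:
    """A contiguous suprathreshold interval with its mass and p-value."""

    start_s: float
    end_s: float
    mass: float  # sum of |t| over the cluster
    p_value: float
    sign: int  # sign of t inside the cluster


@dataclass
class ClusterTestResult:
    """Outcome of a cluster-based permutation test on one channel."""

    clusters: list[Cluster]
    t_values: np.ndarray  # (n_times,)
    threshold: float  # cluster-forming |t| threshold
    times: np.ndarray
    channel: str | int
    cluster_forming_p: float
    n_permutations: int
    seed: int | None
    null_max_mass: np.ndarray = field(repr=False, default=None)

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.01) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


def _pooled_t(sum1, sumsq1, n1, sum2, sumsq2, n2):
    """Vectorized two-sample pooled-variance t statistic."""
    m1, m2 = sum1 / n1, sum2 / n2
    ss1 = sumsq1 - n1 * m1**2
    ss2 = sumsq2 - n2 * m2**2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def _find_clusters(t: np.ndarray, threshold: float):
    """Runs of contiguous samples with |t| > threshold, as (start, stop, mass, sign)."""
    supra = np.abs(t) > threshold
    out = []
    i = 0
    n = t.shape[0]
    while i < n:
        if supra[i]:
            j = i
            sign = int(np.sign(t[i]))
            # split runs where the sign flips so each cluster is one-signed
            while j < n and supra[j] and int(np.sign(t[j])) == sign:
                j += 1
            out.append((i, j, float(np.sum(np.abs(t[i:j]))), sign))
            i = j
        else:
            i += 1
    return out


def cluster_permutation_test(
    epochs: EpochSet,
    channel: str | int = 0,
    conditions: Sequence[str] = ("oddball", "standard"),
    cluster_forming_p: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> ClusterTestResult:
    """Cluster-based permutation t-test between two conditions on one channel.

    Procedure: (1) pooled-variance two-sample t at every time sample;
    (2) contiguous one-signed runs with |t| above the two-sided threshold at
    *cluster_forming_p* become clusters with mass = sum of |t|; (3) condition
    labels are permuted *n_permutations* times and the maximal cluster mass
    of each permutation forms the null; (4) each observed cluster gets
    ``p = (1 + #{null >= mass}) / (n_permutations + 1)``.

    Observed clusters depend only on the data (permuting epoch order changes
    nothing); only the permutation draw uses the seed.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    ch = epochs.channel_index(channel)
    cond_a, cond_b = conditions
    xa = epochs.select(cond_a)[:, ch, :]
    xb = epochs.select(cond_b)[:, ch, :]
    n1, n2 = xa.shape[0], xb.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >= 2 epochs per condition, got {cond_a}: {n1}, {cond_b}: {n2}"
        )
    x = np.concatenate([xa, xb], axis=0)  # (n, T)
    xsq = x**2
    df = n1 + n2 - 2
    threshold = float(stats.t.ppf(1.0 - cluster_forming_p / 2.0, df))

    total_sum = x.sum(axis=0)
    total_sumsq = xsq.sum(axis=0)
    obs_sum1 = xa.sum(axis=0)
    obs_sumsq1 = (xa**2).sum(axis=0)
    t_obs = _pooled_t(
        obs_sum1, obs_sumsq1, n1, total_sum - obs_sum1, total_sumsq - obs_sumsq1, n2
    )
    observed = _find_clusters(t_obs, threshold)

    # Permutation null: boolean group-membership matrix times the data gives
    # all per-permutation group sums in two matmuls.
    rng = np.random.default_rng(seed)
    n = n1 + n2
    member = np.zeros((n_permutations, n), dtype=float)
    for p in range(n_permutations):
        member[p, rng.permutation(n)[:n1]] = 1.0
    sum1 = member @ x
    sumsq1 = member @ xsq
    t_null = _pooled_t(sum1, sumsq1, n1, total_sum - sum1, total_sumsq - sumsq1, n2)
    null_max = np.zeros(n_permutations)
    supra = np.abs(t_null) > threshold
    for p in np.flatnonzero(supra.any(axis=1)):
        runs = _find_clusters(t_null[p], threshold)
        null_max[p] = max(r[2] for r in runs)

    dt = 1.0 / epochs.fs
    clusters = [
        Cluster(
            start_s=float(epochs.times[i0]),
            end_s=float(epochs.times[j0 - 1] + dt),
            mass=mass,
            p_value=float((1 + np.sum(null_max >= mass)) / (n_permutations + 1)),
            sign=sign,
        )
        for i0, j0, mass, sign in observed
    ]
    return ClusterTestResult(
        clusters=clusters,
        t_values=t_obs,
        threshold=threshold,
        times=epochs.times,
        channel=channel if isinstance(channel, str) else ch,
        cluster_forming_p=cluster_forming_p,
        n_permutations=n_permutations,
        seed=seed,
        null_max_mass=null_max,
    )
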