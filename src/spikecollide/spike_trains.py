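"""Ground-truth spike-train generation and correlogram analysis.

Two generators are provided. ``generate_independent`` draws homogeneous
Poisson trains. ``generate_correlated`` implements a mixture process: a
shared mother Poisson process runs at rate ``r / c`` and each unit copies
every mother spike independently with probability ``c`` (the target
correlation level), jittering each copy with zero-mean Gaussian noise.
Each unit's marginal rate is then ``r``, the pairwise count correlation
equals ``c``, and the fraction of a unit's spikes shared with any other
unit is also ``c``. The Gaussian jitter gives the pairwise
cross-correlograms a Gaussian-shaped central excess. At ``c = 0`` the
construction degenerates to independent Poisson trains.

Both generators enforce a refractory period by a greedy time-order scan
that deletes any spike closer than the refractory period to the last kept
spike, and then compensate the rate loss by topping the train up with
additional independent spikes (re-pruned) until the empirical rate is
within 1% of nominal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigurationError, derive_rng

__all__ = [
    "SpikeTrainSet",
    "CorrelogramSet",
    "generate_independent",
    "generate_correlated",
    "prune_refractory",
    "compute_correlograms",
]


@dataclass
class SpikeTrainSet:
    """Per-unit sorted spike times in seconds over a fixed duration."""

    unit_ids: np.ndarray
    times: dict[int, np.ndarray]
    duration: float
    nominal_rate: float | None = None
    nominal_correlation: float | None = None

    def __post_init__(self):
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        self.times = {int(u): np.asarray(t, dtype=float) for u, t in self.times.items()}

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def n_spikes(self, unit: int) -> int:
        return len(self.times[int(unit)])

    def total_spikes(self) -> int:
        return sum(len(t) for t in self.times.values())

    def empirical_rates(self) -> dict[int, float]:
        return {int(u): len(self.times[int(u)]) / self.duration for u in self.unit_ids}

    def mean_rate(self) -> float:
        """Total spike count divided by (n_units * duration), in Hz."""
        return self.total_spikes() / (self.n_units * self.duration)

    def min_isi(self) -> float:
        isis = [np.diff(t) for t in self.times.values() if len(t) > 1]
        if not isis:
            return np.inf
        return float(min(i.min() for i in isis))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (int(u), float(t))
            for u in self.unit_ids
            for t in self.times[int(u)]
        ]
        return pd.DataFrame(rows, columns=["unit_id", "time_s"])

    def save(self, path: str | Path) -> None:
        """Write as a two-column CSV (unit_id, time_s) plus a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.9f")
        sidecar = {
            "duration_s": self.duration,
            "unit_ids": [int(u) for u in self.unit_ids],
            "nominal_rate_hz": self.nominal_rate,
            "nominal_correlation": self.nominal_correlation,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpikeTrainSet":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        unit_ids = np.asarray(meta["unit_ids"], dtype=int)
        times = {
            int(u): np.sort(df.loc[df["unit_id"] == u, "time_s"].to_numpy())
            for u in unit_ids
        }
        return cls(
            unit_ids=unit_ids,
            times=times,
            duration=float(meta["duration_s"]),
            nominal_rate=meta.get("nominal_rate_hz"),
            nominal_correlation=meta.get("nominal_correlation"),
        )


@dataclass
class CorrelogramSet:
    """Binned spike-time-difference histograms for all unit pairs.

    ``counts[i, j, l]`` counts differences t_j - t_i falling in lag bin l;
    the diagonal holds auto-correlograms with the zero-lag self pairs
    removed. Mirror symmetry holds exactly: counts[i, j, l] ==
    counts[j, i, n_bins - 1 - l].
    """

    unit_ids: np.ndarray
    counts: np.ndarray
    bin_edges_ms: np.ndarray
    bin_size_ms: float
    window_ms: float

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:]) / 2.0

    def pair(self, i: int, j: int) -> np.ndarray:
        idx = {int(u): k for k, u in enumerate(self.unit_ids)}
        return self.counts[idx[int(i)], idx[int(j)]]


# ---------------------------------------------------------------------------
# Refractory pruning
# ---------------------------------------------------------------------------

def prune_refractory(times: np.ndarray, refractory_ms: float) -> np.ndarray:
    """Greedy scan deleting spikes within the refractory period.

    Scanning in time order, a spike closer than ``refractory_ms`` to the
    last *kept* spike is deleted (the earlier spike of a violating pair is
    kept). Output times are a subset of the input and have minimum ISI >=
    the refractory period.
    """
    times = np.asarray(times, dtype=float)
    if len(times) <= 1 or refractory_ms <= 0:
        return times.copy()
    refr = refractory_ms / 1000.0
    keep = np.empty(len(times), dtype=bool)
    keep[0] = True
    last = times[0]
    for k in range(1, len(times)):
        if times[k] - last >= refr:
            keep[k] = True
            last = times[k]
        else:
            keep[k] = False
    return times[keep]


def _compensate_rate(
    times: np.ndarray,
    rate: float,
    duration: float,
    refractory_ms: float,
    rng: np.random.Generator,
    tol: float = 0.01,
    max_rounds: int = 5,
) -> np.ndarray:
    """Top a pruned train up with independent Poisson spikes until the
    empirical rate is within ``tol`` of nominal (re-pruning each round)."""
    for _ in range(max_rounds):
        deficit = rate - len(times) / duration
        if deficit <= tol * rate:
            break
        n_extra = rng.poisson(deficit * duration)
        if n_extra == 0:
            continue
        extra = rng.uniform(0.0, duration, n_extra)
        times = prune_refractory(np.sort(np.concatenate([times, extra])), refractory_ms)
    return times


def _check_feasible(rate: float, duration: float, refractory_ms: float) -> None:
    if rate <= 0 or duration < 0:
        raise ConfigurationError("rate must be > 0 and duration >= 0")
    if refractory_ms < 0:
        raise ConfigurationError("refractory period must be >= 0")
    if rate * refractory_ms / 1000.0 >= 1.0:
        raise ConfigurationError(
            "rate x refractory >= 1: the requested rate cannot be sustained"
        )


def generate_independent(
    n_units: int,
    rate: float,
    duration: float,
    refractory_ms: float = 4.0,
    seed: int = 0,
) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains with refractory pruning.

    Each unit is an independent Poisson process at ``rate`` Hz, pruned to
    the refractory period and rate-compensated so the empirical rate stays
    close to nominal. Deterministic under ``seed``.
    """
    _check_feasible(rate, duration, refractory_ms)
    if duration == 0:
        warnings.warn("zero duration: returning empty spike trains", stacklevel=2)
    times = {}
    for u in range(n_units):
        rng = derive_rng(seed, "indep", u)
        t = np.sort(rng.uniform(0.0, duration, rng.poisson(rate * duration)))
        t = prune_refractory(t, refractory_ms)
        t = _compensate_rate(t, rate, duration, refractory_ms, rng) if duration > 0 else t
        times[u] = t
    return SpikeTrainSet(
        unit_ids=np.arange(n_units),
        times=times,
        duration=float(duration),
        nominal_rate=float(rate),
        nominal_correlation=0.0,
    )


def generate_correlated(
    n_units: int,
    rate: float,
    correlation: float,
    jitter_sd_ms: float = 0.5,
    duration: float = 1800.0,
    refractory_ms: float = 4.0,
    seed: int = 0,
) -> SpikeTrainSet:
    """Correlated trains via a jittered mixture (mother) process.

    A mother Poisson process runs at ``rate / correlation``; each unit
    copies each mother spike independently with probability
    ``correlation`` and adds zero-mean Gaussian jitter (sd
    ``jitter_sd_ms``). Each train is then sorted, refractory-pruned and
    rate-compensated. The construction leaves every unit's marginal rate
    at ``rate`` while the pairwise count correlation — and the expected
    fraction of a unit's spikes shared with any other unit — equals
    ``correlation``. At ``correlation = 0`` it reduces to independent
    Poisson trains.
    """
    _check_feasible(rate, duration, refractory_ms)
    if not (0.0 <= correlation < 1.0):
        raise ConfigurationError("correlation must be in [0, 1)")
    if jitter_sd_ms <= 0:
        raise ConfigurationError("jitter_sd_ms must be positive")

    if correlation == 0.0:
        out = generate_independent(n_units, rate, duration, refractory_ms, seed)
        out.nominal_correlation = 0.0
        return out

    mother_rng = derive_rng(seed, "mother")
    mother_rate = rate / correlation
    mother = np.sort(
        mother_rng.uniform(0.0, duration, mother_rng.poisson(mother_rate * duration))
    )
    jitter_sd = jitter_sd_ms / 1000.0

    times = {}
    for u in range(n_units):
        rng = derive_rng(seed, "corr", u)
        copied = mother[rng.random(len(mother)) < correlation]
        t = copied + rng.normal(0.0, jitter_sd, len(copied))
        t = np.sort(t[(t >= 0.0) & (t <= duration)])
        t = prune_refractory(t, refractory_ms)
        t = _compensate_rate(t, rate, duration, refractory_ms, rng) if duration > 0 else t
        times[u] = t
    return SpikeTrainSet(
        unit_ids=np.arange(n_units),
        times=times,
        duration=float(duration),
        nominal_rate=float(rate),
        nominal_correlation=float(correlation),
    )


# ---------------------------------------------------------------------------
# Correlograms
# ---------------------------------------------------------------------------

def _pair_ccg(
    t_i: np.ndarray, t_j: np.ndarray, window: float, bin_size: float, n_bins: int,
    auto: bool,
) -> np.ndarray:
    """Histogram of differences t_j - t_i within +/- window (seconds)."""
    if len(t_i) == 0 or len(t_j) == 0:
        return np.zeros(n_bins, dtype=np.int64)
    lo = np.searchsorted(t_j, t_i - window, side="left")
    hi = np.searchsorted(t_j, t_i + window, side="right")
    reps = hi - lo
    total = int(reps.sum())
    if total == 0:
        return np.zeros(n_bins, dtype=np.int64)
    # flatten the per-spike partner ranges [lo[k], hi[k]) into index arrays
    cs = np.cumsum(reps)
    j_idx = np.repeat(lo, reps) + (np.arange(total) - np.repeat(cs - reps, reps))
    i_idx = np.repeat(np.arange(len(t_i)), reps)
    if auto:
        keep = j_idx != i_idx  # drop each spike paired with itself
        j_idx, i_idx = j_idx[keep], i_idx[keep]
    d = t_j[j_idx] - t_i[i_idx]
    b = np.clip(np.floor((d + window) / bin_size).astype(np.int64), 0, n_bins - 1)
    return np.bincount(b, minlength=n_bins).astype(np.int64)


def compute_correlograms(
    trains: SpikeTrainSet,
    bin_size_ms: float = 1.0,
    window_ms: float = 50.0,
) -> CorrelogramSet:
    """Cross- and auto-correlograms for all unit pairs.

    Counts differences t_j - t_i within +/- ``window_ms`` in bins of
    ``bin_size_ms`` (which must divide the full window span into an integer
    number of bins). The diagonal holds auto-correlograms excluding the
    zero-lag self pairs; a refractory-pruned train therefore shows empty
    bins for |lag| smaller than the refractory period. The lower triangle
    is the exact lag-mirror of the upper triangle.
    """
    if bin_size_ms <= 0 or window_ms <= 0:
        raise ConfigurationError("bin_size_ms and window_ms must be positive")
    n_bins_f = 2.0 * window_ms / bin_size_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ConfigurationError("bin_size must divide the 2*window span evenly")

    window = window_ms / 1000.0
    bin_size = bin_size_ms / 1000.0
    n = trains.n_units
    counts = np.zeros((n, n, n_bins), dtype=np.int64)
    ids = trains.unit_ids
    for a in range(n):
        t_a = trains.times[int(ids[a])]
        counts[a, a] = _pair_ccg(t_a, t_a, window, bin_size, n_bins, auto=True)
        for b in range(a + 1, n):
            t_b = trains.times[int(ids[b])]
            cab = _pair_ccg(t_a, t_b, window, bin_size, n_bins, auto=False)
            counts[a, b] = cab
            counts[b, a] = cab[::-1]
    edges = np.linspace(-window_ms, window_ms, n_bins + 1)
    return CorrelogramSet(
        unit_ids=ids.copy(),
        counts=counts,
        bin_edges_ms=edges,
        bin_size_ms=float(bin_size_ms),
        window_ms=float(window_ms),
    )
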