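"""Collision-specific performance metrics.

A *synchronous event* (spike collision) is a pair of spikes from two
distinct ground-truth units occurring within 2 ms of each other. Events
are binned by lag into 11 bins spanning [-2, 2] ms, and the *collision
recall* of a bin is the fraction of the collided ground-truth spikes in
that bin that the sorter recovered (labelled TP). Per-pair profiles can be
pooled by the cosine similarity of the pair's templates (event-weighted),
and integrated over lags to give a recall-versus-similarity curve.

A complementary, application-facing metric is the lag-wise relative error
between ground-truth cross-correlograms and those computed from the
matched sorted trains, averaged over matched pairs above a similarity
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ConfigurationError
from .gt_compare import MatchResult
from .probe_templates import SimilarityMatrix
from .spike_trains import SpikeTrainSet, _pair_ccg

__all__ = [
    "CollisionProfile",
    "CorrelogramErrorProfile",
    "find_synchronous_events",
    "collision_recall_by_lag",
    "pool_profiles_by_similarity",
    "collision_recall_by_similarity",
    "correlogram_relative_error",
    "DEFAULT_SYNCHRONY_WINDOW_MS",
    "DEFAULT_N_LAG_BINS",
    "DEFAULT_SIMILARITY_EDGES",
]

logger = logging.getLogger(__name__)

DEFAULT_SYNCHRONY_WINDOW_MS = 2.0
DEFAULT_N_LAG_BINS = 11
DEFAULT_SIMILARITY_EDGES = np.arange(-0.4, 1.01, 0.2)


@dataclass
class CollisionProfile:
    """Collision recall per lag bin for one pair (or one pooled group).

    ``n_tp`` and ``n_events`` count collided ground-truth spikes per lag
    bin (each synchronous event contributes both of its spikes, binned at
    the event's lag). Bins with no events are reported as NaN, never as a
    silent zero.
    """

    lag_bin_edges_ms: np.ndarray
    n_tp: np.ndarray
    n_events: np.ndarray
    label: object = None  # pair tuple or similarity-bin identifier

    @property
    def n_bins(self) -> int:
        return len(self.lag_bin_edges_ms) - 1

    @property
    def lag_bin_centers_ms(self) -> np.ndarray:
        return (self.lag_bin_edges_ms[:-1] + self.lag_bin_edges_ms[1:]) / 2.0

    @property
    def recall(self) -> np.ndarray:
        """Per-bin recall; NaN where the bin holds no events."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.n_tp / self.n_events
        return np.where(self.n_events > 0, r, np.nan)

    @property
    def is_empty(self) -> bool:
        return int(self.n_events.sum()) == 0

    def overall_recall(self) -> float:
        """Event-weighted recall integrated over all lag bins."""
        total = self.n_events.sum()
        return float(self.n_tp.sum() / total) if total > 0 else float("nan")

    def symmetrized(self) -> "CollisionProfile":
        """Average bins at +/- lag (the lag-sign convention is arbitrary)."""
        return CollisionProfile(
            lag_bin_edges_ms=self.lag_bin_edges_ms.copy(),
            n_tp=self.n_tp + self.n_tp[::-1],
            n_events=self.n_events + self.n_events[::-1],
            label=self.label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_ms": self.lag_bin_centers_ms,
            "recall": self.recall,
            "n_tp": self.n_tp,
            "n_events": self.n_events,
        })


@dataclass
class CorrelogramErrorProfile:
    """Mean relative cross-correlogram error per lag, over matched pairs."""

    lags_ms: np.ndarray
    mean_relative_error: np.ndarray
    n_pairs: int
    similarity_threshold: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lag_ms": self.lags_ms,
            "mean_relative_error": self.mean_relative_error,
        })


# ---------------------------------------------------------------------------
# Synchronous events
# ---------------------------------------------------------------------------

def find_synchronous_events(
    gt: SpikeTrainSet, window_ms: float = DEFAULT_SYNCHRONY_WINDOW_MS
) -> pd.DataFrame:
    """Detect all cross-unit spike pairs within ``window_ms`` (inclusive).

    Returns a DataFrame with one row per event: unit_i, unit_j (i < j in
    unit-id order), the spike indices and times on each side, and the lag
    ``t_j - t_i`` in ms. Same-unit pairs are excluded; every qualifying
    cross-unit pair is emitted exactly once.
    """
    if window_ms <= 0:
        raise ConfigurationError("window_ms must be positive")
    w = window_ms / 1000.0
    frames = []
    ids = sorted(int(u) for u in gt.unit_ids)
    for a_pos, i in enumerate(ids):
        t_i = gt.times[i]
        for j in ids[a_pos + 1:]:
            t_j = gt.times[j]
            if len(t_i) == 0 or len(t_j) == 0:
                continue
            lo = np.searchsorted(t_j, t_i - w, side="left")
            hi = np.searchsorted(t_j, t_i + w, side="right")
            reps = hi - lo
            total = int(reps.sum())
            if total == 0:
                continue
            cs = np.cumsum(reps)
            m = np.repeat(lo, reps) + (np.arange(total) - np.repeat(cs - reps, reps))
            k = np.repeat(np.arange(len(t_i)), reps)
            frames.append(pd.DataFrame({
                "unit_i": i, "unit_j": j, "index_i": k, "index_j": m,
                "time_i": t_i[k], "time_j": t_j[m],
                "lag_ms": (t_j[m] - t_i[k]) * 1000.0,
            }))
    cols = ["unit_i", "unit_j", "index_i", "index_j", "time_i", "time_j", "lag_ms"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def lag_bin_edges(
    n_bins: int = DEFAULT_N_LAG_BINS,
    window_ms: float = DEFAULT_SYNCHRONY_WINDOW_MS,
) -> np.ndarray:
    """Edges of the lag bins: ``n_bins`` equal bins spanning +/- window."""
    return np.linspace(-window_ms, window_ms, n_bins + 1)


def collision_recall_by_lag(
    events: pd.DataFrame,
    match: MatchResult,
    n_bins: int = DEFAULT_N_LAG_BINS,
    window_ms: float = DEFAULT_SYNCHRONY_WINDOW_MS,
) -> dict[tuple[int, int], CollisionProfile]:
    """Per-pair collision recall profiles over lag bins.

    Both spikes of every event contribute, each binned at the event's lag
    (sign convention: lag = t_j - t_i for the pair (i, j) with i < j). A
    collided ground-truth spike counts as recovered when the comparison
    labelled it TP. Pairs with zero events yield an empty, flagged profile.
    """
    edges = lag_bin_edges(n_bins, window_ms)
    profiles: dict[tuple[int, int], CollisionProfile] = {}
    if len(events) == 0:
        return profiles
    masks = match.gt_tp_masks
    for (i, j), ev in events.groupby(["unit_i", "unit_j"], sort=True):
        n_tp = np.zeros(n_bins, dtype=np.int64)
        n_ev = np.zeros(n_bins, dtype=np.int64)
        b = np.clip(
            np.digitize(ev["lag_ms"].to_numpy(), edges) - 1, 0, n_bins - 1
        )
        tp_i = masks[int(i)][ev["index_i"].to_numpy()]
        tp_j = masks[int(j)][ev["index_j"].to_numpy()]
        np.add.at(n_ev, b, 2)
        np.add.at(n_tp, b, tp_i.astype(np.int64) + tp_j.astype(np.int64))
        profiles[(int(i), int(j))] = CollisionProfile(
            lag_bin_edges_ms=edges, n_tp=n_tp, n_events=n_ev, label=(int(i), int(j))
        )
    return profiles


def pool_profiles_by_similarity(
    profiles: dict[tuple[int, int], CollisionProfile],
    similarity: SimilarityMatrix,
    similarity_edges: np.ndarray = DEFAULT_SIMILARITY_EDGES,
) -> dict[tuple[float, float], CollisionProfile]:
    """Pool per-pair profiles into similarity bins (event-weighted).

    Pooling sums TP and event counts per lag bin over all pairs whose
    template similarity falls in the bin, which is exactly the
    event-weighted average of the per-pair recalls. Empty similarity bins
    are omitted (and logged).
    """
    similarity_edges = np.asarray(similarity_edges, dtype=float)
    pooled: dict[tuple[float, float], CollisionProfile] = {}
    for k in range(len(similarity_edges) - 1):
        lo, hi = similarity_edges[k], similarity_edges[k + 1]
        members = [
            p for pair, p in profiles.items()
            if lo <= similarity[pair] < hi
            or (k == len(similarity_edges) - 2 and similarity[pair] == hi)
        ]
        if not members:
            logger.info("similarity bin [%.2f, %.2f) holds no pairs", lo, hi)
            continue
        edges = members[0].lag_bin_edges_ms
        pooled[(float(lo), float(hi))] = CollisionProfile(
            lag_bin_edges_ms=edges,
            n_tp=np.sum([p.n_tp for p in members], axis=0),
            n_events=np.sum([p.n_events for p in members], axis=0),
            label=(float(lo), float(hi)),
        )
    return pooled


def collision_recall_by_similarity(
    profiles: dict[tuple[int, int], CollisionProfile],
    similarity: SimilarityMatrix,
    similarity_edges: np.ndarray = DEFAULT_SIMILARITY_EDGES,
) -> pd.DataFrame:
    """Recall integrated over all lag bins, per similarity bin.

    The integration is event-weighted over the lag bins of the pooled
    profile, giving one recall value per populated similarity bin.
    """
    pooled = pool_profiles_by_similarity(profiles, similarity, similarity_edges)
    rows = [
        (lo, hi, (lo + hi) / 2.0, p.overall_recall(), int(p.n_events.sum()))
        for (lo, hi), p in pooled.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["sim_lo", "sim_hi", "sim_center", "recall", "n_events"],
    )


# ---------------------------------------------------------------------------
# Correlogram relative error
# ---------------------------------------------------------------------------

def correlogram_relative_error(
    gt: SpikeTrainSet,
    sorting: SpikeTrainSet,
    assignment: dict[int, int],
    similarity: SimilarityMatrix | None = None,
    sim_threshold: float = 0.5,
    bin_size_ms: float = 0.5,
    window_ms: float = 10.0,
) -> CorrelogramErrorProfile:
    """Lag-wise relative cross-correlogram error over matched pairs.

    For each ground-truth pair (i, j) with both units matched (and, if a
    similarity matrix is given, similarity above ``sim_threshold``), the
    cross-correlogram of the ground-truth trains and that of the matched
    sorted trains are compared bin by bin:

        error(l) = |ccg_gt(l) - ccg_sorted(l)| / mean(ccg_gt)

    normalising by the mean ground-truth count over the window to avoid
    division by near-empty bins. Errors are averaged over pairs; pairs with
    a zero baseline (no ground-truth coincidences in the window) are
    skipped and logged.
    """
    if not assignment:
        raise ConfigurationError("assignment is empty: run the comparison first")
    n_bins = int(round(2.0 * window_ms / bin_size_ms))
    if abs(2.0 * window_ms / bin_size_ms - n_bins) > 1e-9 or n_bins < 1:
        raise ConfigurationError("bin_size must divide the 2*window span evenly")
    w = window_ms / 1000.0
    b = bin_size_ms / 1000.0

    errors = []
    ids = sorted(int(u) for u in gt.unit_ids)
    for a_pos, i in enumerate(ids):
        for j in ids[a_pos + 1:]:
            if i not in assignment or j not in assignment:
                continue
            if similarity is not None and similarity[(i, j)] <= sim_threshold:
                continue
            ccg_gt = _pair_ccg(gt.times[i], gt.times[j], w, b, n_bins, auto=False)
            baseline = ccg_gt.mean()
            if baseline == 0:
                logger.info("pair (%d, %d): empty ground-truth CCG, skipped", i, j)
                continue
            ccg_s = _pair_ccg(
                sorting.times[assignment[i]], sorting.times[assignment[j]],
                w, b, n_bins, auto=False,
            )
            errors.append(np.abs(ccg_gt - ccg_s) / baseline)

    edges = np.linspace(-window_ms, window_ms, n_bins + 1)
    lags = (edges[:-1] + edges[1:]) / 2.0
    if errors:
        mean_err = np.mean(errors, axis=0)
    else:
        mean_err = np.full(n_bins, np.nan)
    return CorrelogramErrorProfile(
        lags_ms=lags,
        mean_relative_error=mean_err,
        n_pairs=len(errors),
        similarity_threshold=sim_threshold if similarity is not None else None,
    )
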