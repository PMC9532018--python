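"""Ground-truth comparison of sorting outputs.

The comparison follows the standard agreement-score pipeline: spikes of a
ground-truth train and a sorted train are matched one-to-one when their
times differ by at most a matching window delta (0.4 ms by default,
inclusive); the agreement score of a pair of units is the Jaccard-like
ratio

    score_ij = n_matches / (n_gt_i + n_sorted_j - n_matches)

computed for every (ground-truth, sorted) unit pair; a Hungarian
assignment then matches ground-truth to sorted units by maximising the
total agreement score, discarding zero-score assignments. For each
matched pair, spikes are labelled TP (matched on both sides), FN
(ground-truth only) or FP (sorted only), giving per-unit

    accuracy  = TP / (TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

and finally each sorted unit is classified as well detected, false
positive, redundant, overmerged, or other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._util import ConfigurationError
from .spike_trains import SpikeTrainSet

__all__ = [
    "AgreementMatrix",
    "MatchResult",
    "count_matches",
    "match_spikes",
    "agreement_scores",
    "hungarian_assign",
    "label_spikes",
    "unit_metrics",
    "classify_units",
    "compare_sorting",
    "DEFAULT_DELTA_MS",
]

logger = logging.getLogger(__name__)

DEFAULT_DELTA_MS = 0.4

UNIT_CLASSES = ("well_detected", "false_positive", "redundant", "overmerged", "other")


@dataclass
class AgreementMatrix:
    """Agreement scores between every (ground-truth, sorted) unit pair."""

    scores: pd.DataFrame          # index: gt unit ids, columns: sorted unit ids
    n_gt_spikes: pd.Series
    n_sorted_spikes: pd.Series
    delta_ms: float


@dataclass
class MatchResult:
    """Full outcome of a ground-truth comparison.

    ``gt_tp_masks`` holds, for every ground-truth unit, a boolean array
    aligned with its spike times marking which spikes were recovered (TP)
    by the assigned sorted unit; unmatched ground-truth units have all-False
    masks. Collision metrics consume these masks directly.
    """

    agreement: AgreementMatrix
    assignment: dict[int, int]            # gt unit -> sorted unit
    gt_tp_masks: dict[int, np.ndarray]
    sorted_tp_masks: dict[int, np.ndarray]
    metrics: pd.DataFrame                 # per gt unit: tp/fp/fn, accuracy/precision/recall
    unit_classes: dict[int, str]          # per sorted unit

    def to_dict(self) -> dict:
        return {
            "delta_ms": self.agreement.delta_ms,
            "assignment": {str(k): int(v) for k, v in self.assignment.items()},
            "unit_classes": {str(k): v for k, v in self.unit_classes.items()},
            "metrics": self.metrics.to_dict(orient="index"),
        }

    def spike_labels(self) -> pd.DataFrame:
        """Per-spike label table (side, unit_id, time_s, label)."""
        rows = []
        for u, mask in self.gt_tp_masks.items():
            for t, ok in zip(self._gt_times[u], mask):
                rows.append(("gt", u, t, "TP" if ok else "FN"))
        for u, mask in self.sorted_tp_masks.items():
            for t, ok in zip(self._sorted_times[u], mask):
                rows.append(("sorted", u, t, "TP" if ok else "FP"))
        return pd.DataFrame(rows, columns=["side", "unit_id", "time_s", "label"])

    # filled in by compare_sorting for label export
    _gt_times: dict[int, np.ndarray] = None          # type: ignore[assignment]
    _sorted_times: dict[int, np.ndarray] = None      # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Spike-level matching
# ---------------------------------------------------------------------------

def match_spikes(
    gt_train: np.ndarray, sorted_train: np.ndarray, delta_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Maximal one-to-one pairing of spikes within ``delta_ms`` (inclusive).

    Returns boolean masks (matched_gt, matched_sorted). Both inputs must be
    sorted. A two-pointer sweep is used: because the compatibility relation
    |t_gt - t_sorted| <= delta is an interval structure on sorted sequences,
    matching the earliest compatible pair first is optimal, so the sweep
    attains the maximum bipartite matching size.
    """
    if delta_ms <= 0:
        raise ConfigurationError("delta_ms must be positive")
    delta = delta_ms / 1000.0
    a = np.asarray(gt_train, dtype=float)
    b = np.asarray(sorted_train, dtype=float)
    ma = np.zeros(len(a), dtype=bool)
    mb = np.zeros(len(b), dtype=bool)
    i = j = 0
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if abs(d) <= delta:
            ma[i] = True
            mb[j] = True
            i += 1
            j += 1
        elif d > 0:
            j += 1
        else:
            i += 1
    return ma, mb


def count_matches(gt_train: np.ndarray, sorted_train: np.ndarray, delta_ms: float) -> int:
    """Size of the maximal one-to-one spike pairing within ``delta_ms``."""
    ma, _ = match_spikes(gt_train, sorted_train, delta_ms)
    return int(ma.sum())


def agreement_scores(
    gt: SpikeTrainSet, sorting: SpikeTrainSet, delta_ms: float = DEFAULT_DELTA_MS
) -> AgreementMatrix:
    """Agreement score matrix between all ground-truth and sorted units.

    score_ij = n_matches / (n_gt_i + n_sorted_j - n_matches); a pair of two
    empty trains scores 0 (logged).
    """
    scores = pd.DataFrame(
        0.0, index=pd.Index(gt.unit_ids, name="gt_unit"),
        columns=pd.Index(sorting.unit_ids, name="sorted_unit"),
    )
    for gi in gt.unit_ids:
        tg = gt.times[int(gi)]
        for sj in sorting.unit_ids:
            ts = sorting.times[int(sj)]
            denom = len(tg) + len(ts)
            if denom == 0:
                logger.info("both trains empty for pair (%s, %s); score := 0", gi, sj)
                continue
            m = count_matches(tg, ts, delta_ms)
            scores.loc[gi, sj] = m / (denom - m)
    return AgreementMatrix(
        scores=scores,
        n_gt_spikes=pd.Series({int(u): gt.n_spikes(u) for u in gt.unit_ids}),
        n_sorted_spikes=pd.Series({int(u): sorting.n_spikes(u) for u in sorting.unit_ids}),
        delta_ms=float(delta_ms),
    )


def hungarian_assign(agreement: AgreementMatrix) -> dict[int, int]:
    """One-to-one partial assignment maximising total agreement score.

    Pairs assigned with zero score are discarded, so units without any
    overlap remain unmatched.
    """
    s = agreement.scores.to_numpy(dtype=float)
    if s.size == 0:
        return {}
    rows, cols = linear_sum_assignment(-s)
    gt_ids = agreement.scores.index.to_numpy()
    sorted_ids = agreement.scores.columns.to_numpy()
    return {
        int(gt_ids[r]): int(sorted_ids[c])
        for r, c in zip(rows, cols)
        if s[r, c] > 0.0
    }


def label_spikes(
    gt_train: np.ndarray, sorted_train: np.ndarray, delta_ms: float = DEFAULT_DELTA_MS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spike TP masks for a matched pair of trains.

    Returns (gt_mask, sorted_mask): True marks TP spikes; False marks FN on
    the ground-truth side and FP on the sorted side.
    """
    return match_spikes(gt_train, sorted_train, delta_ms)


def unit_metrics(tp: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, precision and recall from spike label counts.

    All-zero denominators yield 0 with a warning rather than NaN.
    """
    out = {}
    for name, denom in (
        ("accuracy", tp + fp + fn),
        ("precision", tp + fp),
        ("recall", tp + fn),
    ):
        if denom == 0:
            warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=2)
            out[name] = 0.0
        else:
            out[name] = tp / denom
    return out


def classify_units(
    agreement: AgreementMatrix,
    assignment: dict[int, int],
    metrics: pd.DataFrame,
) -> dict[int, str]:
    """Classify each sorted unit.

    Rules, applied in order (first match wins):
      well detected  - assigned to a ground-truth unit with accuracy >= 0.8
                       (inclusive bound);
      false positive - unassigned and agreement score < 0.2 with every
                       ground-truth unit;
      redundant      - score >= 0.2 with some ground-truth unit but never
                       that unit's best match;
      overmerged     - score >= 0.2 with more than one ground-truth unit;
      other          - anything left (e.g. assigned with accuracy < 0.8).
    """
    s = agreement.scores
    inv = {v: k for k, v in assignment.items()}
    best_match = {}  # gt unit -> sorted unit with highest score
    for g in s.index:
        row = s.loc[g]
        if row.max() > 0:
            best_match[g] = row.idxmax()

    classes = {}
    for j in s.columns:
        col = s[j]
        n_above = int((col >= 0.2).sum())
        if j in inv and metrics.loc[inv[j], "accuracy"] >= 0.8:
            cls = "well_detected"
        elif j not in inv and (col.max() if len(col) else 0.0) < 0.2:
            cls = "false_positive"
        elif n_above >= 1 and all(best_match.get(g) != j for g in s.index[col >= 0.2]):
            cls = "redundant"
        elif n_above > 1:
            cls = "overmerged"
        else:
            cls = "other"
        classes[int(j)] = cls
    return classes


def compare_sorting(
    gt: SpikeTrainSet, sorting: SpikeTrainSet, delta_ms: float = DEFAULT_DELTA_MS
) -> MatchResult:
    """Run the full comparison pipeline and bundle the results.

    Ground-truth units left unassigned get zero metrics and an all-False
    TP mask (all their spikes count as missed).
    """
    agreement = agreement_scores(gt, sorting, delta_ms)
    assignment = hungarian_assign(agreement)

    gt_tp = {}
    sorted_tp = {int(u): np.zeros(sorting.n_spikes(u), dtype=bool) for u in sorting.unit_ids}
    rows = []
    for g in gt.unit_ids:
        g = int(g)
        tg = gt.times[g]
        if g in assignment:
            j = assignment[g]
            mg, ms = label_spikes(tg, sorting.times[j], delta_ms)
            gt_tp[g] = mg
            sorted_tp[j] = ms
            tp = int(mg.sum())
            fp = int((~ms).sum())
            fn = int((~mg).sum())
        else:
            gt_tp[g] = np.zeros(len(tg), dtype=bool)
            tp, fp, fn = 0, 0, len(tg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = unit_metrics(tp, fp, fn)
        rows.append((g, assignment.get(g), tp, fp, fn,
                     m["accuracy"], m["precision"], m["recall"]))

    metrics = pd.DataFrame(
        rows,
        columns=["gt_unit", "sorted_unit", "tp", "fp", "fn",
                 "accuracy", "precision", "recall"],
    ).set_index("gt_unit")

    classes = classify_units(agreement, assignment, metrics)
    result = MatchResult(
        agreement=agreement,
        assignment=assignment,
        gt_tp_masks=gt_tp,
        sorted_tp_masks=sorted_tp,
        metrics=metrics,
        unit_classes=classes,
    )
    result._gt_times = {int(u): gt.times[int(u)] for u in gt.unit_ids}
    result._sorted_times = {int(u): sorting.times[int(u)] for u in sorting.unit_ids}
    return result
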