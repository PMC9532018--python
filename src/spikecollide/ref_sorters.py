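"""Built-in reference sorters.

Three sorting procedures make the benchmark executable without any
external spike sorter:

* ``oracle_sorter`` — copies the ground truth (renumbered), giving perfect
  scores everywhere; the identity check for the whole comparison stack.
* ``degraded_oracle`` — the ground truth corrupted by a controlled
  degradation model (lag/similarity-dependent deletion of collided
  spikes, Gaussian time jitter, spurious spikes), used to verify that the
  collision metrics recover known failure probabilities.
* ``greedy_tm_sorter`` — a minimal template-matching sorter operating by
  iterative peeling: threshold detection on the residual traces, best
  (template, time, amplitude) fit per detected peak, subtraction, repeat.
  It receives the true templates (no clustering stage), so its failures
  isolate the collision-resolution behaviour of the matching step itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ._util import ConfigurationError, derive_rng
from .probe_templates import SimilarityMatrix, TemplateSet
from .recording import Recording, estimate_noise
from .spike_trains import SpikeTrainSet

__all__ = [
    "DegradationModel",
    "oracle_sorter",
    "degraded_oracle",
    "greedy_tm_sorter",
]


def oracle_sorter(gt: SpikeTrainSet) -> SpikeTrainSet:
    """Identity copy of the ground truth with fresh unit ids."""
    new_ids = np.arange(1000, 1000 + gt.n_units)
    times = {int(n): gt.times[int(o)].copy() for n, o in zip(new_ids, gt.unit_ids)}
    return SpikeTrainSet(unit_ids=new_ids, times=times, duration=gt.duration)


@dataclass
class DegradationModel:
    """Controlled corruption of a ground-truth sorting.

    ``p_drop`` is either a constant in [0, 1] or a callable
    ``p_drop(lag_ms, similarity) -> probability`` giving the deletion
    probability of a collided spike as a function of the event's lag and
    (optionally) the pair's template similarity. Surviving spikes are
    jittered with zero-mean Gaussian noise of sd ``jitter_sd_ms``;
    ``fp_rate_hz`` spurious spikes per second are injected per unit.
    """

    p_drop: float | Callable[[float, float | None], float] = 0.0
    jitter_sd_ms: float = 0.0
    fp_rate_hz: float = 0.0
    seed: int = 0

    def drop_probability(self, lag_ms: float, similarity: float | None) -> float:
        p = self.p_drop(lag_ms, similarity) if callable(self.p_drop) else self.p_drop
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(f"p_drop returned {p}, outside [0, 1]")
        return float(p)


def degraded_oracle(
    gt: SpikeTrainSet,
    events: pd.DataFrame,
    model: DegradationModel,
    similarity: SimilarityMatrix | None = None,
) -> SpikeTrainSet:
    """Corrupt the ground truth per the degradation model.

    Each ground-truth spike participating in at least one synchronous
    event is deleted with probability ``p_drop(lag, similarity)``; for a
    spike in several events, the event with the smallest absolute lag is
    used. Deterministic under the model's seed.
    """
    # smallest-|lag| event per (unit, spike index)
    per_spike: dict[tuple[int, int], tuple[float, float | None]] = {}
    for row in events.itertuples(index=False):
        sim = similarity[(row.unit_i, row.unit_j)] if similarity is not None else None
        for unit, idx in ((row.unit_i, row.index_i), (row.unit_j, row.index_j)):
            key = (int(unit), int(idx))
            if key not in per_spike or abs(row.lag_ms) < abs(per_spike[key][0]):
                per_spike[key] = (row.lag_ms, sim)

    new_ids = np.arange(1000, 1000 + gt.n_units)
    times = {}
    for new, old in zip(new_ids, gt.unit_ids):
        old = int(old)
        rng = derive_rng(model.seed, "degrade", old)
        t = gt.times[old]
        keep = np.ones(len(t), dtype=bool)
        for k in range(len(t)):
            hit = per_spike.get((old, k))
            if hit is not None:
                p = model.drop_probability(hit[0], hit[1])
                if rng.random() < p:
                    keep[k] = False
        out = t[keep]
        if model.jitter_sd_ms > 0:
            out = out + rng.normal(0.0, model.jitter_sd_ms / 1000.0, len(out))
        if model.fp_rate_hz > 0:
            n_fp = rng.poisson(model.fp_rate_hz * gt.duration)
            out = np.concatenate([out, rng.uniform(0.0, gt.duration, n_fp)])
        out = np.sort(out)
        times[int(new)] = out[(out >= 0.0) & (out <= gt.duration)]
    return SpikeTrainSet(unit_ids=new_ids, times=times, duration=gt.duration)


# ---------------------------------------------------------------------------
# Greedy template matching
# ---------------------------------------------------------------------------

def _detect_peaks(min_trace: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of local minima of the channel-wise minimum trace below
    -threshold."""
    below = min_trace < -threshold
    if not below.any():
        return np.empty(0, dtype=np.int64)
    idx = np.nonzero(below)[0]
    idx = idx[(idx > 0) & (idx < len(min_trace) - 1)]
    is_min = (min_trace[idx] <= min_trace[idx - 1]) & (min_trace[idx] <= min_trace[idx + 1])
    return idx[is_min]


def greedy_tm_sorter(
    recording: Recording,
    templates: TemplateSet,
    threshold: float = 5.0,
    max_passes: int = 6,
    jitter_samples: int = 2,
    amp_bounds: tuple[float, float] = (0.7, 1.3),
    amp_accept: tuple[float, float] = (0.5, 1.5),
    chunk_s: float = 10.0,
    exclusion_ms: float = 0.5,
) -> SpikeTrainSet:
    """Minimal greedy template-matching sorter with iterative peeling.

    Per chunk of traces: (1) detect negative peaks crossing ``threshold``
    noise-SD on the channel-minimum of the residual; (2) for every peak,
    fit all templates at time offsets within ``+/- jitter_samples`` by
    least squares, the amplitude clipped to ``amp_bounds``; a fit is
    acceptable when its unclipped amplitude lies in ``amp_accept`` and
    subtracting it reduces the residual squared norm; (3) accept fits
    greedily by residual reduction, enforcing a minimum separation of
    ``exclusion_ms`` within a pass (overlapping spikes are peeled on
    later passes, once the first waveform has been subtracted); (4)
    subtract and repeat up to ``max_passes`` times.

    The sorter is given the true templates — there is no clustering
    stage — so its errors isolate the collision-resolution behaviour of
    the matching procedure.
    """
    if templates.n_channels != recording.n_channels:
        raise ConfigurationError("template / recording channel count mismatch")
    fs = recording.sampling_rate
    n_t = templates.n_samples
    n_units = templates.n_units
    peak = templates.peak_sample()
    wf = templates.waveforms.astype(np.float32)
    norms2 = (wf.reshape(n_units, -1) ** 2).sum(axis=1)

    noise_sd = estimate_noise(recording)
    # floor keeps the detection threshold meaningful on noiseless traces
    thr = threshold * max(float(np.median(noise_sd)), 1e-3)

    offsets = np.arange(-jitter_samples, jitter_samples + 1)
    exclusion = max(1, int(round(exclusion_ms / 1000.0 * fs)))
    chunk_len = max(n_t * 4, int(round(chunk_s * fs)))
    margin = n_t  # overlap so spikes at chunk borders are fit with full context

    found_t: list[np.ndarray] = []
    found_u: list[np.ndarray] = []
    n_samples = recording.n_samples
    for c0 in range(0, n_samples, chunk_len):
        c1 = min(c0 + chunk_len, n_samples)
        lo = max(0, c0 - margin)
        hi = min(n_samples, c1 + margin)
        residual = np.array(recording.traces[lo:hi], dtype=np.float32)
        spikes_t, spikes_u = _peel_chunk(
            residual, wf, norms2, peak, thr, offsets, exclusion,
            max_passes, amp_bounds, amp_accept,
        )
        keep = (spikes_t + lo >= c0) & (spikes_t + lo < c1)
        found_t.append(spikes_t[keep] + lo)
        found_u.append(spikes_u[keep])

    all_t = np.concatenate(found_t) if found_t else np.empty(0, dtype=np.int64)
    all_u = np.concatenate(found_u) if found_u else np.empty(0, dtype=np.int64)
    times = {}
    new_ids = np.arange(2000, 2000 + n_units)
    for k, new in enumerate(new_ids):
        sel = all_u == k
        times[int(new)] = np.sort(all_t[sel] / fs)
    return SpikeTrainSet(unit_ids=new_ids, times=times, duration=recording.duration)


def _peel_chunk(
    residual: np.ndarray,
    wf: np.ndarray,
    norms2: np.ndarray,
    peak: np.ndarray,
    thr: float,
    offsets: np.ndarray,
    exclusion: int,
    max_passes: int,
    amp_bounds: tuple[float, float],
    amp_accept: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative peeling on one residual block; returns (peak samples, unit rows)."""
    n_units, n_t, n_ch = wf.shape
    n = residual.shape[0]
    n_off = len(offsets)
    pk_max = int(peak.max())
    pk_min = int(peak.min())
    # snippet long enough to hold any template at any offset, trough on the
    # candidate sample: length = template span + jitter span + trough spread
    snip_len = n_t + int(offsets[-1] - offsets[0]) + (pk_max - pk_min)

    # fit bank: template u at offset oi embedded in a zero snippet, so all
    # inner products reduce to one (ncand, snip_len*n_ch) @ bank.T matmul
    bank = np.zeros((n_off * n_units, snip_len, n_ch), dtype=np.float32)
    for oi in range(n_off):
        for u in range(n_units):
            q = (pk_max - int(peak[u])) + int(offsets[oi] - offsets[0])
            bank[oi * n_units + u, q:q + n_t] = wf[u]
    bank_flat = bank.reshape(n_off * n_units, -1)
    norms2_tiled = np.tile(norms2, n_off)

    out_t: list[int] = []
    out_u: list[int] = []
    for _ in range(max_passes):
        cands = _detect_peaks(residual.min(axis=1), thr)
        w0s = cands + int(offsets[0]) - pk_max
        valid = (w0s >= 0) & (w0s + snip_len <= n)
        cands, w0s = cands[valid], w0s[valid]
        if len(cands) == 0:
            break
        # gather snippets: (ncand, snip_len, n_ch)
        snips = residual[w0s[:, None] + np.arange(snip_len)[None, :]]
        dots = snips.reshape(len(cands), -1) @ bank_flat.T  # (ncand, noff*nunits)
        amp = dots / norms2_tiled[None, :]
        amp_c = np.clip(amp, *amp_bounds)
        red = 2.0 * amp_c * dots - amp_c ** 2 * norms2_tiled[None, :]
        red[(amp < amp_accept[0]) | (amp > amp_accept[1])] = -np.inf
        flat_best = np.argmax(red, axis=1)
        rows = np.arange(len(cands))
        best_red = red[rows, flat_best]
        best_amp = amp_c[rows, flat_best]
        best_off = offsets[flat_best // n_units]
        best_tmp = flat_best % n_units

        ok = np.nonzero(best_red > 0)[0]
        if len(ok) == 0:
            break
        order = ok[np.argsort(-best_red[ok])]
        occupied = np.zeros(n, dtype=bool)
        n_accepted = 0
        for ci in order:
            t_fit = int(cands[ci] + best_off[ci])
            lo = max(0, t_fit - exclusion + 1)
            if occupied[lo:t_fit + exclusion].any():
                continue
            u = int(best_tmp[ci])
            s = t_fit - int(peak[u])
            if s < 0 or s + n_t > n:
                continue
            residual[s:s + n_t] -= np.float32(best_amp[ci]) * wf[u]
            occupied[t_fit] = True
            out_t.append(t_fit)
            out_u.append(u)
            n_accepted += 1
        if n_accepted == 0:
            break
    return np.asarray(out_t, dtype=np.int64), np.asarray(out_u, dtype=np.int64)
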