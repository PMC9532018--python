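"""Assembly and I/O of continuous extracellular traces.

A recording is built by linear superposition: for every ground-truth
spike, the unit's template — scaled by a per-spike multiplicative
amplitude-modulation factor (Gaussian around 1, truncated) — is added to
the traces with its negative trough aligned to the nearest sample, and
i.i.d. Gaussian noise is added to every sample of every channel. Traces
are generated chunk by chunk so that half-hour recordings never need to
fit in memory at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import median_abs_deviation

from ._util import ConfigurationError, derive_rng
from .probe_templates import ProbeLayout, TemplateSet
from .spike_trains import SpikeTrainSet

__all__ = ["Recording", "assemble_recording", "estimate_noise"]

DEFAULT_CHUNK_S = 10.0


@dataclass
class Recording:
    """Continuous multi-channel traces in microvolts.

    ``traces`` is (n_samples, n_channels) float32. ``provenance`` records
    the seeds and generation parameters used to build the recording.
    """

    traces: np.ndarray
    sampling_rate: float
    probe: ProbeLayout | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.traces.shape[0]

    @property
    def n_channels(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def save(self, path: str | Path) -> None:
        """Write flat float32 binary (sample-major) plus a JSON sidecar.

        If the traces are already a memmap backed by ``path`` (chunked
        assembly straight to disk), only the sidecar is written.
        """
        path = Path(path)
        backing = getattr(self.traces, "filename", None)
        if backing is not None and Path(backing).resolve() == path.resolve():
            self.traces.flush()
        else:
            np.ascontiguousarray(self.traces, dtype=np.float32).tofile(path)
        sidecar = {
            "sampling_rate": self.sampling_rate,
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
            "dtype": "float32",
            "order": "sample_major",
            "units": "uV",
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path, probe: ProbeLayout | None = None) -> "Recording":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        traces = np.fromfile(path, dtype=np.float32).reshape(
            meta["n_samples"], meta["n_channels"]
        )
        return cls(
            traces=traces,
            sampling_rate=float(meta["sampling_rate"]),
            probe=probe,
            provenance=meta.get("provenance", {}),
        )


def assemble_recording(
    templates: TemplateSet,
    trains: SpikeTrainSet,
    noise_sd: float = 5.0,
    amp_mod_sd: float = 0.05,
    amp_mod_bounds: tuple[float, float] = (0.7, 1.3),
    seed: int = 0,
    chunk_s: float = DEFAULT_CHUNK_S,
    probe: ProbeLayout | None = None,
    out_path: str | Path | None = None,
) -> Recording:
    """Superpose spike waveforms on Gaussian noise.

    Every spike inserts its unit's template scaled by an i.i.d. modulation
    factor drawn from N(1, amp_mod_sd) truncated to ``amp_mod_bounds``,
    with the template trough at the sample nearest the spike time
    (templates running past either end of the recording are truncated).
    Uncorrelated Gaussian noise with standard deviation ``noise_sd`` uV is
    added per sample per channel. Identical inputs and seed give
    bit-identical traces for a fixed chunk size.

    With ``out_path`` the traces are written chunk by chunk to a float32
    memmap instead of held in RAM, so half-hour, 32-channel recordings
    (about 7 GB) can be assembled on a desktop.
    """
    if noise_sd < 0 or amp_mod_sd < 0:
        raise ConfigurationError("noise_sd and amp_mod_sd must be >= 0")
    missing = set(int(u) for u in trains.unit_ids) - set(int(u) for u in templates.unit_ids)
    if missing:
        raise ConfigurationError(f"trains reference unknown template unit ids {sorted(missing)}")

    fs = templates.sampling_rate
    n_samples = int(round(trains.duration * fs))
    n_channels = templates.n_channels
    n_t = templates.n_samples
    peak = templates.peak_sample()
    unit_index = {int(u): k for k, u in enumerate(templates.unit_ids)}

    # Per-spike insertion plan: (start_sample, unit_row, modulation)
    mod_rng = derive_rng(seed, "ampmod")
    inserts = []
    lo, hi = amp_mod_bounds
    for u in trains.unit_ids:
        u = int(u)
        t = trains.times[u]
        row = unit_index[u]
        samples = np.round(t * fs).astype(np.int64)
        if amp_mod_sd > 0:
            mods = np.clip(mod_rng.normal(1.0, amp_mod_sd, len(t)), lo, hi)
        else:
            mods = np.ones(len(t))
        starts = samples - peak[row]
        inserts.append((starts, np.full(len(t), row), mods))
    if inserts:
        starts = np.concatenate([x[0] for x in inserts])
        rows = np.concatenate([x[1] for x in inserts])
        mods = np.concatenate([x[2] for x in inserts])
    else:
        starts = np.empty(0, dtype=np.int64)
        rows = np.empty(0, dtype=np.int64)
        mods = np.empty(0)

    noise_rng = derive_rng(seed, "noise")
    chunk_len = max(1, int(round(chunk_s * fs)))
    if out_path is not None:
        traces = np.memmap(out_path, dtype=np.float32, mode="w+",
                           shape=(n_samples, n_channels))
        traces[:] = 0.0
    else:
        traces = np.zeros((n_samples, n_channels), dtype=np.float32)
    wf32 = templates.waveforms.astype(np.float32)

    for c0 in range(0, n_samples, chunk_len):
        c1 = min(c0 + chunk_len, n_samples)
        block = traces[c0:c1]
        if noise_sd > 0:
            block += noise_rng.normal(0.0, noise_sd, block.shape).astype(np.float32)
        sel = np.nonzero((starts < c1) & (starts + n_t > c0))[0]
        for k in sel:
            s = int(starts[k])
            w0 = max(0, c0 - s)
            w1 = min(n_t, c1 - s)
            if w1 <= w0:
                continue
            a = s + w0 - c0
            if s + w0 < 0:  # truncated at recording start
                w0 = -s
                a = 0
                if w1 <= w0:
                    continue
            block[a:a + (w1 - w0)] += mods[k] * wf32[int(rows[k]), w0:w1]

    return Recording(
        traces=traces,
        sampling_rate=fs,
        probe=probe,
        provenance={
            "seed": int(seed),
            "noise_sd_uv": float(noise_sd),
            "amp_mod_sd": float(amp_mod_sd),
            "amp_mod_bounds": [float(lo), float(hi)],
            "chunk_s": float(chunk_s),
            "n_units": int(trains.n_units),
            "duration_s": float(trains.duration),
        },
    )


def estimate_noise(recording: Recording) -> np.ndarray:
    """Robust per-channel noise SD in uV via the scaled MAD.

    The median absolute deviation scaled to the Gaussian SD is insensitive
    to the sparse, large-amplitude spike waveforms riding on the noise.
    """
    if recording.duration < 1.0:
        raise ConfigurationError("need at least 1 s of data for a noise estimate")
    # 10 s is ample for a stable MAD; avoids scanning half-hour recordings.
    n = min(recording.n_samples, int(10 * recording.sampling_rate))
    return median_abs_deviation(
        recording.traces[:n].astype(np.float64), axis=0, scale="normal"
    )
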