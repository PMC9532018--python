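"""Probe geometry and parametric extracellular templates.

The probe is a multi-column layout with hexagonal (staggered) packing, the
default being a 32-channel, 3-column array with 18 um x-pitch and 22 um
y-pitch. Templates are parametric spatiotemporal waveforms: a biphasic
temporal kernel (sharp negative lobe followed by a slower positive
after-wave) attenuated over the probe by a Lorentzian distance decay from the
unit's soma, plus a weaker positive-polarity return-current lobe displaced
along a dendritic axis. The return lobe is what makes negative pairwise
cosine similarities achievable: when one unit's soma sits near another
unit's dendrite, the two units drive overlapping channels with opposite
polarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from ._util import ConfigurationError, ZeroNormError, derive_rng

__all__ = [
    "ProbeLayout",
    "TemplateSet",
    "SimilarityMatrix",
    "make_probe",
    "synthesize_templates",
    "cosine_similarity",
    "template_barycenter",
]


# ---------------------------------------------------------------------------
# Probe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeLayout:
    """A planar multi-column probe with staggered (hexagonal) channel rows.

    Attributes
    ----------
    channel_ids : ndarray of int
        Channel identifiers, one per electrode.
    positions : ndarray, shape (n_channels, 2)
        (x, y) channel positions in micrometres.
    pitch_x, pitch_y : float
        Column spacing and within-column row spacing, micrometres.
    n_columns : int
        Number of columns.
    """

    channel_ids: np.ndarray
    positions: np.ndarray
    pitch_x: float
    pitch_y: float
    n_columns: int

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def to_dict(self) -> dict:
        return {
            "channel_ids": [int(c) for c in self.channel_ids],
            "positions_um": [[float(x), float(y)] for x, y in self.positions],
            "pitch": {"x_um": float(self.pitch_x), "y_um": float(self.pitch_y)},
            "n_columns": int(self.n_columns),
        }

    def save(self, path: str | Path) -> None:
        """Write the layout as PRB-style JSON."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ProbeLayout":
        d = json.loads(Path(path).read_text())
        return cls(
            channel_ids=np.asarray(d["channel_ids"], dtype=int),
            positions=np.asarray(d["positions_um"], dtype=float),
            pitch_x=float(d["pitch"]["x_um"]),
            pitch_y=float(d["pitch"]["y_um"]),
            n_columns=int(d["n_columns"]),
        )


def make_probe(
    n_channels: int = 32,
    n_columns: int = 3,
    pitch_x: float = 18.0,
    pitch_y: float = 22.0,
) -> ProbeLayout:
    """Build a staggered multi-column probe layout.

    Channels are distributed over ``n_columns`` columns as evenly as possible
    (column sizes differ by at most one; leftover channels go to the leading
    columns). Column ``c`` sits at ``x = c * pitch_x``; rows within a column
    are ``pitch_y`` apart, and odd columns are shifted by ``pitch_y / 2`` to
    produce the hexagonal arrangement. The default call reproduces the
    32-channel, 3-column layout with 18/22 um pitch.
    """
    if n_channels < 1 or n_columns < 1:
        raise ConfigurationError("n_channels and n_columns must be positive")
    if pitch_x <= 0 or pitch_y <= 0:
        raise ConfigurationError("pitches must be positive")
    if n_columns > n_channels:
        raise ConfigurationError("more columns than channels")

    base, extra = divmod(n_channels, n_columns)
    col_sizes = [base + (1 if c < extra else 0) for c in range(n_columns)]

    xs, ys = [], []
    for c, size in enumerate(col_sizes):
        offset = (pitch_y / 2.0) if (c % 2 == 1) else 0.0
        for r in range(size):
            xs.append(c * pitch_x)
            ys.append(r * pitch_y + offset)
    positions = np.column_stack([xs, ys]).astype(float)
    return ProbeLayout(
        channel_ids=np.arange(n_channels),
        positions=positions,
        pitch_x=float(pitch_x),
        pitch_y=float(pitch_y),
        n_columns=int(n_columns),
    )


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass
class TemplateSet:
    """Per-unit spatiotemporal waveforms in microvolts.

    ``waveforms`` has shape (n_units, n_samples, n_channels); flattening a
    template concatenates the channel traces. ``unit_positions`` holds the
    (x, y, z) soma position of each unit in micrometres, z being the
    perpendicular distance from the probe plane.
    """

    waveforms: np.ndarray
    sampling_rate: float
    unit_positions: np.ndarray
    unit_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.waveforms = np.asarray(self.waveforms, dtype=np.float64)
        if self.waveforms.ndim != 3:
            raise ConfigurationError("waveforms must be (units, samples, channels)")
        if not np.all(np.isfinite(self.waveforms)):
            raise ConfigurationError("waveforms must be finite")
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.waveforms.shape[0])
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)

    @property
    def n_units(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    @property
    def n_channels(self) -> int:
        return self.waveforms.shape[2]

    def peak_sample(self) -> np.ndarray:
        """Sample index of the global negative peak per unit."""
        flat = self.waveforms.reshape(self.n_units, -1)
        return np.argmin(flat, axis=1) // self.n_channels

    def peak_channel(self) -> np.ndarray:
        """Channel carrying the largest absolute amplitude per unit."""
        return np.argmax(np.abs(self.waveforms).max(axis=1), axis=1)

    def peak_amplitude(self) -> np.ndarray:
        """Largest absolute amplitude per unit (uV), across all channels."""
        return np.abs(self.waveforms).max(axis=(1, 2))

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("waveforms", data=self.waveforms)
            f.create_dataset("unit_positions", data=self.unit_positions)
            f.create_dataset("unit_ids", data=self.unit_ids)
            f.attrs["sampling_rate_hz"] = self.sampling_rate
            f.attrs["units"] = "uV"

    @classmethod
    def load(cls, path: str | Path) -> "TemplateSet":
        with h5py.File(path, "r") as f:
            return cls(
                waveforms=f["waveforms"][()],
                sampling_rate=float(f.attrs["sampling_rate_hz"]),
                unit_positions=f["unit_positions"][()],
                unit_ids=f["unit_ids"][()],
            )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise cosine similarity between flattened templates, in [-1, 1]."""

    values: np.ndarray
    unit_ids: np.ndarray

    def __getitem__(self, pair):
        i, j = pair
        idx = {u: k for k, u in enumerate(self.unit_ids)}
        return float(self.values[idx[i], idx[j]])


def _temporal_kernel(t_ms: np.ndarray, sigma_neg: float, sigma_pos: float,
                     delay_pos: float, rel_pos: float, t_peak: float) -> np.ndarray:
    """Biphasic kernel: sharp negative Gaussian plus slower positive after-wave.

    Normalised so the negative trough equals -1.
    """
    k = -np.exp(-0.5 * ((t_ms - t_peak) / sigma_neg) ** 2)
    k = k + rel_pos * np.exp(-0.5 * ((t_ms - t_peak - delay_pos) / sigma_pos) ** 2)
    return k / np.abs(k.min())


def _spatial_decay(dist_um: np.ndarray, decay_um: float) -> np.ndarray:
    return 1.0 / (1.0 + (dist_um / decay_um) ** 2)


def synthesize_templates(
    probe: ProbeLayout,
    n_units: int = 20,
    amplitude_range: tuple[float, float] = (30.0, 200.0),
    duration_ms: float = 5.0,
    seed: int = 0,
    sampling_rate: float = 32000.0,
    decay_um: float = 30.0,
    z_range: tuple[float, float] = (10.0, 60.0),
    min_peak_uv: float = 30.0,
    similarity_span: tuple[float, float] = (-0.2, 0.8),
    max_unit_attempts: int = 100,
    max_set_attempts: int = 60,
) -> TemplateSet:
    """Draw a set of parametric templates for units placed near the probe.

    Each unit is given a biphasic temporal kernel, a soma position in a
    margin around the probe with perpendicular offset z, a peak amplitude
    drawn uniformly from ``amplitude_range``, and a positive-polarity
    dendritic return lobe displaced in the probe plane. A unit whose
    peak-channel amplitude falls below ``min_peak_uv`` is re-drawn (up to
    ``max_unit_attempts`` times). The whole placement is resampled until the
    pairwise cosine similarities span at least ``similarity_span``, so the
    similarity axis used by the collision analysis is populated on both the
    negative and the high-similarity side; if no draw achieves the span
    within ``max_set_attempts``, the widest-spanning draw is returned with a
    warning.

    The same seed always returns a bit-identical TemplateSet.
    """
    if n_units < 1:
        raise ConfigurationError("n_units must be >= 1")
    if duration_ms <= 0:
        raise ConfigurationError("duration_ms must be positive")
    lo, hi = amplitude_range
    if lo > hi:
        raise ConfigurationError("amplitude_range is inverted")

    n_samples = int(round(duration_ms * sampling_rate / 1000.0))
    t_ms = np.arange(n_samples) / sampling_rate * 1000.0
    t_peak = duration_ms / 3.0

    chan_pos = np.column_stack([probe.positions, np.zeros(probe.n_channels)])
    x_lo, x_hi = probe.positions[:, 0].min() - 30.0, probe.positions[:, 0].max() + 30.0
    y_lo, y_hi = probe.positions[:, 1].min() - 20.0, probe.positions[:, 1].max() + 20.0

    best: TemplateSet | None = None
    best_span = -np.inf
    for attempt in range(max_set_attempts):
        rng = derive_rng(seed, "templates", attempt)
        waveforms = np.zeros((n_units, n_samples, probe.n_channels))
        positions = np.zeros((n_units, 3))
        for u in range(n_units):
            for _ in range(max_unit_attempts):
                soma = np.array([
                    rng.uniform(x_lo, x_hi),
                    rng.uniform(y_lo, y_hi),
                    rng.uniform(*z_range),
                ])
                amp = rng.uniform(lo, hi)
                kernel = _temporal_kernel(
                    t_ms,
                    sigma_neg=rng.uniform(0.15, 0.25),
                    sigma_pos=rng.uniform(0.6, 0.9),
                    delay_pos=rng.uniform(0.6, 0.9),
                    rel_pos=rng.uniform(0.30, 0.45),
                    t_peak=t_peak,
                )
                # dendritic axis in the probe plane
                theta = rng.uniform(0, 2 * np.pi)
                dend = soma + rng.uniform(40.0, 90.0) * np.array(
                    [np.cos(theta), np.sin(theta), 0.0]
                )
                rel_return = rng.uniform(0.35, 0.6)

                d_soma = np.linalg.norm(chan_pos - soma, axis=1)
                d_dend = np.linalg.norm(chan_pos - dend, axis=1)
                spatial_main = amp * _spatial_decay(d_soma, decay_um)
                spatial_ret = rel_return * amp * _spatial_decay(d_dend, 1.5 * decay_um)
                wave = (
                    kernel[:, None] * spatial_main[None, :]
                    - kernel[:, None] * spatial_ret[None, :]
                )
                if np.abs(wave).max() >= min_peak_uv:
                    waveforms[u] = wave
                    positions[u] = soma
                    break
            else:
                raise ConfigurationError(
                    "could not place a unit satisfying the amplitude floor"
                )
        ts = TemplateSet(waveforms, sampling_rate, positions)
        if n_units < 2:
            return ts
        sim = cosine_similarity(ts).values
        off = sim[~np.eye(n_units, dtype=bool)]
        span = off.max() - off.min()
        if off.min() <= similarity_span[0] and off.max() >= similarity_span[1]:
            return ts
        if span > best_span:
            best_span, best = span, ts

    warnings.warn(
        "template placement did not reach the requested similarity span; "
        "returning the widest draw",
        stacklevel=2,
    )
    return best  # type: ignore[return-value]


def cosine_similarity(templates: TemplateSet) -> SimilarityMatrix:
    """Pairwise cosine similarity of flattened templates.

    Entry (i, j) is the cosine of the angle between the flattened waveforms
    of units i and j: dot(T_i, T_j) / (||T_i|| ||T_j||). The matrix is
    symmetric with unit diagonal, bounded in [-1, 1]: -1 for anti-parallel
    templates, 0 for orthogonal (e.g. disjoint channel support), 1 for
    parallel ones.
    """
    if templates.n_units < 1:
        raise ConfigurationError("need at least one unit")
    flat = templates.waveforms.reshape(templates.n_units, -1)
    norms = np.linalg.norm(flat, axis=1)
    if np.any(norms == 0):
        bad = templates.unit_ids[norms == 0].tolist()
        raise ZeroNormError(f"zero-norm template(s) for unit(s) {bad}")
    unit = flat / norms[:, None]
    values = np.clip(unit @ unit.T, -1.0, 1.0)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, unit_ids=templates.unit_ids.copy())


def template_barycenter(templates: TemplateSet, probe: ProbeLayout) -> np.ndarray:
    """Estimate each unit's (x, y) position as an amplitude-weighted barycenter.

    Channel positions are weighted by the per-channel peak absolute
    amplitude of the unit's template, with weights normalised to sum to 1.
    """
    if probe.n_channels != templates.n_channels:
        raise ConfigurationError("probe / template channel count mismatch")
    weights = np.abs(templates.waveforms).max(axis=1)  # (units, channels)
    totals = weights.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ZeroNormError("all-zero template has no barycenter")
    weights = weights / totals
    return weights @ probe.positions
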