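"""Pairwise functional-connectivity measures: Pearson correlation and PLV.

Correlation captures amplitude co-variation,

    Cor(i, j) = Cov(i, j) / sqrt(Var(i) Var(j)),

while the phase-locking value captures phase synchrony of two narrowband
signals irrespective of amplitude,

    PLV(i, j) = | (1/L) * sum_t exp(j * (phi_i(t) - phi_j(t))) |,

with phi the instantaneous (Hilbert/analytic-signal) phase and L the
number of phase samples averaged. The modulus makes PLV real in [0, 1]:
1 for a constant phase offset, ~1/sqrt(L) for independent phases.

The analytic signal is distorted near segment ends, so a fixed fraction
of samples is trimmed from both ends of each phase series before the
phasor average; the trimmed L is recorded on the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocessing import Band, BandEpoch

#: Fraction of samples discarded at each end of a phase series.
EDGE_TRIM_FRACTION = 0.05


class UndefinedFeatureError(ValueError):
    """A connectivity value is mathematically undefined for this input
    (zero-variance channel, all-zero signal)."""


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise UndefinedFeatureError("correlation undefined for constant input")
    return float(np.clip((xc @ yc) / np.sqrt(vx * vy), -1.0, 1.0))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, in (-pi, pi].

    Meaningful only for narrowband input; callers should trim the ends
    (see :data:`EDGE_TRIM_FRACTION`) before averaging phases.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 16:
        raise ValueError("need at least 16 samples for a usable analytic signal")
    if not np.any(x):
        raise UndefinedFeatureError("phase undefined for all-zero signal")
    return np.angle(hilbert(x, axis=-1))


def _trim(n: int, fraction: float = EDGE_TRIM_FRACTION) -> slice:
    k = int(np.floor(n * fraction))
    return slice(k, n - k)


def plv(x: np.ndarray, y: np.ndarray, *, trim: float = EDGE_TRIM_FRACTION) -> float:
    """Phase-locking value of two narrowband signals in the same band."""
    px = instantaneous_phase(x)
    py = instantaneous_phase(y)
    if px.shape != py.shape:
        raise ValueError("inputs must have equal length")
    sl = _trim(px.shape[-1], trim)
    return float(np.abs(np.mean(np.exp(1j * (px[sl] - py[sl])))))


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise connectivity over the epoch's channels.

    ``channel_index`` preserves (label, hemisphere) tags so that the
    10 x 10 left x right inter-hemispheric block can be recovered.
    """

    method: str  # "correlation" | "plv"
    band: Band
    state: str
    subject_id: str
    group: str
    epoch_index: int
    matrix: np.ndarray
    channel_index: list[tuple[str, str]]
    n_phase_samples: int | None = None  # trimmed L entering the PLV average

    def hemisphere_rows(self, side: str) -> np.ndarray:
        return np.array(
            [i for i, (_, h) in enumerate(self.channel_index) if h == side], dtype=int
        )

    def interhemispheric_block(self) -> np.ndarray:
        """The left x right rectangle of pairwise values (100 pairs here)."""
        left = self.hemisphere_rows("left")
        right = self.hemisphere_rows("right")
        return self.matrix[np.ix_(left, right)]


def connectivity_matrix(epoch: BandEpoch, method: str) -> ConnectivityMatrix:
    """Full n x n symmetric matrix of pairwise correlation or PLV."""
    data = np.asarray(epoch.data, dtype=float)
    n_ch, n_s = data.shape
    if np.any(data.std(axis=1) == 0):
        bad = [i for i in range(n_ch) if data[i].std() == 0]
        raise UndefinedFeatureError(f"constant channel(s) within epoch: {bad}")

    n_phase = None
    if method == "correlation":
        m = np.corrcoef(data)
    elif method == "plv":
        phases = instantaneous_phase(data)
        sl = _trim(n_s)
        z = np.exp(1j * phases[:, sl])
        L = z.shape[1]
        m = np.abs(z @ z.conj().T) / L
        n_phase = L
    else:
        raise ValueError(f"unknown connectivity method {method!r}")

    m = (m + m.T) / 2.0  # enforce exact symmetry against float round-off
    m = np.clip(m, -1.0, 1.0) if method == "correlation" else np.clip(m, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    left, right = epoch.hemisphere_split
    labels = [f"ch{i}" for i in range(n_ch)]
    channel_index = [
        (labels[i], "left" if i in set(left.tolist()) else "right") for i in range(n_ch)
    ]
    return ConnectivityMatrix(
        method=method,
        band=epoch.band,
        state=epoch.state,
        subject_id=epoch.subject_id,
        group=epoch.group,
        epoch_index=epoch.epoch_index,
        matrix=m,
        channel_index=channel_index,
        n_phase_samples=n_phase,
    )
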