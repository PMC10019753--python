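"""Channel selection, state segmentation and band decomposition.

EEG analysis here operates on the 20 prefrontal channels (10 per
hemisphere) and on four canonical frequency bands:

    delta 0.3-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz.

Band extraction uses a zero-phase forward-backward Butterworth filter;
zero phase is mandatory because downstream phase-locking estimates are
phase-sensitive and any group delay would masquerade as (de)synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class Band:
    """A frequency band with inclusive passband edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band edges: {self.low}..{self.high}")


#: The four canonical EEG bands used throughout the pipeline.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.3, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
)

BAND_BY_NAME: Mapping[str, Band] = {b.name: b for b in DEFAULT_BANDS}

#: Order of the four recording states in a session.
STATE_ORDER: tuple[str, ...] = ("baseline", "meditation", "transmission", "post")


@dataclass
class BandEpoch:
    """One band-filtered, fixed-length window of a multichannel state segment.

    ``hemisphere_split`` holds the (left, right) row-index arrays into
    ``data``; the two sets are disjoint, equal-sized and cover all rows.
    """

    subject_id: str
    group: str
    state: str
    band: Band
    epoch_index: int
    data: np.ndarray  # channels x samples
    sampling_rate: float
    hemisphere_split: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        left, right = self.hemisphere_split
        left = np.asarray(left, dtype=int)
        right = np.asarray(right, dtype=int)
        if len(left) != len(right):
            raise ValueError("hemisphere index sets must be equal-sized")
        both = np.concatenate([left, right])
        if len(set(both.tolist())) != len(both) or len(both) != self.data.shape[0]:
            raise ValueError("hemisphere index sets must be disjoint and cover all channels")
        self.hemisphere_split = (left, right)


def select_prefrontal(recording, montage_map: Mapping[str, str]):
    """Restrict a recording to the prefrontal channels named in ``montage_map``.

    ``montage_map`` maps channel label -> ``"left"``, ``"right"`` or
    ``"drop"``. The returned recording contains the retained channels
    reordered left block first then right block, preserving the original
    relative order inside each block.
    """
    keep = {lab: side for lab, side in montage_map.items() if side in ("left", "right")}
    labels = [lab for lab, _ in recording.montage]
    missing = sorted(set(keep) - set(labels))
    if missing:
        raise ValueError(f"montage_map retains labels absent from recording: {missing}")
    left = [labels.index(lab) for lab in labels if keep.get(lab) == "left"]
    right = [labels.index(lab) for lab in labels if keep.get(lab) == "right"]
    if len(left) != len(right) or not left:
        raise ValueError(
            f"unequal hemisphere counts: {len(left)} left vs {len(right)} right"
        )
    order = left + right
    montage = [(labels[i], "left") for i in left] + [(labels[i], "right") for i in right]
    return replace(recording, data=recording.data[order], montage=montage)


def segment_states(recording) -> dict[str, np.ndarray]:
    """Slice the recording into per-state channels x samples matrices.

    Schedule entries are half-open ``[start, end)`` sample intervals;
    overlapping entries are an error, states absent from the schedule are
    absent from the result.
    """
    entries = sorted(recording.schedule, key=lambda e: e[1])
    n = recording.data.shape[1]
    prev_end = 0
    out: dict[str, np.ndarray] = {}
    for state, start, end in entries:
        if start < prev_end:
            raise ValueError(f"overlapping schedule entries at state {state!r}")
        if not (0 <= start < end <= n):
            raise ValueError(f"schedule entry {state!r} [{start},{end}) outside data length {n}")
        if state in out:
            raise ValueError(f"duplicate schedule entry for state {state!r}")
        out[state] = recording.data[:, start:end]
        prev_end = end
    return out


def _bandpass_sos(sampling_rate: float, band: Band):
    nyq = sampling_rate / 2.0
    if band.high >= nyq:
        raise ValueError(f"band edge {band.high} Hz at/above Nyquist {nyq} Hz")
    return signal.butter(4, [band.low, band.high], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(data: np.ndarray, sampling_rate: float, band: Band) -> np.ndarray:
    """Zero-phase band-pass filter (Butterworth order 4 per pass).

    Applied forward-backward, so the effective magnitude response is
    squared (~48 dB/octave roll-off per pass direction) and the phase
    response is identically zero. Ends are reflect-padded by roughly one
    filter-settling length (three low-edge periods) before filtering.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    sos = _bandpass_sos(sampling_rate, band)
    # settling of the slow (low-edge) pole dominates edge transients
    padlen = min(data.shape[-1] - 1, int(3 * sampling_rate / band.low))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def epoch(
    state_data: np.ndarray,
    sampling_rate: float,
    epoch_seconds: float,
    band: Band,
    *,
    subject_id: str,
    group: str,
    state: str,
    hemisphere_split: tuple[Sequence[int], Sequence[int]],
) -> list[BandEpoch]:
    """Band-filter a whole state segment, then cut non-overlapping windows.

    Filtering precedes slicing so that each window is free of per-epoch
    filter edge artifacts; a trailing partial window is discarded.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    n_per = int(round(epoch_seconds * sampling_rate))
    filtered = bandpass(state_data, sampling_rate, band)
    n_epochs = filtered.shape[1] // n_per
    return [
        BandEpoch(
            subject_id=subject_id,
            group=group,
            state=state,
            band=band,
            epoch_index=k,
            data=filtered[:, k * n_per : (k + 1) * n_per],
            sampling_rate=sampling_rate,
            hemisphere_split=(np.asarray(hemisphere_split[0]), np.asarray(hemisphere_split[1])),
        )
        for k in range(n_epochs)
    ]
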