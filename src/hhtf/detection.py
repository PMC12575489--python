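"""Impact detection by acceleration-norm thresholding with angular-rate gating.

An impact core is a contiguous excursion of the acceleration norm above a
threshold (default 15 g).  A candidate is accepted as a true impact only if
the gyroscope norm within the core also exceeds a gate (default 400 deg/s):
real impacts on a necked headform rotate the head, while handling artifacts
(taps, sensor adjustments) spike the accelerometer with little rotation.
Accepted cores are padded by a fixed margin (default ±0.25 s) to capture the
whole waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .signal_core import ImuRecording, vector_norm

ACCEL_THRESH_G = 15.0
GYRO_THRESH_DPS = 400.0
PAD_S = 0.25

#: Cores separated by less than this are merged (threshold chatter guard).
MERGE_GAP_S = 0.05


@dataclass
class ImpactSegment:
    """A padded impact window cut from a recording.

    ``core_start``/``core_end`` are the half-open threshold-crossing bounds
    in the source recording's sample indices; ``start``/``end`` the padded
    window bounds (clipped to the recording).  ``accel``/``gyro`` hold the
    padded window.
    """

    sensor: str
    core_start: int
    core_end: int
    start: int
    end: int
    accel: np.ndarray
    gyro: np.ndarray
    rate: float
    frame: str = "FF"
    location: str | None = None
    energy_j: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def core_slice_local(self) -> slice:
        """Core window expressed in the padded window's local indices."""
        return slice(self.core_start - self.start, self.core_end - self.start)


def _threshold_runs(norms: np.ndarray, thresh: float) -> list[tuple[int, int]]:
    """Half-open [start, end) runs where ``norms >= thresh``."""
    above = norms >= thresh
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(norms.size)
    return list(zip(starts, ends))


def detect_impacts(rec: ImuRecording,
                   accel_thresh: float = ACCEL_THRESH_G,
                   gyro_thresh: float = GYRO_THRESH_DPS,
                   pad: float = PAD_S,
                   gyro_gate: Literal["require_above", "reject_above"] = "require_above",
                   merge_gap: float = MERGE_GAP_S) -> list[ImpactSegment]:
    """Segment impacts from a continuous recording.

    The recording should already be at the working rate (helmet traces are
    upsampled to 10 kHz first).  Returns time-ordered segments with
    non-overlapping cores; an empty recording yields an empty list.
    """
    if accel_thresh <= 0 or gyro_thresh <= 0:
        raise ValueError("thresholds must be positive")
    a_norm = vector_norm(rec.accel)
    g_norm = vector_norm(rec.gyro)
    runs = _threshold_runs(a_norm, accel_thresh)

    # merge cores closer than merge_gap (chatter around the threshold)
    gap_samples = int(round(merge_gap * rec.rate))
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    pad_samples = int(round(pad * rec.rate))
    segments = []
    for s, e in merged:
        gyro_peak = g_norm[s:e].max()
        keep = gyro_peak >= gyro_thresh if gyro_gate == "require_above" else gyro_peak < gyro_thresh
        if not keep:
            continue
        w0 = max(0, s - pad_samples)
        w1 = min(rec.n_samples, e + pad_samples)
        segments.append(ImpactSegment(
            sensor=rec.sensor, core_start=int(s), core_end=int(e),
            start=int(w0), end=int(w1),
            accel=rec.accel[:, w0:w1].copy(), gyro=rec.gyro[:, w0:w1].copy(),
            rate=rec.rate, frame=rec.frame,
            meta={"accel_peak_g": float(a_norm[s:e].max()),
                  "gyro_peak_dps": float(gyro_peak)},
        ))
    return segments
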