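"""Functional-frame calibration of the helmet IMU.

The helmet sensor reports in its own technical frame (TF).  The anatomical
functional frame (FF: X antero-posterior, Y axial, Z medial-lateral) is
recovered from two recorded pure rotations — the helmet is spun for ~5 s
about the FF Y axis, then ~5 s about the FF Z axis.  PCA on each gyroscope
segment yields the rotation axis; the two axes define the TF->FF rotation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .signal_core import ImuRecording, vector_norm

#: Minimum fraction of gyro variance the first principal component must
#: explain for a segment to count as a pure rotation.
MIN_PC1_VARIANCE = 0.60

#: Gyro-norm floor (deg/s) that qualifies a sample as "rotating".
ROTATION_FLOOR_DPS = 100.0

#: Rest-gap detection between the two calibration rotations.
REST_THRESH_DPS = 50.0
REST_MIN_S = 0.5


class CalibrationError(ValueError):
    """Calibration recording does not support a reliable frame estimate."""


def estimate_rotation_axis(gyro_segment: np.ndarray,
                           floor_dps: float = ROTATION_FLOOR_DPS) -> np.ndarray:
    """First principal axis of a gyroscope segment recorded during a pure rotation.

    Returns a unit 3-vector; its sign is fixed so that the mean projection of
    the gyro signal onto the axis is positive (the recorded spin direction).
    """
    g = np.atleast_2d(np.asarray(gyro_segment, dtype=float))
    if g.shape[0] != 3:
        raise ValueError("gyro segment must be 3xN")
    norms = vector_norm(g)
    if np.mean(norms > floor_dps) <= 0.5:
        raise CalibrationError("segment does not contain a sustained rotation")
    centered = g - g.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / g.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] / evals.sum() < MIN_PC1_VARIANCE:
        raise CalibrationError(
            "gyro energy is near-isotropic; first principal component explains "
            f"{100 * evals[-1] / evals.sum():.0f}% < {100 * MIN_PC1_VARIANCE:.0f}% of variance"
        )
    axis = evecs[:, -1]
    if np.mean(g.T @ axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def build_functional_frame(axis_y: np.ndarray, axis_z: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping TF vectors into the FF.

    The empirically measured Y axis (first rotation) is trusted exactly; the
    Z axis is Gram-Schmidt-orthogonalized against it; X completes the
    right-handed triad (X = Y x Z).  ``R @ axis_y == (0, 1, 0)``.
    """
    y = np.asarray(axis_y, dtype=float)
    z = np.asarray(axis_z, dtype=float)
    y = y / np.linalg.norm(y)
    z = z / np.linalg.norm(z)
    if abs(float(y @ z)) >= 0.5:
        raise CalibrationError("calibration axes are near-parallel")
    z = z - (y @ z) * y
    z = z / np.linalg.norm(z)
    x = np.cross(y, z)
    # rows of R are the FF basis vectors expressed in TF, so R v_TF = v_FF
    return np.vstack([x, y, z])


def check_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    """Raise unless ``R`` is a proper rotation (orthonormal, det +1)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if np.abs(R.T @ R - np.eye(3)).max() > max(tol, 1e-9):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection, not a rotation")


def apply_frame(rec: ImuRecording, R: np.ndarray, tol: float = 1e-6) -> ImuRecording:
    """Rotate a TF recording into the FF sample-wise."""
    check_rotation(R, tol=tol)
    if rec.frame != "TF":
        raise ValueError(f"expected a TF recording, got frame {rec.frame!r}")
    from dataclasses import replace

    return replace(rec, accel=R @ rec.accel, gyro=R @ rec.gyro, frame="FF")


def segment_calibration(rec: ImuRecording,
                        rest_thresh: float = REST_THRESH_DPS,
                        rest_min_s: float = REST_MIN_S) -> tuple[np.ndarray, np.ndarray]:
    """Split one calibration recording into its Y- and Z-rotation gyro blocks.

    Rotation blocks are maximal runs with gyro norm above ``rest_thresh``;
    the two longest runs separated by a rest gap of at least ``rest_min_s``
    are taken, in temporal order (Y first, then Z per the protocol).
    """
    norms = vector_norm(rec.gyro)
    active = norms > rest_thresh
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = list(edges[~active[edges]] + 1)
    ends = list(edges[active[edges]] + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(norms.size)
    runs = [(s, e) for s, e in zip(starts, ends) if (e - s) / rec.rate > rest_min_s]
    if len(runs) < 2:
        raise CalibrationError("could not find two rotation blocks separated by a rest gap")
    runs = sorted(sorted(runs, key=lambda r: r[1] - r[0], reverse=True)[:2])
    (s1, e1), (s2, e2) = runs
    return rec.gyro[:, s1:e1], rec.gyro[:, s2:e2]


def calibrate(rec: ImuRecording) -> np.ndarray:
    """Full calibration: segment the recording, estimate both axes, build R."""
    gy, gz = segment_calibration(rec)
    return build_functional_frame(estimate_rotation_axis(gy), estimate_rotation_axis(gz))


def geodesic_angle_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Rotation angle (degrees) between two rotation matrices."""
    c = (np.trace(np.asarray(R1).T @ np.asarray(R2)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def save_frame(R: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"rotation_row_major": np.asarray(R).ravel().tolist()}))


def load_frame(path: str | Path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    R = np.asarray(data["rotation_row_major"], dtype=float).reshape(3, 3)
    check_rotation(R, tol=1e-6)
    return R
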