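"""Impact-direction estimation and azimuthal region classification.

The main impact direction is estimated from the padded acceleration window
in three steps: PCA denoising (keep the first principal component and
back-project), truncation of the signal at the acceleration-norm peak (the
helmet and head move together during the build-up, so only the pre-peak
samples are trusted), and a final PCA whose first component is the
direction.  Classification uses the azimuth only (the impactor's line of
action lies in the transverse X-Z plane): eight 45 deg sectors centred on
the reference directions 0, +-45, +-90, +-135 and 180 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import ImpactSegment

#: Reference azimuths (deg) and their region tags.  X_FF points forward,
#: positive azimuth rotates toward the right side (+Z_FF).
REGIONS = {
    0.0: "front",
    45.0: "front_oblique_R",
    90.0: "side_R",
    135.0: "rear_oblique_R",
    180.0: "back",
    -135.0: "rear_oblique_L",
    -90.0: "side_L",
    -45.0: "front_oblique_L",
}
REGION_HALF_WIDTH_DEG = 22.5


@dataclass
class DirectionEstimate:
    """Unit direction in the FF plus its azimuth and region tag."""

    vector: np.ndarray  # unit 3-vector, FF
    azimuth_deg: float  # (-180, 180], from +X_FF toward +Z_FF
    region: str


@dataclass
class MainAxisTrace:
    """Acceleration projected on the main impact direction (g), peak-positive."""

    values: np.ndarray
    rate: float
    segment: ImpactSegment | None = None
    frame: str = "PCA"

    @property
    def peak(self) -> float:
        return float(np.max(self.values))


class DirectionError(ValueError):
    """Segment is too degenerate for a direction estimate."""


def pca_denoise(accel: np.ndarray, n_keep: int = 1) -> np.ndarray:
    """Project 3xK acceleration onto its top ``n_keep`` principal components.

    Mean-centred PCA; the retained components are back-projected to the
    original axes, so the output has the input's shape and mean.
    """
    if n_keep not in (1, 2, 3):
        raise ValueError("n_keep must be 1, 2 or 3")
    a = np.atleast_2d(np.asarray(accel, dtype=float))
    if a.shape[0] != 3 or a.shape[1] <= 3:
        raise ValueError("expected 3xK with K > 3")
    mean = a.mean(axis=1, keepdims=True)
    centered = a - mean
    cov = centered @ centered.T / a.shape[1]
    _, evecs = np.linalg.eigh(cov)
    basis = evecs[:, ::-1][:, :n_keep]  # descending eigenvalue order
    return basis @ (basis.T @ centered) + mean


def truncate_to_peak(accel: np.ndarray) -> np.ndarray:
    """Prefix of a 3xK matrix up to (and including) its norm argmax.

    Ties at the maximum resolve to the first occurrence.
    """
    a = np.atleast_2d(np.asarray(accel, dtype=float))
    if a.size == 0:
        raise ValueError("empty segment")
    norms = np.linalg.norm(a, axis=0)
    return a[:, : int(np.argmax(norms)) + 1]


def estimate_direction(segment: ImpactSegment, n_keep: int = 1) -> DirectionEstimate:
    """Main impact direction of a segment (expects FF acceleration)."""
    denoised = pca_denoise(segment.accel, n_keep=n_keep)
    prefix = truncate_to_peak(denoised)
    centered = prefix - prefix.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / max(prefix.shape[1], 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise DirectionError("zero-energy segment")
    direction = evecs[:, -1]
    # sign: the acceleration peak must project positively on the direction
    peak_sample = segment.accel[:, int(np.argmax(np.linalg.norm(segment.accel, axis=0)))]
    if float(peak_sample @ direction) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    azimuth = float(np.degrees(np.arctan2(direction[2], direction[0])))
    if azimuth == -180.0:  # convention: azimuth in (-180, 180]
        azimuth = 180.0
    return DirectionEstimate(vector=direction, azimuth_deg=azimuth,
                             region=classify_region(azimuth))


def classify_region(azimuth_deg: float) -> str:
    """Region tag for an azimuth under the half-open [ref-22.5, ref+22.5) partition."""
    if not np.isfinite(azimuth_deg):
        return "unclassified"
    theta = (float(azimuth_deg) + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    if theta == -180.0:
        theta = 180.0
    for ref, tag in REGIONS.items():
        delta = (theta - ref + 180.0) % 360.0 - 180.0
        if -REGION_HALF_WIDTH_DEG <= delta < REGION_HALF_WIDTH_DEG:
            return tag
    return "unclassified"  # unreachable: the eight sectors tile the circle


def project_main(segment: ImpactSegment, direction: DirectionEstimate) -> MainAxisTrace:
    """Dot-project the padded acceleration onto the main direction."""
    d = np.asarray(direction.vector, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    values = d @ segment.accel
    return MainAxisTrace(values=values, rate=segment.rate, segment=segment)
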