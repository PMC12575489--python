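"""Synthetic paired helmet/headform impact generator.

No public dataset accompanies the pendulum-rig protocol this package
targets, so every stage is exercised against a generator that reproduces
the *structure* of such recordings rather than any measured magnitudes:

* the headform (head centre of mass) pulse is Gaussian-like;
* the helmet trace shares the build-up phase, then shows a delayed
  second lobe ("double peak") plus band-limited high-frequency noise from
  helmet-head decoupling;
* sessions follow the pendulum test matrix — trials of three impacts a
  fixed gap apart, per location (front, +-45 deg obliques, sides,
  rear-obliques) and impact energy (33 or 79 J);
* handling artifacts (accelerometer spikes with sub-threshold gyro) are
  injected between trials, and a calibration recording (5 s spins about
  the functional Y then Z axes) can be produced for any true rotation.

Peak magnitudes are generator conventions chosen to sit inside the +-200 g
helmet sensor range, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_core import (HEADFORM_RATE_HZ, HELMET_RATE_HZ, ImuRecording)

#: Azimuth of each impact location (deg, +X_FF forward, + toward right side).
LOCATION_AZIMUTH_DEG = {
    "front": 0.0,
    "front_oblique_R": 45.0,
    "front_oblique_L": -45.0,
    "side_R": 90.0,
    "side_L": -90.0,
    "rear_oblique_R": 135.0,
    "rear_oblique_L": -135.0,
}

#: Headform peak conventions per impact energy (g): mean, sd.
ENERGY_PEAK_G = {33.0: (45.0, 8.0), 79.0: (80.0, 12.0)}

#: Gaussian full width at 5% of peak <-> sigma conversion.
_WIDTH_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(20.0)))


@dataclass
class ImpactScenario:
    """One location x energy block of the pendulum test matrix."""

    location: str = "front"
    energy_j: float = 33.0
    azimuth_deg: float | None = None      # default: the location's azimuth
    peak_mean_g: float | None = None      # default: energy convention
    peak_sd_g: float | None = None
    duration_ms: float = 10.0
    duration_sd_ms: float = 1.0
    # decoupling morphology
    second_peak_rel: float = 0.6
    second_peak_delay_ms: float = 6.0
    hf_noise_sd_g: float = 6.0
    hf_band_hz: tuple[float, float] = (300.0, 500.0)
    # protocol
    n_trials: int = 14
    impacts_per_trial: int = 3
    gap_s: float = 20.0
    n_handling_artifacts: int = 2
    # sensors
    helmet_rate: float = HELMET_RATE_HZ
    headform_rate: float = HEADFORM_RATE_HZ
    helmet_clip_g: float = 200.0
    headform_clip_g: float = 500.0
    helmet_gyro_clip_dps: float = 2000.0
    headform_gyro_clip_dps: float = 8000.0
    # nuisance structure
    off_axis_frac: float = 0.10
    baseline_noise_sd_g: float = 0.15
    gyro_noise_sd_dps: float = 2.0
    impact_gyro_peak_dps: float = 800.0
    direction_jitter_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.azimuth_deg is None:
            self.azimuth_deg = LOCATION_AZIMUTH_DEG[self.location]
        if self.peak_mean_g is None:
            self.peak_mean_g, default_sd = ENERGY_PEAK_G[self.energy_j]
            if self.peak_sd_g is None:
                self.peak_sd_g = default_sd
        elif self.peak_sd_g is None:
            self.peak_sd_g = 0.1 * self.peak_mean_g
        if self.second_peak_delay_ms <= 0:
            raise ValueError("second-peak delay must be positive")

    @property
    def n_impacts(self) -> int:
        return self.n_trials * self.impacts_per_trial


@dataclass
class GroundTruth:
    """Per-impact truth emitted alongside a simulated session."""

    impacts: list = field(default_factory=list)    # dicts, see simulate_session
    artifacts: list = field(default_factory=list)  # artifact centre times, s
    seed: int = 0
    clipped: bool = False

    def to_dict(self) -> dict:
        return {"impacts": self.impacts, "artifacts": self.artifacts,
                "seed": self.seed, "clipped": self.clipped}


def simulate_headform_pulse(peak: float, duration_ms: float, rate: float,
                            margin: float = 2.0) -> np.ndarray:
    """Gaussian pulse with max ``peak`` g and 5%-crossing width ``duration_ms``."""
    if peak <= 15.0:
        raise ValueError("pulse peak must exceed the 15 g detection threshold")
    if not 5.0 <= duration_ms <= 30.0:
        raise ValueError("duration must lie in [5, 30] ms")
    sigma = duration_ms / 1000.0 * _WIDTH_TO_SIGMA
    half = int(round(margin * duration_ms / 1000.0 * rate / 2.0))
    t = (np.arange(2 * half + 1) - half) / rate
    return peak * np.exp(-0.5 * (t / sigma) ** 2)


def _band_noise(n: int, band: tuple[float, float], rate: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    from scipy import signal as sps
    lo, hi = band
    hi = min(hi, 0.45 * rate)
    sos = sps.butter(2, [lo, hi], btype="band", fs=rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_helmet_trace(headform_pulse: np.ndarray, rate: float,
                          rng: np.random.Generator,
                          second_peak_rel: float = 0.6,
                          second_peak_delay_ms: float = 6.0,
                          hf_noise_sd_g: float = 6.0,
                          hf_band_hz: tuple[float, float] = (300.0, 500.0)) -> np.ndarray:
    """Decoupling-corrupted helmet counterpart of a headform pulse.

    Identical to the reference during the build-up, then a delayed second
    lobe makes the descent late, and high-frequency noise (windowed to start
    near the peak) rides on the tail.  Zero decoupling parameters return the
    pulse unchanged.
    """
    pulse = np.asarray(headform_pulse, dtype=float)
    peak_idx = int(np.argmax(pulse))
    peak = float(pulse[peak_idx])
    # sigma recovered from the 5% support width
    above = np.flatnonzero(pulse >= 0.05 * peak)
    sigma_smp = max((above[-1] - above[0]) * _WIDTH_TO_SIGMA, 1.0)
    delay_smp = second_peak_delay_ms / 1000.0 * rate
    n = int(pulse.size + delay_smp + 4 * sigma_smp)
    t = np.arange(n, dtype=float)
    out = np.zeros(n)
    out[:pulse.size] = pulse
    if second_peak_rel > 0:
        centre = peak_idx + delay_smp
        out += second_peak_rel * peak * np.exp(
            -0.5 * ((t - centre) / (1.2 * sigma_smp)) ** 2)
    if hf_noise_sd_g > 0:
        rise = 1.0 / (1.0 + np.exp(-(t - peak_idx) / (sigma_smp / 4.0)))
        decay_start = peak_idx + delay_smp + sigma_smp
        decay = np.exp(-np.maximum(0.0, t - decay_start) / (4.0 * sigma_smp))
        out += hf_noise_sd_g * _band_noise(n, hf_band_hz, rate, rng) * rise * decay
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _direction_vectors(azimuth_deg: float, elevation_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impact direction in the FF plus two orthogonal off-axis unit vectors."""
    az = np.radians(azimuth_deg)
    el = np.radians(elevation_deg)
    d = np.array([np.cos(el) * np.cos(az), np.sin(el), np.cos(el) * np.sin(az)])
    ref = np.array([0.0, 1.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(d, ref))
    e2 = np.cross(d, e1)
    return d, e1, e2


def simulate_session(scenario: ImpactScenario) -> tuple[ImuRecording, ImuRecording, GroundTruth]:
    """Full paired helmet/headform session for one scenario.

    The session is generated on the 10 kHz headform grid; helmet channels
    are then sampled onto the 1024 Hz helmet grid.  Gyroscope pulses above
    the 400 deg/s gate accompany every impact; handling artifacts (helmet
    accelerometer spikes with quiet gyro) are placed between trials.
    """
    rng = np.random.default_rng(scenario.seed)
    # helmet-only noise comes from its own stream so decoupling parameters
    # (which change how much noise is drawn) cannot perturb the headform
    rng_helm = np.random.default_rng(scenario.seed + 986_243)
    rate = scenario.headform_rate
    gap = scenario.gap_s
    n_impacts = scenario.n_impacts
    total_s = gap * (n_impacts + 1)
    n = int(round(total_s * rate))
    t = np.arange(n) / rate

    head_acc = rng.normal(0.0, scenario.baseline_noise_sd_g, (3, n))
    head_gyr = rng.normal(0.0, scenario.gyro_noise_sd_dps, (3, n))
    helm_acc = rng_helm.normal(0.0, scenario.baseline_noise_sd_g, (3, n))
    helm_gyr = rng_helm.normal(0.0, scenario.gyro_noise_sd_dps, (3, n))

    truth = GroundTruth(seed=scenario.seed)
    for k in range(n_impacts):
        centre_s = gap * (k + 1) + rng.uniform(-0.1, 0.1) * gap * 0.05
        peak = max(20.0, rng.normal(scenario.peak_mean_g, scenario.peak_sd_g))
        duration = float(np.clip(rng.normal(scenario.duration_ms,
                                            scenario.duration_sd_ms), 6.0, 20.0))
        az = scenario.azimuth_deg + rng.normal(0.0, scenario.direction_jitter_deg)
        el = rng.normal(0.0, scenario.direction_jitter_deg)
        d, e1, e2 = _direction_vectors(az, el)

        pulse = simulate_headform_pulse(peak, duration, rate)
        i0 = int(round(centre_s * rate)) - int(np.argmax(pulse))
        off1 = scenario.off_axis_frac * simulate_headform_pulse(
            max(16.0, 0.99 * peak), duration * 1.2, rate)[:pulse.size] * rng.uniform(0.5, 1.0)
        off2 = scenario.off_axis_frac * simulate_headform_pulse(
            max(16.0, 0.99 * peak), duration * 0.9, rate)[:pulse.size] * rng.uniform(0.5, 1.0)
        helm_pulse = simulate_helmet_trace(
            pulse, rate, rng_helm,
            second_peak_rel=scenario.second_peak_rel,
            second_peak_delay_ms=scenario.second_peak_delay_ms,
            hf_noise_sd_g=scenario.hf_noise_sd_g,
            hf_band_hz=scenario.hf_band_hz)

        def _add(mat: np.ndarray, vec: np.ndarray, sig: np.ndarray, start: int) -> None:
            s0, s1 = max(0, start), min(n, start + sig.size)
            if s1 > s0:
                mat[:, s0:s1] += np.outer(vec, sig[s0 - start:s1 - start])

        _add(head_acc, d, pulse, i0)
        _add(head_acc, e1, off1, i0)
        _add(head_acc, e2, off2, i0)
        _add(helm_acc, d, helm_pulse, i0)
        _add(helm_acc, e1, off1, i0)
        _add(helm_acc, e2, off2, i0)

        # head rotation about an axis orthogonal to the impact direction
        gyro_peak = max(450.0, rng.normal(scenario.impact_gyro_peak_dps, 150.0))
        gyro_pulse = simulate_headform_pulse(gyro_peak, duration * 1.5, rate)
        i0g = int(round(centre_s * rate)) - int(np.argmax(gyro_pulse))
        _add(head_gyr, e1, gyro_pulse, i0g)
        _add(helm_gyr, e1, gyro_pulse, i0g)

        onset_rel = np.flatnonzero(pulse >= 15.0)
        truth.impacts.append({
            "onset_s": float((i0 + (onset_rel[0] if onset_rel.size else 0)) / rate),
            "centre_s": float(centre_s),
            "direction": d.tolist(),
            "azimuth_deg": float(az),
            "region": scenario.location,
            "peak_g": float(peak),
            "duration_ms": float(duration),
        })
        if peak >= scenario.headform_clip_g:
            truth.clipped = True

    # handling artifacts: sharp helmet accel spikes with quiet gyro
    for a in range(scenario.n_handling_artifacts):
        centre_s = gap * 0.5 + a * gap * max(1, n_impacts // max(1, scenario.n_handling_artifacts))
        spike = simulate_headform_pulse(rng.uniform(20.0, 30.0), 6.0, rate)
        i0 = int(round(centre_s * rate)) - spike.size // 2
        d, e1, _ = _direction_vectors(rng.uniform(-180, 180), 0.0)
        s0, s1 = max(0, i0), min(n, i0 + spike.size)
        if s1 > s0:
            helm_acc[:, s0:s1] += np.outer(d, spike[s0 - i0:s1 - i0])
            # small rotation, well under the 400 deg/s gate
            helm_gyr[:, s0:s1] += np.outer(e1, 0.2 * spike[s0 - i0:s1 - i0])
        truth.artifacts.append(float(centre_s))

    head_acc = np.clip(head_acc, -scenario.headform_clip_g, scenario.headform_clip_g)
    head_gyr = np.clip(head_gyr, -scenario.headform_gyro_clip_dps,
                       scenario.headform_gyro_clip_dps)

    headform = ImuRecording(time=t, accel=head_acc, gyro=head_gyr, rate=rate,
                            frame="FF", sensor="headform")

    # sample the helmet channels onto the 1024 Hz grid
    hr = scenario.helmet_rate
    n_h = int(np.floor(t[-1] * hr)) + 1
    t_h = np.arange(n_h) / hr
    idx = np.minimum((t_h * rate).round().astype(int), n - 1)
    helm_acc_h = np.clip(helm_acc[:, idx], -scenario.helmet_clip_g, scenario.helmet_clip_g)
    helm_gyr_h = np.clip(helm_gyr[:, idx], -scenario.helmet_gyro_clip_dps,
                         scenario.helmet_gyro_clip_dps)
    helmet = ImuRecording(time=t_h, accel=helm_acc_h, gyro=helm_gyr_h, rate=hr,
                          frame="FF", sensor="helmet")
    return helmet, headform, truth


def simulate_calibration(R_true: np.ndarray, rng: np.random.Generator | int = 0,
                         rate: float = HELMET_RATE_HZ,
                         spin_dps: float = 360.0,
                         noise_sd_dps: float = 5.0) -> ImuRecording:
    """Calibration recording: 5 s spin about FF-Y, rest, 5 s about FF-Z.

    ``R_true`` maps TF -> FF, so the recorded TF gyro during the Y block is
    ``R_true.T @ (0, spin, 0)`` plus noise.  The calibration module should
    recover ``R_true`` from this recording.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    R = np.asarray(R_true, dtype=float)
    block = int(5 * rate)
    rest = int(1 * rate)
    n = 3 * rest + 2 * block
    gyro = rng.normal(0.0, noise_sd_dps, (3, n))
    ramp = np.minimum(1.0, np.arange(block) / (0.2 * rate))
    profile = spin_dps * ramp * ramp[::-1] / max(ramp.max() ** 2, 1e-12)
    y_tf = R.T @ np.array([0.0, 1.0, 0.0])
    z_tf = R.T @ np.array([0.0, 0.0, 1.0])
    s1 = rest
    gyro[:, s1:s1 + block] += np.outer(y_tf, profile)
    s2 = 2 * rest + block
    gyro[:, s2:s2 + block] += np.outer(z_tf, profile)
    accel = rng.normal(0.0, 0.05, (3, n))
    accel[1] += 1.0  # gravity-ish constant, unused by the calibration
    t = np.arange(n) / rate
    return ImuRecording(time=t, accel=accel, gyro=gyro, rate=rate,
                        frame="TF", sensor="helmet")


def simulate_alternate_helmet(scenario: ImpactScenario, severity: float
                              ) -> tuple[ImuRecording, ImuRecording, GroundTruth]:
    """Same protocol with decoupling amplified by ``severity`` (> 1).

    Stands in for a different helmet model whose shell decouples more: a
    larger, later second lobe and stronger high-frequency noise.  The
    headform reference (and hence the ground truth) is unaffected.
    """
    if severity < 1.0:
        raise ValueError("severity multiplier must be >= 1")
    worse = replace(scenario,
                    second_peak_rel=scenario.second_peak_rel * severity,
                    second_peak_delay_ms=scenario.second_peak_delay_ms * severity,
                    hf_noise_sd_g=scenario.hf_noise_sd_g * severity)
    return simulate_session(worse)


def test_matrix_scenarios(locations=("front", "front_oblique_R", "side_R", "rear_oblique_L"),
                     n_trials: int | None = None, gap_s: float | None = None,
                     seed: int = 0, **overrides) -> list[ImpactScenario]:
    """Scenario list shaped like the pendulum test matrix.

    Front, front-oblique and side rows run at both energies (14 trials x 3
    impacts each at full scale); the rear-oblique row runs at 33 J only
    (15 trials).  ``n_trials``/``gap_s`` rescale the protocol for fast runs.
    """
    out = []
    k = 0
    for loc in locations:
        energies = (33.0,) if loc.startswith("rear_oblique") else (33.0, 79.0)
        for e in energies:
            trials = n_trials if n_trials is not None else (15 if loc.startswith("rear_oblique") else 14)
            kw = dict(location=loc, energy_j=e, n_trials=trials, seed=seed + 37 * k)
            if gap_s is not None:
                kw["gap_s"] = gap_s
            kw.update(overrides)
            out.append(ImpactScenario(**kw))
            k += 1
    return out
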