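"""Autoregressive helmet-to-head transfer function.

Helmet-shell sensors over-read the head's motion once the shell decouples
from the head: after the shared build-up phase the helmet trace shows a
delayed "double peak" plus high-frequency noise, while the head centre of
mass follows a single Gaussian-like pulse.  The transfer function exploits
the shared build-up: an AR(l) model

    a_t = c0 + c1*a_{t-1} + ... + cl*a_{t-l} + eps_t

is trained on concatenated, zero-baselined headform pulses, then run
recursively from the helmet build-up curve to extrapolate a head-like pulse
past the point where decoupling corrupts the helmet signal.  A power-law
peak adjustment maps the predicted peak toward the reference scale, and a
confidence-weighted blend restores the measured post-impact baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline

from .direction import MainAxisTrace
from .signal_core import FilterSpec, lowpass_trace

#: Fraction of the peak below which a sample counts as baseline ("at rest").
REST_FRACTION = 0.05

#: First-local-maximum qualification height for the build-up curve.
BUILDUP_MIN_PEAK_FRACTION = 0.10

#: Forecast stop rule: below REST_FRACTION of the build-up peak for this long.
FORECAST_STOP_S = 0.002
FORECAST_CAP_S = 0.100

LAG_GRID_DEFAULT = range(10, 301, 10)
FIXED_LAG_SAMPLES = 170  # 17 ms at the 10 kHz working rate


class FitError(ValueError):
    pass


class ExtractionError(ValueError):
    pass


class InstabilityError(RuntimeError):
    pass


@dataclass
class ARModel:
    """Intercept + lag coefficients of a conditional-least-squares AR fit."""

    intercept: float
    coef: np.ndarray  # (lag,) — coefficient i multiplies a_{t-1-i}
    rate: float
    meta: dict = field(default_factory=dict)

    @property
    def lag(self) -> int:
        return int(self.coef.size)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "intercept": self.intercept, "coef": np.asarray(self.coef).tolist(),
            "rate": self.rate, "meta": self.meta}))

    @classmethod
    def load(cls, path: str | Path) -> "ARModel":
        d = json.loads(Path(path).read_text())
        return cls(intercept=float(d["intercept"]),
                   coef=np.asarray(d["coef"], dtype=float),
                   rate=float(d["rate"]), meta=d.get("meta", {}))


@dataclass
class BuildUpCurve:
    """Helmet build-up phase, spline-extended to ``alpha`` x the raw peak.

    ``start_index`` locates the curve's first sample inside the padded
    impact window it was extracted from.
    """

    values: np.ndarray
    rate: float
    alpha: float
    lp_cutoff: float
    source_peak: float  # absolute peak of the raw trace, g
    start_index: int = 0

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.values)))


@dataclass
class PeakAdjuster:
    """Per-(location, intensity) linear map: prediction peak -> relative peak error (%)."""

    lines: dict  # group key -> (slope, intercept)

    def predict_rel_error(self, group, peak: float) -> float:
        slope, intercept = self.lines[group]
        return slope * peak + intercept

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {str(k): list(v) for k, v in self.lines.items()}))

    @classmethod
    def load(cls, path: str | Path) -> "PeakAdjuster":
        d = json.loads(Path(path).read_text())
        return cls(lines={k: tuple(v) for k, v in d.items()})


@dataclass
class ReconstructionParams:
    """Baseline-reconstruction settings (Step: blend AR output with measured tail)."""

    rest_thresh: float = REST_FRACTION          # fraction of peak defining t_end
    baseline_lp_hz: float = 40.0                # cutoff for the measured baseline
    # hand-over width ~ two pulse durations: the 40 Hz-filtered measurement
    # still carries a smeared pulse remnant right after t_end, so the blend
    # waits for it to decay before trusting the measured baseline
    transition_width_s: float = 0.020
    pre_impact_blend: bool = True               # mirror the blend before impact start

    def __post_init__(self) -> None:
        if not 0 < self.rest_thresh < 0.5:
            raise ValueError("rest_thresh must lie in (0, 0.5)")
        if self.transition_width_s <= 0:
            raise ValueError("transition width must be positive")


@dataclass
class TransferConfig:
    """Hyperparameters of the transfer function and the grid-search objective weights."""

    lp_cutoff: float = 200.0
    alpha: float = 0.7
    w1: float = 0.5
    w2: float = 0.5
    negate_delta: bool = False

    def __post_init__(self) -> None:
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("ErrorScore weights must sum to 1")
        if not 0.4 <= self.alpha <= 0.9:
            raise ValueError("alpha must lie in [0.4, 0.9]")


# ---------------------------------------------------------------------------
# Step 3a — training series and AR fitting
# ---------------------------------------------------------------------------

def pulse_support(values: np.ndarray, rest_thresh: float = REST_FRACTION) -> tuple[int, int]:
    """Half-open [start, end) span of the pulse around the global argmax.

    ``start`` is the sample after the last sub-threshold sample before the
    argmax; ``end`` the first sub-threshold sample after it.
    """
    v = np.asarray(values, dtype=float)
    peak_idx = int(np.argmax(v))
    thr = rest_thresh * v[peak_idx]
    below = v < thr
    pre = np.flatnonzero(below[:peak_idx])
    start = int(pre[-1]) + 1 if pre.size else 0
    post = np.flatnonzero(below[peak_idx:])
    end = peak_idx + int(post[0]) if post.size else v.size
    return start, end


def zero_baselines(trace: MainAxisTrace | np.ndarray,
                   rest_thresh: float = REST_FRACTION) -> np.ndarray:
    """Set the pre- and post-impact baselines of a main-axis trace to zero.

    Samples outside the ``rest_thresh``-of-peak support around the argmax
    become exactly 0; pulse samples are untouched.  An all-zero trace is
    returned unchanged.
    """
    v = np.asarray(trace.values if isinstance(trace, MainAxisTrace) else trace,
                   dtype=float).copy()
    if not v.any():
        return v
    start, end = pulse_support(v, rest_thresh)
    v[:start] = 0.0
    v[end:] = 0.0
    return v


def concatenate_training(traces: list[MainAxisTrace], seed: int | np.random.Generator,
                         rest_thresh: float = REST_FRACTION) -> np.ndarray:
    """Zero-baseline, randomly reorder and concatenate headform pulses."""
    if len(traces) < 2:
        raise ValueError("need at least two training traces")
    rates = {t.rate for t in traces}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates in training traces: {rates}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(traces))
    return np.concatenate([zero_baselines(traces[i], rest_thresh) for i in order])


def fit_ar(series: np.ndarray, lag: int, rate: float = 10_000.0,
           meta: dict | None = None) -> ARModel:
    """Conditional least squares AR(l): OLS of a_t on (1, a_{t-1}, ..., a_{t-l})."""
    s = np.asarray(series, dtype=float)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if s.size <= 3 * lag:
        raise FitError(f"series of length {s.size} too short for lag {lag}")
    n = s.size - lag
    X = np.empty((n, lag + 1))
    X[:, 0] = 1.0
    for k in range(1, lag + 1):
        X[:, k] = s[lag - k:s.size - k]
    y = s[lag:]
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < lag + 1:
        warnings.warn("rank-deficient AR regressor matrix; using minimum-norm solution")
    return ARModel(intercept=float(coef[0]), coef=coef[1:], rate=rate,
                   meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Step 3b — build-up curve extraction
# ---------------------------------------------------------------------------

def _first_qualifying_local_max(filt: np.ndarray, min_height: float) -> int:
    """Index of the first local maximum at or above ``min_height``."""
    interior = np.flatnonzero(
        (filt[1:-1] >= filt[:-2]) & (filt[1:-1] > filt[2:]) & (filt[1:-1] >= min_height)
    )
    if interior.size:
        return int(interior[0]) + 1
    # a monotone rise peaks at the global argmax
    peak = int(np.argmax(filt))
    if filt[peak] >= min_height:
        return peak
    raise ExtractionError("no local maximum above the 10% qualification height")


def extract_buildup(trace: MainAxisTrace, lp_cutoff: float, alpha: float | None,
                    order: int = 4) -> BuildUpCurve:
    """Build the AR seed curve from a helmet main-axis trace.

    The trace is zero-phase low-pass filtered at ``lp_cutoff``; the impact
    start and the first local maximum at >= 10% of the filtered absolute
    peak bound the raw build-up; a degree-2 spline through it is extended
    until it reaches ``alpha`` x the absolute peak of the *raw* trace (the
    endpoint is set to exactly that value).  ``alpha=None`` skips the spline
    extension and returns the filtered build-up as-is (used during lag
    selection, before the hyperparameters exist).
    """
    if alpha is not None and not 0.4 <= alpha <= 0.9:
        raise ValueError("alpha must lie in [0.4, 0.9]")
    if lp_cutoff not in (100.0, 200.0, 300.0, 400.0):
        warnings.warn(f"LP cutoff {lp_cutoff:g} Hz is outside the standard grid")
    raw = np.asarray(trace.values, dtype=float)
    filt = lowpass_trace(raw, FilterSpec(cutoff=lp_cutoff, order=order), trace.rate)
    fpeak = float(np.max(np.abs(filt)))
    if fpeak <= 0:
        raise ExtractionError("flat trace")
    i_lm = _first_qualifying_local_max(filt, BUILDUP_MIN_PEAK_FRACTION * fpeak)
    # impact start: last sub-5% sample before the local maximum
    below = np.flatnonzero(filt[:i_lm] < REST_FRACTION * fpeak)
    t1 = int(below[-1]) + 1 if below.size else 0
    prefix = filt[t1:i_lm + 1]
    source_peak = float(np.max(np.abs(raw)))
    if alpha is None:
        return BuildUpCurve(values=prefix.copy(), rate=trace.rate, alpha=np.nan,
                            lp_cutoff=lp_cutoff, source_peak=source_peak,
                            start_index=t1)
    target = alpha * source_peak
    reached = np.flatnonzero(prefix >= target)
    if reached.size:
        curve = prefix[:int(reached[0]) + 1].copy()
    else:
        # the spline must keep rising past the end of the fitted data, so it
        # is fitted on the strictly rising limb (up to 90% of the local-max
        # height) rather than on the flattening top
        rising_end = np.flatnonzero(prefix >= 0.9 * prefix[-1])
        cut = int(rising_end[0]) if rising_end.size else prefix.size - 1
        cut = max(cut, 2)
        if prefix.size < 3:
            raise ExtractionError("build-up too short for a degree-2 spline")
        base = prefix[:cut + 1]
        idx = np.arange(base.size, dtype=float)
        spline = InterpolatedUnivariateSpline(idx, base, k=2)
        cap = int(0.05 * trace.rate)  # never extrapolate more than 50 ms
        ext = spline(np.arange(base.size, base.size + cap, dtype=float))
        hit = np.flatnonzero(ext >= target)
        if hit.size:
            curve = np.concatenate([base, ext[:int(hit[0]) + 1]])
        else:
            # concave spline that tops out below the target: continue at the
            # end slope of the rising limb instead
            slope = float(np.mean(np.diff(base[-3:])))
            if slope <= 0:
                raise ExtractionError(
                    f"build-up never rises toward alpha x peak = {target:.1f} g")
            n_lin = int(np.ceil((target - base[-1]) / slope))
            if n_lin > cap:
                raise ExtractionError(
                    f"build-up too shallow to reach alpha x peak = {target:.1f} g")
            curve = np.concatenate([base, base[-1] + slope * np.arange(1, n_lin + 1)])
    curve[-1] = target
    return BuildUpCurve(values=curve, rate=trace.rate, alpha=alpha,
                        lp_cutoff=lp_cutoff, source_peak=source_peak,
                        start_index=t1)


# ---------------------------------------------------------------------------
# Step 3a/3c — forecasting and peak adjustment
# ---------------------------------------------------------------------------

def forecast(model: ARModel, buildup: BuildUpCurve,
             stop_fraction: float = REST_FRACTION,
             stop_duration_s: float = FORECAST_STOP_S,
             cap_s: float = FORECAST_CAP_S) -> np.ndarray:
    """Recursive one-step AR prediction seeded with the build-up curve.

    Returns the build-up followed by forecast samples; stops once the
    forecast stays below ``stop_fraction`` of the build-up peak for
    ``stop_duration_s``, or at the ``cap_s`` hard cap.
    """
    if abs(model.rate - buildup.rate) > 1e-6:
        raise ValueError("model and build-up sampling rates differ")
    lag = model.lag
    seed = buildup.values
    if seed.size < lag:
        seed = np.concatenate([np.zeros(lag - seed.size), seed])
    state = seed[-lag:].copy()
    peak = buildup.peak
    stop_n = max(1, int(round(stop_duration_s * model.rate)))
    cap_n = int(round(cap_s * model.rate))
    out = []
    below = 0
    rev_coef = model.coef[::-1]  # align with chronological state vector
    for _ in range(cap_n):
        nxt = model.intercept + float(rev_coef @ state)
        if abs(nxt) > 10.0 * peak:
            raise InstabilityError("AR forecast diverged beyond 10x the build-up peak")
        out.append(nxt)
        state = np.roll(state, -1)
        state[-1] = nxt
        below = below + 1 if nxt < stop_fraction * peak else 0
        if below >= stop_n:
            break
    return np.concatenate([buildup.values, np.asarray(out)])


def fit_peak_adjuster(train_predictions: list[np.ndarray],
                      train_references: list[np.ndarray],
                      groups: list | None = None) -> PeakAdjuster:
    """OLS lines mapping AR-prediction peaks to relative peak errors.

    The relative error of a training pair is
    ``(max(pred) - max(ref)) / max(pred) * 100`` — expressed relative to the
    AR prediction.  One line is fitted per group key (location, intensity);
    with ``groups=None`` a single line keyed ``"default"`` is fitted.
    """
    if len(train_predictions) != len(train_references):
        raise ValueError("prediction/reference lists differ in length")
    if groups is None:
        groups = ["default"] * len(train_predictions)
    lines: dict = {}
    for g in sorted(set(groups), key=str):
        pk = np.array([np.max(p) for p, gg in zip(train_predictions, groups) if gg == g])
        rf = np.array([np.max(r) for r, gg in zip(train_references, groups) if gg == g])
        if pk.size < 2:
            raise FitError(f"group {g!r} has fewer than 2 training pairs")
        rel_err = (pk - rf) / pk * 100.0
        if np.ptp(pk) < 1e-12:  # degenerate abscissa: flat line at the mean error
            lines[g] = (0.0, float(rel_err.mean()))
        else:
            slope, intercept = np.polyfit(pk, rel_err, 1)
            lines[g] = (float(slope), float(intercept))
    return PeakAdjuster(lines=lines)


def power_adjust(trace: np.ndarray, delta_peak: float) -> np.ndarray:
    """Raise a peak-positive trace to the power x with max^x = max + delta.

    Solving ``max(a)^x = max(a) + delta`` gives
    ``x = ln(max + delta) / ln(max)``; each sample is mapped
    sign-preservingly as ``sign(a) * |a|^x``, which weights the correction
    toward the peak and leaves near-baseline samples almost unchanged.
    Requires a peak above 1 g (the power map is ill-conditioned at 1).
    """
    v = np.asarray(trace, dtype=float)
    m = float(np.max(v))
    if m <= 1.0:
        raise ValueError("peak must exceed 1 g for the power adjustment")
    if m + delta_peak <= 1.0:
        # ln(m + delta) changes sign at 1, inverting the power map
        raise ValueError("adjusted peak must stay above 1 g")
    x = np.log(m + delta_peak) / np.log(m)
    return np.sign(v) * np.abs(v) ** x


def adjust_peak(trace: np.ndarray, adjuster: PeakAdjuster, group="default",
                negate_delta: bool = False) -> np.ndarray:
    """Apply the regression-predicted peak correction to an AR prediction."""
    m = float(np.max(trace))
    rel_err = adjuster.predict_rel_error(group, m)
    delta = rel_err / 100.0 * m
    if negate_delta:
        delta = -delta
    return power_adjust(trace, delta)


# ---------------------------------------------------------------------------
# Step 3d — baseline reconstruction
# ---------------------------------------------------------------------------

def reconstruct_baseline(adjusted: np.ndarray, raw_trace: MainAxisTrace,
                         params: ReconstructionParams | None = None) -> np.ndarray:
    """Blend the adjusted AR pulse with the measured (40 Hz filtered) baseline.

    ``adjusted`` must already sit on the raw window's grid (zeros outside the
    reconstructed pulse).  A confidence weight w equals 1 up to ``t_end``
    (first return of the adjusted pulse to 5% of its peak) then hands over to
    the low-passed measurement through a sigmoid of the configured width.
    """
    params = params or ReconstructionParams()
    adj = np.asarray(adjusted, dtype=float)
    raw = np.asarray(raw_trace.values, dtype=float)
    if adj.shape != raw.shape:
        raise ValueError("adjusted trace must be on the raw window grid")
    n = adj.size
    rate = raw_trace.rate
    peak_idx = int(np.argmax(np.abs(adj)))
    thr = params.rest_thresh * float(np.abs(adj[peak_idx]))
    post = np.flatnonzero(np.abs(adj[peak_idx:]) < thr)
    if post.size:
        t_end = peak_idx + int(post[0])
    else:
        warnings.warn("adjusted pulse never returns to the rest threshold; "
                      "using the window end as t_end")
        t_end = n - 1
    t = np.arange(n)
    width = params.transition_width_s * rate
    s = width / 10.0  # logistic scale: w ~ 0.7% at t_end + width
    w = 1.0 / (1.0 + np.exp(np.clip((t - (t_end + width / 2.0)) / s, -500, 500)))
    w[:t_end + 1] = 1.0
    if params.pre_impact_blend:
        pre = np.flatnonzero(np.abs(adj[:peak_idx]) >= thr)
        t_start = int(pre[0]) if pre.size else 0
        w_pre = 1.0 / (1.0 + np.exp(np.clip(((t_start - width / 2.0) - t) / s, -500, 500)))
        w_pre[t_start:] = 1.0
        w = w * w_pre
    baseline = lowpass_trace(raw, FilterSpec(cutoff=params.baseline_lp_hz, order=4), rate)
    return w * adj + (1.0 - w) * baseline


# ---------------------------------------------------------------------------
# Full pipeline per impact
# ---------------------------------------------------------------------------

def apply_transfer(trace: MainAxisTrace, model: ARModel, adjuster: PeakAdjuster,
                   config: TransferConfig, params: ReconstructionParams | None = None,
                   group="default") -> np.ndarray:
    """Run the whole transfer function on one helmet main-axis trace.

    extract_buildup -> forecast -> adjust_peak -> reconstruct_baseline; the
    output is a head-estimate trace on the input window's grid.
    """
    buildup = extract_buildup(trace, config.lp_cutoff, config.alpha)
    pred = forecast(model, buildup)
    adjusted = adjust_peak(pred, adjuster, group=group,
                           negate_delta=config.negate_delta)
    full = np.zeros_like(np.asarray(trace.values, dtype=float))
    t1 = buildup.start_index
    take = min(adjusted.size, full.size - t1)
    full[t1:t1 + take] = adjusted[:take]
    return reconstruct_baseline(full, trace, params)


def reconstruct_on_grid(trace: MainAxisTrace, model: ARModel,
                        lp_cutoff: float, alpha: float | None) -> np.ndarray:
    """Buildup + forecast placed on the trace's grid, no peak adjustment.

    Used by lag selection and by the grid search before an adjuster exists.
    """
    buildup = extract_buildup(trace, lp_cutoff, alpha)
    pred = forecast(model, buildup)
    full = np.zeros_like(np.asarray(trace.values, dtype=float))
    t1 = buildup.start_index
    take = min(pred.size, full.size - t1)
    full[t1:t1 + take] = pred[:take]
    return full


def select_lag(train_series: np.ndarray,
               opt_pairs: list[tuple[MainAxisTrace, MainAxisTrace]],
               lags=LAG_GRID_DEFAULT, rate: float = 10_000.0,
               lp_cutoff: float = 200.0, tolerance: float = 0.02) -> int:
    """Pick the smallest lag whose mean reconstruction RMSE is near-optimal.

    For each candidate lag an AR model is fitted on the training series and
    run from each optimization helmet build-up (no spline extension); the
    mean RMSE against the paired headform traces forms the selection curve.
    The smallest lag within ``tolerance`` (relative) of the curve minimum is
    returned — the error plateaus beyond a direction-dependent onset and a
    short lag keeps the model cheap.
    """
    from .evaluation import rmse_trace

    lags = list(lags)
    if not lags:
        raise ValueError("empty lag grid")
    if not opt_pairs:
        raise ValueError("empty optimization set")
    curve = []
    for lag in lags:
        model = fit_ar(train_series, lag, rate=rate)
        errs = []
        for helmet, headform in opt_pairs:
            try:
                rec = reconstruct_on_grid(helmet, model, lp_cutoff, alpha=None)
                errs.append(rmse_trace(rec, np.asarray(headform.values), rate))
            except (ExtractionError, InstabilityError):
                errs.append(np.inf)
        curve.append(float(np.mean(errs)))
    curve = np.asarray(curve)
    best = curve.min()
    ok = np.flatnonzero(curve <= best * (1.0 + tolerance))
    return int(lags[int(ok[0])])
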