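"""Impulse error metrics, hyperparameter grid search and method comparison.

Metrics compare a reconstructed (or raw / low-pass filtered) helmet trace
with the paired headform reference:

* ``mape_peaks`` — mean absolute percentage error of pulse peaks,
* ``rmse_trace`` — RMSE over a 40 ms window centred on the pulse,
* ``mean_slope_error`` / ``duration_error`` — percentage errors of the
  rising-limb mean slope and of the 5%-to-5% pulse duration,
* ``error_score`` — the weighted slope/duration score minimized by the
  LP-cutoff x alpha grid search (peak error is excluded because the peak
  adjustment drives it to zero by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .direction import MainAxisTrace
from .signal_core import FilterSpec, lowpass_trace
from .transfer import (ARModel, PeakAdjuster, ReconstructionParams,
                       TransferConfig, adjust_peak, forecast, extract_buildup,
                       ExtractionError, InstabilityError, apply_transfer)

CUTOFF_GRID_HZ = (100.0, 200.0, 300.0, 400.0)
ALPHA_GRID = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
RMSE_WINDOW_MS = 40.0
ONSET_THRESH_G = 15.0


class MetricError(ValueError):
    pass


def _rising_segment(trace: np.ndarray) -> slice:
    """[first sample above 5% of peak, argmax] of a peak-positive trace."""
    v = np.asarray(trace, dtype=float)
    peak_idx = int(np.argmax(v))
    above = np.flatnonzero(v[:peak_idx + 1] > 0.05 * v[peak_idx])
    if not above.size or above[0] == peak_idx:
        raise MetricError("empty rising segment")
    return slice(int(above[0]), peak_idx + 1)


def mean_slope_error(pred: np.ndarray, ref: np.ndarray, rate: float) -> float:
    """Percentage error (vs reference) of the rising-limb mean slope, g/s."""
    slopes = []
    for v in (pred, ref):
        seg = np.asarray(v, dtype=float)[_rising_segment(v)]
        slopes.append(float(np.mean(np.diff(seg)) * rate))
    if slopes[1] == 0:
        raise MetricError("reference slope is zero")
    return abs(slopes[0] - slopes[1]) / abs(slopes[1]) * 100.0


def pulse_duration_s(trace: np.ndarray, rate: float) -> float:
    """Time for a peak-positive trace to exceed and return to 5% of its peak."""
    v = np.asarray(trace, dtype=float)
    peak_idx = int(np.argmax(v))
    thr = 0.05 * v[peak_idx]
    above = np.flatnonzero(v[:peak_idx + 1] > thr)
    if not above.size:
        raise MetricError("trace never exceeds 5% of its peak")
    start = int(above[0])
    post = np.flatnonzero(v[peak_idx:] < thr)
    if not post.size:
        raise MetricError("trace never returns to 5% of its peak")
    end = peak_idx + int(post[0])
    return (end - start) / rate


def duration_error(pred: np.ndarray, ref: np.ndarray, rate: float) -> float:
    """Absolute percentage error of the 5%-to-5% pulse duration."""
    dp = pulse_duration_s(pred, rate)
    dr = pulse_duration_s(ref, rate)
    return abs(dp - dr) / dr * 100.0


def error_score(pred: np.ndarray, ref: np.ndarray, rate: float,
                w1: float = 0.5, w2: float = 0.5) -> float:
    """Weighted slope/duration score: w1*MSE%/100 + w2*DE%/100."""
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative")
    return (w1 * mean_slope_error(pred, ref, rate) / 100.0
            + w2 * duration_error(pred, ref, rate) / 100.0)


def mape_peaks(preds: list[np.ndarray], refs: list[np.ndarray]) -> float:
    """Mean absolute percentage error of pulse peaks, reference denominators."""
    if len(preds) != len(refs) or not preds:
        raise ValueError("need equally many (>= 1) predictions and references")
    errs = []
    for p, r in zip(preds, refs):
        ref_peak = float(np.max(r))
        if ref_peak == 0:
            raise MetricError("zero reference peak")
        errs.append(abs(ref_peak - float(np.max(p))) / ref_peak)
    return 100.0 * float(np.mean(errs))


def _onset_index(trace: np.ndarray, thresh: float) -> int:
    above = np.flatnonzero(np.asarray(trace) >= thresh)
    return int(above[0]) if above.size else int(np.argmax(trace))


def rmse_trace(pred: np.ndarray, ref: np.ndarray, rate: float,
               window_ms: float = RMSE_WINDOW_MS,
               onset_thresh: float = ONSET_THRESH_G,
               align: str = "onset") -> float:
    """RMSE (g) over a 40 ms window around the pulse.

    With ``align='onset'`` (the default, for traces cut from different
    sensors' windows) each trace is aligned at its detected onset (first
    sample at or above ``onset_thresh``) and the window spans
    [onset - window/8, onset + 7*window/8], clipped to the traces.
    ``align='none'`` compares traces that already share a grid, windowed at
    the reference onset.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    w = int(round(window_ms / 1000.0 * rate))
    if min(p.size, r.size) < 2:
        raise MetricError("traces too short for the RMSE window")
    orf = _onset_index(r, onset_thresh)
    op = _onset_index(p, onset_thresh) if align == "onset" else orf
    pre = w // 8
    i0p, i0r = max(0, op - pre), max(0, orf - pre)
    n = min(w, p.size - i0p, r.size - i0r)
    if n < 2:
        raise MetricError("window does not fit inside the traces")
    d = p[i0p:i0p + n] - r[i0r:i0r + n]
    return float(np.sqrt(np.mean(d * d)))


# ---------------------------------------------------------------------------
# Dataset split and grid search
# ---------------------------------------------------------------------------

def split_dataset(n: int, fractions: tuple[float, float] = (0.50, 0.25),
                  seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded train/optimization/test index partition of ``n`` impacts.

    Counts are round(fraction * n) with the remainder going to test; the
    three sets are disjoint and exhaustive.
    """
    if sum(fractions) >= 1.0:
        raise ValueError("split fractions must sum to < 1")
    if n < 4:
        raise ValueError("need at least 4 impacts to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = round(fractions[0] * n)
    n_opt = round(fractions[1] * n)
    return (np.sort(perm[:n_train]), np.sort(perm[n_train:n_train + n_opt]),
            np.sort(perm[n_train + n_opt:]))


def grid_search(opt_pairs: list[tuple[MainAxisTrace, MainAxisTrace]],
                model: ARModel, adjuster: PeakAdjuster, group="default",
                cutoffs=CUTOFF_GRID_HZ, alphas=ALPHA_GRID,
                w1: float = 0.5, w2: float = 0.5,
                negate_delta: bool = False) -> tuple[TransferConfig, dict]:
    """Exhaustive LP-cutoff x alpha search minimizing the mean ErrorScore.

    Returns the winning :class:`TransferConfig` and the full score table
    ``{(cutoff, alpha): mean score}``.  Ties break toward the lower cutoff,
    then the lower alpha.
    """
    if not opt_pairs:
        raise ValueError("empty optimization set")
    table: dict = {}
    for cutoff in cutoffs:
        for alpha in alphas:
            scores = []
            for helmet, headform in opt_pairs:
                try:
                    buildup = extract_buildup(helmet, cutoff, alpha)
                    pred = forecast(model, buildup)
                    adj = adjust_peak(pred, adjuster, group=group,
                                      negate_delta=negate_delta)
                    scores.append(error_score(adj, np.asarray(headform.values),
                                              helmet.rate, w1, w2))
                except (ExtractionError, InstabilityError, MetricError, ValueError):
                    scores.append(np.inf)
            table[(cutoff, alpha)] = float(np.mean(scores))
    best = min(table, key=lambda k: (table[k], k[0], k[1]))
    if not np.isfinite(table[best]):
        raise RuntimeError("every grid cell failed")
    return TransferConfig(lp_cutoff=best[0], alpha=best[1], w1=w1, w2=w2,
                          negate_delta=negate_delta), table


# ---------------------------------------------------------------------------
# Raw / LP / transfer comparison
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Per-method MAPE and RMSE summary plus the per-impact breakdown."""

    mape: dict = field(default_factory=dict)          # method -> %
    rmse_mean: dict = field(default_factory=dict)     # method -> g
    rmse_iqr: dict = field(default_factory=dict)      # method -> g
    per_impact: list = field(default_factory=list)    # dicts, one per impact

    def to_dict(self) -> dict:
        return {"mape": self.mape, "rmse_mean": self.rmse_mean,
                "rmse_iqr": self.rmse_iqr, "per_impact": self.per_impact}


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def compare_methods(test_pairs: list[tuple[MainAxisTrace, MainAxisTrace]],
                    model: ARModel, adjuster: PeakAdjuster,
                    config: TransferConfig,
                    params: ReconstructionParams | None = None,
                    group="default") -> ErrorReport:
    """MAPE and RMSE of raw, LP-filtered and transfer-reconstructed traces.

    The LP variant filters the raw helmet trace at the configuration's
    optimal cutoff; all three are scored against the headform references.
    """
    report = ErrorReport()
    traces: dict[str, list[np.ndarray]] = {"raw": [], "lp": [], "transfer": []}
    refs: list[np.ndarray] = []
    rate = test_pairs[0][0].rate if test_pairs else 10_000.0
    for helmet, headform in test_pairs:
        raw = np.asarray(helmet.values, dtype=float)
        lp = lowpass_trace(raw, FilterSpec(cutoff=config.lp_cutoff, order=4), rate)
        tf = apply_transfer(helmet, model, adjuster, config, params, group=group)
        traces["raw"].append(raw)
        traces["lp"].append(lp)
        traces["transfer"].append(tf)
        refs.append(np.asarray(headform.values, dtype=float))
    for method, preds in traces.items():
        rmses = np.array([rmse_trace(p, r, rate) for p, r in zip(preds, refs)])
        report.mape[method] = mape_peaks(preds, refs)
        report.rmse_mean[method] = float(rmses.mean())
        report.rmse_iqr[method] = _iqr(rmses)
    for i, (h, r) in enumerate(zip(traces["transfer"], refs)):
        report.per_impact.append({
            "impact": i,
            "rmse_transfer_g": rmse_trace(h, r, rate),
            "peak_ref_g": float(np.max(r)),
            "peak_transfer_g": float(np.max(h)),
        })
    return report
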