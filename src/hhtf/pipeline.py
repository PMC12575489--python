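"""End-to-end orchestration: simulate -> detect -> direction -> train -> evaluate.

`run_pipeline` drives the whole chain on synthetic sessions and returns (and
optionally writes) a JSON-serializable results dictionary: detection counts,
direction-classification accuracy, the fitted AR models, per-configuration
grid-search winners and the raw / LP-filtered / transfer error comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import detection, direction, evaluation, synthetic, transfer
from .signal_core import WORKING_RATE_HZ, ImuRecording, resample

log = logging.getLogger("hhtf")


@dataclass
class ImpactPair:
    """One impact seen by both sensors, projected on its main direction."""

    location: str
    energy_j: float
    helmet_trace: direction.MainAxisTrace
    headform_trace: direction.MainAxisTrace
    helmet_region: str
    headform_region: str
    onset_s: float
    truth: dict | None = None


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    seed: int = 0
    locations: tuple = ("front", "front_oblique_R", "side_R", "rear_oblique_L")
    n_trials: int = 4          # per (location, energy) configuration
    gap_s: float = 2.0         # inter-impact gap of the demo protocol
    accel_thresh_g: float = detection.ACCEL_THRESH_G
    gyro_thresh_dps: float = detection.GYRO_THRESH_DPS
    pad_s: float = detection.PAD_S
    gyro_gate: str = "require_above"
    lag_mode: str = "fixed"    # 'fixed' (170 samples = 17 ms) or 'auto'
    lag: int = transfer.FIXED_LAG_SAMPLES
    fractions: tuple = (0.50, 0.25)
    negate_delta: bool = False
    out_dir: str | None = None
    scenario_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        valid = set(cls.__dataclass_fields__)
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("locations", "fractions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def pair_impacts(helmet: ImuRecording, headform: ImuRecording,
                 truth: synthetic.GroundTruth | None = None,
                 location: str | None = None, energy_j: float | None = None,
                 accel_thresh: float = detection.ACCEL_THRESH_G,
                 gyro_thresh: float = detection.GYRO_THRESH_DPS,
                 pad: float = detection.PAD_S,
                 gyro_gate: str = "require_above",
                 match_tol_s: float = 0.1) -> list[ImpactPair]:
    """Detect impacts on both sensors, match them in time and project them.

    The helmet recording is upsampled to the working rate first.  Segments
    whose core onsets agree within ``match_tol_s`` form a pair; each side's
    main direction is estimated independently and the padded windows are
    projected onto it.
    """
    helmet_up = resample(helmet, WORKING_RATE_HZ) if helmet.rate < WORKING_RATE_HZ else helmet
    segs_h = detection.detect_impacts(helmet_up, accel_thresh, gyro_thresh, pad,
                                      gyro_gate=gyro_gate)
    segs_r = detection.detect_impacts(headform, accel_thresh, gyro_thresh, pad,
                                      gyro_gate=gyro_gate)
    truth_onsets = [imp["onset_s"] for imp in truth.impacts] if truth else None
    pairs = []
    j = 0
    for sh in segs_h:
        t_h = sh.core_start / sh.rate
        while j < len(segs_r) and segs_r[j].core_start / segs_r[j].rate < t_h - match_tol_s:
            j += 1
        if j >= len(segs_r) or abs(segs_r[j].core_start / segs_r[j].rate - t_h) > match_tol_s:
            continue
        sr = segs_r[j]
        j += 1
        sh.location = sr.location = location
        sh.energy_j = sr.energy_j = energy_j
        dir_h = direction.estimate_direction(sh)
        dir_r = direction.estimate_direction(sr)
        tr_h = direction.project_main(sh, dir_h)
        tr_r = direction.project_main(sr, dir_r)
        entry = None
        if truth_onsets:
            k = int(np.argmin([abs(t - t_h) for t in truth_onsets]))
            if abs(truth_onsets[k] - t_h) < 1.0:
                entry = truth.impacts[k]
        pairs.append(ImpactPair(location=location or "unknown",
                                energy_j=energy_j if energy_j is not None else np.nan,
                                helmet_trace=tr_h, headform_trace=tr_r,
                                helmet_region=dir_h.region,
                                headform_region=dir_r.region,
                                onset_s=t_h, truth=entry))
    return pairs


def pairs_from_session_dir(session_dir: str | Path, location: str | None = None,
                           energy_j: float | None = None) -> list[ImpactPair]:
    """Pair the helmet.csv / headform.csv of a simulated (or recorded) session."""
    from .signal_core import read_recording

    d = Path(session_dir)
    helmet = read_recording(d / "helmet.csv", sensor="helmet", frame="FF")
    headform = read_recording(d / "headform.csv", sensor="headform", frame="FF")
    truth = None
    if (d / "truth.json").exists():
        t = json.loads((d / "truth.json").read_text())
        truth = synthetic.GroundTruth(impacts=t["impacts"],
                                      artifacts=t.get("artifacts", []),
                                      seed=t.get("seed", 0))
    return pair_impacts(helmet, headform, truth, location=location,
                        energy_j=energy_j)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain on the configured synthetic protocol.

    Per location: pool the impacts of both energies, split them 50/25/25
    into training/optimization/test, train the AR model on the concatenated
    headform training pulses, fit the peak adjuster per (location, energy),
    grid-search LP cutoff x alpha per (location, energy) and compare raw /
    LP / transfer errors on the test impacts.
    """
    rng = np.random.default_rng(config.seed)
    scenarios = synthetic.test_matrix_scenarios(
        locations=config.locations, n_trials=config.n_trials,
        gap_s=config.gap_s, seed=config.seed, **config.scenario_overrides)

    by_location: dict[str, list[ImpactPair]] = {}
    detection_counts: dict[str, dict] = {}
    region_hits = {"helmet": 0, "headform": 0, "total": 0}
    for sc in scenarios:
        log.info("simulating %s @ %.0f J: %d impacts", sc.location, sc.energy_j,
                 sc.n_impacts)
        helmet, headform, truth = synthetic.simulate_session(sc)
        pairs = pair_impacts(helmet, headform, truth, location=sc.location,
                             energy_j=sc.energy_j,
                             accel_thresh=config.accel_thresh_g,
                             gyro_thresh=config.gyro_thresh_dps,
                             pad=config.pad_s, gyro_gate=config.gyro_gate)
        key = f"{sc.location}_{sc.energy_j:.0f}J"
        detection_counts[key] = {"expected": sc.n_impacts, "detected": len(pairs)}
        for p in pairs:
            region_hits["total"] += 1
            region_hits["helmet"] += p.helmet_region == sc.location
            region_hits["headform"] += p.headform_region == sc.location
        by_location.setdefault(sc.location, []).extend(pairs)

    results: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "detection": detection_counts,
        "direction_accuracy": {
            s: region_hits[s] / region_hits["total"] if region_hits["total"] else np.nan
            for s in ("helmet", "headform")},
        "locations": {},
    }

    for loc, pairs in by_location.items():
        n = len(pairs)
        if n < 4:
            log.warning("skipping %s: only %d impacts", loc, n)
            continue
        tr_idx, opt_idx, test_idx = evaluation.split_dataset(
            n, config.fractions, seed=rng)
        train = [pairs[i] for i in tr_idx]
        opt = [pairs[i] for i in opt_idx]
        test = [pairs[i] for i in test_idx]

        series = transfer.concatenate_training(
            [p.headform_trace for p in train], seed=rng)
        if config.lag_mode == "auto":
            lag = transfer.select_lag(
                series, [(p.helmet_trace, p.headform_trace) for p in opt],
                rate=WORKING_RATE_HZ)
        else:
            lag = config.lag
        model = transfer.fit_ar(series, lag, rate=WORKING_RATE_HZ,
                                meta={"location": loc, "n_train": len(train),
                                      "seed": config.seed})
        log.info("%s: AR lag %d trained on %d impacts", loc, lag, len(train))

        # peak adjuster per (location, energy), fitted on training pairs
        groups = sorted({p.energy_j for p in train})
        preds, refs, keys = [], [], []
        for p in train:
            try:
                rec = transfer.reconstruct_on_grid(
                    p.helmet_trace, model, lp_cutoff=200.0, alpha=0.7)
            except (transfer.ExtractionError, transfer.InstabilityError):
                continue
            preds.append(rec)
            refs.append(np.asarray(p.headform_trace.values))
            keys.append(p.energy_j)
        adjuster = transfer.fit_peak_adjuster(preds, refs, keys)

        loc_result = {"lag": lag, "n_train": len(train), "n_opt": len(opt),
                      "n_test": len(test), "configs": {}, "errors": {}}
        for energy in groups:
            opt_pairs = [(p.helmet_trace, p.headform_trace)
                         for p in opt if p.energy_j == energy]
            test_pairs = [(p.helmet_trace, p.headform_trace)
                          for p in test if p.energy_j == energy]
            if not opt_pairs or not test_pairs or energy not in adjuster.lines:
                log.warning("%s @ %.0f J: split left a stage without impacts; "
                            "skipping this configuration", loc, energy)
                continue
            cfg, table = evaluation.grid_search(
                opt_pairs, model, adjuster, group=energy,
                negate_delta=config.negate_delta)
            report = evaluation.compare_methods(
                test_pairs, model, adjuster, cfg, group=energy)
            key = f"{energy:.0f}J"
            loc_result["configs"][key] = {"lp_cutoff_hz": cfg.lp_cutoff,
                                          "alpha": cfg.alpha,
                                          "error_score": table[(cfg.lp_cutoff, cfg.alpha)]}
            loc_result["errors"][key] = report.to_dict()
        results["locations"][loc] = loc_result
        results["models"] = results.get("models", {})
        results["models"][loc] = {"lag": lag, "intercept": model.intercept,
                                  "n_coef": model.lag}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(results, indent=2))
        log.info("report written to %s", out / "report.json")
    return results


def cross_helmet_comparison(location: str = "front", energy_j: float = 33.0,
                            severity: float = 2.0, n_trials: int = 8,
                            gap_s: float = 2.0, seed: int = 0) -> dict:
    """Train on the base helmet scenario, evaluate on an amplified-decoupling one.

    Mirrors swapping helmet models without retraining: the AR model, peak
    adjuster and grid-searched configuration are fitted on the base
    scenario's training/optimization splits, then scored both on the base
    test split and on a session whose decoupling is ``severity`` times
    stronger.  Returns the two MAPE/RMSE summaries.  ``n_trials`` defaults
    higher than the demo protocol because peak MAPE over a handful of
    impacts is dominated by single outliers.
    """
    sc = synthetic.ImpactScenario(location=location, energy_j=energy_j,
                                  n_trials=n_trials, gap_s=gap_s, seed=seed)
    helmet, headform, truth = synthetic.simulate_session(sc)
    pairs = pair_impacts(helmet, headform, truth, location=location,
                         energy_j=energy_j)
    rng = np.random.default_rng(seed)
    tr_idx, opt_idx, test_idx = evaluation.split_dataset(len(pairs), seed=rng)
    train = [pairs[i] for i in tr_idx]
    series = transfer.concatenate_training([p.headform_trace for p in train],
                                           seed=rng)
    model = transfer.fit_ar(series, transfer.FIXED_LAG_SAMPLES,
                            rate=WORKING_RATE_HZ)
    preds = [transfer.reconstruct_on_grid(p.helmet_trace, model, 200.0, 0.7)
             for p in train]
    refs = [np.asarray(p.headform_trace.values) for p in train]
    adjuster = transfer.fit_peak_adjuster(preds, refs)
    cfg, _ = evaluation.grid_search(
        [(pairs[i].helmet_trace, pairs[i].headform_trace) for i in opt_idx],
        model, adjuster)
    base_report = evaluation.compare_methods(
        [(pairs[i].helmet_trace, pairs[i].headform_trace) for i in test_idx],
        model, adjuster, cfg)

    alt_sc = synthetic.ImpactScenario(location=location, energy_j=energy_j,
                                      n_trials=n_trials, gap_s=gap_s,
                                      seed=seed + 1)
    a_helmet, a_headform, a_truth = synthetic.simulate_alternate_helmet(alt_sc, severity)
    alt_pairs = pair_impacts(a_helmet, a_headform, a_truth, location=location,
                             energy_j=energy_j)
    alt_report = evaluation.compare_methods(
        [(p.helmet_trace, p.headform_trace) for p in alt_pairs],
        model, adjuster, cfg)
    return {"severity": severity,
            "config": {"lp_cutoff_hz": cfg.lp_cutoff, "alpha": cfg.alpha},
            "n_base": len(test_idx), "n_alternate": len(alt_pairs),
            "base": {"mape": base_report.mape, "rmse_mean": base_report.rmse_mean},
            "alternate": {"mape": alt_report.mape, "rmse_mean": alt_report.rmse_mean}}


def direction_rmse_summary(results: dict) -> dict:
    """Per-direction mean RMSE of raw / LP / transfer, pooled over energies."""
    summary = {}
    for loc, res in results.get("locations", {}).items():
        pooled = {"raw": [], "lp": [], "transfer": []}
        weights = []
        for rep in res.get("errors", {}).values():
            n = len(rep["per_impact"])
            weights.append(n)
            for m in pooled:
                pooled[m].append(rep["rmse_mean"][m] * n)
        total = sum(weights)
        if total:
            summary[loc] = {m: sum(v) / total for m, v in pooled.items()}
    return summary
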