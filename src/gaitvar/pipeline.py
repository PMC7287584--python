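"""End-to-end orchestration: sessions, outcomes, entropy, reliability report.

A session (one 3-min walk, simulated or loaded from CSV) is pushed through
the three detection chains:

* force plate  → heel-strikes → right strides (step 1),
* ankle IMU    → HS/TO pairing → strides (step 1), matched to force strides,
* waist IMU    → Madgwick vertical acceleration → wavelet heel-strikes,
  matched to force heel-strikes → strides (step 2),

each stride set passes the 1.25 median-ratio filter before outcomes
(mean/SD/CV of stride duration) are reported, and the waist resultant
acceleration is analysed for RCME/RMPE over 1-min epochs.  Reported IMU
outcomes rely on matching to the concurrent force plate (as in the
validation protocol); ``standalone=True`` skips the matching for field use
without a force plate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .agreement import PairedSample, agreement_battery, scale_correlations
from .entropy import DEFAULT_SCALES, session_entropy, split_epochs
from .events import HS, EventSeries
from .forceplate import detect_force_heelstrikes, right_strides
from .imu_events import detect_ankle_events, detect_waist_heelstrikes, pair_ankle_events, ricker_kernel
from .kinematics import ScalarSeries, madgwick_orientation, resultant_acceleration, vertical_acceleration
from .signal_io import ForcePlateRecording, ImuRecording, read_forceplate, read_imu
from .strides import GaitOutcomes, StrideSeries, build_strides, gait_outcomes, match_events, median_ratio_filter
from .synthetic import GaitSimParams, generate_stride_plan, simulate_session

__all__ = ["SessionConfig", "SessionResult", "run_session", "run_reliability",
           "simulate_cohort_outcomes", "waist_vertical"]

logger = logging.getLogger(__name__)

MADGWICK_RUNIN_S = 5.0


@dataclass
class SessionConfig:
    """Inputs and analysis parameters for one session.

    Provide either ``simulate`` (generator parameters) or file paths plus
    ``body_mass_kg``.  Omitted inputs simply leave the corresponding fields
    out of the result.
    """

    simulate: GaitSimParams | None = None
    force_path: str | None = None
    waist_path: str | None = None
    ankle_path: str | None = None
    body_mass_kg: float | None = None
    use_force: bool = True
    use_waist: bool = True
    use_ankle: bool = True
    wavelet_hz: float = 16.0
    beta: float = 0.1
    epoch_s: float = 60.0
    scales: tuple = DEFAULT_SCALES
    entropy_m: int = 4
    entropy_r_frac: float = 0.3
    match_tol_s: float = 0.2
    median_ratio: float = 1.25
    sagittal_axis: int = 1
    sagittal_sign: float = 1.0
    min_swing_dps: float = 100.0
    right_fy_positive: bool = True
    standalone: bool = False
    compute_entropy: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        d["scales"] = list(self.scales)
        return d


@dataclass
class SessionResult:
    """Per-source outcomes, entropy profiles and provenance of one session."""

    outcomes: dict
    entropy: dict
    counts: dict
    provenance: dict

    def to_dict(self) -> dict:
        out = {
            "outcomes": {
                src: dataclasses.asdict(o) for src, o in self.outcomes.items()
            },
            "entropy": {
                kind: {
                    "scales": prof.scales.tolist(),
                    "values": prof.values.tolist(),
                    "n_epochs_averaged": prof.n_epochs_averaged,
                }
                for kind, prof in self.entropy.items()
            },
            "counts": self.counts,
            "provenance": self.provenance,
        }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_inputs(config: SessionConfig):
    if config.simulate is not None:
        force, waist, ankle, _truth = simulate_session(config.simulate)
    else:
        force = waist = ankle = None
        if config.force_path:
            if config.body_mass_kg is None:
                raise ValueError("body_mass_kg required to read a force-plate file")
            force = read_forceplate(config.force_path, config.body_mass_kg)
        if config.waist_path:
            waist = read_imu(config.waist_path, "waist")
        if config.ankle_path:
            ankle = read_imu(config.ankle_path, "ankle")
    if not config.use_force:
        force = None
    if not config.use_waist:
        waist = None
    if not config.use_ankle:
        ankle = None
    return force, waist, ankle


def waist_vertical(imu: ImuRecording, beta: float = 0.1) -> ScalarSeries:
    """Earth-frame vertical acceleration with a convergence warm start.

    The filter first runs over the opening seconds of the stream and its
    final quaternion seeds the full pass, so initial-alignment transients do
    not leak into event detection.
    """
    n_runin = min(int(MADGWICK_RUNIN_S * imu.sample_rate), len(imu))
    init = None
    if n_runin > 1:
        warm = ImuRecording(
            t=imu.t[:n_runin], acc=imu.acc[:n_runin], gyr=imu.gyr[:n_runin],
            placement=imu.placement, sample_rate=imu.sample_rate,
        )
        init = madgwick_orientation(warm, beta=beta).q[-1]
    orientation = madgwick_orientation(imu, beta=beta, init=init)
    return vertical_acceleration(imu, orientation)


def _outcome(series: StrideSeries, config: SessionConfig) -> tuple[GaitOutcomes, StrideSeries]:
    filtered = median_ratio_filter(series, ratio=config.median_ratio)
    return gait_outcomes(filtered), filtered


def run_session(config: SessionConfig) -> SessionResult:
    """Run every available detection chain and assemble the session result."""
    force, waist, ankle = _load_inputs(config)
    outcomes: dict = {}
    entropy: dict = {}
    counts: dict = {}

    force_events = None
    force_strides = None
    if force is not None and len(force) > 1:
        force_events = detect_force_heelstrikes(
            force, right_fy_positive=config.right_fy_positive
        )
        counts["force_heelstrikes"] = len(force_events)
        raw = right_strides(force_events)
        counts["force_strides_raw"] = len(raw)
        if len(raw) >= 2:
            outcomes["force"], force_strides = _outcome(raw, config)
            counts["force_strides"] = len(force_strides)
        logger.info("force chain: %d HS, %d raw strides", len(force_events), len(raw))

    if ankle is not None and len(ankle) > 1:
        gyro_sag = ScalarSeries(
            config.sagittal_sign * ankle.gyr[:, config.sagittal_axis],
            ankle.sample_rate, "sagittal_gyro_dps", float(ankle.t[0]),
        )
        ev = pair_ankle_events(
            detect_ankle_events(gyro_sag, min_swing_dps=config.min_swing_dps)
        )
        counts["ankle_events"] = len(ev)
        raw = build_strides(ev.select(label=HS), step=1, source="ankle")
        counts["ankle_strides_raw"] = len(raw)
        filtered = median_ratio_filter(raw, ratio=config.median_ratio)
        if not config.standalone and force_strides is not None:
            pairs = match_events(force_strides.start_times, filtered.start_times,
                                 tol_s=config.match_tol_s)
            matched = np.isin(filtered.start_times, [c for _, c in pairs])
            filtered = StrideSeries(filtered.start_times[matched],
                                    filtered.durations_ms[matched], "ankle")
        counts["ankle_strides"] = len(filtered)
        if len(filtered) >= 2:
            outcomes["ankle"] = gait_outcomes(filtered)
        logger.info("ankle chain: %d events, %d strides kept", len(ev), len(filtered))

    if waist is not None and len(waist) > 1:
        vacc = waist_vertical(waist, beta=config.beta)
        kernel = ricker_kernel(config.wavelet_hz, waist.sample_rate)
        hs = detect_waist_heelstrikes(vacc, kernel)
        counts["waist_heelstrikes"] = len(hs)
        hs_times = hs.times
        if not config.standalone and force_events is not None:
            pairs = match_events(force_events.times, hs_times, tol_s=config.match_tol_s)
            hs_times = np.asarray(sorted(c for _, c in pairs))
        raw = build_strides(hs_times, step=2, source="waist")
        counts["waist_strides_raw"] = len(raw)
        if len(raw) >= 2:
            outcomes["waist"], filtered = _outcome(raw, config)
            counts["waist_strides"] = len(filtered)
        logger.info("waist chain: %d HS, %d raw strides", len(hs), len(raw))

        if config.compute_entropy:
            resultant = resultant_acceleration(waist)
            epochs = split_epochs(resultant, epoch_s=config.epoch_s)
            counts["entropy_epochs"] = len(epochs)
            if len(epochs) > 0:
                entropy["RCME"] = session_entropy(
                    epochs, "RCME", m=config.entropy_m,
                    r_frac=config.entropy_r_frac, scales=config.scales,
                )
                entropy["RMPE"] = session_entropy(
                    epochs, "RMPE", m=config.entropy_m, scales=config.scales,
                )

    provenance = {"config": config.to_dict(), "gaitvar_version": _version}
    return SessionResult(outcomes=outcomes, entropy=entropy, counts=counts,
                         provenance=provenance)


def _outcome_frame(results: list[SessionResult]) -> pd.DataFrame:
    rows = []
    for i, res in enumerate(results):
        for src, o in res.outcomes.items():
            rows.append({"subject": i, "source": src, "mean_ms": o.mean_ms,
                         "sd_ms": o.sd_ms, "cv_pct": o.cv_pct})
    return pd.DataFrame(rows)


def run_reliability(
    session1: list[SessionResult],
    session2: list[SessionResult],
) -> dict:
    """Test–retest agreement battery across a cohort of paired sessions.

    Both lists must cover the same subjects in the same order.  Returns a
    report with per-outcome (mean/SD/CV per source) reliability statistics,
    per-scale entropy reliability, and the correlation of each entropy scale
    with the force-plate stride-duration SD of session 1.
    """
    if len(session1) != len(session2):
        raise ValueError("session lists must cover the same subjects")
    f1 = _outcome_frame(session1)
    f2 = _outcome_frame(session2)
    report: dict = {"n_subjects": len(session1), "outcomes": {}, "entropy": {}}

    for src in sorted(set(f1["source"]) & set(f2["source"])):
        for metric in ("mean_ms", "sd_ms", "cv_pct"):
            a = f1.loc[f1.source == src, metric].to_numpy()
            b = f2.loc[f2.source == src, metric].to_numpy()
            if len(a) != len(b) or len(a) < 3:
                continue
            res = agreement_battery(PairedSample(a, b))
            report["outcomes"][f"{src}.{metric}"] = dataclasses.asdict(res)

    for kind in ("RCME", "RMPE"):
        prof1 = [r.entropy.get(kind) for r in session1]
        prof2 = [r.entropy.get(kind) for r in session2]
        if any(p is None for p in prof1 + prof2):
            continue
        scales = prof1[0].scales
        per_scale = []
        for j, scale in enumerate(scales):
            a = np.array([p.values[j] for p in prof1])
            b = np.array([p.values[j] for p in prof2])
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                per_scale.append({"scale": int(scale), "icc": float("nan")})
                continue
            res = agreement_battery(PairedSample(a[ok], b[ok]))
            per_scale.append({"scale": int(scale), **dataclasses.asdict(res)})
        report["entropy"][kind] = per_scale

    # congruence: session-1 entropy per scale vs force stride-duration SD
    ref = np.array([
        r.outcomes["force"].sd_ms if "force" in r.outcomes else np.nan
        for r in session1
    ])
    for kind in ("RCME", "RMPE"):
        profs = [r.entropy.get(kind) for r in session1]
        if any(p is None for p in profs) or not np.isfinite(ref).sum() >= 3:
            continue
        mat = np.vstack([p.values for p in profs])
        corr = scale_correlations(
            pd.DataFrame(mat, columns=list(profs[0].scales)), ref
        )
        report[f"congruence_{kind.lower()}"] = corr.to_dict(orient="list")
    return report


def simulate_cohort_outcomes(
    n_subjects: int = 27,
    n_sessions: int = 2,
    seed: int = 0,
    mean_center_ms: float = 1040.0,
    between_mean_sd_ms: float = 100.0,
    sd_center_ms: float = 19.6,
    between_sd_sd_ms: float = 7.5,
    session_sd_jitter_ms: float = 0.0,
    subject_effects: bool = True,
    duration_s: float = 180.0,
) -> pd.DataFrame:
    """Cohort of simulated stride plans and their true-stride outcomes.

    Each subject carries persistent gait traits (mean stride duration and
    stride-duration SD drawn from the cohort distributions); each session
    re-samples the walk.  ``subject_effects=False`` redraws the traits every
    session (exchangeable sessions, zero expected ICC);
    ``session_sd_jitter_ms`` adds week-to-week wobble to the SD trait.
    Outcomes are computed from the plan's true stride durations, bypassing
    signal synthesis, so large cohorts stay cheap.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    rows = []
    for i in range(n_subjects):
        mean_i = rng.normal(mean_center_ms, between_mean_sd_ms)
        sd_i = max(rng.normal(sd_center_ms, between_sd_sd_ms), 3.0)
        for s in range(n_sessions):
            if not subject_effects:
                mean_is = rng.normal(mean_center_ms, between_mean_sd_ms)
                sd_is = max(rng.normal(sd_center_ms, between_sd_sd_ms), 3.0)
            else:
                mean_is = mean_i
                sd_is = max(sd_i + rng.normal(0.0, session_sd_jitter_ms), 3.0)
            params = GaitSimParams(
                mean_stride_ms=float(mean_is),
                stride_sd_ms=float(sd_is),
                duration_s=duration_s,
                seed=int(rng.integers(2**31 - 1)),
            )
            truth = generate_stride_plan(params)
            durations = truth.stride_durations_ms
            o = gait_outcomes(StrideSeries(truth.right_hs[:-1], durations, "plan"))
            rows.append({
                "subject": i, "session": s, "true_mean_ms": mean_is,
                "true_sd_ms": sd_is, "n_strides": o.n_strides,
                "mean_ms": o.mean_ms, "sd_ms": o.sd_ms, "cv_pct": o.cv_pct,
            })
    return pd.DataFrame(rows)
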