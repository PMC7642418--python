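"""End-to-end synthetic study harness.

Ties the whole pipeline together the way the clinical validation was run:

1. train the general network on a simulated training cohort (per-beat
   features from full signal processing, targets from manual readings);
2. for each study subject, take 3 calibration pairs and fit per-subject
   correction terms;
3. run the 7-measurement protocol session, estimate each watch measurement
   with the calibrated model, pair against the closest manual readings and
   compute the validation report.

The watch's *reading* is the pipeline estimate plus the subject's
systematic device bias (default 0) plus per-measurement device noise
(default sd 6 mmHg) — the catch-all for everything a real sensing chain
adds that the idealized signal model does not.  Because the noise enters
at the reading level, the error of the offset-calibrated device has a
closed form (see :func:`expected_within_pct`) against which the simulated
study can be checked.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import CalibrationPair, CalibrationTerms, fit_calibration
from .model import (
    BPNetwork,
    BPNetworkResults,
    GeneralModel,
    TrainConfig,
    extract_measurement_features,
)
from .sim import simulate_cohort, simulate_recording, simulate_subject_session
from .types import CohortSpec, NoiseConfig, SubjectProfile
from .validation import ValidationReport, build_report, pair_readings

__all__ = [
    "StudyResult",
    "make_training_data",
    "train_study_model",
    "run_validation_study",
    "expected_within_pct",
    "model_within_subject_residual_sd",
    "DEFAULT_DEVICE_NOISE_SD",
    "DEFAULT_OBSERVER_SD",
]

DEFAULT_DEVICE_NOISE_SD = 6.0  # mmHg, per watch measurement
DEFAULT_OBSERVER_SD = 2.0      # mmHg, per human observer
_FS = 250.0
_DURATION = 24.0


def _seed_for(root: np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root.entropy, spawn_key=key)


def make_training_data(
    n_subjects: int = 40,
    n_measurements: int = 3,
    seed: int = 0,
    noise: Optional[NoiseConfig] = None,
    observer_sd: float = DEFAULT_OBSERVER_SD,
    cohort_kwargs: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Simulated manufacturer training set, built through the full signal
    chain: per-beat features with the paired manual reading as target.

    Returns ``(X, y, groups)``; QC-rejected measurements are simply absent,
    as they would be from a curated training dataset.
    """
    noise = noise if noise is not None else NoiseConfig()
    spec = CohortSpec(n_subjects=n_subjects, seed=seed, **(cohort_kwargs or {}))
    profiles = simulate_cohort(spec)
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(_seed_for(root, 0))
    X_parts, y_parts, groups = [], [], []
    for si, prof in enumerate(profiles):
        for mi in range(n_measurements):
            rec = simulate_recording(
                prof, fs=_FS, duration=_DURATION, noise=noise,
                seed=_seed_for(root, 1, si, mi),
            )
            table, qc = extract_measurement_features(rec, prof)
            if table is None:
                continue
            from .sim import simulate_manual_reading

            man_sbp, man_dbp = simulate_manual_reading(
                rng, prof.true_sbp, prof.true_dbp, observer_sd
            )
            X_parts.append(table)
            y_parts.append(
                pd.DataFrame(
                    {"sbp": [man_sbp] * len(table), "dbp": [man_dbp] * len(table)}
                )
            )
            groups.extend([prof.subject_id] * len(table))
    X = pd.concat(X_parts, ignore_index=True)
    y = pd.concat(y_parts, ignore_index=True)
    return X, y, np.array(groups)


def train_study_model(
    seed: int = 0,
    n_subjects: int = 40,
    n_measurements: int = 3,
    config: Optional[TrainConfig] = None,
    screen: bool = True,
) -> BPNetworkResults:
    """Train the general model on a simulated training cohort.

    ``config`` defaults to a compact search (1-2 layers x 16 nodes, relu,
    3-fold) adequate for the synthetic coupling; pass a full
    :class:`TrainConfig` to sweep the complete space.
    """
    X, y, groups = make_training_data(
        n_subjects=n_subjects, n_measurements=n_measurements, seed=seed
    )
    if screen:
        from .screen import screen_features

        _, mask, _ = screen_features(X)
        X, y, groups = X.loc[mask], y.loc[mask], groups[mask]
    cfg = config if config is not None else TrainConfig(
        layer_options=(1, 2),
        node_options=(16,),
        activation_options=("relu",),
        cv_folds=3,
        max_epochs=400,
        seed=seed,
    )
    return BPNetwork(X, y, groups).fit(cfg)


@dataclass
class StudyResult:
    """Everything a synthetic validation study produces."""

    report: ValidationReport
    diffs_sbp_vs_truth: np.ndarray
    diffs_dbp_vs_truth: np.ndarray
    est_sbp: np.ndarray
    true_sbp: np.ndarray
    r_sbp_vs_truth: float
    pct10_vs_truth: float
    n_qc_retries: int
    terms: dict = field(default_factory=dict)
    # Offset-shifted subjects: per-subject mean error before/after calibration
    pre_cal_bias: np.ndarray = field(default_factory=lambda: np.array([]))
    post_cal_bias: np.ndarray = field(default_factory=lambda: np.array([]))
    pre_cal_mae: np.ndarray = field(default_factory=lambda: np.array([]))
    post_cal_mae: np.ndarray = field(default_factory=lambda: np.array([]))


def _device_reading(
    model: GeneralModel,
    profile: SubjectProfile,
    recording,
    rng: np.random.Generator,
    device_noise_sd: float,
) -> Optional[tuple[float, float, np.ndarray]]:
    """Uncalibrated watch reading: pipeline estimate + bias + device noise."""
    from .model import estimate_measurement

    est = estimate_measurement(model, recording, profile)
    if not est.ok:
        return None
    sbp = est.sbp + profile.device_bias + device_noise_sd * rng.standard_normal()
    dbp = est.dbp + 0.5 * profile.device_bias + device_noise_sd * 0.7 * rng.standard_normal()
    return sbp, dbp, est.hidden_mean


def run_validation_study(
    model: GeneralModel,
    n_subjects: int = 35,
    seed: int = 1000,
    device_noise_sd: float = DEFAULT_DEVICE_NOISE_SD,
    observer_sd: float = DEFAULT_OBSERVER_SD,
    n_offset_subjects: int = 0,
    offset_mmhg: float = 8.0,
    n_holdout_measurements: int = 10,
    noise: Optional[NoiseConfig] = None,
    ridge_lambda: Optional[float] = None,
) -> StudyResult:
    """Simulate the full 35-subject validation protocol against ``model``.

    Each subject is calibrated on 3 (manual, watch) pairs, then measured in
    the alternating 7-event sequence; watch estimates are calibrated,
    paired with the closest manual reference and aggregated into the
    validation report.  The first ``n_offset_subjects`` subjects carry an
    extra systematic device bias of ``offset_mmhg`` and are additionally
    given ``n_holdout_measurements`` extra watch measurements to quantify
    how much calibration reduces their bias.

    A QC-rejected watch measurement is re-measured (fresh simulated
    recording), as the clinical protocol would.
    """
    from .calibration import DEFAULT_RIDGE_LAMBDA, apply_calibration_values

    lam = DEFAULT_RIDGE_LAMBDA if ridge_lambda is None else ridge_lambda
    noise = noise if noise is not None else NoiseConfig()
    spec = CohortSpec(n_subjects=n_subjects, seed=seed + 17)
    profiles = simulate_cohort(spec)
    profiles = [
        replace(p, device_bias=offset_mmhg) if i < n_offset_subjects else p
        for i, p in enumerate(profiles)
    ]
    root = np.random.SeedSequence(seed)
    noise_rng = np.random.default_rng(_seed_for(root, 90))

    all_pairs = []
    diffs_s, diffs_d, est_s, truth_s = [], [], [], []
    pre_bias, post_bias, pre_mae, post_mae = [], [], [], []
    terms_by_subject: dict[str, CalibrationTerms] = {}
    n_retries = 0

    for si, prof in enumerate(profiles):
        session = simulate_subject_session(
            prof, seed=_seed_for(root, 2, si), noise=noise, observer_sd=observer_sd
        )
        # --- calibration ---
        cal_pairs = []
        for manual_ev, watch_ev in session.calibration:
            reading = _device_reading(
                model, prof, watch_ev.recording, noise_rng, device_noise_sd
            )
            retry = 0
            while reading is None and retry < 3:
                n_retries += 1
                retry += 1
                rec = simulate_recording(
                    prof, fs=_FS, duration=_DURATION, noise=noise,
                    seed=_seed_for(root, 3, si, retry),
                )
                reading = _device_reading(model, prof, rec, noise_rng, device_noise_sd)
            if reading is None:
                continue
            sbp_u, dbp_u, hidden = reading
            cal_pairs.append(
                CalibrationPair(
                    device_sbp=sbp_u, device_dbp=dbp_u,
                    manual_sbp=manual_ev.sbp, manual_dbp=manual_ev.dbp,
                    timestamp=watch_ev.t_s, hidden=hidden,
                )
            )
        terms = fit_calibration(model, cal_pairs, ridge_lambda=lam)
        terms_by_subject[prof.subject_id] = terms

        # --- primary 7-event sequence ---
        for ev in session.events:
            if ev.kind != "watch":
                continue
            reading = _device_reading(
                model, prof, ev.recording, noise_rng, device_noise_sd
            )
            retry = 0
            while reading is None and retry < 3:
                n_retries += 1
                retry += 1
                rec = simulate_recording(
                    prof, fs=_FS, duration=_DURATION, noise=noise,
                    seed=_seed_for(root, 4, si, retry),
                )
                reading = _device_reading(model, prof, rec, noise_rng, device_noise_sd)
            if reading is None:
                raise RuntimeError(
                    f"subject {prof.subject_id}: watch measurement failed QC repeatedly"
                )
            sbp_u, dbp_u, _ = reading
            sbp_c, dbp_c = apply_calibration_values(model, terms, sbp_u, dbp_u)
            ev.sbp, ev.dbp = sbp_c, dbp_c
            diffs_s.append(sbp_c - prof.true_sbp)
            diffs_d.append(dbp_c - prof.true_dbp)
            est_s.append(sbp_c)
            truth_s.append(prof.true_sbp)
        all_pairs.extend(pair_readings(session.events, subject_id=prof.subject_id))

        # --- held-out measurements for offset-shifted subjects ---
        if si < n_offset_subjects and n_holdout_measurements > 0:
            pre_errs, post_errs = [], []
            for mi in range(n_holdout_measurements):
                rec = simulate_recording(
                    prof, fs=_FS, duration=_DURATION, noise=noise,
                    seed=_seed_for(root, 5, si, mi),
                )
                reading = _device_reading(model, prof, rec, noise_rng, device_noise_sd)
                if reading is None:
                    continue
                sbp_u, _, _ = reading
                sbp_c, _ = apply_calibration_values(model, terms, sbp_u, 0.0)
                pre_errs.append(sbp_u - prof.true_sbp)
                post_errs.append(sbp_c - prof.true_sbp)
            if pre_errs:
                pre_errs, post_errs = np.array(pre_errs), np.array(post_errs)
                pre_bias.append(pre_errs.mean())
                post_bias.append(post_errs.mean())
                pre_mae.append(np.abs(pre_errs).mean())
                post_mae.append(np.abs(post_errs).mean())

    diffs_s = np.array(diffs_s)
    diffs_d = np.array(diffs_d)
    est_s = np.array(est_s)
    truth_s = np.array(truth_s)
    r = float(np.corrcoef(est_s, truth_s)[0, 1])
    report = build_report(all_pairs, n_total_subjects=n_subjects)
    return StudyResult(
        report=report,
        diffs_sbp_vs_truth=diffs_s,
        diffs_dbp_vs_truth=diffs_d,
        est_sbp=est_s,
        true_sbp=truth_s,
        r_sbp_vs_truth=r,
        pct10_vs_truth=float(100.0 * np.mean(np.abs(diffs_s) <= 10.0)),
        n_qc_retries=n_retries,
        terms=terms_by_subject,
        pre_cal_bias=np.array(pre_bias),
        post_cal_bias=np.array(post_bias),
        pre_cal_mae=np.array(pre_mae),
        post_cal_mae=np.array(post_mae),
    )


def expected_within_pct(
    threshold: float = 10.0,
    device_noise_sd: float = DEFAULT_DEVICE_NOISE_SD,
    observer_sd: float = DEFAULT_OBSERVER_SD,
    n_calibration_pairs: int = 3,
    ridge_lambda: Optional[float] = None,
    model_residual_sd: float = 0.0,
) -> float:
    """Closed-form expectation of the within-threshold percentage for the
    offset-calibrated device, versus true BP.

    Error model: with constant true BP T across a session, the uncalibrated
    reading of measurement j is ``T + b + w_j`` (b: subject bias, w_j:
    device noise plus within-subject model residual, sd ``s_w``), and each
    manual reading errs with sd ``s_m = observer_sd/sqrt(2)`` (two-observer
    mean).  Calibration on n pairs gives gain g (ridge-shrunk; expected
    value ``g* = lambda / (lambda + (n-1) s_w^2)`` since the pairs carry no
    true BP spread) and offset ``o = mean(manual) - g*mean(device)``, so a
    new calibrated reading errs by ``g*(w_new - mean(w_cal)) + mean(e_man)``:

        sigma_eff^2 = g*^2 s_w^2 (1 + 1/n) + s_m^2 / n
        expected pct = 100 * (2 Phi(threshold / sigma_eff) - 1)

    The subject bias b cancels exactly — that is what calibration is for.
    """
    from .calibration import DEFAULT_RIDGE_LAMBDA

    lam = DEFAULT_RIDGE_LAMBDA if ridge_lambda is None else ridge_lambda
    s_w2 = device_noise_sd**2 + model_residual_sd**2
    s_m2 = observer_sd**2 / 2.0
    n = n_calibration_pairs
    g = lam / (lam + (n - 1) * s_w2)
    sigma_eff = np.sqrt(g**2 * s_w2 * (1.0 + 1.0 / n) + s_m2 / n)
    return float(100.0 * (2.0 * norm.cdf(threshold / sigma_eff) - 1.0))


def model_within_subject_residual_sd(
    model: GeneralModel,
    n_subjects: int = 8,
    n_measurements: int = 4,
    seed: int = 77,
) -> float:
    """Empirical within-subject sd of the *pipeline's own* estimate error,
    with no injected device noise: fresh subjects, repeated clean-ish
    measurements, uncalibrated estimates, deviations from each subject's
    mean pooled with the proper degrees of freedom."""
    from .model import estimate_measurement

    spec = CohortSpec(n_subjects=n_subjects, seed=seed + 5)
    profiles = simulate_cohort(spec)
    root = np.random.SeedSequence(seed)
    ss_total, df_total = 0.0, 0
    for si, prof in enumerate(profiles):
        errs = []
        for mi in range(n_measurements):
            rec = simulate_recording(
                prof, seed=_seed_for(root, 6, si, mi)
            )
            est = estimate_measurement(model, rec, prof)
            if est.ok:
                errs.append(est.sbp - prof.true_sbp)
        if len(errs) >= 2:
            errs = np.array(errs)
            ss_total += float(((errs - errs.mean()) ** 2).sum())
            df_total += len(errs) - 1
    if df_total == 0:
        raise RuntimeError("no repeated measurements survived QC")
    return float(np.sqrt(ss_total / df_total))
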