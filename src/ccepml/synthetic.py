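"""Synthetic CCEP cohorts with known ground truth.

The study's patient recordings are not public, so this module generates
EDF cohorts that emulate their structure: 26 patients with 2–16 averaged
stimulation tests each, 8 or 16 ECoG channels at 25 kHz over a 300 ms
post-stimulus epoch, one responding channel carrying Gaussian-shaped evoked
deflections (an early N1-like trough and later positive waves, each with
patient-specific amplitude and latency), a decaying stimulus artifact in
the first milliseconds, additive noise, and strong within-patient repeat
similarity. The binary outcome (postoperative speech deterioration) is
drawn per patient from a logistic model on the patient's standardized peak
amplitude and latency, with the intercept calibrated to a target
prevalence — so recovery of the effect by the downstream pipeline can be
measured against a known effect size.

The evoked morphology is deliberately simple: the pipeline consumes only
amplitudes and latencies, so Gaussian bumps suffice; no biophysics of
cortical connectivity is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_edf import (MANIFEST_COLUMNS, EcogEpoch, LabelledTest,
                     standardize_channels, write_epoch_file)

__all__ = ["SyntheticCohortSpec", "generate_epoch", "generate_tests",
           "generate_cohort", "recovery_report"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Ground-truth parameters of a simulated cohort.

    Morphology defaults follow typical intraoperative CCEP reports: an
    early negative deflection near 30 ms, a dominant positive wave near
    80 ms (≈30 μV between patients), and optional later waves. Cohort
    structure defaults mirror the study: 26 patients, 2–16 pre-resection
    tests each, half of which survive quality screening. ``effect_amp`` /
    ``effect_latency`` are logistic coefficients on the *standardized*
    patient-level peak amplitude and latency; the intercept is calibrated
    so the expected patient prevalence of deterioration equals
    ``prevalence``.
    """

    n_patients: int = 26
    tests_per_patient: tuple[int, int] = (2, 16)
    channel_counts: tuple[int, ...] = (8, 16)
    sampling_rate: float = 25_000.0
    epoch_ms: float = 300.0

    # patient-level (between-patient) morphology
    peak1_latency_mean: float = 80.0   # ms
    peak1_latency_sd: float = 15.0
    peak1_amp_mean: float = 30.0       # μV
    peak1_amp_sd: float = 10.0
    peak2_prob: float = 0.6            # later positive wave, ~0.6 × peak1
    trough1_prob: float = 0.8          # early N1-like negativity
    trough1_latency_mean: float = 35.0
    trough1_latency_sd: float = 8.0
    trough1_amp_mean: float = 18.0     # magnitude, μV
    trough1_amp_sd: float = 6.0
    trough2_prob: float = 0.4
    bump_width_ms: float = 9.0         # Gaussian sd of each deflection

    artifact_amp: float = 60.0         # μV at t=0 on every channel
    artifact_decay_ms: float = 3.0
    noise_sd: float = 2.0              # μV additive white noise, all channels
    within_patient_sd: float = 0.3     # fraction of the between-patient sd

    effect_amp: float = 2.0
    effect_latency: float = 0.0
    prevalence: float = 0.6
    quality_pass_rate: float = 0.5     # screening survival, ≈105/216
    include_post_phase: bool = False   # post-resection files exist unanalyzed
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tests_per_patient
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid tests_per_patient range ({lo}, {hi})")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.within_patient_sd > 1:
            raise ValueError("within_patient_sd is a fraction of the "
                             "between-patient sd and must be <= 1")
        if self.peak1_amp_mean <= 0 or self.trough1_amp_mean <= 0:
            raise ValueError("deflection amplitudes must be positive")


def _draw_patients(spec: SyntheticCohortSpec, rng: np.random.Generator
                   ) -> list[dict]:
    """Patient-level latent morphology and outcome probabilities."""
    n = spec.n_patients
    amp = np.maximum(rng.normal(spec.peak1_amp_mean, spec.peak1_amp_sd, n), 6.0)
    lat = np.clip(rng.normal(spec.peak1_latency_mean, spec.peak1_latency_sd, n),
                  40.0, 250.0)
    z_amp = (amp - spec.peak1_amp_mean) / spec.peak1_amp_sd
    z_lat = (lat - spec.peak1_latency_mean) / spec.peak1_latency_sd
    lin = spec.effect_amp * z_amp + spec.effect_latency * z_lat

    def excess(b0: float) -> float:
        return float(expit(b0 + lin).mean() - spec.prevalence)

    b0 = brentq(excess, -30.0, 30.0)
    prob = expit(b0 + lin)
    labels = (rng.random(n) < prob).astype(int)

    patients = []
    for i in range(n):
        pre = int(rng.integers(0, 20))
        if labels[i]:
            post = min(45, pre + int(rng.integers(1, 11)))
        else:
            post = max(0, pre - int(rng.integers(0, 4)))
        patients.append({
            "patient_id": f"P{i + 1:02d}",
            "peak1_amp": float(amp[i]),
            "peak1_latency": float(lat[i]),
            "has_peak2": bool(rng.random() < spec.peak2_prob),
            "peak2_latency": float(np.clip(lat[i] + rng.normal(70, 15),
                                           lat[i] + 40, 280)),
            "has_trough1": bool(rng.random() < spec.trough1_prob),
            "trough1_amp": float(max(
                rng.normal(spec.trough1_amp_mean, spec.trough1_amp_sd), 6.0)),
            "trough1_latency": float(np.clip(
                rng.normal(spec.trough1_latency_mean, spec.trough1_latency_sd),
                25.0, 60.0)),
            "has_trough2": bool(rng.random() < spec.trough2_prob),
            "trough2_latency": float(np.clip(lat[i] + rng.normal(100, 20),
                                             lat[i] + 50, 290)),
            "n_channels": int(rng.choice(spec.channel_counts)),
            "response_channel": None,  # filled below, depends on n_channels
            "p_deteriorate": float(prob[i]),
            "target": int(labels[i]),
            "pre_score": pre,
            "post_score": post,
            "intercept": float(b0),
        })
        patients[-1]["response_channel"] = int(
            rng.integers(0, patients[-1]["n_channels"]))
    return patients


def _bump(t_ms: np.ndarray, amp: float, lat: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t_ms - lat) / width) ** 2)


def generate_epoch(patient: dict, test_index: int, rng: np.random.Generator,
                   spec: SyntheticCohortSpec = SyntheticCohortSpec()
                   ) -> EcogEpoch:
    """One stimulation test for a patient.

    The response channel carries the patient's deflections with amplitudes
    and latencies jittered by ``within_patient_sd`` × the between-patient
    sd; every channel receives white noise and the decaying stimulus
    artifact. The non-responding channels therefore show only low-amplitude
    oscillation after smoothing, as in real recordings.
    """
    n_samp = round(spec.sampling_rate * spec.epoch_ms / 1000.0)
    n_ch = patient["n_channels"]
    t_ms = np.arange(n_samp) / spec.sampling_rate * 1000.0
    w = spec.within_patient_sd

    resp = np.zeros(n_samp)
    amp1 = max(patient["peak1_amp"]
               + rng.normal(0, w * spec.peak1_amp_sd), 5.5)
    lat1 = float(np.clip(patient["peak1_latency"]
                         + rng.normal(0, w * spec.peak1_latency_sd), 30, 280))
    resp += _bump(t_ms, amp1, lat1, spec.bump_width_ms)
    if patient["has_peak2"]:
        resp += _bump(t_ms, 0.6 * amp1,
                      patient["peak2_latency"] + rng.normal(0, 3),
                      spec.bump_width_ms * 1.4)
    if patient["has_trough1"]:
        resp -= _bump(t_ms,
                      max(patient["trough1_amp"]
                          + rng.normal(0, w * spec.trough1_amp_sd), 5.5),
                      patient["trough1_latency"] + rng.normal(0, 2),
                      spec.bump_width_ms * 0.8)
    if patient["has_trough2"]:
        resp -= _bump(t_ms, 0.5 * patient["trough1_amp"],
                      patient["trough2_latency"] + rng.normal(0, 3),
                      spec.bump_width_ms * 1.5)

    samples = rng.normal(0.0, spec.noise_sd, (n_ch, n_samp))
    samples[patient["response_channel"]] += resp
    if spec.artifact_amp > 0:
        samples += spec.artifact_amp * np.exp(-t_ms / spec.artifact_decay_ms)
    return EcogEpoch(
        test_id=f"{patient['patient_id']}_t{test_index:02d}",
        patient_id=patient["patient_id"],
        phase="pre",
        samples=samples,
        sampling_rate=spec.sampling_rate,
        epoch_ms=spec.epoch_ms,
    )


def generate_tests(spec: SyntheticCohortSpec, seed: int | None = None
                   ) -> tuple[list[LabelledTest], dict]:
    """In-memory cohort: labelled, channel-standardized epochs + ground truth.

    Same generative model as :func:`generate_cohort` but without the EDF
    round trip — the form simulation studies use when only the extracted
    features matter. Quality-screened-out tests are dropped, mirroring
    what :func:`ccepml.io_edf.load_cohort` would return.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    patients = _draw_patients(spec, rng)
    lo, hi = spec.tests_per_patient
    tests = []
    for pat in patients:
        n_tests = int(rng.integers(lo, hi + 1))
        for t in range(n_tests):
            epoch = generate_epoch(pat, t, rng, spec)
            if spec.include_post_phase and rng.random() < 0.2:
                continue  # post-phase tests are outside the analyzed cohort
            if rng.random() >= spec.quality_pass_rate:
                continue
            tests.append(LabelledTest(
                test_id=epoch.test_id, patient_id=pat["patient_id"],
                epoch=standardize_channels(epoch), target=pat["target"]))
    truth = {"spec": asdict(spec), "patients": patients,
             "effect": {"amp": spec.effect_amp,
                        "latency": spec.effect_latency,
                        "intercept": patients[0]["intercept"] if patients
                        else None}}
    return tests, truth


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path,
                    seed: int | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Write a full cohort (EDF files + manifest.csv + ground_truth.json).

    Returns the manifest DataFrame and the ground-truth record (patient
    latent features, logistic coefficients, labels). Deterministic given
    the seed: identical manifests and waveforms on every call.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create cohort directory {out_dir}: {err}") from err
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    patients = _draw_patients(spec, rng)

    lo, hi = spec.tests_per_patient
    rows = []
    for pat in patients:
        n_tests = int(rng.integers(lo, hi + 1))
        for t in range(n_tests):
            epoch = generate_epoch(pat, t, rng, spec)
            fname = f"{epoch.test_id}.edf"
            write_epoch_file(out_dir / fname, epoch.samples,
                             spec.sampling_rate)
            phase = "pre"
            if spec.include_post_phase and rng.random() < 0.2:
                phase = "post"
            rows.append({
                "test_id": epoch.test_id,
                "file_path": fname,
                "patient_id": pat["patient_id"],
                "phase": phase,
                "quality_ok": bool(rng.random() < spec.quality_pass_rate),
                "pre_score": pat["pre_score"],
                "post_score": pat["post_score"],
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth = {
        "spec": asdict(spec),
        "patients": patients,
        "effect": {"amp": spec.effect_amp, "latency": spec.effect_latency,
                   "intercept": patients[0]["intercept"] if patients else None},
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return manifest, truth


def recovery_report(truth: dict, metrics: pd.DataFrame) -> dict:
    """Summarize how well the benchmark recovered the simulated effect.

    Reports, per split mode, the mean AUC and F1 over all grid cells of the
    averaged metrics table, next to the generating effect size — the basis
    of null-calibration and power checks.
    """
    out = {"effect": truth["effect"],
           "prevalence": float(np.mean([p["target"]
                                        for p in truth["patients"]]))}
    for sm, sub in metrics.groupby("split_mode"):
        out[sm] = {"auc": float(sub["auc"].mean()),
                   "f1": float(sub["f1"].mean())}
    return out
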