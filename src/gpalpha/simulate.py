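"""Synthetic cohort generator with known ground truth.

Emulates a small DBS cohort: bilateral 4-contact leads whose trajectories pass
near a planted alpha "hotspot", ~20 s bipolar LFP snippets at 250 Hz whose
expected spectra follow the Lorentzian-with-knee aperiodic model plus Gaussian
alpha and beta peaks and a 60 Hz line component, per-visit symptom scores
coupled to a latent severity variable, and active-contact labels correlated
with the true per-contact alpha amplitude.  Everything is a pure function of
(config, seed), so every pipeline stage can be tested against the planted
truth without any external data.

The generator emulates the spectral and statistical structure of the data,
not its biophysics: narrowband peaks are realized as spectrally shaped
Gaussian noise rather than coupled oscillators, anatomical structures are toy
spheres, and no cardiac or movement artifacts are simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .io import (ALL_PAIRS, ClinicalRecord, Cohort, ContactGeometry, Recording,
                 reconstruct_sample_grid, write_cohort)
from .spectral import model_psd

HOTSPOT_MNI = (-10.12, 4.07, -4.0)

#: Toy anatomical structures (synthetic spheres, not anatomical atlases):
#: name -> (center mm, radius mm), placed around the lead trajectory.
TOY_STRUCTURES: dict[str, tuple[tuple[float, float, float], float]] = {
    "GPe": ((-12.0, 4.0, -2.0), 6.0),
    "NAcc": ((-8.0, 10.0, -8.0), 5.0),
    "BNST": ((-6.0, 0.0, 0.0), 3.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_patients: int = 13
    n_sessions: int = 4            # patient 1 gets a single session (cross-sectional only)
    fs: float = 250.0
    duration_s: float = 20.0
    n_repeats: int = 1             # snippets per pair per session

    # aperiodic priors (offset in µV²/Hz at 1 Hz, log-log slope, knee)
    log_offset_range: tuple[float, float] = (0.0, 1.0)
    exponent_range: tuple[float, float] = (1.0, 2.0)
    knee_prob: float = 0.07
    knee_range_hz: tuple[float, float] = (2.0, 8.0)
    no_knee_range_hz: tuple[float, float] = (0.05, 0.6)

    # periodic peak priors (amplitudes in log10-power units)
    alpha_freq_range: tuple[float, float] = (8.0, 12.0)
    alpha_width_range: tuple[float, float] = (1.2, 2.0)
    alpha_base_amplitude: float = 0.45
    beta_freq_range: tuple[float, float] = (16.0, 24.0)
    beta_width_range: tuple[float, float] = (2.0, 4.0)
    beta_amplitude_range: tuple[float, float] = (0.05, 0.2)
    line_freq_hz: float = 60.0
    line_amplitude: float = 0.5
    line_width_hz: float = 1.0

    # spatial truth
    hotspot_mni: tuple[float, float, float] = HOTSPOT_MNI
    decay_mm: float = 6.0          # spatial decay length of the alpha field
    contact_spacing_mm: float = 2.0
    lead_jitter_mm: float = 1.5
    right_offset_mm: tuple[float, float, float] = (0.0, 0.6, 0.0)

    # severity coupling and longitudinal model
    severity_floor: float = 0.3    # alpha amplitude factor at zero severity
    severity_range: tuple[float, float] = (0.15, 0.95)
    improvement_range: tuple[float, float] = (0.1, 0.8)
    severity_noise: float = 0.04
    right_coupling: float = 0.4    # longitudinal coupling weight, right hemisphere
    ybocs_noise: float = 1.5

    # labels and acquisition
    label_noise: float = 0.1       # prob. the active contact is not the alpha argmax
    double_monopolar_prob: float = 1.0 / 12.0
    packet_loss_prob: float = 0.0  # per-packet drop probability (packetized fixture)
    sensor_noise_uv: float = 0.5

    structures: dict = field(default_factory=lambda: dict(TOY_STRUCTURES))
    implant_date: str = "2024-01-01"
    s1_delay_days: int = 20
    session_spacing_days: int = 90


@dataclass
class GroundTruth:
    """Planted quantities the pipeline is expected to recover."""

    hotspot_mni: tuple[float, float, float]
    decay_mm: float
    # (patient_id, hemisphere, session_index, contact) -> true alpha amplitude
    alpha_amplitude: dict
    # (patient_id, session_index) -> latent severity in [0, 1]
    severity: dict
    # (patient_id, hemisphere) -> contact(s) with maximal true alpha at S1
    optimal_contacts: dict
    seed: int


def _sessions_for(config: GeneratorConfig, p: int) -> int:
    return 1 if p == 0 else config.n_sessions


def generate_geometry(
    config: GeneratorConfig, seed: int | np.random.Generator
) -> list[ContactGeometry]:
    """Bilateral 4-contact leads on jittered trajectories near the hotspot."""
    rng = np.random.default_rng(seed)
    hx, hy, hz = config.hotspot_mni
    out = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        for hemi in ("L", "R"):
            direction = np.array([0.25, 0.35, 1.0]) + rng.normal(0, 0.1, 3)
            direction /= np.linalg.norm(direction)
            center = np.array([hx, hy, hz]) + rng.normal(0, config.lead_jitter_mm, 3)
            if hemi == "R":
                center[0] = -center[0] + config.right_offset_mm[0]
                center[1] += config.right_offset_mm[1]
                center[2] += config.right_offset_mm[2]
                direction = direction * np.array([-1.0, 1.0, 1.0])
            for c in range(4):
                pos = center + (c - 1.5) * config.contact_spacing_mm * direction
                out.append(ContactGeometry(pid, hemi, c, tuple(float(v) for v in pos)))
    return out


def _severity_factor(config: GeneratorConfig, sev_s1: float, sev_t: float,
                     hemisphere: str) -> float:
    """Alpha amplitude multiplier; the right hemisphere tracks severity less."""
    if hemisphere == "L":
        s = sev_t
    else:
        w = config.right_coupling
        s = (1 - w) * sev_s1 + w * sev_t
    return config.severity_floor + (1 - config.severity_floor) * s


def true_alpha_field(
    geometry: list[ContactGeometry],
    config: GeneratorConfig,
    severity_factor: dict | None = None,
) -> dict:
    """True per-contact alpha amplitude: base * exp(-d²/2ℓ²) * severity factor.

    ``severity_factor`` maps (patient_id, hemisphere) to a multiplier;
    omitted factors default to 1.  Distances are to the hotspot, mirrored for
    the right hemisphere.
    """
    hx, hy, hz = config.hotspot_mni
    out = {}
    for g in geometry:
        target = np.array([hx if g.hemisphere == "L" else -hx, hy, hz])
        d = float(np.linalg.norm(np.asarray(g.mni) - target))
        fac = 1.0 if severity_factor is None else severity_factor.get(
            (g.patient_id, g.hemisphere), 1.0)
        out[(g.patient_id, g.hemisphere, g.contact)] = (
            config.alpha_base_amplitude * np.exp(-d**2 / (2 * config.decay_mm**2)) * fac)
    return out


def generate_lfp(
    offset: float,
    knee_hz: float,
    exponent: float,
    peaks: np.ndarray | list,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to the target model spectrum.

    The expected one-sided Welch PSD of the output equals
    ``model_psd(f, offset, knee_hz, exponent, peaks)``; phases are random
    under the given seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = model_psd(freqs, offset, knee_hz, exponent, peaks)
    coeffs = np.fft.rfft(rng.standard_normal(n))
    coeffs *= np.sqrt(target * fs / 2.0)
    coeffs[0] = 0.0
    return np.fft.irfft(coeffs, n=n)


def bipolar_from_monopolar(
    contact_signals: np.ndarray,
    sensor_noise_uv: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[int, int], np.ndarray]:
    """Differential pair signals from 4 contact signals plus sensor noise."""
    rng = np.random.default_rng(seed)
    contact_signals = np.asarray(contact_signals, dtype=float)
    if contact_signals.shape[0] != 4:
        raise ValueError("expected signals for exactly 4 contacts")
    n = contact_signals.shape[1]
    return {
        (a, b): contact_signals[a] - contact_signals[b]
                + sensor_noise_uv * rng.standard_normal(n)
        for a, b in ALL_PAIRS
    }


_PACKET_SAMPLES = 63  # telemetry packet payload size


def _apply_packet_loss(
    sig: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Emulate packetized acquisition: drop packets, reconstruct the grid."""
    if config.packet_loss_prob <= 0:
        return sig, np.zeros(sig.size, dtype=bool)
    packets = []
    for start in range(0, sig.size, _PACKET_SAMPLES):
        stop = min(start + _PACKET_SAMPLES, sig.size)
        keep = rng.random() >= config.packet_loss_prob
        # never drop the terminal packets, so the grid length is preserved
        if keep or start == 0 or stop == sig.size:
            packets.append((start / config.fs * 1000.0,
                            list(sig[start:stop])))
    samples, gap_mask, _ = reconstruct_sample_grid(packets, fs=config.fs)
    return samples, gap_mask


def _latent_severity(config: GeneratorConfig, rng: np.random.Generator,
                     n_sessions: int) -> np.ndarray:
    s1 = rng.uniform(*config.severity_range)
    improvement = rng.uniform(*config.improvement_range)
    t = np.arange(n_sessions)
    denom = max(n_sessions - 1, 1)
    sev = s1 * (1 - improvement * t / denom)
    sev = sev + rng.normal(0, config.severity_noise, n_sessions)
    sev[0] = s1
    return np.clip(sev, 0.02, 1.0)


def generate_clinical(
    config: GeneratorConfig,
    truth_alpha_s1: dict,
    severity: dict,
    rng: np.random.Generator,
) -> tuple[list[ClinicalRecord], dict]:
    """Per-visit clinical records and the true optimal-contact labels.

    S1 severity drives the Y-BOCS score affinely (plus noise, clipped to
    0-40); active contacts are the argmax of true S1 alpha per hemisphere,
    corrupted with probability ``label_noise``, occasionally doubled to
    emulate double-monopolar programming.
    """
    implant = date.fromisoformat(config.implant_date)
    records = []
    optimal = {}
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        n_sess = _sessions_for(config, p)
        sev = np.array([severity[(pid, s)] for s in range(1, n_sess + 1)])
        baseline = int(np.clip(round(10 + 28 * sev[0] + abs(rng.normal(2, 2))), 8, 40))

        active = {}
        for hemi in ("L", "R"):
            amps = np.array([truth_alpha_s1[(pid, hemi, c)] for c in range(4)])
            best = int(np.argmax(amps))
            optimal[(pid, hemi)] = (best,)
            if rng.random() < config.label_noise:
                best = int(rng.choice([c for c in range(4) if c != best]))
            chosen = {best}
            if rng.random() < config.double_monopolar_prob:
                second = int(np.argsort(amps)[-2])
                chosen.add(second if second != best else int(np.argsort(amps)[-3]))
            active[hemi] = frozenset(chosen)

        stim = 0.0  # stimulation is first programmed at S1
        for s in range(1, n_sess + 1):
            days = config.s1_delay_days + (s - 1) * config.session_spacing_days
            ybocs = int(np.clip(round(10 + 28 * sev[s - 1]
                                      + rng.normal(0, config.ybocs_noise)), 0, 40))
            # amplitude follows clinical titration: a drifting random walk,
            # deliberately not a deterministic function of visit number
            if s == 2:
                stim = float(rng.uniform(1.0, 3.5))
            elif s > 2:
                stim = float(np.clip(stim + rng.normal(0.3, 0.6), 0.5, 6.0))
            records.append(ClinicalRecord(
                patient_id=pid,
                visit_date=implant + timedelta(days=days),
                ybocs=ybocs,
                baseline_ybocs=baseline,
                stim_amplitude_mA={"L": stim, "R": stim},
                days_since_dbs_onset=days,
                active_contacts={h: frozenset(active[h]) for h in ("L", "R")},
            ))
    return records, optimal


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[Cohort, GroundTruth]:
    """Generate the full synthetic cohort with its ground truth."""
    config = config or GeneratorConfig()
    master = np.random.default_rng(seed)
    geometry = generate_geometry(config, master.integers(2**31))
    clin_rng = np.random.default_rng(master.integers(2**31))
    lfp_rng = np.random.default_rng(master.integers(2**31))
    implant = date.fromisoformat(config.implant_date)

    severity = {}
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        sev = _latent_severity(config, clin_rng, _sessions_for(config, p))
        for s, v in enumerate(sev, start=1):
            severity[(pid, s)] = float(v)

    # true S1 alpha amplitudes define the active-contact truth
    factor_s1 = {
        (f"P{p + 1:02d}", h): _severity_factor(
            config, severity[(f"P{p + 1:02d}", 1)], severity[(f"P{p + 1:02d}", 1)], h)
        for p in range(config.n_patients) for h in ("L", "R")
    }
    alpha_s1 = true_alpha_field(geometry, config, factor_s1)
    clinical, optimal = generate_clinical(config, alpha_s1, severity, clin_rng)

    geom_by_lead: dict[tuple[str, str], list[ContactGeometry]] = {}
    for g in geometry:
        geom_by_lead.setdefault((g.patient_id, g.hemisphere), []).append(g)

    recordings = []
    alpha_truth = {}
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        n_sess = _sessions_for(config, p)
        sev_s1 = severity[(pid, 1)]
        for hemi in ("L", "R"):
            # aperiodic background and beta peak are lead-stable
            log_a = clin_rng.uniform(*config.log_offset_range)
            chi = clin_rng.uniform(*config.exponent_range)
            if clin_rng.random() < config.knee_prob:
                fk = clin_rng.uniform(*config.knee_range_hz)
            else:
                fk = clin_rng.uniform(*config.no_knee_range_hz)
            alpha_fc = clin_rng.uniform(*config.alpha_freq_range)
            alpha_w = clin_rng.uniform(*config.alpha_width_range)
            beta_fc = clin_rng.uniform(*config.beta_freq_range)
            beta_w = clin_rng.uniform(*config.beta_width_range)
            beta_a = clin_rng.uniform(*config.beta_amplitude_range)

            factor = {}
            for s in range(1, n_sess + 1):
                factor[s] = _severity_factor(config, sev_s1, severity[(pid, s)], hemi)
            field_base = true_alpha_field(
                geom_by_lead[(pid, hemi)], config,
                {(pid, hemi): 1.0})

            for s in range(1, n_sess + 1):
                visit = implant + timedelta(
                    days=config.s1_delay_days + (s - 1) * config.session_spacing_days)
                contact_sigs = []
                for c in range(4):
                    amp = field_base[(pid, hemi, c)] * factor[s]
                    alpha_truth[(pid, hemi, s, c)] = float(amp)
                    peaks = [
                        (amp, alpha_fc, alpha_w),
                        (beta_a, beta_fc, beta_w),
                        (config.line_amplitude, config.line_freq_hz, config.line_width_hz),
                    ]
                    # split the background between contacts so each bipolar
                    # difference carries roughly one unit of aperiodic power
                    contact_sigs.append(generate_lfp(
                        10.0**log_a / 2, fk, chi, peaks,
                        config.duration_s, config.fs, lfp_rng.integers(2**31)))
                pair_sigs = bipolar_from_monopolar(
                    np.asarray(contact_sigs), config.sensor_noise_uv,
                    lfp_rng.integers(2**31))
                for pair, sig in pair_sigs.items():
                    for _ in range(config.n_repeats):
                        samples, gap_mask = _apply_packet_loss(
                            sig, config, lfp_rng)
                        recordings.append(Recording(
                            patient_id=pid, hemisphere=hemi, session_index=s,
                            pair=pair, samples=samples, fs=config.fs,
                            gap_mask=gap_mask, recorded_at=visit))

    truth = GroundTruth(
        hotspot_mni=config.hotspot_mni,
        decay_mm=config.decay_mm,
        alpha_amplitude=alpha_truth,
        severity=severity,
        optimal_contacts=optimal,
        seed=seed,
    )
    return Cohort(recordings=recordings, clinical=clinical, geometry=geometry), truth


def _sphere_points(center, radius: float, n: int = 200) -> np.ndarray:
    """Fibonacci lattice on a sphere surface (border point cloud)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return np.asarray(center) + radius * pts


def write_fixture(cohort: Cohort, truth: GroundTruth, path: Path | str,
                  config: GeneratorConfig | None = None) -> None:
    """Write the cohort, toy structure point clouds and the ground truth."""
    path = Path(path)
    manifest = write_cohort(cohort, path)
    config = config or GeneratorConfig()

    structures = {}
    for name, (center, radius) in config.structures.items():
        pts = _sphere_points(center, radius)
        fname = f"structure_{name}_synthetic.csv"
        with open(path / fname, "w") as fh:
            fh.write("x,y,z\n")
            for x, y, z in pts:
                fh.write(f"{x:.4f},{y:.4f},{z:.4f}\n")
        structures[name] = fname
    manifest["structures"] = structures

    truth_obj = {
        "hotspot_mni": list(truth.hotspot_mni),
        "decay_mm": truth.decay_mm,
        "seed": truth.seed,
        "alpha_amplitude": {
            "|".join(map(str, k)): v for k, v in truth.alpha_amplitude.items()},
        "severity": {"|".join(map(str, k)): v for k, v in truth.severity.items()},
        "optimal_contacts": {
            "|".join(k): list(v) for k, v in truth.optimal_contacts.items()},
    }
    (path / "truth.json").write_text(json.dumps(truth_obj, indent=1))
    manifest["truth"] = "truth.json"
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def synthetic_lme_table(
    n_patients: int = 12,
    n_sessions: int = 4,
    beta_alpha: float = 15.0,
    beta_stim: float = 0.0,
    beta_days: float = 0.0,
    beta_hemi: float = 0.0,
    beta_interaction: float = 0.0,
    intercept: float = 24.0,
    sigma_patient: float = 3.0,
    sigma_resid: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> "pd.DataFrame":
    """Mixed-model test-bed table with known generating coefficients.

    The outcome is left continuous and unclipped so estimator recovery can be
    assessed without truncation bias.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        u = rng.normal(0, sigma_patient)
        for hemi in ("L", "R"):
            for s in range(1, n_sessions + 1):
                alpha = rng.normal(0.3, 0.15)
                stim = rng.uniform(1.0, 5.0)
                days = 20 + 90 * (s - 1)
                is_r = 1.0 if hemi == "R" else 0.0
                y = (intercept + beta_alpha * alpha + beta_stim * stim
                     + beta_days * days + beta_hemi * is_r
                     + beta_interaction * is_r * alpha
                     + u + rng.normal(0, sigma_resid))
                rows.append({"patient_id": pid, "hemisphere": hemi,
                             "session_index": s, "alpha": alpha,
                             "stim_amplitude_mA": stim,
                             "days_since_dbs_onset": days, "ybocs": y})
    return pd.DataFrame(rows)
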