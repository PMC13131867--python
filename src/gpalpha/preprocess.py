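"""Signal conditioning and clinical matching.

Drift removal uses a zero-phase 4th-order Butterworth high-pass at 1 Hz
(forward-backward, so narrowband alpha phase is untouched).  An automated
quality screen replaces manual artifact inspection: it flags excessive packet
loss, amplitude outliers (robust z-score of 1-s RMS) and flat segments.
Recordings are matched to the nearest symptom assessment of the same patient
within a one-week window, preferring same-day visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io import ClinicalRecord, Recording

logger = logging.getLogger("gpalpha")


@dataclass
class QCReport:
    recording_key: tuple
    flags: frozenset[str]

    @property
    def passed(self) -> bool:
        return not self.flags


def drift_filter(rec: Recording, order: int = 4, cutoff_hz: float = 1.0) -> Recording:
    """Remove drifts with a zero-phase Butterworth high-pass."""
    if rec.fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    min_len = 3 * (2 * order + 1)
    if rec.samples.size < min_len:
        raise ValueError("too short to filter")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered, gap_mask=rec.gap_mask.copy())


def qc_screen(
    rec: Recording,
    max_gap_frac: float = 0.005,
    amp_z_thresh: float = 8.0,
) -> QCReport:
    """Screen one recording for gaps, amplitude outliers and flat segments."""
    flags: set[str] = set()
    if rec.gap_fraction > max_gap_frac:
        flags.add("excess_gaps")
    win = int(rec.fs)
    n_win = rec.samples.size // win
    if n_win >= 1:
        segs = rec.samples[: n_win * win].reshape(n_win, win)
        if np.any(segs.var(axis=1) == 0.0):
            flags.add("flatline")
        rms = np.sqrt((segs**2).mean(axis=1))
        med = np.median(rms)
        mad = np.median(np.abs(rms - med))
        if mad > 0:
            z = (rms - med) / (1.4826 * mad)
            if np.any(np.abs(z) > amp_z_thresh):
                flags.add("amplitude_outlier")
    return QCReport(recording_key=rec.key(), flags=frozenset(flags))


def match_clinical(
    recordings: list[Recording],
    clinical: list[ClinicalRecord],
    max_days: int = 7,
) -> tuple[pd.DataFrame, int]:
    """Join each recording to the nearest-in-time clinical record.

    Returns a tidy table with one row per matched recording and the count of
    recordings that had no assessment within ``max_days``.  Equidistant visits
    tie-break to the earlier one.
    """
    by_patient: dict[str, list[ClinicalRecord]] = {}
    for c in clinical:
        by_patient.setdefault(c.patient_id, []).append(c)
    for visits in by_patient.values():
        visits.sort(key=lambda c: c.visit_date)

    rows = []
    n_unmatched = 0
    for rec in recordings:
        visits = by_patient.get(rec.patient_id, [])
        best: ClinicalRecord | None = None
        best_delta = None
        if rec.recorded_at is not None:
            for c in visits:
                delta = abs((c.visit_date - rec.recorded_at).days)
                if delta > max_days:
                    continue
                if best is None or delta < best_delta:
                    best, best_delta = c, delta
                elif delta == best_delta and c.visit_date < best.visit_date:
                    logger.info(
                        "patient %s: equidistant visits, keeping earlier %s",
                        rec.patient_id, c.visit_date)
                    best = c
        if best is None:
            n_unmatched += 1
            continue
        rows.append({
            "patient_id": rec.patient_id,
            "hemisphere": rec.hemisphere,
            "session_index": rec.session_index,
            "pair": rec.pair,
            "recorded_at": rec.recorded_at,
            "visit_date": best.visit_date,
            "delta_days": best_delta,
            "ybocs": best.ybocs,
            "baseline_ybocs": best.baseline_ybocs,
            "stim_amplitude_mA": best.stim_amplitude_mA[rec.hemisphere],
            "days_since_dbs_onset": best.days_since_dbs_onset,
            "active_contacts": tuple(sorted(best.active_contacts[rec.hemisphere])),
        })
    if n_unmatched:
        logger.info("match_clinical: %d recordings without assessment in window",
                    n_unmatched)
    return pd.DataFrame(rows), n_unmatched
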