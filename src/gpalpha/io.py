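"""Cohort I/O: recordings, clinical records and contact geometry.

Recordings are stored as JSON lines (one object per bipolar snippet), clinical
assessments as CSV, contact coordinates as CSV.  A simplified packetized form
(``{"packets": [{"tick_ms": ..., "values": [...]}]}``) is accepted for
recordings and reconstructed onto a uniform sample grid, mirroring how
telemetry streams from sensing-enabled implanted pulse generators ship data in
timestamped packets that occasionally drop.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np

logger = logging.getLogger("gpalpha")

#: The six bipolar pairs of a 4-contact DBS lead, ventral (0) to dorsal (3).
ALL_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
)


@dataclass
class Recording:
    """One ~20 s bipolar LFP snippet from a single lead pair.

    ``samples`` are voltages in microvolt on a uniform grid at ``fs`` Hz;
    ``gap_mask`` marks samples that were lost in transmission and
    reconstructed by interpolation.
    """

    patient_id: str
    hemisphere: str  # "L" or "R"
    session_index: int
    pair: tuple[int, int]
    samples: np.ndarray
    fs: float = 250.0
    gap_mask: np.ndarray | None = None
    recorded_at: date | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.samples.size, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        a, b = self.pair
        if not (0 <= a < b <= 3):
            raise ValueError(f"invalid contact pair {self.pair}")
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size != self.gap_mask.size:
            raise ValueError("samples and gap_mask must have equal length")

    @property
    def gap_fraction(self) -> float:
        return float(np.mean(self.gap_mask)) if self.gap_mask.size else 0.0

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def key(self) -> tuple:
        return (self.patient_id, self.hemisphere, self.session_index, self.pair)


@dataclass
class ClinicalRecord:
    """One clinic visit: symptom severity and stimulation settings."""

    patient_id: str
    visit_date: date
    ybocs: int
    baseline_ybocs: int
    stim_amplitude_mA: dict[str, float]  # per hemisphere, {"L": ..., "R": ...}
    days_since_dbs_onset: int
    active_contacts: dict[str, frozenset[int]]  # per hemisphere

    def __post_init__(self) -> None:
        if not 0 <= self.ybocs <= 40:
            raise ValueError(f"Y-BOCS must be in 0..40, got {self.ybocs}")
        for hemi, contacts in self.active_contacts.items():
            contacts = frozenset(int(c) for c in contacts)
            if contacts and not contacts <= {0, 1, 2, 3}:
                raise ValueError(f"active contacts out of range: {sorted(contacts)}")
            if contacts and len(contacts) not in (1, 2):
                raise ValueError("active contact set must have size 1 or 2")
            self.active_contacts[hemi] = contacts


@dataclass
class ContactGeometry:
    """Template-space (MNI, mm) location of one lead contact."""

    patient_id: str
    hemisphere: str
    contact: int
    mni: tuple[float, float, float]
    flipped: bool = False  # True once pooled onto the left hemisphere

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.mni)):
            raise ValueError("contact coordinates must be finite")


@dataclass
class Cohort:
    recordings: list[Recording] = field(default_factory=list)
    clinical: list[ClinicalRecord] = field(default_factory=list)
    geometry: list[ContactGeometry] = field(default_factory=list)


def reconstruct_sample_grid(
    packets: list[tuple[float, list[float]]], fs: float = 250.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Place packetized samples onto a uniform grid and interpolate gaps.

    Parameters
    ----------
    packets : list of (tick_ms, values)
        Packet start timestamps in milliseconds (strictly increasing) and the
        samples each packet carried.
    fs : float
        Nominal sampling rate in Hz.

    Returns
    -------
    samples, gap_mask, gap_fraction
        Uniform-grid samples; True where the sample was missing and linearly
        interpolated; fraction of reconstructed samples.
    """
    if not packets:
        raise ValueError("no packets to reconstruct")
    ticks = [p[0] for p in packets]
    if any(t1 >= t2 for t1, t2 in zip(ticks, ticks[1:])):
        raise ValueError("packet ticks must be strictly increasing")
    t0 = ticks[0]
    last_tick, last_vals = packets[-1]
    n_total = int(round((last_tick - t0) * fs / 1000.0)) + len(last_vals)
    samples = np.full(n_total, np.nan)
    filled = np.zeros(n_total, dtype=bool)
    for tick, values in packets:
        start = int(round((tick - t0) * fs / 1000.0))
        stop = start + len(values)
        if filled[start:stop].any():
            raise ValueError(f"overlapping packet at tick {tick} ms")
        samples[start:stop] = values
        filled[start:stop] = True
    gap_mask = ~filled
    if gap_mask.any():
        idx = np.arange(n_total)
        samples[gap_mask] = np.interp(idx[gap_mask], idx[filled], samples[filled])
    return samples, gap_mask, float(gap_mask.mean())


def _parse_date(s: str) -> date:
    return date.fromisoformat(s)


_KNOWN_REC_FIELDS = {
    "patient_id", "hemisphere", "session_index", "pair", "fs",
    "recorded_at", "samples", "gap_mask", "packets",
}


def _recording_from_obj(obj: dict, row: int) -> Recording:
    unknown = set(obj) - _KNOWN_REC_FIELDS
    if unknown:
        logger.warning("recordings row %d: ignoring unknown fields %s", row, sorted(unknown))
    fs = float(obj.get("fs", 250.0))
    if "packets" in obj:
        packets = [(p["tick_ms"], p["values"]) for p in obj["packets"]]
        samples, gap_mask, frac = reconstruct_sample_grid(packets, fs=fs)
        if frac:
            logger.info("recordings row %d: reconstructed %.2f%% of samples", row, 100 * frac)
    else:
        samples = np.asarray(obj["samples"], dtype=float)
        gap_mask = np.asarray(obj.get("gap_mask", np.zeros(samples.size)), dtype=bool)
    return Recording(
        patient_id=str(obj["patient_id"]),
        hemisphere=str(obj["hemisphere"]),
        session_index=int(obj["session_index"]),
        pair=tuple(int(c) for c in obj["pair"]),
        samples=samples,
        fs=fs,
        gap_mask=gap_mask,
        recorded_at=_parse_date(obj["recorded_at"]) if obj.get("recorded_at") else None,
    )


def _parse_contact_set(cell: str) -> frozenset[int]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(int(tok) for tok in cell.split(";") if tok.strip() != "")


def read_recordings(path: Path) -> list[Recording]:
    recs = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                recs.append(_recording_from_obj(json.loads(line), i))
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}: malformed recording at line {i}: {exc}") from exc
    return recs


def read_clinical(path: Path) -> list[ClinicalRecord]:
    out = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                out.append(ClinicalRecord(
                    patient_id=row["patient_id"],
                    visit_date=_parse_date(row["visit_date"]),
                    ybocs=int(row["ybocs"]),
                    baseline_ybocs=int(row["baseline_ybocs"]),
                    stim_amplitude_mA={
                        "L": float(row["stim_L_mA"]), "R": float(row["stim_R_mA"]),
                    },
                    days_since_dbs_onset=int(row["days_since_dbs_onset"]),
                    active_contacts={
                        "L": _parse_contact_set(row.get("active_contacts_L", "")),
                        "R": _parse_contact_set(row.get("active_contacts_R", "")),
                    },
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed clinical row {i}: {exc}") from exc
    return out


def read_contacts(path: Path) -> list[ContactGeometry]:
    out = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                out.append(ContactGeometry(
                    patient_id=row["patient_id"],
                    hemisphere=row["hemisphere"],
                    contact=int(row["contact"]),
                    mni=(float(row["x"]), float(row["y"]), float(row["z"])),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed contacts row {i}: {exc}") from exc
    return out


def read_cohort(path: Path | str) -> Cohort:
    """Read a cohort directory or an explicit ``manifest.json``.

    The manifest maps logical names to relative file paths, e.g.
    ``{"recordings": "recordings.jsonl", "clinical": "clinical.csv",
    "contacts": "contacts.csv"}``.  A directory containing files with those
    default names is accepted directly.  Every referenced file must exist.
    """
    path = Path(path)
    if path.is_dir():
        manifest_path = path / "manifest.json"
        base = path
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
        else:
            manifest = {
                name: fname
                for name, fname in (
                    ("recordings", "recordings.jsonl"),
                    ("clinical", "clinical.csv"),
                    ("contacts", "contacts.csv"),
                )
                if (path / fname).exists()
            }
    else:
        manifest = json.loads(path.read_text())
        base = path.parent

    cohort = Cohort()
    readers = {"recordings": read_recordings, "clinical": read_clinical,
               "contacts": read_contacts}
    for name, reader in readers.items():
        if name not in manifest:
            continue
        fpath = base / manifest[name]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file: {fpath}")
        setattr(cohort, {"recordings": "recordings", "clinical": "clinical",
                         "contacts": "geometry"}[name], reader(fpath))
    known = {"recordings", "clinical", "contacts", "structures", "truth"}
    for extra in set(manifest) - known:
        logger.warning("manifest: ignoring unknown entry %r", extra)
    # cross-reference patient ids
    rec_ids = {r.patient_id for r in cohort.recordings}
    clin_ids = {c.patient_id for c in cohort.clinical}
    for pid in sorted(rec_ids - clin_ids):
        logger.warning("patient %s has recordings but no clinical record", pid)
    return cohort


def write_cohort(cohort: Cohort, path: Path | str, ndigits: int = 6) -> dict[str, str]:
    """Write a cohort in the documented formats; returns the manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    if cohort.recordings:
        with open(path / "recordings.jsonl", "w") as fh:
            for r in cohort.recordings:
                obj = {
                    "patient_id": r.patient_id,
                    "hemisphere": r.hemisphere,
                    "session_index": r.session_index,
                    "pair": list(r.pair),
                    "fs": r.fs,
                    "recorded_at": r.recorded_at.isoformat() if r.recorded_at else None,
                    "samples": [round(float(v), ndigits) for v in r.samples],
                }
                if r.gap_mask.any():
                    obj["gap_mask"] = [bool(g) for g in r.gap_mask]
                fh.write(json.dumps(obj) + "\n")
        manifest["recordings"] = "recordings.jsonl"

    if cohort.clinical:
        with open(path / "clinical.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "visit_date", "ybocs", "baseline_ybocs",
                        "stim_L_mA", "stim_R_mA", "days_since_dbs_onset",
                        "active_contacts_L", "active_contacts_R"])
            for c in cohort.clinical:
                w.writerow([
                    c.patient_id, c.visit_date.isoformat(), c.ybocs, c.baseline_ybocs,
                    c.stim_amplitude_mA["L"], c.stim_amplitude_mA["R"],
                    c.days_since_dbs_onset,
                    ";".join(str(i) for i in sorted(c.active_contacts["L"])),
                    ";".join(str(i) for i in sorted(c.active_contacts["R"])),
                ])
        manifest["clinical"] = "clinical.csv"

    if cohort.geometry:
        with open(path / "contacts.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "hemisphere", "contact", "x", "y", "z"])
            for g in cohort.geometry:
                w.writerow([g.patient_id, g.hemisphere, g.contact, *g.mni])
        manifest["contacts"] = "contacts.csv"

    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
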