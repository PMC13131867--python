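"""End-to-end orchestration: fixture -> spectra -> fits -> biomarkers ->
contact prediction, spatial mapping and cohort statistics.

Results are evaluated over an explicit multiverse grid of defensible analytic
choices — hemisphere sampling (pooled / left / right) x within-hemisphere
summary (max pair / mean of pairs) x spectrum kind (absolute / relative /
periodic) — realized as a factorial grid in a single run with no selective
reporting.  Every stochastic stage takes its seed from the config, the config
is serialized into the output directory, and the report is a pure function of
(inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as met
from . import prediction as pred
from . import spatial as spa
from . import stats as st
from .io import read_cohort
from .monopolar import pseudo_monopolar
from .preprocess import drift_filter, match_clinical, qc_screen
from .spectral import (SpecparamSettings, average_session_psd, fit_specparam,
                       periodic_spectrum, relative_spectrum, welch_psd)

logger = logging.getLogger("gpalpha")

STAGES = ("preprocess", "spectra", "fit", "metrics", "monopolar",
          "predict", "spatial", "stats")

HEMI_STRATEGIES = ("pooled", "left", "right")
SUMMARIES = ("max_pair", "mean_pairs")
KINDS = ("absolute", "relative", "periodic")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "run"
    alpha_band: tuple[float, float] = met.CANONICAL_ALPHA
    peak_half_width: float = met.PEAK_HALF_WIDTH
    fit_range: tuple[float, float] = (1.0, 65.0)
    max_n_peaks: int = 8
    min_peak_height: float = 0.1
    peak_threshold: float = 2.0
    lam: float = 100.0
    max_gap_frac: float = 0.005
    amp_z_thresh: float = 8.0
    match_max_days: int = 7
    n_perm: int = 10_000
    n_boot: int = 10_000
    alpha_fw: float = 0.01
    alpha_cluster: float = 0.05
    seed: int | None = 0
    severity_threshold: float | None = None
    make_figures: bool = True

    def specparam_settings(self) -> SpecparamSettings:
        return SpecparamSettings(
            fit_range=tuple(self.fit_range), max_n_peaks=self.max_n_peaks,
            min_peak_height=self.min_peak_height,
            peak_threshold=self.peak_threshold, lam=self.lam)


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema/range checks; returns a list of human-readable issues."""
    issues = []
    lo, hi = config.alpha_band
    if lo >= hi:
        issues.append(f"alpha_band out of order: {config.alpha_band}")
    flo, fhi = config.fit_range
    if flo >= fhi or flo <= 0:
        issues.append(f"invalid fit_range: {config.fit_range}")
    if config.seed is None:
        issues.append("missing seed: every stochastic stage needs one")
    for name in ("n_perm", "n_boot"):
        if getattr(config, name) < 1:
            issues.append(f"{name} must be >= 1")
    for name in ("alpha_fw", "alpha_cluster"):
        v = getattr(config, name)
        if not 0 < v < 1:
            issues.append(f"{name} must be in (0, 1)")
    if not 0 <= config.max_gap_frac <= 1:
        issues.append("max_gap_frac must be in [0, 1]")
    return issues


def _peak_or_canonical(row: pd.Series) -> float:
    v = row["peak_alpha"]
    return row["canonical_alpha"] if pd.isna(v) else v


# --------------------------------------------------------------------------
# stage implementations (state in, state out)

def _stage_preprocess(state: dict, cfg: PipelineConfig) -> None:
    cohort = state.pop("_cohort", None) or read_cohort(cfg.input_dir)
    kept, dropped = [], 0
    for rec in cohort.recordings:
        filtered = drift_filter(rec)
        if qc_screen(filtered, cfg.max_gap_frac, cfg.amp_z_thresh).passed:
            kept.append(filtered)
        else:
            dropped += 1
    matched, unmatched = match_clinical(kept, cohort.clinical, cfg.match_max_days)
    state["recordings"] = kept
    state["matched"] = matched
    state["geometry"] = cohort.geometry
    state["clinical"] = cohort.clinical
    state["qc"] = {"n_input": len(cohort.recordings), "n_dropped_qc": dropped,
                   "n_unmatched": unmatched}


def _stage_spectra(state: dict, cfg: PipelineConfig) -> None:
    by_key: dict[tuple, list] = {}
    for rec in state["recordings"]:
        by_key.setdefault(rec.key(), []).append(rec)
    spectra = {}
    for key, recs in by_key.items():
        spectra[key] = average_session_psd([welch_psd(r) for r in recs])
    state["psd_absolute"] = spectra


def _stage_fit(state: dict, cfg: PipelineConfig) -> None:
    settings = cfg.specparam_settings()
    fits, periodic, relative = {}, {}, {}
    for key, psd in state["psd_absolute"].items():
        fit = fit_specparam(psd, settings)
        fits[key] = fit
        periodic[key] = periodic_spectrum(psd, fit)
        relative[key] = relative_spectrum(psd)
    state["fits"] = fits
    state["psd_periodic"] = periodic
    state["psd_relative"] = relative


def _stage_metrics(state: dict, cfg: PipelineConfig) -> None:
    lo, hi = cfg.alpha_band
    rows = []
    for key, fit in state["fits"].items():
        pid, hemi, session, pair = key
        peak = met.individual_alpha_peak(fit, state["psd_periodic"][key],
                                         band=cfg.alpha_band)
        for kind, store in (("absolute", "psd_absolute"),
                            ("relative", "psd_relative"),
                            ("periodic", "psd_periodic")):
            spec = state[store][key]
            rows.append({
                "patient_id": pid, "hemisphere": hemi, "session_index": session,
                "pair": f"{pair[0]}-{pair[1]}", "spectrum_kind": kind,
                "canonical_alpha": met.band_power(spec, lo, hi),
                "peak_freq": peak,
                "peak_alpha": (met.peak_alpha_power(spec, peak, cfg.peak_half_width)
                               if peak is not None else np.nan),
            })
    state["metrics"] = pd.DataFrame(rows)


def _stage_monopolar(state: dict, cfg: PipelineConfig) -> None:
    m = state["metrics"]
    s1 = m[m["session_index"] == 1]
    rows = []
    for (pid, hemi, kind), grp in s1.groupby(["patient_id", "hemisphere",
                                              "spectrum_kind"]):
        pair_powers = {
            tuple(int(c) for c in row["pair"].split("-")): _peak_or_canonical(row)
            for _, row in grp.iterrows()
        }
        mp = pseudo_monopolar(pair_powers, lead=(pid, hemi, 1))
        norm, degenerate = met.minmax_normalize(mp.estimates)
        for c in range(4):
            rows.append({
                "patient_id": pid, "hemisphere": hemi, "session_index": 1,
                "spectrum_kind": kind, "contact": c,
                "estimate": mp.estimates[c], "normalized": norm[c],
                "winning_rule": mp.winning_rule[c], "degenerate": degenerate,
            })
    state["monopolar"] = pd.DataFrame(rows)


def _active_labels(state: dict) -> dict[tuple[str, str], tuple[int, ...]]:
    matched = state["matched"]
    s1 = matched[matched["session_index"] == 1]
    return {
        (pid, hemi): tuple(grp["active_contacts"].iloc[0])
        for (pid, hemi), grp in s1.groupby(["patient_id", "hemisphere"])
    }


def _stage_predict(state: dict, cfg: PipelineConfig) -> None:
    rng = np.random.default_rng(cfg.seed)
    labels = _active_labels(state)
    mono = state["monopolar"]
    out = {}
    for kind, grp in mono.groupby("spectrum_kind"):
        normalized, is_active, rankings, optimal = [], [], [], []
        for (pid, hemi), lead in grp.groupby(["patient_id", "hemisphere"]):
            active = labels.get((pid, hemi), ())
            lead = lead.sort_values("contact")
            est = lead["estimate"].to_numpy()
            normalized.extend(lead["normalized"])
            is_active.extend(c in active for c in lead["contact"])
            if active:
                rankings.append(pred.rank_contacts(est))
                optimal.append(active)
        curve = pred.selection_curve(rankings, optimal)
        out[kind] = {
            "active_vs_inactive": pred.compare_active_inactive(
                np.asarray(normalized), np.asarray(is_active),
                n_iter=cfg.n_perm, seed=rng.integers(2**31)),
            "curve": curve,
            "auc": pred.auc(curve),
            "auc_test": pred.auc_permutation_test(
                rankings, optimal, n_perm=cfg.n_perm, seed=rng.integers(2**31)),
            "rank_difference": pred.rank_difference(
                rankings, optimal, n_boot=cfg.n_boot, n_perm=cfg.n_perm,
                seed=rng.integers(2**31)),
            "chance_auc": pred.auc(pred.chance_curve(4)),
        }
    state["prediction"] = out


def _stage_spatial(state: dict, cfg: PipelineConfig) -> None:
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    pooled = spa.pool_hemispheres(state["geometry"])
    coords = {(g.patient_id, g.hemisphere, g.contact): g.mni for g in pooled}
    mono = state["monopolar"]
    out = {}
    for kind, grp in mono.groupby("spectrum_kind"):
        grp = grp.sort_values(["patient_id", "hemisphere", "contact"])
        pts = np.array([coords[(r.patient_id, r.hemisphere, r.contact)]
                        for r in grp.itertuples()])
        values = grp["estimate"].to_numpy()
        hemi_labels = np.array([f"{r.patient_id}:{r.hemisphere}"
                                for r in grp.itertuples()])
        dist = spa.SpatialDistribution.from_values(pts, values)
        centroid = spa.top_percentile_centroid(dist, pct=5.0)
        inertia = spa.moment_of_inertia(dist)
        out[kind] = {
            "centroid": centroid,
            "distance_correlation": spa.distance_power_correlation(
                dist, centroid, n_boot=cfg.n_boot, seed=rng.integers(2**31)),
            "inertia_mm2": inertia,
            "radius_gyration_mm": spa.radius_of_gyration(inertia),
            "inertia_test": spa.inertia_permutation_test(
                dist, hemi_labels, n_perm=cfg.n_perm, seed=rng.integers(2**31)),
            "heatmaps": {plane: spa.heatmap_2d(dist, plane)
                         for plane in ("axial", "coronal", "sagittal")},
        }
    state["spatial"] = out


def _hemisphere_table(state: dict, kind: str, summary: str) -> pd.DataFrame:
    """One row per (patient, hemisphere, session) with summarized alpha."""
    m = state["metrics"]
    sel = m[m["spectrum_kind"] == kind]
    rows = []
    for (pid, hemi, session), grp in sel.groupby(
            ["patient_id", "hemisphere", "session_index"]):
        vals = [_peak_or_canonical(r) for _, r in grp.iterrows()]
        canon = grp["canonical_alpha"].tolist()
        rows.append({
            "patient_id": pid, "hemisphere": hemi, "session_index": session,
            "alpha_peak": met.hemisphere_summary(vals, summary),
            "alpha_canonical": met.hemisphere_summary(canon, summary),
        })
    return pd.DataFrame(rows)


def _clinical_per_session(state: dict) -> pd.DataFrame:
    matched = state["matched"]
    cols = ["patient_id", "hemisphere", "session_index", "ybocs",
            "baseline_ybocs", "stim_amplitude_mA", "days_since_dbs_onset"]
    return matched[cols].drop_duplicates(
        subset=["patient_id", "hemisphere", "session_index"])


def _stage_stats(state: dict, cfg: PipelineConfig) -> None:
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 2)
    clin = _clinical_per_session(state)
    out: dict = {"cells": {}}

    # cross-sectional multiverse grid at S1
    for kind in KINDS:
        for summary in SUMMARIES:
            table = _hemisphere_table(state, kind, summary).merge(
                clin, on=["patient_id", "hemisphere", "session_index"])
            s1 = table[table["session_index"] == 1]
            for hemi_strategy in HEMI_STRATEGIES:
                sub = s1 if hemi_strategy == "pooled" else s1[
                    s1["hemisphere"] == ("L" if hemi_strategy == "left" else "R")]
                cell = {}
                for metric in ("alpha_peak", "alpha_canonical"):
                    try:
                        cell[metric] = st.spearman_bootstrap(
                            sub[metric].to_numpy(), sub["ybocs"].to_numpy(),
                            n_boot=cfg.n_boot, n_perm=cfg.n_perm,
                            seed=rng.integers(2**31))
                    except ValueError as exc:
                        cell[metric] = {"error": str(exc)}
                out["cells"][f"{hemi_strategy}|{summary}|{kind}"] = cell

    # severity split and spectral contrasts on periodic spectra at S1
    s1_clin = clin[clin["session_index"] == 1]
    groups = st.stratify_severity(s1_clin, threshold=cfg.severity_threshold)
    out["severity_groups"] = groups
    periodic = state["psd_periodic"]
    freqs = next(iter(periodic.values())).freqs
    spec_by_unit: dict[tuple, np.ndarray] = {}
    for key, spec in periodic.items():
        pid, hemi, session, _pair = key
        spec_by_unit.setdefault((pid, hemi, session), []).append(spec.power)
    unit_spectra = {k: np.mean(v, axis=0) for k, v in spec_by_unit.items()}

    less = [unit_spectra[k] for k in unit_spectra
            if k[2] == 1 and k[0] in groups["less_severe"]]
    more = [unit_spectra[k] for k in unit_spectra
            if k[2] == 1 and k[0] in groups["more_severe"]]
    out["severity_contrast"] = st.cluster_permutation_spectra(
        np.asarray(more), np.asarray(less), freqs, paired=False,
        alpha_fw=cfg.alpha_fw, alpha_cluster=cfg.alpha_cluster,
        n_perm=cfg.n_perm, seed=rng.integers(2**31))

    s1_keys = sorted(k for k in unit_spectra if k[2] == 1)
    ybocs_map = {(r.patient_id, r.hemisphere): r.ybocs
                 for r in s1_clin.itertuples()}
    usable = [k for k in s1_keys if (k[0], k[1]) in ybocs_map]
    out["frequencywise"] = st.frequencywise_correlation(
        np.asarray([unit_spectra[k] for k in usable]),
        np.asarray([ybocs_map[(k[0], k[1])] for k in usable]),
        freqs, n_boot=cfg.n_boot, n_perm=cfg.n_perm,
        alpha_fw=cfg.alpha_fw, alpha_cluster=cfg.alpha_cluster,
        seed=rng.integers(2**31))

    # longitudinal analyses on peak periodic alpha, max-pair summary
    table = _hemisphere_table(state, "periodic", "max_pair").merge(
        clin, on=["patient_id", "hemisphere", "session_index"])
    deltas, shift = st.session_deltas(table, alpha_col="alpha_peak")
    out["session_deltas_shift"] = shift
    if len(deltas) >= 4:
        out["delta_correlation"] = st.spearman_bootstrap(
            deltas["dalpha_log"].to_numpy(), deltas["dybocs_pct"].to_numpy(),
            n_boot=cfg.n_boot, n_perm=cfg.n_perm, seed=rng.integers(2**31))
        out["session_deltas"] = deltas

    lme = {}
    try:
        lme["pooled_interaction"] = st.fit_lme(table, "pooled_interaction",
                                               alpha_col="alpha_peak")
        for hemi in ("L", "R"):
            lme[f"hemisphere_{hemi}"] = st.fit_lme(
                table[table["hemisphere"] == hemi], "per_hemisphere",
                alpha_col="alpha_peak")
    except (ValueError, RuntimeError) as exc:
        lme["error"] = str(exc)
    out["lme"] = lme

    # responders and best-session contrast (patient-level spectra)
    resp = {}
    for pid, grp in clin.groupby("patient_id"):
        last = grp.sort_values("session_index").iloc[-1]
        resp[pid] = st.classify_responder(float(last["baseline_ybocs"]),
                                          float(last["ybocs"]))
    out["responders"] = resp

    patient_spectra: dict[tuple, list] = {}
    for (pid, hemi, session), spec in unit_spectra.items():
        patient_spectra.setdefault((pid, session), []).append(spec)
    patient_spectra = {k: np.mean(v, axis=0) for k, v in patient_spectra.items()}
    session_table = clin.groupby(["patient_id", "session_index"]).agg(
        ybocs=("ybocs", "mean"), baseline_ybocs=("baseline_ybocs", "mean"),
    ).reset_index()
    try:
        out["best_session"] = st.best_session_contrast(
            session_table, patient_spectra, freqs,
            alpha_fw=cfg.alpha_fw, alpha_cluster=cfg.alpha_cluster,
            n_perm=cfg.n_perm, seed=rng.integers(2**31))
    except ValueError as exc:
        out["best_session"] = {"error": str(exc)}

    state["stats"] = out


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "spectra": _stage_spectra,
    "fit": _stage_fit,
    "metrics": _stage_metrics,
    "monopolar": _stage_monopolar,
    "predict": _stage_predict,
    "spatial": _stage_spatial,
    "stats": _stage_stats,
}


# --------------------------------------------------------------------------
# report serialization

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        if obj.size > 2048:
            return {"summary": "array", "shape": list(obj.shape)}
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (pred.PermutationResult,)):
        return {"observed": obj.observed, "p": obj.p_value,
                "sidedness": obj.sidedness, "n_perm": obj.n_perm,
                "null_mean": float(np.mean(obj.null))}
    if isinstance(obj, pred.SelectionCurve):
        return {"k": obj.k.tolist(), "cum_prob": obj.cum_prob.tolist(),
                "n_hemispheres": obj.n_hemispheres}
    if isinstance(obj, st.ClusterResult):
        return {"clusters": obj.clusters,
                "significant": obj.significant, "alpha_fw": obj.alpha_fw}
    if isinstance(obj, pd.DataFrame):
        return {"summary": "table", "n_rows": len(obj)}
    if isinstance(obj, (float, int, str, bool)) or obj is None:
        return obj
    return str(obj)


def _write_outputs(state: dict, cfg: PipelineConfig, completed: list[str]) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, default=str))
    (out / "MANIFEST.json").write_text(json.dumps(
        {"completed_stages": completed}, indent=1))
    if "metrics" in state:
        state["metrics"].to_csv(out / "metrics.csv", index=False)
    if "monopolar" in state:
        state["monopolar"].to_csv(out / "monopolar.csv", index=False)
    if "prediction" in state:
        for kind, res in state["prediction"].items():
            curve = res["curve"]
            pd.DataFrame({"k": curve.k, "cum_prob": curve.cum_prob}).to_csv(
                out / f"selection_curve_{kind}.csv", index=False)
    if "stats" in state and isinstance(state["stats"].get("session_deltas"),
                                       pd.DataFrame):
        state["stats"]["session_deltas"].to_csv(
            out / "session_deltas.csv", index=False)
    report = {k: _jsonable(state[k]) for k in
              ("qc", "prediction", "spatial", "stats") if k in state}
    (out / "report.json").write_text(json.dumps(report, indent=1))
    if cfg.make_figures and "spatial" in state:
        _write_figures(state, out)


def _write_figures(state: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sp = state["spatial"].get("periodic")
    if sp is not None:
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (plane, hm) in zip(axes, sp["heatmaps"].items()):
            im = ax.pcolormesh(hm["x"], hm["y"], hm["values"].T, shading="auto")
            ax.set_title(f"{plane} (periodic peak alpha)")
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(out / "heatmaps_periodic.png", dpi=110)
        plt.close(fig)
    if "prediction" in state:
        fig, ax = plt.subplots(figsize=(5, 4))
        for kind, res in state["prediction"].items():
            ax.plot(res["curve"].k, res["curve"].cum_prob, marker="o",
                    label=f"{kind} (AUC={res['auc']:.2f})")
        ax.plot([1, 2, 3, 4], [0.25, 0.5, 0.75, 1.0], "k--", label="chance")
        ax.set_xlabel("contacts tested")
        ax.set_ylabel("P(optimal found)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "selection_curves.png", dpi=110)
        plt.close(fig)


def analyze_cohort(cohort, config: PipelineConfig,
                   stages: list[str] | None = None,
                   write: bool = False) -> dict:
    """Run the pipeline stages on an in-memory cohort (no input files)."""
    return run_pipeline(config, stages=stages, _cohort=cohort, _write=write)


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None,
                 _cohort=None, _write: bool = True) -> dict:
    """Run the requested stages (all by default) and write the report bundle.

    Any stage error aborts with the stage name; outputs of completed stages
    are retained together with a MANIFEST listing them.
    """
    issues = validate_config(config)
    blocking = [i for i in issues if "seed" in i or "must" in i or "invalid" in i
                or "out of order" in i]
    if blocking:
        raise ValueError("invalid config: " + "; ".join(blocking))

    wanted = list(STAGES) if stages is None else list(stages)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # stages are ordered and cumulative: run everything up to the last wanted
    last = max(STAGES.index(s) for s in wanted)
    todo = STAGES[: last + 1]

    state: dict = {}
    if _cohort is not None:
        state["_cohort"] = _cohort
    completed: list[str] = []
    for stage in todo:
        try:
            _STAGE_FUNCS[stage](state, config)
        except Exception as exc:
            if _write:
                _write_outputs(state, config, completed)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        completed.append(stage)
    if _write:
        _write_outputs(state, config, completed)
    return state
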