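"""Cohort statistics: severity stratification, cluster-corrected spectral
contrasts and correlations, longitudinal deltas, mixed-effects models,
responder classification and bootstrap/permutation utilities.

Frequency-wise contrasts use cluster-based permutation correction: per-bin
statistics (Welch t, paired t or Spearman R) are thresholded at a per-bin
two-sided level (``alpha_cluster``, default 0.05 — a free parameter of the
method), contiguous same-sign supra-threshold bins form clusters whose mass is
the summed statistic, and each observed cluster is compared against the null
distribution of the maximum absolute cluster mass over label permutations
(unpaired), sign flips (paired) or outcome permutations (correlation).  A
cluster is significant when its corrected p falls below the family-wise level
``alpha_fw`` (default 0.01).

Mixed-effects models (symptom severity against an alpha-power metric with
stimulation amplitude and days since stimulation onset as covariates and a
random intercept per patient) are fitted by REML via statsmodels; F tests for
the fixed effects use a Satterthwaite approximation of the denominator
degrees of freedom computed from the closed-form random-intercept REML
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .prediction import _perm_p

logger = logging.getLogger("gpalpha")


# ---------------------------------------------------------------------------
# severity stratification and responder rule

def stratify_severity(
    s1_table: pd.DataFrame, threshold: float | None = None
) -> dict:
    """Median split of patients into less/more severe groups at S1.

    Patients at the threshold go to the more-severe group (>= convention).
    An explicit ``threshold`` overrides the median.
    """
    per_patient = s1_table.groupby("patient_id")["ybocs"].mean()
    if len(per_patient) < 2:
        raise ValueError("need at least 2 patients to stratify")
    if per_patient.nunique() == 1 and threshold is None:
        raise ValueError("all Y-BOCS identical: median split undefined")
    thr = float(np.median(per_patient)) if threshold is None else float(threshold)
    more = sorted(per_patient.index[per_patient >= thr])
    less = sorted(per_patient.index[per_patient < thr])
    return {"less_severe": less, "more_severe": more, "threshold": thr}


def classify_responder(baseline_ybocs: float, ybocs: float) -> bool:
    """Responder: at least 35% improvement relative to the pre-operative score."""
    if baseline_ybocs <= 0:
        raise ValueError("baseline Y-BOCS must be positive")
    return 100.0 * (baseline_ybocs - ybocs) / baseline_ybocs >= 35.0


# ---------------------------------------------------------------------------
# cluster-based permutation machinery

@dataclass
class ClusterResult:
    freqs: np.ndarray
    stat: np.ndarray                  # per-bin statistic (t or R)
    crit: np.ndarray                  # per-bin cluster-forming threshold (abs)
    clusters: list[dict] = field(default_factory=list)
    alpha_fw: float = 0.01
    null_max: np.ndarray | None = None

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] < self.alpha_fw]


def _cluster_spans(stat: np.ndarray, crit: np.ndarray) -> list[tuple[int, int, float]]:
    """Contiguous same-sign supra-threshold runs of a 1-D statistic."""
    sup = np.abs(stat) > crit
    out = []
    i, n = 0, stat.size
    while i < n:
        if not sup[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sup[j + 1] and (stat[j + 1] >= 0) == (stat[i] >= 0):
            j += 1
        out.append((i, j, float(stat[i:j + 1].sum())))
        i = j + 1
    return out


def _max_cluster_mass(stat2d: np.ndarray, crit2d: np.ndarray) -> np.ndarray:
    """Max |cluster mass| per row of a (n_perm, n_freqs) statistic array."""
    n, f = stat2d.shape
    pad_s = np.zeros((n, 1))
    pad_c = np.full((n, 1), np.inf)
    t = np.concatenate([stat2d, pad_s], axis=1).ravel()
    c = np.concatenate([np.broadcast_to(crit2d, stat2d.shape), pad_c], axis=1).ravel()
    sup = np.abs(t) > c
    sgn = t >= 0
    cont = np.zeros_like(sup)
    cont[1:] = sup[:-1] & (sgn[1:] == sgn[:-1])
    starts = np.flatnonzero(sup & ~cont)
    rowmax = np.zeros(n)
    if starts.size == 0:
        return rowmax
    tm = np.where(sup, t, 0.0)
    masses = np.add.reduceat(tm, starts)
    rows = starts // (f + 1)
    np.maximum.at(rowmax, rows, np.abs(masses))
    return rowmax


def _welch_t(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin Welch t and Welch-Satterthwaite df for 2-D group arrays."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(0), xb.mean(0)
    va, vb = xa.var(0, ddof=1), xb.var(0, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
        df = np.where(sa + sb > 0,
                      (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1)),
                      na + nb - 2)
    return t, df


def cluster_permutation_spectra(
    group_a: np.ndarray,
    group_b: np.ndarray,
    freqs: np.ndarray,
    paired: bool = False,
    alpha_fw: float = 0.01,
    alpha_cluster: float = 0.05,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster-corrected frequency-wise contrast of two spectrum stacks.

    ``group_a`` and ``group_b`` are (n_units, n_freqs) arrays; paired
    contrasts require matched rows and use sign flips of the differences,
    unpaired contrasts use Welch t with group-label permutations.
    """
    rng = np.random.default_rng(seed)
    group_a = np.atleast_2d(np.asarray(group_a, dtype=float))
    group_b = np.atleast_2d(np.asarray(group_b, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if group_a.shape[1] != freqs.size or group_b.shape[1] != freqs.size:
        raise ValueError("spectra and frequency grid disagree")
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("need at least 2 units per group")

    if paired:
        if group_a.shape != group_b.shape:
            raise ValueError("paired contrast requires matched units")
        d = group_a - group_b
        n = d.shape[0]
        sd = d.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_obs = np.where(sd > 0, d.mean(0) / (sd / np.sqrt(n)), 0.0)
        crit = np.full(freqs.size, sps.t.ppf(1 - alpha_cluster / 2, n - 1))
        # sign-flip null
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
        mean_p = signs @ d / n
        sum_d2 = (d**2).sum(0)
        var_p = (sum_d2 - n * mean_p**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(var_p > 0, mean_p / np.sqrt(var_p / n), 0.0)
        null_max = _max_cluster_mass(t_null, crit)
    else:
        na = group_a.shape[0]
        x = np.vstack([group_a, group_b])
        t_obs, df_obs = _welch_t(group_a, group_b)
        crit = sps.t.ppf(1 - alpha_cluster / 2, df_obs)
        n_tot = x.shape[0]
        perm_rows = np.argsort(rng.random((n_perm, n_tot)), axis=1)
        null_max = np.empty(n_perm)
        # chunked label permutations keep memory flat
        chunk = max(1, 20_000_000 // (n_tot * freqs.size))
        for s in range(0, n_perm, chunk):
            rows = perm_rows[s:s + chunk]
            lab = np.zeros((rows.shape[0], n_tot))
            np.put_along_axis(lab, rows[:, :na], 1.0, axis=1)
            nb = n_tot - na
            sa1 = lab @ x
            sa2 = lab @ (x**2)
            st1 = x.sum(0) - sa1
            st2 = (x**2).sum(0) - sa2
            ma, mb = sa1 / na, st1 / nb
            va = (sa2 - na * ma**2) / (na - 1)
            vb = (st2 - nb * mb**2) / (nb - 1)
            qa, qb = va / na, vb / nb
            denom = np.sqrt(qa + qb)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_null = np.where(denom > 0, (ma - mb) / denom, 0.0)
                df_null = np.where(qa + qb > 0,
                                   (qa + qb) ** 2 / (qa**2 / (na - 1) + qb**2 / (nb - 1)),
                                   n_tot - 2)
            crit_null = sps.t.ppf(1 - alpha_cluster / 2, df_null)
            null_max[s:s + rows.shape[0]] = _max_cluster_mass(t_null, crit_null)

    clusters = []
    for i, j, mass in _cluster_spans(t_obs, crit):
        clusters.append({
            "f_lo": float(freqs[i]), "f_hi": float(freqs[j]), "mass": mass,
            "p": _perm_p(null_max, abs(mass), "right"),
        })
    return ClusterResult(freqs=freqs, stat=t_obs, crit=np.asarray(crit),
                         clusters=clusters, alpha_fw=alpha_fw, null_max=null_max)


# ---------------------------------------------------------------------------
# rank correlations

def _rank_rows(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=-1)


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    m = r.mean(axis=-1, keepdims=True)
    s = r.std(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(s > 0, (r - m) / s, 0.0)


def _spearman_vs_columns(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Spearman R of y (n,) against each column of x (n, F)."""
    zy = _standardize_rows(_rank_rows(y))
    zx = _standardize_rows(_rank_rows(x.T))  # (F, n)
    return np.clip(zx @ zy / y.size, -1.0, 1.0)


def spearman_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    sidedness: str = "two",
) -> dict:
    """Spearman R with percentile bootstrap 95% CI and permutation p."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(sps.spearmanr(x, y).statistic)

    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    zx = _standardize_rows(_rank_rows(x[idx]))
    zy = _standardize_rows(_rank_rows(y[idx]))
    boot = np.clip((zx * zy).mean(axis=-1), -1.0, 1.0)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    perm_y = y[np.argsort(rng.random((n_perm, y.size)), axis=1)]
    zxo = _standardize_rows(_rank_rows(x))
    zyp = _standardize_rows(_rank_rows(perm_y))
    null = np.clip(zyp @ zxo / x.size, -1.0, 1.0)
    p = _perm_p(null, r, sidedness)
    return {"r": r, "ci95": ci, "p": p, "boot": boot, "null": null}


def frequencywise_correlation(
    spectra: np.ndarray,
    ybocs: np.ndarray,
    freqs: np.ndarray,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    alpha_fw: float = 0.01,
    alpha_cluster: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Per-bin Spearman correlation of spectra with severity, cluster-corrected.

    Returns the R(f) curve, a bootstrap mean and 95% CI band, and a
    ``ClusterResult`` formed on the correlation statistic with an
    outcome-permutation null.
    """
    rng = np.random.default_rng(seed)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    ybocs = np.asarray(ybocs, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    n = ybocs.size
    if spectra.shape != (n, freqs.size):
        raise ValueError("spectra must be (n_units, n_freqs)")
    if n < 5:
        raise ValueError("need at least 5 units")
    if np.ptp(ybocs) == 0:
        raise ValueError("constant Y-BOCS: correlation undefined")

    r_obs = _spearman_vs_columns(ybocs, spectra)

    # bootstrap band over unit resamples (chunked)
    boot = np.empty((n_boot, freqs.size))
    chunk = max(1, 5_000_000 // (n * freqs.size))
    for s in range(0, n_boot, chunk):
        m = min(chunk, n_boot - s)
        idx = rng.integers(0, n, size=(m, n))
        zx = _standardize_rows(_rank_rows(np.swapaxes(spectra[idx], 1, 2)))
        zy = _standardize_rows(_rank_rows(ybocs[idx]))
        boot[s:s + m] = np.clip(np.einsum("bfn,bn->bf", zx, zy) / n, -1.0, 1.0)
    band = {
        "mean": boot.mean(axis=0),
        "lo": np.percentile(boot, 2.5, axis=0),
        "hi": np.percentile(boot, 97.5, axis=0),
    }

    # cluster correction with a permutation null on the outcome
    t_crit = sps.t.ppf(1 - alpha_cluster / 2, n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
    perm_y = ybocs[np.argsort(rng.random((n_perm, n)), axis=1)]
    zyp = _standardize_rows(_rank_rows(perm_y))
    zxo = _standardize_rows(_rank_rows(spectra.T))  # (F, n)
    r_null = zyp @ zxo.T / n
    null_max = _max_cluster_mass(r_null, np.full(freqs.size, r_crit))
    clusters = [
        {"f_lo": float(freqs[i]), "f_hi": float(freqs[j]), "mass": mass,
         "p": _perm_p(null_max, abs(mass), "right")}
        for i, j, mass in _cluster_spans(r_obs, np.full(freqs.size, r_crit))
    ]
    cluster_result = ClusterResult(freqs=freqs, stat=r_obs,
                                   crit=np.full(freqs.size, r_crit),
                                   clusters=clusters, alpha_fw=alpha_fw,
                                   null_max=null_max)
    return {"r": r_obs, "band": band, "clusters": cluster_result}


# ---------------------------------------------------------------------------
# longitudinal deltas and best-session contrast

def session_deltas(table: pd.DataFrame, alpha_col: str = "alpha") -> tuple[pd.DataFrame, float]:
    """Per-session changes vs S1: Y-BOCS as percentage, alpha as log-ratio.

    A positive Y-BOCS delta is clinical improvement; a negative alpha
    log-ratio is suppression of oscillatory power.  Alpha values that are not
    strictly positive (periodic power is a log residual) are made positive by
    one cohort-wide affine shift, returned as metadata.  S1 rows are excluded
    from the output; units with Y-BOCS 0 at S1 are dropped with a warning.
    """
    alpha = table[alpha_col].to_numpy(dtype=float)
    shift = 0.0
    if np.any(alpha <= 0):
        span = np.ptp(alpha)
        shift = float(-alpha.min() + (0.01 * span if span > 0 else 1.0))
        logger.info("session_deltas: shifting %s by %+.4g to positivity",
                    alpha_col, shift)
    work = table.assign(_alpha=alpha + shift)

    rows = []
    for (pid, hemi), grp in work.groupby(["patient_id", "hemisphere"]):
        grp = grp.sort_values("session_index")
        s1 = grp[grp["session_index"] == 1]
        if s1.empty:
            logger.warning("unit (%s, %s) has no S1; skipped", pid, hemi)
            continue
        y1 = float(s1["ybocs"].iloc[0])
        a1 = float(s1["_alpha"].iloc[0])
        if y1 == 0:
            logger.warning("unit (%s, %s) has Y-BOCS 0 at S1; dropped", pid, hemi)
            continue
        for _, row in grp[grp["session_index"] != 1].iterrows():
            rows.append({
                "patient_id": pid, "hemisphere": hemi,
                "session_index": int(row["session_index"]),
                "dybocs_pct": 100.0 * (y1 - float(row["ybocs"])) / y1,
                "dalpha_log": float(np.log(float(row["_alpha"]) / a1)),
            })
    return pd.DataFrame(rows), shift


def best_session_contrast(
    session_table: pd.DataFrame,
    spectra: dict[tuple, np.ndarray],
    freqs: np.ndarray,
    alpha_fw: float = 0.01,
    alpha_cluster: float = 0.05,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Paired cluster contrast of S1 vs each patient's best clinical session.

    ``session_table`` has one row per (patient_id, session_index) with
    ``ybocs`` and ``baseline_ybocs``; ``spectra`` maps those keys to per-unit
    spectra on ``freqs``.  The best session maximizes the baseline-relative
    Y-BOCS reduction (ties break to the earlier session); patients whose best
    session is S1 itself, or with only S1, are excluded.
    """
    a_rows, b_rows, chosen = [], [], {}
    for pid, grp in session_table.groupby("patient_id"):
        grp = grp.sort_values("session_index")
        if grp["session_index"].nunique() < 2 or 1 not in set(grp["session_index"]):
            logger.warning("patient %s lacks S1 + follow-up; excluded", pid)
            continue
        reduction = (grp["baseline_ybocs"] - grp["ybocs"]) / grp["baseline_ybocs"]
        best = grp.loc[reduction.idxmax()]
        best_session = int(best["session_index"])
        if best_session == 1:
            logger.warning("patient %s: best session is S1; excluded", pid)
            continue
        key1, keyb = (pid, 1), (pid, best_session)
        if key1 not in spectra or keyb not in spectra:
            continue
        chosen[pid] = best_session
        a_rows.append(spectra[key1])
        b_rows.append(spectra[keyb])
    if len(a_rows) < 2:
        raise ValueError("fewer than 2 patients eligible for the paired contrast")
    result = cluster_permutation_spectra(
        np.asarray(b_rows), np.asarray(a_rows), freqs, paired=True,
        alpha_fw=alpha_fw, alpha_cluster=alpha_cluster, n_perm=n_perm, seed=seed)
    return {"clusters": result, "best_sessions": chosen}


# ---------------------------------------------------------------------------
# linear mixed-effects model with Satterthwaite F tests

def _reml_loglike(X: np.ndarray, y: np.ndarray, group_idx: list[np.ndarray],
                  sb2: float, se2: float) -> float:
    """REML log-likelihood of a random-intercept Gaussian mixed model."""
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet = 0.0
    parts = []
    for idx in group_idx:
        Xi, yi = X[idx], y[idx]
        ni = idx.size
        c = sb2 / (se2 + ni * sb2)
        logdet += (ni - 1) * np.log(se2) + np.log(se2 + ni * sb2)
        sx, sy = Xi.sum(0), yi.sum()
        xtvx += (Xi.T @ Xi - c * np.outer(sx, sx)) / se2
        xtvy += (Xi.T @ yi - c * sx * sy) / se2
        parts.append((Xi, yi, c, sx, sy))
    beta = np.linalg.solve(xtvx, xtvy)
    quad = 0.0
    for Xi, yi, c, sx, sy in parts:
        ri = yi - Xi @ beta
        sr = ri.sum()
        quad += (ri @ ri - c * sr * sr) / se2
    sign, ld_xtvx = np.linalg.slogdet(xtvx)
    return -0.5 * (logdet + ld_xtvx + quad)


def _satterthwaite_df(X, y, group_idx, sb2, se2, contrast) -> float:
    """Satterthwaite denominator df for a single-row contrast L' beta."""

    def phi(theta):
        b2, e2 = theta
        p = X.shape[1]
        xtvx = np.zeros((p, p))
        for idx in group_idx:
            Xi = X[idx]
            c = b2 / (e2 + idx.size * b2)
            sx = Xi.sum(0)
            xtvx += (Xi.T @ Xi - c * np.outer(sx, sx)) / e2
        cov = np.linalg.inv(xtvx)
        return float(contrast @ cov @ contrast)

    theta = np.array([max(sb2, 1e-10), max(se2, 1e-10)])
    h = 1e-4 * np.maximum(theta, 1e-6)

    grad = np.empty(2)
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm[k] = max(tm[k] - h[k], 1e-12)
        grad[k] = (phi(tp) - phi(tm)) / (tp[k] - tm[k])

    def ll(theta_):
        return _reml_loglike(X, y, group_idx, max(theta_[0], 1e-12),
                             max(theta_[1], 1e-12))

    hess = np.empty((2, 2))
    for a in range(2):
        for b in range(a, 2):
            ta = theta.copy(); tb = theta.copy(); tab = theta.copy(); t0 = theta.copy()
            ta[a] += h[a]
            tb[b] += h[b]
            tab[a] += h[a]; tab[b] += h[b]
            hess[a, b] = hess[b, a] = (
                ll(tab) - ll(ta) - ll(tb) + ll(t0)) / (h[a] * h[b])
    try:
        cov_theta = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return float(y.size - X.shape[1])
    var_phi = float(grad @ cov_theta @ grad)
    if var_phi <= 0:
        return float(y.size - X.shape[1])
    df = 2.0 * phi(theta) ** 2 / var_phi
    return float(np.clip(df, 1.0, y.size - X.shape[1]))


def _build_design(table: pd.DataFrame, model: str, alpha_col: str) -> tuple:
    """Design matrix with centered covariates; hemisphere coded L = reference."""
    t = table.copy()

    def _center(col, scale=False):
        v = t[col].astype(float)
        v = v - v.mean()
        sd = v.std(ddof=0)
        return v / sd if scale and sd > 0 else v

    # alpha stays in its own units (the coefficient of interest); the
    # nuisance covariates are standardized for numerical conditioning
    t["alpha_c"] = _center(alpha_col)
    t["stim_c"] = _center("stim_amplitude_mA", scale=True)
    t["days_c"] = _center("days_since_dbs_onset", scale=True)
    cols = {"Intercept": np.ones(len(t))}
    if model == "pooled_interaction":
        hemi_r = (t["hemisphere"] == "R").astype(float).to_numpy()
        cols["Hemisphere[R]"] = hemi_r
        cols["alpha"] = t["alpha_c"].to_numpy()
        cols["Hemisphere[R]:alpha"] = hemi_r * t["alpha_c"].to_numpy()
    elif model == "per_hemisphere":
        cols["alpha"] = t["alpha_c"].to_numpy()
    else:
        raise ValueError(f"unknown model {model!r}")
    cols["stim_amplitude"] = t["stim_c"].to_numpy()
    cols["days_since_onset"] = t["days_c"].to_numpy()
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), t


def fit_lme(
    table: pd.DataFrame,
    model: str = "pooled_interaction",
    alpha_col: str = "alpha",
) -> dict:
    """REML fit of Y-BOCS on an alpha metric with a per-patient random intercept.

    ``pooled_interaction`` includes hemisphere and its interaction with alpha;
    ``per_hemisphere`` is the simpler model meant to be fitted on one
    hemisphere's rows.  Returns coefficients, SEs, variance components and
    Satterthwaite-approximate F tests per fixed effect.
    """
    import statsmodels.api as sm

    X, names, t = _build_design(table, model, alpha_col)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-8)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    counts = t.groupby("patient_id")["session_index"].nunique()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 patients with at least 2 sessions")

    y = t["ybocs"].to_numpy(dtype=float)
    groups = t["patient_id"].to_numpy()
    mod = sm.MixedLM(y, X, groups=groups)
    res, last_exc = None, None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            cand = mod.fit(reml=True, method=[method])
        except Exception as exc:  # optimizer-dependent linear-algebra errors
            last_exc = exc
            continue
        if cand.converged:
            res = cand
            break
        last_exc = RuntimeError(f"{method} did not converge")
    if res is None:
        raise RuntimeError(f"mixed model did not converge: {last_exc}") from last_exc

    sb2 = float(np.asarray(res.cov_re)[0, 0])
    se2 = float(res.scale)
    uniq = pd.unique(groups)
    group_idx = [np.flatnonzero(groups == g) for g in uniq]

    ftests = {}
    for i, name in enumerate(names):
        if name == "Intercept":
            continue
        contrast = np.zeros(X.shape[1])
        contrast[i] = 1.0
        beta_i = float(res.fe_params[i])
        se_i = float(res.bse_fe[i])
        fstat = (beta_i / se_i) ** 2 if se_i > 0 else np.inf
        df = _satterthwaite_df(X, y, group_idx, sb2, se2, contrast)
        ftests[name] = {"F": fstat, "df1": 1.0, "df2": df,
                        "p": float(sps.f.sf(fstat, 1, df))}

    return {
        "names": names,
        "beta": {n: float(b) for n, b in zip(names, res.fe_params)},
        "se": {n: float(s) for n, s in zip(names, res.bse_fe)},
        "sigma_b2": sb2,
        "sigma_e2": se2,
        "ftests": ftests,
        "n_obs": int(y.size),
        "n_patients": int(len(uniq)),
    }
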