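"""Optimal-stimulation-contact prediction from pseudo-monopolar power.

Contacts within each hemisphere are ranked by power (rank 1 = highest) and
compared against the contact(s) clinically chosen for therapeutic
stimulation.  Performance is summarized by the cumulative probability of
having found the optimal contact after testing the top-k ranked contacts, and
its AUC: the mean cumulative probability over the first n-1 tested contacts,
the convention under which a chance strategy on a 4-contact lead scores 0.5
and a predictor that always ranks the optimal contact first scores 1.
Hemispheres stimulated in a double-monopolar configuration count as found at
the better of their two optimal contacts' ranks.  All permutation p-values
use the +1-corrected estimator (1 + #{null >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionCurve", "PermutationResult", "compare_active_inactive",
    "rank_contacts", "chance_curve", "selection_curve", "auc",
    "auc_permutation_test", "rank_difference",
]


@dataclass
class SelectionCurve:
    """Cumulative probability of finding the optimal contact within top-k."""

    k: np.ndarray
    cum_prob: np.ndarray
    n_hemispheres: int

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.cum_prob = np.asarray(self.cum_prob, dtype=float)
        if np.any(np.diff(self.cum_prob) < -1e-12):
            raise ValueError("cumulative probability must be non-decreasing")


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    sidedness: str
    n_perm: int


def _perm_p(null: np.ndarray, observed: float, side: str) -> float:
    null = np.asarray(null, dtype=float)
    if side == "right":
        extreme = np.sum(null >= observed)
    elif side == "left":
        extreme = np.sum(null <= observed)
    elif side == "two":
        extreme = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown sidedness {side!r}")
    return float((1 + extreme) / (1 + null.size))


def compare_active_inactive(
    normalized: np.ndarray,
    is_active: np.ndarray,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
    null_pool: str = "all",
) -> PermutationResult:
    """Right-sided size-balanced permutation test of active vs inactive contacts.

    ``normalized`` are per-lead min-max normalized contact estimates pooled
    across hemispheres.  The observed statistic is the mean over active
    contacts; the null resamples subsets matched in size to the active set.
    With ``null_pool="all"`` (default) subsets are drawn from all contacts —
    a label-permutation null, calibrated under exchangeability.  With
    ``null_pool="inactive"`` subsets are drawn from the inactive contacts
    only, the display-oriented balanced-subsampling variant; its null omits
    the active values and is anti-conservative under the global null, so it
    is not the default.
    """
    rng = np.random.default_rng(seed)
    normalized = np.asarray(normalized, dtype=float)
    is_active = np.asarray(is_active, dtype=bool)
    active = normalized[is_active]
    inactive = normalized[~is_active]
    if active.size == 0:
        raise ValueError("no active contacts")
    if inactive.size == 0:
        raise ValueError("no inactive contacts")
    if null_pool not in ("all", "inactive"):
        raise ValueError("null_pool must be 'all' or 'inactive'")
    observed = float(active.mean())
    pool = normalized if null_pool == "all" else inactive
    k = min(active.size, pool.size)
    idx = np.argsort(rng.random((n_iter, pool.size)), axis=1)[:, :k]
    null = pool[idx].mean(axis=1)
    return PermutationResult(observed, null, _perm_p(null, observed, "right"),
                             "right", n_iter)


def rank_contacts(estimates: np.ndarray) -> np.ndarray:
    """Descending ranking of 4 contact estimates (rank 1 = highest power).

    Exact ties break toward the lower contact index, deterministically.
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.shape != (4,):
        raise ValueError("expected 4 contact estimates")
    order = np.lexsort((np.arange(4), -estimates))  # stable: index breaks ties
    ranks = np.empty(4, dtype=int)
    ranks[order] = np.arange(1, 5)
    return ranks


def chance_curve(n_contacts: int = 4) -> SelectionCurve:
    """Selection curve of blind sequential testing: k/n after k contacts."""
    if n_contacts < 2:
        raise ValueError("need at least 2 contacts")
    k = np.arange(1, n_contacts + 1)
    return SelectionCurve(k=k, cum_prob=k / n_contacts, n_hemispheres=0)


def _best_optimal_rank(ranks: np.ndarray, optimal: tuple[int, ...]) -> int:
    return int(min(ranks[c] for c in optimal))


def selection_curve(
    rankings: list[np.ndarray],
    optimal_contacts: list[tuple[int, ...]],
    n_contacts: int = 4,
) -> SelectionCurve:
    """Empirical cumulative selection curve over hemispheres."""
    best_ranks = []
    for ranks, optimal in zip(rankings, optimal_contacts, strict=True):
        if not optimal:
            continue
        best_ranks.append(_best_optimal_rank(np.asarray(ranks), tuple(optimal)))
    if not best_ranks:
        raise ValueError("no hemisphere has a labeled optimal contact")
    best_ranks = np.asarray(best_ranks)
    k = np.arange(1, n_contacts + 1)
    cum = np.array([(best_ranks <= kk).mean() for kk in k])
    return SelectionCurve(k=k, cum_prob=cum, n_hemispheres=best_ranks.size)


def auc(curve: SelectionCurve) -> float:
    """Mean cumulative probability over the first n-1 tested contacts."""
    if curve.k.size < 2:
        raise ValueError("curve must cover at least 2 contacts")
    return float(curve.cum_prob[:-1].mean())


def _random_rankings(rng: np.random.Generator, n_hemi: int, n_contacts: int) -> np.ndarray:
    """Independent uniform rank orders per hemisphere, shape (n_hemi, n_contacts)."""
    perm = np.argsort(rng.random((n_hemi, n_contacts)), axis=1)
    ranks = np.empty_like(perm)
    rows = np.arange(n_hemi)[:, None]
    ranks[rows, perm] = np.arange(1, n_contacts + 1)
    return ranks


def _null_best_ranks(rng, n_perm, n_opt_per_hemi, n_contacts=4):
    """Null best-optimal ranks: (n_perm, n_hemi) under shuffled rank order."""
    n_hemi = len(n_opt_per_hemi)
    out = np.empty((n_perm, n_hemi), dtype=int)
    for j, n_opt in enumerate(n_opt_per_hemi):
        # rank of the best of n_opt optimal contacts under a uniform ranking
        draws = np.argsort(rng.random((n_perm, n_contacts)), axis=1)[:, :n_opt] + 1
        out[:, j] = draws.min(axis=1)
    return out


def auc_permutation_test(
    rankings: list[np.ndarray],
    optimal_contacts: list[tuple[int, ...]],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    n_contacts: int = 4,
) -> PermutationResult:
    """Right-sided AUC test against per-hemisphere shuffled rank orders."""
    rng = np.random.default_rng(seed)
    curve = selection_curve(rankings, optimal_contacts, n_contacts)
    observed = auc(curve)
    n_opt = [len(o) for o in optimal_contacts if o]
    best = _null_best_ranks(rng, n_perm, n_opt, n_contacts)
    # AUC = mean over hemispheres of (n - best_rank) / (n - 1)
    null = ((n_contacts - best) / (n_contacts - 1)).mean(axis=1)
    return PermutationResult(observed, null, _perm_p(null, observed, "right"),
                             "right", n_perm)


def rank_difference(
    rankings: list[np.ndarray],
    optimal_contacts: list[tuple[int, ...]],
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    n_contacts: int = 4,
) -> dict:
    """Rank distance between clinically optimal (rank 1) and predicted rank.

    Returns per-hemisphere differences, their mean with a percentile bootstrap
    95% CI, and a left-sided permutation p against shuffled rankings.
    """
    rng = np.random.default_rng(seed)
    diffs = []
    n_opt = []
    for ranks, optimal in zip(rankings, optimal_contacts, strict=True):
        if not optimal:
            continue
        diffs.append(_best_optimal_rank(np.asarray(ranks), tuple(optimal)) - 1)
        n_opt.append(len(optimal))
    if not diffs:
        raise ValueError("no hemisphere has a labeled optimal contact")
    diffs = np.asarray(diffs, dtype=float)
    observed = float(diffs.mean())
    boot_idx = rng.integers(0, diffs.size, size=(n_boot, diffs.size))
    boot = diffs[boot_idx].mean(axis=1)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    null = (_null_best_ranks(rng, n_perm, n_opt, n_contacts) - 1).mean(axis=1)
    perm = PermutationResult(observed, null, _perm_p(null, observed, "left"),
                             "left", n_perm)
    return {"per_hemisphere": diffs, "mean": observed, "ci95": ci,
            "permutation": perm}
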