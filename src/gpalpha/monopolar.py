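"""Pseudo-monopolar projection of bipolar pair power onto lead contacts.

Bipolar recordings cannot be attributed to single contacts directly.  The
pattern-based rule used here assigns each contact the maximum of two
quantities: (1) the mean power of the three pairs that include the contact,
and (2) the power of pairs that span the contact without including it
(e.g. pair 0-2 spans contact 1).  Outer contacts 0 and 3 have no spanning
pair.  When several pairs span a contact their maximum is used, consistent
with the outer max rule (a mean variant is available via ``spanning="mean"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ALL_PAIRS

logger = logging.getLogger("gpalpha")

Pair = tuple[int, int]


@dataclass
class MonopolarMap:
    """Per-contact pseudo-monopolar power estimates for one 4-contact lead."""

    estimates: np.ndarray            # shape (4,)
    winning_rule: tuple[str, ...]    # "including_mean" or "spanning" per contact
    lead: tuple | None = None        # (patient, hemisphere, session) identity

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.estimates.shape != (4,) or not np.all(np.isfinite(self.estimates)):
            raise ValueError("a lead needs exactly 4 finite contact estimates")


def pseudo_monopolar(
    pair_powers: dict[Pair, float],
    lead: tuple | None = None,
    spanning: str = "max",
) -> MonopolarMap:
    """Project 6 bipolar pair powers onto 4 contact-level estimates."""
    if spanning not in ("max", "mean"):
        raise ValueError("spanning must be 'max' or 'mean'")
    pair_powers = {tuple(sorted(p)): float(v) for p, v in pair_powers.items()}
    unknown = set(pair_powers) - set(ALL_PAIRS)
    if unknown:
        raise ValueError(f"unknown pairs {sorted(unknown)}")
    if not pair_powers:
        raise ValueError("no pair powers supplied")
    if len(pair_powers) < len(ALL_PAIRS):
        missing = sorted(set(ALL_PAIRS) - set(pair_powers))
        logger.warning("lead %s: missing pairs %s; including-mean uses available pairs",
                       lead, missing)

    estimates = np.empty(4)
    rules = []
    for c in range(4):
        including = [v for (a, b), v in pair_powers.items() if c in (a, b)]
        if not including:
            raise ValueError(f"contact {c}: no pair including it is available")
        q1 = float(np.mean(including))
        spanning_vals = [v for (a, b), v in pair_powers.items() if a < c < b]
        if spanning_vals:
            q2 = float(np.max(spanning_vals) if spanning == "max"
                       else np.mean(spanning_vals))
        else:
            q2 = -np.inf
        if q2 > q1:
            estimates[c], rule = q2, "spanning"
        else:
            estimates[c], rule = q1, "including_mean"
        rules.append(rule)
    return MonopolarMap(estimates=estimates, winning_rule=tuple(rules), lead=lead)
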