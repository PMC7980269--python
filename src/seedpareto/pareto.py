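"""Pareto-front identification for the two emergence-timing objectives.

Populations are compared on two trait axes with fixed optimization
directions: *earlier* mean transformed emergence time (minimize) and
*larger* seed persistence fraction (maximize).  A population is on the
Pareto front when no other sampled population is at least as good in both
objectives and strictly better in at least one (weak dominance, the
default), or — under the strict rule — when no other population is strictly
better in both.  Both traits are weighted equally; weights do not affect
pure front membership and are recorded only as metadata.

``identify_front`` is an O(n log n) sort-and-sweep; ``front_oracle`` is the
exhaustive O(n^2) all-pairs check used as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParetoResult", "identify_front", "front_oracle"]

DIRECTIONS = {"mean_sqrt_emergence": "minimize", "persistence_fraction": "maximize"}


@dataclass(frozen=True)
class ParetoResult:
    """Front membership under declared optimization directions."""

    front_ids: tuple
    dominance_rule: str
    dominated_by: dict  # off-front id -> one witness dominator id
    directions: dict = field(default_factory=lambda: dict(DIRECTIONS))
    weights: dict = field(
        default_factory=lambda: {"mean_sqrt_emergence": 1.0, "persistence_fraction": 1.0}
    )

    def on_front(self, point_id) -> bool:
        return point_id in set(self.front_ids)


def _coerce_points(points) -> tuple[list, np.ndarray, np.ndarray]:
    """Accept a list of (id, emergence, persistence) or a DataFrame."""
    if isinstance(points, pd.DataFrame):
        ids = list(points["population_id"])
        emergence = points["mean_sqrt_emergence"].to_numpy(dtype=float)
        persistence = points["persistence_fraction"].to_numpy(dtype=float)
    else:
        ids = [p[0] for p in points]
        emergence = np.array([p[1] for p in points], dtype=float)
        persistence = np.array([p[2] for p in points], dtype=float)
    bad = ~(np.isfinite(emergence) & np.isfinite(persistence))
    if bad.any():
        culprit = [ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"missing or non-finite trait value for populations {culprit}")
    return ids, emergence, persistence


def _dominates(e_j, p_j, e_i, p_i, rule: str) -> bool:
    if rule == "weak":
        return e_j <= e_i and p_j >= p_i and (e_j < e_i or p_j > p_i)
    return e_j < e_i and p_j > p_i


def _sorted_result(ids, emergence, on_front_mask, dominated_by, rule) -> ParetoResult:
    order = sorted(
        (i for i in range(len(ids)) if on_front_mask[i]),
        key=lambda i: (emergence[i], str(ids[i])),
    )
    return ParetoResult(
        front_ids=tuple(ids[i] for i in order),
        dominance_rule=rule,
        dominated_by=dominated_by,
    )


def identify_front(points, rule: str = "weak") -> ParetoResult:
    """Non-dominated set by sort-and-sweep.

    Points are sorted by emergence ascending (persistence descending within
    ties); a point survives unless an already-swept point dominates it.  For
    off-front points one witness dominator is recorded.
    """
    if rule not in ("weak", "strict"):
        raise ValueError(f"unknown dominance rule {rule!r}")
    ids, emergence, persistence = _coerce_points(points)
    n = len(ids)
    if n == 0:
        raise ValueError("no points supplied")
    order = sorted(range(n), key=lambda i: (emergence[i], -persistence[i], str(ids[i])))
    on_front = np.zeros(n, dtype=bool)
    dominated_by: dict = {}
    best_p = -np.inf  # best persistence among swept points with e strictly smaller
    best_p_id = None
    # sweep groups of equal emergence together so equal-e points never
    # dominate each other under the weak rule via the persistence tie-break
    k = 0
    while k < n:
        grp = [order[k]]
        while k + 1 < n and emergence[order[k + 1]] == emergence[order[k]]:
            k += 1
            grp.append(order[k])
        k += 1
        grp_best_p = -np.inf
        grp_best_id = None
        for i in grp:
            if rule == "weak":
                # dominated by a strictly-earlier point with >= persistence,
                # or by an equal-emergence point with strictly greater persistence
                if best_p >= persistence[i]:
                    dominated_by[ids[i]] = best_p_id
                elif grp_best_p > persistence[i]:
                    dominated_by[ids[i]] = grp_best_id
                else:
                    on_front[i] = True
            else:
                if best_p > persistence[i]:
                    dominated_by[ids[i]] = best_p_id
                else:
                    on_front[i] = True
            if persistence[i] > grp_best_p:
                grp_best_p, grp_best_id = persistence[i], ids[i]
        if grp_best_p > best_p:
            best_p, best_p_id = grp_best_p, grp_best_id
    return _sorted_result(ids, emergence, on_front, dominated_by, rule)


def front_oracle(points, rule: str = "weak") -> ParetoResult:
    """Exhaustive all-pairs dominance check (independent cross-check)."""
    if rule not in ("weak", "strict"):
        raise ValueError(f"unknown dominance rule {rule!r}")
    ids, emergence, persistence = _coerce_points(points)
    n = len(ids)
    if n == 0:
        raise ValueError("no points supplied")
    on_front = np.ones(n, dtype=bool)
    dominated_by: dict = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if _dominates(emergence[j], persistence[j], emergence[i], persistence[i], rule):
                on_front[i] = False
                dominated_by[ids[i]] = ids[j]
                break
    return _sorted_result(ids, emergence, on_front, dominated_by, rule)
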