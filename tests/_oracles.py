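"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: overlap tail
probabilities come from explicit subset enumeration, exact Spearman
p-values from an explicit loop over permutations, and the coexpression
threshold rules from a from-scratch reimplementation on top of rank
transforms and the t formula.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations

import numpy as np
from scipy import stats as _st


def overlap_tail_by_enumeration(n: int, n_marked: int, n_drawn: int, x: int) -> Fraction:
    """P(overlap >= x) by enumerating all size-``n_drawn`` subsets of an
    ``n``-element universe whose first ``n_marked`` elements are marked."""
    total = 0
    hits = 0
    for subset in combinations(range(n), n_drawn):
        total += 1
        overlap = sum(1 for i in subset if i < n_marked)
        if overlap >= x:
            hits += 1
    if total == 0:
        return Fraction(1) if x == 0 else Fraction(0)
    return Fraction(hits, total)


def overlap_distribution_by_enumeration(n: int, n_marked: int, n_drawn: int) -> dict[int, Fraction]:
    """P(overlap == k) for all k, by subset enumeration."""
    counts: dict[int, int] = {}
    total = 0
    for subset in combinations(range(n), n_drawn):
        total += 1
        k = sum(1 for i in subset if i < n_marked)
        counts[k] = counts.get(k, 0) + 1
    return {k: Fraction(c, total) for k, c in counts.items()}


def exact_spearman_p_by_enumeration(x, y) -> float:
    """Two-sided exact permutation p for Spearman rho, one permutation
    at a time via np.corrcoef on ranks."""
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= rho_obs - 1e-9:
            hits += 1
    return hits / total


def coexpression_edges_by_bruteforce(
    candidates, matrix, labels, rho_min=0.5, p_max=0.01
):
    """Recompute the per-group positive-rho screen from scratch.

    Returns the set of (lnc_id, mrna_id, group) triples that pass
    ``rho > rho_min`` and two-sided t-approximation ``p < p_max``.
    """
    values = matrix.values
    groups = sorted(set(labels.values()))
    retained = set()
    for cand in candidates:
        if cand.lnc_id not in values.index or cand.mrna_id not in values.index:
            continue
        for g in groups:
            cols = [s for s in values.columns if labels[s] == g]
            xv = values.loc[cand.lnc_id, cols].to_numpy(dtype=float)
            yv = values.loc[cand.mrna_id, cols].to_numpy(dtype=float)
            rx = _st.rankdata(xv)
            ry = _st.rankdata(yv)
            if np.ptp(rx) == 0 or np.ptp(ry) == 0:
                continue
            rho = float(np.corrcoef(rx, ry)[0, 1])
            n = len(cols)
            if abs(rho) >= 1.0:
                p = 0.0
            else:
                t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
                p = 2.0 * float(_st.t.sf(abs(t), n - 2))
            if p < p_max and rho > rho_min:
                retained.add((cand.lnc_id, cand.mrna_id, g))
    return retained


def candidates_by_bruteforce(lnc_map, mrna_map, n_universe, min_shared=4, alpha=0.05):
    """Recompute the shared-target screen pair by pair with plain set
    intersections (no inverted index, no vectorisation)."""
    retained = set()
    for lid, lset in lnc_map.entries.items():
        for mid, mset in mrna_map.entries.items():
            x = len(lset & mset)
            if x < min_shared:
                continue
            p = float(_st.hypergeom.sf(x - 1, n_universe, len(lset), len(mset)))
            if p < alpha:
                retained.add((lid, mid))
    return retained
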