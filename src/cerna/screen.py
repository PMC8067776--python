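"""Hypergeometric screening of lncRNA-mRNA pairs by shared miRNA targets.

The ceRNA hypothesis predicts that a lncRNA and an mRNA sharing many
miRNA response elements compete for those miRNAs.  The screen asks, for
each lncRNA-mRNA pair, whether the number of shared targeting miRNAs is
larger than chance: with N miRNAs in the background, L of them targeting
the lncRNA and M targeting the mRNA, the shared count X under random
overlap is hypergeometric, and the evidence is the survival probability

    P(X >= x) = sum_{k=x}^{min(L,M)} C(L,k) C(N-L, M-k) / C(N,M).

A pair is a ceRNA candidate when x exceeds a shared-count floor (default
x >= 4, i.e. "more than 3" shared miRNAs) and the survival probability
is below alpha (default 0.05, uncorrected; Benjamini-Hochberg optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactions import MirnaUniverse, TargetMap, UniverseError

logger = logging.getLogger(__name__)

CORRECTIONS = ("none", "benjamini_hochberg")


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of one shared-target test.

    n_universe
        Background miRNA count (N).
    n_lnc_targets
        miRNAs targeting the lncRNA (L).
    n_mrna_targets
        miRNAs targeting the mRNA (M).
    n_shared
        miRNAs targeting both (x), the observed overlap.
    """

    n_universe: int
    n_lnc_targets: int
    n_mrna_targets: int
    n_shared: int

    def __post_init__(self) -> None:
        for name in ("n_universe", "n_lnc_targets", "n_mrna_targets", "n_shared"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.n_lnc_targets > self.n_universe:
            raise ValueError("n_lnc_targets exceeds universe size")
        if self.n_mrna_targets > self.n_universe:
            raise ValueError("n_mrna_targets exceeds universe size")
        if not (0 <= self.n_shared <= min(self.n_lnc_targets, self.n_mrna_targets)):
            raise ValueError("n_shared outside [0, min(L, M)]")

    def sf(self) -> float:
        return hypergeom_sf(
            self.n_universe, self.n_lnc_targets, self.n_mrna_targets, self.n_shared
        )


@dataclass(frozen=True)
class CandidatePair:
    """A screened lncRNA-mRNA pair with its hypergeometric evidence."""

    lnc_id: str
    mrna_id: str
    params: HypergeomParams
    shared_ids: frozenset[str]
    p_value: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if len(self.shared_ids) != self.params.n_shared:
            raise ValueError("shared_ids size inconsistent with n_shared")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.q_value is not None and self.q_value < self.p_value - 1e-15:
            raise ValueError("q_value below p_value")


@dataclass(frozen=True)
class ScreenStats:
    """Counts emitted by one run of :func:`screen_pairs`."""

    n_lnc: int
    n_mrna: int
    pairs_evaluated: int      # pairs with nonzero shared-target overlap
    pairs_min_shared: int     # pairs meeting the shared-count floor
    pairs_retained: int       # pairs also meeting the significance cut


def shared_mirnas(lnc_targets: frozenset[str], mrna_targets: frozenset[str]) -> frozenset[str]:
    """Exact intersection of two nonempty miRNA target sets."""
    if not lnc_targets or not mrna_targets:
        raise ValueError("target sets must be nonempty")
    return frozenset(lnc_targets) & frozenset(mrna_targets)


def hypergeom_sf(
    n_universe: int, n_lnc_targets: int, n_mrna_targets: int, n_shared: int
) -> float:
    """Survival probability P(X >= x) of the shared-target overlap.

    X is hypergeometric: ``n_mrna_targets`` draws without replacement
    from a universe of ``n_universe`` miRNAs of which ``n_lnc_targets``
    are marked.  Computed in log space (log-gamma) by scipy, so it is
    stable for universes of many thousands of miRNAs.  An overlap larger
    than ``min(L, M)`` is impossible and yields 0.0.
    """
    if n_lnc_targets > n_universe or n_mrna_targets > n_universe:
        raise ValueError("target-set size exceeds universe size")
    if min(n_universe, n_lnc_targets, n_mrna_targets, n_shared) < 0:
        raise ValueError("negative hypergeometric parameter")
    if n_shared == 0:
        return 1.0
    if n_shared > min(n_lnc_targets, n_mrna_targets):
        return 0.0
    return float(
        stats.hypergeom.sf(n_shared - 1, n_universe, n_lnc_targets, n_mrna_targets)
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def screen_pairs(
    lnc_map: TargetMap,
    mrna_map: TargetMap,
    universe: MirnaUniverse,
    min_shared: int = 4,
    alpha: float = 0.05,
    correction: str = "none",
) -> tuple[list[CandidatePair], ScreenStats]:
    """Screen every lncRNA-mRNA pair for shared-miRNA enrichment.

    Returns the candidate pairs with ``x >= min_shared`` whose p-value
    (q-value under ``benjamini_hochberg``) is below ``alpha``, sorted by
    ascending p then (lnc_id, mrna_id), together with screen statistics.
    The BH family is the set of pairs meeting the shared-count floor.

    Overlap counts for all pairs are obtained with one boolean
    matrix product over an inverted miRNA index, so all-vs-all screening
    stays tractable at database scale.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if not lnc_map.entries or not mrna_map.entries:
        raise ValueError("target maps must be nonempty")
    max_set = max(lnc_map.max_target_set_size(), mrna_map.max_target_set_size())
    if universe.size < max_set:
        raise UniverseError(
            f"universe ({universe.size}) smaller than the largest target set ({max_set})"
        )

    lnc_ids = sorted(lnc_map.entries)
    mrna_ids = sorted(mrna_map.entries)
    mir_ids = sorted(lnc_map.mirna_ids() | mrna_map.mirna_ids())
    mir_index = {m: j for j, m in enumerate(mir_ids)}

    A = np.zeros((len(lnc_ids), len(mir_ids)), dtype=np.int32)
    for i, lid in enumerate(lnc_ids):
        A[i, [mir_index[m] for m in lnc_map.entries[lid]]] = 1
    B = np.zeros((len(mrna_ids), len(mir_ids)), dtype=np.int32)
    for j, mid in enumerate(mrna_ids):
        B[j, [mir_index[m] for m in mrna_map.entries[mid]]] = 1

    X = A @ B.T  # shared-target counts for every pair
    L = A.sum(axis=1)
    M = B.sum(axis=1)

    pairs_evaluated = int((X > 0).sum())
    cand_i, cand_j = np.nonzero(X >= min_shared)
    pairs_min_shared = cand_i.size

    pvals = stats.hypergeom.sf(
        X[cand_i, cand_j] - 1, universe.size, L[cand_i], M[cand_j]
    ).astype(float)
    qvals = bh_adjust(pvals) if correction == "benjamini_hochberg" else None

    retained: list[CandidatePair] = []
    for k in range(pairs_min_shared):
        score = qvals[k] if qvals is not None else pvals[k]
        if score >= alpha:
            continue
        i, j = int(cand_i[k]), int(cand_j[k])
        lid, mid = lnc_ids[i], mrna_ids[j]
        shared = shared_mirnas(lnc_map.entries[lid], mrna_map.entries[mid])
        retained.append(
            CandidatePair(
                lnc_id=lid,
                mrna_id=mid,
                params=HypergeomParams(
                    n_universe=universe.size,
                    n_lnc_targets=int(L[i]),
                    n_mrna_targets=int(M[j]),
                    n_shared=int(X[i, j]),
                ),
                shared_ids=shared,
                p_value=float(pvals[k]),
                q_value=float(qvals[k]) if qvals is not None else None,
            )
        )
    retained.sort(key=lambda c: (c.p_value, c.lnc_id, c.mrna_id))
    stats_out = ScreenStats(
        n_lnc=len(lnc_ids),
        n_mrna=len(mrna_ids),
        pairs_evaluated=pairs_evaluated,
        pairs_min_shared=int(pairs_min_shared),
        pairs_retained=len(retained),
    )
    logger.info(
        "screen: %d x %d pairs, %d with overlap, %d with x>=%d, %d retained at alpha=%g (%s)",
        stats_out.n_lnc, stats_out.n_mrna, pairs_evaluated,
        pairs_min_shared, min_shared, len(retained), alpha, correction,
    )
    return retained, stats_out


CANDIDATE_COLUMNS = [
    "lnc_id", "mrna_id", "N", "L", "M", "x", "shared_mirnas", "p_value", "q_value",
]


def write_candidates(pairs: Iterable[CandidatePair], path: str | Path) -> None:
    """Write candidate pairs as TSV (shared miRNAs comma-joined, sorted)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in pairs:
            q = "" if c.q_value is None else repr(c.q_value)
            fh.write(
                "\t".join([
                    c.lnc_id, c.mrna_id,
                    str(c.params.n_universe), str(c.params.n_lnc_targets),
                    str(c.params.n_mrna_targets), str(c.params.n_shared),
                    ",".join(sorted(c.shared_ids)),
                    repr(c.p_value), q,
                ]) + "\n"
            )


def read_candidates(path: str | Path) -> list[CandidatePair]:
    """Read a candidate-pair TSV written by :func:`write_candidates`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing candidate column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        shared = frozenset(s for s in row.shared_mirnas.split(",") if s)
        out.append(
            CandidatePair(
                lnc_id=row.lnc_id,
                mrna_id=row.mrna_id,
                params=HypergeomParams(
                    n_universe=int(row.N), n_lnc_targets=int(row.L),
                    n_mrna_targets=int(row.M), n_shared=int(row.x),
                ),
                shared_ids=shared,
                p_value=float(row.p_value),
                q_value=float(row.q_value) if row.q_value else None,
            )
        )
    return out
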