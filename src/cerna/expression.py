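"""Expression filtering and group-wise Spearman coexpression screening.

Candidate ceRNA pairs from the hypergeometric screen are only kept when
the lncRNA and mRNA are actually coexpressed.  Genes must first be
expressed (nonzero) in more than half of the samples; the surviving
candidates are then tested for Spearman correlation within each sample
group (e.g. disease vs control), and an edge is retained when rho
exceeds a floor (default 0.5, signed positive) at p below a cap
(default 0.01).

Two p-value methods are available.  The asymptotic t approximation
(`t = rho * sqrt((n-2)/(1-rho^2))`) is the default; the exact
full-permutation null is provided for small n, where it is the honest
choice — with n = 4 samples the smallest achievable exact two-sided p is
2/24 ≈ 0.083, so no edge can ever clear p < 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .screen import CandidatePair, HypergeomParams

logger = logging.getLogger(__name__)

GENE_CLASSES = ("lncRNA", "mRNA", "unknown")
P_METHODS = ("auto", "asymptotic_t", "exact_permutation")
SIGN_MODES = ("positive", "absolute")
SCOPE_MODES = ("per_group", "pooled")

# n! permutations are enumerated exactly up to this n (auto mode)
EXACT_N_MAX = 9


class ConstantInputError(ValueError):
    """A vector has zero rank variance; Spearman rho is undefined."""


class GroupTooSmallError(ValueError):
    """A sample group has fewer than 3 samples; correlation undefined."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative gene-by-sample expression values with gene classes.

    ``values`` is a genes x samples DataFrame (gene ids as index, sample
    ids as columns).  ``gene_class`` maps each gene to lncRNA / mRNA /
    unknown; genes absent from the mapping are treated as unknown.
    """

    values: pd.DataFrame
    gene_class: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("expression values must be finite and >= 0")
        for g, cls in self.gene_class.items():
            if cls not in GENE_CLASSES:
                raise ValueError(f"unknown gene class {cls!r} for {g!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def class_of(self, gene_id: str) -> str:
        return self.gene_class.get(gene_id, "unknown")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "asymptotic_t" | "exact_permutation"


@dataclass(frozen=True)
class CoexpressionResult:
    """One retained lncRNA-mRNA edge in one sample group."""

    lnc_id: str
    mrna_id: str
    group: str
    rho: float
    p_value: float
    n_samples: int
    method: str
    candidate: CandidatePair | None = None

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("rho outside [-1, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 for a defined p")


def read_expression(
    path: str | Path, gene_class: dict[str, str] | None = None
) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df.astype(float), gene_class=dict(gene_class or {}))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id, group`` into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing label column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in label table")
    return dict(zip(df["sample_id"], df["group"]))


def write_group_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in labels.items():
            fh.write(f"{s}\t{g}\n")


def filter_expressed(
    matrix: ExpressionMatrix, min_fraction: float = 0.5, strict: bool = True
) -> ExpressionMatrix:
    """Keep genes expressed (value > 0) in more than ``min_fraction`` of samples.

    With the defaults this is the "nonzero in more than half of the
    samples" rule: a gene passes when its nonzero-sample count strictly
    exceeds ``min_fraction * n_samples`` (or is >= it when
    ``strict=False``).  The sample set is unchanged; the operation is
    idempotent.
    """
    if not (0 <= min_fraction < 1):
        raise ValueError("min_fraction must be in [0, 1)")
    n_samples = matrix.values.shape[1]
    if n_samples == 0:
        raise ValueError("expression matrix has zero samples")
    counts = (matrix.values > 0).sum(axis=1)
    cutoff = min_fraction * n_samples
    keep = counts > cutoff if strict else counts >= cutoff
    removed = matrix.values.index[~keep]
    by_class: dict[str, int] = {}
    for g in removed:
        by_class[matrix.class_of(g)] = by_class.get(matrix.class_of(g), 0) + 1
    logger.info(
        "expression filter: removed %d of %d genes (%s)",
        len(removed), len(matrix.values), by_class or "none",
    )
    return ExpressionMatrix(
        values=matrix.values.loc[keep], gene_class=matrix.gene_class
    )


# --- Spearman -----------------------------------------------------------

_null_cache: dict[int, np.ndarray] = {}


def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    if n not in _null_cache:
        base = np.arange(1, n + 1, dtype=float)
        perms = np.array(list(permutations(base)))
        d2 = ((perms - base) ** 2).sum(axis=1)
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        _null_cache[n] = np.sort(np.abs(rho))
    return _null_cache[n]


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman(x, y, p_method: str = "auto") -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average (midrank) ranks, hence
    invariant under strictly increasing transforms of either vector and
    symmetric in its arguments.  ``auto`` enumerates the full
    permutation null exactly for tie-free vectors with n <= 9 and falls
    back to the t approximation otherwise.
    """
    if p_method not in P_METHODS:
        raise ValueError(f"p_method must be one of {P_METHODS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0:
        raise ConstantInputError("x has zero rank variance; rho undefined")
    if np.ptp(ry) == 0:
        raise ConstantInputError("y has zero rank variance; rho undefined")

    ties = (np.unique(rx).size < n) or (np.unique(ry).size < n)
    if p_method == "auto":
        p_method = "exact_permutation" if (n <= EXACT_N_MAX and not ties) else "asymptotic_t"

    if p_method == "asymptotic_t":
        rho, p = stats.spearmanr(x, y)
        return SpearmanResult(rho=float(rho), p_value=float(p), n=n, method="asymptotic_t")

    # exact permutation
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > EXACT_N_MAX:
        raise ValueError(f"exact permutation limited to n <= {EXACT_N_MAX}")
    if not ties:
        null = _exact_null_abs_rho(n)
        k = null.size - np.searchsorted(null, abs(rho) - 1e-9, side="left")
        p = k / null.size
    else:
        # ties: permute the observed midranks of y
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = math.sqrt(float(rxc @ rxc)) * np.sqrt((pc * pc).sum(axis=1))
        rho_null = num / den
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-9))
    return SpearmanResult(rho=rho, p_value=float(p), n=n, method="exact_permutation")


def coexpression_filter(
    candidates: list[CandidatePair],
    matrix: ExpressionMatrix,
    labels: dict[str, str],
    rho_min: float = 0.5,
    p_max: float = 0.01,
    sign: str = "positive",
    scope: str = "per_group",
    p_method: str = "asymptotic_t",
) -> list[CoexpressionResult]:
    """Apply the Spearman coexpression screen to candidate pairs.

    Under ``per_group`` scope (default) every candidate is evaluated
    separately within each group's samples, yielding group-specific edge
    lists from which per-group ceRNA networks are built; ``pooled``
    evaluates one correlation across all samples.  An edge is retained
    iff ``p < p_max`` and ``rho > rho_min`` (``|rho| > rho_min`` under
    ``sign="absolute"``).  Candidates whose genes are missing from the
    matrix are skipped (counted in the log); pairs with zero rank
    variance in a group are skipped likewise.  Output is sorted by
    (group, lnc_id, mrna_id).
    """
    if sign not in SIGN_MODES:
        raise ValueError(f"sign must be one of {SIGN_MODES}")
    if scope not in SCOPE_MODES:
        raise ValueError(f"scope must be one of {SCOPE_MODES}")
    if not (0 < p_max <= 1) or not (0 <= rho_min < 1):
        raise ValueError("thresholds outside valid ranges")
    unlabeled = [s for s in matrix.sample_ids if s not in labels]
    if unlabeled:
        raise ValueError(f"samples without group label: {unlabeled}")

    if scope == "per_group":
        groups = sorted({labels[s] for s in matrix.sample_ids})
        group_samples = {
            g: [s for s in matrix.sample_ids if labels[s] == g] for g in groups
        }
    else:
        group_samples = {"pooled": list(matrix.sample_ids)}
    for g, samples in group_samples.items():
        if len(samples) < 3:
            raise GroupTooSmallError(
                f"group {g!r} has {len(samples)} samples; need >= 3"
            )

    present = set(matrix.gene_ids)
    values = matrix.values
    n_skipped_missing = 0
    n_skipped_constant = 0
    retained: list[CoexpressionResult] = []
    for cand in candidates:
        if cand.lnc_id not in present or cand.mrna_id not in present:
            n_skipped_missing += 1
            continue
        xv = values.loc[cand.lnc_id].to_numpy(dtype=float)
        yv = values.loc[cand.mrna_id].to_numpy(dtype=float)
        col_index = {s: k for k, s in enumerate(matrix.sample_ids)}
        for g, samples in group_samples.items():
            idx = [col_index[s] for s in samples]
            try:
                res = spearman(xv[idx], yv[idx], p_method=p_method)
            except ConstantInputError:
                n_skipped_constant += 1
                continue
            effect = res.rho if sign == "positive" else abs(res.rho)
            if res.p_value < p_max and effect > rho_min:
                retained.append(
                    CoexpressionResult(
                        lnc_id=cand.lnc_id,
                        mrna_id=cand.mrna_id,
                        group=g,
                        rho=res.rho,
                        p_value=res.p_value,
                        n_samples=res.n,
                        method=res.method,
                        candidate=cand,
                    )
                )
    retained.sort(key=lambda r: (r.group, r.lnc_id, r.mrna_id))
    logger.info(
        "coexpression: %d candidates x %d group(s) -> %d edges retained "
        "(%d pairs absent from matrix, %d constant-input evaluations skipped)",
        len(candidates), len(group_samples), len(retained),
        n_skipped_missing, n_skipped_constant,
    )
    return retained


EDGE_COLUMNS = [
    "lnc_id", "mrna_id", "group", "rho", "p_value", "n_samples", "method",
    "N", "L", "M", "x", "shared_mirnas", "p_hyper", "q_hyper",
]


def write_edges(edges: list[CoexpressionResult], path: str | Path) -> None:
    """Write retained coexpression edges as TSV, hypergeometric evidence
    carried through from the candidate screen."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in edges:
            c = e.candidate
            hyper = (
                ["", "", "", "", "", "", ""] if c is None else [
                    str(c.params.n_universe), str(c.params.n_lnc_targets),
                    str(c.params.n_mrna_targets), str(c.params.n_shared),
                    ",".join(sorted(c.shared_ids)), repr(c.p_value),
                    "" if c.q_value is None else repr(c.q_value),
                ]
            )
            fh.write(
                "\t".join([
                    e.lnc_id, e.mrna_id, e.group, repr(e.rho), repr(e.p_value),
                    str(e.n_samples), e.method, *hyper,
                ]) + "\n"
            )


def read_edges(path: str | Path) -> list[CoexpressionResult]:
    """Read an edge TSV written by :func:`write_edges`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing edge column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        cand = None
        if row.N:
            cand = CandidatePair(
                lnc_id=row.lnc_id,
                mrna_id=row.mrna_id,
                params=HypergeomParams(
                    n_universe=int(row.N), n_lnc_targets=int(row.L),
                    n_mrna_targets=int(row.M), n_shared=int(row.x),
                ),
                shared_ids=frozenset(s for s in row.shared_mirnas.split(",") if s),
                p_value=float(row.p_hyper),
                q_value=float(row.q_hyper) if row.q_hyper else None,
            )
        out.append(
            CoexpressionResult(
                lnc_id=row.lnc_id, mrna_id=row.mrna_id, group=row.group,
                rho=float(row.rho), p_value=float(row.p_value),
                n_samples=int(row.n_samples), method=row.method, candidate=cand,
            )
        )
    return out
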