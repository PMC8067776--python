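"""Synthetic interaction tables and expression data with planted ceRNA pairs.

Every stage of the pipeline is testable without database downloads: the
generator emits (a) two bipartite miRNA-target maps with heavy-tailed
target-set sizes, into which a chosen number of lncRNA-mRNA pairs with a
guaranteed shared-miRNA count are planted, and (b) a two-group
expression matrix in which each planted pair is Spearman-correlated at a
target rho while all other genes are independent.

Correlation is planted through a Gaussian copula: latent bivariate
normals with Pearson correlation r = 2 sin(pi * rho_s / 6) have expected
Spearman correlation rho_s, and pushing the latent values through any
strictly increasing marginal (here lognormal, mimicking expression skew)
preserves ranks and hence Spearman exactly.  Optional dropout zeroes
values independently, exercising the expressed-in-more-than-half filter
(dropout is applied after correlation generation and attenuates the
realised rho).

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CoexpressionResult, ExpressionMatrix
from .interactions import TargetMap, write_target_map
from .expression import write_expression, write_group_labels

logger = logging.getLogger(__name__)

TARGET_COUNT_LAWS = ("fixed", "heavy_tailed")

# lognormal marginal: exp(mu + sigma * z); any strictly increasing map
# preserves Spearman, these just shape the scale
LOGNORM_MU = 3.0
LOGNORM_SIGMA = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the desk-scale recovery design: 200 miRNAs, 50 lncRNAs,
    300 mRNAs, 40 planted pairs each sharing 6 miRNAs and coexpressed at
    Spearman 0.85 in both groups, 20 samples per group, no dropout.
    Group sizes are larger than a 7-vs-4 clinical design so the
    correlation screen has nontrivial power; see
    :func:`study_scale_config` for the small-cohort variant.
    """

    n_mirna: int = 200
    n_lnc: int = 50
    n_mrna: int = 300
    target_count_law: str = "heavy_tailed"
    target_law_exponent: float = 3.0
    target_min: int = 5
    target_max: int | None = None  # default n_mirna // 2
    fixed_target_count: int = 10
    n_planted: int = 40
    planted_shared: int = 6
    groups: tuple[tuple[str, int], ...] = (("ALS", 20), ("control", 20))
    planted_rho: float = 0.85
    dropout_rate: float = 0.0
    hub_lnc_pairs: int = 0  # plant this many pairs on one hub lncRNA
    seed: int = 42

    def __post_init__(self) -> None:
        if self.target_count_law not in TARGET_COUNT_LAWS:
            raise ValueError(f"target_count_law must be one of {TARGET_COUNT_LAWS}")
        if not (0 < self.planted_rho < 1):
            raise ValueError("planted_rho must be in (0, 1)")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.planted_shared > self.n_mirna:
            raise ValueError("planted_shared exceeds the miRNA pool")
        if self.n_planted > min(self.n_mrna, self.n_lnc * self.n_mrna):
            raise ValueError("n_planted exceeds the available distinct pairs")
        if self.hub_lnc_pairs > self.n_planted:
            raise ValueError("hub_lnc_pairs exceeds n_planted")
        if self.effective_target_max() < self.target_min:
            raise ValueError("target_max below target_min")
        if self.planted_shared > self.effective_target_max() + self.planted_shared:
            raise ValueError("planted_shared infeasible")
        for name, n in self.groups:
            if n < 1:
                raise ValueError(f"group {name!r} has no samples")

    def effective_target_max(self) -> int:
        return self.target_max if self.target_max is not None else self.n_mirna // 2


def study_scale_config(**overrides) -> SimConfig:
    """The small-cohort design: 7 disease vs 4 control samples.

    Provided to demonstrate the power problem of correlation screening
    at clinical cohort sizes (an exact two-sided Spearman p with n = 4
    can never reach 0.01).
    """
    base = SimConfig(groups=(("ALS", 7), ("control", 4)))
    return replace(base, **overrides)


@dataclass(frozen=True)
class PlantedPair:
    lnc_id: str
    mrna_id: str
    shared_mirna_ids: frozenset[str]
    planted_rho: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Ledger of planted structure, for recovery evaluation."""

    planted_pairs: tuple[PlantedPair, ...]
    hub_ids: tuple[str, ...] = ()

    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((p.lnc_id, p.mrna_id) for p in self.planted_pairs)


@dataclass(frozen=True)
class RecoveryResult:
    """Sensitivity/precision of planted-pair recovery.

    ``precision`` is None (explicit NA) when nothing was retained.
    """

    sensitivity: float
    precision: float | None
    n_planted: int
    n_retained: int
    n_true_positive: int
    n_false_positive: int
    table: pd.DataFrame


def _mirna_id(i: int) -> str:
    return f"mir{i:04d}"


def _lnc_id(i: int) -> str:
    return f"LNC{i:04d}"


def _mrna_id(i: int) -> str:
    return f"MRNA{i:04d}"


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _target_set_sizes(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.target_count_law == "fixed":
        return np.full(n, config.fixed_target_count, dtype=int)
    lo, hi = config.target_min, config.effective_target_max()
    support = np.arange(lo, hi + 1, dtype=float)
    w = support ** (-config.target_law_exponent)
    w /= w.sum()
    return rng.choice(np.arange(lo, hi + 1), size=n, p=w)


def simulate_interactions(
    config: SimConfig,
) -> tuple[TargetMap, TargetMap, SyntheticTruth]:
    """Generate the two miRNA-target maps with planted shared-target pairs.

    Background target sets are drawn independently per regulator under
    the configured size law (heavy-tailed by default, so a few
    regulators have many targets).  For each planted pair,
    ``planted_shared`` specific miRNAs are forced into both regulators'
    sets, guaranteeing an overlap of at least that size.  With
    ``hub_lnc_pairs > 0`` the first that-many pairs all attach to a
    single lncRNA, planting a network hub.
    """
    rng = _rng(config.seed, 1)
    lnc_sizes = _target_set_sizes(config, config.n_lnc, rng)
    mrna_sizes = _target_set_sizes(config, config.n_mrna, rng)

    lnc_sets: list[set[str]] = []
    for i in range(config.n_lnc):
        idx = rng.choice(config.n_mirna, size=lnc_sizes[i], replace=False)
        lnc_sets.append({_mirna_id(j) for j in idx})
    mrna_sets: list[set[str]] = []
    for i in range(config.n_mrna):
        idx = rng.choice(config.n_mirna, size=mrna_sizes[i], replace=False)
        mrna_sets.append({_mirna_id(j) for j in idx})

    # planted pairs: distinct mRNAs (so each mRNA follows one lncRNA in
    # the expression model); lncRNAs may repeat, forming natural hubs
    mrna_pick = rng.choice(config.n_mrna, size=config.n_planted, replace=False)
    lnc_pick = rng.integers(0, config.n_lnc, size=config.n_planted)
    hub_ids: tuple[str, ...] = ()
    if config.hub_lnc_pairs > 0:
        hub = int(rng.integers(0, config.n_lnc))
        lnc_pick[: config.hub_lnc_pairs] = hub
        hub_ids = (_lnc_id(hub),)

    planted: list[PlantedPair] = []
    for li, mi in zip(lnc_pick, mrna_pick):
        forced = rng.choice(config.n_mirna, size=config.planted_shared, replace=False)
        forced_ids = {_mirna_id(j) for j in forced}
        lnc_sets[li] |= forced_ids
        mrna_sets[mi] |= forced_ids
        planted.append(
            PlantedPair(
                lnc_id=_lnc_id(li),
                mrna_id=_mrna_id(mi),
                shared_mirna_ids=frozenset(forced_ids),
                planted_rho=config.planted_rho,
            )
        )

    lnc_map = TargetMap(
        regulator_class="lncRNA",
        entries={_lnc_id(i): frozenset(s) for i, s in enumerate(lnc_sets)},
        source_label="synthetic",
    )
    mrna_map = TargetMap(
        regulator_class="mRNA",
        entries={_mrna_id(i): frozenset(s) for i, s in enumerate(mrna_sets)},
        source_label="synthetic",
    )
    truth = SyntheticTruth(planted_pairs=tuple(planted), hub_ids=hub_ids)
    logger.info(
        "simulated interactions: %d lncRNAs, %d mRNAs, %d miRNAs, %d planted pairs",
        config.n_lnc, config.n_mrna, config.n_mirna, config.n_planted,
    )
    return lnc_map, mrna_map, truth


def rho_spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving expected Spearman ``rho_s``
    under a Gaussian copula: r = 2 sin(pi * rho_s / 6)."""
    if abs(rho_s) >= 1:
        raise ValueError("|rho_s| must be < 1")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_expression(
    config: SimConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Generate the two-group expression matrix matching the truth ledger.

    Within each group, each planted mRNA's latent values are a mixture
    of its lncRNA's latents and fresh noise with Pearson weight
    r = 2 sin(pi * planted_rho / 6); all other genes are independent
    standard normals.  Latents map through the lognormal quantile
    transform and dropout (if any) zeroes entries independently.
    """
    rng = _rng(config.seed, 2)
    lnc_ids = [_lnc_id(i) for i in range(config.n_lnc)]
    mrna_ids = [_mrna_id(i) for i in range(config.n_mrna)]
    gene_ids = lnc_ids + mrna_ids
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    r = rho_spearman_to_pearson(config.planted_rho)

    blocks = []
    labels: dict[str, str] = {}
    sample_ids: list[str] = []
    for gname, n_s in config.groups:
        if n_s < 1:
            raise ValueError(f"group {gname!r} has 0 samples")
        z = rng.standard_normal((len(gene_ids), n_s))
        for pair in truth.planted_pairs:
            li = gene_index[pair.lnc_id]
            mi = gene_index[pair.mrna_id]
            z[mi] = r * z[li] + math.sqrt(1.0 - r * r) * rng.standard_normal(n_s)
        vals = np.exp(LOGNORM_MU + LOGNORM_SIGMA * z)
        if config.dropout_rate > 0:
            vals[rng.random(vals.shape) < config.dropout_rate] = 0.0
        blocks.append(vals)
        for k in range(n_s):
            sid = f"{gname}_s{k + 1:02d}"
            sample_ids.append(sid)
            labels[sid] = gname

    values = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=gene_ids, columns=sample_ids
    )
    gene_class = {g: "lncRNA" for g in lnc_ids}
    gene_class.update({g: "mRNA" for g in mrna_ids})
    return ExpressionMatrix(values=values, gene_class=gene_class), labels


def evaluate_recovery(
    retained_edges: list[CoexpressionResult], truth: SyntheticTruth
) -> RecoveryResult:
    """Score retained edges against the planted-pair ledger.

    A planted pair counts as recovered when it is retained in at least
    one group.  Sensitivity = recovered / planted; precision =
    recovered planted pairs / all retained pairs (None when nothing was
    retained).
    """
    retained_pairs = sorted({(e.lnc_id, e.mrna_id) for e in retained_edges})
    groups_by_pair: dict[tuple[str, str], set[str]] = {}
    for e in retained_edges:
        groups_by_pair.setdefault((e.lnc_id, e.mrna_id), set()).add(e.group)

    planted = truth.pair_set()
    tp = [p for p in retained_pairs if p in planted]
    fp = [p for p in retained_pairs if p not in planted]
    sensitivity = len(tp) / len(planted) if planted else float("nan")
    precision = len(tp) / len(retained_pairs) if retained_pairs else None

    rows = []
    for p in sorted(truth.planted_pairs, key=lambda q: (q.lnc_id, q.mrna_id)):
        key = (p.lnc_id, p.mrna_id)
        rows.append({
            "lnc_id": p.lnc_id,
            "mrna_id": p.mrna_id,
            "planted_rho": p.planted_rho,
            "recovered": key in groups_by_pair,
            "groups": ",".join(sorted(groups_by_pair.get(key, ()))),
        })
    table = pd.DataFrame(
        rows, columns=["lnc_id", "mrna_id", "planted_rho", "recovered", "groups"]
    )
    return RecoveryResult(
        sensitivity=sensitivity,
        precision=precision,
        n_planted=len(planted),
        n_retained=len(retained_pairs),
        n_true_positive=len(tp),
        n_false_positive=len(fp),
        table=table,
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lnc_id\tmrna_id\tplanted_shared\tplanted_rho\tshared_mirnas\n")
        for p in sorted(truth.planted_pairs, key=lambda q: (q.lnc_id, q.mrna_id)):
            fh.write(
                f"{p.lnc_id}\t{p.mrna_id}\t{len(p.shared_mirna_ids)}\t"
                f"{p.planted_rho!r}\t{','.join(sorted(p.shared_mirna_ids))}\n"
            )


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    pairs = tuple(
        PlantedPair(
            lnc_id=row.lnc_id,
            mrna_id=row.mrna_id,
            shared_mirna_ids=frozenset(s for s in row.shared_mirnas.split(",") if s),
            planted_rho=float(row.planted_rho),
        )
        for row in df.itertuples(index=False)
    )
    return SyntheticTruth(planted_pairs=pairs)


def write_simulation(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate one full dataset and write it in pipeline input formats.

    Emits ``lnc_mirna.tsv``, ``mrna_mirna.tsv``, ``expression.tsv``,
    ``labels.tsv`` and ``truth.tsv`` under ``outdir`` and returns their
    paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lnc_map, mrna_map, truth = simulate_interactions(config)
    matrix, labels = simulate_expression(config, truth)
    paths = {
        "lnc_mirna": outdir / "lnc_mirna.tsv",
        "mrna_mirna": outdir / "mrna_mirna.tsv",
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_target_map(lnc_map, paths["lnc_mirna"])
    write_target_map(mrna_map, paths["mrna_mirna"])
    write_expression(matrix, paths["expression"])
    write_group_labels(labels, paths["labels"])
    write_truth(truth, paths["truth"])
    return paths


def powerlaw_degree_graph(
    n_nodes: int,
    exponent: float,
    seed: int,
    d_min: int = 1,
    d_max: int | None = None,
    sequence: str = "expected",
):
    """Configuration-model multigraph with a power-law degree sequence.

    The configuration model is defined by a prescribed degree sequence.
    With ``sequence="expected"`` (default) the sequence is the expected
    histogram of the discrete law P(d) ∝ d^-exponent on [d_min, d_max]
    — count(d) = round(n * P(d)) — so the realised degree distribution
    follows the target law up to integer rounding and the seed controls
    only the random stub matching.  ``sequence="sampled"`` instead draws
    each degree independently from the law; its raw histogram carries a
    long singleton tail, which visibly flattens an unweighted log-log
    least-squares fit (a known bias of histogram-based estimators).
    Used to test power-law exponent recovery.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    if d_max is None:
        d_max = min(n_nodes - 1, 1000)
    support = np.arange(d_min, d_max + 1)
    w = support.astype(float) ** (-exponent)
    w /= w.sum()
    if sequence == "expected":
        counts = np.round(n_nodes * w).astype(int)
        degrees = np.repeat(support, counts)
        if degrees.size == 0:
            raise ValueError("degenerate power-law sequence")
    elif sequence == "sampled":
        degrees = rng.choice(support, size=n_nodes, p=w)
    else:
        raise ValueError(f"unknown sequence mode {sequence!r}")
    degrees = degrees.copy()
    if degrees.sum() % 2 == 1:
        degrees[0] += 1
    return nx.configuration_model(degrees.tolist(), seed=int(seed))
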