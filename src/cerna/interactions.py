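"""Reading, validating and indexing miRNA-target interaction tables.

ceRNA screening starts from two bipartite regulator maps: miRNA->lncRNA
(as distributed by lncBase-style databases) and miRNA->mRNA (as from
miRTarBase-style databases).  This module loads such tables from TSV,
collapses duplicate rows to set membership, and derives the miRNA
universe whose size ``N`` is the background of the hypergeometric
shared-target test.

Tables are treated as unweighted: an interaction either exists or it
does not, and any evidence-type column is ignored (evidence filtering,
e.g. keeping only experimentally supported pairs, belongs upstream of
this package).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

REGULATOR_CLASSES = ("lncRNA", "mRNA")
UNIVERSE_MODES = ("union", "intersection", "explicit")


class InteractionTableError(ValueError):
    """Base class for malformed interaction-table input."""


class MissingColumnsError(InteractionTableError):
    """A required column is absent from the table header."""


class EmptyTableError(InteractionTableError):
    """The table parses to zero interaction rows."""


class MalformedRowError(InteractionTableError):
    """A data row has a blank miRNA or regulator field."""


class UniverseError(ValueError):
    """The miRNA universe is inconsistent with the target maps."""


def normalize_mirna_id(raw: str) -> str:
    """Canonical miRNA id: surrounding whitespace stripped, case-folded.

    No miRBase-name harmonisation is attempted; ids are opaque strings.
    """
    return raw.strip().casefold()


@dataclass(frozen=True)
class TargetMap:
    """miRNA target sets for one regulator class (lncRNA or mRNA).

    ``entries`` maps each regulator id to the (nonempty) set of miRNAs
    targeting it.  For a lncRNA map the set sizes are the ``L`` of the
    hypergeometric test; for an mRNA map they are the ``M``.
    """

    regulator_class: str
    entries: dict[str, frozenset[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.regulator_class not in REGULATOR_CLASSES:
            raise ValueError(
                f"regulator_class must be one of {REGULATOR_CLASSES}, "
                f"got {self.regulator_class!r}"
            )
        for reg, targets in self.entries.items():
            if not reg:
                raise ValueError("blank regulator id in TargetMap")
            if not targets:
                raise ValueError(f"empty target set for regulator {reg!r}")
            if any(not m for m in targets):
                raise ValueError(f"blank miRNA id in target set of {reg!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def mirna_ids(self) -> frozenset[str]:
        """All miRNA ids appearing anywhere in this map."""
        out: set[str] = set()
        for targets in self.entries.values():
            out |= targets
        return frozenset(out)

    def max_target_set_size(self) -> int:
        return max(len(t) for t in self.entries.values())


@dataclass(frozen=True)
class MirnaUniverse:
    """The miRNA background of the hypergeometric test (its ``N``)."""

    size: int
    mode: str
    id_set: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in UNIVERSE_MODES:
            raise ValueError(f"unknown universe mode {self.mode!r}")
        if self.size < 1:
            raise ValueError("universe size must be >= 1")
        if self.id_set is not None and len(self.id_set) != self.size:
            raise ValueError("universe size inconsistent with id_set")


def read_interactions(
    path: str | Path,
    regulator_class: str,
    mirna_col: str = "mirna",
    target_col: str = "target",
    source_label: str | None = None,
) -> TargetMap:
    """Load a miRNA-target table from TSV into a deduplicated TargetMap.

    The file must have a header row naming ``mirna_col`` and
    ``target_col``; any further columns (e.g. an evidence type) are
    ignored.  Duplicate (miRNA, target) rows collapse to a single
    membership.  miRNA ids are normalised (strip + casefold); regulator
    ids are stripped only, so gene symbols keep their case.

    Raises
    ------
    FileNotFoundError, MissingColumnsError, EmptyTableError,
    MalformedRowError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in (mirna_col, target_col) if c not in df.columns]
    if missing:
        raise MissingColumnsError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    if len(df) == 0:
        raise EmptyTableError(f"empty interaction table: {path}")

    entries: dict[str, set[str]] = {}
    n_pairs = 0
    seen: set[tuple[str, str]] = set()
    for i, (mir_raw, reg_raw) in enumerate(
        zip(df[mirna_col].tolist(), df[target_col].tolist())
    ):
        line_no = i + 2  # header is line 1
        mir = normalize_mirna_id(mir_raw)
        reg = reg_raw.strip()
        if not mir:
            raise MalformedRowError(f"{path}: blank miRNA field at line {line_no}")
        if not reg:
            raise MalformedRowError(f"{path}: blank target field at line {line_no}")
        if (mir, reg) not in seen:
            seen.add((mir, reg))
            entries.setdefault(reg, set()).add(mir)
        n_pairs += 1

    n_dup = n_pairs - len(seen)
    tmap = TargetMap(
        regulator_class=regulator_class,
        entries={reg: frozenset(t) for reg, t in entries.items()},
        source_label=source_label if source_label is not None else str(path),
    )
    logger.info(
        "read %s: %d rows, %d duplicates, %d %s regulators, %d distinct miRNAs",
        path, n_pairs, n_dup, len(tmap), regulator_class, len(tmap.mirna_ids()),
    )
    return tmap


def write_target_map(tmap: TargetMap, path: str | Path) -> None:
    """Serialise a TargetMap as a two-column TSV (``mirna``, ``target``).

    Rows are emitted in lexicographic (mirna, target) order so output is
    deterministic and re-reading it with :func:`read_interactions`
    reproduces the map exactly.
    """
    rows = sorted(
        (mir, reg) for reg, targets in tmap.entries.items() for mir in targets
    )
    with open(path, "w") as fh:
        fh.write("mirna\ttarget\n")
        for mir, reg in rows:
            fh.write(f"{mir}\t{reg}\n")


def mirna_universe(
    lnc_map: TargetMap,
    mrna_map: TargetMap,
    mode: str = "union",
    explicit_n: int | None = None,
) -> MirnaUniverse:
    """Derive the hypergeometric background ``N`` from two target maps.

    ``union`` (default) counts every miRNA id appearing in either map —
    the most inclusive reading of "the total number of miRNAs".
    ``intersection`` counts ids present in both maps.  ``explicit``
    passes a user-supplied total through unchanged (for reproducing a
    published analysis whose database-wide totals are known).

    In every mode the resulting size must be at least as large as the
    largest single target set, otherwise the test parameters would be
    inconsistent (``L > N`` or ``M > N``) and :class:`UniverseError` is
    raised.
    """
    if not lnc_map.entries or not mrna_map.entries:
        raise UniverseError("both target maps must be nonempty")
    max_set = max(lnc_map.max_target_set_size(), mrna_map.max_target_set_size())
    if mode == "explicit":
        if explicit_n is None:
            raise UniverseError("explicit universe mode requires explicit_n")
        if explicit_n < max_set:
            raise UniverseError(
                f"explicit_n={explicit_n} smaller than the largest "
                f"target set ({max_set})"
            )
        return MirnaUniverse(size=explicit_n, mode="explicit")
    if mode == "union":
        ids = lnc_map.mirna_ids() | mrna_map.mirna_ids()
    elif mode == "intersection":
        ids = lnc_map.mirna_ids() & mrna_map.mirna_ids()
    else:
        raise UniverseError(f"unknown universe mode {mode!r}")
    if len(ids) < max_set:
        raise UniverseError(
            f"{mode} universe ({len(ids)} miRNAs) smaller than the "
            f"largest target set ({max_set})"
        )
    return MirnaUniverse(size=len(ids), mode=mode, id_set=frozenset(ids))
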