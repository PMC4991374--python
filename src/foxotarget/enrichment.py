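"""Gene-set overlap enrichment.

Loads named gene lists (one identifier per line), computes pairwise overlaps
with optional exclusions, and reports observed k, the random-chance baseline
m*n/N and the hypergeometric upper-tail p-value for each comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .stats import HypergeomParams, expected_overlap, hypergeom_upper_tail

__all__ = [
    "DEFAULT_UNIVERSE_SIZE",
    "GeneSet",
    "OverlapReport",
    "normalize_gene_id",
    "load_gene_list",
    "compute_overlap",
    "enrichment_table",
    "write_enrichment_tsv",
    "read_enrichment_tsv",
]

logger = logging.getLogger(__name__)

#: Conventional approximation for the number of protein-coding genes in the
#: C. elegans genome; the default overlap-test universe.
DEFAULT_UNIVERSE_SIZE = 20000


def normalize_gene_id(raw: str) -> str:
    """Whitespace-trim and case-fold a gene identifier (daf-16 == DAF-16)."""
    return raw.strip().casefold()


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.members):
            raise ValueError(f"gene set {self.name!r} contains an empty identifier")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(normalize_gene_id(g) for g in genes))

    def __len__(self) -> int:
        return len(self.members)


def load_gene_list(path: str | Path, name: Optional[str] = None) -> GeneSet:
    """Read a gene list file: one identifier per line, '#' starts a comment.

    Identifiers are trimmed and case-folded; duplicates (after normalization)
    are dropped with a logged count.  An empty list after filtering is an
    error.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    n_dupes = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene = normalize_gene_id(line)
            if gene in seen:
                n_dupes += 1
            else:
                seen[gene] = None
    if not seen:
        raise ValueError(f"gene list {path} is empty after comment/blank filtering")
    if n_dupes:
        logger.info("dropped %d duplicate identifiers while reading %s", n_dupes, path)
    return GeneSet(name=name or path.stem, members=frozenset(seen))


@dataclass(frozen=True)
class OverlapReport:
    """Full result of one overlap-enrichment comparison.

    m and n are the effective set sizes after exclusions; k the observed
    overlap; expected = m*n/N; p_value the upper-tail hypergeometric
    probability of an overlap at least as large.
    """

    name1: str
    name2: str
    k: int
    m: int
    n: int
    N: int
    expected: float
    p_value: float
    overlap_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.overlap_ids and len(self.overlap_ids) != self.k:
            raise ValueError("k does not match |overlap_ids|")
        if self.k > min(self.m, self.n):
            raise ValueError("overlap exceeds a set size")


def compute_overlap(
    set1: GeneSet,
    set2: GeneSet,
    N: int = DEFAULT_UNIVERSE_SIZE,
    exclude: Optional[GeneSet] = None,
) -> OverlapReport:
    """Overlap of two gene sets against an N-gene universe.

    If ``exclude`` is given its members are removed from BOTH sets before
    sizing — the generalization of excluding genes that one study contributed
    to the other (e.g. reducing a 109-gene list to 95 for a comparison that
    supplied 14 of its members).
    """
    drop = exclude.members if exclude is not None else frozenset()
    s1 = set1.members - drop
    s2 = set2.members - drop
    if len(s1) > N or len(s2) > N:
        raise ValueError(
            f"universe N={N} smaller than a set ({len(s1)}, {len(s2)} after exclusions)"
        )
    shared = frozenset(s1 & s2)
    params = HypergeomParams(N=N, m=len(s1), n=len(s2), k=len(shared))
    return OverlapReport(
        name1=set1.name,
        name2=set2.name,
        k=len(shared),
        m=len(s1),
        n=len(s2),
        N=N,
        expected=expected_overlap(len(s1), len(s2), N),
        p_value=hypergeom_upper_tail(params),
        overlap_ids=shared,
    )


_TABLE_COLUMNS = ["name1", "name2", "k", "m", "n", "N", "expected", "p_value"]


def _round_display(x: float) -> float:
    """3 significant figures capped at 2 decimal places (2.8013 -> 2.8,
    18.5082 -> 18.5, 0.4687 -> 0.47) — the conventional precision for
    random-chance baselines in enrichment reports."""
    if x == 0:
        return 0.0
    from math import floor, log10

    decimals = -int(floor(log10(abs(x)))) + 2
    return round(x, min(2, decimals))


def enrichment_table(reports: list[OverlapReport]) -> pd.DataFrame:
    """One row per comparison; adds a display column with a rounded expected
    overlap while keeping full precision in ``expected``."""
    if not reports:
        raise ValueError("need at least one report")
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in _TABLE_COLUMNS} for r in reports],
        columns=_TABLE_COLUMNS,
    )
    df["expected_display"] = [_round_display(r.expected) for r in reports]
    return df


def write_enrichment_tsv(reports: list[OverlapReport], path: str | Path) -> None:
    enrichment_table(reports).to_csv(path, sep="\t", index=False)


def read_enrichment_tsv(path: str | Path) -> list[OverlapReport]:
    df = pd.read_csv(path, sep="\t")
    return [
        OverlapReport(
            name1=row.name1,
            name2=row.name2,
            k=int(row.k),
            m=int(row.m),
            n=int(row.n),
            N=int(row.N),
            expected=float(row.expected),
            p_value=float(row.p_value),
        )
        for row in df.itertuples()
    ]
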