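"""IUPAC consensus-motif scanning of promoter windows.

Scans fixed-width consensus words written in the 15-letter IUPAC DNA alphabet
across promoter sequences (nominally the 1 kb immediately upstream of the
transcription start site, supplied 5'->3') and classifies each gene by which
transcription-factor binding elements its promoter contains.

The built-in motifs are the FOXO/DAF-16 binding element (DBE, GTAAACA with
reverse orientation TGTTTAC, degenerate form RTAAAYA) and the PQM-1-recognized
DAF-16-associated element (DAE, TGATAAG / CTTATCA).  The scan itself is
forward-strand only: reverse-orientation detection is achieved by listing both
orientation words explicitly, so a reverse-complement pass is redundant for
the default motif sets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "DBE_MOTIFS",
    "DAE_MOTIFS",
    "DBE_LOOSE_MOTIFS",
    "IupacMotif",
    "Promoter",
    "MotifHit",
    "MotifClassification",
    "iupac_char_match",
    "parse_promoter_fasta",
    "scan",
    "classify",
    "upstream_distance",
    "format_both_report",
]

logger = logging.getLogger(__name__)

#: Degeneracy sets of the IUPAC DNA alphabet.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SEQUENCE_ALPHABET = frozenset("ACGTN")

# 2-bit-per-base encoding: A=1 C=2 G=4 T=8; sequence 'N' encodes to 0 so it
# matches no IUPAC code (conservative-unknown rule for masked regions).
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 0}
_ENCODE = np.zeros(256, dtype=np.uint8)
for _b, _v in _BASE_BITS.items():
    _ENCODE[ord(_b)] = _v


@dataclass(frozen=True)
class IupacMotif:
    """A named consensus word over the IUPAC DNA alphabet."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        consensus = self.consensus.upper()
        object.__setattr__(self, "consensus", consensus)
        if not consensus:
            raise ValueError(f"motif {self.name!r} has an empty consensus")
        bad = set(consensus) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"motif {self.name!r} has non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.consensus)


DBE_MOTIFS = [IupacMotif("DBE", "GTAAACA"), IupacMotif("DBE", "TGTTTAC")]
DAE_MOTIFS = [IupacMotif("DAE", "TGATAAG"), IupacMotif("DAE", "CTTATCA")]
# degenerate DBE; both orientation words listed, like the strict set
DBE_LOOSE_MOTIFS = [IupacMotif("DBE_loose", "RTAAAYA"), IupacMotif("DBE_loose", "TRTTTAY")]


@dataclass(frozen=True)
class Promoter:
    """A promoter window: gene identifier plus its sequence (5'->3', ending at
    the TSS)."""

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"promoter for {self.gene!r} is empty")
        bad = set(seq) - _SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"promoter for {self.gene!r} has invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """A positioned motif match.

    ``start`` is the 1-based offset of the match's first base from the 5' end
    of the supplied promoter sequence; ``word`` is the concrete substring that
    matched.
    """

    gene: str
    motif_name: str
    word: str
    start: int


def iupac_char_match(base: str, code: str) -> bool:
    """True iff sequence character ``base`` satisfies IUPAC ``code``.

    A sequence 'N' matches nothing, including consensus 'N' — unknown bases
    never produce hits.
    """
    base = base.upper()
    code = code.upper()
    if base not in _SEQUENCE_ALPHABET:
        raise ValueError(f"invalid sequence character {base!r}")
    if code not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC code {code!r}")
    if base == "N":
        return False
    return base in IUPAC_SETS[code]


def parse_promoter_fasta(
    path: str | Path, expected_length: int = 1000
) -> list[Promoter]:
    """Read promoters from FASTA.

    The gene identifier is the record id (first whitespace-delimited token of
    the header).  Sequences are upper-cased and 'U' is mapped to 'T'.  Records
    whose length differs from ``expected_length`` are kept, with a logged
    warning; duplicated gene ids are an error.
    """
    path = Path(path)
    promoters: list[Promoter] = []
    seen: set[str] = set()
    for idx, record in enumerate(SeqIO.parse(str(path), "fasta")):
        if record.id in seen:
            raise ValueError(f"duplicate gene id {record.id!r} in {path}")
        seen.add(record.id)
        try:
            promoter = Promoter(gene=record.id, sequence=str(record.seq))
        except ValueError as exc:
            raise ValueError(f"record {idx} ({record.id!r}) in {path}: {exc}") from exc
        if len(promoter) != expected_length:
            logger.warning(
                "promoter %s has length %d (expected %d)",
                record.id,
                len(promoter),
                expected_length,
            )
        promoters.append(promoter)
    if not promoters:
        raise ValueError(f"no FASTA records found in {path}")
    return promoters


def _match_positions(codes: np.ndarray, motif: IupacMotif) -> np.ndarray:
    """0-based start positions where ``motif`` matches the encoded sequence."""
    w = len(motif)
    L = codes.size
    if w > L:
        return np.empty(0, dtype=np.intp)
    masks = np.array(
        [sum(_BASE_BITS[b] for b in IUPAC_SETS[c]) for c in motif.consensus],
        dtype=np.uint8,
    )
    ok = np.ones(L - w + 1, dtype=bool)
    for j in range(w):
        ok &= (codes[j : L - w + 1 + j] & masks[j]) != 0
    return np.flatnonzero(ok)


def scan(promoter: Promoter, motifs: Sequence[IupacMotif]) -> list[MotifHit]:
    """All matches of every motif in one promoter.

    Every window position is tested for every motif; overlapping and
    self-overlapping matches are all reported.  Hits are sorted by
    (start, motif_name, word).  A motif longer than the sequence yields no
    hits (logged, not an error).
    """
    codes = _ENCODE[np.frombuffer(promoter.sequence.encode("ascii"), dtype=np.uint8)]
    hits: list[MotifHit] = []
    for motif in motifs:
        if len(motif) > len(promoter):
            logger.warning(
                "motif %s (%d nt) longer than promoter %s (%d nt); skipped",
                motif.name,
                len(motif),
                promoter.gene,
                len(promoter),
            )
            continue
        for pos in _match_positions(codes, motif):
            start = int(pos) + 1  # 1-based from the 5' end
            hits.append(
                MotifHit(
                    gene=promoter.gene,
                    motif_name=motif.name,
                    word=promoter.sequence[pos : pos + len(motif)],
                    start=start,
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif_name, h.word))
    return hits


def upstream_distance(start: int, sequence_length: int, motif_length: int) -> int:
    """Convert a 1-based 5'-offset ``start`` into the distance of the match's
    3'-most base upstream of the TSS (the alternative coordinate convention
    for a window that ends at the TSS)."""
    return sequence_length - start - motif_length + 2


CATEGORIES = ("DBE_only", "DAE_only", "both", "neither")


@dataclass(frozen=True)
class MotifClassification:
    """Per-gene DBE/DAE category plus aggregate counts.

    Categories partition the gene set: a gene is DBE-positive iff any DBE
    motif hits its promoter, DAE-positive likewise; counts sum to the number
    of genes.
    """

    per_gene: dict[str, str]
    counts: dict[str, int]


def classify(
    promoters: Sequence[Promoter],
    dbe_motifs: Sequence[IupacMotif] = tuple(DBE_MOTIFS),
    dae_motifs: Sequence[IupacMotif] = tuple(DAE_MOTIFS),
) -> MotifClassification:
    """Classify each gene as DBE_only / DAE_only / both / neither."""
    if not promoters:
        raise ValueError("need at least one promoter")
    per_gene: dict[str, str] = {}
    for promoter in promoters:
        has_dbe = bool(scan(promoter, dbe_motifs))
        has_dae = bool(scan(promoter, dae_motifs))
        if has_dbe and has_dae:
            category = "both"
        elif has_dbe:
            category = "DBE_only"
        elif has_dae:
            category = "DAE_only"
        else:
            category = "neither"
        per_gene[promoter.gene] = category
    counts = Counter(per_gene.values())
    return MotifClassification(
        per_gene=per_gene, counts={c: counts.get(c, 0) for c in CATEGORIES}
    )


def format_both_report(
    promoters: Sequence[Promoter],
    dbe_motifs: Sequence[IupacMotif] = tuple(DBE_MOTIFS),
    dae_motifs: Sequence[IupacMotif] = tuple(DAE_MOTIFS),
) -> list[str]:
    """Lines ``gene\\t[word: pos]...\\t[word: pos]...`` for genes whose
    promoter contains both element classes — the co-regulation table."""
    lines = []
    for promoter in promoters:
        dbe_hits = scan(promoter, dbe_motifs)
        dae_hits = scan(promoter, dae_motifs)
        if dbe_hits and dae_hits:
            fmt = lambda hs: "".join(f"[{h.word}: {h.start}]" for h in hs)
            lines.append(f"{promoter.gene}\t{fmt(dbe_hits)}\t{fmt(dae_hits)}")
    return lines


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tmotif\tword\tstart\n")
        for h in hits:
            fh.write(f"{h.gene}\t{h.motif_name}\t{h.word}\t{h.start}\n")


def write_classification_tsv(
    classification: MotifClassification, path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tcategory\n")
        for gene, category in classification.per_gene.items():
            fh.write(f"{gene}\t{category}\n")
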