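"""Seeded generators for every input the pipeline consumes.

Three generators emulate the study's real inputs with planted, recorded
ground truth: gene-set pairs with an exact planted overlap, promoter FASTA
files with motif words spiked at known offsets on a motif-free background,
and random interaction networks with a planted high-degree, mutually
interacting target subset.  Each generator writes the exact file formats the
readers consume plus a ground-truth JSON sidecar, and is byte-deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "OverlapGroundTruth",
    "PromoterSpike",
    "PromoterGroundTruth",
    "NetworkGroundTruth",
    "gen_overlap_pair",
    "gen_promoters",
    "gen_planted_hub_network",
]

_BASES = np.array(list("ACGT"))


def _write_ground_truth(truth, path: Path) -> None:
    path.write_text(json.dumps(asdict(truth), indent=1, sort_keys=True) + "\n")


@dataclass(frozen=True)
class OverlapGroundTruth:
    """Planted structure of a gene-set overlap pair."""

    N: int
    m: int
    n: int
    k: int
    seed: int
    overlap_ids: list[str]
    set1_ids: list[str]
    set2_ids: list[str]


def gen_overlap_pair(
    N: int,
    m: int,
    n: int,
    k: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, Path, Path, OverlapGroundTruth]:
    """Two gene lists with exactly ``k`` shared identifiers.

    Synthesizes an ``N``-identifier universe, draws set 1 of size ``m`` and
    set 2 of size ``n`` with |intersection| exactly ``k``, and writes
    universe/set1/set2 gene-list files plus a ground-truth sidecar.
    Infeasible requests (k > min(m, n) or m + n - k > N) are an error.
    """
    if k > min(m, n):
        raise ValueError(f"planted overlap k={k} exceeds min(m, n)={min(m, n)}")
    if m + n - k > N:
        raise ValueError(
            f"union m + n - k = {m + n - k} exceeds universe size N={N}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(max(N - 1, 1)))
    universe = [f"gene-{i:0{width}d}" for i in range(N)]
    order = rng.permutation(N)
    shared = [universe[i] for i in order[:k]]
    only1 = [universe[i] for i in order[k : m]]
    only2 = [universe[i] for i in order[m : m + n - k]]
    set1 = sorted(shared + only1)
    set2 = sorted(shared + only2)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = (out_dir / "universe.txt", out_dir / "set1.txt", out_dir / "set2.txt")
    for path, genes in zip(paths, (universe, set1, set2)):
        path.write_text("".join(f"{g}\n" for g in genes))
    truth = OverlapGroundTruth(
        N=N, m=m, n=n, k=k, seed=seed,
        overlap_ids=sorted(shared), set1_ids=set1, set2_ids=set2,
    )
    _write_ground_truth(truth, out_dir / "ground_truth.json")
    return (*paths, truth)


@dataclass(frozen=True)
class PromoterSpike:
    """One planted motif word: which gene (by record index), what concrete
    word, and the 1-based offset of its first base from the 5' end."""

    gene_index: int
    word: str
    offset: int
    motif_name: str = ""


@dataclass(frozen=True)
class PromoterGroundTruth:
    count: int
    length: int
    gc_fraction: float
    seed: int
    genes: list[str]
    spikes: list[PromoterSpike] = field(default_factory=list)


def _find_word(seq: str, word: str) -> list[int]:
    """1-based start positions of exact occurrences of ``word`` (overlaps
    included)."""
    hits, start = [], 0
    while True:
        pos = seq.find(word, start)
        if pos < 0:
            return hits
        hits.append(pos + 1)
        start = pos + 1


def gen_promoters(
    count: int,
    length: int = 1000,
    gc_fraction: float = 0.5,
    spikes: Sequence[PromoterSpike] = (),
    seed: int = 0,
    out_path: str | Path = "promoters.fasta",
    max_redraws: int = 200,
) -> tuple[Path, PromoterGroundTruth]:
    """Promoter FASTA with motif words planted at known offsets.

    Background sequence is i.i.d. nucleotides at the requested GC fraction.
    Every sequence is redrawn until it contains no accidental occurrence of
    any spiked word anywhere in the dataset, so planted counts are exact by
    construction; spiked words within one gene must not overlap each other.
    Exceeding ``max_redraws`` raises, advising longer sequences or fewer
    constraints.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    by_gene: dict[int, list[PromoterSpike]] = {}
    for spike in spikes:
        word = spike.word.upper()
        if not set(word) <= set("ACGT"):
            raise ValueError(f"spiked word {word!r} must be concrete DNA (ACGT)")
        if not 0 <= spike.gene_index < count:
            raise ValueError(f"spike gene_index {spike.gene_index} out of range")
        if not 1 <= spike.offset <= length - len(word) + 1:
            raise ValueError(
                f"spike at offset {spike.offset} does not fit in a {length} nt sequence"
            )
        by_gene.setdefault(spike.gene_index, []).append(spike)
    for gene_index, gene_spikes in by_gene.items():
        spans = sorted((s.offset, s.offset + len(s.word) - 1) for s in gene_spikes)
        for (a1, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError(
                    f"spiked words overlap in record {gene_index} (positions {a1}-{b1} and {a2}-...)"
                )
    # exactness must hold for both orientation words of every spiked motif:
    # the scanners search the reverse-orientation word explicitly, so the
    # background must be free of accidental reverse-complement hits too
    comp = str.maketrans("ACGT", "TGCA")
    spiked_words = {s.word.upper() for s in spikes}
    forbidden = sorted(
        spiked_words | {w.translate(comp)[::-1] for w in spiked_words}
    )

    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    width = len(str(max(count - 1, 1)))
    genes = [f"synthgene-{i:0{width}d}" for i in range(count)]
    records: list[str] = []
    for i in range(count):
        gene_spikes = by_gene.get(i, [])
        expected = {}
        for s in gene_spikes:
            expected.setdefault(s.word.upper(), []).append(s.offset)
        for attempt in range(max_redraws + 1):
            seq = "".join(rng.choice(_BASES, size=length, p=p))
            chars = list(seq)
            for s in gene_spikes:
                word = s.word.upper()
                chars[s.offset - 1 : s.offset - 1 + len(word)] = word
            seq = "".join(chars)
            ok = all(
                _find_word(seq, word) == sorted(expected.get(word, []))
                for word in forbidden
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not draw a background for record {i} free of accidental "
                f"spiked-word hits after {max_redraws} redraws; use longer "
                "sequences or fewer spike constraints"
            )
        records.append(seq)

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with out_path.open("w", encoding="utf-8") as fh:
        for gene, seq in zip(genes, records):
            fh.write(f">{gene}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")
    truth = PromoterGroundTruth(
        count=count, length=length, gc_fraction=gc_fraction, seed=seed,
        genes=genes, spikes=list(spikes),
    )
    _write_ground_truth(truth, out_path.with_suffix(".ground_truth.json"))
    return out_path, truth


@dataclass(frozen=True)
class NetworkGroundTruth:
    n_nodes: int
    background_mean_degree: float
    target_count: int
    degree_multiplier: float
    within_target_bias: float
    seed: int
    targets: list[str]
    n_edges: int


def gen_planted_hub_network(
    n_nodes: int,
    background_mean_degree: float,
    target_count: int,
    degree_multiplier: float,
    within_target_bias: float,
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, Path, NetworkGroundTruth]:
    """Random graph with a planted high-degree, mutually interacting subset.

    Chung-Lu-style expected-degree sampling: every node gets weight equal to
    its expected degree (``background_mean_degree``, multiplied by
    ``degree_multiplier`` for target nodes) and each pair {i, j} is an edge
    independently with probability w_i * w_j / sum(w); for target-target
    pairs the connection odds are further scaled by ``within_target_bias``.
    Self-loops and duplicates cannot arise (each unordered pair is sampled
    once).  Writes an edge-list TSV, a target gene list and a ground-truth
    sidecar.
    """
    if not 2 <= target_count < n_nodes:
        raise ValueError("need n_nodes > target_count >= 2")
    w_target = background_mean_degree * degree_multiplier
    if background_mean_degree <= 0 or w_target >= n_nodes - 1:
        raise ValueError(
            f"expected degrees infeasible: background {background_mean_degree}, "
            f"targets {w_target}, n_nodes {n_nodes}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes - 1))
    names = np.array([f"node-{i:0{width}d}" for i in range(n_nodes)])
    is_target = np.zeros(n_nodes, dtype=bool)
    is_target[rng.choice(n_nodes, size=target_count, replace=False)] = True

    w = np.where(is_target, w_target, background_mean_degree).astype(float)
    iu, ju = np.triu_indices(n_nodes, k=1)
    prob = np.minimum(w[iu] * w[ju] / w.sum(), 1.0)
    both_target = is_target[iu] & is_target[ju]
    if within_target_bias != 1.0:
        # scale the odds p/(1-p) by the bias, then map back to a probability
        p = prob[both_target]
        prob[both_target] = within_target_bias * p / (1.0 + (within_target_bias - 1.0) * p)
    edge_mask = rng.random(prob.size) < prob

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / "edges.tsv"
    with edges_path.open("w", encoding="utf-8") as fh:
        fh.write("# planted-hub synthetic interaction network\n")
        for a, b in zip(names[iu[edge_mask]], names[ju[edge_mask]]):
            fh.write(f"{a}\t{b}\n")
    targets_path = out_dir / "targets.txt"
    target_names = sorted(names[is_target])
    targets_path.write_text("".join(f"{t}\n" for t in target_names))
    truth = NetworkGroundTruth(
        n_nodes=n_nodes,
        background_mean_degree=background_mean_degree,
        target_count=target_count,
        degree_multiplier=degree_multiplier,
        within_target_bias=within_target_bias,
        seed=seed,
        targets=target_names,
        n_edges=int(edge_mask.sum()),
    )
    _write_ground_truth(truth, out_dir / "ground_truth.json")
    return edges_path, targets_path, truth
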