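"""Promoter motif scanning: which genes carry DBE and/or DAE elements?

Builds ten synthetic 1 kb promoters with binding-site words planted at known
offsets — the DAF-16 binding element (DBE, GTAAACA/TGTTTAC) and the
PQM-1-recognized DAF-16 associated element (DAE, TGATAAG/CTTATCA) — then
scans them and classifies each gene by which elements its promoter contains.
"""

import tempfile
from pathlib import Path

from foxotarget import DAE_MOTIFS, DBE_MOTIFS, classify, parse_promoter_fasta, scan
from foxotarget.simulate import PromoterSpike, gen_promoters

out = Path(tempfile.mkdtemp(prefix="foxotarget-"))
spikes = [
    PromoterSpike(0, "GTAAACA", 108, "DBE"),   # DBE only, like daf-2's promoter
    PromoterSpike(1, "TGTTTAC", 925, "DBE"),   # reverse-orientation DBE
    PromoterSpike(2, "TGATAAG", 448, "DAE"),   # DAE only
    PromoterSpike(3, "GTAAACA", 44, "DBE"),    # both elements
    PromoterSpike(3, "CTTATCA", 417, "DAE"),
]
fasta_path, _ = gen_promoters(
    count=10, length=1000, spikes=spikes, seed=7, out_path=out / "promoters.fasta"
)

promoters = parse_promoter_fasta(fasta_path)
for promoter in promoters[:4]:
    hits = scan(promoter, DBE_MOTIFS + DAE_MOTIFS)
    described = " ".join(f"[{h.word}: {h.start}]" for h in hits) or "no elements"
    print(f"{promoter.gene}: {described}")

result = classify(promoters, DBE_MOTIFS, DAE_MOTIFS)
print()
print("category counts:", result.counts)
print()
print("Each hit is reported as [word: offset] with the offset counted from")
print("the 5' end of the 1 kb window; every planted site is recovered at")
print("its exact position and the motif-free promoters are 'neither'.")
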