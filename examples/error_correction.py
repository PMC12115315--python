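"""Show how family clustering undoes sequencing error.

Simulates reads from a 60-clone pool at a 0.5% per-base substitution rate,
extracts guides by anchored backbone trimming, and collapses the observed
sequence variants into families with the directional count-ratio rule.
The template ledger from the simulator tells us each read's true clone, so
we can measure how often a read ends up in the right family.
"""

from amirscreen import (
    ExtractionConfig,
    SeqParams,
    cluster_families,
    count_raw,
    extract_guide,
    generate_library,
    initial_pool,
)
from amirscreen.sequencing import simulate_reads

library = generate_library(60, 22, seed=11)
pool = initial_pool(library, 6_000)
params = SeqParams(depth=20_000, error_rate=0.005, seed=17)
reads, templates = simulate_reads(pool, library, params)

config = ExtractionConfig(
    backbone5=library.backbone5, backbone3=library.backbone3,
    max_anchor_mm=1, guide_len=library.guide_len,
)
table = count_raw((("r", read, "") for read in reads), config, sample_id="demo")
assignment, families = cluster_families(table, d_max=1)

n_assigned = n_correct = 0
for read, t in zip(reads, templates):
    guide = extract_guide(read, config)
    if guide is None:
        continue
    n_assigned += 1
    if assignment.representative.get(guide) == library.guides[t]:
        n_correct += 1

print(f"reads simulated          : {len(reads)}")
print(f"guides extracted         : {n_assigned} ({100 * n_assigned / len(reads):.2f}%)")
print(f"distinct sequences seen  : {len(table.counts)}")
print(f"families after collapsing: {len(families.counts)} (true clones: {library.n_clones})")
print(f"reads in correct family  : {100 * n_correct / n_assigned:.2f}% of assigned")
print(
    "\nErrors inflate 60 true guides into hundreds of rare variants; the"
    "\ndirectional rule (merge a variant into a neighbor at Hamming <= 1 whose"
    "\ncount is at least 2x-1 its own) re-absorbs nearly all of them, leaving"
    "\nclose to one family per true clone and >99% of assigned reads correctly"
    "\nattributed."
)
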