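"""Simulate and analyze a small pooled screen end to end.

Builds a 100-clone amiRNA library with two clones planted at a 3-fold
per-passage growth advantage, passages it twice-replicated through MOI-0.1
infection bottlenecks for 4 rounds, sequences every sample, collapses reads
into families, and prints the enrichment leaderboard.  The planted clones
should dominate it: a 3-fold odds advantage compounds to 81-fold over four
passages.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from amirscreen import ScreenConfig, run_full_screen

outdir = Path(tempfile.mkdtemp(prefix="amirscreen_")) / "tiny_screen"
config = ScreenConfig(n_clones=100, depth=5_000, n_replicates=2, seed=1)
run_full_screen(config, outdir)

manifest = json.load(open(outdir / "manifest.json"))
library = pd.read_csv(outdir / "library.tsv", sep="\t").set_index("clone_id")
planted = manifest["planted_clones"]
print(f"planted clones (fitness {config.planted_fitness}): {planted}")

report = pd.read_csv(outdir / "enrichment" / "enrichment.tsv", sep="\t")
top = report.head(4)[["family", "f_input", "pooled_f_p4", "recurrence"]]
top.insert(0, "planted", top["family"].isin(library.loc[planted, "guide"].values))
print(top.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nEach row is one amiRNA family: its input frequency (~1% each of 100"
    "\nclones), its pooled frequency across both replicate P4 samples, and in"
    "\nhow many replicates it exceeded the 1% hit threshold.  The two planted"
    "\nclones rise from ~1% to >30% and recur in both replicates."
)
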