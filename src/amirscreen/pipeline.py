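"""End-to-end screen pipeline: simulate -> sequence -> count -> enrich.

Composes the simulator and the analysis stages into a reproducible run that
writes plain-text artifacts (library TSV, trajectories, FASTQs, count
tables, enrichment report) plus a manifest with per-file digests, so that a
rerun under the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enrichment import (
    HitCallConfig,
    call_hits,
    frequency_long_table,
    records_to_frame,
    top_n_table,
)
from .extraction import ExtractionConfig, count_raw, write_qc
from .families import cluster_families, family_table_to_tsv
from .library import (
    DEFAULT_BACKBONE3,
    DEFAULT_BACKBONE5,
    assign_fitness,
    generate_library,
)
from .passage import PassageConfig, run_screen, write_trajectories
from .sequencing import SeqParams, emit_reads

logger = logging.getLogger("amirscreen")

__all__ = ["PipelineError", "ScreenConfig", "make_fixtures", "run_full_screen"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ScreenConfig:
    """Full configuration of a simulated screen plus its analysis.

    Defaults are the study conditions: a 16,000-clone library passaged 4
    times through an MOI-0.1 bottleneck on 5e6 cells in 5 replicates, with
    two planted clones at fitness 3 and 200,000 reads per sample at a 0.5%
    substitution rate.
    """

    # library
    n_clones: int = 16_000
    guide_len: int = 22
    backbone5: str = DEFAULT_BACKBONE5
    backbone3: str = DEFAULT_BACKBONE3
    n_planted: int = 2
    planted_fitness: float = 3.0
    # passaging
    n_cells: int = 5_000_000
    moi: float = 0.1
    n_passages: int = 4
    n_replicates: int = 5
    burst_size: int = 100
    mode: str = "stochastic"
    # sequencing
    depth: int = 200_000
    error_rate: float = 0.005
    # read processing
    max_anchor_mm: int = 1
    d_max: int = 1
    len_tolerance: int = 0
    # hit calling
    threshold: float = 0.01
    pseudocount: float = 0.5
    top_n: int = 10
    # reproducibility
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_planted < 0 or self.n_planted > self.n_clones:
            raise ValueError("n_planted must lie in [0, n_clones]")
        if self.planted_fitness < 0:
            raise ValueError("planted_fitness must be >= 0")
        self.passage_config()  # validates the passaging block up front

    def passage_config(self) -> PassageConfig:
        return PassageConfig(
            n_cells=self.n_cells,
            moi=self.moi,
            n_passages=self.n_passages,
            n_replicates=self.n_replicates,
            burst_size=self.burst_size,
            mode=self.mode,
            seed=self.seed,
        )

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            backbone5=self.backbone5,
            backbone3=self.backbone3,
            max_anchor_mm=self.max_anchor_mm,
            guide_len=self.guide_len,
            len_tolerance=self.len_tolerance,
        )

    def hit_config(self) -> HitCallConfig:
        return HitCallConfig(
            threshold=self.threshold, pseudocount=self.pseudocount, top_n=self.top_n
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.as_dict(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    """Independent sequencing stream per sample, derived from the run seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1000, sample_index))
    )


def plant_clones(library, config: ScreenConfig):
    """Assign ``planted_fitness`` to ``n_planted`` clones chosen reproducibly.

    Returns (library with fitness set, tuple of planted clone_ids).
    """
    if config.n_planted == 0:
        return library, ()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(99,)))
    chosen = rng.choice(library.n_clones, size=config.n_planted, replace=False)
    planted = tuple(library.clone_ids[i] for i in sorted(chosen))
    return (
        assign_fitness(library, {cid: config.planted_fitness for cid in planted}),
        planted,
    )


def run_full_screen(config: ScreenConfig, outdir: str | Path) -> Path:
    """Run the whole pipeline into ``outdir``; returns the output directory.

    Stages: library generation, serial passaging, read emission, counting
    and family clustering, enrichment/hit calling, manifest.  Any stage
    failure aborts with the failing stage named.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fastq").mkdir(exist_ok=True)
    (out / "counts").mkdir(exist_ok=True)
    (out / "enrichment").mkdir(exist_ok=True)
    timings: dict[str, float] = {}
    outputs: list[Path] = []

    def run_stage(name, fn):
        start = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - start
        logger.info("stage %s: done in %.2fs", name, timings[name])
        return result

    def build_library():
        lib = generate_library(
            config.n_clones,
            config.guide_len,
            config.seed,
            backbone5=config.backbone5,
            backbone3=config.backbone3,
        )
        lib, planted = plant_clones(lib, config)
        lib.to_tsv(out / "library.tsv")
        outputs.append(out / "library.tsv")
        return lib, planted

    library, planted = run_stage("library", build_library)

    def passage():
        screen = run_screen(library, config.passage_config())
        write_trajectories(screen, out / "trajectories.tsv")
        outputs.append(out / "trajectories.tsv")
        return screen

    screen = run_stage("passage", passage)

    def sequence():
        params = SeqParams(depth=config.depth, error_rate=config.error_rate)
        samples = {"input": screen[1][0]}
        for rep in sorted(screen):
            samples[f"rep{rep}_P{config.n_passages}"] = screen[rep][-1]
        for i, (name, pool) in enumerate(samples.items()):
            path = out / "fastq" / f"{name}.fastq"
            emit_reads(
                pool,
                library,
                params,
                path,
                read_prefix=name,
                rng=_sample_rng(config.seed, i),
            )
            outputs.append(path)
        return list(samples)

    sample_names = run_stage("sequencing", sequence)

    def count():
        ext = config.extraction_config()
        raw_tables = []
        family_tables = {}
        for name in sample_names:
            raw = count_raw(out / "fastq" / f"{name}.fastq", ext, sample_id=name)
            raw_tables.append(raw)
            raw.to_tsv(out / "counts" / f"{name}.raw.tsv")
            assignment, fam = cluster_families(raw, config.d_max)
            family_table_to_tsv(
                assignment, fam, out / "counts" / f"{name}.families.tsv"
            )
            outputs.extend(
                [
                    out / "counts" / f"{name}.raw.tsv",
                    out / "counts" / f"{name}.families.tsv",
                ]
            )
            family_tables[name] = fam
        write_qc(raw_tables, out / "counts" / "qc.json")
        outputs.append(out / "counts" / "qc.json")
        return family_tables

    family_tables = run_stage("count", count)

    def enrich():
        input_table = family_tables["input"]
        p4_tables = {
            rep: family_tables[f"rep{rep}_P{config.n_passages}"]
            for rep in sorted(screen)
        }
        records = call_hits(p4_tables, input_table, config.hit_config())
        records_to_frame(records).to_csv(
            out / "enrichment" / "enrichment.tsv", sep="\t", index=False
        )
        top_n_table(records, min(config.top_n, len(records))).to_csv(
            out / "enrichment" / f"top{config.top_n}.tsv", sep="\t"
        )
        frequency_long_table(input_table, p4_tables).to_csv(
            out / "enrichment" / "frequencies_long.tsv", sep="\t", index=False
        )
        outputs.extend(
            [
                out / "enrichment" / "enrichment.tsv",
                out / "enrichment" / f"top{config.top_n}.tsv",
                out / "enrichment" / "frequencies_long.tsv",
            ]
        )
        return records

    run_stage("enrich", enrich)

    def manifest():
        digests = {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in outputs
        }
        payload = {
            "tool": "amirscreen",
            "version": __version__,
            "seed": config.seed,
            "config": config.as_dict(),
            "planted_clones": list(planted),
            "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
            "digests": digests,
        }
        with open(out / "manifest.json", "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")

    run_stage("manifest", manifest)
    return out


TINY_OVERRIDES = dict(n_clones=100, depth=5_000, n_replicates=2)


def make_fixtures(scale: str, outdir: str | Path, seed: int = 1) -> Path:
    """Generate a seeded fixture run: ``tiny`` (CI-fast) or ``default`` (full scale)."""
    if scale == "tiny":
        config = ScreenConfig(seed=seed, **TINY_OVERRIDES)
    elif scale == "default":
        config = ScreenConfig(seed=seed)
    else:
        raise ValueError("scale must be 'tiny' or 'default'")
    return run_full_screen(config, outdir)
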