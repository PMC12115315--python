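"""Pooled amiRNA virus libraries: unique guide sequences plus fitness annotations.

The screening unit is a short guide (default 22 nt) embedded in a constant
miR-30-style cassette carried by a replicating oncolytic virus.  A library is
an ordered collection of clones, each identified by a unique guide sequence,
together with a per-clone relative fitness ``w`` used by the serial-passage
simulator: ``w = 1`` is neutral, ``w > 1`` confers a per-passage growth
advantage, and ``w = 0`` is lethal (no progeny).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

# miR-30-style constant flanks surrounding the variable hairpin region.  Any
# non-empty pair works; these defaults give a 58-nt amplicon for 22-nt guides.
DEFAULT_BACKBONE5 = "TGCTGTTGACAGTGAGCGA"
DEFAULT_BACKBONE3 = "TAGTGAAGCCACAGATGTA"


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} must be a non-empty DNA string")
    if set(seq) - set(ALPHABET):
        raise ValueError(f"{what} contains characters outside ACGT: {seq!r}")


@dataclass(frozen=True)
class GuideSequence:
    """A single clone: an opaque identifier and its variable guide sequence."""

    clone_id: str
    guide: str

    def __post_init__(self) -> None:
        if not self.clone_id:
            raise ValueError("clone_id must be non-empty")
        _check_dna(self.guide, "guide")


@dataclass(frozen=True)
class AmiRNALibrary:
    """An ordered clone set under selection.

    Parameters
    ----------
    clones
        Ordered collection of :class:`GuideSequence`; guides must be pairwise
        distinct and of equal length.
    backbone5, backbone3
        Constant cassette flanks placed 5' and 3' of the guide in every
        sequencing amplicon.
    fitness
        Map clone_id -> relative per-passage fitness ``w`` (dimensionless,
        >= 0, 1 = neutral).  Must cover every clone.
    """

    clones: tuple[GuideSequence, ...]
    backbone5: str = DEFAULT_BACKBONE5
    backbone3: str = DEFAULT_BACKBONE3
    fitness: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "clones", tuple(self.clones))
        if not self.clones:
            raise ValueError("library must contain at least one clone")
        _check_dna(self.backbone5, "backbone5")
        _check_dna(self.backbone3, "backbone3")
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("clone_ids must be unique within a library")
        guides = [c.guide for c in self.clones]
        if len(set(guides)) != len(guides):
            raise ValueError("guides must be pairwise distinct")
        if len({len(g) for g in guides}) != 1:
            raise ValueError("all guides must have equal length")
        if self.fitness is None:
            object.__setattr__(self, "fitness", {i: 1.0 for i in ids})
        else:
            object.__setattr__(self, "fitness", dict(self.fitness))
        missing = set(ids) - set(self.fitness)
        if missing:
            raise ValueError(f"fitness undefined for {len(missing)} clones")
        for cid, w in self.fitness.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"fitness for {cid!r} must be finite and >= 0, got {w}")

    # -- derived views -------------------------------------------------

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def guide_len(self) -> int:
        return len(self.clones[0].guide)

    @property
    def clone_ids(self) -> tuple[str, ...]:
        return tuple(c.clone_id for c in self.clones)

    @property
    def guides(self) -> tuple[str, ...]:
        return tuple(c.guide for c in self.clones)

    def fitness_array(self) -> np.ndarray:
        """Fitness values in clone order, as a float array."""
        return np.array([self.fitness[c.clone_id] for c in self.clones], dtype=float)

    # -- I/O -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": self.clone_ids,
                "guide": self.guides,
                "fitness": [self.fitness[i] for i in self.clone_ids],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        backbone5: str = DEFAULT_BACKBONE5,
        backbone3: str = DEFAULT_BACKBONE3,
    ) -> "AmiRNALibrary":
        df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "guide": str})
        clones = tuple(GuideSequence(r.clone_id, r.guide) for r in df.itertuples())
        fitness = dict(zip(df["clone_id"], df["fitness"].astype(float)))
        return cls(clones, backbone5, backbone3, fitness)


def generate_library(
    n_clones: int,
    guide_len: int = 22,
    seed: int = 0,
    *,
    backbone5: str = DEFAULT_BACKBONE5,
    backbone3: str = DEFAULT_BACKBONE3,
) -> AmiRNALibrary:
    """Generate a library of ``n_clones`` distinct random guides, all neutral.

    The same seed always yields the identical library.  Raises ``ValueError``
    when uniqueness is impossible (``4**guide_len < n_clones``).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if guide_len < 1:
        raise ValueError("guide_len must be >= 1 nt")
    space = 4**guide_len
    if space < n_clones:
        raise ValueError(
            f"cannot draw {n_clones} distinct guides of length {guide_len} "
            f"(only {space} exist)"
        )
    rng = np.random.default_rng(seed)
    if space <= max(4 * n_clones, 1 << 16):
        # Dense regime: enumerate the whole sequence space and permute, which
        # is exact even when n_clones == 4**guide_len.
        universe = ["".join(p) for p in itertools.product(ALPHABET, repeat=guide_len)]
        order = rng.permutation(space)[:n_clones]
        guides = [universe[i] for i in order]
    else:
        # Sparse regime: rejection sampling; collisions are rare.
        seen: set[str] = set()
        guides = []
        while len(guides) < n_clones:
            batch = max(n_clones - len(guides), 1024)
            codes = rng.integers(0, 4, size=(batch, guide_len), dtype=np.uint8)
            raw = _BASE_CODES[codes].tobytes()
            for i in range(batch):
                s = raw[i * guide_len : (i + 1) * guide_len].decode("ascii")
                if s not in seen:
                    seen.add(s)
                    guides.append(s)
                    if len(guides) == n_clones:
                        break
    width = max(5, len(str(n_clones)))
    clones = tuple(
        GuideSequence(f"amiR-{i + 1:0{width}d}", g) for i, g in enumerate(guides)
    )
    return AmiRNALibrary(clones, backbone5, backbone3)


def assign_fitness(
    library: AmiRNALibrary, effects: Mapping[str, float]
) -> AmiRNALibrary:
    """Return a copy of ``library`` with fitness overridden for listed clones.

    Clones not named in ``effects`` are reset to neutral (w = 1).  Unknown
    clone ids raise ``KeyError``; negative fitness raises ``ValueError``.
    """
    known = set(library.clone_ids)
    unknown = set(effects) - known
    if unknown:
        raise KeyError(f"unknown clone_ids in effects: {sorted(unknown)[:5]}")
    for cid, w in effects.items():
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"fitness for {cid!r} must be finite and >= 0, got {w}")
    fitness = {cid: 1.0 for cid in library.clone_ids}
    fitness.update({cid: float(w) for cid, w in effects.items()})
    return dataclasses.replace(library, fitness=fitness)


def amplicon(library: AmiRNALibrary, guide: str) -> str:
    """The full sequenced amplicon for a guide: 5' flank + guide + 3' flank."""
    return library.backbone5 + guide + library.backbone3
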