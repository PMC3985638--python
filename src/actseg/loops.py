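"""Random loop model: permanent intra-chromosomal loops with stiffened springs.

Without loops, 1 Mb bead-spring chromosomes behave as (self-avoiding) random
walks and intermingle freely; experimentally, intra-chromosomal distances
saturate, indicating compact chromosomes.  The random loop model restores
compactness by connecting randomly chosen monomer pairs on the same chain
with permanent springs ten times stiffer than backbone bonds.

Loop drawing: every monomer independently becomes a loop-initiating anchor
with probability ``p_loop`` and is paired with a distinct partner drawn
uniformly from its own chain, so the expected loop count is ~``N * p_loop``
(minus a small duplicate/degenerate correction).  The three presets are
calibrated so that expected counts on the full 6098-monomer system match the
published realized counts 424, 712 and 1404.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import MonomerTable
from .potentials import ForceField

__all__ = ["LoopSet", "generate_loops", "loop_presets", "FULL_SYSTEM_N"]

#: Diploid monomer count of the full system against which presets are calibrated.
FULL_SYSTEM_N = 6098

#: Published realized loop counts per preset on the full system.
_PRESET_COUNTS = {"low": 424, "mid": 712, "high": 1404}


@dataclass(frozen=True)
class LoopSet:
    """Permanent loops as (i, j, spring constant) with i < j, both on one chain."""

    i: np.ndarray  # int64, global monomer ids
    j: np.ndarray  # int64
    k_spring: np.ndarray  # float64

    def __post_init__(self) -> None:
        if not (len(self.i) == len(self.j) == len(self.k_spring)):
            raise ValueError("LoopSet columns have mismatched lengths")
        if np.any(self.i >= self.j):
            raise ValueError("LoopSet requires i < j for every loop")

    def __len__(self) -> int:
        return len(self.i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"i": self.i, "j": self.j, "k_spring": self.k_spring})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def empty(cls) -> "LoopSet":
        return cls(
            i=np.empty(0, dtype=np.int64),
            j=np.empty(0, dtype=np.int64),
            k_spring=np.empty(0, dtype=np.float64),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LoopSet":
        df = pd.read_csv(path)
        return cls(
            i=df["i"].to_numpy(dtype=np.int64),
            j=df["j"].to_numpy(dtype=np.int64),
            k_spring=df["k_spring"].to_numpy(dtype=np.float64),
        )


def loop_presets() -> dict[str, float]:
    """Looping probabilities calibrated to the published realized counts."""
    return {name: count / FULL_SYSTEM_N for name, count in _PRESET_COUNTS.items()}


def generate_loops(
    table: MonomerTable,
    p_loop: float,
    ff: ForceField,
    seed: int | None = None,
) -> LoopSet:
    """Draw a permanent LoopSet for the given monomer table.

    Each monomer independently initiates a loop with probability ``p_loop``;
    the partner is uniform over the other monomers of the same chain (same
    chromosome AND copy — loops never bridge homologs).  Duplicate pairs are
    dropped; an anchor on a length-1 chain is silently skipped.  Loops are
    drawn once and are permanent.  Deterministic given the seed.
    """
    if not 0.0 <= p_loop <= 1.0:
        raise ValueError(f"p_loop must be in [0, 1], got {p_loop}")
    rng = np.random.default_rng(seed)
    n = len(table)
    anchors = np.nonzero(rng.random(n) < p_loop)[0]

    chain_id = table.chain_id
    slices = table.chain_slices()
    pairs: set[tuple[int, int]] = set()
    for a in anchors:
        sl = slices[chain_id[a]]
        lo, hi = sl.start, sl.stop
        if hi - lo < 2:
            continue  # no valid partner on a length-1 chain
        partner = int(rng.integers(lo, hi - 1))
        if partner >= a:
            partner += 1  # uniform over the chain excluding the anchor itself
        pair = (min(int(a), partner), max(int(a), partner))
        pairs.add(pair)

    if not pairs:
        return LoopSet.empty()
    arr = np.array(sorted(pairs), dtype=np.int64)
    k = np.full(len(arr), ff.loop_k_multiplier * ff.k_bond, dtype=np.float64)
    return LoopSet(i=arr[:, 0], j=arr[:, 1], k_spring=k)
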