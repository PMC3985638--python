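"""Coarse-grained genome model: karyotype, gene-density tracks, monomer table.

The nucleus is modelled as a melt of bead-spring polymers, one chain per
chromosome copy, with each bead (monomer) standing for a 1 Mb chromatin
domain.  The female human karyotype (22 autosomal pairs plus two copies of
the X) discretized at 1 Mb yields 6098 monomers in total.

Activity enters through the gene content of each 1 Mb bin: monomers in the
top fraction of the genome-wide gene-content distribution (default 5%) are
classed *active* and assigned an elevated effective temperature ``T_a``
(default 20 in units of the physiological temperature ``T_eq``), standing in
for the enhanced non-thermal noise produced by ATP-dependent remodeling and
transcription machinery.  All other monomers stay at ``T_eq``.

The original gene counts were extracted from a proprietary gene catalogue
and are not redistributable, so this module ships a synthetic-track
generator (:func:`synthesize_gene_track`) whose per-chromosome means are
constrained to the published densities, plus :func:`default_gene_track`,
the deterministic packaged fixture built from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "GeneDensityTrack",
    "MonomerTable",
    "default_karyotype",
    "load_gene_track",
    "write_gene_track",
    "synthesize_gene_track",
    "default_gene_track",
    "build_monomer_table",
    "assign_activity",
    "chromosome_density_summary",
    "DEFAULT_DENSITY_CONSTRAINTS",
    "T_EQ",
    "DEFAULT_T_A",
    "DEFAULT_ACTIVE_FRACTION",
]

#: Physiological (thermodynamic) temperature in reduced units.  All effective
#: temperatures are expressed as multiples of this.
T_EQ = 1.0

#: Default active effective temperature, in units of T_eq.  The hydrolysis of
#: a single ATP molecule liberates ~20 k_B T, which sets the scale of the
#: non-thermal noise experienced by remodeling-machinery-rich chromatin.
DEFAULT_T_A = 20.0

#: Default fraction of monomers classed as active (top of the gene-content
#: distribution).
DEFAULT_ACTIVE_FRACTION = 0.05

#: Published mean gene densities (genes per Mb) for the chromosome pairs used
#: throughout the analysis: 18/19 are similar in size but differ in density,
#: 12/20 differ in size at comparable density.
DEFAULT_DENSITY_CONSTRAINTS = {
    "chr12": 30.92,
    "chr18": 18.64,
    "chr19": 62.03,
    "chr20": 29.71,
}

#: Default mean density (genes/Mb) for chromosomes without a published
#: constraint in the synthetic fixture.
DEFAULT_UNCONSTRAINED_MEAN = 20.0


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome of a karyotype.

    Parameters
    ----------
    name
        Chromosome label, unique within a karyotype (e.g. ``"chr19"``).
    length_mb
        Integer length in megabases; one monomer per Mb.
    copies
        Copy number; 2 for autosomes and for X in the female karyotype.
    """

    name: str
    length_mb: int
    copies: int = 2

    def __post_init__(self) -> None:
        if self.length_mb < 1:
            raise ValueError(f"{self.name}: length_mb must be >= 1, got {self.length_mb}")
        if self.copies < 1:
            raise ValueError(f"{self.name}: copies must be >= 1, got {self.copies}")


# GRCh37 chromosome lengths rounded to the Mb, with the four published sizes
# (chr12 134, chr18 78, chr19 60, chr20 63) fixed and chr1 absorbing the
# remainder so that the haploid sum is 3049 Mb -> 6098 diploid monomers.
_DEFAULT_LENGTHS_MB = {
    "chr1": 263,
    "chr2": 243,
    "chr3": 198,
    "chr4": 191,
    "chr5": 181,
    "chr6": 171,
    "chr7": 159,
    "chr8": 146,
    "chr9": 141,
    "chr10": 136,
    "chr11": 135,
    "chr12": 134,
    "chr13": 115,
    "chr14": 107,
    "chr15": 103,
    "chr16": 90,
    "chr17": 81,
    "chr18": 78,
    "chr19": 60,
    "chr20": 63,
    "chr21": 48,
    "chr22": 51,
    "chrX": 155,
}


def default_karyotype() -> list[ChromosomeSpec]:
    """The packaged diploid female human karyotype (6098 monomers at 1 Mb)."""
    return [ChromosomeSpec(name, length, 2) for name, length in _DEFAULT_LENGTHS_MB.items()]


def _validate_karyotype(karyotype: list[ChromosomeSpec]) -> None:
    names = [c.name for c in karyotype]
    if len(set(names)) != len(names):
        raise ValueError("karyotype chromosome names must be unique")


class GeneDensityTrack:
    """Per-chromosome gene content at 1 Mb resolution.

    Bins are 0-based, half-open, exactly 1 Mb wide and contiguous from 0
    within each chromosome.  Gene content is a non-negative real (genes per
    Mb-bin); fractional values arise naturally from the mean-constrained
    synthesis used for the packaged fixture.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "gene_content"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene track missing columns: {sorted(missing)}")
        df = df[["chrom", "start", "gene_content"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["gene_content"] = df["gene_content"].astype(np.float64)
        if (df["gene_content"] < 0).any():
            bad = df.loc[df["gene_content"] < 0, "chrom"].iloc[0]
            raise ValueError(f"negative gene content on {bad}")
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = np.sort(grp["start"].to_numpy())
            if len(starts) != len(np.unique(starts)):
                raise ValueError(f"duplicate bin on {chrom}")
            if starts[0] != 0 or not np.array_equal(starts, np.arange(len(starts))):
                raise ValueError(f"non-contiguous bins on {chrom}")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def length_mb(self, chrom: str) -> int:
        n = int((self.df["chrom"] == chrom).sum())
        if n == 0:
            raise KeyError(f"chromosome {chrom!r} not in track")
        return n

    def values(self, chrom: str) -> np.ndarray:
        sel = self.df[self.df["chrom"] == chrom].sort_values("start")
        if sel.empty:
            raise KeyError(f"chromosome {chrom!r} not in track")
        return sel["gene_content"].to_numpy()

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def total_content(self) -> float:
        return float(self.df["gene_content"].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneDensityTrack):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"GeneDensityTrack({len(self.chromosomes)} chromosomes, {self.n_bins} bins)"


def load_gene_track(path: str | Path) -> GeneDensityTrack:
    """Read a BED-like gene-density track.

    Tab-separated columns ``chrom  start(Mb)  end(Mb)  gene_content``; lines
    starting with ``#`` are comments.  Starts must be Mb-aligned integers and
    bins contiguous from 0 within each chromosome.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            chrom, start, end, content = parts[0], parts[1], parts[2], parts[3]
            start_i, end_i = int(start), int(end)
            if end_i != start_i + 1:
                raise ValueError(f"{path}:{lineno}: bins must be exactly 1 Mb wide")
            rows.append((chrom, start_i, float(content)))
    if not rows:
        raise ValueError(f"{path}: empty gene track")
    df = pd.DataFrame(rows, columns=["chrom", "start", "gene_content"])
    return GeneDensityTrack(df)


def write_gene_track(track: GeneDensityTrack, path: str | Path) -> None:
    """Write a track in the BED-like format read by :func:`load_gene_track`."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart_mb\tend_mb\tgene_content\n")
        for chrom, start, content in track.df.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{content!r}\n")


def synthesize_gene_track(
    karyotype: list[ChromosomeSpec],
    density_constraints: dict[str, float] | None = None,
    default_mean: float = DEFAULT_UNCONSTRAINED_MEAN,
    shape_sigma: float = 1.0,
    seed: int | None = None,
) -> GeneDensityTrack:
    """Draw a synthetic gene-density track with exact per-chromosome means.

    Per-bin gene contents are drawn from a lognormal distribution (heavy
    tailed and non-negative, like real 1 Mb gene counts) with log-scale
    standard deviation ``shape_sigma``, then rescaled multiplicatively per
    chromosome so each constrained chromosome's mean genes/Mb equals its
    constraint exactly (to float round-off).  Unconstrained chromosomes are
    rescaled to ``default_mean``.  The same seed reproduces the same track
    bitwise.
    """
    _validate_karyotype(karyotype)
    names = {c.name for c in karyotype}
    constraints = dict(density_constraints or {})
    for chrom, mean in constraints.items():
        if chrom not in names:
            raise KeyError(f"constraint on unknown chromosome {chrom!r}")
        if mean < 0:
            raise ValueError(f"negative mean density for {chrom}: {mean}")
    if default_mean < 0:
        raise ValueError(f"negative default mean density: {default_mean}")

    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    for spec in karyotype:
        raw = rng.lognormal(mean=0.0, sigma=shape_sigma, size=spec.length_mb)
        target = constraints.get(spec.name, default_mean)
        scaled = raw * (target / raw.mean()) if target > 0 else np.zeros_like(raw)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": spec.name,
                    "start": np.arange(spec.length_mb, dtype=np.int64),
                    "gene_content": scaled,
                }
            )
        )
    return GeneDensityTrack(pd.concat(rows, ignore_index=True))


#: Seed of the packaged deterministic fixture track.
DEFAULT_TRACK_SEED = 20140122


def default_gene_track() -> GeneDensityTrack:
    """The packaged fixture track: default karyotype, published densities.

    Deterministic (fixed seed); chromosome means for chr12/18/19/20 equal
    the published values exactly, all other chromosomes use the default
    mean of 20 genes/Mb.
    """
    return synthesize_gene_track(
        default_karyotype(),
        density_constraints=DEFAULT_DENSITY_CONSTRAINTS,
        seed=DEFAULT_TRACK_SEED,
    )


@dataclass
class MonomerTable:
    """Per-monomer registry — the model's single source of truth.

    One row per (chromosome copy, 1 Mb bin).  Homologous copies carry
    identical ``gene_content`` sequences.  ``chain_id`` numbers each
    (chromosome, copy) chain consecutively in table order and is what the
    dynamics and territory analysis treat as "the same chromosome".
    """

    chrom: np.ndarray  # object/str, shape (N,)
    copy: np.ndarray  # int, 0-based copy index
    chain_index: np.ndarray  # int, position along the chain
    gene_content: np.ndarray  # float
    activity_class: np.ndarray  # str: "active" | "inactive"
    T_eff: np.ndarray  # float, units of T_eq
    chain_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.chrom)
        for name in ("copy", "chain_index", "gene_content", "activity_class", "T_eff"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MonomerTable column {name} has wrong length")
        if self.chain_id is None:
            keys = list(zip(self.chrom.tolist(), self.copy.tolist()))
            seen: dict[tuple, int] = {}
            cid = np.empty(n, dtype=np.int64)
            for i, k in enumerate(keys):
                if k not in seen:
                    seen[k] = len(seen)
                cid[i] = seen[k]
            self.chain_id = cid
        if np.any(self.T_eff <= 0):
            raise ValueError("T_eff must be positive")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if len(self) else 0

    @property
    def ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    @property
    def is_active(self) -> np.ndarray:
        return self.activity_class == "active"

    def backbone_bonds(self) -> tuple[np.ndarray, np.ndarray]:
        """Global (i, j) index pairs of consecutive monomers on each chain."""
        same_chain = self.chain_id[:-1] == self.chain_id[1:]
        i = np.nonzero(same_chain)[0]
        return i, i + 1

    def chain_slices(self) -> list[slice]:
        """Contiguous index slice of every chain, in chain_id order."""
        bounds = np.nonzero(np.diff(self.chain_id))[0] + 1
        edges = np.concatenate([[0], bounds, [len(self)]])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "chrom": self.chrom,
                "copy": self.copy,
                "chain_index": self.chain_index,
                "gene_content": self.gene_content,
                "activity_class": self.activity_class,
                "T_eff": self.T_eff,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MonomerTable":
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            copy=df["copy"].to_numpy(dtype=np.int64),
            chain_index=df["chain_index"].to_numpy(dtype=np.int64),
            gene_content=df["gene_content"].to_numpy(dtype=np.float64),
            activity_class=df["activity_class"].to_numpy(dtype=object),
            T_eff=df["T_eff"].to_numpy(dtype=np.float64),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MonomerTable":
        return cls.from_frame(pd.read_csv(path))


def build_monomer_table(
    karyotype: list[ChromosomeSpec], track: GeneDensityTrack
) -> MonomerTable:
    """Lay out one monomer per (copy, Mb bin) of every chromosome.

    Gene content is copied from the track identically onto each homologous
    copy.  Activity fields start unset: every monomer is "inactive" at
    ``T_eff = T_eq`` until :func:`assign_activity` is applied.
    """
    _validate_karyotype(karyotype)
    chroms, copies, chain_idx, content = [], [], [], []
    for spec in karyotype:
        try:
            values = track.values(spec.name)
        except KeyError as exc:
            raise ValueError(f"track does not cover chromosome {spec.name}") from exc
        if len(values) != spec.length_mb:
            raise ValueError(
                f"track/karyotype length mismatch on {spec.name}: "
                f"track {len(values)} Mb vs karyotype {spec.length_mb} Mb"
            )
        for c in range(spec.copies):
            chroms.extend([spec.name] * spec.length_mb)
            copies.extend([c] * spec.length_mb)
            chain_idx.extend(range(spec.length_mb))
            content.extend(values)
    n = len(chroms)
    return MonomerTable(
        chrom=np.array(chroms, dtype=object),
        copy=np.array(copies, dtype=np.int64),
        chain_index=np.array(chain_idx, dtype=np.int64),
        gene_content=np.array(content, dtype=np.float64),
        activity_class=np.array(["inactive"] * n, dtype=object),
        T_eff=np.full(n, T_EQ),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def assign_activity(
    table: MonomerTable,
    mode: str,
    active_fraction: float = DEFAULT_ACTIVE_FRACTION,
    T_a: float = DEFAULT_T_A,
) -> MonomerTable:
    """Assign activity classes and effective temperatures.

    Modes
    -----
    ``"inhomogeneous"``
        The top ``round(active_fraction * N)`` monomers by gene content are
        flagged active at ``T_eff = T_a`` (ties broken by gene content
        descending, then global id ascending); the rest stay at ``T_eq``.
        This is the model's central assumption: gene-dense chromatin hosts
        more ATP-consuming machinery, hence larger athermal noise.
    ``"homogeneous"``
        Every monomer at ``T_a`` — a control in which activity is uniform.
    ``"equilibrium"``
        Every monomer at ``T_eq`` — the passive thermal control.

    Returns a new table; re-applying the same assignment is idempotent.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError(f"active_fraction must be in [0, 1], got {active_fraction}")
    if T_a < T_EQ:
        raise ValueError(f"T_a must be >= T_eq = {T_EQ} (in T_eq units), got {T_a}")

    n = len(table)
    activity = np.array(["inactive"] * n, dtype=object)
    t_eff = np.full(n, T_EQ)
    if mode == "inhomogeneous":
        n_active = _round_half_away(active_fraction * n)
        if n_active > 0:
            order = np.lexsort((table.ids, -table.gene_content))
            active_ids = order[:n_active]
            activity[active_ids] = "active"
            t_eff[active_ids] = T_a
    elif mode == "homogeneous":
        activity[:] = "active"
        t_eff[:] = T_a
    elif mode == "equilibrium":
        pass
    else:
        raise ValueError(
            f"unknown activity mode {mode!r}; "
            "expected 'inhomogeneous', 'homogeneous' or 'equilibrium'"
        )
    return MonomerTable(
        chrom=table.chrom.copy(),
        copy=table.copy.copy(),
        chain_index=table.chain_index.copy(),
        gene_content=table.gene_content.copy(),
        activity_class=activity,
        T_eff=t_eff,
        chain_id=table.chain_id.copy(),
    )


def chromosome_density_summary(table: MonomerTable, chromosome: str) -> float:
    """Mean genes/Mb over all monomers (both copies) of one chromosome."""
    mask = table.chrom == chromosome
    if not mask.any():
        raise KeyError(f"chromosome {chromosome!r} not in table")
    return float(table.gene_content[mask].mean())
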